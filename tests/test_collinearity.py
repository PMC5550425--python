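"""VIF computation and iterative elimination against an OLS oracle."""

import numpy as np
import pandas as pd
import pytest

from blastograde import collinearity as col
from blastograde.errors import DegenerateEliminationError, UnderdeterminedDesignError


def statsmodels_vif(df: pd.DataFrame, name: str) -> float:
    """Independent oracle: 1/(1-R^2) via a statsmodels OLS fit."""
    import statsmodels.api as sm
    others = df.drop(columns=[name])
    fit = sm.OLS(df[name], sm.add_constant(others)).fit()
    return 1.0 / (1.0 - fit.rsquared)


def _table_with_r2(r2: float, n: int = 200, seed: int = 0) -> pd.DataFrame:
    """Two-column table where regressing y on x gives R^2 = r2 exactly."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    e = rng.normal(size=n)
    xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
    e = e - e.mean() - (e - e.mean()) @ xc * xc  # orthogonal to x and constant
    e /= np.linalg.norm(e)
    y = np.sqrt(r2) * xc + np.sqrt(1 - r2) * e
    return pd.DataFrame({"y": y, "x": x})


def test_vif_orthogonal_variable_is_one():
    rng = np.random.default_rng(1)
    design = np.column_stack([np.ones(60), rng.normal(size=(60, 3))])
    q, _ = np.linalg.qr(design)  # columns 1..3 orthogonal to the intercept too
    df = pd.DataFrame(q[:, 1:], columns=["a", "b", "c"])
    assert col.vif(df, "a") == pytest.approx(1.0, abs=1e-9)


def test_vif_at_r2_09_is_ten():
    df = _table_with_r2(0.9)
    assert col.vif(df, "y") == pytest.approx(10.0, abs=1e-8)


def test_duplicated_column_gives_infinite_vif():
    rng = np.random.default_rng(2)
    a = rng.normal(size=50)
    df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=50)})
    assert col.vif(df, "a") == np.inf


def test_vif_matches_statsmodels_oracle():
    rng = np.random.default_rng(3)
    for _ in range(5):
        base = rng.normal(size=(80, 5))
        base[:, 4] = base[:, 0] * 0.8 + base[:, 1] * 0.5 + rng.normal(0, 0.4, 80)
        df = pd.DataFrame(base, columns=list("abcde"))
        for name in df.columns:
            assert col.vif(df, name) == pytest.approx(
                statsmodels_vif(df, name), abs=1e-8)


def test_independent_columns_survive_untouched():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(size=(100, 6)),
                      columns=[f"v{i}" for i in range(6)])
    report = col.eliminate(df)
    assert report.removed == []
    assert report.surviving == list(df.columns)
    assert report.n_iterations == 1  # the terminal all-clear check


def test_planted_collinearity_removes_exactly_one_variable():
    rng = np.random.default_rng(5)
    base = rng.normal(size=(200, 6))
    df = pd.DataFrame(base, columns=[f"x{i}" for i in range(1, 7)])
    df["x3"] = df["x1"] + df["x2"] + rng.normal(0, 0.01, 200)
    report = col.eliminate(df)
    assert len(report.removed) == 1
    assert report.removed[0] in {"x1", "x2", "x3"}
    assert max(report.final_vifs.values()) <= 10.0
    for name, value in report.final_vifs.items():
        assert value == pytest.approx(
            statsmodels_vif(df[report.surviving], name), abs=1e-8)
    # deterministic for fixed input
    again = col.eliminate(df)
    assert again.removed == report.removed
    assert again.final_vifs == report.final_vifs


def test_elimination_records_vifs_per_step():
    rng = np.random.default_rng(6)
    base = rng.normal(size=(150, 5))
    df = pd.DataFrame(base, columns=list("abcde"))
    df["d"] = df["a"] + rng.normal(0, 0.02, 150)
    df["e"] = df["b"] - df["c"] + rng.normal(0, 0.02, 150)
    report = col.eliminate(df)
    assert len(report.iterations) == len(report.removed) >= 1
    for step in report.iterations:
        assert step.all_vifs[step.removed_variable] == step.vif
        assert step.vif == max(step.all_vifs.values())
    assert sorted(report.removed + report.surviving) == sorted(df.columns)


def test_degenerate_designs_rejected():
    rng = np.random.default_rng(7)
    with pytest.raises(UnderdeterminedDesignError):
        col.vif(pd.DataFrame(rng.normal(size=(4, 5)), columns=list("abcde")), "a")
    with pytest.raises(UnderdeterminedDesignError):
        col.vif(pd.DataFrame({"a": rng.normal(size=10)}), "a")
    df = pd.DataFrame({"a": rng.normal(size=30)})
    df["b"] = df["a"] * 2
    with pytest.raises(DegenerateEliminationError):
        col.eliminate(df)


def test_report_json_roundtrip(tmp_path):
    import json
    rng = np.random.default_rng(8)
    df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
    report = col.eliminate(df)
    path = tmp_path / "report.json"
    report.to_json(path)
    payload = json.loads(path.read_text())
    assert payload["surviving"] == report.surviving
    assert payload["threshold"] == 10.0
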