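"""Exception hierarchy for the blastograde pipeline.

``BlastogradeError`` is the base for everything the pipeline can raise on
bad inputs or failed processing; the CLI maps it to exit code 2 (processing
error) while ``ConfigurationError`` maps to exit code 1.
"""


class BlastogradeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(BlastogradeError):
    """Invalid parameters, config files or genome specifications."""


class UnsupportedFormatError(BlastogradeError):
    """Image with a channel layout the pipeline cannot standardize."""


class EmbryoNotFoundError(BlastogradeError):
    """Segmentation found no component plausibly being an embryo."""


class EmbryoTooSmallError(BlastogradeError):
    """Detected embryo radius too small for the reduced-radius mask."""


class EmptyRegionError(BlastogradeError):
    """A mask with no pixels (or no valid pixel pair) was supplied."""


class UnderdeterminedDesignError(BlastogradeError):
    """Fewer observations than variables in a regression design."""


class DegenerateEliminationError(BlastogradeError):
    """Collinearity elimination would leave fewer than two variables."""


class InputSchemaError(BlastogradeError):
    """Feature vector does not match a trained model's variable list."""


class TrainingDivergedError(BlastogradeError):
    """Network training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"training diverged (non-finite mse) at epoch {epoch}")
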