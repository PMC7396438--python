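"""Exception hierarchy shared across the pipeline stages."""


class XlinkDockError(Exception):
    """Base class for all package errors."""


class PDBFormatError(XlinkDockError):
    """A coordinate file could not be parsed; the message names the line."""


class EmptyInputError(XlinkDockError):
    """An input structure or table contained no usable records."""


class SelectionError(XlinkDockError):
    """A chain or residue lookup failed."""


class EmptySelectionError(XlinkDockError):
    """An atom filter removed every atom of a residue."""


class GenerationError(XlinkDockError):
    """The synthetic-system generator could not satisfy its invariants."""


class GridResourceError(XlinkDockError):
    """A requested grid exceeds the configured size cap."""


class GridCompatibilityError(XlinkDockError):
    """Two grids with different spacings were combined."""


class ConfigError(XlinkDockError):
    """A user-supplied configuration is inconsistent or incomplete."""


class AnchorError(XlinkDockError):
    """A cross-link anchor atom could not be resolved on a residue."""


class ParameterizationError(XlinkDockError):
    """An element or residue type is missing from an energy/score table."""


class MeasurementError(XlinkDockError):
    """A band measurement is unusable (e.g. zero internal control)."""


class InputError(XlinkDockError):
    """Generic invalid input to a desk-calculation operation."""


class StageError(XlinkDockError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code
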