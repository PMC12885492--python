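"""Exception hierarchy.

Every contract violation in the package raises a subclass of
:class:`HemotransError`, so callers (and the CLI) can catch one type.
"""


class HemotransError(Exception):
    """Base class for all hemotrans errors."""


class InvalidRecordError(HemotransError):
    """A raw intensity record violates its invariants."""


class IncompleteWindowError(HemotransError):
    """A sampling window is missing one of the two wavelengths."""


class MissingSensorError(HemotransError):
    """A sensor expected in a calibration set has no windows."""


class DegenerateDenominatorError(HemotransError):
    """ln(I850) is too close to zero for the ratio R to be stable."""


class DomainError(HemotransError):
    """A physical quantity is outside its valid domain."""


class ProtocolError(HemotransError):
    """An experiment protocol is malformed (empty grids, bad counts)."""


class InsufficientBinError(HemotransError):
    """A hemoglobin bin holds fewer samples than the fit requires."""


class InsufficientVariationError(HemotransError):
    """A regression target is constant, leaving R^2 undefined."""


class ParameterError(HemotransError):
    """A user-supplied parameter is outside its allowed range."""


class FoldError(HemotransError):
    """Too few samples for the requested number of CV folds."""


class RankDeficiencyError(HemotransError):
    """Unpenalized design matrix is singular."""


class NotFittedError(HemotransError):
    """Prediction was requested from an unfitted model."""


class InsufficientStructureError(HemotransError):
    """Too few usable hemoglobin bins to fit the saturation model."""


class EmptyInputError(HemotransError):
    """A statistic was requested on an empty set of pairs."""


class InsufficientDataError(HemotransError):
    """Fewer pairs than the statistic needs."""


class UndefinedR2Error(HemotransError):
    """Reference values have zero variance; R^2 is undefined."""


class DataIntegrityError(HemotransError):
    """Input tables do not join cleanly on sample_id."""


class UnknownSensorError(HemotransError):
    """A sensor_id is absent from the calibration bundle scalings."""


class FormatError(HemotransError):
    """An input file does not match the expected CSV/JSON schema."""
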