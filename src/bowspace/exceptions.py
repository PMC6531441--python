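"""Error taxonomy shared by all bowspace modules."""


class BowspaceError(ValueError):
    """Base class for all bowspace errors."""


class InvalidInputError(BowspaceError):
    """Malformed or inconsistent user input (bad sequence, bad mask, bad ids)."""


class DegenerateLengthError(BowspaceError):
    """Sequence too short for the requested descriptor (e.g. zero CMV normalizer)."""


class DanglingReferenceError(BowspaceError):
    """An edge or pair references an entity with no sequence/fingerprint record."""


class InfeasibleRequestError(BowspaceError):
    """A sampling request exceeds the available population."""


class DegenerateTrainingError(BowspaceError):
    """Training data with a single class; no classifier can be fitted."""


class SignatureError(BowspaceError):
    """Prediction-time feature columns do not match the training signature."""


class UndefinedMetricError(BowspaceError):
    """A metric is undefined for the given inputs (e.g. AUC with one class)."""
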