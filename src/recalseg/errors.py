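"""Exception hierarchy."""


class RecalsegError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(RecalsegError, ValueError):
    """Phantom specification violates its invariants."""


class MissingInputError(RecalsegError, FileNotFoundError):
    """A required input file (e.g. a modality NIfTI) is absent."""


class InconsistentCaseError(RecalsegError, ValueError):
    """Shapes or spacings disagree across the files of one case."""


class InvalidLabelError(RecalsegError, ValueError):
    """A label volume contains values outside {0, 1, 2, 4}."""


class DegenerateInputError(RecalsegError, ValueError):
    """An input is degenerate for the requested operation (e.g. constant channel)."""


class InvalidShapeError(RecalsegError, ValueError):
    """An array shape is incompatible with the network topology."""


class InvalidConfigError(RecalsegError, ValueError):
    """A configuration value is out of its permitted range."""
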