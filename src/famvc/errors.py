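"""Exception hierarchy used across the package."""


class FamvcError(Exception):
    """Base class for all famvc errors."""


class FormatError(FamvcError):
    """A file does not conform to its declared on-disk format."""


class ConsistencyError(FamvcError):
    """Mutually inconsistent inputs (e.g. mismatched sample/SNP counts)."""


class EmptyPanelError(FamvcError):
    """A filter removed every SNP (or every individual)."""


class DegenerateTraitError(FamvcError):
    """A trait has no usable variation."""


class ConfigurationError(FamvcError):
    """An invalid run or simulation configuration."""


class NumericalError(FamvcError):
    """A linear-algebra failure during model fitting."""
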