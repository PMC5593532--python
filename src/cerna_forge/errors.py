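"""Exception hierarchy shared by all stages."""


class CernaForgeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CernaForgeError):
    """A file violates its declared on-disk format."""


class ParseError(FormatError):
    """A cell or token could not be parsed; message carries row/column coordinates."""


class MetadataError(CernaForgeError):
    """Sample/gene metadata is missing or inconsistent with the data it describes."""


class ConsistencyError(CernaForgeError):
    """Cross-references between objects do not line up (unknown ids, de genes outside the universe, ...)."""


class ConfigError(CernaForgeError):
    """A configuration value is out of its legal domain."""


class SpecError(CernaForgeError):
    """A simulation specification is infeasible or self-contradictory."""


class DataError(CernaForgeError):
    """Input data is structurally valid but unusable (missing measurements, zero variance, ...)."""
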