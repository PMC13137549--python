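"""Exception hierarchy for caremap."""


class CaremapError(ValueError):
    """Base class for all caremap validation and configuration errors."""


class RegistryError(CaremapError):
    """Invalid indicator registry (cardinality, duplicate ids, bad scale)."""


class PortraitError(CaremapError):
    """Assessment record fails portrait validation."""


class RuleMatrixError(CaremapError):
    """Mapping matrix violates its schema or the totality invariant."""


class ConfigError(CaremapError):
    """Invalid similarity / stratification / policy configuration."""
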