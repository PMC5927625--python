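"""Exception hierarchy; the CLI maps these onto exit codes."""


class MemaError(Exception):
    """Base class for all package errors."""


class ConfigError(MemaError):
    """Invalid pipeline configuration (unknown keys, bad paths, bad values)."""


class DesignError(MemaError):
    """Infeasible or inconsistent array design."""


class ParameterError(MemaError):
    """Non-finite or out-of-range simulation parameters."""


class SchemaError(MemaError):
    """Table does not match the expected column schema."""


class SpotKeyError(MemaError):
    """Cell rows reference spots that do not exist in the design."""


class LayoutError(MemaError):
    """Arrays do not share a common printed spot layout."""


class NumericalError(MemaError):
    """A normalization or scoring computation is ill-posed."""
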