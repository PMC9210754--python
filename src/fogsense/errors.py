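"""Exception hierarchy shared across the pipeline stages."""


class FogSenseError(Exception):
    """Base class for all fogsense errors."""


class ConfigError(FogSenseError, ValueError):
    """Invalid generator/run configuration."""


class DataError(FogSenseError, ValueError):
    """Input data violates a stage precondition (e.g. all-missing channel)."""


class SchemaError(FogSenseError, ValueError):
    """Mismatched feature identifiers between tables/models."""


class DesignError(FogSenseError, ValueError):
    """Infeasible filter design request."""


class ParseError(FogSenseError, ValueError):
    """Malformed on-disk file."""
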