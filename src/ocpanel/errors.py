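"""Exception hierarchy for ocpanel."""


class OcpanelError(Exception):
    """Base class for all ocpanel errors."""


class SchemaError(OcpanelError):
    """A required column is missing or mistyped in a cohort table."""


class IntegrityError(OcpanelError):
    """The data violate a cohort invariant (duplicate IDs, dangling refs, ...)."""


class ParseError(OcpanelError):
    """A cell could not be parsed; carries row context."""


class ConfigurationError(OcpanelError):
    """Invalid pipeline or bin configuration."""
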