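"""Exception hierarchy.

``UsageError`` signals a caller mistake (wrong task type, schema mismatch),
``DataError`` signals invalid or insufficient data in an otherwise
well-formed input, ``SchemaError`` a malformed record, and
``ValidationError`` a record that parses but violates a domain invariant.
"""


class GripSenseError(Exception):
    """Base class for all package errors."""


class UsageError(GripSenseError):
    """The caller violated an API contract (wrong scope, mismatched keys...)."""


class ConfigError(GripSenseError):
    """Invalid configuration (infeasible geometry, bad YAML values...)."""


class SchemaError(GripSenseError):
    """A record is missing required fields or has the wrong shape."""


class ValidationError(GripSenseError):
    """A parsed record violates a domain invariant."""


class DataError(GripSenseError):
    """Data is present but unusable (too short, all-missing channel...)."""
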