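"""Exception hierarchy.

``UsageError`` — the caller asked for something the API cannot do
(bad arguments, unsupported format).  ``DataError`` — the input file or
stream is readable but violates an invariant (non-monotonic timestamps,
non-overlapping devices).  ``FormatError`` — the file cannot be parsed at
all.  ``ConfigError`` — an invalid configuration value.
"""


class WalkanchorError(Exception):
    """Base class for all package errors."""


class UsageError(WalkanchorError):
    pass


class DataError(WalkanchorError):
    pass


class FormatError(WalkanchorError):
    pass


class ConfigError(WalkanchorError):
    pass


class ProfileError(WalkanchorError):
    """Invalid synthetic-participant profile (e.g. overlapping segments)."""
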