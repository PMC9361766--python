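"""Exception hierarchy shared by all pipeline stages."""


class GuildnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GuildnetError):
    """A file or table violates the expected on-disk format."""


class DegenerateSampleError(GuildnetError):
    """A sample column is unusable (e.g. all-zero counts)."""

    def __init__(self, sample_id: str, message: str | None = None):
        self.sample_id = sample_id
        super().__init__(message or f"sample {sample_id!r} has zero total count")


class ConfigurationError(GuildnetError):
    """A parameter combination is invalid or inconsistent."""


class PreconditionError(GuildnetError):
    """An operation was called on inputs that violate its contract."""
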