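"""Exception hierarchy for loxmd.

Every error raised deliberately by the package derives from :class:`LoxmdError`
so callers (and the CLI) can distinguish analysis failures from bugs.
"""


class LoxmdError(Exception):
    """Base class for all loxmd errors."""


class ConfigError(LoxmdError):
    """A topology/selection or pipeline configuration is invalid."""


class UnresolvedAddressError(LoxmdError):
    """An atom address in a selection does not match exactly one atom."""

    def __init__(self, address):
        self.address = address
        super().__init__(f"unresolved atom address: {address!r}")


class InputError(LoxmdError):
    """An input file is missing, malformed, or internally inconsistent."""


class RaggedFrameError(InputError):
    """Frames in a trajectory input do not share one atom list."""


class EmptyTrajectoryError(InputError):
    """A trajectory input contains no frames."""


class DegenerateGeometryError(LoxmdError):
    """A geometric operation received a degenerate point configuration."""


class FitError(LoxmdError):
    """A model fit failed to converge or produced inadmissible estimates."""
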