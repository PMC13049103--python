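"""Exception hierarchy.

All package-specific failures derive from :class:`CtpsegError` so callers
(and the CLI) can distinguish configuration problems (exit code 2) from
runtime failures (exit code 1).
"""


class CtpsegError(Exception):
    """Base class for all errors raised by ctpseg."""


class ConfigError(CtpsegError):
    """Invalid parameter value or inconsistent configuration."""


class GeometryError(CtpsegError):
    """Phantom geometry does not fit the voxel grid or is malformed."""


class FormatError(CtpsegError):
    """A file on disk is missing or cannot be parsed; names the file."""


class LabelValidationError(CtpsegError):
    """Nested-contour invariants violated (inner not contained in outer, ...)."""


class PairingError(CtpsegError):
    """Paired statistics requested on mismatched case sets."""


class TimingError(CtpsegError):
    """Physiologically or structurally invalid timing inputs."""
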