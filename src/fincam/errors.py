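"""Exception hierarchy shared by all fincam stages.

The CLI maps these onto distinct exit codes (see :mod:`fincam.cli`), so every
stage raises the most specific class that applies rather than a bare
``ValueError``/``OSError``.
"""


class FincamError(Exception):
    """Base class for all fincam errors."""


class ArgumentError(FincamError, ValueError):
    """A caller-supplied argument violates a documented precondition."""


class DataError(FincamError):
    """Input data is structurally invalid (duplicates, missing labels, ...)."""


class CapabilityError(FincamError):
    """An optional dependency or external tool required by this code path is
    not available; other code paths remain usable."""


class ProbeError(FincamError, OSError):
    """A file could not be probed or decoded as video."""


class WriteError(FincamError, OSError):
    """A clip or artefact could not be written."""
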