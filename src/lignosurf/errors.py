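"""Exception hierarchy shared across the package."""


class LignosurfError(Exception):
    """Base class for all package-specific errors."""


class SpectrumError(LignosurfError):
    """Malformed or unusable spectral data (too few points, duplicate axis...)."""


class WindowError(LignosurfError):
    """An analysis window falls outside the spectrum axis or holds too few points."""


class FitError(LignosurfError):
    """A least-squares fit failed to converge or produced a non-physical result."""


class ConfigError(LignosurfError):
    """Invalid configuration or manifest content."""
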