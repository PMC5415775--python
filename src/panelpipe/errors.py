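"""Exception hierarchy for panelpipe."""


class PanelPipeError(Exception):
    """Base class for all panelpipe errors."""


class ConfigError(PanelPipeError):
    """Invalid configuration or lesion specification."""


class PanelError(PanelPipeError):
    """Panel design violates its constraints (bounds, control counts)."""


class SamImportError(PanelPipeError):
    """SAM file inconsistent with the supplied reference."""


class ConvergenceError(PanelPipeError):
    """Iterative model fit failed to converge (or separated)."""
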