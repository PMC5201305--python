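"""Exception types raised across the package."""


class ParameterError(ValueError):
    """A configuration value violates its documented constraint."""


class SceneSizingError(ParameterError):
    """Requested cell layout does not fit on the canvas."""


class DegenerateDataError(ValueError):
    """Input data carry no usable signal (flat, empty, or zero-variance)."""
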