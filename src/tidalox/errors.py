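"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A physiological or ventilator parameter is outside its valid range."""


class ResolutionError(ValueError):
    """The integration step is too coarse for the requested waveform."""


class ModelValidityError(RuntimeError):
    """The simulated state left the domain in which the model is meaningful
    (e.g. alveolar O2 fraction outside (0, 1))."""


class CalibrationError(RuntimeError):
    """An iterative calibration (e.g. FIO2 to a target mean PaO2) failed."""


class GeometryError(ValueError):
    """CT volumes being combined do not share shape, voxel size or mask."""
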