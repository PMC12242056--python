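"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """A model or run configuration is internally inconsistent."""


class ShapeError(ValueError):
    """An array argument has an incompatible shape."""


class ConsistencyError(ValueError):
    """Metadata of combined objects disagrees (montage, subject, image id...)."""
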