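"""Exception hierarchy used across the package."""


class WeanlabError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(WeanlabError, ValueError):
    """A physiological or ventilator parameter is outside its valid domain."""


class ConfigurationError(WeanlabError, ValueError):
    """A simulation or pipeline configuration cannot be honoured."""


class IngestionError(WeanlabError, ValueError):
    """A waveform or EIT file failed validation on read."""


class AnalysisError(WeanlabError, RuntimeError):
    """An analysis step cannot produce a result from the given input."""
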