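"""Exception hierarchy for the flexrelax pipeline."""


class FlexRelaxError(Exception):
    """Base class for all package errors."""


class ConfigError(FlexRelaxError):
    """Invalid configuration (bad layout, non-positive durations, ...)."""


class InputError(FlexRelaxError):
    """Input data violate a precondition (too short, wrong shape, ...)."""


class SegmentationError(FlexRelaxError):
    """The angle trace could not be segmented into movement phases."""


class PipelineError(FlexRelaxError):
    """A trial or cohort became unusable mid-pipeline (e.g. all channels excluded)."""
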