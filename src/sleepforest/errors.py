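"""Structured exception hierarchy.

Every error raised by the library derives from :class:`SleepForestError` and
carries enough context (record id, feature name, ...) to be actionable.
"""


class SleepForestError(Exception):
    """Base class for all library errors."""


class ChannelMismatchError(SleepForestError):
    """Channels of one recording disagree in length or count."""


class UnknownLabelError(SleepForestError):
    """A sleep-stage label outside the accepted vocabulary."""


class InsufficientDataError(SleepForestError):
    """An operation requested more data than is available."""


class DegenerateInputError(SleepForestError):
    """Zero-variance / constant / all-zero input where a spread is required."""


class FeatureComputationError(SleepForestError):
    """A per-feature failure, annotated with the feature name."""

    def __init__(self, feature: str, message: str):
        self.feature = feature
        super().__init__(f"{feature}: {message}")


class OntologyError(SleepForestError):
    """Referential-integrity or typing violation in the ontology store."""


class SelectionError(SleepForestError):
    """Feature selection produced no usable subset."""


class TableFormatError(SleepForestError):
    """A feature table or confusion matrix file is malformed."""
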