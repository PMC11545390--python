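"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`SpeechMarkersError`
so that callers (and the CLI) can catch pipeline failures in one place.
"""


class SpeechMarkersError(Exception):
    """Base class for all speechmarkers errors."""


class CorpusParseError(SpeechMarkersError):
    """A transcript line (or pre-tagged chunk) could not be parsed."""


class CorpusValidationError(SpeechMarkersError):
    """A record violates the corpus schema or its invariants."""


class PosMappingError(SpeechMarkersError):
    """A native analyzer POS tag has no entry in the mapping table."""


class ConfigurationError(SpeechMarkersError):
    """An invalid mode, lexicon, or generator configuration."""


class UntokenizedSegmentError(SpeechMarkersError):
    """Feature extraction was asked to run on segments without tokens."""


class DegenerateSessionError(SpeechMarkersError):
    """A session has no denominator tokens; ratios would be undefined."""


class SampleSizeError(SpeechMarkersError):
    """A t-test was given fewer than two observations per sample."""


class DegenerateVarianceError(SpeechMarkersError):
    """A t-test denominator is zero (constant differences or samples)."""


class CompletenessError(SpeechMarkersError):
    """The comparison battery is missing required sessions or groups."""
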