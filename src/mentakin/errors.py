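"""Exception hierarchy.

Every error the library raises derives from :class:`MentakinError` so callers
can catch one type at pipeline boundaries while tests assert on specifics.
"""


class MentakinError(Exception):
    """Base class for all mentakin errors."""


class InvalidDesignError(MentakinError):
    """Cohort design request violates the crossover-design constraints."""


class ParameterError(MentakinError):
    """A generator or kinematic parameter is out of its valid domain."""


class InsufficientDataError(MentakinError):
    """Too few frames to evaluate the requested finite difference."""


class SamplingError(MentakinError):
    """Trajectory timestamps deviate from uniform sampling beyond tolerance."""


class LinkageError(MentakinError):
    """A trial cannot be linked to a self-produced animation."""


class MalformedTrialError(MentakinError):
    """An animation trial is missing rating scales or has bad labels."""


class CardinalityError(MentakinError):
    """Wrong number of trials for a word-by-session cell."""


class DegeneratePredictorError(MentakinError):
    """A predictor is constant and cannot be standardised."""


class RegistryError(MentakinError):
    """Unknown model name."""


class SchemaError(MentakinError):
    """An analysis table is missing required columns."""


class ComparabilityError(MentakinError):
    """Model fits do not share an observation set."""


class PipelineError(MentakinError):
    """A pipeline stage failed or stage outputs are inconsistent."""


class ReportError(MentakinError):
    """Report requested from a results directory with missing outputs."""
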