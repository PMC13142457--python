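"""Exception hierarchy for phonoseq.

All package errors derive from :class:`PhonoseqError` so callers can catch
one base class; subtypes distinguish design misuse from data problems.
"""


class PhonoseqError(Exception):
    """Base class for all phonoseq errors."""


class DesignError(PhonoseqError):
    """Invalid task design (empty inventory, bad slot counts, no pairs...)."""


class LabelError(PhonoseqError):
    """A condition label is inconsistent with the declared inventory/design."""


class ConstructionError(PhonoseqError):
    """A ground-truth code with the requested geometry cannot be built."""


class EpochError(PhonoseqError):
    """A required trial epoch is absent or a window falls outside the data."""


class EmptySelectionError(PhonoseqError):
    """A trial/group selection matched nothing."""


class ShapeError(PhonoseqError):
    """Array dimensions are inconsistent with the model or session."""


class FoldError(PhonoseqError):
    """Cross-validation folds cannot be constructed as requested."""


class EvaluationError(PhonoseqError):
    """A metric is undefined on the provided scores/labels."""


class SessionIOError(PhonoseqError):
    """A session bundle is missing, corrupt, or has the wrong schema version."""


class ConfigError(PhonoseqError):
    """A scenario/CLI configuration document is invalid."""
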