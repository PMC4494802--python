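"""Exception hierarchy for the n-of-1 pipeline.

All pipeline errors derive from :class:`Nof1Error` so callers can catch one
type at the CLI boundary.
"""


class Nof1Error(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(Nof1Error, ValueError):
    """Malformed or out-of-contract input (negative counts, empty matrix...)."""


class SizeFactorUndefinedError(Nof1Error):
    """No gene with positive reference geometric mean and positive count."""

    def __init__(self, sample_id: str):
        self.sample_id = sample_id
        super().__init__(
            f"size factor undefined for sample {sample_id!r}: no gene with "
            "positive geometric mean and positive count"
        )


class InsufficientNormalsError(Nof1Error):
    """Fewer than two normal samples available for parameter fitting."""


class CutoffUndefinedError(Nof1Error):
    """Expression cutoff cannot be computed (empty background gene set)."""


class ReferenceFormatError(Nof1Error):
    """Frozen reference archive is unreadable, truncated or wrong version."""


class TrainingError(Nof1Error):
    """Classifier training preconditions violated (class too small...)."""


class UnsolvablePathwayError(Nof1Error):
    """(I - B) is singular for a pathway topology; perturbation undefined."""

    def __init__(self, pathway_id: str):
        self.pathway_id = pathway_id
        super().__init__(f"pathway {pathway_id!r}: (I - B) is singular")


class FormatError(Nof1Error):
    """A tabular input file is missing required columns or malformed."""


class IntegrationError(Nof1Error):
    """Stage outputs disagree (e.g. inconsistent patient identifiers)."""
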