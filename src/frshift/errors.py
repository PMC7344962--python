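"""Exception hierarchy for frshift."""


class FrshiftError(Exception):
    """Base class for all frshift errors."""


class InputError(FrshiftError):
    """Malformed or non-physical user input (bad residues, bad parameters)."""


class AlignmentError(FrshiftError):
    """A sequence cannot be mapped onto the numbering scheme (e.g. FR indel)."""


class DomainIncompatibilityError(FrshiftError):
    """Two domains cannot be compared (different chain kinds or position sets)."""


class DegenerateInputError(FrshiftError):
    """Structurally valid input that carries no information (all-zero spectrum,
    empty comparable position set)."""


class StructuralGapError(FrshiftError):
    """A residue required for a distance computation has no coordinates."""


class ConfigurationError(FrshiftError):
    """Inconsistent or incomplete run configuration."""


class GraftingError(FrshiftError):
    """A donor framework cannot supply a residue the parent requires."""


class NoTransitionError(FrshiftError):
    """A centroid curve shows no resolvable unfolding transition."""
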