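"""Framework grafting, Protein-L mutations, back-mutation variant
enumeration, and scFv assembly with computed protein parameters.

The variant naming scheme follows the "S1<VH letter><VL digit>" convention:
the VH letter encodes which substitution clusters a variant carries
(A = none, B = III, C = II, D = II+III, Z = I+II+III) and the VL digit a
fixed lattice of light-chain mutation sets built from the grafted set, the
Protein-L recognition mutation T8P, and back-mutations at positions 96
and 4.  All mutation sets are expressed relative to the wild-type parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .clusters import ClusterAssignment
from .errors import ConfigurationError, GraftingError, InputError
from .germline import GermlineRecord
from .imgt import (
    Mutation,
    NumberedDomain,
    RegionScheme,
    mutations_between,
)

#: (Gly4Ser)3 flexible linker joining VH and VL.
DEFAULT_LINKER = "GGGGSGGGGSGGGGS"
#: C-terminal Gly3-Ala-Ser-His6 purification flag (11 residues).
DEFAULT_TAG = "GGGASHHHHHH"

#: The 12 constructs of the default design series, as (VH letter, VL digit).
DEFAULT_SERIES = (
    ("A", "0"), ("Z", "9"), ("Z", "8"), ("Z", "4"),
    ("D", "4"), ("B", "4"), ("C", "4"), ("A", "4"),
    ("B", "3"), ("B", "2"), ("B", "1"), ("A", "1"),
)

VH_LETTER_CLUSTERS = {
    "A": (),
    "B": ("III",),
    "C": ("II",),
    "D": ("II", "III"),
    "Z": ("I", "II", "III"),
}


@dataclass(frozen=True)
class VariantSpec:
    """A named back-mutation variant: which designed substitutions it keeps."""

    name: str
    vh_mutation_set: frozenset
    vl_mutation_set: frozenset
    parent: str = ""


@dataclass(frozen=True)
class ScFvConstruct:
    """An assembled single-chain fragment in VH-VL orientation."""

    vh: NumberedDomain
    linker: str
    vl: NumberedDomain
    tag: str
    full_sequence: str
    mw: float  # Da
    pI: float
    extinction: float  # M^-1 cm^-1 at 280 nm, reduced
    name: str = ""


# ---------------------------------------------------------------------------
# Grafting and Protein-L mutations
# ---------------------------------------------------------------------------


def graft_frameworks(
    parent: NumberedDomain,
    v_donor: GermlineRecord,
    j_donor: GermlineRecord,
    scheme: RegionScheme,
):
    """Replace the parent's framework residues with donor residues.

    The V donor supplies FR1-FR3, the J donor FR4; CDR and extended-paratope
    positions keep the parent residue.  Returns the grafted domain and its
    mutation list relative to the parent.
    """
    for donor in (v_donor, j_donor):
        if donor.chain_kind != parent.chain_kind:
            raise InputError(
                f"donor {donor.label} chain kind {donor.chain_kind} does not "
                f"match parent {parent.chain_kind}"
            )
    if v_donor.segment != "V" or j_donor.segment != "J":
        raise InputError("graft_frameworks needs one V donor and one J donor")

    paratope = scheme.paratope_positions()
    fr123 = scheme.fr_positions() - scheme.positions("FR4")
    fr4 = scheme.positions("FR4")
    vmap = v_donor.residue_map()
    jmap = j_donor.residue_map()

    substitutions = {}
    for pos, aa in parent.residues:
        if pos in paratope:
            continue
        if pos in fr123:
            donor_label, donor_map = v_donor.label, vmap
        elif pos in fr4:
            donor_label, donor_map = j_donor.label, jmap
        else:
            continue  # CDR position outside the extension
        donor_aa = donor_map.get(pos)
        if donor_aa is None:
            raise GraftingError(
                f"donor {donor_label} has a gap at framework position {pos} "
                f"required by {parent.name or 'parent'}"
            )
        if donor_aa != aa:
            substitutions[pos] = donor_aa

    grafted = parent.with_substitutions(substitutions, name=f"{parent.name}-graft")
    return grafted, mutations_between(parent, grafted)


#: Protein-L recognition substitutions on kappa light chains (IMGT positions).
PPL_PRIMARY = (8, "P")  # T8P confers Protein-L recognition
PPL_SECONDARY = (24, "R")  # S24R strengthens Protein-L affinity


def apply_ppl_mutations(vl: NumberedDomain, variant: str = "T8P_only") -> NumberedDomain:
    """Introduce the Protein-L recognition residue(s) into a kappa VL.

    variant='T8P_only' places proline at position 8; 'T8P_and_S24R' also
    places arginine at 24.  Idempotent: positions already carrying the
    target residue are left untouched.
    """
    if vl.chain_kind != "VL_kappa":
        raise InputError("Protein-L mutations apply to kappa light chains only")
    if variant not in ("T8P_only", "T8P_and_S24R"):
        raise InputError(f"unknown Protein-L variant {variant!r}")
    targets = [PPL_PRIMARY] if variant == "T8P_only" else [PPL_PRIMARY, PPL_SECONDARY]
    subs = {}
    for pos, aa in targets:
        current = vl.aa_at(pos)
        if current is None:
            raise InputError(f"VL position {pos} is not occupied")
        if current != aa:
            subs[pos] = aa
    if not subs:
        return vl
    return vl.with_substitutions(subs, name=vl.name)


# ---------------------------------------------------------------------------
# Back-mutation enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantNaming:
    """Data-driven registry for the variant naming scheme.

    ``vl_back_positions`` are the VL positions whose grafted substitutions
    the digit series back-mutates individually (first digit 3, second
    digit 2, both absent in digit 1).
    """

    prefix: str = "S1"
    series: tuple = DEFAULT_SERIES
    vl_back_positions: tuple = (96, 4)


def build_vl_digit_sets(
    grafted_vl_mutations,
    ppl_primary: Mutation,
    ppl_secondary_position: int = 24,
    back_positions: tuple = (96, 4),
) -> dict:
    """Construct the VL digit -> mutation-set lattice.

    digit 0: wild type; 9: grafted set; 8: 9 + the Protein-L primary
    mutation; 4: 8 minus the substitution at the Protein-L secondary
    position (back to wild type); 3/2: 4 minus the substitution at the
    first/second back position; 1: 4 minus both.
    """
    grafted = frozenset(grafted_vl_mutations)
    set9 = grafted
    set8 = set9 | {ppl_primary}
    set4 = frozenset(
        m for m in set8 if m.imgt_position != ppl_secondary_position
    )
    pos_a, pos_b = back_positions
    set3 = frozenset(m for m in set4 if m.imgt_position != pos_a)
    set2 = frozenset(m for m in set4 if m.imgt_position != pos_b)
    set1 = frozenset(
        m for m in set4 if m.imgt_position not in (pos_a, pos_b)
    )
    return {
        "0": frozenset(),
        "9": set9,
        "8": set8,
        "4": set4,
        "3": set3,
        "2": set2,
        "1": set1,
    }


def enumerate_backmutants(
    full_design: ClusterAssignment,
    naming: VariantNaming = VariantNaming(),
    vl_digit_sets: dict | None = None,
    full_cross_product: bool = False,
):
    """Emit the named variant series from a clustered full design.

    VH letters draw on the cluster partition (A/B/C/D/Z); VL digits on the
    digit lattice.  By default only the study's 12 constructs are emitted;
    ``full_cross_product=True`` yields every letter x digit combination.
    """
    vh_sets = {
        letter: frozenset(
            m for c in clusters_needed for m in full_design.cluster(c)
        )
        for letter, clusters_needed in VH_LETTER_CLUSTERS.items()
    }
    if vl_digit_sets is None:
        vl_muts = full_design.cluster("IV")
        if vl_muts:
            ppl_primary = next(
                (m for m in vl_muts if m.imgt_position == 8), None
            )
            if ppl_primary is None:
                raise ConfigurationError(
                    "VL cluster has no substitution at the Protein-L primary "
                    "position 8; supply vl_digit_sets explicitly"
                )
            grafted = [m for m in vl_muts if m is not ppl_primary]
            vl_digit_sets = build_vl_digit_sets(
                grafted, ppl_primary, back_positions=naming.vl_back_positions
            )
        else:
            vl_digit_sets = {"0": frozenset()}

    if set(vl_digit_sets) == {"0"}:
        # no VL design: every named digit degenerates to the wild-type VL
        naming = VariantNaming(
            prefix=naming.prefix,
            series=tuple((letter, "0") for letter, _d in naming.series),
            vl_back_positions=naming.vl_back_positions,
        )
    if full_cross_product:
        combos = [
            (letter, digit)
            for letter in sorted(vh_sets)
            for digit in sorted(vl_digit_sets)
        ]
    else:
        combos = list(naming.series)

    specs = []
    seen_names = set()
    for letter, digit in combos:
        if letter not in vh_sets:
            raise ConfigurationError(f"unknown VH letter {letter!r}")
        if digit not in vl_digit_sets:
            raise ConfigurationError(f"unknown VL digit {digit!r}")
        if f"{naming.prefix}{letter}{digit}" in seen_names:
            continue
        seen_names.add(f"{naming.prefix}{letter}{digit}")
        specs.append(
            VariantSpec(
                name=f"{naming.prefix}{letter}{digit}",
                vh_mutation_set=vh_sets[letter],
                vl_mutation_set=vl_digit_sets[digit],
                parent=f"{naming.prefix}A0",
            )
        )
    # collapse an all-empty design to the single wild-type variant
    if all(not s.vh_mutation_set and not s.vl_mutation_set for s in specs):
        return [
            VariantSpec(
                name=f"{naming.prefix}A0",
                vh_mutation_set=frozenset(),
                vl_mutation_set=frozenset(),
                parent=f"{naming.prefix}A0",
            )
        ]
    return specs


# ---------------------------------------------------------------------------
# scFv assembly and protein parameters
# ---------------------------------------------------------------------------

_EXT_TRP = 5500.0
_EXT_TYR = 1490.0


def protein_params(sequence: str):
    """(molecular weight Da, isoelectric point, reduced extinction at 280 nm).

    mw and pI follow the ProtParam conventions (average isotopic masses;
    Bjellqvist pKa set); the extinction coefficient sums the published
    280 nm coefficients of tryptophan and tyrosine.
    """
    if not sequence:
        raise InputError("empty sequence")
    bad = set(sequence) - set("ACDEFGHIKLMNPQRSTVWY")
    if bad:
        raise InputError(f"non-standard residues {sorted(bad)} in sequence")
    analysis = ProteinAnalysis(sequence)
    mw = analysis.molecular_weight()
    pI = analysis.isoelectric_point()
    extinction = _EXT_TRP * sequence.count("W") + _EXT_TYR * sequence.count("Y")
    return mw, pI, extinction


def assemble_scfv(
    vh: NumberedDomain,
    vl: NumberedDomain,
    linker: str = DEFAULT_LINKER,
    tag: str = DEFAULT_TAG,
    name: str = "",
) -> ScFvConstruct:
    """Join VH and VL (VH-VL orientation) with a linker and C-terminal tag."""
    if len(vh) == 0 or len(vl) == 0:
        raise InputError("cannot assemble an scFv from an empty domain")
    full = vh.sequence + linker + vl.sequence + tag
    mw, pI, extinction = protein_params(full)
    return ScFvConstruct(
        vh=vh, linker=linker, vl=vl, tag=tag,
        full_sequence=full, mw=mw, pI=pI, extinction=extinction, name=name,
    )


def realize_variant(
    spec: VariantSpec,
    parent_vh: NumberedDomain,
    parent_vl: NumberedDomain,
    linker: str = DEFAULT_LINKER,
    tag: str = DEFAULT_TAG,
) -> ScFvConstruct:
    """Apply a variant's mutation sets to the wild-type domains and assemble."""
    vh = parent_vh.apply_mutations(
        sorted(spec.vh_mutation_set), name=f"VH-{spec.name}"
    )
    vl = parent_vl.apply_mutations(
        sorted(spec.vl_mutation_set), name=f"VL-{spec.name}"
    )
    return assemble_scfv(vh, vl, linker=linker, tag=tag, name=spec.name)


def design_table(entries) -> str:
    """Tab-separated design summary from (VariantSpec, ScFvConstruct) pairs."""
    lines = ["name\tvh_mutations\tvl_mutations\tlength\tmw_Da\tpI\textinction_M-1cm-1"]
    for spec, c in entries:
        lines.append(
            "\t".join(
                [
                    spec.name,
                    ";".join(str(m) for m in sorted(spec.vh_mutation_set)),
                    ";".join(str(m) for m in sorted(spec.vl_mutation_set)),
                    str(len(c.full_sequence)),
                    f"{c.mw:.2f}",
                    f"{c.pI:.2f}",
                    f"{c.extinction:.0f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
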