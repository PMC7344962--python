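"""Germline framework selection: identity scoring, filtering, ranking.

Step 1 of framework shifting compares a query variable domain against a
directory of germline V and J segments.  Candidates are scored with overall
and framework-only percent identity, filtered by hard rules (a cap on FR1
modifications, required stability/interaction residues such as VH-Y103), and
ranked by framework identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DegenerateInputError, DomainIncompatibilityError, InputError
from .imgt import (
    FR_REGIONS,
    GAP_CHAR,
    REGIONS,
    STANDARD_AA,
    Mutation,
    NumberedDomain,
    RegionScheme,
)

#: IMGT positions covered by a germline V segment (FR1 through FR3).
V_SPAN = (1, 104)
#: IMGT positions covered by a germline J segment, restricted to FR4.
J_SPAN = (118, 128)


@dataclass(frozen=True)
class GermlineRecord:
    """One germline gene segment, IMGT-gapped over its span."""

    gene: str
    allele: str
    segment: str  # "V" or "J"
    chain_kind: str  # "VH" or "VL_kappa"
    gapped_sequence: str
    species: str = "Mus musculus"

    def __post_init__(self) -> None:
        if self.segment not in ("V", "J"):
            raise InputError(f"segment must be V or J, got {self.segment!r}")
        if self.chain_kind not in ("VH", "VL_kappa"):
            raise InputError(f"unknown chain kind {self.chain_kind!r}")
        start, end = self.span
        if len(self.gapped_sequence) != end - start + 1:
            raise InputError(
                f"{self.label}: gapped sequence length {len(self.gapped_sequence)} "
                f"does not match the {self.segment}-segment span {end - start + 1}"
            )
        bad = set(self.gapped_sequence) - STANDARD_AA - {GAP_CHAR}
        if bad:
            raise InputError(f"{self.label}: invalid characters {sorted(bad)}")

    @property
    def span(self):
        return V_SPAN if self.segment == "V" else J_SPAN

    @property
    def label(self) -> str:
        return f"{self.gene}*{self.allele}"

    def residue_map(self) -> dict:
        """IMGT position -> residue for occupied positions."""
        start, _ = self.span
        return {
            start + i: aa
            for i, aa in enumerate(self.gapped_sequence)
            if aa != GAP_CHAR
        }


@dataclass(frozen=True)
class IdentityReport:
    """Overall / FR-only identity with per-region mismatch lists."""

    overall_identity: float
    fr_identity: float
    per_region_mismatches: dict  # region -> list of Mutation (query -> candidate)
    n_substitutions: int
    n_compared: int

    def mismatches_in(self, *regions) -> int:
        return sum(len(self.per_region_mismatches.get(r, ())) for r in regions)


@dataclass(frozen=True)
class RankedCandidate:
    record: GermlineRecord
    report: IdentityReport
    accepted: bool
    rejection_reason: str = ""


@dataclass(frozen=True)
class CandidateRanking:
    candidates: tuple  # RankedCandidate, accepted first (sorted), then rejected

    @property
    def accepted(self):
        return [c for c in self.candidates if c.accepted]

    @property
    def rejected(self):
        return [c for c in self.candidates if not c.accepted]

    def best(self):
        acc = self.accepted
        return acc[0] if acc else None


@dataclass(frozen=True)
class FilterRules:
    """Hard selection rules applied before ranking.

    ``max_fr1_mismatches`` caps modifications in FR1 (optionally restricted
    to a sub-interval approximating the A and B strands).  ``required_residues``
    lists (position, residue) pairs a candidate must carry where it occupies
    the position.
    """

    max_fr1_mismatches: int = 4
    fr1_strand_interval: tuple | None = None  # optional (start, end) within FR1
    required_residues: tuple = ()  # ((imgt_position, amino_acid), ...)


#: Default rules for heavy chains: Y103 preserves stability, V42 preserves
#: the VH/VL interaction.
DEFAULT_VH_RULES = FilterRules(required_residues=((103, "Y"), (42, "V")))
#: Default rules for kappa light chains: Y103 preserves stability.
DEFAULT_VL_RULES = FilterRules(required_residues=((103, "Y"),))


def _round_percent(value: float) -> float:
    """Round half-up to one decimal, matching reported identity values."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _residue_map(obj) -> dict:
    if isinstance(obj, NumberedDomain):
        return dict(obj.residues)
    if isinstance(obj, GermlineRecord):
        return obj.residue_map()
    raise InputError(f"cannot compare object of type {type(obj).__name__}")


def identity_report(
    query: NumberedDomain,
    candidate,
    scheme: RegionScheme,
    mode: str = "overall",
) -> IdentityReport:
    """Percent identity between a query domain and a candidate.

    mode='overall' compares every position occupied in both; 'fr_only'
    restricts to framework positions; 'design' excludes the extended
    paratope (the positions framework design never touches).
    """
    if mode not in ("overall", "fr_only", "design"):
        raise InputError(f"unknown identity mode {mode!r}")
    qmap = _residue_map(query)
    cmap = _residue_map(candidate)
    comparable = set(qmap) & set(cmap)
    if mode == "fr_only":
        comparable &= scheme.fr_positions()
    elif mode == "design":
        comparable -= scheme.paratope_positions()
    if not comparable:
        raise DegenerateInputError("no comparable positions between query and candidate")

    label = query.domain_label
    mismatches = {region: [] for region in REGIONS}
    n_sub = 0
    for pos in sorted(comparable):
        if qmap[pos] != cmap[pos]:
            n_sub += 1
            mismatches[scheme.region_of(pos)].append(
                Mutation(label, qmap[pos], pos, cmap[pos])
            )

    n = len(comparable)
    overall = _round_percent(100.0 * (n - n_sub) / n)

    fr_comparable = comparable & scheme.fr_positions()
    if fr_comparable:
        fr_sub = sum(
            len(v) for r, v in mismatches.items() if r in FR_REGIONS
        )
        fr_identity = _round_percent(
            100.0 * (len(fr_comparable) - fr_sub) / len(fr_comparable)
        )
    else:
        fr_identity = overall
    return IdentityReport(
        overall_identity=overall,
        fr_identity=fr_identity,
        per_region_mismatches={r: tuple(v) for r, v in mismatches.items()},
        n_substitutions=n_sub,
        n_compared=n,
    )


def combined_identity(*reports: IdentityReport) -> float:
    """Pooled percent identity across several domain comparisons (e.g. VH+VL
    of an scFv): substitutions and compared positions are summed before the
    percentage is taken."""
    n = sum(r.n_compared for r in reports)
    subs = sum(r.n_substitutions for r in reports)
    if n == 0:
        raise DegenerateInputError("no compared positions")
    return _round_percent(100.0 * (n - subs) / n)


def _fr1_mismatch_count(report: IdentityReport, rules: FilterRules) -> int:
    muts = report.per_region_mismatches.get("FR1", ())
    if rules.fr1_strand_interval is not None:
        lo, hi = rules.fr1_strand_interval
        muts = [m for m in muts if lo <= m.imgt_position <= hi]
    return len(muts)


def _check_rules(record: GermlineRecord, report: IdentityReport, rules: FilterRules) -> str:
    """Return a rejection reason, or '' if the candidate passes."""
    n_fr1 = _fr1_mismatch_count(report, rules)
    if n_fr1 > rules.max_fr1_mismatches:
        return f"FR1>{rules.max_fr1_mismatches}"
    cmap = record.residue_map()
    for pos, aa in rules.required_residues:
        present = cmap.get(pos)
        if present is not None and present != aa:
            return f"requires {aa}{pos}"
    return ""


def filter_candidates(
    query: NumberedDomain,
    directory,
    scheme: RegionScheme,
    rules: FilterRules | None = None,
) -> CandidateRanking:
    """Apply filter rules and rank accepted candidates by FR identity.

    Ties break by fewer FR1+FR2 mismatches, then by gene/allele name.  The
    output is a permutation of the input directory: rejected candidates
    follow the accepted ones, each with a reason.
    """
    if not directory:
        raise InputError("germline directory is empty")
    if rules is None:
        rules = DEFAULT_VH_RULES if query.chain_kind == "VH" else DEFAULT_VL_RULES

    scored = []
    for record in directory:
        report = identity_report(query, record, scheme, mode="fr_only")
        reason = _check_rules(record, report, rules)
        scored.append(RankedCandidate(record, report, reason == "", reason))

    def sort_key(c: RankedCandidate):
        return (
            -c.report.fr_identity,
            c.report.mismatches_in("FR1", "FR2"),
            c.record.gene,
            c.record.allele,
        )

    ordered = sorted((c for c in scored if c.accepted), key=sort_key) + [
        c for c in scored if not c.accepted
    ]
    return CandidateRanking(tuple(ordered))


def select_j_segment(
    query: NumberedDomain, j_records, scheme: RegionScheme
) -> CandidateRanking:
    """Rank J segments by identity over FR4 positions only."""
    if any(r.segment != "J" for r in j_records):
        raise InputError("select_j_segment expects J records only")
    if not j_records:
        raise InputError("no J records supplied")

    qmap = dict(query.residues)
    fr4 = scheme.positions("FR4")
    label = query.domain_label
    scored = []
    for record in j_records:
        cmap = record.residue_map()
        comparable = sorted(set(qmap) & set(cmap) & fr4)
        if not comparable:
            raise DegenerateInputError(f"{record.label}: no comparable FR4 positions")
        muts = tuple(
            Mutation(label, qmap[p], p, cmap[p])
            for p in comparable
            if qmap[p] != cmap[p]
        )
        ident = _round_percent(100.0 * (len(comparable) - len(muts)) / len(comparable))
        report = IdentityReport(
            overall_identity=ident,
            fr_identity=ident,
            per_region_mismatches={"FR4": muts},
            n_substitutions=len(muts),
            n_compared=len(comparable),
        )
        scored.append(RankedCandidate(record, report, True, ""))
    ordered = sorted(
        scored,
        key=lambda c: (-c.report.fr_identity, c.record.gene, c.record.allele),
    )
    return CandidateRanking(tuple(ordered))


# ---------------------------------------------------------------------------
# Directory I/O  (FASTA, headers "GENE*ALLELE|SEGMENT|CHAIN|SPECIES")
# ---------------------------------------------------------------------------

_CHAIN_TAGS = {"VH": "VH", "VL_kappa": "VL"}
_TAG_CHAINS = {v: k for k, v in _CHAIN_TAGS.items()}


def write_germline_fasta(records, path) -> None:
    out = []
    for r in records:
        header = f"{r.label}|{r.segment}|{_CHAIN_TAGS[r.chain_kind]}|{r.species.replace(' ', '_')}"
        out.append(SeqRecord(Seq(r.gapped_sequence), id=header, description=""))
    SeqIO.write(out, path, "fasta")


def read_germline_fasta(path):
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 4 or parts[1] not in ("V", "J") or parts[2] not in _TAG_CHAINS:
            raise InputError(f"unrecognized germline FASTA header {rec.id!r}")
        gene, _, allele = parts[0].partition("*")
        records.append(
            GermlineRecord(
                gene=gene,
                allele=allele,
                segment=parts[1],
                chain_kind=_TAG_CHAINS[parts[2]],
                gapped_sequence=str(rec.seq),
                species=parts[3].replace("_", " "),
            )
        )
    return records


def ranking_table(ranking: CandidateRanking) -> str:
    """Tab-separated export of a candidate ranking."""
    header = [
        "gene", "allele", "overall_pct", "fr_pct",
        *(f"{r}_mismatches" for r in REGIONS),
        "accepted", "reason",
    ]
    lines = ["\t".join(header)]
    for c in ranking.candidates:
        row = [
            c.record.gene,
            c.record.allele,
            f"{c.report.overall_identity:.1f}",
            f"{c.report.fr_identity:.1f}",
            *(str(len(c.report.per_region_mismatches.get(r, ()))) for r in REGIONS),
            "yes" if c.accepted else "no",
            c.rejection_reason,
        ]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
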