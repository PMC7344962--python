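"""Antibody variable domains under IMGT unique numbering.

The IMGT unique numbering assigns every variable-domain residue a position in
1..128, with unoccupied positions (shorter CDR loops) represented as gaps.
This module provides the :class:`NumberedDomain` container, the FR/CDR
:class:`RegionScheme` with an extended-paratope mask, point
:class:`Mutation` records, and the operations that map raw sequences onto the
scheme and diff two numbered domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, DomainIncompatibilityError, InputError

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP_CHAR = "."

#: First and last IMGT position of a variable domain.
POSITION_MIN = 1
POSITION_MAX = 128

REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
FR_REGIONS = ("FR1", "FR2", "FR3", "FR4")
CDR_REGIONS = ("CDR1", "CDR2", "CDR3")

#: Default FR/CDR boundaries of the IMGT unique numbering (inclusive).
DEFAULT_BOUNDARIES = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 104),
    "CDR3": (105, 117),
    "FR4": (118, 128),
}

#: Default "slightly extended" paratope: each CDR grows by one position on its
#: N-terminal flank.  Position 39 (a classic framework design position on the
#: C strand) must stay in the framework, which rules out a symmetric +/-1
#: extension; the flank widths are configurable per CDR.
DEFAULT_PARATOPE_EXTENSION = {
    "CDR1": (1, 0),
    "CDR2": (1, 0),
    "CDR3": (1, 0),
}


@dataclass(frozen=True, order=True)
class Mutation:
    """A point substitution, expressed relative to a reference (wild-type)
    domain, e.g. ``VL-T8P``."""

    domain: str  # "VH" or "VL"
    from_aa: str
    imgt_position: int
    to_aa: str

    def __post_init__(self) -> None:
        if self.domain not in ("VH", "VL"):
            raise InputError(f"mutation domain must be VH or VL, got {self.domain!r}")
        for aa in (self.from_aa, self.to_aa):
            if aa not in STANDARD_AA:
                raise InputError(f"non-standard amino acid {aa!r} in mutation")
        if self.from_aa == self.to_aa:
            raise InputError(
                f"mutation at position {self.imgt_position} does not change the residue"
            )
        if not POSITION_MIN <= self.imgt_position <= POSITION_MAX:
            raise InputError(f"IMGT position {self.imgt_position} out of range")

    def __str__(self) -> str:
        return f"{self.domain}-{self.from_aa}{self.imgt_position}{self.to_aa}"

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        """Parse ``'VL-T8P'`` (or ``'T8P'`` with an explicit default domain
        via :meth:`parse_in_domain`)."""
        domain, _, body = text.partition("-")
        if not body:
            raise InputError(f"cannot parse mutation {text!r}: missing domain prefix")
        return cls.parse_in_domain(body, domain)

    @classmethod
    def parse_in_domain(cls, body: str, domain: str) -> "Mutation":
        if len(body) < 3:
            raise InputError(f"cannot parse mutation body {body!r}")
        return cls(domain, body[0], int(body[1:-1]), body[-1])

    def reversed(self) -> "Mutation":
        """The back-mutation (to_aa -> from_aa at the same position)."""
        return Mutation(self.domain, self.to_aa, self.imgt_position, self.from_aa)


@dataclass(frozen=True)
class RegionScheme:
    """FR/CDR interval boundaries plus per-CDR paratope extension flanks."""

    boundaries: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDARIES))
    paratope_extension: dict = field(
        default_factory=lambda: dict(DEFAULT_PARATOPE_EXTENSION)
    )

    def __post_init__(self) -> None:
        prev_end = 0
        for region in REGIONS:
            if region not in self.boundaries:
                raise InputError(f"region scheme missing {region}")
            start, end = self.boundaries[region]
            if not (start <= end and start == prev_end + 1):
                raise InputError(
                    f"region intervals must be ordered and contiguous; {region} "
                    f"starts at {start} after previous end {prev_end}"
                )
            prev_end = end
        if prev_end != POSITION_MAX or self.boundaries["FR1"][0] != POSITION_MIN:
            raise InputError("region intervals must cover 1..128 exactly")
        ext_intervals = [self.extended_interval(c) for c in CDR_REGIONS]
        for (a0, a1), (b0, b1) in zip(ext_intervals, ext_intervals[1:]):
            if a1 >= b0:
                raise InputError("extended paratope intervals overlap")

    def interval(self, region: str):
        return self.boundaries[region]

    def extended_interval(self, cdr: str):
        before, after = self.paratope_extension.get(cdr, (0, 0))
        start, end = self.boundaries[cdr]
        return (start - before, end + after)

    def region_of(self, position: int) -> str:
        for region in REGIONS:
            start, end = self.boundaries[region]
            if start <= position <= end:
                return region
        raise InputError(f"IMGT position {position} out of range")

    def positions(self, region: str) -> set:
        start, end = self.boundaries[region]
        return set(range(start, end + 1))

    def fr_positions(self) -> set:
        return set().union(*(self.positions(r) for r in FR_REGIONS))

    def cdr_positions(self) -> set:
        return set().union(*(self.positions(r) for r in CDR_REGIONS))

    def paratope_positions(self) -> set:
        """CDR union extended by the per-CDR flanks."""
        out: set = set()
        for cdr in CDR_REGIONS:
            start, end = self.extended_interval(cdr)
            out |= set(range(max(start, POSITION_MIN), min(end, POSITION_MAX) + 1))
        return out

    # -- plain key/value (de)serialization ---------------------------------

    def to_config_text(self) -> str:
        lines = []
        for region in REGIONS:
            s, e = self.boundaries[region]
            lines.append(f"{region} = {s}-{e}")
        for cdr in CDR_REGIONS:
            b, a = self.paratope_extension.get(cdr, (0, 0))
            lines.append(f"{cdr}_extension = {b},{a}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config_text(cls, text: str) -> "RegionScheme":
        boundaries = dict(DEFAULT_BOUNDARIES)
        extension = dict(DEFAULT_PARATOPE_EXTENSION)
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in REGIONS:
                s, e = value.split("-")
                boundaries[key] = (int(s), int(e))
            elif key.endswith("_extension") and key[:-10] in CDR_REGIONS:
                b, a = value.split(",")
                extension[key[:-10]] = (int(b), int(a))
            else:
                raise InputError(f"unknown region-scheme key {key!r}")
        return cls(boundaries, extension)


@dataclass(frozen=True)
class NumberedDomain:
    """A variable domain as an ordered list of (IMGT position, residue)."""

    chain_kind: str  # "VH" or "VL_kappa"
    residues: tuple  # tuple of (imgt_position, amino_acid)
    name: str = ""

    def __post_init__(self) -> None:
        if self.chain_kind not in ("VH", "VL_kappa"):
            raise InputError(f"unknown chain kind {self.chain_kind!r}")
        object.__setattr__(self, "residues", tuple(self.residues))
        prev = 0
        for pos, aa in self.residues:
            if pos <= prev:
                raise AlignmentError("IMGT positions must be strictly increasing")
            if not POSITION_MIN <= pos <= POSITION_MAX:
                raise InputError(f"IMGT position {pos} out of range")
            if aa not in STANDARD_AA:
                raise InputError(f"non-standard residue {aa!r} at position {pos}")
            prev = pos

    @property
    def domain_label(self) -> str:
        """'VH' or 'VL' -- the label used in mutation strings."""
        return "VH" if self.chain_kind == "VH" else "VL"

    @property
    def positions(self) -> tuple:
        return tuple(pos for pos, _ in self.residues)

    @property
    def occupied(self) -> frozenset:
        return frozenset(pos for pos, _ in self.residues)

    @property
    def gaps(self) -> frozenset:
        return frozenset(range(POSITION_MIN, POSITION_MAX + 1)) - self.occupied

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def aa_at(self, position: int):
        return dict(self.residues).get(position)

    def gapped_sequence(self) -> str:
        """Length-128 string with '.' at unoccupied positions."""
        by_pos = dict(self.residues)
        return "".join(
            by_pos.get(p, GAP_CHAR) for p in range(POSITION_MIN, POSITION_MAX + 1)
        )

    def with_substitutions(self, substitutions: dict, name: str = "") -> "NumberedDomain":
        """New domain with residues replaced at the given positions."""
        missing = set(substitutions) - self.occupied
        if missing:
            raise InputError(f"positions {sorted(missing)} not occupied in {self.name}")
        residues = tuple(
            (pos, substitutions.get(pos, aa)) for pos, aa in self.residues
        )
        return replace(self, residues=residues, name=name or self.name)

    def apply_mutations(self, mutations, name: str = "") -> "NumberedDomain":
        subs = {}
        for m in mutations:
            if m.domain != self.domain_label:
                raise DomainIncompatibilityError(
                    f"mutation {m} targets {m.domain}, domain is {self.domain_label}"
                )
            current = self.aa_at(m.imgt_position)
            if current != m.from_aa:
                raise InputError(
                    f"mutation {m}: position carries {current}, not {m.from_aa}"
                )
            subs[m.imgt_position] = m.to_aa
        return self.with_substitutions(subs, name=name)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def occupy_cdr_slots(start: int, end: int, n: int):
    """IMGT-style loop numbering: fill a CDR interval of slots [start, end]
    with n residues from both ends inward (extra residue on the N-terminal
    side for odd n); the gap sits in the middle of the loop."""
    width = end - start + 1
    if n < 0 or n > width:
        raise AlignmentError(f"cannot place {n} residues in a {width}-slot CDR")
    left = math.ceil(n / 2)
    right = n - left
    return list(range(start, start + left)) + list(range(end - right + 1, end + 1))


def number_sequence(
    raw_sequence: str, reference: NumberedDomain, scheme: RegionScheme
) -> NumberedDomain:
    """Map an ungapped sequence onto IMGT positions using a numbered
    reference as a gapped profile.

    Equal-length sequences map position-wise.  A length difference is
    absorbed inside a single CDR (tried CDR3, CDR1, CDR2; the placement
    maximizing framework identity to the reference wins); framework indels
    are rejected.
    """
    bad = set(raw_sequence) - STANDARD_AA
    if bad:
        raise InputError(f"non-standard characters in sequence: {sorted(bad)}")
    ref_len = len(reference)
    if abs(len(raw_sequence) - ref_len) > 15:
        raise AlignmentError(
            f"sequence length {len(raw_sequence)} too far from reference {ref_len}"
        )
    delta = len(raw_sequence) - ref_len
    if delta == 0:
        residues = tuple(zip(reference.positions, raw_sequence))
        return NumberedDomain(reference.chain_kind, residues, name="")

    # Try absorbing the whole indel in one CDR.
    ref_positions = list(reference.positions)
    fr_pos = scheme.fr_positions()
    best = None
    for cdr in ("CDR3", "CDR1", "CDR2"):
        start, end = scheme.interval(cdr)
        cdr_idx = [i for i, p in enumerate(ref_positions) if start <= p <= end]
        if not cdr_idx:
            continue
        n_new = len(cdr_idx) + delta
        if n_new < 0 or n_new > (end - start + 1):
            continue
        lo, hi = cdr_idx[0], cdr_idx[-1]
        new_cdr_positions = occupy_cdr_slots(start, end, n_new)
        positions = ref_positions[:lo] + new_cdr_positions + ref_positions[hi + 1 :]
        if len(positions) != len(raw_sequence):
            continue
        residues = tuple(zip(positions, raw_sequence))
        score = sum(
            1
            for (pos, aa), (rpos, raa) in zip(residues, reference.residues)
            if pos == rpos and pos in fr_pos and aa == raa
        )
        if best is None or score > best[0]:
            best = (score, residues)
    if best is None:
        raise AlignmentError(
            "length difference cannot be absorbed inside a CDR (framework indel)"
        )
    return NumberedDomain(reference.chain_kind, best[1], name="")


def mutations_between(a: NumberedDomain, b: NumberedDomain):
    """One :class:`Mutation` per position where ``b`` differs from ``a``,
    ordered by IMGT position."""
    if a.chain_kind != b.chain_kind:
        raise DomainIncompatibilityError(
            f"chain kinds differ: {a.chain_kind} vs {b.chain_kind}"
        )
    if a.occupied != b.occupied:
        raise DomainIncompatibilityError("occupied IMGT position sets differ")
    b_at = dict(b.residues)
    return [
        Mutation(a.domain_label, aa, pos, b_at[pos])
        for pos, aa in a.residues
        if b_at[pos] != aa
    ]


def paratope_mask(domain: NumberedDomain, scheme: RegionScheme) -> set:
    """Occupied positions of the domain that fall in the extended paratope."""
    return set(domain.occupied) & scheme.paratope_positions()


# ---------------------------------------------------------------------------
# FASTA I/O  (header convention ">NAME|VH|IMGT", gapped to 128 columns)
# ---------------------------------------------------------------------------

_CHAIN_TAGS = {"VH": "VH", "VL_kappa": "VL"}
_TAG_CHAINS = {"VH": "VH", "VL": "VL_kappa"}


def write_domains_fasta(domains, path) -> None:
    records = []
    for d in domains:
        header = f"{d.name}|{_CHAIN_TAGS[d.chain_kind]}|IMGT"
        records.append(SeqRecord(Seq(d.gapped_sequence()), id=header, description=""))
    SeqIO.write(records, path, "fasta")


def read_domains_fasta(path):
    domains = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3 or parts[2] != "IMGT" or parts[1] not in _TAG_CHAINS:
            raise InputError(f"unrecognized domain FASTA header {rec.id!r}")
        seq = str(rec.seq)
        if len(seq) != POSITION_MAX:
            raise InputError(
                f"{rec.id}: gapped domain sequence must have {POSITION_MAX} columns"
            )
        residues = tuple(
            (i + 1, aa) for i, aa in enumerate(seq) if aa != GAP_CHAR
        )
        domains.append(
            NumberedDomain(_TAG_CHAINS[parts[1]], residues, name=parts[0])
        )
    return domains
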