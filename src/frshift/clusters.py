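"""Partition framework substitutions into spatial/sequence clusters.

Cluster I collects VH substitutions close to the paratope in 3D, cluster II
the substitutions on the loop connecting the C and C' strands (IMGT VH
45-49), cluster III every other VH substitution, and cluster IV all VL
substitutions.  Proximity is measured as the minimum heavy-atom distance to
any paratope residue in an Fv structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError, StructuralGapError
from .imgt import Mutation, RegionScheme

#: Default interval of the loop connecting the C and C' strands of VH.
DEFAULT_CC_LOOP = (45, 49)
#: Default heavy-atom distance cutoff (Angstrom) for "close to CDRs".
DEFAULT_PROXIMITY_CUTOFF = 5.0

CLUSTERS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class FvStructure:
    """Minimal Fv coordinate set: (chain, IMGT position, atom name, xyz)."""

    atoms: tuple  # tuple of (chain, imgt_position, atom_name, (x, y, z))
    source: str = ""

    def __post_init__(self) -> None:
        for chain, pos, _name, xyz in self.atoms:
            if chain not in ("H", "L"):
                raise InputError(f"chain must be H or L, got {chain!r}")
            if not all(np.isfinite(xyz)):
                raise InputError(f"non-finite coordinates at {chain}{pos}")

    def coords_for(self, chain: str, imgt_position: int) -> np.ndarray:
        pts = [
            xyz
            for c, p, _n, xyz in self.atoms
            if c == chain and p == imgt_position
        ]
        if not pts:
            raise StructuralGapError(
                f"no coordinates for residue {chain}{imgt_position} in {self.source or 'structure'}"
            )
        return np.asarray(pts, dtype=float)

    def residues_present(self, chain: str) -> set:
        return {p for c, p, _n, _xyz in self.atoms if c == chain}

    def transformed(self, rotation: np.ndarray, translation) -> "FvStructure":
        """Rigid-body transform of every atom (for invariance checks)."""
        rot = np.asarray(rotation, dtype=float)
        tr = np.asarray(translation, dtype=float)
        atoms = tuple(
            (c, p, n, tuple(rot @ np.asarray(xyz) + tr))
            for c, p, n, xyz in self.atoms
        )
        return FvStructure(atoms, source=self.source)


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of a mutation set into clusters I-IV, with evidence."""

    assignment: dict  # Mutation -> cluster label
    evidence: dict  # Mutation -> (min_distance or None, in_cc_loop)

    def cluster(self, label: str):
        return sorted(
            (m for m, c in self.assignment.items() if c == label),
            key=lambda m: (m.domain, m.imgt_position),
        )

    def counts(self) -> dict:
        return {c: len(self.cluster(c)) for c in CLUSTERS}


def min_distance_to_paratope(
    structure: FvStructure, position, paratope
) -> float:
    """Minimum Euclidean heavy-atom distance (Angstrom) from one residue to
    any residue of the paratope set.

    ``position`` and the paratope entries are (chain, imgt_position) pairs.
    """
    if not paratope:
        raise InputError("paratope set is empty")
    chain, pos = position
    own = structure.coords_for(chain, pos)
    best = np.inf
    for pchain, ppos in paratope:
        if (pchain, ppos) == (chain, pos):
            return 0.0
        try:
            pts = structure.coords_for(pchain, ppos)
        except StructuralGapError:
            continue
        d = np.sqrt(((own[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).min()
        best = min(best, d)
    if not np.isfinite(best):
        raise StructuralGapError("no paratope residue has coordinates")
    return float(best)


def assign_clusters(
    mutations,
    structure: FvStructure | None,
    scheme: RegionScheme,
    cc_loop: tuple = DEFAULT_CC_LOOP,
    proximity_cutoff: float = DEFAULT_PROXIMITY_CUTOFF,
    paratope: set | None = None,
    cluster_i_positions: set | None = None,
) -> ClusterAssignment:
    """Assign each mutation to exactly one cluster.

    Rules, in order: VL mutations -> IV; VH mutations inside the C-C' loop
    interval -> II (loop membership is a sequence criterion and wins over
    proximity); VH mutations within ``proximity_cutoff`` of the paratope
    -> I; everything else -> III.  Without a structure, cluster I must be
    supplied explicitly as ``cluster_i_positions``.
    """
    lo, hi = cc_loop
    vh_muts = [m for m in mutations if m.domain == "VH"]
    needs_proximity = [m for m in vh_muts if not lo <= m.imgt_position <= hi]
    if structure is None and cluster_i_positions is None and needs_proximity:
        raise ConfigurationError(
            "no Fv structure given: supply cluster_i_positions (an explicit set of "
            "VH IMGT positions considered CDR-proximal) to assign clusters I/III"
        )
    if structure is not None and paratope is None:
        paratope = {
            ("H", p)
            for p in scheme.paratope_positions() & structure.residues_present("H")
        } | {
            ("L", p)
            for p in scheme.paratope_positions() & structure.residues_present("L")
        }

    assignment: dict = {}
    evidence: dict = {}
    for m in mutations:
        dist = None
        in_loop = m.domain == "VH" and lo <= m.imgt_position <= hi
        if m.domain == "VL":
            label = "IV"
        elif in_loop:
            label = "II"
        else:
            if structure is not None:
                dist = min_distance_to_paratope(structure, ("H", m.imgt_position), paratope)
                label = "I" if dist <= proximity_cutoff else "III"
            else:
                label = "I" if m.imgt_position in cluster_i_positions else "III"
        assignment[m] = label
        evidence[m] = (dist, in_loop)
    return ClusterAssignment(assignment, evidence)


def assignment_table(assignment: ClusterAssignment) -> str:
    """Tab-separated export: mutation, cluster, distance, in_loop."""
    lines = ["mutation\tcluster\tmin_distance_A\tin_cc_loop"]
    for m in sorted(assignment.assignment, key=lambda m: (m.domain, m.imgt_position)):
        dist, in_loop = assignment.evidence[m]
        lines.append(
            "\t".join(
                [
                    str(m),
                    assignment.assignment[m],
                    "" if dist is None else f"{dist:.2f}",
                    "yes" if in_loop else "no",
                ]
            )
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------


def read_fv_structure(path, chain_map: dict | None = None) -> FvStructure:
    """Read ATOM records from a PDB file into an :class:`FvStructure`.

    ``chain_map`` maps PDB chain identifiers to 'H'/'L' (default: chains H
    and L kept as themselves).  Only altloc '' or 'A' atoms are kept;
    residue numbers are taken as IMGT positions (renumber beforehand).
    """
    import gemmi

    chain_map = chain_map or {"H": "H", "L": "L"}
    st = gemmi.read_pdb(str(path))
    atoms = []
    model = st[0]
    for chain in model:
        if chain.name not in chain_map:
            continue
        kind = chain_map[chain.name]
        for residue in chain:
            if residue.het_flag != "A":  # ATOM records only
                continue
            for atom in residue:
                if atom.altloc not in ("", "\x00", "A"):
                    continue
                if atom.element == gemmi.Element("H"):
                    continue
                atoms.append(
                    (
                        kind,
                        residue.seqid.num,
                        atom.name,
                        (atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
    return FvStructure(tuple(atoms), source=str(path))
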