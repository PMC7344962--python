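"""Synthetic fixtures: toy germline directory, parental Fv with planted
cluster geometry, two-state melting/denaturation spectra, and noisy
single-cycle sensorgrams.

Every generator is a pure, seeded function of its configuration.  The
parental VH/VL sequences are synthetic stand-ins: they carry the named
design mutations at the correct IMGT positions (cluster I: L39M, E69Q,
L78M, A80V, T82K; cluster II: positions 45-49 mutated to RPGHG; the four VL
substitutions V4M, R24S, Q96P, F103Y and the Protein-L mutation T8P), while
the nine cluster-III substitutions are synthetic placeholders chosen to
reproduce the design's 2/6/8/3 FR1-FR4 distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clusters import FvStructure
from .errors import InputError
from .germline import GermlineRecord, J_SPAN, V_SPAN
from .imgt import (
    GAP_CHAR,
    Mutation,
    NumberedDomain,
    RegionScheme,
    occupy_cdr_slots,
)
from .spr import (
    InjectionSchedule,
    KineticModelParams,
    Sensorgram,
    simulate_sensorgram,
)
from .stability import SpectrumSeries

GAS_CONSTANT = 8.314  # J mol^-1 K^-1

# ---------------------------------------------------------------------------
# The packaged design: named + placeholder mutations
# ---------------------------------------------------------------------------

#: CDR-proximal VH substitutions (cluster I).
CLUSTER_I_MUTATIONS = (
    ("L", 39, "M"), ("E", 69, "Q"), ("L", 78, "M"), ("A", 80, "V"), ("T", 82, "K"),
)
#: C-C' loop substitutions (cluster II): parent SASQT -> RPGHG at 45-49.
CLUSTER_II_MUTATIONS = (
    ("S", 45, "R"), ("A", 46, "P"), ("S", 47, "G"), ("Q", 48, "H"), ("T", 49, "G"),
)
#: Synthetic cluster-III placeholders (2 FR1, 4 FR3, 3 FR4).
CLUSTER_III_MUTATIONS = (
    ("Q", 5, "E"), ("S", 13, "T"),
    ("K", 71, "R"), ("N", 84, "S"), ("D", 87, "E"), ("I", 90, "V"),
    ("T", 119, "S"), ("L", 120, "V"), ("S", 123, "A"),
)
#: VL substitutions introduced by the framework graft.
VL_GRAFT_MUTATIONS = (
    ("V", 4, "M"), ("R", 24, "S"), ("Q", 96, "P"), ("F", 103, "Y"),
)
#: The Protein-L recognition substitution (applied after grafting).
VL_PPL_MUTATION = ("T", 8, "P")

VH_DESIGN = CLUSTER_I_MUTATIONS + CLUSTER_II_MUTATIONS + CLUSTER_III_MUTATIONS

#: Occupied CDR lengths of the toy parent (IMGT slots filled middle-out).
VH_CDR_LENGTHS = {"CDR1": 8, "CDR2": 7, "CDR3": 10}
VL_CDR_LENGTHS = {"CDR1": 6, "CDR2": 3, "CDR3": 6}

_AA_CYCLE = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    vh_length: int = 118
    vl_length: int = 108
    directory_size: int = 20
    n_j_records: int = 4
    spectrum_noise_sd: float = 100.0  # counts per replicate
    sensorgram_noise_sd: float = 2.0  # RU
    replicates: int = 4


def _occupied_positions(scheme: RegionScheme, cdr_lengths: dict):
    positions = sorted(scheme.fr_positions())
    for cdr, n in cdr_lengths.items():
        start, end = scheme.interval(cdr)
        positions.extend(occupy_cdr_slots(start, end, n))
    return sorted(positions)


def _base_aa(position: int, offset: int) -> str:
    return _AA_CYCLE[(position * 3 + offset) % 20]


def _parent_domain(chain_kind: str, scheme: RegionScheme, name: str) -> NumberedDomain:
    if chain_kind == "VH":
        cdr_lengths, offset = VH_CDR_LENGTHS, 0
        overrides = {pos: aa for aa, pos, _to in VH_DESIGN}
        overrides.update({42: "V", 103: "Y"})  # interface / stability residues
    else:
        cdr_lengths, offset = VL_CDR_LENGTHS, 7
        overrides = {pos: aa for aa, pos, _to in VL_GRAFT_MUTATIONS}
        overrides[VL_PPL_MUTATION[1]] = VL_PPL_MUTATION[0]
    positions = _occupied_positions(scheme, cdr_lengths)
    residues = tuple(
        (p, overrides.get(p, _base_aa(p, offset))) for p in positions
    )
    return NumberedDomain(chain_kind, residues, name=name)


def make_parent_vh(scheme: RegionScheme | None = None) -> NumberedDomain:
    """Synthetic 118-residue parental VH ('VH A' stand-in)."""
    return _parent_domain("VH", scheme or RegionScheme(), "VH-A")


def make_parent_vl(scheme: RegionScheme | None = None) -> NumberedDomain:
    """Synthetic 108-residue parental kappa VL ('VL 0' stand-in)."""
    return _parent_domain("VL_kappa", scheme or RegionScheme(), "VL-0")


def design_mutations():
    """The full design set: (VH mutation list, VL graft mutation list)."""
    vh = [Mutation("VH", f, p, t) for f, p, t in VH_DESIGN]
    vl = [Mutation("VL", f, p, t) for f, p, t in VL_GRAFT_MUTATIONS]
    return vh, vl


# ---------------------------------------------------------------------------
# Toy germline directory
# ---------------------------------------------------------------------------


def _gapped(domain_map: dict, span) -> str:
    start, end = span
    return "".join(domain_map.get(p, GAP_CHAR) for p in range(start, end + 1))


def _mutate_map(base: dict, subs: dict) -> dict:
    out = dict(base)
    for pos, aa in subs.items():
        if pos in out:
            out[pos] = aa
    return out


def _shift_aa(aa: str, step: int = 5) -> str:
    return _AA_CYCLE[(_AA_CYCLE.index(aa) + step) % 20]


def make_toy_germline_directory(config: FixtureConfig, chain_kind: str = "VH",
                                scheme: RegionScheme | None = None):
    """A seeded toy V/J directory with controlled mismatch structure.

    Plants (i) a best V donor carrying exactly the packaged design's
    FR1-FR3 substitutions, (ii) one record violating the FR1 rule with five
    FR1 mismatches, and (iii) decoys with 18-24 framework mismatches placed
    in FR2/FR3.  J records include an FR4-identical segment and one carrying
    the design's three FR4 substitutions.
    """
    if config.directory_size < 5:
        raise InputError("directory_size must be >= 5")
    scheme = scheme or RegionScheme()
    rng = np.random.default_rng(config.seed)
    if chain_kind == "VH":
        parent = make_parent_vh(scheme)
        gene_v, gene_j = "IGHVS", "IGHJS"
        v_design = {p: t for _f, p, t in VH_DESIGN if p <= V_SPAN[1]}
        j_design = {p: t for _f, p, t in VH_DESIGN if p >= J_SPAN[0]}
        protected = {42, 103}
    else:
        parent = make_parent_vl(scheme)
        gene_v, gene_j = "IGKVS", "IGKJS"
        v_design = {p: t for _f, p, t in VL_GRAFT_MUTATIONS if p <= V_SPAN[1]}
        j_design = {}
        protected = {103}
    base = dict(parent.residues)

    records = []

    def add_v(gene, allele, subs):
        records.append(
            GermlineRecord(
                gene=gene, allele=allele, segment="V", chain_kind=chain_kind,
                gapped_sequence=_gapped(_mutate_map(base, subs), V_SPAN),
            )
        )

    # planted best donor: the design's V-segment substitutions
    add_v(f"{gene_v}1-1", "01", v_design)
    # planted FR1-rule violator: five FR1 mismatches
    fr1_positions = (2, 3, 11, 12, 14)
    add_v(f"{gene_v}9-9", "01", {p: _shift_aa(base[p]) for p in fr1_positions})
    # decoys: many mismatches confined to FR2/FR3, sparing protected residues
    fr23 = sorted(
        (scheme.positions("FR2") | scheme.positions("FR3"))
        & parent.occupied - protected
    )
    for i in range(config.directory_size - 2):
        n_mut = int(rng.integers(18, 25))
        chosen = rng.choice(fr23, size=n_mut, replace=False)
        add_v(f"{gene_v}2-{i + 1}", "01", {int(p): _shift_aa(base[int(p)]) for p in chosen})

    # J records
    def add_j(gene, allele, subs):
        records.append(
            GermlineRecord(
                gene=gene, allele=allele, segment="J", chain_kind=chain_kind,
                gapped_sequence=_gapped(_mutate_map(base, subs), J_SPAN),
            )
        )

    fr4 = sorted(scheme.positions("FR4") & parent.occupied)
    # nearest J donor: carries exactly the design's FR4 substitutions
    # (for the light chain the design leaves FR4 unchanged)
    add_j(f"{gene_j}2", "01", j_design)
    # a slightly worse alternative with one extra FR4 mismatch
    extra = next(p for p in fr4 if p not in j_design)
    add_j(f"{gene_j}3", "01", {**j_design, extra: _shift_aa(base[extra])})
    for i in range(max(0, config.n_j_records - 2)):
        n_mut = 5 + i
        chosen = rng.choice(fr4, size=min(n_mut, len(fr4)), replace=False)
        add_j(f"{gene_j}{4 + i}", "01", {int(p): _shift_aa(base[int(p)]) for p in chosen})
    return records


# ---------------------------------------------------------------------------
# Toy Fv structure
# ---------------------------------------------------------------------------


def make_parental_fv(config: FixtureConfig | None = None,
                     scheme: RegionScheme | None = None):
    """(VH, VL, toy Fv structure) with planted cluster geometry.

    C-alpha-only coordinates place every extended-paratope residue in a
    compact patch near the origin, cluster-I positions within ~3 A of the
    patch, and all remaining framework residues tens of Angstroms away, so
    proximity-based cluster assignment is unambiguous.  One C-C' loop
    residue (position 45) is also placed close to the paratope to exercise
    the loop-wins tie rule.
    """
    scheme = scheme or RegionScheme()
    vh = make_parent_vh(scheme)
    vl = make_parent_vl(scheme)
    paratope = scheme.paratope_positions()
    cluster_i = {p for _f, p, _t in CLUSTER_I_MUTATIONS}
    loop = set(range(45, 50))

    atoms = []
    k_par = 0
    k_far = 0
    for chain, domain in (("H", vh), ("L", vl)):
        for pos, _aa in domain.residues:
            if pos in paratope:
                xyz = (0.5 * k_par, 0.0, 0.0)
                k_par += 1
            elif chain == "H" and pos in cluster_i:
                xyz = (0.0, 3.0, 0.01 * pos)
            elif chain == "H" and pos == 45:
                xyz = (0.0, 3.5, 0.0)  # loop residue that is also CDR-proximal
            else:
                base_y = 50.0 if chain == "H" else -50.0
                xyz = (0.0, base_y + (1.0 if base_y > 0 else -1.0) * k_far, 0.0)
                k_far += 1
            atoms.append((chain, pos, "CA", xyz))
    return vh, vl, FvStructure(tuple(atoms), source="toy-fv (synthetic)")


# ---------------------------------------------------------------------------
# Two-state spectra
# ---------------------------------------------------------------------------

#: Emission band centers/width of the folded and unfolded states (nm).
FOLDED_BAND_NM = 335.0
UNFOLDED_BAND_NM = 355.0
BAND_SIGMA_NM = 12.0
PEAK_COUNTS = 1.0e4

#: Default thermal van 't Hoff enthalpy (J/mol) and chemical m-value (J/mol/M).
DEFAULT_DELTA_H = 5.0e5
DEFAULT_M_VALUE = 1.5e4
#: Incubation temperature of the chemical titration (K).
DENATURATION_TEMPERATURE_K = 310.15

DEFAULT_MELT_GRID = np.arange(25.0, 98.0, 4.0)  # 25-97 degC, 19 points
DEFAULT_DENAT_GRID = np.arange(0.0, 5.01, 0.25)  # 0-5 M, 21 points
DEFAULT_WAVELENGTHS = np.arange(310.0, 411.0, 1.0)  # 101 points


def fraction_unfolded_thermal(temperature_C, tm_C: float, delta_h: float = DEFAULT_DELTA_H):
    """Two-state van 't Hoff unfolded fraction along a temperature ramp."""
    t = np.asarray(temperature_C, dtype=float) + 273.15
    tm = tm_C + 273.15
    return 1.0 / (1.0 + np.exp(delta_h / GAS_CONSTANT * (1.0 / t - 1.0 / tm)))


def fraction_unfolded_chemical(
    denaturant_M, dc50_M: float, m_value: float = DEFAULT_M_VALUE,
    temperature_K: float = DENATURATION_TEMPERATURE_K,
):
    """Linear-extrapolation two-state unfolded fraction vs denaturant."""
    d = np.asarray(denaturant_M, dtype=float)
    rt = GAS_CONSTANT * temperature_K
    return 1.0 / (1.0 + np.exp(-m_value * (d - dc50_M) / rt))


def _two_state_series(
    axis_kind, axis, fraction, wavelengths, noise_sd, replicates, rng
) -> SpectrumSeries:
    wl = np.asarray(wavelengths, dtype=float)
    folded = np.exp(-0.5 * ((wl - FOLDED_BAND_NM) / BAND_SIGMA_NM) ** 2)
    unfolded = np.exp(-0.5 * ((wl - UNFOLDED_BAND_NM) / BAND_SIGMA_NM) ** 2)
    clean = PEAK_COUNTS * (
        (1.0 - fraction)[:, None] * folded[None, :]
        + fraction[:, None] * unfolded[None, :]
    )
    total = np.zeros_like(clean)
    for _ in range(replicates):
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
        total += np.clip(noisy, 0.0, None)
    return SpectrumSeries(
        axis_kind=axis_kind,
        axis_values=np.asarray(axis, dtype=float),
        wavelengths=wl,
        intensities=total,
        replicates_summed=replicates,
    )


def simulate_melt_series(
    true_midpoint: float = 60.9,
    delta_h: float = DEFAULT_DELTA_H,
    temperatures=None,
    wavelengths=None,
    noise_sd: float = 100.0,
    replicates: int = 4,
    seed: int = 0,
) -> SpectrumSeries:
    """Thermal two-state emission series on the standard ramp."""
    temps = DEFAULT_MELT_GRID if temperatures is None else np.asarray(temperatures, float)
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    if not temps[0] <= true_midpoint <= temps[-1]:
        raise InputError("true midpoint lies outside the temperature grid")
    frac = fraction_unfolded_thermal(temps, true_midpoint, delta_h)
    rng = np.random.default_rng(seed)
    return _two_state_series("temperature_C", temps, frac, wl, noise_sd, replicates, rng)


def simulate_denat_series(
    true_midpoint: float = 2.6,
    m_value: float = DEFAULT_M_VALUE,
    concentrations=None,
    wavelengths=None,
    noise_sd: float = 100.0,
    replicates: int = 4,
    seed: int = 0,
) -> SpectrumSeries:
    """Chemical-denaturation two-state emission series on the 0-5 M grid."""
    conc = DEFAULT_DENAT_GRID if concentrations is None else np.asarray(concentrations, float)
    wl = DEFAULT_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, float)
    if not conc[0] <= true_midpoint <= conc[-1]:
        raise InputError("true midpoint lies outside the denaturant grid")
    frac = fraction_unfolded_chemical(conc, true_midpoint, m_value)
    rng = np.random.default_rng(seed)
    return _two_state_series("denaturant_M", conc, frac, wl, noise_sd, replicates, rng)


# ---------------------------------------------------------------------------
# Sensorgrams
# ---------------------------------------------------------------------------

#: Default true kinetics: Kd = kd1/ka1 = 2e-7 M.
DEFAULT_KINETICS = KineticModelParams(
    "langmuir_1to1", ka1=1.0e5, kd1=2.0e-2, rmax=100.0
)


def simulate_noisy_sensorgram(
    params: KineticModelParams = DEFAULT_KINETICS,
    schedule: InjectionSchedule = InjectionSchedule(),
    noise_sd: float = 2.0,
    dt: float = 0.05,
    seed: int = 0,
) -> Sensorgram:
    """A noisy single-cycle sensorgram under the standard schedule."""
    return simulate_sensorgram(params, schedule, dt=dt, noise_sd=noise_sd, seed=seed)
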