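# Methods

This note documents the models, assumptions, parameter choices, and known
limitations of the `frshift` toolkit. All numerical values quoted here are
package defaults, defined in code (`frshift.imgt`, `frshift.clusters`,
`frshift.stability`, `frshift.spr`, `frshift.synthetic`).

## Domain representation and numbering

Variable domains are stored as sparse maps from IMGT unique-numbering
positions (1–128) to amino acids. Region boundaries (defaults): FR1 1–26,
CDR1 27–38, FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117, FR4 118–128.
Gaps are permitted only inside CDRs and follow the IMGT middle-out
convention: a loop of length *n* occupies ⌈n/2⌉ slots from the CDR start and
⌊n/2⌋ slots from the CDR end, leaving the gap in the middle.

Renumbering a variant against a reference assumes the variant is a
framework-compatible relative: equal-length sequences are mapped
positionally, and a length difference is absorbed entirely within one CDR
(CDR3, then CDR1, then CDR2 are tried; the placement maximizing framework
agreement wins). Sequences that cannot be explained this way are rejected
rather than force-aligned — the toolkit is not a general aligner.

**Extended paratope.** The positions grafting must preserve are the CDRs
plus a per-CDR framework flank. The default extension is one position on
the N-terminal side of each CDR and none on the C-terminal side. Rationale:
the residue preceding a CDR caps the loop conformation, while the framework
position immediately after CDR1 (IMGT 39) is a buried interface position
that framework-shifting deliberately does mutate; a symmetric ±1 flank
would wrongly freeze it. The extension is configurable per CDR.

## Germline identity and selection

Identity between a query domain and a candidate is computed over the
positions occupied in both (V segments span IMGT 1–104, J segments
118–128), as `100·(L−n)/L` for `n` mismatches over `L` compared positions,
rounded half-up to one decimal (decimal arithmetic, not binary float
rounding, so 83.85 → 83.9 deterministically). Scoring modes: `overall`
(all shared positions), `fr_only` (framework positions only), and `design`
(framework positions outside the extended paratope — the set a graft can
actually change).

Hard filters applied before ranking (defaults): at most 4 FR1 mismatches
(FR1 carries the Protein-L binding site on kappa chains, and heavy FR1
mismatches there are poorly tolerated); required residues VH 103 Y and
VH 42 V, VL 103 Y (conserved core/interface positions). Accepted candidates
are sorted by descending framework identity, then by fewer FR1+FR2
mismatches, then lexically by gene and allele for a deterministic order.

## Framework grafting and the variant series

The V donor supplies FR1–FR3, the J donor FR4; extended-paratope positions
are never transferred. A donor gap at a framework position the parent
occupies is an error (no deletion designs). The output is both the grafted
domain and the parent-relative mutation list.

Designed substitutions are clustered: **II** if the VH position lies in the
C-C′ loop (IMGT 45–49, checked first, so the loop rule wins ties), **I** if
the VH residue's minimum heavy-atom distance to any extended-paratope
residue is ≤ 5.0 Å, **III** for all other VH positions, **IV** for all VL
positions. The 5.0 Å cutoff is a conventional heavy-atom contact threshold;
assignments are invariant under rigid-body motion of the structure and
monotone in the cutoff. Without coordinates, cluster I membership must be
given explicitly — the toolkit refuses to guess.

Variant names are `S1<letter><digit>`: letters keep VH cluster unions
(A = ∅, B = III, C = II, D = II∪III, Z = I∪II∪III); digits walk the VL
lattice (0 wild type; 9 full graft; 8 graft + T8P; 4 drops the secondary
Protein-L position 24 substitution; 3/2 drop the position 96/position 4
graft substitutions from 4; 1 keeps only T8P and F103Y). The default series
is the twelve-construct design set. scFv assembly joins VH, a (G₄S)₃
linker, VL, and an 11-residue GGGAS-His₆ tag. Molecular weight and pI come
from Biopython's `ProteinAnalysis` (Bjellqvist pKa set; note Biopython
clamps pI to [4.05, 12]); ε₂₈₀ = 5500·nW + 1490·nY M⁻¹cm⁻¹ (reduced
cysteines assumed).

## Stability readouts

A spectrum series is a matrix of fluorescence intensities over a wavelength
grid (default 310–410 nm, 1 nm step) at each axis value (temperature or
denaturant). Replicates (default 4) are summed, not averaged; the spectral
centroid Σλ·I/ΣI is scale-invariant, so the distinction does not affect the
midpoint. The midpoint (Tm or DC50) is the extremum of the centroid curve's
first derivative. Two refinement modes: `grid` (finite differences on the
native axis; the midpoint is the center of the steepest interval, so
resolution is half the experimental step) and `spline` (derivative of a
cubic spline, maximized on a 0.01-step grid; used for reported values).
A centroid range below 10⁻³ nm is treated as "no transition" and rejected
rather than returning a spurious extremum.

## SPR kinetics

Single-cycle schedules inject increasing analyte concentrations (default
7.5, 22, 66, 200, 600 nM) for 60 s each, followed by 600 s of dissociation.
Models: 1:1 Langmuir (dR/dt = ka·C·(Rmax−R) − kd·R) and two-state binding
with a conformational change (AB ⇌ AB\*; equilibrium
Kd = (kd1/ka1)·kd2/(kd2+ka2)). Because the analyte concentration is
piecewise constant, both models are linear ODEs per phase and are solved
exactly (scalar exponential; 2×2 eigendecomposition) instead of by a
generic time stepper — no discretization error, and fits run in well under
a second. Fitting minimizes least squares over log₁₀-parameters within
broad physical bounds (`scipy.optimize.least_squares`, trust-region
reflective); initial guesses come from the trace itself (tail log-slope for
kd, plateau for Rmax). A fit whose amplitude is negligible is reported as
non-converged rather than raising.

## Synthetic data (study conditions)

The packaged fixtures define the study conditions and are fixed a priori:

- Parent domains: VH 118 aa (CDR lengths 8/7/10), VL kappa 108 aa (6/3/6);
  residues follow a deterministic 20-letter cycle with named overrides so
  every design mutation has a defined wild-type residue.
- Design: 19 VH substitutions (2/6/8/3 across FR1–FR4) and 4 VL graft
  substitutions plus the Protein-L T8P, partitioning 5/5/9/5 into clusters
  I–IV.
- Germline directory: 20 V records per chain — a planted best donor
  carrying exactly the design's V-segment substitutions, one FR1-rule
  violator (5 FR1 mismatches), and decoys with 18–24 FR2/FR3 mismatches
  sparing the required residues; 4 J records, the nearest carrying exactly
  the design's FR4 substitutions (three for VH, none for VL).
- Structure: a Cα-only toy geometry with cluster-I residues placed within
  the 5 Å cutoff and cluster-III residues far outside; it encodes the
  intended distance relations, not protein geometry.
- Thermal melts: two-state van't Hoff model, f_unfolded =
  1/(1+exp(ΔH/R·(1/T−1/Tm))) with ΔH = 5·10⁵ J/mol; grid 25–97 °C, 4 °C
  step. Chemical denaturation: linear-extrapolation model,
  f = 1/(1+exp(−m(D−DC50)/RT)) with m = 1.5·10⁴ J mol⁻¹ M⁻¹ at 310.15 K;
  grid 0–5 M, 0.25 M step. Spectra are two Gaussian bands (335 nm folded,
  355 nm unfolded, σ = 12 nm, 10⁴ peak counts) with additive Gaussian noise
  (σ = 100 counts per replicate), 4 replicates summed, clipped at zero.
- Sensorgrams: defaults ka = 10⁵ M⁻¹s⁻¹, kd = 2·10⁻² s⁻¹, Rmax = 100 RU,
  Gaussian noise σ = 2 RU, sampled at 20 Hz.

All stochastic fixtures are seeded (`numpy.random.default_rng`); the same
seed reproduces byte-identical outputs.

## Limitations

- The numbering routine handles framework-compatible relatives of a
  reference, not arbitrary sequences; insertions outside CDRs are rejected.
- The toy structure supports distance-rule logic only; no packing, SASA, or
  interface energetics are modeled.
- Stability models are strictly two-state with temperature-independent ΔH
  and linear m-value; aggregation, irreversibility, and baseline slopes in
  the unfolded spectra are not modeled.
- SPR models ignore mass transport, drift, and bulk refractive-index jumps;
  baseline subtraction is a constant-plus-drift correction supplied by the
  caller.
- pI values inherit Biopython's bisection bounds (clamped to [4.05, 12])
  and the Bjellqvist pKa set's assumptions (no structural environment
  effects).
- The synthetic study reproduces the *procedures* and their arithmetic, not
  laboratory measurements: expression yields, per-variant stability
  differences, and binding differences between constructs have no synthetic
  counterpart here.
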