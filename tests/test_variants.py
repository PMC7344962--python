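"""Grafting, Protein-L mutations, variant enumeration, scFv assembly."""

from collections import Counter

import numpy as np
import pytest
from Bio.SeqUtils.IsoelectricPoint import (
    negative_pKs,
    pKcterminal,
    pKnterminal,
    positive_pKs,
)
from scipy.optimize import brentq

from frshift.clusters import assign_clusters
from frshift.errors import GraftingError, InputError
from frshift.germline import GermlineRecord, V_SPAN
from frshift.imgt import GAP_CHAR, Mutation, mutations_between
from frshift.synthetic import VH_DESIGN, VL_GRAFT_MUTATIONS
from frshift.variants import (
    DEFAULT_LINKER,
    DEFAULT_TAG,
    VariantNaming,
    apply_ppl_mutations,
    assemble_scfv,
    enumerate_backmutants,
    graft_frameworks,
    protein_params,
    realize_variant,
)


def record_from_domain(domain, segment, substitutions=None, gene="X", allele="01"):
    base = dict(domain.residues)
    base.update(substitutions or {})
    start, end = V_SPAN if segment == "V" else (118, 128)
    seq = "".join(base.get(p, GAP_CHAR) for p in range(start, end + 1))
    return GermlineRecord(
        gene=gene, allele=allele, segment=segment,
        chain_kind=domain.chain_kind, gapped_sequence=seq,
    )


class TestGraftFrameworks:
    def test_identical_donor_changes_nothing(self, scheme, parent_vh):
        v = record_from_domain(parent_vh, "V")
        j = record_from_domain(parent_vh, "J")
        grafted, muts = graft_frameworks(parent_vh, v, j, scheme)
        assert muts == [] and grafted.sequence == parent_vh.sequence

    def test_packaged_design_distribution(self, scheme, parent_vh):
        v_subs = {p: t for _f, p, t in VH_DESIGN if p <= V_SPAN[1]}
        j_subs = {p: t for _f, p, t in VH_DESIGN if p >= 118}
        v = record_from_domain(parent_vh, "V", v_subs)
        j = record_from_domain(parent_vh, "J", j_subs)
        grafted, muts = graft_frameworks(parent_vh, v, j, scheme)
        assert len(muts) == 19
        by_region = Counter(scheme.region_of(m.imgt_position) for m in muts)
        assert (by_region["FR1"], by_region["FR2"], by_region["FR3"], by_region["FR4"]) == (2, 6, 8, 3)

    @pytest.mark.parametrize("seed", range(3))
    def test_round_trip_against_mutations_between(self, scheme, parent_vh, seed):
        rng = np.random.default_rng(seed)
        fr = sorted(scheme.fr_positions() & parent_vh.occupied)
        chosen = rng.choice(fr, size=12, replace=False)
        subs = {
            int(p): ("W" if parent_vh.aa_at(int(p)) != "W" else "F") for p in chosen
        }
        v = record_from_domain(parent_vh, "V", subs)
        j = record_from_domain(parent_vh, "J", subs)
        grafted, muts = graft_frameworks(parent_vh, v, j, scheme)
        assert muts == mutations_between(parent_vh, grafted)

    def test_paratope_positions_not_transferred(self, scheme, parent_vh):
        # a donor difference at an extended-paratope framework position
        # (26, the CDR1 N-flank) must not be grafted
        v = record_from_domain(
            parent_vh, "V", {26: "W" if parent_vh.aa_at(26) != "W" else "F"}
        )
        j = record_from_domain(parent_vh, "J")
        _grafted, muts = graft_frameworks(parent_vh, v, j, scheme)
        assert muts == []

    def test_donor_gap_at_framework_position_rejected(self, scheme, parent_vh):
        v = record_from_domain(parent_vh, "V")
        seq = list(v.gapped_sequence)
        seq[9] = GAP_CHAR  # IMGT position 10, FR1
        v_gapped = GermlineRecord(
            gene="X", allele="01", segment="V", chain_kind="VH",
            gapped_sequence="".join(seq),
        )
        with pytest.raises(GraftingError):
            graft_frameworks(parent_vh, v_gapped, record_from_domain(parent_vh, "J"), scheme)


class TestProteinLMutations:
    def test_t8p_changes_only_position_8(self, parent_vl, design_vl_mutations):
        vl9 = parent_vl.apply_mutations(design_vl_mutations)
        vl8 = apply_ppl_mutations(vl9, "T8P_only")
        muts = mutations_between(vl9, vl8)
        assert [str(m) for m in muts] == ["VL-T8P"]

    def test_s24r_added_on_top(self, parent_vl, design_vl_mutations):
        vl9 = parent_vl.apply_mutations(design_vl_mutations)
        vl8 = apply_ppl_mutations(vl9, "T8P_only")
        vl4 = apply_ppl_mutations(vl8, "T8P_and_S24R")
        assert vl4.aa_at(24) == "R" and vl4.aa_at(8) == "P"
        # relative to wild type, the secondary site is back to its parental R
        assert {str(m) for m in mutations_between(parent_vl, vl4)} == {
            "VL-V4M", "VL-T8P", "VL-Q96P", "VL-F103Y"
        }

    def test_idempotence(self, parent_vl, design_vl_mutations):
        vl9 = parent_vl.apply_mutations(design_vl_mutations)
        once = apply_ppl_mutations(vl9, "T8P_and_S24R")
        twice = apply_ppl_mutations(once, "T8P_and_S24R")
        assert once.residues == twice.residues

    def test_heavy_chain_rejected(self, parent_vh):
        with pytest.raises(InputError):
            apply_ppl_mutations(parent_vh)


@pytest.fixture(scope="module")
def full_assignment(scheme, fv_structure, full_design_mutations):
    return assign_clusters(full_design_mutations, fv_structure, scheme)


class TestEnumerateBackmutants:
    def test_emits_the_twelve_named_constructs(self, full_assignment):
        specs = enumerate_backmutants(full_assignment)
        assert [s.name for s in specs] == [
            "S1A0", "S1Z9", "S1Z8", "S1Z4", "S1D4", "S1B4", "S1C4",
            "S1A4", "S1B3", "S1B2", "S1B1", "S1A1",
        ]

    def test_d_series_drops_cluster_i(self, full_assignment):
        by_name = {s.name: s for s in enumerate_backmutants(full_assignment)}
        z, d = by_name["S1Z4"], by_name["S1D4"]
        assert len(z.vh_mutation_set) == 19 and len(d.vh_mutation_set) == 14
        assert d.vh_mutation_set < z.vh_mutation_set
        dropped = z.vh_mutation_set - d.vh_mutation_set
        assert {str(m) for m in dropped} == {
            "VH-L39M", "VH-E69Q", "VH-L78M", "VH-A80V", "VH-T82K"
        }

    def test_vl_digit_lattice(self, full_assignment):
        by_name = {s.name: s for s in enumerate_backmutants(full_assignment)}
        as_str = lambda s: {str(m) for m in s}
        assert as_str(by_name["S1Z9"].vl_mutation_set) == {
            "VL-V4M", "VL-R24S", "VL-Q96P", "VL-F103Y"
        }
        assert as_str(by_name["S1Z8"].vl_mutation_set) == {
            "VL-V4M", "VL-R24S", "VL-Q96P", "VL-F103Y", "VL-T8P"
        }
        assert as_str(by_name["S1Z4"].vl_mutation_set) == {
            "VL-V4M", "VL-T8P", "VL-Q96P", "VL-F103Y"
        }
        assert as_str(by_name["S1B3"].vl_mutation_set) == {
            "VL-V4M", "VL-T8P", "VL-F103Y"
        }
        assert as_str(by_name["S1B2"].vl_mutation_set) == {
            "VL-T8P", "VL-Q96P", "VL-F103Y"
        }
        assert as_str(by_name["S1A1"].vl_mutation_set) == {"VL-T8P", "VL-F103Y"}

    def test_subset_lattice(self, full_assignment):
        specs = {s.name[2]: s.vh_mutation_set
                 for s in enumerate_backmutants(full_assignment, full_cross_product=True)
                 if s.name[3] == "0"}
        assert specs["A"] < specs["B"] < specs["D"] < specs["Z"]
        assert specs["A"] < specs["C"] < specs["D"]
        assert all(v <= specs["Z"] for v in specs.values())

    def test_empty_design_collapses_to_wild_type(self):
        from frshift.clusters import ClusterAssignment

        empty = ClusterAssignment({}, {})
        specs = enumerate_backmutants(empty)
        assert [s.name for s in specs] == ["S1A0"]
        assert not specs[0].vh_mutation_set and not specs[0].vl_mutation_set

    def test_custom_prefix(self, full_assignment):
        specs = enumerate_backmutants(full_assignment, VariantNaming(prefix="Q7"))
        assert specs[0].name == "Q7A0"


class TestAssembly:
    def test_component_length_sum(self, parent_vh, parent_vl):
        c = assemble_scfv(parent_vh, parent_vl)
        assert len(c.full_sequence) == 118 + 15 + 108 + 11 == 252
        assert c.full_sequence == (
            parent_vh.sequence + DEFAULT_LINKER + parent_vl.sequence + DEFAULT_TAG
        )

    def test_empty_tag(self, parent_vh, parent_vl):
        c = assemble_scfv(parent_vh, parent_vl, tag="")
        assert len(c.full_sequence) == 241

    def test_fasta_round_trip(self, tmp_path, parent_vh, parent_vl):
        from Bio import SeqIO

        c = assemble_scfv(parent_vh, parent_vl, name="S1A0")
        path = tmp_path / "scfv.fasta"
        with open(path, "w") as fh:
            fh.write(f">{c.name}\n{c.full_sequence}\n")
        rec = next(SeqIO.parse(path, "fasta"))
        assert str(rec.seq) == c.full_sequence

    def test_realize_variant_applies_both_sets(self, parent_vh, parent_vl, full_assignment):
        by_name = {s.name: s for s in enumerate_backmutants(full_assignment)}
        c = realize_variant(by_name["S1Z4"], parent_vh, parent_vl)
        assert c.vh.aa_at(45) == "R" and c.vh.aa_at(49) == "G"
        assert c.vl.aa_at(8) == "P" and c.vl.aa_at(24) == "R"


def bjellqvist_charge(sequence, pH):
    """Independent net-charge oracle using the published Bjellqvist pKa set,
    including the residue-specific terminal pKs."""
    counts = Counter(sequence)
    pos_pks = dict(positive_pKs)
    neg_pks = dict(negative_pKs)
    pos_pks["Nterm"] = pKnterminal.get(sequence[0], pos_pks["Nterm"])
    neg_pks["Cterm"] = pKcterminal.get(sequence[-1], neg_pks["Cterm"])
    counts["Nterm"] = counts["Cterm"] = 1
    positive = sum(
        counts.get(aa, 0) / (1.0 + 10 ** (pH - pk)) for aa, pk in pos_pks.items()
    )
    negative = sum(
        counts.get(aa, 0) / (1.0 + 10 ** (pk - pH)) for aa, pk in neg_pks.items()
    )
    return positive - negative


class TestProteinParams:
    def test_single_glycine_mass(self):
        mw, _pi, _ext = protein_params("G")
        assert mw == pytest.approx(75.07, abs=0.01)

    def test_extinction_coefficient_sum(self):
        _mw, _pi, ext = protein_params("WYYAAG")
        assert ext == 5500 + 2 * 1490 == 8480

    def test_mass_additivity_minus_water(self):
        a, b = "ACDEFG", "HIKLMN"
        mw_a, *_ = protein_params(a)
        mw_b, *_ = protein_params(b)
        mw_ab, *_ = protein_params(a + b)
        assert mw_ab == pytest.approx(mw_a + mw_b - 18.02, abs=0.02)

    @pytest.mark.parametrize("seq", ["DDEGGKKA", "KKRRGGDA", "ACDEFGHIKLMNPQRSTVWY"])
    def test_pi_matches_bisection_oracle(self, seq):
        _mw, pi, _ext = protein_params(seq)
        root = brentq(lambda ph: bjellqvist_charge(seq, ph), 0.1, 13.9, xtol=1e-8)
        assert pi == pytest.approx(root, abs=0.02)
        assert abs(bjellqvist_charge(seq, root)) < 1e-4

    def test_acidic_below_basic_pi(self):
        acidic = protein_params("DDEGGKKA")[1]
        basic = protein_params("KKRRGGDA")[1]
        assert acidic < 7.0 < basic

    def test_non_standard_residue_rejected(self):
        with pytest.raises(InputError):
            protein_params("ACDX")
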