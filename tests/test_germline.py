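"""Germline identity scoring, filtering and ranking."""

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pytest

from frshift.errors import DegenerateInputError
from frshift.germline import (
    DEFAULT_VH_RULES,
    FilterRules,
    GermlineRecord,
    J_SPAN,
    V_SPAN,
    combined_identity,
    filter_candidates,
    identity_report,
    read_germline_fasta,
    select_j_segment,
    write_germline_fasta,
)
from frshift.imgt import GAP_CHAR


def pct(n_same, n_total):
    """Independent half-up percentage oracle."""
    return float(
        Decimal(repr(100.0 * n_same / n_total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


class TestIdentityReport:
    def test_vh_design_identity(self, scheme, parent_vh, design_vh_mutations):
        grafted = parent_vh.apply_mutations(design_vh_mutations)
        rep = identity_report(parent_vh, grafted, scheme)
        assert rep.n_compared == 118 and rep.n_substitutions == 19
        assert rep.overall_identity == 83.9

    def test_vl_design_identity(self, scheme, parent_vl, design_vl_mutations):
        vl9 = parent_vl.apply_mutations(design_vl_mutations)
        rep = identity_report(parent_vl, vl9, scheme)
        assert rep.n_compared == 108 and rep.n_substitutions == 4
        assert rep.overall_identity == 96.3

    def test_combined_scfv_identity(
        self, scheme, parent_vh, parent_vl, design_vh_mutations, design_vl_mutations
    ):
        rep_h = identity_report(
            parent_vh, parent_vh.apply_mutations(design_vh_mutations), scheme
        )
        rep_l = identity_report(
            parent_vl, parent_vl.apply_mutations(design_vl_mutations), scheme
        )
        assert rep_h.n_compared + rep_l.n_compared == 226
        assert rep_h.n_substitutions + rep_l.n_substitutions == 23
        assert combined_identity(rep_h, rep_l) == 89.8
        assert combined_identity(rep_h, rep_l) == pct(226 - 23, 226)

    @pytest.mark.parametrize("mode", ["overall", "fr_only", "design"])
    def test_self_identity_is_100(self, scheme, parent_vh, mode):
        rep = identity_report(parent_vh, parent_vh, scheme, mode=mode)
        assert rep.overall_identity == 100.0
        assert all(not v for v in rep.per_region_mismatches.values())

    def test_identity_decreases_with_substitutions(self, scheme, parent_vh):
        fr_positions = sorted(scheme.fr_positions() & parent_vh.occupied)
        last = 100.1
        for k in (1, 3, 7, 15):
            subs = {
                p: ("W" if parent_vh.aa_at(p) != "W" else "F")
                for p in fr_positions[:k]
            }
            rep = identity_report(parent_vh, parent_vh.with_substitutions(subs), scheme)
            assert rep.overall_identity < last
            assert rep.overall_identity == pct(118 - k, 118)
            last = rep.overall_identity

    def test_fr_only_ignores_cdr_mismatches(self, scheme, parent_vh):
        cdr_pos = sorted(scheme.cdr_positions() & parent_vh.occupied)[0]
        new = "W" if parent_vh.aa_at(cdr_pos) != "W" else "F"
        mutant = parent_vh.with_substitutions({cdr_pos: new})
        rep = identity_report(parent_vh, mutant, scheme, mode="fr_only")
        assert rep.fr_identity == 100.0 and rep.n_substitutions == 0
        assert identity_report(parent_vh, mutant, scheme).n_substitutions == 1

    def test_design_mode_ignores_extended_paratope(self, scheme, parent_vh):
        # position 26 is framework but belongs to the extended paratope
        flank = 26
        assert flank in scheme.paratope_positions()
        mutant = parent_vh.with_substitutions(
            {flank: "W" if parent_vh.aa_at(flank) != "W" else "F"}
        )
        rep = identity_report(parent_vh, mutant, scheme, mode="design")
        assert rep.n_substitutions == 0
        assert identity_report(parent_vh, mutant, scheme, mode="fr_only").n_substitutions == 1

    def test_empty_comparable_set(self, scheme, parent_vh):
        empty = GermlineRecord(
            gene="X", allele="01", segment="J", chain_kind="VH",
            gapped_sequence=GAP_CHAR * (J_SPAN[1] - J_SPAN[0] + 1),
        )
        with pytest.raises(DegenerateInputError):
            identity_report(parent_vh, empty, scheme, mode="fr_only")


def brute_force_rules(query, records, scheme, rules):
    """Rule-by-rule oracle re-deriving the accepted subset."""
    accepted = set()
    for rec in records:
        rep = identity_report(query, rec, scheme, mode="fr_only")
        fr1 = len(rep.per_region_mismatches.get("FR1", ()))
        if fr1 > rules.max_fr1_mismatches:
            continue
        rmap = rec.residue_map()
        if any(rmap.get(p, aa) != aa for p, aa in rules.required_residues):
            continue
        accepted.add(rec.label)
    return accepted


class TestFilterCandidates:
    def test_fr1_violator_rejected(self, scheme, parent_vh, vh_directory):
        vrecs = [r for r in vh_directory if r.segment == "V"]
        ranking = filter_candidates(parent_vh, vrecs, scheme)
        rejected = {c.record.label: c.rejection_reason for c in ranking.rejected}
        assert rejected.get("IGHVS9-9*01") == "FR1>4"

    def test_identical_framework_ranks_first(self, scheme, parent_vh, vh_directory):
        vrecs = [r for r in vh_directory if r.segment == "V"]
        self_record = GermlineRecord(
            gene="SELF", allele="01", segment="V", chain_kind="VH",
            gapped_sequence="".join(
                dict(parent_vh.residues).get(p, GAP_CHAR)
                for p in range(V_SPAN[0], V_SPAN[1] + 1)
            ),
        )
        ranking = filter_candidates(parent_vh, vrecs + [self_record], scheme)
        assert ranking.best().record.label == "SELF*01"
        assert ranking.best().report.fr_identity == 100.0

    def test_accepted_subset_matches_rule_oracle(self, scheme, parent_vh, vh_directory):
        vrecs = [r for r in vh_directory if r.segment == "V"]
        ranking = filter_candidates(parent_vh, vrecs, scheme, DEFAULT_VH_RULES)
        assert {c.record.label for c in ranking.accepted} == brute_force_rules(
            parent_vh, vrecs, scheme, DEFAULT_VH_RULES
        )

    def test_output_is_permutation_of_input(self, scheme, parent_vh, vh_directory):
        vrecs = [r for r in vh_directory if r.segment == "V"]
        ranking = filter_candidates(parent_vh, vrecs, scheme)
        assert sorted(c.record.label for c in ranking.candidates) == sorted(
            r.label for r in vrecs
        )

    def test_accepted_sorted_by_fr_identity(self, scheme, parent_vh, vh_directory):
        vrecs = [r for r in vh_directory if r.segment == "V"]
        ranking = filter_candidates(parent_vh, vrecs, scheme)
        idents = [c.report.fr_identity for c in ranking.accepted]
        assert idents == sorted(idents, reverse=True)
        assert all(c.rejection_reason for c in ranking.rejected)


class TestSelectJSegment:
    def test_design_j_ranks_first_with_three_fr4_mismatches(
        self, scheme, parent_vh, vh_directory
    ):
        jrecs = [r for r in vh_directory if r.segment == "J"]
        ranking = select_j_segment(parent_vh, jrecs, scheme)
        assert ranking.candidates[0].record.label == "IGHJS2*01"
        assert ranking.candidates[0].report.n_substitutions == 3

    def test_runner_up_j_has_one_extra_mismatch(self, scheme, parent_vh, vh_directory):
        jrecs = [r for r in vh_directory if r.segment == "J"]
        ranking = select_j_segment(parent_vh, jrecs, scheme)
        by_label = {c.record.label: c.report for c in ranking.candidates}
        assert by_label["IGHJS3*01"].n_substitutions == 4

    def test_vl_design_leaves_fr4_unchanged(self, scheme, parent_vl, vl_directory):
        jrecs = [r for r in vl_directory if r.segment == "J"]
        ranking = select_j_segment(parent_vl, jrecs, scheme)
        assert ranking.candidates[0].record.label == "IGKJS2*01"
        assert ranking.candidates[0].report.n_substitutions == 0

    def test_ordering_matches_hamming_oracle(self, scheme, parent_vh, vh_directory):
        jrecs = [r for r in vh_directory if r.segment == "J"]
        qmap = dict(parent_vh.residues)

        def hamming(rec):
            return sum(
                1
                for p, aa in rec.residue_map().items()
                if p in qmap and qmap[p] != aa
            )

        ranking = select_j_segment(parent_vh, jrecs, scheme)
        counts = [c.report.n_substitutions for c in ranking.candidates]
        assert counts == sorted(hamming(r) for r in jrecs)


def test_germline_fasta_round_trip(tmp_path, vh_directory):
    path = tmp_path / "germline.fasta"
    write_germline_fasta(vh_directory, path)
    back = read_germline_fasta(path)
    assert back == vh_directory
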