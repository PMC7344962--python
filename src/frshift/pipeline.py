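"""End-to-end design pipeline: germline selection -> grafting -> Protein-L
mutations -> cluster assignment -> back-mutation variant enumeration ->
scFv assembly.

Every stage is an ordinary library call; this module only wires them
together and writes the tabular/FASTA artifacts with a provenance header.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .clusters import (
    ClusterAssignment,
    assign_clusters,
    assignment_table,
    read_fv_structure,
)
from .config import RunConfig
from .errors import ConfigurationError, InputError
from .germline import (
    CandidateRanking,
    FilterRules,
    filter_candidates,
    ranking_table,
    read_germline_fasta,
    select_j_segment,
)
from .imgt import Mutation, NumberedDomain, read_domains_fasta
from .variants import (
    VariantNaming,
    apply_ppl_mutations,
    design_table,
    enumerate_backmutants,
    graft_frameworks,
    realize_variant,
)


@dataclass
class DesignReport:
    parent_vh: NumberedDomain
    parent_vl: NumberedDomain
    vh_ranking: CandidateRanking
    vl_ranking: CandidateRanking
    vh_j_ranking: CandidateRanking
    vl_j_ranking: CandidateRanking
    assignment: ClusterAssignment
    specs: list
    constructs: list
    output_files: dict


def _provenance() -> str:
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    return f"# frshift {__version__}\n# generated: {stamp}\n"


def _pick_donor(ranking: CandidateRanking, label: str, stage: str):
    if label:
        for cand in ranking.candidates:
            if cand.record.label == label:
                return cand.record
        raise ConfigurationError(f"{stage}: requested donor {label!r} not in directory")
    best = ranking.best() if hasattr(ranking, "best") else None
    if best is None:
        raise ConfigurationError(f"{stage}: no germline candidate passed the filters")
    return best.record


def run_design_pipeline(
    parent_fasta,
    germline_fasta,
    structure_file=None,
    config: RunConfig | None = None,
) -> DesignReport:
    """Execute the five design steps and write all artifacts.

    ``parent_fasta`` must contain one VH and one VL domain (IMGT-gapped);
    ``germline_fasta`` a V/J directory for both chains.
    """
    config = config or RunConfig()
    scheme = config.scheme
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    domains = read_domains_fasta(parent_fasta)
    try:
        parent_vh = next(d for d in domains if d.chain_kind == "VH")
        parent_vl = next(d for d in domains if d.chain_kind == "VL_kappa")
    except StopIteration:
        raise InputError("parent FASTA must contain one VH and one VL domain")

    directory = read_germline_fasta(germline_fasta)

    def subset(chain, segment):
        return [r for r in directory if r.chain_kind == chain and r.segment == segment]

    # step 1: germline selection and framework grafting, per chain
    rankings, grafts = {}, {}
    for chain, parent, v_override, j_override in (
        ("VH", parent_vh, config.vh_v_gene, config.vh_j_gene),
        ("VL_kappa", parent_vl, config.vl_v_gene, config.vl_j_gene),
    ):
        rules = FilterRules(
            max_fr1_mismatches=config.max_fr1_mismatches,
            required_residues=config.required_residues(
                "VH" if chain == "VH" else "VL"
            ),
        )
        v_ranking = filter_candidates(parent, subset(chain, "V"), scheme, rules)
        j_ranking = select_j_segment(parent, subset(chain, "J"), scheme)
        v_donor = _pick_donor(v_ranking, v_override, f"{chain} V selection")
        j_donor = _pick_donor(j_ranking, j_override, f"{chain} J selection")
        grafted, muts = graft_frameworks(parent, v_donor, j_donor, scheme)
        rankings[chain] = (v_ranking, j_ranking)
        grafts[chain] = (grafted, muts)

    vh_graft, vh_muts = grafts["VH"]
    vl_graft, vl_muts = grafts["VL_kappa"]

    # step 2: Protein-L recognition on the light chain
    apply_ppl_mutations(vl_graft, "T8P_only")  # validates position 8 is mutable
    if parent_vl.aa_at(8) != "P":
        ppl_mut = Mutation("VL", parent_vl.aa_at(8), 8, "P")
        all_vl_muts = list(vl_muts) + [ppl_mut]
    else:
        all_vl_muts = list(vl_muts)

    # step 3: cluster assignment
    structure = read_fv_structure(structure_file) if isinstance(structure_file, (str, Path)) else structure_file
    assignment = assign_clusters(
        list(vh_muts) + all_vl_muts,
        structure,
        scheme,
        cc_loop=config.cc_loop_interval(),
        proximity_cutoff=config.proximity_cutoff,
        cluster_i_positions=config.cluster_i_position_set(),
    )

    # steps 4-5: back-mutation variant enumeration and assembly
    naming = VariantNaming(prefix=config.variant_prefix)
    specs = enumerate_backmutants(assignment, naming)
    constructs = [
        realize_variant(s, parent_vh, parent_vl, linker=config.linker, tag=config.tag)
        for s in specs
    ]

    # artifacts
    files = {}
    header = _provenance()
    for chain, tag in (("VH", "vh"), ("VL_kappa", "vl")):
        v_ranking, j_ranking = rankings[chain]
        path = out_dir / f"ranking_{tag}.tsv"
        path.write_text(header + ranking_table(v_ranking))
        files[f"ranking_{tag}"] = path
        path = out_dir / f"ranking_{tag}_j.tsv"
        path.write_text(header + ranking_table(j_ranking))
        files[f"ranking_{tag}_j"] = path
    path = out_dir / "clusters.tsv"
    path.write_text(header + assignment_table(assignment))
    files["clusters"] = path
    path = out_dir / "design_table.tsv"
    path.write_text(header + design_table(zip(specs, constructs)))
    files["design_table"] = path
    path = out_dir / "variants.fasta"
    with open(path, "w") as fh:
        for c in constructs:
            fh.write(f">{c.name} scFv VH-linker-VL-tag\n{c.full_sequence}\n")
    files["variants"] = path

    return DesignReport(
        parent_vh=parent_vh,
        parent_vl=parent_vl,
        vh_ranking=rankings["VH"][0],
        vl_ranking=rankings["VL_kappa"][0],
        vh_j_ranking=rankings["VH"][1],
        vl_j_ranking=rankings["VL_kappa"][1],
        assignment=assignment,
        specs=specs,
        constructs=constructs,
        output_files=files,
    )
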