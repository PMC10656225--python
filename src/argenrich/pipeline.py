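"""End-to-end orchestration: simulate -> enrich -> sites -> cluster.

A single :class:`RunConfig` carries every threshold with its published
default, so a bare run reproduces the analysis rules exactly. The
packaged transcriptions of the published result tables are exposed as a
first-class verification command.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import enrichment, io_formats, network, sites, synthetic_data
from .io_formats import KO, WT
from .synthetic_data import SimConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults equal the published values."""

    out_dir: str = "run_out"
    seed: int = 0
    # stage inputs: either a simulation config or explicit file paths
    sim: SimConfig | None = None
    protein_groups_path: str | None = None
    design_path: str | None = None
    evidence_path: str | None = None
    fasta_path: str | None = None
    edges_path: str | None = None
    # thresholds (published defaults)
    fc_threshold: float = 1.5
    alpha: float = 0.05
    min_wt_detected: int = 2
    min_razor_unique: int = 2
    loc_threshold: float = 0.75
    pep_threshold: float = 0.01
    min_score: float = 0.40
    inflation: float = 1.7
    # interpretation switches
    fc_average: str = "linear"
    site_granularity: str = "row"
    volcano_plot: bool = False


def _load_inputs(config: RunConfig, out_dir: Path):
    if config.sim is not None:
        sim = config.sim
        table, evidence, seqdb, truth = synthetic_data.simulate_experiment(sim)
        io_formats.write_protein_groups(table, out_dir / "protein_groups.tsv")
        io_formats.write_site_table(evidence, out_dir / "evidence.tsv")
        io_formats.write_fasta(seqdb, out_dir / "proteome.fasta")
        table.design.to_yaml(out_dir / "design.yaml")
        truth.proteins.to_csv(out_dir / "truth_proteins.tsv", sep="\t", index=False)
        truth.sites.to_csv(out_dir / "truth_sites.tsv", sep="\t", index=False)
        edges = None
        if config.edges_path:
            edges = io_formats.read_edge_list(config.edges_path)
        return table, evidence, seqdb, edges
    if not config.protein_groups_path or not config.design_path:
        raise ValueError("either sim or protein_groups_path + design_path must be set")
    design = io_formats.SampleDesign.from_yaml(config.design_path)
    table = io_formats.read_protein_groups(config.protein_groups_path, design)
    evidence = io_formats.read_site_table(config.evidence_path) if config.evidence_path else []
    seqdb = io_formats.read_fasta(config.fasta_path) if config.fasta_path else None
    edges = io_formats.read_edge_list(config.edges_path) if config.edges_path else None
    return table, evidence, seqdb, edges


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write the result tables and return the run report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, evidence, seqdb, edges = _load_inputs(config, out_dir)

    drops: list[dict] = []
    qc_kept = set(
        enrichment.qc_filter(table, config.min_razor_unique).protein_ids
    )
    for pid in table.protein_ids:
        if pid not in qc_kept:
            drops.append({"record": pid, "stage": "qc_filter",
                          "reason": "razor+unique count below threshold in both genotypes"})

    records, enrich_report = enrichment.run_enrichment(
        table,
        min_razor_unique=config.min_razor_unique,
        fc_threshold=config.fc_threshold,
        alpha=config.alpha,
        min_wt_detected=config.min_wt_detected,
        fc_average=config.fc_average,
        seed=config.seed,
    )
    io_formats.write_results(records, out_dir / "enriched.tsv")
    if config.volcano_plot:
        plot_volcano(records, out_dir / "volcano.png", alpha=config.alpha,
                     fc_threshold=config.fc_threshold)

    mapped, unmapped = sites.map_sites(evidence, seqdb, config.site_granularity)
    for u in unmapped:
        drops.append({"record": f"{u.evidence.leading_protein}:{u.evidence.peptide_seq}",
                      "stage": "map_sites", "reason": u.reason})
    filtered = sites.apply_preceding_arg_filter(mapped)
    classified = sites.classify_confidence(filtered, config.loc_threshold, config.pep_threshold)
    classified.sort(key=lambda s: (s.protein_id, s.peptide_seq, s.positions_key()))
    sites.sites_to_frame(classified).to_csv(out_dir / "classified_sites.tsv", sep="\t", index=False)
    site_summary = sites.summarize_sites(classified)

    cluster_report = None
    if edges is not None:
        enriched_genes = sorted({r.gene.split(";")[0].strip() for r in records if r.enriched})
        high_genes = sorted(
            {s.first_gene for s in classified if s.confidence == sites.CONF_HIGH}
        )
        nodes = sorted(set(enriched_genes) | set(high_genes))
        # interactions among query proteins only
        node_set = set(nodes)
        query_edges = [e for e in edges if e.node_a in node_set and e.node_b in node_set]
        graph = network.build_graph(query_edges, nodes, config.min_score)
        result = network.mcl_cluster(graph, inflation=config.inflation)
        network.write_clusters(result, out_dir / "clusters.tsv")
        cluster_report = {
            "n_nodes": len(nodes),
            "n_clusters": result.n_clusters,
            "converged": result.converged,
        }

    for s in classified:
        if s.confidence == sites.CONF_REMOVED:
            drops.append({"record": f"{s.protein_id}:{s.peptide_seq}",
                          "stage": "preceding_arg_filter",
                          "reason": "peptide-start residue directly preceded by Arg"})
    pd.DataFrame(drops, columns=["record", "stage", "reason"]).to_csv(
        out_dir / "drops.tsv", sep="\t", index=False
    )

    report = {
        "config": _config_dict(config),
        "seed": config.seed,
        "enrichment": enrich_report,
        "sites": {
            "n_evidence_rows": len(evidence),
            "n_mapped_sites": len(mapped),
            "n_unmapped_evidence": len(unmapped),
            "summary": site_summary,
        },
        "clustering": cluster_report,
        "warnings": [u.reason for u in unmapped],
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def plot_volcano(records, path, alpha: float = 0.05, fc_threshold: float = 1.5) -> None:
    """log2 fold change vs -log2 p, enriched calls highlighted."""
    lfc = np.log2([max(r.avg_fold_change, 1e-12) for r in records])
    logp = -np.log2([max(r.p_value, 1e-300) for r in records])
    called = np.array([r.enriched for r in records])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(lfc[~called], logp[~called], s=8, c="grey", alpha=0.6, label="not enriched")
    ax.scatter(lfc[called], logp[called], s=8, c="red", alpha=0.8, label="enriched")
    ax.axhline(-np.log2(alpha), ls="--", lw=0.8, c="black")
    ax.axvline(np.log2(fc_threshold), ls="--", lw=0.8, c="black")
    ax.set_xlabel("log2 fold change (WT vs KO, input-normalized)")
    ax.set_ylabel("-log2 p value")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# fixture verification
# ---------------------------------------------------------------------------

EXPECTED_TABLE1_RECORDS = 108
EXPECTED_TABLE2_SITES = 17
EXPECTED_TABLE2_PROTEINS = 15
EXPECTED_TABLE1_MAX_FC = 2206.8
EXPECTED_TABLE1_MAX_FC_GENE = "Sh3bgrl3"


def verify_fixtures() -> list[dict]:
    """Check the packaged published-table transcriptions against their
    stated headline counts; returns one record per check."""
    checks = []

    t1 = synthetic_data.make_table1_fixture()
    checks.append(_check("table1_record_count", EXPECTED_TABLE1_RECORDS, len(t1)))
    imax = int(t1["fold_change"].idxmax())
    checks.append(_check("table1_max_fold_change", EXPECTED_TABLE1_MAX_FC,
                         float(t1["fold_change"].max())))
    checks.append(_check("table1_max_fold_change_gene", EXPECTED_TABLE1_MAX_FC_GENE,
                         str(t1.loc[imax, "gene_names"]).split(";")[0].strip()))

    evidence = synthetic_data.make_table2_fixture()
    mapped, _ = sites.map_sites(evidence, db=None)
    classified = sites.classify_confidence(mapped)
    summary = sites.summarize_sites(classified)
    n_sites = sum(tier["n_sites"] for tier in summary.values())
    n_proteins = len({s.first_gene for s in classified})
    checks.append(_check("table2_site_count", EXPECTED_TABLE2_SITES, n_sites))
    checks.append(_check("table2_distinct_protein_count", EXPECTED_TABLE2_PROTEINS, n_proteins))

    # Strict reclassification under the stated thresholds. One published
    # row (Rrbp1, PEP 0.0146506 > 0.01) violates the stated PEP criterion;
    # the strict rule tiers it medium and this check reports that openly.
    medium = sorted(s.first_gene for s in classified if s.confidence == sites.CONF_MEDIUM)
    checks.append(_check("table2_strict_medium_rows", ["Rrbp1"], medium))
    checks.append(
        _check(
            "table2_strict_high_count",
            EXPECTED_TABLE2_SITES - 1,
            summary[sites.CONF_HIGH]["n_sites"],
            note="one published row exceeds the stated PEP threshold and "
            "reclassifies as medium under the strict rule",
        )
    )
    return checks


def _check(name, expected, observed, note: str = "") -> dict:
    rec = {"name": name, "expected": expected, "observed": observed,
           "passed": expected == observed}
    if note:
        rec["note"] = note
    return rec
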