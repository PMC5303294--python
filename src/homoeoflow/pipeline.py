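"""End-to-end runs of the homoeologue expression pipeline.

Two entry points:

* :func:`run_pipeline` — simulate an experiment and push it through
  artefact filtering, quantification, DE, classification and reporting.
  ``read_level=True`` additionally exercises sequence simulation, protein
  grouping and diagnostic-site read assignment (slower); otherwise the
  generator's counts and groups are used directly.
* :func:`analyse_counts` — the same analysis for user-provided tables
  (counts, sample sheet, groups, gene lengths).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import assignment, classify, grouping, report, simulate

log = logging.getLogger(__name__)


def analyse_counts(counts: pd.DataFrame, samples: pd.DataFrame,
                   groups: pd.DataFrame, lengths: pd.Series,
                   alpha: float = 0.05,
                   apply_artefact_filter: bool = True) -> dict:
    """Classification and reporting for a genome-resolved count table."""
    genomes = pd.Series(
        {row[f"gene_{g}"]: g for _, row in groups.iterrows()
         for g in ("A", "B", "D") if row[f"gene_{g}"]})
    if apply_artefact_filter:
        flagged = assignment.artefact_filter(counts, samples, genomes,
                                             lengths)
        if len(flagged):
            log.info("artefact filter removed %d genes", len(flagged))
        counts = counts.drop(index=flagged)
    results = classify.classify_groups(counts, samples, groups,
                                       lengths.reindex(counts.index), alpha)
    corr = report.correlation_matrix(results["fpkm"])
    tables = report.summary_report(results, genomes)
    return {
        "counts": counts,
        "genomes": genomes,
        "results": results,
        "correlation": corr,
        "newick": report.dendrogram_newick(corr),
        "f1_joins_s1_first": report.f1_joins_s1_first(corr, samples),
        "tables": tables,
    }


def run_pipeline(config: simulate.SimConfig, outdir: str | Path | None = None,
                 read_level: bool = False, alpha: float = 0.05) -> dict:
    """Simulate one experiment and analyse it.

    With ``read_level`` the homoeologue groups are rebuilt from the
    simulated proteins and the counts re-derived by assigning every
    simulated read to its subgenome through diagnostic sites; otherwise the
    generator's own groups and counts feed the analysis directly.
    """
    config.validate()
    genes, groups, truth = simulate.simulate_universe(config)
    counts, samples, factors = simulate.simulate_counts(truth, config)
    lengths = genes.set_index("gene_id")["length"]

    assign_stats = None
    if read_level:
        seqs = simulate.simulate_sequences(genes, config)
        proteins = seqs.set_index("gene_id")["protein"]
        genome_labels = seqs.set_index("gene_id")["genome"]
        graph = grouping.build_similarity_graph(proteins, genome_labels)
        groups = grouping.partition_groups(graph, genome_labels)
        assigner = assignment.ReadAssigner(
            seqs.set_index("gene_id")["transcript"], genome_labels,
            _group_of(groups))
        per_sample = {}
        tallies = {}
        reads_of = {}
        for sample, rid, seq in simulate.simulate_reads(seqs, counts, config):
            reads_of.setdefault(sample, []).append(seq)
        for sample, reads in reads_of.items():
            assigned, tally = assigner.count_sample(reads)
            per_sample[sample] = assigned
            tallies[sample] = tally
        counts = pd.DataFrame(per_sample)[counts.columns]
        assign_stats = assignment.assignment_stats(tallies)

    out = analyse_counts(counts, samples, groups, lengths, alpha)
    out.update({
        "config": config,
        "genes": genes,
        "groups": groups,
        "truth": truth,
        "truth_groups": simulate.truth_group_summary(truth),
        "samples": samples,
        "size_factors_true": factors,
        "assignment_stats": assign_stats,
    })
    if outdir is not None:
        _write(out, Path(outdir))
    return out


def _group_of(groups: pd.DataFrame) -> pd.Series:
    return pd.Series(
        {row[f"gene_{g}"]: row["group_id"] for _, row in groups.iterrows()
         for g in ("A", "B", "D") if row[f"gene_{g}"]})


def _write(out: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    out["counts"].to_csv(outdir / "counts_analysed.tsv", sep="\t")
    out["samples"].to_csv(outdir / "samples.tsv", sep="\t", index=False)
    out["groups"].to_csv(outdir / "groups.tsv", sep="\t", index=False)
    out["truth"].to_csv(outdir / "truth.tsv", sep="\t", index=False)
    results = out["results"]
    results["fpkm"].to_csv(outdir / "fpkm.tsv", sep="\t")
    results["uth_calls"].to_csv(outdir / "uth_calls.tsv", sep="\t",
                                index=False)
    results["classification"].to_csv(outdir / "classification.tsv", sep="\t")
    results["restoration_calls"].to_csv(outdir / "restoration.tsv", sep="\t")
    results["restoration_stats"].to_csv(outdir / "restoration_stats.tsv",
                                        sep="\t", index=False)
    results["singletons"]["venn_regions"].to_csv(
        outdir / "singleton_venn.tsv", sep="\t", index=False)
    for gen, de in results["de_own_parent"].items():
        de.to_csv(outdir / f"de_{gen}_vs_parent.tsv", sep="\t")
    results["s1_vs_f1"].to_csv(outdir / "de_S1_vs_F1.tsv", sep="\t")
    for gen, block in results["per_generation"].items():
        for name, table in block["contrasts"].items():
            table.to_csv(outdir / f"totals_{gen}_{name}.tsv", sep="\t")
    out["correlation"].to_csv(outdir / "sample_correlation.tsv", sep="\t")
    (outdir / "dendrogram.nwk").write_text(out["newick"] + "\n")
    if out.get("assignment_stats") is not None:
        out["assignment_stats"].to_csv(outdir / "assignment_stats.tsv",
                                       sep="\t", index=False)
    report.write_summary(out["tables"], outdir / "summary")
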