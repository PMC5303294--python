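"""Cross-sample diagnostics, enrichment and figure-style summary tables.

Percentages throughout are computed as half-up roundings to a fixed number
of decimals so that reported tables are self-consistent with their counts
and reproduce the arithmetic of published count/denominator pairs exactly.
The sample dendrogram is complete-linkage agglomeration on 1 - Pearson r of
log2(FPKM + 1), emitted as Newick.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .diffexp import bh_adjust


def percentage(count: float, denominator: float, decimals: int = 1) -> float:
    """Half-up percentage, the convention of printed summary tables."""
    if denominator == 0:
        return 0.0
    scale = 10 ** decimals
    return math.floor(count / denominator * 100 * scale + 0.5) / scale


def worked_example_counts() -> pd.DataFrame:
    """Reference count/denominator pairs for a two-lineage synthetic
    hexaploid wheat experiment, with the percentages their source tables
    print; used as worked examples for the percentage layer."""
    ref = importlib.resources.files("homoeoflow.data") / "worked_counts.tsv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    table["computed_pct"] = [
        percentage(c, d, int(k))
        for c, d, k in zip(table["count"], table["denominator"],
                           table["decimals"])]
    return table


# ---------------------------------------------------------------------------
# correlations and dendrogram


def correlation_matrix(fpkm: pd.DataFrame) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation of log2(FPKM + 1).

    Zero-variance samples yield missing correlations (NaN) against every
    other sample; the diagonal is 1 by convention.
    """
    if fpkm.shape[1] < 2:
        raise ValueError("need at least two samples")
    log_table = np.log2(fpkm + 1.0)
    corr = log_table.corr(method="pearson")
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def dendrogram_linkage(corr: pd.DataFrame, method: str = "complete"):
    """Agglomerative linkage on the 1 - r distance."""
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    if np.isnan(dist).any():
        raise ValueError("correlation matrix contains missing values")
    dist = (dist + dist.T) / 2.0
    np.clip(dist, 0.0, None, out=dist)
    return linkage(squareform(dist, checks=False), method=method)


def dendrogram_newick(corr: pd.DataFrame, method: str = "complete") -> str:
    """Newick tree with branch lengths from the linkage heights."""
    lk = dendrogram_linkage(corr, method)
    tree = to_tree(lk)
    labels = list(corr.columns)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


def cophenetic_genotype_distance(corr: pd.DataFrame,
                                 samples: pd.DataFrame,
                                 method: str = "complete") -> pd.DataFrame:
    """Mean cophenetic distance between the samples of each genotype pair."""
    lk = dendrogram_linkage(corr, method)
    coph = squareform(cophenet(lk))
    idx = {s: i for i, s in enumerate(corr.columns)}
    gts = sorted(samples["genotype"].unique())
    bygt = {gt: [idx[s] for s in samples.loc[samples["genotype"] == gt,
                                             "sample"]] for gt in gts}
    out = pd.DataFrame(0.0, index=gts, columns=gts)
    for g1 in gts:
        for g2 in gts:
            if g1 == g2:
                continue
            vals = [coph[i, j] for i in bygt[g1] for j in bygt[g2]]
            out.loc[g1, g2] = float(np.mean(vals))
    return out


def f1_joins_s1_first(corr: pd.DataFrame, samples: pd.DataFrame,
                      method: str = "complete") -> bool:
    """True when the hybrid clusters with the doubled hybrid before its
    tetraploid progenitor."""
    d = cophenetic_genotype_distance(corr, samples, method)
    return bool(d.loc["F1", "S1"] < d.loc["F1", "P_AB"])


# ---------------------------------------------------------------------------
# enrichment


def hypergeometric_enrichment(query, universe, term_map: dict,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric term enrichment with BH correction.

    ``term_map`` maps term id -> iterable of gene ids.  The universe is the
    background gene set; the query must be contained in it.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    if not query:
        return pd.DataFrame(columns=["term", "overlap", "term_size",
                                     "query_size", "universe_size",
                                     "pvalue", "qvalue", "enriched"])
    rows = []
    m = len(universe)
    n = len(query)
    for term, genes in sorted(term_map.items()):
        members = set(genes) & universe
        k = len(members & query)
        size = len(members)
        p = float(hypergeom.sf(k - 1, m, size, n)) if size else 1.0
        rows.append({"term": term, "overlap": k, "term_size": size,
                     "query_size": n, "universe_size": m,
                     "pvalue": min(p, 1.0)})
    res = pd.DataFrame(rows)
    res["qvalue"] = bh_adjust(res["pvalue"].to_numpy())
    res["enriched"] = res["qvalue"] < alpha
    return res


# ---------------------------------------------------------------------------
# summary bundle


def _call_counts(de: pd.DataFrame, genomes: pd.Series) -> pd.DataFrame:
    rows = []
    for genome, sub in de.groupby(genomes.reindex(de.index)):
        n = len(sub)
        up = int((sub["call"] == "up").sum())
        down = int((sub["call"] == "down").sum())
        rows.append({"genome": genome, "n_tested": n, "up": up,
                     "down": down,
                     "pct_up": percentage(up, n), "pct_down": percentage(down, n)})
    return pd.DataFrame(rows)


def summary_report(results: dict, genomes: pd.Series) -> dict:
    """Assemble the figure-style tables from a classification run.

    ``results`` is the dict returned by :func:`homoeoflow.classify.classify_groups`.
    Returns a dict of DataFrames plus a JSON-ready summary under 'json'.
    """
    tables = {}
    for gen, de in results["de_own_parent"].items():
        tables[f"de_{gen}_vs_parent"] = _call_counts(de, genomes)
    tables["de_S1_vs_F1"] = _call_counts(results["s1_vs_f1"], genomes)
    tables["uth"] = results["uth_table"]

    add_rows = []
    for gen in ("F1", "S1"):
        add = results["per_generation"][gen]["additivity"]
        n = len(add)
        up = int((add == "nonadd_up").sum())
        down = int((add == "nonadd_down").sum())
        add_rows.append({"generation": gen, "n_tested": n,
                         "nonadd_up": up, "nonadd_down": down,
                         "pct_nonadd": percentage(up + down, n),
                         "pct_down_of_nonadd": percentage(down, up + down)})
    tables["additivity"] = pd.DataFrame(add_rows)

    eld_rows = []
    eld_sets = {}
    for gen in ("F1", "S1"):
        eld = results["per_generation"][gen]["eld"]
        counts = eld["eld"].value_counts()
        eld_sets[gen] = set(eld.index[eld["eld"] == "ELD-ab"])
        eld_rows.append({"generation": gen,
                         "eld_ab": int(counts.get("ELD-ab", 0)),
                         "eld_d": int(counts.get("ELD-d", 0)),
                         "transgressive_up": int(counts.get("transgressive_up", 0)),
                         "transgressive_down": int(counts.get("transgressive_down", 0)),
                         "none": int(counts.get("none", 0))})
    tables["eld"] = pd.DataFrame(eld_rows)
    tables["eld"]["eld_ab_shared_f1_s1"] = len(eld_sets["F1"] & eld_sets["S1"])

    rest = results["restoration_calls"]
    rest_rows = []
    for genome, sub in rest.groupby("genome"):
        n = len(sub)
        restored = int((sub["restoration"] == "restored").sum())
        rest_rows.append({"genome": genome, "n_disturbed_f1": n,
                          "restored": restored,
                          "maintained": n - restored,
                          "pct_restored": percentage(restored, n)})
    tables["restoration"] = pd.DataFrame(rest_rows)
    tables["singleton_venn"] = results["singletons"]["venn_regions"]

    payload = {name: df.to_dict(orient="records")
               for name, df in tables.items()}
    tables["json"] = payload
    return tables


def write_summary(tables: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        if name == "json":
            with open(outdir / "summary.json", "w") as fh:
                json.dump(df, fh, indent=1, sort_keys=True)
        else:
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
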