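"""Homoeologue-group behaviour across hybridization and genome doubling.

Implements the group-level calculus of the allopolyploid design:

* UTH (unequally transcribed homoeologues): within-genotype exact NB tests
  between length-corrected homoeologue counts of triplet groups, per
  subgenome pair, BH-adjusted per genotype and pair.
* Additivity: progeny group totals against a mid-parent-value (MPV)
  pseudo-sample built from normalised parental totals.
* ELD (expression level dominance): progeny totals similar to one parent and
  different from the other, defined only where the parents themselves differ;
  same-direction departures beyond both parents are transgressive.
* Restoration: per-homoeologue disturbances present in the hybrid (F1 vs own
  parent) that are no longer significant after genome doubling (S1 vs own
  parent), with boxplot statistics of the log2 ratios.
* Singleton complementation: per-genotype expressed-singleton sets, their
  Venn partition and single-parent-transcription genes.

Group-total contrasts are run stratified by member composition (triplet,
AD duplet, BD duplet) with median-of-ratios normalisation inside each
stratum: a no-change group's progeny/parent total ratio is a
composition-dependent dosage constant, and stratifying lets normalisation
absorb it so the tests measure deviation from the genome-wide norm — which
is also what size-factor normalisation does on real data.  AB duplets have
no DD-parent copy and are excluded from MPV/ELD calls; parental group totals
are used as measured, with no ploidy rescaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexp import bh_adjust, call_de, run_contrast
from .quantify import fpkm_matrix, retention_filter, size_factors

GENERATIONS = ("F1", "S1")
TOTAL_STRATA = ("triplet", "duplet_AD", "duplet_BD")
PAIRS = (("A", "B"), ("A", "D"), ("B", "D"))
MIN_STRATUM = 8


def genotype_samples(samples: pd.DataFrame) -> dict[str, list[str]]:
    out = {}
    for gt, sub in samples.groupby("genotype"):
        out[gt] = sorted(sub["sample"])
    return out


def group_totals(counts: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Per-group total counts (sum over member genes) per sample."""
    member_of = {}
    for _, row in groups.iterrows():
        for g in ("A", "B", "D"):
            gene = row[f"gene_{g}"]
            if gene:
                member_of[gene] = row["group_id"]
    mapped = counts.index.to_series().map(member_of)
    totals = counts.groupby(mapped).sum()
    totals.index.name = "group_id"
    return totals.reindex(groups["group_id"]).fillna(0).astype(counts.dtypes.iloc[0])


def parental_retention(fpkm: pd.DataFrame, samples: pd.DataFrame,
                       groups: pd.DataFrame,
                       threshold: float = 1.0) -> pd.DataFrame:
    """Per-group retention flags computed from parental group-total FPKM."""
    gsamp = genotype_samples(samples)
    member_of = {}
    for _, row in groups.iterrows():
        for g in ("A", "B", "D"):
            if row[f"gene_{g}"]:
                member_of[row[f"gene_{g}"]] = row["group_id"]
    mapped = fpkm.index.to_series().map(member_of)
    total_fpkm = fpkm.groupby(mapped).sum()
    out = pd.DataFrame(index=groups["group_id"])
    out["retained_pab"] = (total_fpkm[gsamp["P_AB"]].max(axis=1) > threshold) \
        .reindex(out.index, fill_value=False)
    out["retained_pd"] = (total_fpkm[gsamp["P_D"]].max(axis=1) > threshold) \
        .reindex(out.index, fill_value=False)
    out["retained_any_parent"] = out["retained_pab"] | out["retained_pd"]
    return out


# ---------------------------------------------------------------------------
# UTH


def uth_analysis(counts: pd.DataFrame, samples: pd.DataFrame,
                 groups: pd.DataFrame, lengths: pd.Series,
                 eligible: pd.Index, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise homoeologue comparisons within each genotype setting.

    ``eligible`` are triplet group ids passing the parental retention rule
    (at least one homoeologue with parental FPKM above unity).  The
    'parents' setting compares each homoeologue in its own parent (A or B in
    the AABB parent, D in the DD parent); F1 and S1 compare homoeologues
    within the same libraries.  Counts are length-corrected to the pair's
    geometric-mean length before testing; BH runs per (setting, pair).

    Returns rows [group_id, setting, pair, log2fc, pvalue, qvalue, call]
    with call in {left>, left<, ns}; ``log2fc`` is right over left.
    """
    gsamp = genotype_samples(samples)
    trip = groups.set_index("group_id").loc[list(eligible)]
    settings = {
        "parents": None,  # member-specific genotypes
        "F1": "F1",
        "S1": "S1",
    }
    # per-library depth factors within each genotype; homoeologues compared
    # within the same library share its depth, so no cross-column
    # normalisation (which planted expression bias would skew) is applied
    depth = {gt: size_factors(counts[cols]) for gt, cols in gsamp.items()}
    out = []
    for setting, gt in settings.items():
        for left, right in PAIRS:
            # pairs whose members survived upstream filters only
            ok = trip[f"gene_{left}"].isin(counts.index) \
                & trip[f"gene_{right}"].isin(counts.index)
            sub_trip = trip[ok]
            if sub_trip.empty:
                continue
            gl = sub_trip[f"gene_{left}"]
            gr = sub_trip[f"gene_{right}"]
            gt_l = gt or ("P_D" if left == "D" else "P_AB")
            gt_r = gt or ("P_D" if right == "D" else "P_AB")
            cols_l = gsamp[gt_l]
            cols_r = gsamp[gt_r]
            len_l = lengths.reindex(gl).to_numpy(dtype=float)
            len_r = lengths.reindex(gr).to_numpy(dtype=float)
            ref_len = np.sqrt(len_l * len_r)
            mat_l = counts.reindex(gl)[cols_l].to_numpy(dtype=float) \
                * (ref_len / len_l)[:, None]
            mat_r = counts.reindex(gr)[cols_r].to_numpy(dtype=float) \
                * (ref_len / len_r)[:, None]
            pair_counts = pd.DataFrame(
                np.rint(np.hstack([mat_l, mat_r])),
                index=sub_trip.index,
                columns=[f"L_{c}" for c in cols_l] + [f"R_{c}" for c in cols_r],
            ).astype(np.int64)
            sf = None
            if gt_l == gt_r:
                sf = pd.Series(
                    np.concatenate([depth[gt_l][cols_l].to_numpy(),
                                    depth[gt_r][cols_r].to_numpy()]),
                    index=list(pair_counts.columns))
            res = run_contrast(
                pair_counts,
                ref_cols=[f"L_{c}" for c in cols_l],
                tgt_cols=[f"R_{c}" for c in cols_r],
                size_factors=sf,
                alpha=alpha,
                contrast=f"{setting}:{left}v{right}",
            )
            res = res.rename_axis("group_id").reset_index()
            res["setting"] = setting
            res["pair"] = f"{left}:{right}"
            res["call"] = res["call"].map(
                {"up": "left<", "down": "left>", "ns": "ns"})
            out.append(res[["group_id", "setting", "pair",
                            "log2fc", "pvalue", "qvalue", "call"]])
    return pd.concat(out, ignore_index=True)


def uth_table(uth_calls: pd.DataFrame) -> pd.DataFrame:
    """Table-style summary: per setting and pair, the unequal counts with
    percentages of the tested total."""
    rows = []
    for (setting, pair), sub in uth_calls.groupby(["setting", "pair"]):
        left, right = pair.split(":")
        n = len(sub)
        gt = int((sub["call"] == "left>").sum())
        lt = int((sub["call"] == "left<").sum())
        rows.append({
            "setting": setting, "pair": pair, "n_tested": n,
            f"left_gt": gt, f"left_lt": lt,
            "pct_left_gt": _pct(gt, n), "pct_left_lt": _pct(lt, n),
            "pct_uth": _pct(gt + lt, n),
        })
    return pd.DataFrame(rows)


def _pct(count: int, denom: int) -> float:
    from .report import percentage

    return percentage(count, denom)


# ---------------------------------------------------------------------------
# group-total contrasts (stratified)


def _strata(groups: pd.DataFrame, eligible: pd.Index) -> dict[str, list]:
    cls = groups.set_index("group_id")["class"]
    out = {}
    for stratum in TOTAL_STRATA:
        gids = [g for g in eligible if cls[g] == stratum]
        if len(gids) >= MIN_STRATUM:
            out[stratum] = gids
    return out


def _pooled_bh(frames: list[pd.DataFrame], alpha: float) -> pd.DataFrame:
    res = pd.concat(frames)
    res["qvalue"] = bh_adjust(res["pvalue"].to_numpy())
    res["call"] = call_de(res["qvalue"].to_numpy(),
                          res["log2fc"].to_numpy(), alpha)
    return res


def progeny_total_contrasts(totals: pd.DataFrame, samples: pd.DataFrame,
                            groups: pd.DataFrame, eligible: pd.Index,
                            generation: str,
                            alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """The three group-total contrasts behind ELD, plus the MPV contrast.

    Run per composition stratum with in-stratum normalisation, p-values
    pooled across strata before BH.  Returns {'vs_pab', 'vs_pd', 'parents',
    'mpv'} DataFrames indexed by group id (log2fc oriented
    progeny-over-parent, DD-parent-over-AABB-parent, progeny-over-MPV).
    """
    gsamp = genotype_samples(samples)
    prog = gsamp[generation]
    strata = _strata(groups, eligible)
    parts: dict[str, list] = {"vs_pab": [], "vs_pd": [], "parents": [],
                              "mpv": []}
    for stratum, gids in strata.items():
        sub = totals.loc[gids]
        parts["vs_pab"].append(run_contrast(
            sub[gsamp["P_AB"] + prog], gsamp["P_AB"], prog,
            alpha=alpha, contrast=f"{generation}_vs_PAB"))
        parts["vs_pd"].append(run_contrast(
            sub[gsamp["P_D"] + prog], gsamp["P_D"], prog,
            alpha=alpha, contrast=f"{generation}_vs_PD"))
        parts["parents"].append(run_contrast(
            sub[gsamp["P_AB"] + gsamp["P_D"]], gsamp["P_AB"], gsamp["P_D"],
            alpha=alpha, contrast="PD_vs_PAB"))
        parts["mpv"].append(_mpv_contrast(sub, gsamp, prog, generation,
                                          alpha))
    return {key: _pooled_bh(frames, alpha)
            for key, frames in parts.items() if frames}


def mid_parent_pseudosample(pab_norm: pd.DataFrame,
                            pd_norm: pd.DataFrame) -> pd.DataFrame:
    """MPV pseudo-replicates from normalised parental totals.

    Parental replicates are paired in sorted order (one pseudo-replicate per
    pairing, truncated to the shorter side); each pseudo-replicate is the
    rounded arithmetic mean of the pair.
    """
    k = min(pab_norm.shape[1], pd_norm.shape[1])
    cols = {}
    for j in range(k):
        cols[f"MPV_{j + 1}"] = np.rint(
            (pab_norm.iloc[:, j] + pd_norm.iloc[:, j]) / 2.0)
    return pd.DataFrame(cols, index=pab_norm.index).astype(np.int64)


def _mpv_contrast(sub: pd.DataFrame, gsamp: dict, prog: list[str],
                  generation: str, alpha: float) -> pd.DataFrame:
    cols = gsamp["P_AB"] + gsamp["P_D"] + prog
    sf = size_factors(sub[cols])
    norm = sub[cols].div(sf, axis=1)
    mpv = mid_parent_pseudosample(norm[gsamp["P_AB"]], norm[gsamp["P_D"]])
    prog_pseudo = np.rint(norm[prog]).astype(np.int64)
    prog_cols = [f"{generation}_{j + 1}" for j in range(len(prog))]
    pseudo = pd.concat(
        [mpv, prog_pseudo.set_axis(prog_cols, axis=1)], axis=1)
    unit = pd.Series(1.0, index=pseudo.columns)
    return run_contrast(pseudo, list(mpv.columns), prog_cols,
                        size_factors=unit, alpha=alpha,
                        contrast=f"{generation}_vs_MPV")


def classify_additivity(mpv_res: pd.DataFrame) -> pd.Series:
    """additive / nonadd_up / nonadd_down from the MPV contrast calls."""
    return mpv_res["call"].map(
        {"up": "nonadd_up", "down": "nonadd_down", "ns": "additive"})


def classify_eld(vs_pab: pd.DataFrame, vs_pd: pd.DataFrame,
                 parents: pd.DataFrame) -> pd.DataFrame:
    """ELD category and direction per group from the three total contrasts.

    Requires the parents to differ (otherwise 'none', reason recorded).
    ELD-ab: progeny indistinguishable from the AABB parent but different
    from the DD parent (ELD-d symmetric).  Significant same-direction
    departures from both parents are transgressive.  Direction is
    higher_parent when the matched parent carries the larger normalised
    total (sign of the parents contrast).
    """
    idx = vs_pab.index
    cat = pd.Series("none", index=idx, dtype=object)
    direction = pd.Series("na", index=idx, dtype=object)
    reason = pd.Series("", index=idx, dtype=object)

    par_ns = parents["call"] == "ns"
    reason[par_ns] = "parents_ns"
    sig_ab = vs_pab["call"] != "ns"
    sig_d = vs_pd["call"] != "ns"
    pd_higher = parents["log2fc"] > 0  # log2(PD / PAB)

    eld_ab = ~par_ns & ~sig_ab & sig_d
    eld_d = ~par_ns & sig_ab & ~sig_d
    both = ~par_ns & sig_ab & sig_d
    same_dir = np.sign(vs_pab["log2fc"]) == np.sign(vs_pd["log2fc"])
    trans_up = both & same_dir & (vs_pab["log2fc"] > 0)
    trans_down = both & same_dir & (vs_pab["log2fc"] < 0)

    cat[eld_ab] = "ELD-ab"
    cat[eld_d] = "ELD-d"
    cat[trans_up] = "transgressive_up"
    cat[trans_down] = "transgressive_down"
    direction[eld_ab & ~pd_higher] = "higher_parent"
    direction[eld_ab & pd_higher] = "lower_parent"
    direction[eld_d & pd_higher] = "higher_parent"
    direction[eld_d & ~pd_higher] = "lower_parent"
    both_ns = ~par_ns & ~sig_ab & ~sig_d
    reason[both_ns] = "progeny_similar_to_both"
    return pd.DataFrame({"eld": cat, "direction": direction,
                         "reason": reason})


# ---------------------------------------------------------------------------
# restoration


def boxplot_stats(values) -> dict:
    """Quartiles and 1.5-IQR whiskers (whisker = most extreme point within
    1.5 interquartile ranges of the quartile)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {"n": 0, "q1": np.nan, "median": np.nan, "q3": np.nan,
                "whisker_low": np.nan, "whisker_high": np.nan}
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr]
    hi = v[v <= q3 + 1.5 * iqr]
    return {"n": int(v.size), "q1": float(q1), "median": float(med),
            "q3": float(q3),
            "whisker_low": float(lo.min()), "whisker_high": float(hi.max())}


def restoration_analysis(de_f1: pd.DataFrame, de_s1: pd.DataFrame,
                         genomes: pd.Series) -> tuple[pd.DataFrame,
                                                      pd.DataFrame]:
    """Restoration calls and boxplot statistics for F1-disturbed genes.

    ``de_f1`` / ``de_s1`` are per-homoeologue contrasts against the gene's
    own parent (log2fc progeny over parent).  A gene disturbed in F1 is
    'restored' when its S1-vs-parent call is ns, else 'maintained'.  The
    statistics table gives, per genome and F1 direction, the boxplot summary
    of the F1/parent and S1/parent log2 ratios.
    """
    common = de_f1.index.intersection(de_s1.index)
    f1 = de_f1.loc[common]
    s1 = de_s1.loc[common]
    disturbed = f1.index[f1["call"] != "ns"]
    calls = pd.DataFrame(index=disturbed)
    calls["genome"] = genomes.reindex(disturbed)
    calls["f1_call"] = f1.loc[disturbed, "call"]
    calls["restoration"] = np.where(
        s1.loc[disturbed, "call"] == "ns", "restored", "maintained")

    stats = []
    for (genome, f1_call), sub in calls.groupby(["genome", "f1_call"]):
        for gen, table in (("F1", f1), ("S1", s1)):
            st = boxplot_stats(table.loc[sub.index, "log2fc"])
            stats.append({"genome": genome, "f1_direction": f1_call,
                          "generation": gen, **st})
        n_rest = int((sub["restoration"] == "restored").sum())
        stats[-1]["n_restored"] = n_rest
        stats[-1]["n_maintained"] = len(sub) - n_rest
    return calls, pd.DataFrame(stats)


# ---------------------------------------------------------------------------
# singletons


def singleton_complementation(fpkm: pd.DataFrame, samples: pd.DataFrame,
                              groups: pd.DataFrame,
                              threshold: float = 1.0) -> dict:
    """Expressed-singleton sets per genotype, Venn partition and
    single-parent-transcription genes.

    Expression = FPKM above the threshold in at least one sample of the
    genotype.  Single-parent transcription: expressed in exactly one parent
    and in at least one progeny generation.
    """
    gsamp = genotype_samples(samples)
    singles = groups[groups["class"].str.startswith("singleton")]
    gene_col = singles[["gene_A", "gene_B", "gene_D"]].apply(
        lambda r: "".join(r), axis=1)
    genome_col = singles["class"].str.split("_").str[1]
    info = pd.DataFrame({"gene_id": gene_col.to_numpy(),
                         "genome": genome_col.to_numpy()})
    info = info.set_index("gene_id")

    expressed = {}
    for gt, cols in gsamp.items():
        sub = fpkm.reindex(info.index)[cols]
        expressed[gt] = set(info.index[(sub > threshold).any(axis=1)])

    venn_rows = []
    genotypes = list(gsamp)
    for gene in info.index:
        pattern = tuple(gene in expressed[gt] for gt in genotypes)
        venn_rows.append({"gene_id": gene, "genome": info.loc[gene, "genome"],
                          **{f"in_{gt}": inc
                             for gt, inc in zip(genotypes, pattern)}})
    venn = pd.DataFrame(venn_rows).set_index("gene_id")
    region = venn.groupby(
        ["genome"] + [f"in_{gt}" for gt in genotypes]).size()
    region = region.rename("n_genes").reset_index()

    in_parent = {g: (g in expressed["P_AB"], g in expressed["P_D"])
                 for g in info.index}
    spt = [g for g in info.index
           if sum(in_parent[g]) == 1
           and (g in expressed["F1"] or g in expressed["S1"])]
    return {"expressed": expressed, "venn": venn, "venn_regions": region,
            "single_parent_transcription": sorted(spt)}


# ---------------------------------------------------------------------------
# orchestrator


def classify_groups(counts: pd.DataFrame, samples: pd.DataFrame,
                    groups: pd.DataFrame, lengths: pd.Series,
                    alpha: float = 0.05) -> dict:
    """Run the full group-level classification.

    Returns a dict with the FPKM table, retention flags, UTH calls and
    summary, per-generation additivity/ELD classifications, per-homoeologue
    own-parent contrasts, restoration calls/statistics, the singleton
    analysis and a per-group classification table.
    """
    fpkm = fpkm_matrix(counts, lengths)
    retained_genes = retention_filter(fpkm)
    gsamp = genotype_samples(samples)
    ret = parental_retention(fpkm, samples, groups)
    totals = group_totals(counts, groups)

    gidx = groups.set_index("group_id")
    triplets = gidx.index[gidx["class"] == "triplet"]
    uth_eligible = pd.Index([g for g in triplets
                             if ret.loc[g, "retained_any_parent"]])
    uth_calls = uth_analysis(counts, samples, groups, lengths,
                             uth_eligible, alpha)

    total_eligible = pd.Index(
        [g for g in gidx.index
         if gidx.loc[g, "class"] in TOTAL_STRATA
         and ret.loc[g, "retained_pab"] and ret.loc[g, "retained_pd"]])

    per_generation = {}
    for gen in GENERATIONS:
        contrasts = progeny_total_contrasts(totals, samples, groups,
                                            total_eligible, gen, alpha)
        add = classify_additivity(contrasts["mpv"])
        eld = classify_eld(contrasts["vs_pab"], contrasts["vs_pd"],
                           contrasts["parents"])
        per_generation[gen] = {"contrasts": contrasts, "additivity": add,
                               "eld": eld}

    genomes = pd.Series(
        {row[f"gene_{g}"]: g for _, row in groups.iterrows()
         for g in ("A", "B", "D") if row[f"gene_{g}"]})
    de_own_parent = {}
    for gen in GENERATIONS:
        frames = []
        ab_genes = counts.index[genomes.reindex(counts.index).isin(["A", "B"])
                                & retained_genes]
        d_genes = counts.index[(genomes.reindex(counts.index) == "D")
                               & retained_genes]
        if len(ab_genes):
            frames.append(run_contrast(
                counts.loc[ab_genes, gsamp["P_AB"] + gsamp[gen]],
                gsamp["P_AB"], gsamp[gen], alpha=alpha,
                contrast=f"{gen}_vs_parent"))
        if len(d_genes):
            frames.append(run_contrast(
                counts.loc[d_genes, gsamp["P_D"] + gsamp[gen]],
                gsamp["P_D"], gsamp[gen], alpha=alpha,
                contrast=f"{gen}_vs_parent"))
        de_own_parent[gen] = _pooled_bh(frames, alpha)

    s1_vs_f1 = run_contrast(
        counts.loc[retained_genes, gsamp["F1"] + gsamp["S1"]],
        gsamp["F1"], gsamp["S1"], alpha=alpha, contrast="S1_vs_F1")

    restoration_calls, restoration_stats = restoration_analysis(
        de_own_parent["F1"], de_own_parent["S1"], genomes)

    singles = singleton_complementation(fpkm, samples, groups)

    classification = pd.DataFrame(index=pd.Index(total_eligible,
                                                 name="group_id"))
    classification["class"] = gidx.loc[total_eligible, "class"]
    for gen in GENERATIONS:
        classification[f"additivity_{gen}"] = per_generation[gen]["additivity"]
        classification[f"eld_{gen}"] = per_generation[gen]["eld"]["eld"]
        classification[f"eld_direction_{gen}"] = \
            per_generation[gen]["eld"]["direction"]

    return {
        "fpkm": fpkm,
        "retained_genes": retained_genes,
        "parental_retention": ret,
        "totals": totals,
        "uth_calls": uth_calls,
        "uth_table": uth_table(uth_calls),
        "per_generation": per_generation,
        "de_own_parent": de_own_parent,
        "s1_vs_f1": s1_vs_f1,
        "restoration_calls": restoration_calls,
        "restoration_stats": restoration_stats,
        "singletons": singles,
        "classification": classification,
    }
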