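"""Seeded mock allopolyploidization experiment.

Emulates the design of a wheat-style synthetic allohexaploid study: a
tetraploid parent (AABB), a diploid parent (DD), their allotriploid hybrid
(F1, ABD) and the genome-doubled allohexaploid (S1, AABBDD), each sequenced
with a small number of RNA-Seq replicates.  Genes are organised in
homoeologue groups (triplets / duplets / singletons across the A, B and D
subgenomes); counts are negative-binomial; a configurable set of effect
classes is planted (D-homoeologue suppression in the hybrid with partial
restoration after genome doubling, expression-level dominance towards either
parent, non-additive deviation from the mid-parent value, and genome-specific
singletons), and every planted effect is recorded in a truth ledger so that
downstream classifiers can be validated by parameter recovery.

Modelling conventions (see docs/methods.md for rationale):

* NB parameterisation throughout: ``variance = mu + alpha * mu**2`` where
  ``alpha`` is ``nb_dispersion``.
* All members of a group share one baseline per-copy mean, mirroring the
  near-unity median homoeologue abundance ratio observed in real allopolyploid
  leaf transcriptomes.  Parents express only their own subgenome copies;
  progeny express every copy at the parental per-copy level unless an effect
  class says otherwise.
* Per-sample size factors are uniform multipliers in [0.7, 1.3], enough to
  exercise normalisation without overwhelming it.
* Reads are unpaired, fixed-length, substitution-errors-only; read names
  carry an audit tag (gene, genome, group) for truth comparisons.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

GENOMES = ("A", "B", "D")
GENOTYPES = ("P_AB", "P_D", "F1", "S1")

#: planted effect classes a gene can carry (mutually exclusive)
CLASSES = (
    "neutral",
    "f1_down_restored",
    "f1_down_maintained",
    "eld_ab",
    "eld_d",
    "nonadd_up",
    "nonadd_down",
    "singleton_expressed",
    "singleton_silent",
)

# magnitudes of planted group-level effects (log2); fixed design constants
ELD_PARENT_DELTA = 1.5       # |log2 T_D / T_AB| for ELD groups
NONADD_LOG2FC = 1.5          # |log2 progeny / additive expectation|
SINGLETON_EXPRESSED_FRAC = 0.3   # share of singletons with nonzero expression

#: relative substitution rates at codon positions 1/2/3 (mean 1), emulating
#: purifying selection: most divergence accumulates at (largely synonymous)
#: third positions, keeping protein identity high at a given nucleotide
#: divergence, as in real homoeologues
CODON_POSITION_RATE_WEIGHTS = (0.25, 0.15, 2.6)

_SENSE_CODONS = None
_STOPS = ("TAA", "TAG", "TGA")


@dataclasses.dataclass
class SimConfig:
    """Parameters of the mock experiment.

    ``baseline_mean_range`` is on the count scale (expected reads per gene
    per replicate before size factors); gene lengths are in bp and are
    rounded down to whole codons.
    """

    n_triplets: int = 100
    n_duplets: int = 60
    n_singletons_per_genome: int = 50
    divergence_rate: float = 0.02
    gene_length_range: tuple[int, int] = (300, 1500)
    baseline_mean_range: tuple[float, float] = (50.0, 500.0)
    nb_dispersion: float = 0.05
    frac_f1_d_down: float = 0.326
    f1_down_log2fc: float = -2.0
    frac_restored_in_s1: float = 0.38
    frac_eld_ab: float = 0.10
    frac_eld_d: float = 0.02
    frac_nonadditive_up: float = 0.004
    frac_nonadditive_down: float = 0.032
    replicates_per_genotype: int = 2
    library_size_range: tuple[int, int] | None = None
    read_length: int = 100
    read_error_rate: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_f1_d_down": self.frac_f1_d_down,
            "frac_restored_in_s1": self.frac_restored_in_s1,
            "frac_eld_ab": self.frac_eld_ab,
            "frac_eld_d": self.frac_eld_d,
            "frac_nonadditive_up": self.frac_nonadditive_up,
            "frac_nonadditive_down": self.frac_nonadditive_down,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} must lie in [0, 1]")
        cat_sum = (self.frac_eld_ab + self.frac_eld_d
                   + self.frac_nonadditive_up + self.frac_nonadditive_down)
        if cat_sum > 1.0:
            raise ValueError(
                f"planted category fractions sum to {cat_sum:.3f} > 1")
        if not 0.0 <= self.divergence_rate < 0.25:
            raise ValueError("divergence_rate must lie in [0, 0.25)")
        if self.replicates_per_genotype < 1:
            raise ValueError("replicates_per_genotype must be >= 1")
        if self.gene_length_range[0] < self.read_length:
            raise ValueError("gene lengths must be >= read_length")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be (low, high)")
        if self.baseline_mean_range[0] <= 0:
            raise ValueError("baseline means must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("gene_length_range", "baseline_mean_range",
                    "library_size_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def sample_names(self) -> list[str]:
        return [f"{gt}_{r}" for gt in GENOTYPES
                for r in range(1, self.replicates_per_genotype + 1)]

    def sample_sheet(self) -> pd.DataFrame:
        rows = [(f"{gt}_{r}", gt, r) for gt in GENOTYPES
                for r in range(1, self.replicates_per_genotype + 1)]
        return pd.DataFrame(rows, columns=["sample", "genotype", "replicate"])


def expected_pairwise_identity(divergence_rate: float) -> float:
    """Closed-form expected nucleotide identity between two homoeologues.

    Each copy mutates independently from the common ancestor; at a site with
    substitution probability ``r`` (the configured rate times its codon
    position's weight) the copies stay identical when neither mutated or
    both picked the same of the three alternatives: ``(1-r)^2 + r^2/3``
    (equivalently ``1 - 2 r (1-r) k`` with ``k = 1 + r/(3(1-r))``).  The
    expectation averages this over the three codon-position rates.
    """
    d = divergence_rate
    per_site = [(1.0 - d * w) ** 2 + (d * w) ** 2 / 3.0
                for w in CODON_POSITION_RATE_WEIGHTS]
    return float(np.mean(per_site))


def expected_diagnostic_fraction(divergence_rate: float) -> float:
    """Expected fraction of sites at which a homoeologue pair disagrees."""
    return 1.0 - expected_pairwise_identity(divergence_rate)


# ---------------------------------------------------------------------------
# universe


def simulate_universe(config: SimConfig):
    """Create the gene catalogue, homoeologue groups and truth ledger.

    Returns ``(genes, groups, truth)``:

    * ``genes``: DataFrame [gene_id, genome, group_id, length]
    * ``groups``: DataFrame [group_id, class, gene_A, gene_B, gene_D]
    * ``truth``: DataFrame, one row per gene, with the planted class, the
      baseline per-copy mean and the per-copy mean for every genotype (from
      which planted log2 fold changes for any contrast follow).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    group_rows = []
    gene_rows = []
    idx = 0

    def new_group(members: tuple[str, ...]) -> str:
        nonlocal idx
        idx += 1
        gid = f"HG{idx:05d}"
        if len(members) == 3:
            cls = "triplet"
        elif len(members) == 2:
            cls = "duplet_" + "".join(members)
        else:
            cls = "singleton_" + members[0]
        row = {"group_id": gid, "class": cls,
               "gene_A": "", "gene_B": "", "gene_D": ""}
        length = _draw_length(rng, config)
        for g in members:
            gene_id = f"{gid}{g}"
            row[f"gene_{g}"] = gene_id
            gene_rows.append((gene_id, g, gid, length))
        group_rows.append(row)
        return gid

    for _ in range(config.n_triplets):
        new_group(("A", "B", "D"))
    duplet_kinds = [("A", "B"), ("A", "D"), ("B", "D")]
    for _ in range(config.n_duplets):
        new_group(duplet_kinds[rng.integers(0, 3)])
    for g in GENOMES:
        for _ in range(config.n_singletons_per_genome):
            new_group((g,))

    genes = pd.DataFrame(gene_rows,
                         columns=["gene_id", "genome", "group_id", "length"])
    groups = pd.DataFrame(group_rows)

    truth = _plant_effects(genes, groups, config, rng)
    return genes, groups, truth


def _draw_length(rng, config: SimConfig) -> int:
    lo, hi = config.gene_length_range
    length = int(rng.integers(lo, hi + 1))
    length -= length % 3
    return max(length, lo + (3 - lo % 3) % 3)


def _plant_effects(genes: pd.DataFrame, groups: pd.DataFrame,
                   config: SimConfig, rng) -> pd.DataFrame:
    """Assign one effect class per group and derive per-copy means."""
    multi = groups[groups["class"].str.startswith(("triplet", "duplet"))]
    # ELD / non-additivity need a nonzero total in both parents: exclude AB
    # duplets (no D copy => DD parent total is structurally zero).
    eligible = multi[multi["class"] != "duplet_AB"]["group_id"].to_numpy()
    probs = np.array([config.frac_eld_ab, config.frac_eld_d,
                      config.frac_nonadditive_up, config.frac_nonadditive_down])
    labels = np.array(["eld_ab", "eld_d", "nonadd_up", "nonadd_down"])
    draw = rng.random(eligible.size)
    edges = np.concatenate([[0.0], np.cumsum(probs)])
    group_class = {gid: "neutral" for gid in groups["group_id"]}
    for gid, u in zip(eligible, draw):
        k = np.searchsorted(edges, u, side="right") - 1
        if k < len(labels):
            group_class[gid] = labels[k]

    # D-homoeologue suppression among groups still neutral that carry a D copy
    cls_of = dict(zip(groups["group_id"], groups["class"]))
    has_d = set(groups.loc[groups["gene_D"] != "", "group_id"])
    for gid in groups["group_id"]:
        if group_class[gid] == "neutral" and gid in has_d \
                and cls_of[gid] != "singleton_D" \
                and rng.random() < config.frac_f1_d_down:
            if rng.random() < config.frac_restored_in_s1:
                group_class[gid] = "f1_down_restored"
            else:
                group_class[gid] = "f1_down_maintained"

    # singletons
    single = groups[groups["class"].str.startswith("singleton")]
    for gid in single["group_id"]:
        group_class[gid] = ("singleton_expressed"
                            if rng.random() < SINGLETON_EXPRESSED_FRAC
                            else "singleton_silent")

    lo, hi = config.baseline_mean_range
    log_mu = rng.uniform(np.log(lo), np.log(hi), size=len(groups))
    base_mean = dict(zip(groups["group_id"], np.exp(log_mu)))
    eld_sign = {gid: (1.0 if rng.random() < 0.5 else -1.0)
                for gid in groups["group_id"]}

    members = genes.groupby("group_id")["genome"].apply(list).to_dict()
    rows = []
    for _, g in genes.iterrows():
        gid = g["group_id"]
        cls = group_class[gid]
        mu = base_mean[gid]
        mem = members[gid]
        means = _member_means(g["genome"], cls, mu, mem, eld_sign[gid], config)
        rows.append({
            "gene_id": g["gene_id"], "group_id": gid, "genome": g["genome"],
            "length": g["length"], "class": cls, "base_mean": mu,
            **{f"mean_{gt}": means[gt] for gt in GENOTYPES},
        })
    truth = pd.DataFrame(rows)
    return truth


def _member_means(genome: str, cls: str, mu: float, members: list[str],
                  eld_sign: float, config: SimConfig) -> dict[str, float]:
    """Per-copy expected counts for one gene in each genotype."""
    own_parent = "P_D" if genome == "D" else "P_AB"
    means = {gt: 0.0 for gt in GENOTYPES}
    delta = eld_sign * ELD_PARENT_DELTA

    parent_copy = mu
    f1 = mu
    s1 = mu
    if cls == "singleton_silent":
        parent_copy = f1 = s1 = 0.0
    elif cls in ("f1_down_restored", "f1_down_maintained") and genome == "D":
        f1 = mu * 2.0 ** config.f1_down_log2fc
        s1 = mu if cls == "f1_down_restored" else f1
    elif cls == "eld_ab":
        # the DD parent's copy sits off the genome-wide per-copy norm but the
        # progeny stays at the AABB-like norm: the D homoeologue is pulled
        # to mu in the hybrid (up- or down-regulated relative to its parent)
        if genome == "D":
            parent_copy = mu * 2.0 ** delta
    elif cls == "eld_d":
        # progeny follows the deviant DD parent: every copy moves with it
        if genome == "D":
            parent_copy = mu * 2.0 ** delta
        f1 = s1 = mu * 2.0 ** delta
    elif cls in ("nonadd_up", "nonadd_down"):
        sign = 1.0 if cls == "nonadd_up" else -1.0
        f1 = mu * 2.0 ** (sign * NONADD_LOG2FC)
        s1 = mu  # deviation reverts after genome doubling

    means[own_parent] = parent_copy
    means["F1"] = f1
    means["S1"] = s1
    return means


def truth_group_summary(truth: pd.DataFrame) -> pd.DataFrame:
    """Group-level planted expectations derived from the per-copy means.

    Adds the parental totals, the mid-parent value and the planted log2
    deviations of each progeny generation's total from the MPV — the ground
    truth the additivity/ELD classifiers are validated against.
    """
    agg = truth.groupby("group_id").agg(
        cls=("class", "first"),
        t_ab=("mean_P_AB", "sum"),
        t_d=("mean_P_D", "sum"),
        t_f1=("mean_F1", "sum"),
        t_s1=("mean_S1", "sum"),
    )
    n_ab = truth[truth["genome"].isin(["A", "B"])].groupby("group_id").size()
    n_d = truth[truth["genome"] == "D"].groupby("group_id").size()
    agg["n_ab"] = n_ab.reindex(agg.index, fill_value=0)
    agg["n_d"] = n_d.reindex(agg.index, fill_value=0)
    mpv = (agg["t_ab"] + agg["t_d"]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["l2fc_f1_vs_mpv"] = np.log2(agg["t_f1"]) - np.log2(mpv)
        agg["l2fc_s1_vs_mpv"] = np.log2(agg["t_s1"]) - np.log2(mpv)
        agg["l2fc_pd_vs_pab"] = np.log2(agg["t_d"]) - np.log2(agg["t_ab"])
    # A no-change group sits at log2(total/MPV) = 1 whatever its member
    # composition (all copies at the shared per-copy mean, parents together
    # holding every copy once); per-contrast normalisation absorbs that
    # constant, so the planted deviation is measured relative to it.
    agg["mpv_dev_f1"] = agg["l2fc_f1_vs_mpv"] - 1.0
    agg["mpv_dev_s1"] = agg["l2fc_s1_vs_mpv"] - 1.0
    # parents' deviation from the composition-neutral expectation
    # (n_d copies in DD vs n_ab copies in AABB at the shared per-copy mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["parent_dev"] = agg["l2fc_pd_vs_pab"] - (
            np.log2(agg["n_d"].where(agg["n_d"] > 0))
            - np.log2(agg["n_ab"].where(agg["n_ab"] > 0)))
    return agg.reset_index()


# ---------------------------------------------------------------------------
# sequences


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        bases = "ACGT"
        _SENSE_CODONS = [a + b + c for a in bases for b in bases for c in bases
                         if a + b + c not in _STOPS]
    return _SENSE_CODONS


def simulate_sequences(genes: pd.DataFrame, config: SimConfig,
                       rng=None) -> pd.DataFrame:
    """Transcript and protein sequences per gene.

    One ancestral in-frame transcript per group (uniform sense codons); each
    member's copy mutates every site independently with probability
    ``divergence_rate`` (uniform among the three alternatives).  Codons that
    a mutation turns into a stop are repaired by setting the third position
    to ``C``, keeping translation total.  Returns a DataFrame
    [gene_id, genome, group_id, transcript, protein].
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.default_rng(config.seed)
                                    .integers(0, 2**31))
    from Bio.Seq import Seq

    codons = np.array(_sense_codons())
    base_idx = {b: i for i, b in enumerate("ACGT")}
    bases = np.array(list("ACGT"))
    rows = []
    for gid, sub in genes.groupby("group_id", sort=True):
        length = int(sub["length"].iloc[0])
        anc = "".join(rng.choice(codons, size=length // 3))
        anc_arr = np.frombuffer(anc.encode(), dtype="S1").astype("U1")
        anc_idx = np.vectorize(base_idx.get)(anc_arr)
        n_sites = len(anc_idx)
        site_rate = config.divergence_rate * np.tile(
            CODON_POSITION_RATE_WEIGHTS, n_sites // 3)
        for _, g in sub.sort_values("gene_id").iterrows():
            seq_idx = anc_idx.copy()
            if config.divergence_rate > 0:
                hit = rng.random(n_sites) < site_rate
                shift = rng.integers(1, 4, size=int(hit.sum()))
                seq_idx[hit] = (seq_idx[hit] + shift) % 4
            seq = "".join(bases[seq_idx])
            seq = _repair_stops(seq)
            prot = str(Seq(seq).translate())
            rows.append((g["gene_id"], g["genome"], gid, seq, prot))
    return pd.DataFrame(
        rows, columns=["gene_id", "genome", "group_id", "transcript", "protein"])


def _repair_stops(seq: str) -> str:
    out = list(seq)
    for i in range(0, len(out) - 2, 3):
        if "".join(out[i:i + 3]) in _STOPS:
            out[i + 2] = "C"
    return "".join(out)


# ---------------------------------------------------------------------------
# counts


def simulate_counts(truth: pd.DataFrame, config: SimConfig,
                    rng=None) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """NB read counts for every gene x sample.

    Returns ``(counts, samples, size_factors)``; counts index is gene_id and
    columns are sample names.  Parents have structural zeros for the absent
    subgenome; the planted per-copy means of the truth ledger drive F1/S1.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.default_rng(config.seed)
                                    .integers(0, 2**31) + 1)
    samples = config.sample_sheet()
    factors = pd.Series(rng.uniform(0.7, 1.3, size=len(samples)),
                        index=samples["sample"])
    alpha = config.nb_dispersion

    cols = {}
    for _, s in samples.iterrows():
        mu = truth[f"mean_{s['genotype']}"].to_numpy() * factors[s["sample"]]
        if config.library_size_range is not None:
            lo, hi = config.library_size_range
            target = rng.uniform(lo, hi)
            total = mu.sum()
            if total > 0:
                mu = mu * (target / total)
        cols[s["sample"]] = _nb_draw(rng, mu, alpha)
    counts = pd.DataFrame(cols, index=truth["gene_id"])
    counts.index.name = "gene_id"
    return counts, samples, factors


def _nb_draw(rng, mu: np.ndarray, alpha: float) -> np.ndarray:
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if alpha <= 0:
        out[pos] = rng.poisson(mu[pos])
    else:
        shape = 1.0 / alpha
        lam = rng.gamma(shape, alpha * mu[pos])
        out[pos] = rng.poisson(lam)
    return out


# ---------------------------------------------------------------------------
# reads


def simulate_reads(sequences: pd.DataFrame, counts: pd.DataFrame,
                   config: SimConfig, rng=None):
    """Yield ``(sample, read_id, sequence)`` for every read of every sample.

    Exactly ``counts.loc[gene, sample]`` reads per gene, drawn uniformly from
    the gene's own transcript, with independent per-base substitution errors
    at ``read_error_rate``.  Read ids encode the audit tag
    ``gene|genome|group|serial``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.default_rng(config.seed)
                                    .integers(0, 2**31) + 2)
    seqs = sequences.set_index("gene_id")
    too_short = seqs["transcript"].str.len() < config.read_length
    if too_short.any():
        raise ValueError("read_length exceeds the length of some transcripts")
    bases = np.array(list("ACGT"))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    rl = config.read_length
    for sample in counts.columns:
        for gene_id, n in counts[sample].items():
            n = int(n)
            if n == 0:
                continue
            row = seqs.loc[gene_id]
            tpl = np.array([base_idx[b] for b in row["transcript"]],
                           dtype=np.int8)
            starts = rng.integers(0, len(tpl) - rl + 1, size=n)
            for i, st in enumerate(starts):
                read = tpl[st:st + rl].copy()
                if config.read_error_rate > 0:
                    hit = rng.random(rl) < config.read_error_rate
                    if hit.any():
                        read[hit] = (read[hit]
                                     + rng.integers(1, 4, size=int(hit.sum()))) % 4
                rid = f"{gene_id}|{row['genome']}|{row['group_id']}|r{i}"
                yield sample, rid, "".join(bases[read])


# ---------------------------------------------------------------------------
# file output


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_experiment(outdir: str | Path, config: SimConfig,
                     with_reads: bool = True) -> dict[str, Path]:
    """Run the full generator and write the standard file bundle.

    Emits ``transcripts.fasta`` / ``proteins.fasta`` (headers
    ``geneID|genome|groupID``), per-sample FASTQ (optional), ``counts.tsv``,
    ``samples.tsv``, ``truth.tsv`` and ``groups.tsv``.  Byte-identical for
    identical config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, groups, truth = simulate_universe(config)
    seqs = simulate_sequences(genes, config)
    counts, samples, factors = simulate_counts(truth, config)

    paths = {}
    headers = seqs["gene_id"] + "|" + seqs["genome"] + "|" + seqs["group_id"]
    paths["transcripts"] = outdir / "transcripts.fasta"
    write_fasta(zip(headers, seqs["transcript"]), paths["transcripts"])
    paths["proteins"] = outdir / "proteins.fasta"
    write_fasta(zip(headers, seqs["protein"]), paths["proteins"])
    paths["counts"] = outdir / "counts.tsv"
    counts.to_csv(paths["counts"], sep="\t")
    paths["samples"] = outdir / "samples.tsv"
    samples.to_csv(paths["samples"], sep="\t", index=False)
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["groups"] = outdir / "groups.tsv"
    groups.to_csv(paths["groups"], sep="\t", index=False)

    if with_reads:
        handles = {}
        try:
            for sample, rid, seq in simulate_reads(seqs, counts, config):
                fh = handles.get(sample)
                if fh is None:
                    p = outdir / f"reads_{sample}.fastq"
                    paths[f"reads_{sample}"] = p
                    fh = handles[sample] = open(p, "w")
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
        finally:
            for fh in handles.values():
                fh.close()
    return paths
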