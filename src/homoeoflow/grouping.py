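"""Partition genes into homoeologue triplets, duplets and singletons.

All-vs-all protein comparison between subgenomes with a local dynamic
programming aligner (BLOSUM62, affine gaps), a shared-k-mer prefilter in the
role of BLAST seeding, and a fixed-constant Karlin-Altschul-style E-value
proxy.  Pairs passing E-value <= 1e-5, identity >= 90% and coverage >= 90%
of the shorter sequence are joined; connected components with at most one
gene per subgenome become groups directly, and components with within-genome
duplicates are resolved greedily by best summed alignment score, displaced
genes dropping to singletons.

The E-value proxy serves only as a filter (the thresholds are the decision
rule); it is not a calibrated statistic.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from collections import defaultdict

import networkx as nx
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

# fixed gapped-BLOSUM62 constants for the E-value proxy
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclasses.dataclass
class GroupingConfig:
    min_identity: float = 0.90
    min_alignment_coverage: float = 0.90
    max_evalue: float = 1e-5
    scoring: str = "blosum62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    # BLAST-seed-like prefilter: only align pairs sharing enough words
    seed_kmer: int = 5
    min_shared_kmers: int = 2

    def validate(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must lie in (0, 1]")
        if not 0.0 < self.min_alignment_coverage <= 1.0:
            raise ValueError("min_alignment_coverage must lie in (0, 1]")


def _make_aligner(config: GroupingConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(
        config.scoring.upper())
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    return aligner


def align_pair(protein_a: str, protein_b: str,
               config: GroupingConfig | None = None,
               aligner: PairwiseAligner | None = None):
    """Local alignment of two proteins.

    Returns ``(identity, coverage, score, evalue)`` where identity is
    matches over alignment columns (gap columns included), coverage is the
    aligned span over the length of the shorter sequence, and the E-value is
    the fixed-constant proxy ``K * m * n * exp(-lambda * S)``.
    """
    if config is None:
        config = GroupingConfig()
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    if aligner is None:
        aligner = _make_aligner(config)
    alignments = aligner.align(protein_a, protein_b)
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0, 0.0, 0.0, math.inf
    score = float(aln.score)
    matches = 0
    columns = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        seg_a = protein_a[a_start:a_end]
        seg_b = protein_b[b_start:b_end]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        columns += a_end - a_start
    # gap columns between aligned blocks
    blocks_a, blocks_b = aln.aligned
    for i in range(1, len(blocks_a)):
        columns += max(blocks_a[i][0] - blocks_a[i - 1][1],
                       blocks_b[i][0] - blocks_b[i - 1][1])
    if columns == 0:
        return 0.0, 0.0, score, math.inf
    identity = matches / columns
    shorter = min(len(protein_a), len(protein_b))
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    span = span_a if len(protein_a) <= len(protein_b) else span_b
    coverage = span / shorter
    evalue = _KA_K * len(protein_a) * len(protein_b) * math.exp(
        -_KA_LAMBDA * score)
    return identity, coverage, score, evalue


def _kmer_sets(proteins: pd.Series, k: int) -> dict:
    return {gid: {seq[i:i + k] for i in range(len(seq) - k + 1)}
            for gid, seq in proteins.items()}


def build_similarity_graph(proteins: pd.Series, genomes: pd.Series,
                           config: GroupingConfig | None = None) -> nx.Graph:
    """Undirected similarity graph between genes of different subgenomes.

    ``proteins`` maps gene id -> sequence, ``genomes`` gene id -> subgenome
    label.  Edge (g1, g2) iff the genomes differ and the alignment passes the
    E-value, identity and coverage thresholds; edges carry the alignment
    score as weight.  Same-genome pairs are never joined.
    """
    if config is None:
        config = GroupingConfig()
    config.validate()
    if proteins.index.duplicated().any():
        raise ValueError("duplicate gene IDs")
    aligner = _make_aligner(config)
    graph = nx.Graph()
    graph.add_nodes_from(proteins.index)

    kmers = _kmer_sets(proteins, config.seed_kmer)
    by_genome = defaultdict(list)
    for gid in proteins.index:
        by_genome[genomes[gid]].append(gid)
    for ga, gb in itertools.combinations(sorted(by_genome), 2):
        for g1 in by_genome[ga]:
            set1 = kmers[g1]
            for g2 in by_genome[gb]:
                if len(set1 & kmers[g2]) < config.min_shared_kmers:
                    continue
                ident, cov, score, ev = align_pair(
                    proteins[g1], proteins[g2], config, aligner)
                if (ev <= config.max_evalue
                        and ident >= config.min_identity
                        and cov >= config.min_alignment_coverage):
                    graph.add_edge(g1, g2, weight=score)
    return graph


def partition_groups(graph: nx.Graph, genomes: pd.Series) -> pd.DataFrame:
    """Resolve the similarity graph into homoeologue groups.

    Components with at most one gene per subgenome become a group directly.
    In components with within-genome duplicates, subgenomes with a unique
    candidate are fixed first; each remaining subgenome then keeps the gene
    with the highest summed edge weight to the kept members (to all
    other-genome candidates while nothing is kept yet), ties broken by
    lexicographic gene id, and displaced genes become singletons.

    Returns a DataFrame [group_id, class, gene_A, gene_B, gene_D] covering
    every input gene exactly once.
    """
    rows = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        per_genome = defaultdict(list)
        for gid in members:
            per_genome[genomes[gid]].append(gid)
        if all(len(v) == 1 for v in per_genome.values()):
            rows.append({g: v[0] for g, v in per_genome.items()})
            continue
        kept = {g: v[0] for g, v in per_genome.items() if len(v) == 1}
        displaced = []
        for g in sorted(per_genome):
            cands = per_genome[g]
            if len(cands) == 1:
                continue
            anchors = [gid for gg, gid in kept.items() if gg != g]
            if not anchors:
                anchors = [gid for gid in members if genomes[gid] != g]

            def summed(gid):
                return sum(graph[gid][a]["weight"] for a in anchors
                           if graph.has_edge(gid, a))

            best = min(cands, key=lambda gid: (-summed(gid), gid))
            kept[g] = best
            displaced.extend(c for c in cands if c != best)
        rows.append(dict(kept))
        rows.extend({genomes[gid]: gid} for gid in sorted(displaced))

    # deterministic ordering and ids
    rows.sort(key=lambda r: sorted(r.values())[0])
    out = []
    for i, row in enumerate(rows, start=1):
        present = "".join(sorted(row))
        if len(row) == 3:
            cls = "triplet"
        elif len(row) == 2:
            cls = f"duplet_{present}"
        else:
            cls = f"singleton_{present}"
        out.append({
            "group_id": f"HG{i:05d}", "class": cls,
            "gene_A": row.get("A", ""),
            "gene_B": row.get("B", ""),
            "gene_D": row.get("D", ""),
        })
    return pd.DataFrame(out,
                        columns=["group_id", "class",
                                 "gene_A", "gene_B", "gene_D"])


def read_protein_fasta(path) -> tuple[pd.Series, pd.Series]:
    """Load proteins with genome labels from ``geneID|genome|...`` headers."""
    from Bio import SeqIO

    seqs, gens = {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2:
            raise ValueError(f"header {rec.id!r} lacks a genome label")
        gene, genome = parts[0], parts[1]
        seqs[gene] = str(rec.seq)
        gens[gene] = genome
    return pd.Series(seqs), pd.Series(gens)
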