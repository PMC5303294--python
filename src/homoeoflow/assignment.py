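"""Subgenome-of-origin read assignment via diagnostic positions.

Stands in for reference-genome alignment plus homoeologue-specific read
filtering: reads are placed on the known member transcripts of a homoeologue
group (exact match, then bounded edit distance), and the bases they carry at
diagnostic columns — alignment columns where the member transcripts disagree
— vote for the subgenome of origin.  A read whose covered diagnostic
positions all point at one subgenome is assigned to it; disagreeing votes,
or equally good placements with no diagnostic coverage, leave the read
ambiguous; reads that place nowhere are unassigned.  An artefact filter
flags genes that receive expression in the parent that structurally lacks
their subgenome (polymorphism artefacts in the real pipeline) for exclusion
from all downstream contrasts.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict

import edlib
import numpy as np
import pandas as pd

from .quantify import fpkm_matrix

LABELS = ("A", "B", "D", "ambiguous", "unassigned")


@dataclasses.dataclass
class DiagnosticIndex:
    """Diagnostic columns of one homoeologue group.

    ``sites`` is a list of ``(positions, bases)`` pairs: per diagnostic
    column, the 0-based position in each member's own coordinates and the
    base each member carries there.  ``by_member`` gives, per genome, the
    (member position, column index) pairs sorted by position.
    """

    genomes: tuple[str, ...]
    sites: list[tuple[dict, dict]]
    by_member: dict

    def __len__(self) -> int:
        return len(self.sites)


def build_diagnostic_index(members: dict[str, str]) -> DiagnosticIndex:
    """Align the member transcripts of a group and record diagnostic columns.

    Singleton groups yield an empty index (assignment is by unique best
    match).  Equal-length members are compared column-wise; otherwise a star
    alignment against the first member (global pairwise alignments) maps
    every member onto common columns, and only columns present in all
    members are considered.
    """
    genomes = tuple(sorted(members))
    if len(genomes) < 2:
        return DiagnosticIndex(genomes, [], {g: [] for g in genomes})
    seqs = {g: members[g].upper() for g in genomes}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) == 1:
        coords = {g: list(range(len(seqs[g]))) for g in genomes}
        n_cols = lengths.pop()
    else:
        coords, n_cols = _star_coords(seqs, genomes)

    sites = []
    by_member = {g: [] for g in genomes}
    for col in range(n_cols):
        pos = {g: coords[g][col] for g in genomes}
        if any(p is None for p in pos.values()):
            continue
        bases = {g: seqs[g][pos[g]] for g in genomes}
        if len(set(bases.values())) >= 2:
            idx = len(sites)
            sites.append((pos, bases))
            for g in genomes:
                by_member[g].append((pos[g], idx))
    return DiagnosticIndex(genomes, sites, by_member)


def _star_coords(seqs: dict[str, str], genomes: tuple[str, ...]):
    """Map every member onto the first member's columns via global alignment."""
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    ref_g = genomes[0]
    ref = seqs[ref_g]
    coords = {ref_g: list(range(len(ref)))}
    for g in genomes[1:]:
        aln = aligner.align(ref, seqs[g])[0]
        mapped = [None] * len(ref)
        for (r0, r1), (q0, q1) in zip(*aln.aligned):
            for off in range(r1 - r0):
                mapped[r0 + off] = q0 + off
        coords[g] = mapped
    return coords, len(ref)


def assign_read(read: str, index: DiagnosticIndex,
                members: dict[str, str],
                max_edits: int | None = None) -> str:
    """Label one read: a subgenome, 'ambiguous' or 'unassigned'.

    The read is placed on each member (exact substring first, then edlib
    infix alignment within ``max_edits``); members tied at the smallest edit
    distance are the candidate placements.  Bases at covered diagnostic
    columns restrict the candidate subgenomes; a single survivor wins.
    """
    if max_edits is None:
        max_edits = max(2, len(read) // 20)
    placements = {}
    for g, seq in members.items():
        hit = seq.find(read)
        if hit >= 0:
            placements[g] = (0, hit)
            continue
        res = edlib.align(read, seq, mode="HW", task="locations", k=max_edits)
        if res["editDistance"] >= 0 and res["locations"]:
            start = res["locations"][0][0]
            placements[g] = (res["editDistance"], start)
    if not placements:
        return "unassigned"
    best = min(d for d, _ in placements.values())
    cands = {g: st for g, (d, st) in placements.items() if d == best}

    votes = None
    any_covered = False
    for g, start in cands.items():
        end = start + len(read)
        for pos, col in index.by_member.get(g, []):
            if start <= pos < end:
                any_covered = True
                base = read[pos - start]
                _, bases = index.sites[col]
                supported = frozenset(gg for gg, b in bases.items()
                                      if b == base)
                if not supported:
                    continue  # read error at the site: no vote
                votes = supported if votes is None else votes & supported
        break  # columns are shared; one candidate placement suffices
    if votes is None:
        # no informative diagnostic coverage
        if len(members) == 1:
            return next(iter(members))
        return "ambiguous"
    if len(votes) == 1:
        return next(iter(votes))
    return "ambiguous"


class ReadAssigner:
    """Bulk assigner over a whole transcript catalogue.

    Seeds reads onto candidate transcripts through a k-mer index (three
    probe positions per read), scores candidates by mismatch count (edlib
    fallback), resolves the best homoeologue group and applies diagnostic
    voting within it.  Reads whose best placements tie across different
    groups are ambiguous.
    """

    def __init__(self, transcripts: pd.Series, genomes: pd.Series,
                 group_of: pd.Series, k: int = 21):
        self.transcripts = transcripts
        self.genomes = genomes
        self.group_of = group_of
        self.k = k
        self._kmer_index = defaultdict(list)
        for gene, seq in transcripts.items():
            for i in range(0, len(seq) - k + 1):
                self._kmer_index[seq[i:i + k]].append((gene, i))
        members_by_group = defaultdict(dict)
        for gene, seq in transcripts.items():
            members_by_group[group_of[gene]][genomes[gene]] = seq
        self._members = dict(members_by_group)
        self._indices = {gid: build_diagnostic_index(mem)
                         for gid, mem in self._members.items()}

    def assign(self, read: str) -> str:
        return self._assign_with_group(read)[0]

    def assign_sample(self, reads) -> Counter:
        """Label every read; returns a Counter over assignment labels."""
        out = Counter()
        for read in reads:
            out[self.assign(read)] += 1
        return out

    def count_sample(self, reads) -> tuple[pd.Series, Counter]:
        """Genome-resolved per-gene counts plus the label tally.

        A read labelled with subgenome g within its best group increments
        that group's g member; ambiguous/unassigned reads are dropped.
        """
        stats = Counter()
        counts = Counter()
        gene_of = {(self.group_of[gene], self.genomes[gene]): gene
                   for gene in self.transcripts.index}
        for read in reads:
            label, gid = self._assign_with_group(read)
            stats[label] += 1
            if label in ("A", "B", "D") and gid is not None:
                counts[gene_of[(gid, label)]] += 1
        series = pd.Series(counts, dtype=np.int64).reindex(
            self.transcripts.index, fill_value=0)
        return series, stats

    def _assign_with_group(self, read: str):
        k = self.k
        max_edits = max(2, len(read) // 20)
        if len(read) < k:
            return "unassigned", None
        cand = {}
        for probe in (0, (len(read) - k) // 2, len(read) - k):
            for gene, pos in self._kmer_index.get(read[probe:probe + k], ()):
                cand.setdefault(gene, pos - probe)
        if not cand:
            return "unassigned", None
        scored = {}
        for gene, start in cand.items():
            seq = self.transcripts[gene]
            start = min(max(start, 0), max(len(seq) - len(read), 0))
            window = seq[start:start + len(read)]
            if len(window) == len(read):
                d = sum(a != b for a, b in zip(read, window))
            else:
                d = max_edits + 1
            if d > max_edits:
                res = edlib.align(read, seq, mode="HW", task="distance",
                                  k=max_edits)
                d = res["editDistance"] if res["editDistance"] >= 0 \
                    else max_edits + 1
            if d <= max_edits:
                scored[gene] = d
        if not scored:
            return "unassigned", None
        best = min(scored.values())
        best_groups = {self.group_of[g] for g, d in scored.items()
                       if d == best}
        if len(best_groups) > 1:
            return "ambiguous", None
        gid = best_groups.pop()
        label = assign_read(read, self._indices[gid], self._members[gid],
                            max_edits)
        return label, gid


def assignment_stats(per_sample: dict[str, Counter]) -> pd.DataFrame:
    """Per-sample assignment fractions (labels partition the reads)."""
    rows = []
    for sample, tally in per_sample.items():
        total = sum(tally.values())
        row = {"sample": sample, "total_reads": total}
        for lab in LABELS:
            row[f"frac_{lab}"] = tally.get(lab, 0) / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def artefact_filter(counts: pd.DataFrame, samples: pd.DataFrame,
                    genomes: pd.Series, lengths: pd.Series,
                    fpkm_threshold: float = 1.0) -> pd.Index:
    """Genes with wrong-parent expression, to exclude downstream.

    D-subgenome genes with FPKM above the threshold in any replicate of the
    AABB parent, and A/B-subgenome genes likewise in the DD parent, are
    polymorphism artefacts of read placement and are flagged.
    """
    sheet = samples.set_index("sample")
    pab = sheet.index[sheet["genotype"] == "P_AB"]
    pd_ = sheet.index[sheet["genotype"] == "P_D"]
    if len(pab) == 0 or len(pd_) == 0:
        raise ValueError("both parental genotypes are required")
    fp = fpkm_matrix(counts, lengths)
    genomes = genomes.reindex(counts.index)
    wrong_in_pab = (genomes == "D") & (fp[list(pab)] > fpkm_threshold).any(axis=1)
    wrong_in_pd = genomes.isin(["A", "B"]) \
        & (fp[list(pd_)] > fpkm_threshold).any(axis=1)
    return counts.index[wrong_in_pab | wrong_in_pd]
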