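"""Alignment-level diagnostics for multi-gene data sets.

Covers the checks run before concatenating gene alignments: masking of
ambiguously aligned sites, uncorrected-p distances with pairwise or
complete deletion, between-group mean distances, saturation tables
(divergence vs raw substitution counts, with third-codon-position counts),
base-composition heterogeneity, parsimony-informative site counts, and the
g1 tree-length skewness test of phylogenetic signal (Fitch parsimony
lengths over random topologies; strongly negative skewness indicates
hierarchical structure in the data).

IUPAC ambiguity codes and gaps are treated as missing throughout distances
and base counts; for Fitch parsimony an ambiguous residue is treated as the
full set of compatible states.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from scipy import stats

__all__ = [
    "Alignment",
    "SiteMask",
    "DistanceMatrix",
    "G1Result",
    "apply_site_mask",
    "pdistance",
    "group_mean_distance",
    "saturation_table",
    "base_composition_test",
    "g1_statistic",
    "count_informative_sites",
    "fitch_length",
]

_BASES = "ACGT"
# bitmask encoding: A=1, C=2, G=4, T=8; IUPAC ambiguity = union of bits
_IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15, "-": 15, "?": 15,
}


class Alignment:
    """An in-memory nucleotide alignment: ordered label -> sequence."""

    def __init__(self, sequences: Mapping[str, str],
                 codon_positions: Optional[Sequence[int]] = None):
        if not sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self.labels = list(self.sequences)
        self.length = lengths.pop()
        if codon_positions is not None and len(codon_positions) != self.length:
            raise ValueError("codon position annotation length mismatch")
        self.codon_positions = (
            list(codon_positions) if codon_positions is not None else None)

    @classmethod
    def from_fasta(cls, path, codon_positions=None) -> "Alignment":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        return cls(seqs, codon_positions)

    def with_cycling_codon_positions(self) -> "Alignment":
        """Annotate columns 1,2,3,1,2,3,... (protein-coding frame 1)."""
        pos = [(i % 3) + 1 for i in range(self.length)]
        return Alignment(self.sequences, pos)

    def matrix(self) -> np.ndarray:
        """(n_taxa, length) uint8 bitmask matrix (15 = fully missing)."""
        out = np.empty((len(self.labels), self.length), dtype=np.uint8)
        for i, lab in enumerate(self.labels):
            out[i] = [_IUPAC_BITS.get(c, 15) for c in self.sequences[lab]]
        return out

    def __len__(self):
        return self.length

    def __repr__(self):
        return f"<Alignment {len(self.labels)} taxa x {self.length} columns>"


@dataclass(frozen=True)
class SiteMask:
    """1-based inclusive column ranges to discard, e.g. [(90, 102), ...]."""

    ranges: tuple[tuple[int, int], ...]

    @classmethod
    def from_text(cls, text: str) -> "SiteMask":
        """Parse lines like ``90-102`` (1-based inclusive)."""
        ranges = []
        for line in text.splitlines():
            line = line.strip().replace("–", "-")
            if not line or line.startswith("#"):
                continue
            lo, hi = line.split("-")
            ranges.append((int(lo), int(hi)))
        return cls(tuple(ranges))

    def columns(self, length: int) -> set[int]:
        """The set of 0-based columns removed (ranges normalised/unioned)."""
        cols = set()
        for lo, hi in self.ranges:
            if lo < 1 or hi > length or lo > hi:
                raise ValueError(
                    f"mask range {lo}-{hi} outside alignment of length {length}")
            cols.update(range(lo - 1, hi))
        return cols


def apply_site_mask(aln: Alignment, mask: SiteMask) -> tuple[Alignment, int]:
    """Remove masked columns from every sequence; returns (alignment,
    number of columns removed).  Overlapping ranges count once."""
    drop = mask.columns(aln.length)
    keep = [i for i in range(aln.length) if i not in drop]
    seqs = {lab: "".join(s[i] for i in keep) for lab, s in aln.sequences.items()}
    pos = ([aln.codon_positions[i] for i in keep]
           if aln.codon_positions is not None else None)
    return Alignment(seqs, pos), len(drop)


@dataclass
class DistanceMatrix:
    labels: list[str]
    distances: np.ndarray  # NaN where undefined (no shared sites)
    effective_sites: np.ndarray

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.distances[i, j])


def pdistance(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Uncorrected-p distances: differing sites / shared unambiguous sites.

    ``pairwise`` deletion uses, per pair, the sites where both members have
    an unambiguous A/C/G/T; ``complete`` restricts every pair to the global
    intersection of valid columns.  A pair with zero usable sites gets NaN,
    not 0.
    """
    if len(aln.labels) < 2:
        raise ValueError("need at least 2 sequences")
    M = aln.matrix()
    valid = np.isin(M, (1, 2, 4, 8))
    if deletion == "complete":
        shared_all = valid.all(axis=0)
        valid = valid & shared_all[None, :]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = len(aln.labels)
    D = np.zeros((n, n))
    E = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            eff = int(both.sum())
            E[i, j] = E[j, i] = eff
            if eff == 0:
                D[i, j] = D[j, i] = np.nan
            else:
                diff = int(np.sum((M[i] != M[j]) & both))
                D[i, j] = D[j, i] = diff / eff
    return DistanceMatrix(list(aln.labels), D, E)


def group_mean_distance(dm: DistanceMatrix,
                        groups: Mapping[str, str]) -> dict[tuple[str, str], Optional[float]]:
    """Mean pairwise distance between (and within) groups.

    Keys are sorted group-name pairs; within-group means sit on the
    diagonal pair (g, g) and are None for singleton groups.
    """
    ungrouped = [l for l in dm.labels if l not in groups]
    if ungrouped:
        raise KeyError(f"taxa without group assignment: {ungrouped}")
    names = sorted(set(groups.values()))
    out: dict[tuple[str, str], Optional[float]] = {}
    for ga, gb in itertools.combinations_with_replacement(names, 2):
        vals = []
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if j <= i:
                    continue
                pair = tuple(sorted((groups[a], groups[b])))
                if pair == (ga, gb):
                    v = dm.distances[i, j]
                    if not math.isnan(v):
                        vals.append(v)
        out[(ga, gb)] = float(np.mean(vals)) if vals else None
    return out


def saturation_table(aln: Alignment, third_position: bool = True):
    """Per-pair (label_a, label_b, percent divergence, substitutions,
    third-position substitutions) for saturation plotting.

    No asymptote test is performed; the table is meant for visual
    assessment.  Requires codon-position annotation when third-position
    counts are requested.
    """
    if third_position and aln.codon_positions is None:
        raise ValueError("third-position counts need codon-position annotation")
    M = aln.matrix()
    valid = np.isin(M, (1, 2, 4, 8))
    third = (np.asarray(aln.codon_positions) == 3) if third_position else None
    rows = []
    for i, j in itertools.combinations(range(len(aln.labels)), 2):
        both = valid[i] & valid[j]
        eff = int(both.sum())
        diff = (M[i] != M[j]) & both
        subs = int(diff.sum())
        pct = 100.0 * subs / eff if eff else float("nan")
        sub3 = int((diff & third).sum()) if third_position else None
        rows.append((aln.labels[i], aln.labels[j], pct, subs, sub3))
    return rows


@dataclass(frozen=True)
class BaseCompositionResult:
    frequencies: dict[str, tuple[float, float, float, float]]
    mean_frequencies: tuple[float, float, float, float]
    chisq: float
    df: int
    p: float
    excluded: tuple[str, ...] = ()


def base_composition_test(aln: Alignment) -> BaseCompositionResult:
    """Chi-square test of base-composition heterogeneity across taxa.

    Counts unambiguous A/C/G/T per taxon, tests the taxa x 4 table against
    the pooled expectation; df = (taxa - 1) x 3.  Taxa with zero
    unambiguous sites are excluded (reported in the result).
    """
    if len(aln.labels) < 2:
        raise ValueError("need at least 2 sequences")
    M = aln.matrix()
    counts = np.stack([(M == b).sum(axis=1) for b in (1, 2, 4, 8)], axis=1).astype(float)
    keep = counts.sum(axis=1) > 0
    excluded = tuple(l for l, k in zip(aln.labels, keep) if not k)
    counts = counts[keep]
    labels = [l for l, k in zip(aln.labels, keep) if k]
    row = counts.sum(axis=1, keepdims=True)
    colfrac = counts.sum(axis=0) / counts.sum()
    expected = row * colfrac[None, :]
    chisq = float(np.sum((counts - expected) ** 2 / expected))
    df = (len(labels) - 1) * 3
    p = float(stats.chi2.sf(chisq, df)) if df > 0 else float("nan")
    freqs = {
        lab: tuple(counts[i] / counts[i].sum()) for i, lab in enumerate(labels)
    }
    mean_freq = tuple(np.mean([freqs[l] for l in labels], axis=0))
    return BaseCompositionResult(freqs, mean_freq, chisq, df, p, excluded)


def count_informative_sites(aln: Alignment) -> int:
    """Parsimony-informative columns: at least two states each present in
    at least two sequences (gaps/ambiguities ignored).  Additive over
    concatenation."""
    M = aln.matrix()
    count = 0
    for col in M.T:
        states, mult = np.unique(col[np.isin(col, (1, 2, 4, 8))], return_counts=True)
        if np.sum(mult >= 2) >= 2:
            count += 1
    return count


# -- Fitch parsimony and the g1 skewness test -------------------------------

def _random_topology(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform random labeled bifurcating topology by random sequential
    addition; returns (left, right) child ids per internal node, tips are
    ids 0..n-1, internals n..2n-2 in creation order (root last)."""
    # grow an unrooted tree by attaching each new tip to a random edge,
    # then root along the last attachment edge; equivalent to sampling
    # topologies via random addition order
    # representation: nodes as dicts of neighbor ids
    if n < 3:
        if n == 2:
            return [(0, 1)]
        raise ValueError("need >= 2 tips")
    nbr: dict[int, set[int]] = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    edges = [(0, n), (1, n), (2, n)]
    nxt = n + 1
    for tip in range(3, n):
        a, b = edges[rng.integers(len(edges))]
        nbr[a].remove(b)
        nbr[b].remove(a)
        new = nxt
        nxt += 1
        nbr[new] = {a, b, tip}
        nbr[a].add(new)
        nbr[b].add(new)
        nbr[tip] = {new}
        edges.remove((a, b))
        edges.extend([(a, new), (b, new), (tip, new)])
    # root on the edge adjacent to tip 0 and orient
    order: list[tuple[int, int]] = []
    relabel: dict[int, int] = {}

    def resolve(node: int, parent: int) -> int:
        if node < n:
            return node
        kids = [x for x in nbr[node] if x != parent]
        ids = [resolve(k, node) for k in kids]
        while len(ids) > 1:
            b_, a_ = ids.pop(), ids.pop()
            order.append((a_, b_))
            ids.append(n + len(order) - 1)
        return ids[0]

    start = next(iter(nbr[0]))
    left = resolve(start, 0)
    order.append((0, left))
    return order


def fitch_length(topology, tip_masks: np.ndarray) -> int:
    """Fitch parsimony length of one topology over all sites.

    ``topology`` is a list of (left, right) child ids as produced by the
    internal topology sampler (tips 0..n-1 first); ``tip_masks`` is an
    (n_tips, n_sites) uint8 state-bitmask array.
    """
    n = tip_masks.shape[0]
    states = [tip_masks[i] for i in range(n)]
    length = np.zeros(tip_masks.shape[1], dtype=np.int64)
    for a, b in topology:
        inter = states[a] & states[b]
        changed = inter == 0
        length += changed
        states.append(np.where(changed, states[a] | states[b], inter))
    return int(length.sum())


@dataclass(frozen=True)
class G1Result:
    n_trees: int
    g1: float
    mean_length: float
    min_length: int
    max_length: int
    seed: int
    null_g1: Optional[float] = None
    null_percentile: Optional[float] = None


def g1_statistic(aln: Alignment, n_trees: int = 10_000, seed: int = 0,
                 column_shuffle_null: bool = False) -> G1Result:
    """Skewness of Fitch tree lengths over uniform random topologies.

    g1 = m3 / m2^1.5 (moment skewness).  Strongly negative values indicate
    phylogenetic signal.  With ``column_shuffle_null``, the statistic is
    also computed on a column-wise taxon-shuffled copy of the data (which
    destroys hierarchical signal) and the real g1's percentile within a
    recomputation under that null is reported.
    """
    if len(aln.labels) < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    M = aln.matrix()

    def lengths(masks):
        out = np.empty(n_trees)
        for k in range(n_trees):
            topo = _random_topology(masks.shape[0], rng)
            out[k] = fitch_length(topo, masks)
        return out

    L = lengths(M)
    g1 = float(stats.skew(L, bias=True))
    null_g1 = null_pct = None
    if column_shuffle_null:
        shuffled = M.copy()
        for c in range(shuffled.shape[1]):
            rng.shuffle(shuffled[:, c])
        Ln = lengths(shuffled)
        null_g1 = float(stats.skew(Ln, bias=True))
        null_pct = float(np.mean(Ln <= np.mean(L)))
    return G1Result(n_trees, g1, float(L.mean()), int(L.min()), int(L.max()),
                    seed, null_g1, null_pct)
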