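"""Leakage-free training-set construction.

Homologous sequences carry near-duplicate signal; if they straddle a
train/test boundary the measured performance is optimistic.  This module
provides the pieces the curation pipeline needs: global pairwise identity,
annotation propagation from curated references, greedy identity clustering
(deduplication / screening clusters), homology-aware fold partitioning, and
SMOTE oversampling of minority classes.

All-vs-all alignment is quadratic; a k-mer prefilter (pairs sharing no
5-mer are skipped) keeps desk-scale inputs fast.  At the identity thresholds
used here (>= 0.25) a passing pair virtually always shares a 5-mer, so the
prefilter only discards pairs that are below threshold anyway; the exhaustive
checker used in tests runs without it.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_io import LocalizationLabel, ProteinRecord

log = logging.getLogger(__name__)

PREFILTER_K = 5

# Selenocysteine / pyrrolysine fall back to their structural analogues for
# scoring purposes (BLOSUM62 has no U/O columns).
_ALIGN_SANITIZE = str.maketrans({"U": "C", "O": "K"})


def make_aligner(gap_open: float = 11.0, gap_extend: float = 1.0
                 ) -> Align.PairwiseAligner:
    """Global Needleman–Wunsch aligner with affine gaps over BLOSUM62."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class IdentityEdge:
    idA: str
    idB: str
    identity: float
    coverage: float


def global_identity(a: ProteinRecord | str, b: ProteinRecord | str,
                    aligner: Align.PairwiseAligner | None = None
                    ) -> IdentityEdge:
    """Global-alignment identity and coverage between two sequences.

    identity = identical aligned positions / alignment length (terminal gaps
    included); coverage = non-terminal-gap alignment span of the shorter
    sequence / shorter sequence length.
    """
    ida, seqa = (a.id, a.seq) if isinstance(a, ProteinRecord) else ("A", a)
    idb, seqb = (b.id, b.seq) if isinstance(b, ProteinRecord) else ("B", b)
    if not seqa or not seqb:
        raise ValueError("cannot align empty sequences")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(seqa.translate(_ALIGN_SANITIZE),
                        seqb.translate(_ALIGN_SANITIZE))[0]
    counts = aln.counts()
    identity = counts.identities / aln.length
    short_row = 0 if len(seqa) <= len(seqb) else 1
    blocks = aln.aligned[short_row]
    if len(blocks) == 0:
        span = 0
    else:
        span = int(blocks[-1][1] - blocks[0][0])
    coverage = span / min(len(seqa), len(seqb))
    return IdentityEdge(ida, idb, float(identity), float(coverage))


# ---------------------------------------------------------------------------
# Annotation propagation

def propagate_annotation(query: ProteinRecord, reference: ProteinRecord,
                         ref_label: LocalizationLabel,
                         domains_query: list[str], domains_ref: list[str],
                         min_identity: float = 0.25,
                         aligner: Align.PairwiseAligner | None = None
                         ) -> LocalizationLabel | None:
    """Transfer a curated location label from reference to query.

    The label propagates only when global identity reaches ``min_identity``
    AND the ordered domain-accession lists agree exactly — same content and
    same synteny (order); a permuted domain architecture blocks transfer.
    """
    if list(domains_query) != list(domains_ref):
        return None
    edge = global_identity(query, reference, aligner)
    if edge.identity >= min_identity:
        return ref_label
    return None


# ---------------------------------------------------------------------------
# k-mer prefilter

def _kmers(seq: str, k: int = PREFILTER_K) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def candidate_pairs(records: list[ProteinRecord], k: int = PREFILTER_K
                    ) -> set[tuple[int, int]]:
    """Index pairs (i < j) of records sharing at least one k-mer."""
    index: dict[str, list[int]] = defaultdict(list)
    for i, rec in enumerate(records):
        for km in _kmers(rec.seq, k):
            index[km].append(i)
    pairs: set[tuple[int, int]] = set()
    for ids in index.values():
        if len(ids) > 1:
            for x in range(len(ids)):
                for y in range(x + 1, len(ids)):
                    pairs.add((ids[x], ids[y]))
    return pairs


def identity_edges(records: list[ProteinRecord], min_identity: float,
                   min_coverage: float = 0.0, prefilter: bool = True
                   ) -> list[IdentityEdge]:
    """All record pairs at >= min_identity (and >= min_coverage)."""
    aligner = make_aligner()
    if prefilter:
        pairs = sorted(candidate_pairs(records))
    else:
        n = len(records)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    edges = []
    for i, j in pairs:
        edge = global_identity(records[i], records[j], aligner)
        if edge.identity >= min_identity and edge.coverage >= min_coverage:
            edges.append(edge)
    return edges


# ---------------------------------------------------------------------------
# Greedy clustering

@dataclass
class Cluster:
    representative: str
    members: list[str] = field(default_factory=list)


def greedy_cluster(records: list[ProteinRecord], id_thr: float,
                   cov_thr: float,
                   ref_identity: dict[str, float] | None = None
                   ) -> list[Cluster]:
    """Incremental greedy clustering in the style of CD-HIT/mmseqs2.

    Sequences are visited by descending length (ties by id); each joins the
    first existing cluster whose founder it matches at >= id_thr identity and
    >= cov_thr coverage, otherwise it founds a new cluster.  The reported
    representative is the member with the best reference-match identity when
    ``ref_identity`` is given (ties: longest, then lexicographic id), else
    the longest member.
    """
    if not (0 < id_thr <= 1 and 0 < cov_thr <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    aligner = make_aligner()
    order = sorted(records, key=lambda r: (-len(r.seq), r.id))
    by_id = {r.id: r for r in records}
    founders: list[ProteinRecord] = []
    founder_kmers: list[frozenset[str]] = []
    members: list[list[str]] = []
    for rec in order:
        kms = _kmers(rec.seq)
        placed = False
        for ci, founder in enumerate(founders):
            if founder_kmers[ci].isdisjoint(kms):
                continue
            edge = global_identity(rec, founder, aligner)
            if edge.identity >= id_thr and edge.coverage >= cov_thr:
                members[ci].append(rec.id)
                placed = True
                break
        if not placed:
            founders.append(rec)
            founder_kmers.append(kms)
            members.append([rec.id])

    def rep_key(pid: str):
        ref = ref_identity.get(pid, 0.0) if ref_identity else 0.0
        return (-ref, -len(by_id[pid].seq), pid)

    clusters = []
    for ids in members:
        if ref_identity is not None:
            rep = min(ids, key=rep_key)
        else:
            rep = min(ids, key=lambda p: (-len(by_id[p].seq), p))
        clusters.append(Cluster(representative=rep, members=list(ids)))
    return clusters


# ---------------------------------------------------------------------------
# Homology-aware partitioning

@dataclass
class FoldAssignment:
    """Map id -> fold index plus bookkeeping.  In fractions mode the folds
    are named splits (``split_names``); no identity edge at or above the
    partition threshold crosses a fold boundary."""

    folds: dict[str, int]
    n_folds: int
    split_names: list[str] | None = None
    warnings: list[str] = field(default_factory=list)

    def ids_in_fold(self, fold: int) -> list[str]:
        return [pid for pid, f in self.folds.items() if f == fold]

    def split(self, name: str) -> list[str]:
        if self.split_names is None:
            raise ValueError("k-fold assignment has no named splits")
        return self.ids_in_fold(self.split_names.index(name))


def _connected_components(n: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    comps: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        comps[find(i)].append(i)
    return list(comps.values())


def homology_partition(records: list[ProteinRecord],
                       labels: dict[str, LocalizationLabel],
                       k_or_fractions: int | tuple[float, ...],
                       id_thr: float = 0.30, seed: int = 42,
                       prefilter: bool = True) -> FoldAssignment:
    """Assign proteins to folds so that no pair at >= id_thr identity is
    split across folds.

    The identity graph's connected components are atomic; components are
    assigned greedily (largest first) to the fold where they least worsen
    the per-fold, per-class deviation from the target proportions.  Pass an
    int k for k equal folds, or fractions such as (0.7, 0.15, 0.15) for a
    stratified train/val/test split.
    """
    for rec in records:
        if rec.id not in labels:
            raise ValueError(f"record {rec.id!r} has no label")
    if isinstance(k_or_fractions, int):
        fractions = [1.0 / k_or_fractions] * k_or_fractions
        split_names = None
    else:
        fractions = list(k_or_fractions)
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        split_names = (["train", "val", "test"]
                       if len(fractions) == 3 else
                       [f"split{i}" for i in range(len(fractions))])
    n_folds = len(fractions)

    edges = identity_edges(records, id_thr, prefilter=prefilter)
    idx = {r.id: i for i, r in enumerate(records)}
    comps = _connected_components(
        len(records), [(idx[e.idA], idx[e.idB]) for e in edges])

    classes = sorted({labels[r.id] for r in records})
    class_idx = {c: i for i, c in enumerate(classes)}
    totals = np.zeros(len(classes))
    comp_class = []
    for comp in comps:
        counts = np.zeros(len(classes))
        for i in comp:
            counts[class_idx[labels[records[i].id]]] += 1
        comp_class.append(counts)
        totals += counts

    targets = np.outer(fractions, totals)          # (folds, classes)
    current = np.zeros_like(targets)
    rng = np.random.default_rng(seed)
    order = sorted(range(len(comps)),
                   key=lambda c: (-len(comps[c]), rng.random()))
    assignment: dict[str, int] = {}
    warnings: list[str] = []
    largest_target = max(int(round(f * len(records))) for f in fractions)
    for c in order:
        if len(comps[c]) > largest_target:
            warnings.append(
                f"homology component of size {len(comps[c])} exceeds the "
                f"largest fold target {largest_target}; assigned anyway")
        # place where the component's classes are relatively most under
        # target: equalizing relative fill yields proportional (stratified)
        # final counts
        scores = []
        for f in range(n_folds):
            fill = (current[f] + comp_class[c] - targets[f]) / np.maximum(targets[f], 1.0)
            scores.append(float(comp_class[c] @ fill))
        best = int(np.argmin(scores))
        current[best] += comp_class[c]
        for i in comps[c]:
            assignment[records[i].id] = best
    if warnings:
        for w in warnings:
            log.warning(w)
    return FoldAssignment(folds=assignment, n_folds=n_folds,
                          split_names=split_names, warnings=warnings)


def cross_fold_violations(records: list[ProteinRecord],
                          assignment: FoldAssignment,
                          id_thr: float) -> list[IdentityEdge]:
    """Exhaustive (no prefilter) check of the partition contract: returns
    every pair at >= id_thr identity whose members sit in different folds."""
    edges = identity_edges(records, id_thr, prefilter=False)
    return [e for e in edges
            if assignment.folds[e.idA] != assignment.folds[e.idB]]


# ---------------------------------------------------------------------------
# SMOTE

def smote_oversample(X: np.ndarray, y: np.ndarray, k: int = 5,
                     target: str = "balance", seed: int = 42
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling by interpolation.

    Each synthetic row is x_i + u*(x_nn - x_i) with u ~ U(0,1) and x_nn one
    of the k nearest same-class neighbours of x_i.  All classes are brought
    up to the majority-class count; original rows are preserved verbatim.
    """
    from sklearn.neighbors import NearestNeighbors

    if target != "balance":
        raise ValueError("only target='balance' is supported")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    new_X, new_y = [X], [y]
    for cls, count in zip(classes, counts):
        need = majority - count
        if need == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {cls!r} has {count} sample(s); SMOTE needs >= 2")
        Xc = X[y == cls]
        k_eff = min(k, count - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        _, neigh = nn.kneighbors(Xc)
        base = rng.integers(0, count, size=need)
        pick = rng.integers(1, k_eff + 1, size=need)  # skip self at col 0
        u = rng.random(size=(need, 1))
        parents = Xc[base]
        partners = Xc[neigh[base, pick]]
        new_X.append(parents + u * (partners - parents))
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(new_X), np.concatenate(new_y)
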