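"""Gene trees: Tamura-Nei (1993) distances, neighbor joining, bootstrap.

Distances are estimated per pair with gap *and* ambiguity sites excluded in
pairwise fashion, using the closed-form TN93 estimator with base frequencies
taken as the empirical averages over the pair's retained sites. Trees are
built with the canonical Saitou-Nei agglomeration (ties in the Q criterion
broken by the lowest index pair, negative branch-length estimates clamped to
zero) and edge support comes from nonparametric site resampling with the
replicate trees compared to the full-data tree by bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode


@dataclass
class Alignment:
    names: list[str]
    seqs: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.seqs):
            raise ValueError("one name per sequence required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("sequence names must be unique")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have uniform length")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def columns(self) -> np.ndarray:
        return _encode([s for s in self.seqs])


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seqs: list[str]) -> np.ndarray:
    arr = np.full((len(seqs), len(seqs[0])), -1, dtype=np.int8)
    for i, s in enumerate(seqs):
        for j, c in enumerate(s.upper()):
            arr[i, j] = _CODE.get(c, -1)  # gaps and ambiguity codes -> -1
    return arr


def tn93_distance(seq_a, seq_b) -> float:
    """TN93 substitutions/site between two aligned rows; NaN when saturated.

    Sites where either row carries a gap or a non-ACGT code are excluded for
    this pair only. Saturation (a non-positive logarithm argument) yields NaN
    so the caller can flag rather than silently ceiling the distance.
    """
    a = _encode([seq_a])[0] if isinstance(seq_a, str) else np.asarray(seq_a, dtype=np.int8)
    b = _encode([seq_b])[0] if isinstance(seq_b, str) else np.asarray(seq_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal aligned length")
    keep = (a >= 0) & (b >= 0)
    a, b = a[keep], b[keep]
    n = a.size
    if n == 0:
        raise ValueError("no comparable sites after pairwise exclusion")

    counts = np.bincount(np.concatenate([a, b]), minlength=4) / (2 * n)
    pa, pc, pg, pt = counts
    pr, py = pa + pg, pc + pt

    diff = a != b
    transitions_ag = np.sum(diff & (np.minimum(a, b) == 0) & (np.maximum(a, b) == 2))
    transitions_ct = np.sum(diff & (np.minimum(a, b) == 1) & (np.maximum(a, b) == 3))
    p1 = transitions_ag / n
    p2 = transitions_ct / n
    q = (np.sum(diff) - transitions_ag - transitions_ct) / n
    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0
    if min(pa, pc, pg, pt) == 0:
        # a base missing from the pair makes the corresponding term vanish
        pass

    def _safe_log(x: float) -> float:
        return math.log(x) if x > 0 else math.nan

    d = 0.0
    if pa * pg > 0:
        w1 = 2 * pa * pg / pr
        d += w1 * -_safe_log(1 - p1 / w1 - q / (2 * pr))
    elif p1 > 0:
        return math.nan
    if pc * pt > 0:
        w2 = 2 * pc * pt / py
        d += w2 * -_safe_log(1 - p2 / w2 - q / (2 * py))
    elif p2 > 0:
        return math.nan
    if pr * py > 0:
        w3 = 2 * (pr * py - pa * pg * py / pr - pc * pt * pr / py)
        d += w3 * -_safe_log(1 - q / (2 * pr * py))
    elif q > 0:
        return math.nan
    return float(d) if math.isfinite(d) else math.nan


def p_distance(seq_a: str, seq_b: str) -> float:
    a = _encode([seq_a])[0]
    b = _encode([seq_b])[0]
    keep = (a >= 0) & (b >= 0)
    if not keep.any():
        raise ValueError("no comparable sites")
    return float(np.mean(a[keep] != b[keep]))


def distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise TN93 matrix over an alignment (NaN marks saturated pairs)."""
    enc = aln.columns()
    n = len(aln.names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tn93_distance(enc[i], enc[j])
    return d


def nj_tree(d: np.ndarray, labels: list[str]) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Q-criterion ties are broken by the lowest (i, j) index pair in the
    current node list; negative branch-length estimates are clamped to zero.
    The returned tree has a trifurcating root standing in for the unrooted
    topology.
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValueError("matrix/label size mismatch")
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances (saturated pairs?) cannot be joined")

    nodes = [TreeNode(name=name) for name in labels]
    dm = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = dm.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                qij = (m - 2) * dm[i, j] - r[i] - r[j]
                if best is None or qij < best[0] - 1e-12:
                    best = (qij, i, j)
        _, i, j = best
        vi = 0.5 * dm[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = dm[i, j] - vi
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(vi, 0.0)
        child_j.length = max(vj, 0.0)
        new = TreeNode(children=[child_i, child_j])
        dnew = np.array(
            [0.5 * (dm[i, k] + dm[j, k] - dm[i, j]) for k in range(m) if k not in (i, j)]
        )
        keep = [k for k in range(m) if k not in (i, j)]
        dm = dm[np.ix_(keep, keep)]
        dm = np.pad(dm, ((0, 1), (0, 1)))
        dm[-1, :-1] = dm[:-1, -1] = dnew
        nodes = [nodes[k] for k in keep] + [new]

    # final three-way join with closed-form pendant lengths
    d01, d02, d12 = dm[0, 1], dm[0, 2], dm[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, ln in zip(nodes, lengths):
        node.length = max(ln, 0.0)
    return TreeNode(children=list(nodes))


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge bipartitions as canonical leaf-name sets.

    Each internal edge is represented by the side of the split not containing
    the lexicographically first taxon, so the representation is rooting-
    independent.
    """
    taxa = frozenset(t.name for t in tree.tips())
    anchor = min(taxa)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if len(clade) < 2 or len(taxa - clade) < 2:
            continue  # trivial split
        out.add(clade if anchor not in clade else taxa - clade)
    return out


@dataclass
class BootstrapResult:
    tree: TreeNode
    support: dict[frozenset[str], float]
    replicates_used: int
    replicates_dropped: int


def bootstrap_support(
    aln: Alignment, replicates: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Felsenstein site-resampling support for the full-data NJ tree.

    Support for each internal bipartition of the full-data tree is the
    fraction of replicate trees containing it. Replicates producing a
    saturated (non-finite) distance are dropped and counted.
    """
    enc = aln.columns()
    full = nj_tree(distance_matrix(aln), aln.names)
    splits = bipartitions(full)
    if replicates <= 0:
        return BootstrapResult(full, {}, 0, 0)

    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in splits}
    used = dropped = 0
    n_sites = enc.shape[1]
    n_seq = enc.shape[0]
    for _ in range(replicates):
        cols = rng.integers(0, n_sites, size=n_sites)
        sub = enc[:, cols]
        dm = np.zeros((n_seq, n_seq))
        ok = True
        for i in range(n_seq):
            for j in range(i + 1, n_seq):
                dij = tn93_distance(sub[i], sub[j])
                if not math.isfinite(dij):
                    ok = False
                    break
                dm[i, j] = dm[j, i] = dij
            if not ok:
                break
        if not ok:
            dropped += 1
            continue
        used += 1
        rep_splits = bipartitions(nj_tree(dm, aln.names))
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: (counts[s] / used if used else math.nan) for s in splits}
    _annotate_support(full, support)
    return BootstrapResult(full, support, used, dropped)


def _annotate_support(tree: TreeNode, support: dict[frozenset[str], float]) -> None:
    taxa = frozenset(t.name for t in tree.tips())
    anchor = min(taxa)
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        key = clade if anchor not in clade else taxa - clade
        if key in support:
            node.name = str(int(round(100 * support[key])))
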