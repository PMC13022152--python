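"""Distance-based phylogenetics: SNP matrices, TN93 distances, NJ, bootstrap.

Mirrors the common MEGA workflow: a SNP alignment (heterozygotes as IUPAC
ambiguity codes, missing as N), Tamura-Nei 1993 distances with base
frequencies pooled across all sequences (a composite-likelihood-style
approximation of MEGA's Maximum Composite Likelihood distance) under
pairwise deletion, Saitou-Nei neighbor joining with a deterministic
lexicographic tie-break, and non-parametric bootstrap over alignment
columns with low-support edges collapsed into polytomies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popgen import SequenceMatrix
from .variant_io import VariantRecord

__all__ = [
    "DistanceMatrix",
    "PhyloNode",
    "PhyloTree",
    "InestimableDistanceError",
    "vcf_to_seq_matrix",
    "tn93_distance_matrix",
    "nj_tree",
    "bootstrap_support",
]

IUPAC_HET = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

_ACGT = "ACGT"
_IDX = {b: i for i, b in enumerate(_ACGT)}


class InestimableDistanceError(ValueError):
    """A pairwise distance could not be estimated (saturation or no sites)."""


# ---------------------------------------------------------------------------
# VCF -> SNP matrix


def vcf_to_seq_matrix(records: list[VariantRecord], samples: list[str]) -> SequenceMatrix:
    """One alignment column per SNP site; IUPAC codes for heterozygotes.

    Samples absent from a record, or with missing genotypes, become N.
    Non-SNP records (indels, symbolic alleles) are skipped.
    """
    snps = sorted((r for r in records if r.is_snp), key=lambda r: (r.chrom, r.pos))
    n, L = len(samples), len(snps)
    data = np.full((n, L), b"N", dtype="S1")
    positions = np.array([r.pos for r in snps], dtype=np.int64)
    for j, rec in enumerate(snps):
        alleles = [rec.ref] + list(rec.alt)
        for i, s in enumerate(samples):
            call = rec.call(s)
            if call is None:  # sample absent from this record
                continue
            a, b = call.alleles
            if a is None or b is None:
                continue
            if a == b:
                data[i, j] = alleles[a].encode()
            else:
                pair = frozenset((alleles[a], alleles[b]))
                data[i, j] = IUPAC_HET.get(pair, "N").encode()
    return SequenceMatrix(list(samples), data, positions)


# ---------------------------------------------------------------------------
# TN93 distances


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray          # substitutions per site; nan when inestimable
    estimable: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.estimable is None:
            self.estimable = ~np.isnan(self.values)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix/labels shape mismatch")

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.estimable[np.ix_(idx, idx)])


def _pooled_frequencies(data: np.ndarray) -> np.ndarray:
    counts = np.array([(data == b.encode()).sum() for b in _ACGT], dtype=float)
    total = counts.sum()
    if total == 0:
        raise InestimableDistanceError("alignment contains no unambiguous bases")
    return counts / total


def _tn93_pair(nii: float, P1: float, P2: float, Q: float, freqs: np.ndarray) -> float:
    """TN93 distance from mismatch proportions and pooled frequencies.

    P1 = purine-transition proportion (A<->G), P2 = pyrimidine transition
    (C<->T), Q = transversion proportion.  Returns nan on saturation.
    """
    pa, pc, pg, pt = freqs
    pR, pY = pa + pg, pc + pt
    k1 = 2.0 * pa * pg / pR if pR > 0 else 0.0
    k2 = 2.0 * pc * pt / pY if pY > 0 else 0.0
    k3 = 2.0 * (pR * pY - (pa * pg * pY / pR if pR > 0 else 0.0) - (pc * pt * pR / pY if pY > 0 else 0.0))
    d = 0.0
    if P1 > 0 or Q > 0:
        if k1 <= 0:
            return float("nan") if P1 > 0 else d
        arg = 1.0 - P1 / k1 - Q / (2.0 * pR)
        if arg <= 0:
            return float("nan")
        d -= k1 * np.log(arg)
    if P2 > 0 or Q > 0:
        if k2 <= 0:
            return float("nan") if P2 > 0 else d
        arg = 1.0 - P2 / k2 - Q / (2.0 * pY)
        if arg <= 0:
            return float("nan")
        d -= k2 * np.log(arg)
    if Q > 0:
        arg = 1.0 - Q / (2.0 * pR * pY)
        if arg <= 0:
            return float("nan")
        d -= k3 * np.log(arg)
    return float(max(d, 0.0))


def tn93_distance_matrix(
    matrix: SequenceMatrix, deletion_mode: str = "pairwise", model: str = "tn93"
) -> DistanceMatrix:
    """Tamura-Nei 1993 distances with globally pooled base frequencies.

    Under ``pairwise`` deletion, sites with a gap/missing/ambiguous state in
    either member of a pair are skipped for that pair only; ``complete``
    removes such columns for everyone first.  Saturated pairs are flagged
    inestimable (nan).  ``model`` may be downgraded to ``"jc69"`` or the raw
    ``"p"`` distance — useful on sparse SNP-only matrices where the TN93
    logarithms saturate.
    """
    if matrix.n < 2:
        raise ValueError("need >= 2 sequences")
    data = matrix.data
    called = matrix.called_mask()
    if deletion_mode == "complete":
        keep = called.all(axis=0)
        data, called = data[:, keep], called[:, keep]
    elif deletion_mode != "pairwise":
        raise ValueError("deletion_mode must be 'pairwise' or 'complete'")

    freqs = _pooled_frequencies(data[called])
    codes = np.full(data.shape, -1, dtype=np.int8)
    for b, i in _IDX.items():
        codes[data == b.encode()] = i

    n = matrix.n
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            m = int(ok.sum())
            if m == 0:
                values[i, j] = values[j, i] = float("nan")
                continue
            a, b = codes[i, ok], codes[j, ok]
            diff = a != b
            pur = ((a == 0) | (a == 2)) & ((b == 0) | (b == 2))
            pyr = ((a == 1) | (a == 3)) & ((b == 1) | (b == 3))
            P1 = float((diff & pur).sum()) / m
            P2 = float((diff & pyr).sum()) / m
            Q = float((diff & ~pur & ~pyr).sum()) / m
            p = P1 + P2 + Q
            if model == "p":
                d = p
            elif model == "jc69":
                arg = 1.0 - 4.0 * p / 3.0
                d = float("nan") if arg <= 0 else -0.75 * np.log(arg)
            else:
                d = _tn93_pair(m, P1, P2, Q, freqs)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(matrix.labels), values)


# ---------------------------------------------------------------------------
# trees


@dataclass
class PhyloNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None  # percent, internal edges only
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["PhyloNode"]:
        if self.is_leaf:
            return [self]
        return [l for c in self.children for l in c.leaves()]

    def newick_part(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.6g}"
        inner = ",".join(c.newick_part(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.0f}"
        return f"({inner}){label}:{self.length:.6g}"


@dataclass
class PhyloTree:
    """Unrooted tree represented with a trifurcating (or polytomous) root."""

    root: PhyloNode
    dropped_replicates: int = 0

    def leaf_names(self) -> list[str]:
        return sorted(l.name for l in self.root.leaves())

    def to_newick(self, with_support: bool = True) -> str:
        inner = ",".join(c.newick_part(with_support) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> dict[frozenset, PhyloNode]:
        """Internal-edge bipartitions, keyed by canonical leaf-name side.

        The canonical side is the one NOT containing the alphabetically
        first leaf, so each split has a unique key.
        """
        all_leaves = set(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset, PhyloNode] = {}

        def walk(node):
            for child in node.children:
                if not child.is_leaf:
                    side = frozenset(l.name for l in child.leaves())
                    if len(side) >= 2 and len(all_leaves - side) >= 2:
                        key = frozenset(all_leaves - side) if anchor in side else side
                        out[key] = child
                    walk(child)

        walk(self.root)
        return out

    def collapse_below(self, threshold: float) -> "PhyloTree":
        """Contract internal edges with support < threshold into polytomies."""

        def rebuild(node):
            new_children = []
            for child in node.children:
                child = rebuild(child)
                if (
                    not child.is_leaf
                    and child.support is not None
                    and child.support < threshold
                ):
                    for gc in child.children:
                        new_children.append(gc)
                else:
                    new_children.append(child)
            return PhyloNode(node.name, node.length, node.support, new_children)

        return PhyloTree(rebuild(self.root), self.dropped_replicates)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion break on the lexicographically smallest pair of
    cluster representatives (each cluster represented by its smallest leaf
    label), so topologies are deterministic.  Negative branch lengths are
    clamped to zero with the deficit moved to the sister branch.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    bad = np.argwhere(~dm.estimable & ~np.eye(n, dtype=bool))
    if bad.size:
        i, j = bad[0]
        raise InestimableDistanceError(
            f"distance between {dm.labels[i]!r} and {dm.labels[j]!r} is inestimable"
        )
    D = dm.values.copy()
    nodes = [PhyloNode(name=l) for l in dm.labels]
    reps = list(dm.labels)  # smallest leaf label per cluster

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ties = [(i, j) for i, j in ties if i < j]
        i, j = min(ties, key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))))
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        if li < 0:
            li, lj = 0.0, d_ij
        if lj < 0:
            lj, li = 0.0, d_ij
        parent = PhyloNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        d_new = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D_next = np.empty((m - 1, m - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = D_next[:-1, -1] = d_new[keep]
        D_next[-1, -1] = 0.0
        D = D_next
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [new_rep]

    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.0, 0.5 * (dab + dac - dbc))
    b.length = max(0.0, 0.5 * (dab + dbc - dac))
    c.length = max(0.0, 0.5 * (dac + dbc - dab))
    return PhyloTree(PhyloNode(children=[a, b, c]))


def default_builder(matrix: SequenceMatrix) -> PhyloTree:
    return nj_tree(tn93_distance_matrix(matrix))


def bootstrap_support(
    matrix: SequenceMatrix,
    builder=default_builder,
    replicates: int = 1000,
    seed: int = 0,
    collapse_below: float = 60.0,
) -> PhyloTree:
    """Column-resampling bootstrap on the point-estimate tree's bipartitions.

    Support is the percentage of valid replicates containing each internal
    bipartition of the point tree (MEGA convention — supports attach to the
    point tree, not a consensus).  Replicates with an inestimable pair are
    dropped and counted in ``dropped_replicates``.  Edges below
    ``collapse_below`` percent are contracted.
    """
    rng = np.random.default_rng(seed)
    point = builder(matrix)
    biparts = point.bipartitions()
    counts = {key: 0 for key in biparts}
    dropped = 0
    valid = 0
    for _ in range(replicates):
        idx = rng.integers(0, matrix.L, size=matrix.L)
        try:
            rep = builder(matrix.take_columns(idx))
        except (InestimableDistanceError, ValueError):
            dropped += 1
            continue
        valid += 1
        rep_biparts = rep.bipartitions()
        for key in counts:
            if key in rep_biparts:
                counts[key] += 1
    for key, node in biparts.items():
        node.support = 100.0 * counts[key] / valid if valid else 0.0
    point.dropped_replicates = dropped
    if collapse_below and collapse_below > 0:
        point = point.collapse_below(collapse_below)
    return point
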