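"""Nucleotide-diversity and neutrality statistics over aligned sequences.

The statistics follow the classical definitions used by DnaSP: segregating
sites ``S``; total mutations ``eta`` (each extra allele at a multi-allelic
column counts once, hence ``eta >= S``); mean pairwise differences ``k``;
nucleotide diversity ``pi = k / L``; theta per sequence ``eta / a1`` and
Watterson's per-site ``theta_w = eta / (a1 * L)`` with
``a1 = sum_{i=1}^{n-1} 1/i``; and Tajima's ``D`` with its beta-distribution
significance approximation.  Columns containing alignment gaps or missing
data are removed before anything is counted ("complete deletion").

Cohort-level helpers — one-way ANOVA with a Tukey-HSD compact letter
display, and the k-set Venn partition of per-accession SNP sets — live here
too.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "SequenceMatrix",
    "DiversityStats",
    "WindowSpec",
    "TajimaD",
    "harmonic",
    "diversity_stats",
    "tajima_d",
    "window_scan",
    "anova_letters",
    "snp_sharing",
]

_VALID = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SequenceMatrix:
    """Rectangular alignment of ``n`` sequences over ``L`` sites.

    States are single bytes; anything outside ``{A, C, G, T}`` (gap ``-``,
    missing ``N``, IUPAC ambiguity) is treated as a non-called state by the
    complete- and pairwise-deletion rules.  ``positions`` are 1-based
    reference coordinates of the columns.
    """

    labels: list[str]
    data: np.ndarray  # (n, L) dtype S1
    positions: np.ndarray = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype="S1")
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels/data row mismatch")
        if self.positions is None:
            self.positions = np.arange(1, self.data.shape[1] + 1)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape[0] != self.data.shape[1]:
            raise ValueError("positions/data column mismatch")

    @classmethod
    def from_strings(cls, labels, seqs, positions=None) -> "SequenceMatrix":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        arr = np.array([np.frombuffer(s.upper().encode(), dtype="S1") for s in seqs])
        return cls(list(labels), arr, positions)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        return self.data.shape[1]

    def sequence(self, i: int) -> str:
        return self.data[i].tobytes().decode()

    def window(self, start: int, end: int) -> "SequenceMatrix":
        """Sub-matrix of columns with 1-based positions in [start, end]."""
        mask = (self.positions >= start) & (self.positions <= end)
        return SequenceMatrix(self.labels, self.data[:, mask], self.positions[mask])

    def take_columns(self, idx) -> "SequenceMatrix":
        idx = np.asarray(idx, dtype=np.int64)
        return SequenceMatrix(self.labels, self.data[:, idx], self.positions[idx])

    def called_mask(self) -> np.ndarray:
        """(n, L) boolean mask of unambiguously called (ACGT) states."""
        return np.isin(self.data, _VALID)


@dataclass
class DiversityStats:
    n: int
    L_used: int
    S: int
    eta: int
    k: float
    pi: float
    theta_per_seq: float
    theta_w_site: float
    defined: bool = True

    def __iter__(self):  # convenient tuple-ish access in reports
        yield from (self.S, self.eta, self.k, self.pi, self.theta_per_seq, self.theta_w_site)


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: a gene interval extended by ``flank`` bp each side."""

    gene_start: int
    gene_end: int
    flank: int = 10_000

    def __post_init__(self):
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.gene_start > self.gene_end:
            raise ValueError("gene interval reversed")

    @property
    def region(self) -> tuple[int, int]:
        return (max(1, self.gene_start - self.flank), self.gene_end + self.flank)


def harmonic(m: int) -> float:
    """a1-style harmonic number: sum_{i=1}^{m} 1/i."""
    return float(np.sum(1.0 / np.arange(1, m + 1))) if m >= 1 else 0.0


def _column_allele_counts(data: np.ndarray) -> np.ndarray:
    """(4, L) counts of A/C/G/T per column."""
    return np.array([(data == b).sum(axis=0) for b in _VALID])


def diversity_stats(matrix: SequenceMatrix) -> DiversityStats:
    """Compute S, eta, k, pi and the two theta estimators (complete deletion)."""
    if matrix.n < 2:
        raise ValueError("need at least 2 sequences")
    complete = matrix.called_mask().all(axis=0)
    data = matrix.data[:, complete]
    n, L_used = data.shape
    if L_used == 0:
        nan = float("nan")
        return DiversityStats(n, 0, 0, 0, nan, nan, nan, nan, defined=False)
    counts = _column_allele_counts(data)
    n_alleles = (counts > 0).sum(axis=0)
    S = int((n_alleles > 1).sum())
    eta = int((n_alleles - 1).sum())
    pairs_total = n * (n - 1) // 2
    same_pairs = (counts * (counts - 1) // 2).sum(axis=0)
    diff_pairs = pairs_total - same_pairs
    k = float(diff_pairs.sum()) / pairs_total
    a1 = harmonic(n - 1)
    pi = k / L_used
    theta_per_seq = eta / a1
    theta_w_site = theta_per_seq / L_used
    return DiversityStats(n, L_used, S, eta, k, pi, theta_per_seq, theta_w_site)


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_constants(n: int) -> dict:
    a1 = harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


@dataclass
class TajimaD:
    D: float
    p_value: float
    defined: bool = True
    reason: str = ""


def tajima_d(stats: DiversityStats, n: int | None = None) -> TajimaD:
    """Tajima's D from k and S, with the beta-approximation two-sided p.

    ``D = (k - S/a1) / sqrt(e1*S + e2*S*(S-1))``; undefined for ``S == 0``
    or ``n < 4``.  Significance follows the scaled-beta approximation of
    the D distribution over ``[D_min, D_max]`` with zero mean and unit
    variance.
    """
    n = n if n is not None else stats.n
    if n < 4:
        return TajimaD(float("nan"), float("nan"), False, "n < 4")
    if stats.S <= 0:
        return TajimaD(float("nan"), float("nan"), False, "no segregating sites")
    c = _tajima_constants(n)
    var = c["e1"] * stats.S + c["e2"] * stats.S * (stats.S - 1)
    D = (stats.k - stats.S / c["a1"]) / np.sqrt(var)

    dmin = (2.0 / n - 1.0 / c["a1"]) / np.sqrt(c["e2"])
    dmax = ((n + 1.0) / (2.0 * n) - 1.0 / c["a1"]) / np.sqrt(c["e2"])
    # generalized beta on [dmin, dmax] with mean 0, variance 1
    alpha = -(1.0 + dmin * dmax) * dmax / (dmax - dmin)
    beta = (1.0 + dmin * dmax) * dmin / (dmax - dmin)
    x = (D - dmin) / (dmax - dmin)
    x = min(max(x, 0.0), 1.0)
    cdf = sps.beta.cdf(x, beta, alpha)
    p = float(2.0 * min(cdf, 1.0 - cdf))
    return TajimaD(float(D), p)


def window_scan(matrix: SequenceMatrix, spec: WindowSpec) -> DiversityStats:
    """Diversity statistics restricted to sites inside the window region."""
    lo, hi = spec.region
    sub = matrix.window(lo, hi)
    if sub.L == 0:
        nan = float("nan")
        return DiversityStats(matrix.n, 0, 0, 0, nan, nan, nan, nan, defined=False)
    return diversity_stats(sub)


# ---------------------------------------------------------------------------
# Cohort operations


@dataclass
class AnovaLetters:
    F: float
    p: float
    letters: dict[str, str]
    excluded: list[str]


def anova_letters(groups: dict[str, "np.ndarray"], alpha: float = 0.05) -> AnovaLetters:
    """One-way ANOVA plus an all-pairs Tukey-HSD compact letter display.

    Two groups share a letter iff Tukey HSD does not separate them at
    ``alpha``.  Groups with fewer than two values are excluded with a
    warning.  Letters are maximal cliques of the not-significantly-different
    graph, labelled in order of descending group mean.
    """
    import networkx as nx
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    excluded = sorted(set(groups) - set(usable))
    if excluded:
        warnings.warn(f"groups excluded with < 2 values: {excluded}")
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 2 values")

    names = sorted(usable)
    F, p = sps.f_oneway(*(usable[g] for g in names))

    values = np.concatenate([usable[g] for g in names])
    labels = np.concatenate([[g] * len(usable[g]) for g in names])
    nsd = nx.Graph()
    nsd.add_nodes_from(names)
    if np.ptp(values) == 0:  # all observations identical: nothing separable
        nsd.add_edges_from(itertools.combinations(names, 2))
    else:
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
        res = tukey.summary().data[1:]
        for row in res:
            g1, g2, reject = str(row[0]), str(row[1]), row[-1]
            if not reject:
                nsd.add_edge(g1, g2)

    means = {g: float(np.mean(usable[g])) for g in names}
    cliques = [sorted(c) for c in nx.find_cliques(nsd)]
    cliques.sort(key=lambda c: (-max(means[g] for g in c), c))
    letters: dict[str, list[str]] = {g: [] for g in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g].append(letter)
    return AnovaLetters(float(F), float(p), {g: "".join(sorted(v)) for g, v in letters.items()}, excluded)


def snp_sharing(sets: dict[str, set]) -> dict[frozenset, int]:
    """Counts of every exclusive membership region of a k-set Venn diagram.

    Returns a mapping ``frozenset(labels) -> count`` over all ``2^k - 1``
    non-empty label subsets; counts sum to the size of the union.
    """
    k = len(sets)
    if not (2 <= k <= 5):
        raise ValueError("snp_sharing supports 2 to 5 sets")
    names = sorted(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, k + 1):
        for combo in itertools.combinations(names, r):
            out[frozenset(combo)] = 0
    union = set().union(*sets.values())
    for item in union:
        members = frozenset(n for n in names if item in sets[n])
        out[members] += 1
    return out
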