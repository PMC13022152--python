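"""Exact short-period tandem-repeat scanning and presence/absence comparison.

A tandem-repeat locus is a maximal run of at least two exact copies of a
short unit (default periods 8-10 bp, 100% identity; a fractional trailing
copy is allowed).  Runs are reported under their MINIMAL period, so a
homopolymer or dinucleotide run never masquerades as a period-8 repeat.
Accession-versus-reference comparison projects accession coordinates
through a known edit list and classifies each locus as shared, gained
(accession only) or lost (reference only), the red/green semantics of a
TR banding plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TRLocus", "TRComparison", "scan_trs", "compare_trs", "loci_to_bed", "render_track"]


@dataclass(frozen=True)
class TRLocus:
    start: int   # 1-based
    period: int  # minimal period of the run
    copies: float
    unit: str
    span: int

    def __post_init__(self):
        if self.span < 2 * self.period:
            raise ValueError("span must cover at least 2 full copies")

    @property
    def end(self) -> int:
        return self.start + self.span - 1


@dataclass
class TRComparison:
    gained: list[TRLocus]
    lost: list[TRLocus]
    shared: list[tuple[TRLocus, TRLocus]]  # (accession, reference)
    lost_in_deletion: list[TRLocus] = field(default_factory=list)

    @property
    def shared_count(self) -> int:
        return len(self.shared)


def _minimal_period(s: str) -> int:
    """Smallest p with s[i] == s[i-p] for all i >= p (KMP border)."""
    n = len(s)
    fail = np.zeros(n, dtype=np.int64)
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return n - int(fail[-1])


def scan_trs(sequence: str, min_period: int = 8, max_period: int = 10) -> list[TRLocus]:
    """All maximal exact tandem-repeat runs with minimal period in range.

    For each candidate period p, maximal runs of ``s[i] == s[i-p]`` of
    length >= p define blocks with >= 2 full copies; each block is kept iff
    its minimal period falls within [min_period, max_period] (with at least
    two copies of that minimal unit), and is reported once under the
    minimal period with its left-most phase unit.
    """
    L = len(sequence)
    seen: set[tuple[int, int]] = set()
    loci: list[TRLocus] = []
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    for p in range(min_period, max_period + 1):
        if L < 2 * p:
            continue
        match = arr[p:] == arr[:-p]  # match[i] means s[i+p] == s[i]
        # maximal runs of True
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            run_len = int(run_end - run_start)  # number of matching offsets
            if run_len < p:
                continue  # fewer than 2 full copies
            start0 = int(run_start)     # 0-based block start
            span = run_len + p
            block = sequence[start0 : start0 + span]
            q = _minimal_period(block)
            if not (min_period <= q <= max_period) or span < 2 * q:
                continue
            key = (start0, span)
            if key in seen:
                continue
            seen.add(key)
            loci.append(
                TRLocus(
                    start=start0 + 1,
                    period=q,
                    copies=span / q,
                    unit=block[:q],
                    span=span,
                )
            )
    loci.sort(key=lambda l: (l.start, l.period))
    return loci


def _cyclic_equal(a: str, b: str) -> bool:
    return len(a) == len(b) and b in (a + a)


def _projector(deletions):
    """Accession-coordinate -> reference-coordinate mapping over deletions.

    ``deletions`` are (start, end) 1-based inclusive intervals on the
    reference.  Positions map by adding the total deleted length lying
    left of them.
    """
    dels = sorted(tuple(d) for d in deletions)
    junctions, cum, removed = [], [0], 0
    for (s, e) in dels:
        junctions.append(s - 1 - removed)
        removed += e - s + 1
        cum.append(removed)
    junctions = np.asarray(junctions)
    cum = np.asarray(cum)

    def project(pos: int) -> int:
        return int(pos + cum[np.searchsorted(junctions, pos, side="left")])

    return project


def compare_trs(
    accession_loci: list[TRLocus],
    reference_loci: list[TRLocus],
    deletions=(),
    tolerance: int = 50,
) -> TRComparison:
    """Match accession and reference TR loci; classify gained/lost/shared.

    Loci match when their units are identical up to cyclic rotation and
    their (projected) starts lie within ``tolerance`` bp.  Reference loci
    falling inside a deleted interval are counted as lost with a flag.
    """
    project = _projector(deletions)
    dels = sorted(tuple(d) for d in deletions)

    ref_free = []
    lost_in_del = []
    for locus in reference_loci:
        if any(s <= locus.start <= e for (s, e) in dels):
            lost_in_del.append(locus)
        else:
            ref_free.append(locus)

    unmatched_ref = list(ref_free)
    gained, shared = [], []
    for locus in accession_loci:
        proj_start = project(locus.start)
        best = None
        for r in unmatched_ref:
            if _cyclic_equal(locus.unit, r.unit) and abs(proj_start - r.start) <= tolerance:
                if best is None or abs(proj_start - r.start) < abs(proj_start - best.start):
                    best = r
        if best is None:
            gained.append(locus)
        else:
            unmatched_ref.remove(best)
            shared.append((locus, best))
    lost = sorted(unmatched_ref + lost_in_del, key=lambda l: l.start)
    return TRComparison(gained=gained, lost=lost, shared=shared, lost_in_deletion=lost_in_del)


def loci_to_bed(loci: list[TRLocus], chrom: str) -> str:
    """BED text (0-based half-open) for TR loci."""
    lines = [
        f"{chrom}\t{l.start - 1}\t{l.end}\tTR;unit={l.unit};copies={l.copies:.2f}"
        for l in loci
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def render_track(comparison: TRComparison, length: int, width: int = 80) -> str:
    """Text band: '+' where TRs are gained, '-' where lost, '=' shared."""
    track = [" "] * width

    def mark(loci, char, use_ref_coord=False):
        for item in loci:
            locus = item[1] if use_ref_coord and isinstance(item, tuple) else item
            col = min(width - 1, int((locus.start - 1) * width / max(length, 1)))
            track[col] = char

    mark(comparison.shared, "=", use_ref_coord=True)
    mark(comparison.gained, "+")
    mark(comparison.lost, "-")
    return "".join(track)
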