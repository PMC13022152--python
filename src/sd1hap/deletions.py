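"""Long-deletion calling from properly oriented read pairs.

The evidence rule is the classical insert-size one: among forward-reverse
("properly oriented") pairs, a template length far above the library's
typical insert indicates deleted reference material between the mates.
Pairs are discordant when their template length exceeds
``mean + k_sigma * sd`` of a robustly fitted insert model (median and
1.4826*MAD); mutually overlapping inner spans are clustered; the reported
interval is the intersection of the cluster's inner spans — the maximal
region consistent with every supporting pair — and the size estimate is
the median template-length excess.  Exact breakpoints, when the reference
and accession sequences are both available, come from longest exact flank
matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InsertSizeModel",
    "DeletionCall",
    "fit_insert_model",
    "detect_deletions",
    "refine_breakpoints",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "pairs_from_sam",
    "calls_to_bed",
]

PAIR_COLUMNS = ["accession", "chrom", "left_pos", "right_pos", "orientation", "template_length"]


@dataclass(frozen=True)
class InsertSizeModel:
    mean: float
    sd: float
    n_observations: int

    def __post_init__(self):
        if self.n_observations >= 2 and self.sd <= 0:
            raise ValueError("sd must be > 0 with >= 2 observations")

    def threshold(self, k_sigma: float) -> float:
        return self.mean + k_sigma * self.sd


@dataclass
class DeletionCall:
    chrom: str
    start: int  # 1-based
    end: int    # 1-based inclusive
    support: int
    size_estimate: float
    coverage_drop: bool | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("call interval reversed")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def fit_insert_model(pairs: pd.DataFrame) -> InsertSizeModel:
    """Robust insert-size location/scale from forward-reverse pairs.

    Location is the median template length, scale 1.4826 * MAD (floored at
    1 so a degenerate constant library still yields a usable model).
    """
    fr = pairs[pairs["orientation"] == "FR"]
    tlen = fr["template_length"].to_numpy(dtype=float)
    if tlen.size < 2:
        raise ValueError(f"need >= 2 properly oriented pairs, got {tlen.size}")
    med = float(np.median(tlen))
    mad = float(np.median(np.abs(tlen - med)))
    sd = max(1.4826 * mad, 1.0)
    return InsertSizeModel(mean=med, sd=sd, n_observations=tlen.size)


def detect_deletions(
    pairs: pd.DataFrame,
    model: InsertSizeModel,
    *,
    min_support: int = 3,
    k_sigma: float = 4.0,
    read_length: int = 100,
    check_coverage: bool = True,
) -> list[DeletionCall]:
    """Cluster discordant pairs into deletion calls.

    A pair is discordant iff it is FR-oriented and its template length
    strictly exceeds ``model.threshold(k_sigma)``.  A pair's inner span is
    ``[left_pos + read_length, right_pos - 1]`` (between the mates' inner
    ends).  Clusters are maximal sets of mutually overlapping inner spans;
    by the Helly property of intervals these are exactly the sets sharing a
    common point, found by a max-coverage sweep (largest cluster first, so
    an isolated stray discordant pair cannot contaminate a well-supported
    call).  The reported interval is the intersection of the cluster's
    inner spans.  Calls with support below ``min_support`` are suppressed.
    ``coverage_drop`` is set when mean read depth inside the call is below
    10% of the mean depth in 500-bp flanks.
    """
    fr = pairs[pairs["orientation"] == "FR"].reset_index(drop=True)
    disc = fr[fr["template_length"] > model.threshold(k_sigma)]
    if disc.empty:
        return []

    calls: list[DeletionCall] = []
    for chrom, sub in disc.groupby("chrom", sort=True):
        inner_start = (sub["left_pos"] + read_length).to_numpy(dtype=np.int64)
        inner_end = (sub["right_pos"] - 1).to_numpy(dtype=np.int64)
        tlen = sub["template_length"].to_numpy(dtype=float)
        ok = inner_start <= inner_end  # drop degenerate spans (overlapping mates)
        remaining = np.flatnonzero(ok)
        while remaining.size >= min_support:
            starts = inner_start[remaining]
            ends = inner_end[remaining]
            # point of maximal coverage over candidate points (span starts)
            counts = np.array(
                [np.sum((starts <= p) & (p <= ends)) for p in starts]
            )
            best = int(counts.max())
            if best < min_support:
                break
            p = int(starts[counts.argmax()])
            in_clique = (starts <= p) & (p <= ends)
            clique = remaining[in_clique]
            calls.append(
                DeletionCall(
                    chrom=str(chrom),
                    start=int(inner_start[clique].max()),
                    end=int(inner_end[clique].min()),
                    support=int(clique.size),
                    size_estimate=float(np.median(tlen[clique])) - model.mean,
                )
            )
            remaining = remaining[~in_clique]
    calls.sort(key=lambda c: (c.chrom, c.start))

    if check_coverage and calls:
        depth = _depth_profile(fr, read_length)
        for call in calls:
            call.coverage_drop = _has_coverage_drop(depth, call)
    return calls


def _depth_profile(fr: pd.DataFrame, read_length: int) -> np.ndarray:
    hi = int(max(fr["right_pos"].max() + read_length, fr["left_pos"].max() + read_length)) + 2
    depth = np.zeros(hi, dtype=np.int64)
    for col in ("left_pos", "right_pos"):
        starts = fr[col].to_numpy(dtype=np.int64)
        np.add.at(depth, starts, 1)
        np.add.at(depth, np.minimum(starts + read_length, hi - 1), -1)
    return np.cumsum(depth)


def _has_coverage_drop(depth: np.ndarray, call: DeletionCall, flank: int = 500) -> bool:
    lo, hi = call.start, call.end
    inside = depth[lo : hi + 1]
    left = depth[max(0, lo - flank) : lo]
    right = depth[hi + 1 : hi + 1 + flank]
    flank_depth = np.concatenate([left, right])
    if inside.size == 0 or flank_depth.size == 0 or flank_depth.mean() == 0:
        return False
    return float(inside.mean()) < 0.1 * float(flank_depth.mean())


def refine_breakpoints(reference: str, accession_seq: str) -> tuple[int, int] | None:
    """Exact single-deletion breakpoints by longest flank matching.

    Returns the 1-based inclusive deleted interval on the reference, or
    None when the accession is not shorter than the reference.  When the
    deletion is flanked by repeated sequence the left-most placement is
    returned.
    """
    d = len(reference) - len(accession_seq)
    if d <= 0:
        return None
    p = 0
    limit = len(accession_seq)
    while p < limit and reference[p] == accession_seq[p]:
        p += 1
    return (p + 1, p + d)


# ---------------------------------------------------------------------------
# I/O


def read_pairs_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pairs TSV missing columns: {sorted(missing)}")
    return df


def write_pairs_tsv(path: str, pairs: pd.DataFrame) -> None:
    pairs.to_csv(path, sep="\t", index=False, columns=PAIR_COLUMNS)


def pairs_from_sam(path: str, accession: str | None = None) -> pd.DataFrame:
    """Extract FR read pairs from a SAM file (TLEN > 0 representative)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for read in sam:
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or not read.is_paired
                or read.template_length <= 0
                or read.is_reverse
                or not read.mate_is_reverse
            ):
                continue
            rows.append(
                {
                    "accession": accession or (read.get_tag("RG") if read.has_tag("RG") else "sample"),
                    "chrom": read.reference_name,
                    "left_pos": read.reference_start + 1,
                    "right_pos": read.next_reference_start + 1,
                    "orientation": "FR",
                    "template_length": read.template_length,
                }
            )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def calls_to_bed(calls: list[DeletionCall]) -> str:
    """BED text (0-based half-open) for a list of calls."""
    lines = [
        f"{c.chrom}\t{c.start - 1}\t{c.end}\tdel;support={c.support};size={c.size_estimate:.0f}"
        for c in calls
    ]
    return "\n".join(lines) + ("\n" if lines else "")
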