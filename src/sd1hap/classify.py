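"""Assigning rice accessions to the 12 SD1 haplotype classes.

The shipped definition table encodes the 12 published haplotypes in
Nipponbare chromosome-1 coordinates: two long deletions (the 1,279-bp
allele and the 383-bp DGWG allele), seven point loss-of-function or
missense diagnostics, a 2-bp frameshift indel, and the three observed
combinations of the residue-100/340 amino-acid states (GR, EQ, ER; GQ is
absent from natural populations and gets an explicit label rather than an
error).

Classification follows a strict precedence: structural alleles first
(matched to deletion calls by reciprocal overlap), then homozygous point
diagnostics, and only then the residue-100/340 state pair — accessions
carrying a type 3-12 diagnostic may also carry readable 100/340 states, so
the combination is consulted last.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd

from .variant_io import VariantRecord

__all__ = [
    "HaplotypeDefinition",
    "DefinitionTable",
    "HaplotypeCall",
    "FrequencyTable",
    "ClassificationConflict",
    "load_definitions",
    "classify_accession",
    "classify_cohort",
    "tabulate_frequencies",
    "deletion_geometry",
]

# residue-100/340 nucleotide -> amino-acid state at the two diagnostic sites
_STATE_100 = {"ref": "G", "alt": "E"}  # Gly vs Glu
_STATE_340 = {"ref": "R", "alt": "Q"}  # Arg vs Gln
COMBO_LABELS = {("G", "R"): 1, ("E", "Q"): 2, ("E", "R"): 11, ("G", "Q"): "GQ_unobserved"}

STRUCTURAL, POINT_LOF, COMBO = 1, 2, 3


class ClassificationConflict(ValueError):
    """Mutually exclusive structural diagnostics both matched (sample purity)."""


@dataclass(frozen=True)
class HaplotypeDefinition:
    type_id: int
    allele_name: str
    kind: str  # combo | point_snp | indel | long_deletion
    precedence: int
    chrom: str
    positions: tuple[int, ...]
    ref: tuple[str, ...]
    alt: tuple[str, ...]
    expected: tuple[str, ...]
    length: int | None
    aa_detail: str
    note: str = ""

    def __post_init__(self):
        if self.kind in ("long_deletion", "indel"):
            s, e = self.positions
            if e - s + 1 != self.length:
                raise ValueError(
                    f"type {self.type_id}: interval length {e - s + 1} != declared {self.length}"
                )

    @property
    def interval(self) -> tuple[int, int]:
        if self.kind not in ("long_deletion", "indel"):
            raise ValueError(f"type {self.type_id} has no interval diagnostic")
        return (self.positions[0], self.positions[-1])

    def shifted(self, delta: int) -> "HaplotypeDefinition":
        return replace(self, positions=tuple(p + delta for p in self.positions))


@dataclass
class DefinitionTable:
    definitions: list[HaplotypeDefinition]

    def __post_init__(self):
        self.by_id = {d.type_id: d for d in self.definitions}

    def __iter__(self):
        return iter(self.definitions)

    def __getitem__(self, type_id: int) -> HaplotypeDefinition:
        return self.by_id[type_id]

    def shifted(self, delta: int) -> "DefinitionTable":
        return DefinitionTable([d.shifted(delta) for d in self.definitions])

    def of_kind(self, *kinds: str) -> list[HaplotypeDefinition]:
        return [d for d in self.definitions if d.kind in kinds]

    @property
    def combo_sites(self) -> tuple[int, int]:
        combo = self.of_kind("combo")[0]
        return combo.positions[0], combo.positions[1]


def _split(raw: str) -> tuple[str, ...]:
    return tuple(raw.split(",")) if raw != "." else ()


def load_definitions(path: str | None = None) -> DefinitionTable:
    """Load the haplotype definition TSV (shipped table by default)."""
    if path is None:
        path = resources.files("sd1hap.data") / "haplotype_definitions.tsv"
    defs: list[HaplotypeDefinition] = []
    with open(path) as fh:
        rows = [r for r in fh if not r.startswith("#")]
    for row in csv.DictReader(rows, delimiter="\t"):
        raw_pos = row["positions"]
        if "-" in raw_pos:
            s, e = raw_pos.split("-")
            positions = (int(s), int(e))
        else:
            positions = tuple(int(p) for p in raw_pos.split(","))
        defs.append(
            HaplotypeDefinition(
                type_id=int(row["type_id"]),
                allele_name=row["allele_name"],
                kind=row["kind"],
                precedence=int(row["precedence"]),
                chrom=row["chrom"],
                positions=positions,
                ref=_split(row["ref"]),
                alt=_split(row["alt"]),
                expected=_split(row["expected"]),
                length=None if row["length"] == "." else int(row["length"]),
                aa_detail=row["aa_detail"],
                note=row.get("note", ""),
            )
        )
    defs.sort(key=lambda d: (d.precedence, d.type_id))
    return DefinitionTable(defs)


# ---------------------------------------------------------------------------
# geometry


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0] + 1), inter / (b[1] - b[0] + 1))


def deletion_geometry(definitions: DefinitionTable) -> dict:
    """Lengths and pairwise 3'-end distances of the defined long deletions.

    The 3'-end breakpoint is ``end + 1`` — the first retained base after the
    deleted interval; pairwise distances are invariant to using ``end``
    instead, as long as the convention is applied to both.
    """
    dels = definitions.of_kind("long_deletion")
    if not dels:
        raise ValueError("no long-deletion definitions present")
    lengths = {d.type_id: d.interval[1] - d.interval[0] + 1 for d in dels}
    three_prime = {d.type_id: d.interval[1] + 1 for d in dels}
    pairwise = {
        (a.type_id, b.type_id): abs(three_prime[a.type_id] - three_prime[b.type_id])
        for i, a in enumerate(dels)
        for b in dels[i + 1 :]
    }
    return {"lengths": lengths, "three_prime_ends": three_prime, "pairwise_3p_distances": pairwise}


# ---------------------------------------------------------------------------
# classification


@dataclass
class HaplotypeCall:
    accession: str
    label: int | str  # type id, or GQ_unobserved / heterozygous / unclassified
    zygosity: str = "hom"
    evidence: list[str] = field(default_factory=list)


def _genotype_state(rec: VariantRecord | None, sample: str) -> str:
    """'ref' / 'alt' / 'het' / 'missing' for one sample at one site."""
    if rec is None:
        return "ref"  # absent from the (filtered) variant set = reference
    call = rec.call(sample)
    if call is None or call.is_missing:
        return "ref"
    if call.is_het:
        return "het"
    return "alt" if call.is_hom_alt else "ref"


def classify_accession(
    variants: list[VariantRecord],
    deletion_calls,
    definitions: DefinitionTable,
    sample: str,
    *,
    reciprocal_overlap_min: float = 0.9,
    homozygous_only: bool = True,
    indel_tolerance: int = 2,
) -> HaplotypeCall:
    """Assign one accession to a haplotype class.

    ``variants`` are (filtered) records carrying this sample's genotypes;
    ``deletion_calls`` are objects with ``start``/``end`` attributes (or
    (start, end) tuples) in the same coordinate system as ``definitions``.
    """
    by_pos: dict[int, VariantRecord] = {}
    for rec in variants:
        by_pos.setdefault(rec.pos, rec)

    # 1) structural
    matched_structural: dict[int, tuple[int, int]] = {}
    for call in deletion_calls:
        span = (call.start, call.end) if hasattr(call, "start") else tuple(call)
        for d in definitions.of_kind("long_deletion"):
            if reciprocal_overlap(span, d.interval) >= reciprocal_overlap_min:
                matched_structural[d.type_id] = span
    if len(matched_structural) > 1:
        raise ClassificationConflict(
            f"{sample}: deletion calls match multiple structural types "
            f"{sorted(matched_structural)} — possible sample-purity problem"
        )
    if matched_structural:
        ((tid, span),) = matched_structural.items()
        return HaplotypeCall(sample, tid, "hom", [f"deletion {span[0]}-{span[1]}"])

    # 2) homozygous point LOF / frameshift diagnostics
    point_hits: list[tuple[int, str]] = []
    for d in definitions.of_kind("point_snp"):
        rec = by_pos.get(d.positions[0])
        if rec is None:
            continue
        call = rec.call(sample)
        if call is None or not call.is_hom_alt:
            continue
        allele = rec.alt[call.alleles[0] - 1] if call.alleles[0] - 1 < len(rec.alt) else None
        if d.expected and allele != d.expected[0]:
            continue
        point_hits.append((d.type_id, f"hom {rec.ref}>{allele} at {rec.pos} ({d.aa_detail})"))
    for d in definitions.of_kind("indel"):
        s, e = d.interval
        for pos, rec in by_pos.items():
            if rec.is_snp or not (s - indel_tolerance - 1 <= pos <= e + indel_tolerance):
                continue
            call = rec.call(sample)
            if call is None or not call.is_hom_alt:
                continue
            alt = rec.alt[call.alleles[0] - 1]
            if alt.startswith("<"):
                continue
            if abs(len(rec.ref) - len(alt)) == d.length:
                point_hits.append((d.type_id, f"hom {d.length}-bp indel at {pos} ({d.aa_detail})"))
                break
    if point_hits:
        point_hits.sort()
        tid = point_hits[0][0]
        evidence = [ev for _, ev in point_hits]
        return HaplotypeCall(sample, tid, "hom", evidence)

    # 3) residue-100/340 combination
    site100, site340 = definitions.combo_sites
    s100 = _genotype_state(by_pos.get(site100), sample)
    s340 = _genotype_state(by_pos.get(site340), sample)
    if "het" in (s100, s340) and homozygous_only:
        return HaplotypeCall(sample, "heterozygous", "het", [f"100:{s100} 340:{s340}"])
    aa100 = _STATE_100["alt" if s100 in ("alt", "het") else "ref"]
    aa340 = _STATE_340["alt" if s340 in ("alt", "het") else "ref"]
    label = COMBO_LABELS[(aa100, aa340)]
    zyg = "het" if "het" in (s100, s340) else "hom"
    return HaplotypeCall(sample, label, zyg, [f"{aa100}100/{aa340}340"])


def classify_cohort(
    variants: list[VariantRecord],
    deletion_calls_by_sample: dict[str, list],
    definitions: DefinitionTable,
    samples: list[str] | None = None,
    **kwargs,
) -> list[HaplotypeCall]:
    if samples is None:
        seen: dict[str, None] = {}
        for rec in variants:
            for s in rec.calls:
                seen.setdefault(s)
        samples = list(seen)
    return [
        classify_accession(
            variants, deletion_calls_by_sample.get(s, []), definitions, s, **kwargs
        )
        for s in samples
    ]


# ---------------------------------------------------------------------------
# frequency tables


@dataclass
class FrequencyTable:
    counts: pd.DataFrame  # rows = haplotype labels, columns = groups
    percent: pd.DataFrame  # per-column percentages, 1 decimal
    excluded: list[str]  # accessions without metadata
    homozygous_only: bool = True

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def tabulate_frequencies(
    calls: list[HaplotypeCall],
    metadata: pd.DataFrame,
    homozygous_only: bool = True,
    by: str = "subpopulation",
) -> FrequencyTable:
    """Count haplotype labels per metadata group, with percentages.

    Heterozygous calls are excluded from both numerator and denominator when
    ``homozygous_only`` (the published tables count only homozygous
    alleles); accessions without metadata are reported and excluded.
    """
    meta = metadata.set_index("accession")
    rows = []
    excluded = []
    for call in calls:
        if call.accession not in meta.index:
            excluded.append(call.accession)
            continue
        if homozygous_only and call.zygosity == "het":
            continue
        rows.append({"label": str(call.label), "group": meta.loc[call.accession, by]})
    df = pd.DataFrame(rows, columns=["label", "group"])
    counts = df.groupby(["label", "group"]).size().unstack(fill_value=0)
    counts = counts.sort_index(key=lambda idx: [(len(x), x) for x in idx])
    percent = (100.0 * counts / counts.sum(axis=0)).round(1)
    return FrequencyTable(counts, percent, excluded, homozygous_only)
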