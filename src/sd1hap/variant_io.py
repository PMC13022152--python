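"""VCF and metadata I/O plus site-level genotype quality filtering.

Reading and writing go through pysam (htslib); records are held in a small
in-memory representation carrying, per sample, the genotype, read depth and
alternate-allele read fraction — the two quantities the quality filter acts
on (calls are kept only when depth > 5 and alt fraction > 0.8, both strict,
by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
import pysam

__all__ = [
    "GenotypeCall",
    "VariantRecord",
    "FilterPolicy",
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "filter_variants",
    "read_metadata",
]

SUBPOPULATIONS = ("indica", "japonica", "aus", "aromatic", "admix")
CATEGORIES = ("landrace", "modern")


class VcfParseError(ValueError):
    """Malformed VCF content, carrying the offending line number when known."""


@dataclass
class GenotypeCall:
    sample: str
    alleles: tuple[int | None, int | None]
    depth: int | None = None
    alt_fraction: float | None = None

    def __post_init__(self):
        if self.depth is not None and self.depth < 0:
            raise ValueError("negative depth")
        if self.alt_fraction is not None and not (0.0 <= self.alt_fraction <= 1.0):
            raise ValueError("alt_fraction outside [0, 1]")

    @property
    def is_missing(self) -> bool:
        return self.alleles[0] is None or self.alleles[1] is None

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles == (0, 0)

    @property
    def is_het(self) -> bool:
        return not self.is_missing and self.alleles[0] != self.alleles[1]

    @property
    def is_hom_alt(self) -> bool:
        a, b = self.alleles
        return a is not None and a == b and a > 0


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: list[str]
    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    end: int | None = None  # INFO/END for symbolic alleles

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref:
            raise ValueError("empty REF")
        self.ref = self.ref.upper()
        self.alt = [a if a.startswith("<") else a.upper() for a in self.alt]

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 and not a.startswith("<") for a in self.alt)

    def call(self, sample: str) -> GenotypeCall | None:
        return self.calls.get(sample)


@dataclass(frozen=True)
class FilterPolicy:
    """Per-genotype retention thresholds, strict inequalities."""

    min_depth_exclusive: int = 5
    min_alt_fraction_exclusive: float = 0.8

    def __post_init__(self):
        if self.min_depth_exclusive < 0 or self.min_alt_fraction_exclusive < 0:
            raise ValueError("thresholds must be >= 0")

    def keeps(self, call: GenotypeCall) -> bool:
        """Whether a non-reference call survives.

        Homozygous-alt calls must clear both bounds strictly.  Heterozygous
        calls must clear the depth bound; the read-fraction rule is not
        applied to them (a true het sits near 0.5 and the rule exists to
        reject weakly supported homozygous claims), so heterozygosity at a
        diagnostic site remains observable downstream.
        """
        if call.is_missing or call.is_hom_ref:
            return False
        if call.depth is None or call.depth <= self.min_depth_exclusive:
            return False
        if call.is_het:
            return True
        if call.alt_fraction is None:
            return False
        return call.alt_fraction > self.min_alt_fraction_exclusive


def _alt_fraction(depth: int | None, ad: tuple | None, alleles) -> float | None:
    """Alternate-allele read fraction from the AD field (alt depth / total)."""
    if ad is None or any(x is None for x in ad):
        return None
    total = sum(ad)
    if total == 0:
        return None
    return sum(ad[1:]) / total


def read_vcf(path: str) -> list[VariantRecord]:
    """Read a VCF v4.x file into :class:`VariantRecord` objects."""
    records: list[VariantRecord] = []
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        for lineno, rec in enumerate(vf, start=1):
            try:
                alts = list(rec.alts) if rec.alts else []
                calls = {}
                for s in samples:
                    fmt = rec.samples[s]
                    gt = fmt.get("GT", (None, None))
                    if gt is None or len(gt) == 0:
                        gt = (None, None)
                    elif len(gt) == 1:
                        gt = (gt[0], gt[0])
                    depth = fmt.get("DP", None)
                    ad = fmt.get("AD", None)
                    calls[s] = GenotypeCall(
                        sample=s,
                        alleles=(gt[0], gt[1]),
                        depth=depth,
                        alt_fraction=_alt_fraction(depth, ad, gt),
                    )
                end = rec.stop if alts and alts[0] == "<DEL>" else None
                records.append(
                    VariantRecord(rec.chrom, rec.pos, rec.ref, alts, calls, end=end)
                )
            except (ValueError, KeyError) as exc:
                raise VcfParseError(f"malformed record at body line {lineno}: {exc}") from exc
    return records


def write_vcf(path: str, records: list[VariantRecord], contigs: dict[str, int]) -> None:
    """Write records to an uncompressed VCF v4.2 file with GT:DP:AD."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.info.add("END", 1, "Integer", "End position of a symbolic allele")
    header.info.add("SVLEN", 1, "Integer", "Signed length of a structural variant")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allele read depths")
    samples: list[str] = []
    for rec in records:
        for s in rec.calls:
            if s not in samples:
                samples.append(s)
    for s in samples:
        header.add_sample(s)

    ordered = sorted(records, key=lambda r: (r.chrom, r.pos))
    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in ordered:
            kwargs = {}
            if rec.end is not None:
                kwargs["stop"] = rec.end
            vr = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                alleles=tuple([rec.ref] + rec.alt),
                **kwargs,
            )
            if rec.end is not None:
                vr.info["SVLEN"] = -(rec.end - rec.pos)
            for s in samples:
                call = rec.calls.get(s)
                if call is None:
                    vr.samples[s]["GT"] = (None, None)
                    continue
                vr.samples[s]["GT"] = call.alleles
                if call.depth is not None:
                    vr.samples[s]["DP"] = call.depth
                    if call.alt_fraction is not None:
                        alt_reads = round(call.depth * call.alt_fraction)
                        ad = [call.depth - alt_reads] + [0] * len(rec.alt)
                        called_alts = [a for a in call.alleles if a and a > 0]
                        ad[called_alts[0] if called_alts else 1] = alt_reads
                        vr.samples[s]["AD"] = tuple(ad)
            out.write(vr)


def filter_variants(records: list[VariantRecord], policy: FilterPolicy | None = None) -> list[VariantRecord]:
    """Apply the per-genotype depth/frequency filter.

    A sample's non-reference call survives iff depth and alternate-read
    fraction both exceed the policy thresholds strictly; hom-ref and missing
    calls pass through untouched (they carry no alternate evidence to
    filter); sites left with no surviving non-reference call are dropped.
    """
    policy = policy or FilterPolicy()
    out: list[VariantRecord] = []
    for rec in records:
        kept: dict[str, GenotypeCall] = {}
        any_alt = False
        for s, call in rec.calls.items():
            if call.is_hom_ref or call.is_missing:
                kept[s] = call  # no alternate evidence to judge
            elif policy.keeps(call):
                kept[s] = call
                any_alt = True
        if any_alt:
            out.append(replace(rec, calls=kept))
    return out


def read_metadata(path: str) -> pd.DataFrame:
    """Read the accession metadata TSV (accession, subpopulation, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"accession", "subpopulation", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad = set(df["subpopulation"]) - set(SUBPOPULATIONS)
    if bad:
        raise ValueError(f"unknown subpopulations: {sorted(bad)}")
    return df
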