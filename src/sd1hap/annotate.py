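"""Minimal variant-effect annotation against a single-transcript gene model.

Classifies each variant by where it falls (promoter, exon/CDS, intron, splice
site, up/downstream) and by predicted impact (synonymous / missense /
stop-gained / frameshift / in-frame indel / feature-level deletion), in the
style of SnpEff's basic coding annotations.  One transcript, forward or
reverse strand; the CDS is the concatenation of the ``cds_intervals`` in
genomic order (reverse-complemented on the minus strand).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

__all__ = [
    "GeneModel",
    "EffectClass",
    "Annotation",
    "InternalStopError",
    "translate_cds",
    "annotate_variant",
]

SPLICE_WIDTH = 2  # intronic bp on each side of an exon treated as splice site


class InternalStopError(ValueError):
    """Raised when a CDS translates with a premature stop codon."""


class EffectClass(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    EXONIC_DELETION = "exonic_deletion"
    PROMOTER_DELETION = "promoter_deletion"
    INTRONIC = "intronic"
    SPLICE_SITE = "splice_site"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model with 1-based inclusive intervals."""

    chrom: str
    exon_intervals: tuple[tuple[int, int], ...]
    cds_intervals: tuple[tuple[int, int], ...] = ()
    strand: str = "+"
    promoter_flank: int = 1000

    def __post_init__(self):
        exons = tuple(sorted(tuple(iv) for iv in self.exon_intervals))
        object.__setattr__(self, "exon_intervals", exons)
        cds = tuple(sorted(tuple(iv) for iv in self.cds_intervals)) or exons
        object.__setattr__(self, "cds_intervals", cds)
        for (s, e) in exons:
            if s > e:
                raise ValueError(f"malformed exon interval ({s}, {e})")
        for i in range(1, len(exons)):
            if exons[i][0] <= exons[i - 1][1]:
                raise ValueError("exon intervals overlap")
        for (s, e) in cds:
            if not any(s >= xs and e <= xe for (xs, xe) in exons):
                raise ValueError("CDS interval not contained in an exon")
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    # ---- geometry -----------------------------------------------------
    @property
    def gene_start(self) -> int:
        return self.exon_intervals[0][0]

    @property
    def gene_end(self) -> int:
        return self.exon_intervals[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for (s, e) in self.cds_intervals)

    @property
    def intron_intervals(self) -> tuple[tuple[int, int], ...]:
        ivs = []
        for a, b in zip(self.exon_intervals, self.exon_intervals[1:]):
            ivs.append((a[1] + 1, b[0] - 1))
        return tuple(ivs)

    @property
    def promoter_interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return (max(1, self.gene_start - self.promoter_flank), self.gene_start - 1)
        return (self.gene_end + 1, self.gene_end + self.promoter_flank)

    def cds_positions(self) -> list[int]:
        """Genomic positions of CDS bases, in translation order."""
        pos = [p for (s, e) in self.cds_intervals for p in range(s, e + 1)]
        return pos[::-1] if self.strand == "-" else pos

    def cds_index(self, pos: int) -> int | None:
        """1-based index within the CDS of genomic position ``pos``, or None."""
        offset = 0
        ivs = self.cds_intervals if self.strand == "+" else self.cds_intervals[::-1]
        for (s, e) in ivs:
            if s <= pos <= e:
                return offset + (pos - s + 1 if self.strand == "+" else e - pos + 1)
            offset += e - s + 1
        return None

    def extract_cds(self, sequence: str) -> str:
        parts = [sequence[s - 1 : e] for (s, e) in self.cds_intervals]
        cds = "".join(parts)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    def splice_positions(self) -> set[int]:
        out: set[int] = set()
        for (s, e) in self.intron_intervals:
            width = min(SPLICE_WIDTH, e - s + 1)
            out.update(range(s, s + width))
            out.update(range(e - width + 1, e + 1))
        return out


def translate_cds(cds: str, allow_internal_stop: bool = False) -> str:
    """Translate a CDS with the standard code; the trailing stop is dropped.

    Raises :class:`InternalStopError` on a premature stop unless
    ``allow_internal_stop`` is set, in which case the ``*`` is kept in the
    returned string.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if not cds:
        return ""
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa and not allow_internal_stop:
        raise InternalStopError(f"internal stop at codon {aa.index('*') + 1}")
    return aa


@dataclass
class Annotation:
    """Effect of one variant on one transcript.

    ``effect`` is the single primary class; ``classes`` lists every feature
    class a multi-feature deletion overlaps (equal to ``{effect}`` for point
    variants).
    """

    effect: EffectClass
    detail: str = ""
    classes: frozenset[EffectClass] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.classes:
            self.classes = frozenset({self.effect})

    def to_ann(self) -> str:
        """Compact ANN-style text (``effect|detail`` plus extra classes)."""
        extra = sorted(c.value for c in self.classes if c != self.effect)
        tail = ("," + ",".join(extra)) if extra else ""
        return f"{self.effect.value}|{self.detail}{tail}"


def _aa_name(aa: str) -> str:
    return "*" if aa == "*" else seq3(aa)


def _classify_noncoding_point(pos: int, model: GeneModel) -> Annotation:
    ps, pe = model.promoter_interval
    if ps <= pos <= pe:
        return Annotation(EffectClass.UPSTREAM, "promoter")
    if pos in model.splice_positions():
        return Annotation(EffectClass.SPLICE_SITE)
    for (s, e) in model.intron_intervals:
        if s <= pos <= e:
            return Annotation(EffectClass.INTRONIC)
    if pos < model.gene_start:
        which = EffectClass.UPSTREAM if model.strand == "+" else EffectClass.DOWNSTREAM
        return Annotation(which)
    if pos > model.gene_end:
        which = EffectClass.DOWNSTREAM if model.strand == "+" else EffectClass.UPSTREAM
        return Annotation(which)
    # inside an exon but outside the CDS (UTR); closest available label
    return Annotation(EffectClass.INTRONIC, "non_coding_exon")


def _annotate_snp(pos: int, ref: str, alt: str, model: GeneModel, sequence: str) -> Annotation:
    idx = model.cds_index(pos)
    if idx is None:
        return _classify_noncoding_point(pos, model)
    cds = model.extract_cds(sequence)
    codon_no = (idx - 1) // 3 + 1
    off = (idx - 1) % 3
    codon = cds[(codon_no - 1) * 3 : codon_no * 3]
    base, alt_base = ref, alt
    if model.strand == "-":
        base = str(Seq(ref).reverse_complement())
        alt_base = str(Seq(alt).reverse_complement())
    if codon[off] != base:
        raise ValueError(
            f"reference mismatch at {model.chrom}:{pos}: CDS has {codon[off]}, variant says {base}"
        )
    new_codon = codon[:off] + alt_base + codon[off + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new_codon).translate())
    detail = f"{_aa_name(aa_ref)}{codon_no}{_aa_name(aa_alt)}"
    if aa_alt == aa_ref:
        return Annotation(EffectClass.SYNONYMOUS, detail)
    if aa_alt == "*":
        return Annotation(EffectClass.STOP_GAINED, detail)
    return Annotation(EffectClass.MISSENSE, detail)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _annotate_deletion_span(span: tuple[int, int], model: GeneModel) -> Annotation:
    classes: set[EffectClass] = set()
    if _overlaps(span, model.promoter_interval):
        classes.add(EffectClass.PROMOTER_DELETION)
    if any(_overlaps(span, iv) for iv in model.exon_intervals):
        classes.add(EffectClass.EXONIC_DELETION)
    if any(_overlaps(span, iv) for iv in model.intron_intervals):
        classes.add(EffectClass.INTRONIC)
    if not classes:
        if span[1] < model.gene_start:
            classes.add(EffectClass.UPSTREAM if model.strand == "+" else EffectClass.DOWNSTREAM)
        else:
            classes.add(EffectClass.DOWNSTREAM if model.strand == "+" else EffectClass.UPSTREAM)
    order = [
        EffectClass.EXONIC_DELETION,
        EffectClass.PROMOTER_DELETION,
        EffectClass.INTRONIC,
        EffectClass.UPSTREAM,
        EffectClass.DOWNSTREAM,
    ]
    primary = next(c for c in order if c in classes)
    return Annotation(primary, f"{span[0]}-{span[1]}del", frozenset(classes))


def annotate_variant(variant, model: GeneModel, sequence: str) -> Annotation:
    """Annotate one variant record against ``model`` on reference ``sequence``.

    ``variant`` needs ``pos``, ``ref`` and ``alt`` attributes (first ALT
    allele used); symbolic ``<DEL>`` alleles need an ``end`` attribute.
    A variant outside the locus annotates as upstream/downstream, never as an
    error.
    """
    alt = variant.alt[0] if isinstance(variant.alt, (list, tuple)) else variant.alt
    pos, ref = variant.pos, variant.ref

    if alt == "<DEL>":
        end = getattr(variant, "end", None)
        if end is None:
            raise ValueError("symbolic deletion without END")
        return _annotate_deletion_span((pos + 1, end), model)

    if len(ref) == 1 and len(alt) == 1:
        return _annotate_snp(pos, ref, alt, model, sequence)

    # indel with explicit alleles; normalise off the shared anchor base
    if ref[0] == alt[0]:
        if len(ref) > len(alt):  # deletion of ref[len(alt):]
            span = (pos + len(alt), pos + len(ref) - 1)
            dlen = len(ref) - len(alt)
            in_cds = [p for p in range(span[0], span[1] + 1) if model.cds_index(p) is not None]
            if len(in_cds) == span[1] - span[0] + 1 and in_cds:
                return _coding_indel(in_cds[0], dlen, model, sequence)
            return _annotate_deletion_span(span, model)
        dlen = len(alt) - len(ref)  # insertion after pos
        idx = model.cds_index(pos)
        if idx is not None and model.cds_index(pos + 1) is not None:
            return _coding_indel(pos + 1, -dlen, model, sequence)
        return _classify_noncoding_point(pos, model)
    raise ValueError(f"unnormalised indel alleles {ref}>{alt} at {pos}")


def _coding_indel(first_pos: int, deleted_len: int, model: GeneModel, sequence: str) -> Annotation:
    """Classify a CDS indel; ``deleted_len`` < 0 means an insertion."""
    idx = model.cds_index(first_pos)
    codon_no = (idx - 1) // 3 + 1
    protein = translate_cds(model.extract_cds(sequence), allow_internal_stop=True)
    aa = _aa_name(protein[codon_no - 1]) if codon_no <= len(protein) else ""
    if abs(deleted_len) % 3 == 0:
        return Annotation(EffectClass.INFRAME_INDEL, f"{aa}{codon_no}")
    return Annotation(EffectClass.FRAMESHIFT, f"{aa}{codon_no}fs")
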