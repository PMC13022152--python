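"""Synthetic data generator for the SD1 locus pipeline.

Everything the pipeline consumes can be generated here with recorded ground
truth: a 25-kb reference locus carrying a forward-strand three-exon gene
whose codon layout reproduces the published diagnostic geometry (residues
94/100 in exon 1, 240/266 in exon 2, 300/340/342/349 in exon 3, the 383-bp
and 1,279-bp deletions with 3' ends 13 bp apart); accessions edited to carry
each of the 12 haplotypes; paired-end reads under a truncated-Gaussian
insert model reported in reference coordinates; neutral coalescent samples
at a stated theta (msprime, infinite sites, no recombination); and
haplotype-dependent plant heights with Gaussian noise.

Real chromosome-1 coordinates map onto the locus by the single offset
``CHR1_OFFSET`` (locus = chr1 - offset), so the shipped definition table
stays quotable verbatim.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import popgen
from .annotate import GeneModel, translate_cds
from .classify import DefinitionTable, HaplotypeDefinition, load_definitions
from .variant_io import GenotypeCall, VariantRecord, write_vcf

__all__ = [
    "CHR1_OFFSET",
    "SimConfig",
    "TruthSet",
    "Cohort",
    "make_reference",
    "apply_haplotype",
    "simulate_read_pairs",
    "simulate_neutral_sample",
    "simulate_phenotypes",
    "simulate_cohort",
]

# chr1 coordinate = locus coordinate + CHR1_OFFSET
CHR1_OFFSET = 38_372_465
LOCUS_CHROM = "chr01"

# locus-coordinate gene layout consistent with every published diagnostic site
DEFAULT_EXONS = ((10_001, 10_450), (10_553, 10_999), (12_471, 12_743))

# codon number -> codon enforced on the reference CDS (diagnostic geometry)
_FIXED_CODONS = {
    1: "ATG",
    94: "GGA",   # Gly94  (GtA after 38,382,746 G>T = Val)
    100: "GGA",  # Gly100 (GaA after 38,382,764 G>A = Glu)
    130: "CGA",  # Arg130 (frameshift indel region)
    218: "TAC",  # Tyr218 (38,383,221 C>T linked marker, synonymous)
    240: "CCA",  # Pro240 (CtA = Leu)
    266: "CTC",  # Leu266 (Ttc = Phe)
    300: "TAC",  # Tyr300 (TAa = stop)
    340: "CGA",  # Arg340 (CaA = Gln)
    342: "TAC",  # Tyr342 (TAa = stop)
    349: "GAC",  # Asp349 (Cac = His)
    390: "TAA",  # stop
}

# type 7 carries the published linked synonymous marker C>T (chr1 38,383,221)
LINKED_MARKERS = {7: (38_383_221 - CHR1_OFFSET, "C", "T")}

_STOPS = {"TAA", "TAG", "TGA"}
_DEFAULT_HEIGHTS = {
    1: 150.0, 2: 110.0, 3: 58.0, 4: 59.0, 5: 60.0, 6: 95.0, 7: 95.0,
    8: 90.0, 9: 90.0, 10: 90.0, 11: 150.0, 12: 85.0, "heterozygous": 130.0,
}

# subpopulation composition per haplotype (probabilities), after the paper's
# distribution: types 3-6 japonica, 7-10 indica, 2 japonica-dominant, etc.
_SUBPOP_POOLS = {
    1: (("indica", 0.7), ("aus", 0.2), ("admix", 0.1)),
    2: (("japonica", 0.85), ("aromatic", 0.15)),
    3: (("japonica", 1.0),), 4: (("japonica", 1.0),),
    5: (("japonica", 1.0),), 6: (("japonica", 1.0),),
    7: (("indica", 1.0),), 8: (("indica", 1.0),),
    9: (("indica", 1.0),), 10: (("indica", 1.0),),
    11: (("indica", 0.6), ("aus", 0.25), ("japonica", 0.1), ("aromatic", 0.05)),
    12: (("aromatic", 1.0),),
    "heterozygous": (("indica", 0.8), ("admix", 0.2)),
}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    locus_length: int = 25_000
    gene_start: int = DEFAULT_EXONS[0][0]
    exon_intervals: tuple[tuple[int, int], ...] = DEFAULT_EXONS
    promoter_flank: int = 1_000
    insert_mean: float = 400.0
    insert_sd: float = 30.0
    read_length: int = 100
    coverage: float = 30.0
    theta: float = 5.0
    n_samples: int = 20
    height_means: dict = field(default_factory=lambda: dict(_DEFAULT_HEIGHTS))
    height_sd: float = 8.0
    chrom: str = LOCUS_CHROM

    def __post_init__(self):
        exons = tuple(sorted(tuple(iv) for iv in self.exon_intervals))
        object.__setattr__(self, "exon_intervals", exons)
        for i, (s, e) in enumerate(exons):
            if s > e or s < 1 or e > self.locus_length:
                raise ValueError(f"exon {i} outside locus or malformed")
            if i and s <= exons[i - 1][1]:
                raise ValueError("exon intervals overlap")
        if sum(e - s + 1 for s, e in exons) % 3 != 0:
            raise ValueError("exon layout gives CDS length not divisible by 3")
        if self.insert_mean <= 2 * self.read_length:
            raise ValueError("insert_mean must exceed 2 * read_length")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


# ---------------------------------------------------------------------------
# edits


@dataclass(frozen=True)
class Snp:
    pos: int
    ref: str
    alt: str

    @property
    def span(self):
        return (self.pos, self.pos)


@dataclass(frozen=True)
class Deletion:
    start: int
    end: int  # 1-based inclusive

    @property
    def length(self):
        return self.end - self.start + 1

    @property
    def span(self):
        return (self.start, self.end)


@dataclass(frozen=True)
class Insertion:
    after_pos: int
    bases: str

    @property
    def span(self):
        return (self.after_pos, self.after_pos)


@dataclass
class TruthSet:
    """Ground truth for a simulated cohort."""

    haplotypes: dict[str, int | str]  # accession -> type id or 'heterozygous'
    edits: dict[str, tuple] = field(default_factory=dict)
    deletions: dict[str, tuple] = field(default_factory=dict)
    group_means: dict = field(default_factory=dict)

    def label(self, accession: str):
        return self.haplotypes[accession]


# ---------------------------------------------------------------------------
# reference


def make_reference(config: SimConfig) -> tuple[str, GeneModel]:
    """Random locus sequence with the diagnostic-consistent gene model.

    The CDS is assembled from random non-stop codons with the diagnostic
    codons pinned, translates with no internal stop, starts ATG and ends
    with a stop; splice dinucleotides are canonical GT/AG.  Deterministic
    under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    model = GeneModel(
        chrom=config.chrom,
        exon_intervals=config.exon_intervals,
        promoter_flank=config.promoter_flank,
    )
    n_codons = model.cds_length // 3
    if n_codons < max(_FIXED_CODONS):
        raise ValueError("exon layout too short for the diagnostic codon map")

    bases = np.array(list("ACGT"))
    codon_pool = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
    codons = list(rng.choice(codon_pool, size=n_codons))
    for codon_no, codon in _FIXED_CODONS.items():
        if codon_no <= n_codons:
            codons[codon_no - 1] = codon
    cds = "".join(codons)
    translate_cds(cds)  # construction check: no internal stop

    seq = rng.choice(bases, size=config.locus_length)
    cds_positions = model.cds_positions()
    seq[np.asarray(cds_positions) - 1] = list(cds)
    for (s, e) in model.intron_intervals:
        seq[s - 1 : s + 1] = ["G", "T"]
        seq[e - 2 : e] = ["A", "G"]
    return "".join(seq), model


# ---------------------------------------------------------------------------
# haplotype edits


def edits_for_haplotype(
    hapdef: HaplotypeDefinition, reference: str, indel_as_insertion: bool = False
) -> tuple:
    """Edit operations (locus coordinates) a haplotype applies to the reference."""
    edits: list = []
    if hapdef.kind == "combo":
        for pos, exp, ref in zip(hapdef.positions, hapdef.expected, hapdef.ref):
            if exp != ref:
                edits.append(Snp(pos, ref, exp))
    elif hapdef.kind == "point_snp":
        edits.append(Snp(hapdef.positions[0], hapdef.ref[0], hapdef.alt[0]))
    elif hapdef.kind == "indel":
        s, e = hapdef.interval
        if indel_as_insertion:
            edits.append(Insertion(s - 1, reference[s - 1 : e]))
        else:
            edits.append(Deletion(s, e))
    elif hapdef.kind == "long_deletion":
        edits.append(Deletion(*hapdef.interval))
        marker = LINKED_MARKERS.get(hapdef.type_id)
        if marker:
            edits.append(Snp(marker[0], marker[1], marker[2]))
    else:
        raise ValueError(f"unknown diagnostic kind {hapdef.kind!r}")
    for edit in edits:
        if isinstance(edit, Snp) and reference[edit.pos - 1] != edit.ref:
            raise ValueError(
                f"definition/reference mismatch at {edit.pos}: "
                f"reference has {reference[edit.pos - 1]}, expected {edit.ref}"
            )
    spans = sorted(e.span for e in edits)
    for a, b in zip(spans, spans[1:]):
        if b[0] <= a[1]:
            raise ValueError(f"overlapping edits in type {hapdef.type_id}")
    return tuple(edits)


def apply_haplotype(
    reference: str,
    gene_model: GeneModel,
    hapdef: HaplotypeDefinition,
    *,
    indel_as_insertion: bool = False,
) -> tuple[str, tuple]:
    """Edited accession sequence plus the applied edit list.

    SNPs preserve length; deletions shorten the sequence by exactly the
    interval length.  Definitions are expected in locus coordinates (shift
    the table by ``-CHR1_OFFSET`` first).
    """
    edits = edits_for_haplotype(hapdef, reference, indel_as_insertion)
    for e in edits:
        lo, hi = e.span
        if lo < 1 or hi > len(reference):
            raise ValueError(f"edit {e} outside locus of length {len(reference)}")
    seq = list(reference)
    for e in sorted(edits, key=lambda e: -e.span[0]):  # right-to-left keeps coords valid
        if isinstance(e, Snp):
            seq[e.pos - 1] = e.alt
        elif isinstance(e, Deletion):
            del seq[e.start - 1 : e.end]
        else:
            seq[e.after_pos : e.after_pos] = list(e.bases)
    return "".join(seq), edits


def truth_records(
    edits: tuple, reference: str, chrom: str, sample: str, genotype=(1, 1),
    depth: int | None = None,
) -> list[VariantRecord]:
    """VCF-representable truth records for one accession's edits.

    Long deletions become symbolic ``<DEL>`` records anchored one base
    left; short indels carry explicit alleles.
    """
    recs = []
    af = 1.0 if genotype == (1, 1) else 0.5
    for e in edits:
        call = {sample: GenotypeCall(sample, genotype, depth=depth, alt_fraction=af if depth else None)}
        if isinstance(e, Snp):
            recs.append(VariantRecord(chrom, e.pos, e.ref, [e.alt], call))
        elif isinstance(e, Deletion):
            if e.length > 20:
                anchor = reference[e.start - 2]
                recs.append(
                    VariantRecord(chrom, e.start - 1, anchor, ["<DEL>"], call, end=e.end)
                )
            else:
                ref = reference[e.start - 2 : e.end]
                recs.append(VariantRecord(chrom, e.start - 1, ref, [ref[0]], call))
        else:
            anchor = reference[e.after_pos - 1]
            recs.append(VariantRecord(chrom, e.after_pos, anchor, [anchor + e.bases], call))
    return recs


# ---------------------------------------------------------------------------
# read pairs


def _ref_mapper(deletions: tuple):
    """Edited-coordinate -> reference-coordinate machinery for deletions.

    Returns (junctions, cumdel): junction k is the last edited base before
    deleted reference material; a position e maps to e + cumdel[#junctions < e].
    """
    dels = sorted((d.start, d.end) for d in deletions)
    junctions, cum, removed = [], [0], 0
    for (s, e) in dels:
        junctions.append(s - 1 - removed)
        removed += e - s + 1
        cum.append(removed)
    return np.asarray(junctions), np.asarray(cum)


def simulate_read_pairs(
    sequence: str,
    config: SimConfig,
    rng: np.random.Generator,
    deletions: tuple = (),
    accession: str = "acc",
) -> pd.DataFrame:
    """Uniformly placed forward-reverse pairs with truncated-normal inserts.

    ``sequence`` is the accession (edited) sequence; emitted positions are
    REFERENCE coordinates, as after realignment: a pair spanning a deletion
    has its template length inflated by the deletion length.  Reads that
    would cross a deletion junction are dropped (alignment would clip them
    below a usable length).
    """
    Le = len(sequence)
    rl = config.read_length
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    if Le < config.insert_mean:
        raise ValueError("sequence shorter than the mean insert size")
    n_pairs = int(round(config.coverage * Le / (2 * rl)))
    frag = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
    lo = max(2 * rl, 1)
    bad = (frag < lo) | (frag > Le)
    while bad.any():  # truncated-normal resampling
        frag[bad] = rng.normal(config.insert_mean, config.insert_sd, size=int(bad.sum()))
        bad = (frag < lo) | (frag > Le)
    frag = frag.round().astype(np.int64)
    start = (rng.random(n_pairs) * (Le - frag + 1)).astype(np.int64) + 1

    l_start, l_end = start, start + rl - 1
    r_start, r_end = start + frag - rl, start + frag - 1

    junctions, cum = _ref_mapper(deletions)

    def to_ref(pos):
        return pos + cum[np.searchsorted(junctions, pos, side="left")]

    def crosses(a, b):  # read [a, b] spans a junction strictly inside
        return (
            np.searchsorted(junctions, b, side="left")
            - np.searchsorted(junctions, a, side="left")
        ) > 0

    keep = ~(crosses(l_start, l_end) | crosses(r_start, r_end))
    df = pd.DataFrame(
        {
            "accession": accession,
            "chrom": config.chrom,
            "left_pos": to_ref(l_start[keep]),
            "right_pos": to_ref(r_start[keep]),
            "orientation": "FR",
            "template_length": to_ref(r_end[keep]) - to_ref(l_start[keep]) + 1,
        }
    )
    return df


# ---------------------------------------------------------------------------
# neutral coalescent samples


def simulate_neutral_sample(
    n: int, theta: float, locus_length: int, seed: int
) -> popgen.SequenceMatrix:
    """Neutral infinite-sites coalescent sample of ``n`` haploid sequences.

    Hudson coalescent without recombination via msprime; mutations are
    placed on a continuous genome so every mutation hits a fresh site, at a
    total locus rate such that E[pairwise differences] = ``theta`` and
    E[S] = ``theta * a1(n)``.
    """
    import msprime

    if n < 2:
        raise ValueError("need n >= 2")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = np.random.default_rng(seed)
    ref = rng.choice(np.array(list("ACGT")), size=locus_length)
    data = np.repeat(ref[None, :], n, axis=0).astype("S1")
    if theta > 0:
        ts = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1.0,
            sequence_length=locus_length, random_seed=seed % (2**31) + 1,
        )
        mts = msprime.sim_mutations(
            ts, rate=theta / (2.0 * locus_length), random_seed=seed % (2**31) + 2,
            discrete_genome=False,
        )
        used: set[int] = set()
        for var in mts.variants():
            col = int(var.site.position)  # 0-based column
            while col in used:  # continuous positions: collisions only by rounding
                col = (col + 1) % locus_length
            used.add(col)
            alleles = np.array([a.encode() for a in var.alleles])
            data[:, col] = alleles[var.genotypes]
    labels = [f"hap{i:03d}" for i in range(n)]
    return popgen.SequenceMatrix(labels, data)


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(truth: TruthSet, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-accession plant heights ~ Normal(group mean, height_sd)."""
    rows = []
    for acc, label in truth.haplotypes.items():
        if label not in config.height_means:
            raise ValueError(f"no height mean configured for haplotype {label!r}")
        mean = config.height_means[label]
        rows.append(
            {
                "accession": acc,
                "haplotype": label,
                "height_cm": float(mean + config.height_sd * rng.standard_normal()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort


def _weighted_choice(rng, pool):
    names = [p[0] for p in pool]
    probs = np.array([p[1] for p in pool])
    return str(rng.choice(names, p=probs / probs.sum()))


@dataclass
class Cohort:
    """A simulated accession panel with recorded truth."""

    config: SimConfig
    reference: str
    gene_model: GeneModel
    definitions: DefinitionTable  # locus coordinates
    truth: TruthSet
    variants: list[VariantRecord]
    metadata: pd.DataFrame
    phenotypes: pd.DataFrame
    _pair_seeds: dict[str, int] = field(default_factory=dict)

    @property
    def accessions(self) -> list[str]:
        return list(self.truth.haplotypes)

    def sequence_of(self, accession: str) -> str:
        seq = list(self.reference)
        for e in sorted(self.truth.edits[accession], key=lambda e: -e.span[0]):
            if isinstance(e, Snp):
                seq[e.pos - 1] = e.alt
            elif isinstance(e, Deletion):
                del seq[e.start - 1 : e.end]
            else:
                seq[e.after_pos : e.after_pos] = list(e.bases)
        return "".join(seq)

    def aligned_sequence_of(self, accession: str) -> str:
        """Accession sequence padded with gaps at deletions (length L)."""
        seq = list(self.reference)
        for e in self.truth.edits[accession]:
            if isinstance(e, Snp):
                seq[e.pos - 1] = e.alt
            elif isinstance(e, Deletion):
                seq[e.start - 1 : e.end] = ["-"] * e.length
        return "".join(seq)

    def alignment(self) -> popgen.SequenceMatrix:
        return popgen.SequenceMatrix.from_strings(
            self.accessions, [self.aligned_sequence_of(a) for a in self.accessions]
        )

    def pairs_for(self, accession: str) -> pd.DataFrame:
        rng = np.random.default_rng(self._pair_seeds[accession])
        return simulate_read_pairs(
            self.sequence_of(accession),
            self.config,
            rng,
            deletions=self.truth.deletions.get(accession, ()),
            accession=accession,
        )

    def all_pairs(self) -> pd.DataFrame:
        return pd.concat([self.pairs_for(a) for a in self.accessions], ignore_index=True)

    # ---- output -------------------------------------------------------
    def write(self, out_dir: str) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        ref_fa = out / "reference.fasta"
        _write_fasta(ref_fa, [(self.config.chrom, self.reference)])
        paths["reference"] = str(ref_fa)

        acc_fa = out / "accessions.fasta"
        _write_fasta(acc_fa, [(a, self.sequence_of(a)) for a in self.accessions])
        paths["accessions"] = str(acc_fa)

        vcf = out / "cohort.vcf"
        write_vcf(str(vcf), self.variants, {self.config.chrom: self.config.locus_length})
        paths["vcf"] = str(vcf)

        pairs = out / "pairs.tsv"
        self.all_pairs().to_csv(pairs, sep="\t", index=False)
        paths["pairs"] = str(pairs)

        meta = out / "metadata.tsv"
        self.metadata.to_csv(meta, sep="\t", index=False)
        paths["metadata"] = str(meta)

        pheno = out / "phenotypes.tsv"
        self.phenotypes.to_csv(pheno, sep="\t", index=False)
        paths["phenotypes"] = str(pheno)

        gm = out / "gene_model.tsv"
        with open(gm, "w") as fh:
            fh.write("feature\tstart\tend\n")
            for i, (s, e) in enumerate(self.gene_model.exon_intervals, 1):
                fh.write(f"exon{i}\t{s}\t{e}\n")
        paths["gene_model"] = str(gm)
        return paths


def _write_fasta(path, records, width: int = 70):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_cohort(
    config: SimConfig | None = None,
    definitions: DefinitionTable | None = None,
    n_per_class: int = 10,
    n_heterozygous: int = 0,
) -> Cohort:
    """Build a cohort with ``n_per_class`` accessions per haplotype class.

    Heterozygous accessions (GR/EQ heterozygotes at the residue-100/340
    sites, truth label ``"heterozygous"``) are appended when requested.
    Deterministic under ``config.seed``.
    """
    config = config or SimConfig()
    defs = (definitions or load_definitions()).shifted(-CHR1_OFFSET)
    reference, model = make_reference(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    haplotypes: dict[str, int | str] = {}
    edits: dict[str, tuple] = {}
    deletions: dict[str, tuple] = {}
    variants_by_site: dict[tuple, VariantRecord] = {}
    meta_rows = []

    def add_genotype(rec_key, rec_proto: VariantRecord, sample, genotype):
        rec = variants_by_site.setdefault(rec_key, rec_proto)
        depth = max(1, int(rng.poisson(config.coverage)))
        if genotype == (1, 1):
            af = 1.0
        elif genotype == (0, 1):
            af = float(np.clip(rng.binomial(depth, 0.5) / depth, 0.05, 0.95))
        else:
            af = 0.0
        rec.calls[sample] = GenotypeCall(sample, genotype, depth=depth, alt_fraction=af)

    idx = 0
    classes: list[tuple[int | str, int]] = [(d.type_id, n_per_class) for d in sorted(defs, key=lambda d: d.type_id)]
    if n_heterozygous:
        classes.append(("heterozygous", n_heterozygous))

    for label, count in classes:
        for _ in range(count):
            idx += 1
            acc = f"ACC{idx:04d}"
            haplotypes[acc] = label
            if label == "heterozygous":
                site100, site340 = defs.combo_sites
                edits[acc] = ()
                deletions[acc] = ()
                for pos in (site100, site340):
                    proto = VariantRecord(
                        config.chrom, pos, reference[pos - 1], ["A"], {}
                    )
                    add_genotype((pos, "A"), proto, acc, (0, 1))
            else:
                hapdef = defs[label]
                _, acc_edits = apply_haplotype(reference, model, hapdef)
                edits[acc] = acc_edits
                deletions[acc] = tuple(e for e in acc_edits if isinstance(e, Deletion) and e.length > 20)
                for rec in truth_records(acc_edits, reference, config.chrom, acc):
                    key = (rec.pos, rec.alt[0])
                    proto = VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alt, {}, end=rec.end)
                    add_genotype(key, proto, acc, (1, 1))
            meta_rows.append(
                {
                    "accession": acc,
                    "subpopulation": _weighted_choice(rng, _SUBPOP_POOLS[label]),
                    "category": str(rng.choice(["landrace", "modern"])),
                }
            )

    # explicit hom-ref genotypes for non-carriers, as a joint caller emits;
    # sites falling inside an accession's own deletion stay missing (no reads)
    variants = sorted(variants_by_site.values(), key=lambda r: r.pos)
    for rec in variants:
        for acc in haplotypes:
            if acc in rec.calls:
                continue
            span_lo = rec.pos
            span_hi = rec.end if rec.end is not None else rec.pos + len(rec.ref) - 1
            in_del = any(
                d.start <= span_hi and span_lo <= d.end for d in deletions.get(acc, ())
            )
            if in_del:
                rec.calls[acc] = GenotypeCall(acc, (None, None), depth=0, alt_fraction=None)
            else:
                depth = max(1, int(rng.poisson(config.coverage)))
                rec.calls[acc] = GenotypeCall(acc, (0, 0), depth=depth, alt_fraction=0.0)
    truth = TruthSet(haplotypes, edits, deletions, group_means=dict(config.height_means))
    phenotypes = simulate_phenotypes(truth, config, rng)
    metadata = pd.DataFrame(meta_rows)

    pair_ss = np.random.SeedSequence([config.seed, 2])
    pair_seeds = {
        acc: int(s.generate_state(1)[0] % (2**31))
        for acc, s in zip(haplotypes, pair_ss.spawn(len(haplotypes)))
    }
    return Cohort(
        config=config,
        reference=reference,
        gene_model=model,
        definitions=defs,
        truth=truth,
        variants=variants,
        metadata=metadata,
        phenotypes=phenotypes,
        _pair_seeds=pair_seeds,
    )
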