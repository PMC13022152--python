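"""End-to-end orchestration: filter -> annotate -> detect -> classify ->
frequencies -> diversity windows -> phylogeny -> tandem repeats.

Every stage is a pure function of (inputs, config, seed); a run emits a
manifest recording the seed, thresholds and per-stage row counts so the
filtering accounting stays auditable.  A stage failure halts the run with
the stage name and cause; outputs of the failing stage keep a ``.partial``
suffix.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import GeneModel, annotate_variant
from .classify import classify_accession, load_definitions, tabulate_frequencies
from .deletions import calls_to_bed, detect_deletions, fit_insert_model, read_pairs_tsv
from .phylo import bootstrap_support, nj_tree, tn93_distance_matrix, vcf_to_seq_matrix
from .popgen import SequenceMatrix, WindowSpec, diversity_stats, tajima_d, window_scan
from .simulate import CHR1_OFFSET
from .trs import compare_trs, scan_trs
from .variant_io import FilterPolicy, read_metadata, read_vcf

__all__ = ["RunConfig", "StageError", "run_pipeline", "load_run_config"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    vcf: str
    pairs: str
    metadata: str
    reference: str
    out_dir: str
    definitions: str | None = None       # None = shipped Table-1 defaults
    gene_model: str | None = None        # TSV of exon intervals
    accessions: str | None = None        # FASTA of accession sequences (TR stage)
    coordinate_offset: int = -CHR1_OFFSET  # applied to definition coordinates
    seed: int = 0
    min_depth: int = 5
    min_alt_fraction: float = 0.8
    k_sigma: float = 4.0
    min_support: int = 3
    read_length: int = 100
    flanks: tuple[int, ...] = (1_000, 10_000)
    bootstrap: int = 200
    collapse_below: float = 60.0
    alpha: float = 0.05
    stages: tuple[str, ...] = (
        "filter", "annotate", "detect", "classify", "frequencies",
        "diversity", "phylogeny", "tandem_repeats",
    )

    def validate(self):
        for name in ("vcf", "pairs", "metadata", "reference"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if self.definitions and not Path(self.definitions).exists():
            raise FileNotFoundError(f"definitions file not found: {self.definitions}")


def load_run_config(path: str, out_dir: str | None = None) -> RunConfig:
    """Parse a plain-text ``key = value`` run configuration file."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        raw[key] = value
    kwargs: dict = {}
    for key, value in raw.items():
        if key in ("seed", "min_depth", "min_support", "read_length", "bootstrap", "coordinate_offset"):
            kwargs[key] = int(value)
        elif key in ("min_alt_fraction", "k_sigma", "collapse_below", "alpha"):
            kwargs[key] = float(value)
        elif key == "flanks":
            kwargs[key] = tuple(int(v) for v in value.split(","))
        elif key == "stages":
            kwargs[key] = tuple(v.strip() for v in value.split(","))
        else:
            kwargs[key] = value
    if out_dir is not None:
        kwargs["out_dir"] = out_dir
    return RunConfig(**kwargs)


def _read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def _read_gene_model_tsv(path: str, chrom: str) -> GeneModel:
    df = pd.read_csv(path, sep="\t")
    exons = [
        (int(r.start), int(r.end))
        for r in df.itertuples()
        if str(r.feature).startswith("exon")
    ]
    return GeneModel(chrom=chrom, exon_intervals=tuple(exons))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "sd1hap",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_depth": config.min_depth,
            "min_alt_fraction": config.min_alt_fraction,
            "k_sigma": config.k_sigma,
            "min_support": config.min_support,
            "flanks": list(config.flanks),
            "bootstrap": config.bootstrap,
            "collapse_below": config.collapse_below,
            "alpha": config.alpha,
        },
        "stages": {},
    }

    try:
        defs = load_definitions(config.definitions).shifted(config.coordinate_offset)
        records = read_vcf(config.vcf)
        pairs = read_pairs_tsv(config.pairs)
        metadata = read_metadata(config.metadata)
        reference = next(iter(_read_fasta(config.reference).values()))
        chrom = records[0].chrom if records else "chr01"
        model = (
            _read_gene_model_tsv(config.gene_model, chrom)
            if config.gene_model
            else None
        )
        samples = sorted(metadata["accession"])
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        raise StageError("load_inputs", exc) from exc

    state: dict = {"records": records}

    def stage(name):
        return name in config.stages

    def run_stage(name, fn):
        if not stage(name):
            return
        try:
            manifest["stages"][name] = fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage context
            raise StageError(name, exc) from exc

    # -- filter ---------------------------------------------------------
    def _filter():
        policy = FilterPolicy(config.min_depth, config.min_alt_fraction)
        filtered = [r for r in state["records"]]
        from .variant_io import filter_variants

        filtered = filter_variants(filtered, policy)
        state["records"] = filtered
        return {"input_sites": len(records), "surviving_sites": len(filtered)}

    run_stage("filter", _filter)

    # -- annotate -------------------------------------------------------
    def _annotate():
        if model is None:
            return {"skipped": "no gene model supplied"}
        rows = []
        for rec in state["records"]:
            ann = annotate_variant(rec, model, reference)
            rows.append(
                {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                 "alt": ",".join(rec.alt), "effect": ann.effect.value,
                 "detail": ann.detail, "ann": ann.to_ann()}
            )
        df = pd.DataFrame(rows)
        _emit(df, out / "annotations.tsv")
        return {"annotated": len(rows)}

    run_stage("annotate", _annotate)

    # -- detect ---------------------------------------------------------
    deletion_calls: dict[str, list] = {}

    def _detect():
        n_calls = 0
        bed_lines = []
        for acc, sub in pairs.groupby("accession"):
            model_ins = fit_insert_model(sub)
            calls = detect_deletions(
                sub, model_ins, min_support=config.min_support,
                k_sigma=config.k_sigma, read_length=config.read_length,
            )
            deletion_calls[acc] = calls
            n_calls += len(calls)
            for c in calls:
                bed_lines.append(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{acc};support={c.support}")
        _emit("\n".join(bed_lines) + ("\n" if bed_lines else ""), out / "deletions.bed")
        return {"accessions": int(pairs["accession"].nunique()), "calls": n_calls}

    run_stage("detect", _detect)

    # -- classify -------------------------------------------------------
    calls_list: list = []

    def _classify():
        for acc in samples:
            calls_list.append(
                classify_accession(
                    state["records"], deletion_calls.get(acc, []), defs, acc
                )
            )
        df = pd.DataFrame(
            [
                {"accession": c.accession, "haplotype": c.label,
                 "zygosity": c.zygosity, "evidence": ";".join(c.evidence)}
                for c in calls_list
            ]
        )
        _emit(df, out / "haplotype_calls.tsv")
        return {"classified": len(calls_list)}

    run_stage("classify", _classify)

    # -- frequencies ----------------------------------------------------
    def _frequencies():
        table = tabulate_frequencies(calls_list, metadata)
        _emit(table.counts, out / "frequencies_counts.tsv", index=True)
        _emit(table.percent, out / "frequencies_percent.tsv", index=True)
        return {"classes": int(table.counts.shape[0]), "excluded": len(table.excluded)}

    run_stage("frequencies", _frequencies)

    # -- diversity ------------------------------------------------------
    def _diversity():
        matrix = vcf_to_seq_matrix(state["records"], samples)
        if model is None or matrix.L == 0:
            return {"skipped": "no gene model or no SNP columns"}
        rows = []
        for flank in config.flanks:
            spec = WindowSpec(model.gene_start, model.gene_end, flank)
            st = window_scan(matrix, spec)
            td = tajima_d(st) if st.defined and st.S > 0 else None
            rows.append(
                {"flank": flank, "region_start": spec.region[0], "region_end": spec.region[1],
                 "n": st.n, "L_used": st.L_used, "S": st.S, "eta": st.eta, "k": round(st.k, 5),
                 "pi": round(st.pi, 6), "theta_per_seq": round(st.theta_per_seq, 5),
                 "theta_w_site": round(st.theta_w_site, 6),
                 "tajima_D": round(td.D, 5) if td and td.defined else "NA",
                 "p": round(td.p_value, 5) if td and td.defined else "NA"}
            )
        _emit(pd.DataFrame(rows), out / "diversity_windows.tsv")
        return {"windows": len(rows)}

    run_stage("diversity", _diversity)

    # -- phylogeny ------------------------------------------------------
    def _phylogeny():
        from .phylo import InestimableDistanceError, nj_tree as _nj, tn93_distance_matrix as _dist

        matrix = vcf_to_seq_matrix(state["records"], samples)
        if matrix.n < 3 or matrix.L < 2:
            return {"skipped": "not enough samples or SNP columns"}
        used_model = "tn93"
        try:
            tree = bootstrap_support(
                matrix, replicates=config.bootstrap, seed=config.seed,
                collapse_below=config.collapse_below,
            )
        except InestimableDistanceError:
            # sparse SNP-only matrices can saturate TN93; fall back to p-distance
            used_model = "p"
            tree = bootstrap_support(
                matrix,
                builder=lambda m: _nj(_dist(m, model="p")),
                replicates=config.bootstrap, seed=config.seed,
                collapse_below=config.collapse_below,
            )
        _emit(tree.to_newick(), out / "tree.nwk")
        return {"taxa": matrix.n, "snp_columns": int(matrix.L),
                "distance_model": used_model,
                "dropped_replicates": tree.dropped_replicates}

    run_stage("phylogeny", _phylogeny)

    # -- tandem repeats -------------------------------------------------
    def _tandem_repeats():
        ref_loci = scan_trs(reference)
        rows = []
        if config.accessions:
            acc_seqs = _read_fasta(config.accessions)
            for acc, seq in sorted(acc_seqs.items()):
                spans = [(c.start, c.end) for c in deletion_calls.get(acc, [])]
                comp = compare_trs(scan_trs(seq), ref_loci, deletions=spans)
                rows.append({"accession": acc, "gained": len(comp.gained),
                             "lost": len(comp.lost), "shared": comp.shared_count})
        _emit(pd.DataFrame(rows, columns=["accession", "gained", "lost", "shared"]),
              out / "tr_comparison.tsv")
        return {"reference_loci": len(ref_loci), "accessions_compared": len(rows)}

    run_stage("tandem_repeats", _tandem_repeats)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _emit(obj, path: Path, index: bool = False):
    """Write an output atomically; leave a .partial file on failure."""
    tmp = path.with_suffix(path.suffix + ".partial")
    try:
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(tmp, sep="\t", index=index)
        else:
            tmp.write_text(obj if isinstance(obj, str) else str(obj))
        tmp.rename(path)
    except Exception:
        print(f"partial output retained at {tmp}", file=sys.stderr)
        raise
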