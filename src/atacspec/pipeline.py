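"""End-to-end orchestration: consensus -> specificity -> motifs -> integration.

All stage functions operate on in-memory objects so the pipeline can run
either from files or directly from a synthetic bundle.  Every output table
is written with ``#`` header comments naming the parameter values that
produced it, and a JSON manifest records versions, the seed, all parameters
and per-stage row counts.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import consensus as cns
from . import integration as intg
from . import motifs as mtf
from . import specificity as spc
from .formats import (
    Peak,
    Pwm,
    TranscriptModel,
    read_fasta,
    read_gtf,
    read_homer_motifs,
    read_bed,
    read_matrix_tsv,
    read_narrowpeak,
    read_samples_tsv,
    write_bed,
    write_matrix_tsv,
)
from .synthio import SimBundle, SimConfig, generate_bundle

logger = logging.getLogger("atacspec")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the analysis, with its stated default."""

    flank: int = 75
    min_overlap: int = 2
    min_count: int = 10
    group_frac: float = 0.75
    min_total: int = 100
    h_max: float = 2.0
    r_min: float = 0.33
    motif_alpha: float = 0.001
    cis_alpha: float = 0.05
    promoter_window: int = 3000
    tss_window: tuple[int, int] = (-1000, 100)
    bg_ratio: int = 2
    gc_bin: float = 0.05
    expr_min: float = 1.0
    cv_mean_min: float = 20.0
    cv_top_k: int = 50
    seed: int = 7

    def comments(self) -> list[str]:
        return [f"{k}={v}" for k, v in asdict(self).items()]


@dataclass
class InputData:
    """Everything the pipeline consumes, already parsed."""

    samples: pd.DataFrame
    peaksets: dict[str, list[Peak]] | None = None
    fragments: dict[str, pd.DataFrame] | None = None
    counts: pd.DataFrame | None = None          # precomputed, skips build/count
    genome: Mapping[str, str] | None = None
    chrom_lens: Mapping[str, int] | None = None
    transcripts: Sequence[TranscriptModel] | None = None
    motif_library: Sequence[Pwm] | None = None
    expr: pd.DataFrame | None = None
    tf_gene_map: Mapping[str, str] | None = None

    @classmethod
    def from_bundle(cls, bundle: SimBundle) -> "InputData":
        genome = bundle.genome_strings()
        return cls(
            samples=bundle.samples,
            peaksets=bundle.peaksets,
            fragments=bundle.fragments,
            genome=genome,
            chrom_lens={c: len(s) for c, s in genome.items()},
            transcripts=bundle.transcripts,
            motif_library=bundle.motif_library,
            expr=bundle.expr,
            tf_gene_map=bundle.tf_gene_map,
        )

    @classmethod
    def from_files(
        cls,
        samples_tsv: str,
        peaks_dir: str | None = None,
        fragments_dir: str | None = None,
        counts_tsv: str | None = None,
        genome_fa: str | None = None,
        gtf: str | None = None,
        motifs_file: str | None = None,
        expr_tsv: str | None = None,
        tf_map_tsv: str | None = None,
    ) -> "InputData":
        samples = read_samples_tsv(samples_tsv)
        peaksets = fragments = None
        if peaks_dir is not None:
            peaksets = {
                s: read_narrowpeak(os.path.join(peaks_dir, f"{s}.narrowPeak"), s)
                for s in samples.index
            }
        if fragments_dir is not None:
            fragments = {
                s: read_bed(os.path.join(fragments_dir, f"{s}.fragments.bed"))
                for s in samples.index
            }
        counts = read_matrix_tsv(counts_tsv) if counts_tsv else None
        genome = read_fasta(genome_fa) if genome_fa else None
        tf_map = None
        if tf_map_tsv:
            tf_df = pd.read_csv(tf_map_tsv, sep="\t", comment="#")
            tf_map = dict(zip(tf_df.iloc[:, 0], tf_df.iloc[:, 1]))
        return cls(
            samples=samples,
            peaksets=peaksets,
            fragments=fragments,
            counts=counts,
            genome=genome,
            chrom_lens={c: len(s) for c, s in genome.items()} if genome else None,
            transcripts=read_gtf(gtf) if gtf else None,
            motif_library=read_homer_motifs(motifs_file) if motifs_file else None,
            expr=read_matrix_tsv(expr_tsv) if expr_tsv is not None else None,
            tf_gene_map=tf_map,
        )


@dataclass
class PipelineResult:
    regions: list[cns.ConsensusRegion] = field(default_factory=list)
    count_matrix: cns.CountMatrix | None = None
    rpm: pd.DataFrame | None = None
    spec_table: pd.DataFrame | None = None
    qc: spc.QcReport | None = None
    enrichment: pd.DataFrame | None = None
    p_matrix: pd.DataFrame | None = None
    unique_motifs: dict[str, list[str]] | None = None
    motif_upset: pd.DataFrame | None = None
    cv_table: pd.DataFrame | None = None
    cis_scored: pd.DataFrame | None = None
    cis_best: pd.DataFrame | None = None
    cis_counts: pd.Series | None = None
    cis_upset: pd.DataFrame | None = None
    tf_table: pd.DataFrame | None = None
    skipped_tfs: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_consensus(
    inputs: InputData, cfg: PipelineConfig
) -> tuple[list[cns.ConsensusRegion], cns.CountMatrix, pd.DataFrame]:
    """Build, count, filter and normalize the consensus region matrix."""
    if inputs.counts is not None:
        counts = inputs.counts
        regions = _regions_from_counts_index(counts)
        cm = cns.CountMatrix(
            counts=counts.astype(np.int64),
            samples=inputs.samples.loc[counts.columns],
            regions=regions,
        )
    else:
        if inputs.peaksets is None or inputs.fragments is None:
            raise ValueError(
                "need per-sample peaks and fragments (or a precomputed counts matrix)"
            )
        regions = cns.build_consensus(
            inputs.peaksets, flank=cfg.flank, min_overlap=cfg.min_overlap,
            chrom_lens=inputs.chrom_lens,
        )
        cm = cns.count_fragments(inputs.fragments, regions, inputs.samples)
    filtered = cns.filter_regions(
        cm, min_count=cfg.min_count, min_group_fraction=cfg.group_frac,
        min_total=cfg.min_total,
    )
    rpm = cns.rpm_normalize(filtered)
    return filtered.regions, filtered, rpm


def _regions_from_counts_index(counts: pd.DataFrame) -> list[cns.ConsensusRegion]:
    """Reconstruct minimal region records from ``chrom:start-end`` row IDs."""
    regions = []
    for rid in counts.index:
        try:
            chrom, span = str(rid).split(":")
            s, e = span.split("-")
            start, end = int(s), int(e)
        except ValueError:
            raise ValueError(
                f"precomputed counts need 'chrom:start-end' row IDs, got {rid!r}"
            ) from None
        regions.append(
            cns.ConsensusRegion(
                region_id=str(rid), chrom=chrom, start=start, end=end,
                consensus_summit=(start + end) // 2, n_support=0,
            )
        )
    return regions


def run_specificity(
    rpm: pd.DataFrame, inputs: InputData, cfg: PipelineConfig
) -> pd.DataFrame:
    return spc.score_specificity(
        rpm, inputs.samples["tissue"], h_max=cfg.h_max, r_min=cfg.r_min
    )


def run_qc(
    inputs: InputData,
    regions: Sequence[cns.ConsensusRegion],
    cm: cns.CountMatrix,
    rpm: pd.DataFrame,
    cfg: PipelineConfig,
) -> spc.QcReport:
    frip = None
    frag_hist = None
    if inputs.fragments is not None:
        totals = pd.Series({s: len(f) for s, f in inputs.fragments.items()})
        in_region = cm.counts.sum(axis=0)
        frip = spc.qc_frip(totals.loc[in_region.index], in_region)
        frag_hist = spc.fragment_length_histogram(inputs.fragments)
    tss_frac = float("nan")
    if inputs.transcripts:
        tss_frac = spc.tss_peak_fraction(
            list(regions), list(inputs.transcripts), window=cfg.tss_window
        )
    corr = spc.sample_correlation(rpm)
    return spc.QcReport(
        frip=frip if frip is not None else pd.Series(dtype=float),
        tss_peak_fraction=tss_frac,
        sample_correlation=corr,
        fragment_length_histogram=frag_hist,
    )


def run_motifs(
    inputs: InputData,
    regions: Sequence[cns.ConsensusRegion],
    spec_table: pd.DataFrame,
    cfg: PipelineConfig,
) -> dict:
    """Per-tissue known-motif enrichment of tissue-specific regions."""
    if inputs.genome is None or inputs.motif_library is None:
        raise ValueError("motif stage needs a genome FASTA and a motif library")
    genome = inputs.genome
    by_id = {r.region_id: r for r in regions}
    all_targets = [
        (by_id[rid].chrom, by_id[rid].start, by_id[rid].end)
        for rid in spec_table.index[spec_table["label"] != spc.UNCLASSIFIED]
    ]
    frames = []
    tissues = [t for t in dict.fromkeys(inputs.samples["tissue"])]
    for ti, tissue in enumerate(tissues):
        ids = spec_table.index[spec_table["label"] == tissue]
        if len(ids) == 0:
            logger.warning("no %s-specific regions; skipping motif stage there", tissue)
            continue
        coords = [(by_id[r].chrom, by_id[r].start, by_id[r].end) for r in ids]
        target_seqs = [genome[c][s:e] for c, s, e in coords]
        bg = mtf.sample_background(
            genome, coords, ratio=cfg.bg_ratio, gc_bin=cfg.gc_bin,
            exclude=all_targets, seed=cfg.seed + ti,
        )
        frames.append(
            mtf.enrich_tissue(
                target_seqs, list(bg["seq"]), list(inputs.motif_library),
                tissue=tissue, alpha=cfg.motif_alpha,
            )
        )
    records = pd.concat(frames, ignore_index=True)
    pmat = mtf.enrichment_matrix(records)
    unique, upset = mtf.unique_motifs(pmat, alpha=cfg.motif_alpha)
    scores = -np.log10(pmat.clip(lower=1e-300))
    cv = mtf.rank_by_cv(scores, mean_min=cfg.cv_mean_min, top_k=cfg.cv_top_k)
    return {
        "records": records, "p_matrix": pmat, "unique": unique,
        "upset": upset, "cv": cv,
    }


def run_integration(
    inputs: InputData,
    regions: Sequence[cns.ConsensusRegion],
    rpm: pd.DataFrame,
    unique: Mapping[str, list[str]] | None,
    cfg: PipelineConfig,
) -> dict:
    if inputs.expr is None or inputs.transcripts is None:
        raise ValueError("integration needs an expression matrix and a GTF")
    pairs = intg.map_promoter_pairs(
        list(regions), list(inputs.transcripts), window=cfg.promoter_window
    )
    scored = intg.score_cis_pairs(
        rpm, inputs.expr, pairs, inputs.samples["tissue"]
    )
    best, counts, upset = intg.best_positive_cis(scored, alpha=cfg.cis_alpha)

    tf_table, skipped = pd.DataFrame(), []
    if unique and inputs.motif_library is not None:
        tf_of = {m.name: m.tf_name for m in inputs.motif_library}
        rows = [
            {"motif": m, "tf_name": tf_of.get(m, m), "tissue": t}
            for t, ms in unique.items()
            for m in ms
        ]
        if rows:
            tf_table, skipped = intg.tf_support(
                pd.DataFrame(rows), inputs.expr, inputs.samples["tissue"],
                tf_gene_map=inputs.tf_gene_map, expr_min=cfg.expr_min,
                alpha=cfg.cis_alpha,
            )
    return {
        "scored": scored, "best": best, "counts": counts, "upset": upset,
        "tf_table": tf_table, "skipped": skipped,
    }


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def run_all(
    inputs: InputData,
    cfg: PipelineConfig | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    """Run every applicable stage; write outputs and a manifest if requested."""
    cfg = cfg or PipelineConfig()
    result = PipelineResult()
    manifest: dict = {
        "package": "atacspec",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "parameters": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in asdict(cfg).items()},
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    t0 = stage("consensus")
    try:
        regions, cm, rpm = run_consensus(inputs, cfg)
    except Exception as exc:
        raise RuntimeError(f"stage consensus failed: {exc}") from exc
    result.regions, result.count_matrix, result.rpm = regions, cm, rpm
    manifest["stages"]["consensus"] = {
        "regions": len(regions), "samples": cm.counts.shape[1],
        "seconds": round(time.perf_counter() - t0, 2),
    }

    t0 = stage("specificity")
    try:
        spec_table = run_specificity(rpm, inputs, cfg)
        result.qc = run_qc(inputs, regions, cm, rpm, cfg)
    except Exception as exc:
        raise RuntimeError(f"stage specificity failed: {exc}") from exc
    result.spec_table = spec_table
    n_specific = int((spec_table["label"] != spc.UNCLASSIFIED).sum())
    manifest["stages"]["specificity"] = {
        "regions": len(spec_table), "tissue_specific": n_specific,
        "seconds": round(time.perf_counter() - t0, 2),
    }

    if inputs.genome is not None and inputs.motif_library is not None:
        t0 = stage("motifs")
        try:
            m = run_motifs(inputs, regions, spec_table, cfg)
        except Exception as exc:
            raise RuntimeError(f"stage motifs failed: {exc}") from exc
        result.enrichment = m["records"]
        result.p_matrix = m["p_matrix"]
        result.unique_motifs = m["unique"]
        result.motif_upset = m["upset"]
        result.cv_table = m["cv"]
        manifest["stages"]["motifs"] = {
            "tests": len(m["records"]),
            "significant": int(m["records"]["significant"].sum()),
            "seconds": round(time.perf_counter() - t0, 2),
        }

    if inputs.expr is not None and inputs.transcripts is not None:
        t0 = stage("integration")
        try:
            it = run_integration(
                inputs, regions, rpm, result.unique_motifs, cfg
            )
        except Exception as exc:
            raise RuntimeError(f"stage integration failed: {exc}") from exc
        result.cis_scored = it["scored"]
        result.cis_best = it["best"]
        result.cis_counts = it["counts"]
        result.cis_upset = it["upset"]
        result.tf_table = it["tf_table"]
        result.skipped_tfs = it["skipped"]
        manifest["stages"]["integration"] = {
            "pairs_tested": len(it["scored"]),
            "cis_pairs": len(it["best"]),
            "seconds": round(time.perf_counter() - t0, 2),
        }

    result.manifest = manifest
    if out_dir is not None:
        write_outputs(result, cfg, out_dir)
    return result


def write_outputs(result: PipelineResult, cfg: PipelineConfig, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    com = cfg.comments()
    join = lambda name: os.path.join(out_dir, name)  # noqa: E731

    write_bed(cns.regions_to_bed(result.regions), join("consensus.bed"))
    write_matrix_tsv(result.count_matrix.counts, join("counts.tsv"), com)
    write_matrix_tsv(result.rpm, join("rpm.tsv"), com)
    write_matrix_tsv(result.spec_table, join("specificity.tsv"), com)
    if result.spec_table is not None:
        dist = spc.entropy_distribution(result.spec_table["H"])
        write_matrix_tsv(dist, join("entropy_distribution.tsv"), com)
    if result.qc is not None:
        qc_df = pd.DataFrame({"frip": result.qc.frip})
        qc_df.attrs["tss_peak_fraction"] = result.qc.tss_peak_fraction
        write_matrix_tsv(
            qc_df, join("qc.tsv"),
            com + [f"tss_peak_fraction_pct={result.qc.tss_peak_fraction:.3f}"],
        )
        write_matrix_tsv(result.qc.sample_correlation, join("sample_correlation.tsv"), com)
    if result.enrichment is not None:
        write_matrix_tsv(result.enrichment.set_index("motif"), join("enrichment.tsv"), com)
        write_matrix_tsv(result.p_matrix, join("motif_p_matrix.tsv"), com)
        write_matrix_tsv(result.motif_upset, join("motif_upset.tsv"), com)
        write_matrix_tsv(result.cv_table, join("motif_cv_ranking.tsv"), com)
        uniq = pd.DataFrame(
            [(t, m) for t, ms in result.unique_motifs.items() for m in ms],
            columns=["tissue", "motif"],
        )
        write_matrix_tsv(uniq.set_index("tissue"), join("unique_motifs.tsv"), com)
    if result.cis_best is not None:
        write_matrix_tsv(result.cis_best.set_index("gene_id"), join("cis_pairs.tsv"), com)
        write_matrix_tsv(result.cis_counts.to_frame(), join("cis_counts.tsv"), com)
        write_matrix_tsv(result.cis_upset, join("cis_upset.tsv"), com)
        if result.tf_table is not None and len(result.tf_table):
            write_matrix_tsv(result.tf_table.set_index("motif"), join("tf_support.tsv"), com)
    with open(join("manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


def simulate_and_run(
    sim: SimConfig | None = None,
    cfg: PipelineConfig | None = None,
    out_dir: str | None = None,
) -> tuple[SimBundle, PipelineResult]:
    """Generate a synthetic bundle and run the full pipeline on it."""
    sim = sim or SimConfig(seed=(cfg.seed if cfg else 7))
    bundle = generate_bundle(sim)
    result = run_all(InputData.from_bundle(bundle), cfg, out_dir)
    return bundle, result
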