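"""Deterministic synthetic-data generator with known ground truth.

Emulates a 6-tissue x 8-replicate bulk ATAC-seq + RNA-seq design: a random
genome with annotated transcripts, a set of accessible loci (shared plus
per-tissue-specific ones), negative-binomial fragment counts whose tissue
allocation plants a target relative accessibility, motif consensi written
into specific loci, and an expression matrix with planted promoter
accessibility-expression correlations.  Every pipeline input format can be
emitted, and a truth table records the planted label, motif and correlation
of every locus and gene for recovery testing.

Counts are drawn per locus and sample from a negative binomial with
variance mu + dispersion * mu^2 (the convention of bulk RNA/ATAC count
models, where sqrt(dispersion) is the biological coefficient of variation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import motifs as motifs_mod
from .formats import (
    Peak,
    Pwm,
    TranscriptModel,
    write_bed,
    write_fasta,
    write_gtf,
    write_homer_motifs,
    write_matrix_tsv,
    write_narrowpeak,
)

logger = logging.getLogger(__name__)

DEFAULT_TISSUES = ("Amy", "Hip", "HT", "Tal", "AG", "PG")

# one 10-mer consensus per default tissue; pairwise distinct, also under
# reverse complement, so exact planted instances cannot cross-match
PLANTED_CONSENSI = {
    "Amy": "TGACGTCATC",
    "Hip": "CACGTGTTAC",
    "HT": "GGGATTACAG",
    "Tal": "CCGGAAGTAT",
    "AG": "GATAAGGCTC",
    "PG": "GGAACCAATG",
}

PEAK_EMIT_MIN = 5          # a sample reports a narrowPeak at a locus iff count >= 5
FRAGMENT_LEN = 150
SUMMIT_JITTER = 10         # per-sample summit wobble, bp
LOCUS_MARGIN = 160         # min distance of summits from slot/chromosome edges
SHARED_MOTIF_RATE = 0.02   # background planting rate in shared loci
PROMOTER_TARGET_FRACTION = 0.30

_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic bundle."""

    seed: int = 7
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    replicates: int = 8
    n_chrom: int = 2
    chrom_len: int = 1_000_000
    gc: float = 0.42
    n_shared: int = 3000
    n_specific: int = 100          # per tissue
    specificity_fraction: float = 0.6
    nb_mean: float = 50.0          # expected reads per locus per sample
    nb_dispersion: float = 0.2
    planted_motifs: Mapping[str, str] | None = None
    motif_plant_rate: float = 0.8
    n_genes: int = 500
    rho_pos: float = 0.9
    frac_corr_genes: float = 0.3

    def __post_init__(self) -> None:
        if len(self.tissues) < 2:
            raise ValueError("need at least two tissues")
        if self.specificity_fraction <= 1.0 / len(self.tissues):
            raise ValueError(
                "specificity_fraction must exceed 1/n_tissues to plant a signal"
            )
        if not (0 < self.motif_plant_rate <= 1):
            raise ValueError("motif_plant_rate must be in (0, 1]")
        for name in ("replicates", "n_chrom", "chrom_len", "n_shared",
                     "n_specific"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")
        if self.planted_motifs is None:
            consensi = {}
            rng = _stage_rng(self.seed, 9)
            for t in self.tissues:
                consensi[t] = PLANTED_CONSENSI.get(
                    t, "".join("ACGT"[i] for i in rng.integers(0, 4, 10))
                )
            self.planted_motifs = consensi

    @property
    def n_loci(self) -> int:
        return self.n_shared + len(self.tissues) * self.n_specific

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


@dataclass
class SimBundle:
    """All generated inputs plus the ground truth."""

    cfg: SimConfig
    genome: dict[str, bytearray]
    transcripts: list[TranscriptModel]
    samples: pd.DataFrame
    peaksets: dict[str, list[Peak]]
    fragments: dict[str, pd.DataFrame]
    locus_counts: pd.DataFrame
    truth_regions: pd.DataFrame
    expr: pd.DataFrame
    truth_genes: pd.DataFrame
    tf_gene_map: dict[str, str]
    motif_library: list[Pwm]

    def genome_strings(self) -> dict[str, str]:
        return {c: bytes(s).decode("ascii") for c, s in self.genome.items()}

    @property
    def chrom_lens(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    # one independent stream per generation stage, derived from the one seed
    return np.random.default_rng((seed * 7919 + stage) % (2 ** 31 - 1))


def _split_evenly(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


# ---------------------------------------------------------------------------
# Stage 1: genome + annotation
# ---------------------------------------------------------------------------

def generate_genome(cfg: SimConfig) -> tuple[dict[str, bytearray], list[TranscriptModel]]:
    """Random genome at the configured GC plus non-overlapping gene models.

    Bases are i.i.d.; each transcript occupies its own slot of the
    chromosome (so spans never overlap), has a random strand, a span of
    1-3 kb, and 2-5 exons.  Deterministic per seed.
    """
    rng = _stage_rng(cfg.seed, 0)
    p = np.array([(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2])
    genome = {
        name: bytearray(_LUT[rng.choice(4, size=cfg.chrom_len, p=p)].tobytes())
        for name in cfg.chrom_names
    }

    transcripts: list[TranscriptModel] = []
    per_chrom = _split_evenly(cfg.n_genes, cfg.n_chrom)
    idx = 0
    span_max = 3000
    for chrom, n_here in zip(cfg.chrom_names, per_chrom):
        if n_here == 0:
            continue
        slot = cfg.chrom_len // n_here
        if slot < span_max + 200:
            raise ValueError(
                "chromosomes too short to place genes without overlap; "
                "increase chrom_len or reduce n_genes"
            )
        for k in range(n_here):
            span = int(rng.integers(1000, span_max + 1))
            lo = k * slot + 50
            hi = (k + 1) * slot - span - 50
            start = int(rng.integers(lo, hi + 1))
            end = start + span
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _random_exons(rng, start, end)
            biotype = rng.choice(
                ["protein_coding", "lncRNA", "other"], p=[0.8, 0.15, 0.05]
            )
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"tx{idx:04d}",
                    gene_id=f"gene{idx:04d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    biotype=str(biotype),
                    exons=exons,
                )
            )
            idx += 1
    return genome, transcripts


def _random_exons(rng: np.random.Generator, start: int, end: int,
                  min_seg: int = 30) -> tuple[tuple[int, int], ...]:
    span = end - start
    n_exons = int(rng.integers(2, 6))
    n_cuts = 2 * n_exons - 2
    for _ in range(100):
        cuts = np.sort(rng.choice(np.arange(1, span), size=n_cuts, replace=False))
        segs = np.diff(np.concatenate([[0], cuts, [span]]))
        if (segs >= min_seg).all():
            break
    else:  # fall back to even segmentation
        cuts = np.linspace(0, span, n_cuts + 2).astype(int)[1:-1]
    bounds = np.concatenate([[0], cuts, [span]]) + start
    return tuple(
        (int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)
    )


# ---------------------------------------------------------------------------
# Stage 2: loci, counts, peaks, fragments
# ---------------------------------------------------------------------------

def generate_peaks_and_counts(
    cfg: SimConfig,
    genome: Mapping[str, bytearray],
    transcripts: Sequence[TranscriptModel],
    flank: int = 75,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[Peak]],
           dict[str, pd.DataFrame], pd.DataFrame]:
    """Place loci, draw counts, and emit per-sample peak calls and fragments.

    Returns ``(truth_regions, samples, peaksets, fragments, locus_counts)``.
    Specific loci allocate expected accessibility share f to their target
    tissue and (1-f)/(N-1) to each other tissue; shared loci are uniform.
    About 30% of shared loci are pulled next to a TSS so the integration
    stage has promoter regions to work with.  A sample reports a narrowPeak
    at a locus iff its count is >= 5, with a +-10 bp summit wobble;
    fragments are 150 bp intervals centered on the locus summit, one per
    count.
    """
    rng = _stage_rng(cfg.seed, 1)
    tissues = list(cfg.tissues)
    T, R = len(tissues), cfg.replicates

    # --- placement: jittered grid, summits >= 2*LOCUS_MARGIN apart ---------
    per_chrom = _split_evenly(cfg.n_loci, cfg.n_chrom)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for t in transcripts:
        tss_by_chrom.setdefault(t.chrom, [])
    for t in transcripts:
        tss_by_chrom[t.chrom].append(t.tss)
    tss_by_chrom = {c: np.sort(v) for c, v in tss_by_chrom.items()}

    chroms: list[str] = []
    summits: list[int] = []
    slot_ranges: list[tuple[int, int]] = []
    for chrom, n_here in zip(cfg.chrom_names, per_chrom):
        if n_here == 0:
            continue
        slot = cfg.chrom_len // n_here
        if slot < 2 * LOCUS_MARGIN + 10:
            raise ValueError(
                "chromosomes too short for the requested locus count; "
                "increase chrom_len or reduce n_shared/n_specific"
            )
        for k in range(n_here):
            lo = k * slot + LOCUS_MARGIN
            hi = (k + 1) * slot - LOCUS_MARGIN
            chroms.append(chrom)
            summits.append(int(rng.integers(lo, hi)))
            slot_ranges.append((lo, hi))

    n = cfg.n_loci
    labels = np.array(
        ["shared"] * cfg.n_shared
        + [t for t in tissues for _ in range(cfg.n_specific)],
        dtype=object,
    )
    labels = labels[rng.permutation(n)]

    # pull a fraction of shared loci next to a TSS (promoter exercise)
    promoter_targeted = np.zeros(n, dtype=bool)
    shared_idx = np.flatnonzero(labels == "shared")
    want = rng.random(len(shared_idx)) < PROMOTER_TARGET_FRACTION
    for i in shared_idx[want]:
        chrom = chroms[i]
        lo, hi = slot_ranges[i]
        tss = tss_by_chrom.get(chrom, np.array([], dtype=int))
        cand = tss[(tss >= lo - 2000) & (tss <= hi + 2000)]
        if len(cand) == 0:
            continue
        t0 = int(cand[rng.integers(0, len(cand))])
        summits[i] = int(np.clip(t0 + rng.integers(-2000, 2001), lo, hi - 1))
        promoter_targeted[i] = True

    # --- counts ------------------------------------------------------------
    shares = np.full((n, T), 1.0 / T)
    for ti, t in enumerate(tissues):
        mask = labels == t
        shares[mask] = (1.0 - cfg.specificity_fraction) / (T - 1)
        shares[mask, ti] = cfg.specificity_fraction
    mu = cfg.nb_mean * T * shares  # (n, T)

    sample_ids = [f"{t}_r{j + 1}" for t in tissues for j in range(R)]
    samples = pd.DataFrame(
        {
            "tissue": [t for t in tissues for _ in range(R)],
            "replicate": [j + 1 for _ in tissues for j in range(R)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    counts = np.empty((n, T * R), dtype=np.int64)
    for ti in range(T):
        m = np.repeat(mu[:, ti][:, None], R, axis=1)
        if cfg.nb_dispersion > 0:
            size = 1.0 / cfg.nb_dispersion
            counts[:, ti * R:(ti + 1) * R] = rng.negative_binomial(
                size, size / (size + m)
            )
        else:
            counts[:, ti * R:(ti + 1) * R] = rng.poisson(m)

    locus_ids = [f"locus{i:05d}" for i in range(n)]
    locus_counts = pd.DataFrame(counts, index=locus_ids, columns=sample_ids)

    # --- per-sample peaks and fragments -------------------------------------
    summit_arr = np.asarray(summits)
    chrom_arr = np.asarray(chroms, dtype=object)
    peaksets: dict[str, list[Peak]] = {}
    fragments: dict[str, pd.DataFrame] = {}
    for s, sample_id in enumerate(sample_ids):
        c = counts[:, s]
        jitter = rng.integers(-SUMMIT_JITTER, SUMMIT_JITTER + 1, size=n)
        js = summit_arr + jitter
        sel = np.flatnonzero(c >= PEAK_EMIT_MIN)
        peaks = [
            Peak(
                chrom=chrom_arr[i],
                start=int(js[i] - 100),
                end=int(js[i] + 100),
                name=f"{sample_id}_peak{i}",
                score=float(min(1000, c[i])),
                strand=".",
                signal=float(c[i]) / 10.0,
                pvalue_nlog10=4.0,
                qvalue_nlog10=2.0,
                summit_offset=100,
                sample_id=sample_id,
            )
            for i in sel
        ]
        peaksets[sample_id] = peaks
        starts = np.repeat(summit_arr - FRAGMENT_LEN // 2, c)
        fragments[sample_id] = pd.DataFrame(
            {
                "chrom": np.repeat(chrom_arr, c),
                "start": starts,
                "end": starts + FRAGMENT_LEN,
            }
        )

    truth_regions = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "chrom": chrom_arr,
            "start": summit_arr - flank,
            "end": summit_arr + flank + 1,
            "summit": summit_arr,
            "label": labels,
            "motif": "",
            "promoter_targeted": promoter_targeted,
        }
    ).set_index("locus_id")
    return truth_regions, samples, peaksets, fragments, locus_counts


# ---------------------------------------------------------------------------
# Stage 3: motif planting
# ---------------------------------------------------------------------------

def planted_motif_library(cfg: SimConfig) -> list[Pwm]:
    """One sharp PWM per tissue built from its planted consensus.

    Matching bases carry probability 0.97; the scanning threshold is 80% of
    the maximal attainable log2-odds score versus a uniform background,
    which at these matrix sharpnesses admits only exact consensus matches.
    """
    library = []
    for tissue in cfg.tissues:
        consensus = cfg.planted_motifs[tissue]
        L = len(consensus)
        probs = np.full((4, L), 0.01)
        for j, b in enumerate(consensus):
            probs["ACGT".index(b), j] = 0.97
        pwm = Pwm(
            name=f"{tissue}-planted",
            tf_name=f"TF{tissue}",
            probs=probs,
            log_odds_threshold=0.0,
        )
        thr = motifs_mod.default_threshold(pwm)
        library.append(
            Pwm(name=pwm.name, tf_name=pwm.tf_name, probs=probs,
                log_odds_threshold=round(thr, 2))
        )
    return library


def plant_motifs(
    cfg: SimConfig,
    genome: dict[str, bytearray],
    truth_regions: pd.DataFrame,
) -> pd.DataFrame:
    """Write motif consensi into specific loci (in place); returns new truth.

    Each tissue's consensus is planted, on a random strand at a random
    offset within +-40 bp of the summit, into ``motif_plant_rate`` of that
    tissue's specific loci; shared loci receive any tissue's motif at a 2%
    background rate.
    """
    rng = _stage_rng(cfg.seed, 2)
    truth = truth_regions.copy()
    planted_col = truth["motif"].copy()
    for locus_id, row in truth.iterrows():
        label = row["label"]
        here: list[str] = []
        for tissue in cfg.tissues:
            if label == tissue:
                rate = cfg.motif_plant_rate
            elif label == "shared":
                rate = SHARED_MOTIF_RATE
            else:
                continue
            if rng.random() >= rate:
                continue
            consensus = cfg.planted_motifs[tissue]
            L = len(consensus)
            if L > row["end"] - row["start"]:
                raise ValueError(
                    f"motif for {tissue} is longer than the region width"
                )
            pos = int(row["summit"] + rng.integers(-40, 41 - L))
            seq = consensus if rng.random() < 0.5 else _revcomp(consensus)
            genome[row["chrom"]][pos:pos + L] = seq.encode("ascii")
            here.append(f"{tissue}-planted")
        planted_col[locus_id] = ",".join(here)
    truth["motif"] = planted_col
    return truth


# ---------------------------------------------------------------------------
# Stage 4: expression
# ---------------------------------------------------------------------------

def generate_expression(
    cfg: SimConfig,
    truth_regions: pd.DataFrame,
    locus_counts: pd.DataFrame,
    samples: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    promoter_window: int = 3000,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Expression matrix with planted within-tissue promoter correlations.

    For a fraction of genes that own a promoter locus, expression follows
    the locus RPM plus Gaussian noise calibrated so the within-tissue
    correlation is ``rho_pos`` in expectation.  One extra gene per tissue
    becomes that tissue's planted-motif TF, expressed high there and near
    zero elsewhere.  All remaining genes are independent log-normal noise.
    Returns ``(expr, truth_genes, tf_gene_map)``.
    """
    rng = _stage_rng(cfg.seed, 3)
    rpm = locus_counts / locus_counts.sum(axis=0) * 1e6
    tissues = list(cfg.tissues)
    sample_ids = list(samples.index)
    tissue_of = samples["tissue"]

    summits = {
        chrom: grp.sort_values("summit")
        for chrom, grp in truth_regions.reset_index().groupby("chrom")
    }
    gene_locus: dict[str, str] = {}
    for t in transcripts:
        grp = summits.get(t.chrom)
        if grp is None:
            continue
        pos = grp["summit"].to_numpy()
        lo = np.searchsorted(pos, t.tss - promoter_window, side="left")
        hi = np.searchsorted(pos, t.tss + promoter_window, side="right")
        if hi > lo:
            cand = grp.iloc[lo:hi]
            nearest = (cand["summit"] - t.tss).abs().idxmin()
            gene_locus[t.gene_id] = cand.loc[nearest, "locus_id"]

    all_genes = [t.gene_id for t in transcripts]
    eligible = [g for g in all_genes if g in gene_locus]
    n_corr = int(round(cfg.frac_corr_genes * cfg.n_genes))
    if len(eligible) < n_corr:
        logger.info(
            "only %d of %d requested correlated genes have a promoter locus",
            len(eligible), n_corr,
        )
    chosen = list(
        rng.choice(eligible, size=min(n_corr, len(eligible)), replace=False)
    )
    chosen_set = set(chosen)

    tf_candidates = [g for g in all_genes if g not in chosen_set]
    tf_genes = tf_candidates[-len(tissues):]
    tf_gene_map = {f"TF{t}": g for t, g in zip(tissues, tf_genes)}
    tf_tissue_of = {g: t for t, g in zip(tissues, tf_genes)}

    expr = pd.DataFrame(
        index=pd.Index(all_genes, name="gene_id"), columns=sample_ids, dtype=float
    )
    rho = cfg.rho_pos
    rows = []
    for gene in all_genes:
        if gene in chosen_set:
            locus = gene_locus[gene]
            x = rpm.loc[locus]
            scale = 30.0 / max(x.mean(), 1e-9)
            vals = np.empty(len(sample_ids))
            for t in tissues:
                cols = [i for i, s in enumerate(sample_ids) if tissue_of[s] == t]
                xt = x.iloc[cols].to_numpy(dtype=float)
                sd = xt.std(ddof=1)
                if rho >= 1.0:
                    noise = np.zeros(len(cols))
                else:
                    sd_e = scale * sd * np.sqrt(1.0 / rho ** 2 - 1.0)
                    noise = rng.normal(0.0, sd_e, size=len(cols))
                vals[cols] = scale * xt + noise + 5.0
            expr.loc[gene] = vals
            rows.append((gene, rho, locus, False, ""))
        elif gene in tf_tissue_of:
            own = tf_tissue_of[gene]
            vals = np.empty(len(sample_ids))
            for i, s in enumerate(sample_ids):
                if tissue_of[s] == own:
                    vals[i] = rng.normal(50.0, 2.0)
                else:
                    vals[i] = max(0.0, rng.normal(1.0, 0.2))
            expr.loc[gene] = vals
            rows.append((gene, 0.0, "", True, own))
        else:
            expr.loc[gene] = rng.lognormal(3.0, 0.7, size=len(sample_ids))
            rows.append((gene, 0.0, gene_locus.get(gene, ""), False, ""))

    truth_genes = pd.DataFrame(
        rows, columns=["gene_id", "rho", "linked_locus", "is_tf_gene", "tf_tissue"]
    ).set_index("gene_id")
    return expr, truth_genes, tf_gene_map


# ---------------------------------------------------------------------------
# Bundle orchestration and file output
# ---------------------------------------------------------------------------

def generate_bundle(cfg: SimConfig | None = None) -> SimBundle:
    """Run all generation stages and return the in-memory bundle."""
    cfg = cfg or SimConfig()
    genome, transcripts = generate_genome(cfg)
    truth_regions, samples, peaksets, fragments, locus_counts = (
        generate_peaks_and_counts(cfg, genome, transcripts)
    )
    truth_regions = plant_motifs(cfg, genome, truth_regions)
    expr, truth_genes, tf_gene_map = generate_expression(
        cfg, truth_regions, locus_counts, samples, transcripts
    )
    return SimBundle(
        cfg=cfg,
        genome=genome,
        transcripts=transcripts,
        samples=samples,
        peaksets=peaksets,
        fragments=fragments,
        locus_counts=locus_counts,
        truth_regions=truth_regions,
        expr=expr,
        truth_genes=truth_genes,
        tf_gene_map=tf_gene_map,
        motif_library=planted_motif_library(cfg),
    )


def write_bundle(bundle: SimBundle, out_dir) -> None:
    """Write every pipeline input file for the bundle into ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    join = lambda name: os.path.join(out_dir, name)  # noqa: E731

    write_fasta(bundle.genome_strings(), join("genome.fa"))
    write_gtf(bundle.transcripts, join("anno.gtf"))
    bundle.samples.to_csv(join("samples.tsv"), sep="\t")
    for sample_id, peaks in bundle.peaksets.items():
        write_narrowpeak(peaks, join(f"{sample_id}.narrowPeak"))
    for sample_id, frag in bundle.fragments.items():
        frag.to_csv(join(f"{sample_id}.fragments.bed"), sep="\t",
                    header=False, index=False)
    write_matrix_tsv(bundle.expr, join("expr.tsv"))
    write_matrix_tsv(bundle.locus_counts, join("truth_locus_counts.tsv"))
    bundle.truth_regions.to_csv(join("truth_regions.tsv"), sep="\t")
    bundle.truth_genes.to_csv(join("truth_genes.tsv"), sep="\t")
    write_homer_motifs(bundle.motif_library, join("planted.motifs"))
    write_bed(
        [
            (row["chrom"], row["start"], row["end"], locus_id)
            for locus_id, row in bundle.truth_regions.iterrows()
        ],
        join("truth_regions.bed"),
    )
    pd.Series(bundle.tf_gene_map, name="gene_id").rename_axis("tf_name").to_csv(
        join("tf_gene_map.tsv"), sep="\t"
    )
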