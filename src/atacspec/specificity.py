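"""Shannon-entropy tissue-specificity scoring and library QC metrics.

For each region, per-tissue accessibility E_i is the mean RPM over that
tissue's replicates.  Relative accessibility is R_i = E_i / sum(E), and the
specificity index is the Shannon entropy H = -sum(R_i * log2 R_i), which
ranges from 0 (all signal in one tissue) to log2(N) (uniform over the N
tissues).  A region is called tissue-specific when H < h_max (default 2 bits,
strict) and max(R_i) >= r_min (default 0.33, inclusive); the label is the
argmax tissue, ties broken by the configured tissue order.

The module also houses the per-sample QC statistics reported alongside such
an analysis: FRiP, the percentage of peaks near a TSS, replicate correlation
on log10 RPM, and genomic-context annotation of regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .consensus import ConsensusRegion
from .formats import TranscriptModel

DEFAULT_H_MAX = 2.0
DEFAULT_R_MIN = 0.33
UNCLASSIFIED = "none"

TSS_COUNT_WINDOW = (-1000, 100)  # peak-at-TSS QC window, strand-oriented
PROMOTER_UPSTREAM = 3000


def tissue_profile(
    rpm: pd.DataFrame,
    sample_tissues: Mapping[str, str] | pd.Series,
    tissue_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean RPM per tissue (columns) for each region (rows)."""
    tissues = pd.Series(dict(sample_tissues) if not isinstance(sample_tissues, pd.Series)
                        else sample_tissues)
    unknown = [s for s in rpm.columns if s not in tissues.index]
    if unknown:
        raise ValueError(f"samples without tissue label: {unknown}")
    tissues = tissues.loc[rpm.columns]
    if tissue_order is None:
        tissue_order = list(dict.fromkeys(tissues))
    extra = set(tissues) - set(tissue_order)
    if extra:
        raise ValueError(f"unknown tissue labels: {sorted(extra)}")
    profile = pd.DataFrame(index=rpm.index, columns=list(tissue_order), dtype=float)
    for t in tissue_order:
        cols = tissues.index[tissues == t]
        if len(cols) == 0:
            raise ValueError(f"tissue {t!r} has no samples")
        profile[t] = rpm[cols].mean(axis=1)
    return profile


def relative_accessibility(E: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """R_i = E_i / sum(E) per region; all-zero rows stay all-zero."""
    arr = np.asarray(E, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if (arr < 0).any():
        raise ValueError("accessibility values must be non-negative")
    totals = arr.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(totals > 0, arr / np.where(totals > 0, totals, 1.0), 0.0)
    if isinstance(E, pd.DataFrame):
        return pd.DataFrame(R, index=E.index, columns=E.columns)
    return R[0] if squeeze else R


def entropy(R: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray | float:
    """Shannon entropy in bits of each relative-accessibility vector.

    ``0 * log2(0)`` is taken as 0.  All-zero rows (unclassifiable regions)
    yield NaN.  Rows whose sum deviates from 1 by more than 1e-6 are rejected.
    """
    arr = np.asarray(R, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if (arr < 0).any():
        raise ValueError("relative accessibilities must be non-negative")
    sums = arr.sum(axis=1)
    zero = sums == 0
    if (np.abs(sums[~zero] - 1.0) > 1e-6).any():
        bad = float(sums[~zero][np.abs(sums[~zero] - 1.0).argmax()])
        raise ValueError(f"relative accessibilities must sum to 1 (got {bad})")
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(arr > 0, arr * np.log2(np.where(arr > 0, arr, 1.0)), 0.0)
    H = -terms.sum(axis=1) + 0.0  # +0.0 normalizes the one-hot case's -0.0
    H[zero] = np.nan
    if isinstance(R, pd.DataFrame):
        return pd.Series(H, index=R.index, name="H")
    return float(H[0]) if squeeze else H


def classify(
    E: pd.DataFrame,
    h_max: float = DEFAULT_H_MAX,
    r_min: float = DEFAULT_R_MIN,
) -> pd.DataFrame:
    """Score and label regions from their per-tissue accessibility profile.

    Returns a table with E_<tissue>, R_<tissue>, H and label columns.  A
    region is labeled with its argmax tissue iff H < h_max (strict) and
    max(R_i) >= r_min (inclusive); otherwise (or when sum(E) = 0, H = NaN)
    the label is ``"none"``.  Argmax ties break toward the earlier tissue in
    column order.
    """
    tissues = list(E.columns)
    R = relative_accessibility(E)
    H = entropy(R)
    Rarr = R.to_numpy()
    argmax = Rarr.argmax(axis=1)  # first occurrence wins ties
    rmax = Rarr[np.arange(len(Rarr)), argmax]
    labels = np.array(
        [tissues[i] for i in argmax], dtype=object
    )
    ok = (H.to_numpy() < h_max) & (rmax >= r_min) & ~np.isnan(H.to_numpy())
    labels[~ok] = UNCLASSIFIED

    out = pd.concat(
        [E.add_prefix("E_"), R.add_prefix("R_")], axis=1
    )
    out["H"] = H
    out["label"] = labels
    return out


def score_specificity(
    rpm: pd.DataFrame,
    sample_tissues: Mapping[str, str] | pd.Series,
    h_max: float = DEFAULT_H_MAX,
    r_min: float = DEFAULT_R_MIN,
    tissue_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: RPM matrix -> labeled specificity table."""
    E = tissue_profile(rpm, sample_tissues, tissue_order)
    return classify(E, h_max=h_max, r_min=r_min)


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Per-sample and cross-sample library quality metrics."""

    frip: pd.Series
    tss_peak_fraction: float
    sample_correlation: pd.DataFrame
    fragment_length_histogram: pd.Series | None = None
    tss_enrichment: pd.Series | None = None


def qc_frip(
    fragment_totals: pd.Series,
    in_region_totals: pd.Series,
) -> pd.Series:
    """Fraction of fragments falling in consensus regions, per sample."""
    totals = fragment_totals.astype(float)
    inside = in_region_totals.astype(float).reindex(totals.index)
    if (totals <= 0).any():
        raise ValueError("fragment totals must be positive")
    if (inside > totals).any():
        bad = inside.index[inside > totals][0]
        raise ValueError(f"sample {bad!r}: in-region count exceeds total")
    return (inside / totals).rename("frip")


def _tss_windows(
    transcripts: Sequence[TranscriptModel],
    window: tuple[int, int],
) -> dict[str, IntervalTree]:
    """Strand-oriented closed windows around each TSS, as interval trees."""
    lo, hi = window
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        if t.strand == "+":
            a, b = t.tss + lo, t.tss + hi
        else:
            a, b = t.tss - hi, t.tss - lo
        trees.setdefault(t.chrom, IntervalTree()).addi(a, b + 1, t.transcript_id)
    return trees


def tss_peak_fraction(
    regions: Sequence[ConsensusRegion],
    transcripts: Sequence[TranscriptModel],
    window: tuple[int, int] = TSS_COUNT_WINDOW,
) -> float:
    """Percentage of regions whose summit lies in the TSS window.

    The window (default -1000..+100) is oriented by transcript strand and
    inclusive at both ends.
    """
    if not regions:
        raise ValueError("empty region set")
    trees = _tss_windows(transcripts, window)
    n = sum(
        1
        for r in regions
        if r.chrom in trees and trees[r.chrom].overlaps_point(r.consensus_summit)
    )
    return 100.0 * n / len(regions)


def sample_correlation(rpm: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """Pearson correlation between samples on log10(RPM + pseudo).

    Zero-variance samples yield NaN rows/columns (correlation undefined).
    """
    if rpm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    logged = np.log10(rpm + pseudo)
    return logged.corr(method="pearson")


def genomic_context(
    regions: Sequence[ConsensusRegion],
    transcripts: Sequence[TranscriptModel],
    promoter_up: int = PROMOTER_UPSTREAM,
) -> pd.Series:
    """Assign each region midpoint a promoter/exon/intron/other label.

    Promoter is the strand-oriented window from ``promoter_up`` bp upstream of
    the TSS to the TSS itself; intron means inside a transcript span but not
    in an exon.  A midpoint hitting several annotations takes the
    highest-precedence label (promoter > exon > intron > other).
    """
    promoters: dict[str, IntervalTree] = {}
    exons: dict[str, IntervalTree] = {}
    spans: dict[str, IntervalTree] = {}
    for t in transcripts:
        if t.strand == "+":
            pa, pb = t.tss - promoter_up, t.tss + 1
        else:
            pa, pb = t.tss, t.tss + promoter_up + 1
        promoters.setdefault(t.chrom, IntervalTree()).addi(pa, pb)
        spans.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end)
        for s, e in t.exons:
            exons.setdefault(t.chrom, IntervalTree()).addi(s, e)

    labels = []
    for r in regions:
        mid = r.midpoint
        if r.chrom in promoters and promoters[r.chrom].overlaps_point(mid):
            labels.append("promoter")
        elif r.chrom in exons and exons[r.chrom].overlaps_point(mid):
            labels.append("exon")
        elif r.chrom in spans and spans[r.chrom].overlaps_point(mid):
            labels.append("intron")
        else:
            labels.append("other")
    return pd.Series(labels, index=[r.region_id for r in regions], name="context")


def fragment_length_histogram(fragments: Mapping[str, pd.DataFrame]) -> pd.Series:
    """Pooled histogram of fragment lengths across samples (counts per bp)."""
    lengths = pd.concat(
        [df["end"] - df["start"] for df in fragments.values()],
        ignore_index=True,
    )
    return lengths.value_counts().sort_index().rename("count")


def entropy_distribution(H: pd.Series, bins: int = 50) -> pd.DataFrame:
    """Histogram of entropy scores (the specificity distribution curve)."""
    valid = H.dropna()
    counts, edges = np.histogram(valid, bins=bins, range=(0, np.ceil(valid.max())))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
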