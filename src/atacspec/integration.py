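"""Cis correlation of promoter accessibility with gene expression.

Consensus regions whose midpoint lies within +-3 kb of a transcript's TSS
are paired with that transcript.  Within each tissue, the Pearson
correlation between the region's RPM and the gene's expression is computed
across that tissue's replicates; pairs with r > 0 and p < alpha are cis
candidates, and each gene keeps only its highest-r pair per tissue.  A
second filter asks, for each tissue-uniquely enriched motif, whether the
corresponding transcription factor is expressed in that tissue and
significantly higher there than in every other tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusRegion
from .formats import TranscriptModel

DEFAULT_PROMOTER_WINDOW = 3000
DEFAULT_CIS_ALPHA = 0.05
DEFAULT_EXPR_MIN = 1.0


def map_promoter_pairs(
    regions: Sequence[ConsensusRegion],
    transcripts: Sequence[TranscriptModel],
    window: int = DEFAULT_PROMOTER_WINDOW,
) -> pd.DataFrame:
    """Pair regions with transcripts whose TSS is within the promoter window.

    A pair is emitted iff the region midpoint lies in
    ``[tss - window, tss + window]`` (inclusive both ends; the +- window is
    strand-agnostic).  Regions and transcripts may each appear in many pairs.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append((r.midpoint, r.region_id))
    for chrom in by_chrom:
        by_chrom[chrom].sort()

    rows = []
    for t in transcripts:
        if t.chrom not in by_chrom:
            continue
        mids = by_chrom[t.chrom]
        positions = [m for m, _ in mids]
        lo = np.searchsorted(positions, t.tss - window, side="left")
        hi = np.searchsorted(positions, t.tss + window, side="right")
        for m, rid in mids[lo:hi]:
            rows.append((rid, t.transcript_id, t.gene_id, m - t.tss))
    return pd.DataFrame(
        rows, columns=["region_id", "transcript_id", "gene_id", "distance"]
    )


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t test.

    ``p`` comes from ``t = r * sqrt(n-2) / sqrt(1-r^2)`` against the t
    distribution with n-2 degrees of freedom; ``r = +-1`` reports p = 0.
    Zero variance in either vector gives ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx ** 2).sum() * (dy ** 2).sum())
    if denom == 0:
        return (float("nan"), float("nan"))
    r = float(np.clip(dx @ dy / denom, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-14:
        return (r, 0.0)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return (r, float(p))


def min_significant_r(n: int, alpha: float = DEFAULT_CIS_ALPHA) -> float:
    """Smallest |r| reaching two-sided significance at sample size n."""
    tcrit = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(tcrit / np.sqrt(n - 2 + tcrit ** 2))


def score_cis_pairs(
    rpm: pd.DataFrame,
    expr: pd.DataFrame,
    pairs: pd.DataFrame,
    sample_tissues: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Per-tissue Pearson r/p for every promoter pair, across replicates.

    ``rpm`` is regions x samples, ``expr`` genes x samples; only samples
    present in both matrices are used, grouped by tissue.  Pairs whose region
    or gene is absent from the matrices are skipped; zero-variance pairs get
    NaN r and p.
    """
    tissues = pd.Series(dict(sample_tissues) if not isinstance(sample_tissues, pd.Series)
                        else sample_tissues)
    shared = [s for s in rpm.columns if s in expr.columns]
    if not shared:
        raise ValueError("RPM and expression matrices share no samples")
    tissues = tissues.loc[shared]

    usable = pairs[
        pairs["region_id"].isin(rpm.index) & pairs["gene_id"].isin(expr.index)
    ].reset_index(drop=True)

    frames = []
    for tissue, cols in tissues.groupby(tissues).groups.items():
        cols = list(cols)
        n = len(cols)
        if n < 3:
            continue
        X = rpm.loc[usable["region_id"], cols].to_numpy(dtype=float)
        Y = expr.loc[usable["gene_id"], cols].to_numpy(dtype=float)
        dx = X - X.mean(axis=1, keepdims=True)
        dy = Y - Y.mean(axis=1, keepdims=True)
        denom = np.sqrt((dx ** 2).sum(axis=1) * (dy ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.clip((dx * dy).sum(axis=1) / denom, -1.0, 1.0)
        r[denom == 0] = np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.abs(r) >= 1.0 - 1e-14] = 0.0
        out = usable.copy()
        out["tissue"] = tissue
        out["r"] = r
        out["p"] = p
        out["n"] = n
        frames.append(out)
    if not frames:
        raise ValueError("no tissue has >= 3 samples shared between matrices")
    return pd.concat(frames, ignore_index=True)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-aware)."""
    q = np.full_like(p, np.nan, dtype=float)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[mask] = out
    return q


def best_positive_cis(
    scored_pairs: pd.DataFrame,
    alpha: float = DEFAULT_CIS_ALPHA,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Select each gene's best positive cis pair per tissue.

    Keeps pairs with r > 0 and p < alpha, then retains the max-r pair per
    (gene, tissue).  Returns (best_pairs, per-tissue gene counts, UpSet
    table of tissue-set intersection counts over genes).  A BH-adjusted
    ``q`` column (within tissue, over all tested pairs) is carried along for
    reference; the selection itself uses the raw p.
    """
    scored = scored_pairs.copy()
    scored["q"] = np.nan
    for tissue, idx in scored.groupby("tissue").groups.items():
        scored.loc[idx, "q"] = _bh_adjust(scored.loc[idx, "p"].to_numpy())

    qual = scored[(scored["r"] > 0) & (scored["p"] < alpha)].copy()
    qual = qual.sort_values("r", ascending=False, kind="stable")
    best = qual.drop_duplicates(subset=["gene_id", "tissue"], keep="first")
    best = best.sort_values(["tissue", "gene_id"]).reset_index(drop=True)

    counts = best.groupby("tissue")["gene_id"].nunique()
    counts = counts.rename("n_genes")

    tissues = sorted(scored["tissue"].unique())
    gene_sets = {
        t: set(best.loc[best["tissue"] == t, "gene_id"]) for t in tissues
    }
    membership: dict[tuple[bool, ...], int] = {}
    for gene in set(best["gene_id"]):
        key = tuple(gene in gene_sets[t] for t in tissues)
        membership[key] = membership.get(key, 0) + 1
    combos = []
    for mask in range(1, 2 ** len(tissues)):
        key = tuple(bool(mask & (1 << i)) for i in range(len(tissues)))
        combos.append(dict(zip(tissues, key), count=membership.get(key, 0)))
    upset = pd.DataFrame(combos).sort_values(
        "count", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return best, counts, upset


# ---------------------------------------------------------------------------
# TF expression support for tissue-unique motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TfSupportRecord:
    motif: str
    tf_name: str
    tf_gene: str
    tissue: str
    expressed: bool
    tissue_specific_expression: bool


def tf_support(
    unique_motif_records: pd.DataFrame,
    expr: pd.DataFrame,
    sample_tissues: Mapping[str, str] | pd.Series,
    tf_gene_map: Mapping[str, str] | None = None,
    expr_min: float = DEFAULT_EXPR_MIN,
    alpha: float = DEFAULT_CIS_ALPHA,
) -> tuple[pd.DataFrame, list[str]]:
    """Expression support for tissue-uniquely enriched motifs.

    ``unique_motif_records`` needs columns motif, tf_name, tissue.  A TF is
    ``expressed`` when its mean expression in the motif's tissue is >=
    ``expr_min``; it has ``tissue_specific_expression`` when additionally its
    mean there is the maximum over tissues and a one-sided Welch t test
    rejects at ``alpha`` against every other tissue.  TF names that map to no
    gene in the matrix are returned in the skipped list, not an error.
    """
    tissues = pd.Series(dict(sample_tissues) if not isinstance(sample_tissues, pd.Series)
                        else sample_tissues)
    tissues = tissues.loc[[s for s in expr.columns if s in tissues.index]]
    lower_index = {str(g).lower(): g for g in expr.index}
    tf_gene_map = dict(tf_gene_map or {})

    rows = []
    skipped: list[str] = []
    for rec in unique_motif_records.itertuples(index=False):
        gene = tf_gene_map.get(rec.tf_name)
        if gene is None:
            gene = lower_index.get(rec.tf_name.lower())
        if gene is None or gene not in expr.index:
            skipped.append(rec.tf_name)
            continue
        values = expr.loc[gene, tissues.index]
        means = values.groupby(tissues).mean()
        own = values[tissues.index[tissues == rec.tissue]].to_numpy(dtype=float)
        expressed = bool(means.get(rec.tissue, 0.0) >= expr_min)
        specific = expressed and means.idxmax() == rec.tissue
        if specific:
            for other in means.index:
                if other == rec.tissue:
                    continue
                theirs = values[tissues.index[tissues == other]].to_numpy(dtype=float)
                res = stats.ttest_ind(own, theirs, equal_var=False,
                                      alternative="greater")
                if not (res.pvalue < alpha):
                    specific = False
                    break
        row = {
            "motif": rec.motif,
            "tf_name": rec.tf_name,
            "tf_gene": gene,
            "tissue": rec.tissue,
            "expressed": expressed,
            "tissue_specific_expression": specific,
        }
        for t, m in means.items():
            row[f"mean_{t}"] = m
        rows.append(row)
    return pd.DataFrame(rows), skipped
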