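"""Known-motif enrichment in tissue-specific regions.

PWM occurrences are called by log-odds scanning of both strands; enrichment
of each motif in a tissue's specific regions is tested against GC-matched
background windows drawn from the same genome with a hypergeometric tail
test (the statistic behind HOMER's known-motif mode).  Reporting layers
mirror the usual practice: a motif x tissue p-value matrix, per-tissue sets
of uniquely significant motifs with all set-intersection (UpSet) counts, and
a coefficient-of-variation ranking of -log10(p) scores across tissues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .formats import Pwm

DEFAULT_ALPHA = 0.001
DEFAULT_BG_RATIO = 2
DEFAULT_GC_BIN = 0.05
N_SCORE = -10.0  # bits contributed by an N base at any motif position
PROB_FLOOR = 1e-3
FOLD_CAP = 1e6  # sentinel for infinite fold (no background occurrences)

_UNIFORM_BG = np.full(4, 0.25)

# base -> code lookup; A,C,G,T -> 0..3, N -> 4, anything else -> 255
_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
    _CODES[_b + 32] = _i
_CODES[ord("N")] = 4
_CODES[ord("n")] = 4


@dataclass(frozen=True)
class MotifHit:
    """One PWM occurrence; position is the forward-strand leftmost base."""

    seq_id: str
    position: int
    strand: str
    score: float


def encode_sequence(seq: str) -> np.ndarray:
    """Map an A/C/G/T/N string to integer codes 0-4."""
    codes = _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"sequence contains invalid base {bad!r}")
    return codes


def log_odds(pwm: Pwm, background: np.ndarray | None = None) -> np.ndarray:
    """Per-base, per-position log2-odds scores, shape (5, length).

    Probabilities are floored at 1e-3 before the ratio so that zero entries
    stay finite; row 4 is the fixed N-base penalty.
    """
    bg = _UNIFORM_BG if background is None else np.asarray(background, float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background must be 4 frequencies summing to 1")
    if (bg <= 0).any():
        raise ValueError("background frequencies must all be positive")
    scores = np.empty((5, pwm.length))
    scores[:4] = np.log2(np.maximum(pwm.probs, PROB_FLOOR) / bg[:, None])
    scores[4] = N_SCORE
    return scores


def max_score(pwm: Pwm, background: np.ndarray | None = None) -> float:
    """Best attainable log-odds score of the motif."""
    return float(log_odds(pwm, background)[:4].max(axis=0).sum())


def default_threshold(pwm: Pwm, background: np.ndarray | None = None,
                      fraction: float = 0.8) -> float:
    """Fallback scanning threshold: 80% of the maximal attainable score."""
    return fraction * max_score(pwm, background)


def _window_scores(codes: np.ndarray, sm: np.ndarray) -> np.ndarray:
    L = sm.shape[1]
    W = len(codes) - L + 1
    scores = np.zeros(W)
    for j in range(L):
        scores += sm[codes[j:j + W], j]
    return scores


def scan(seq: str, pwm: Pwm, background: np.ndarray | None = None,
         seq_id: str = "", threshold: float | None = None) -> list[MotifHit]:
    """Find motif occurrences on both strands of a sequence.

    The reverse strand is scored by scanning the reverse complement with the
    same matrix; reported positions are always forward-strand leftmost.
    Windows with total score >= the motif's threshold are reported.  A
    sequence shorter than the motif yields an empty list.
    """
    n, L = len(seq), pwm.length
    if n < L:
        return []
    if threshold is None:
        threshold = pwm.log_odds_threshold
    sm = log_odds(pwm, background)
    codes = encode_sequence(seq)
    hits: list[MotifHit] = []

    fwd = _window_scores(codes, sm)
    for pos in np.flatnonzero(fwd >= threshold):
        hits.append(MotifHit(seq_id, int(pos), "+", float(fwd[pos])))

    rc = np.where(codes == 4, 4, 3 - codes)[::-1]
    rev = _window_scores(rc, sm)
    for pos in np.flatnonzero(rev >= threshold):
        hits.append(MotifHit(seq_id, int(n - L - pos), "-", float(rev[pos])))

    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def has_hit(seq: str, pwm: Pwm, background: np.ndarray | None = None,
            threshold: float | None = None) -> bool:
    """Whether a sequence contains at least one occurrence (either strand)."""
    n, L = len(seq), pwm.length
    if n < L:
        return False
    if threshold is None:
        threshold = pwm.log_odds_threshold
    sm = log_odds(pwm, background)
    codes = encode_sequence(seq)
    if (_window_scores(codes, sm) >= threshold).any():
        return True
    rc = np.where(codes == 4, 4, 3 - codes)[::-1]
    return bool((_window_scores(rc, sm) >= threshold).any())


# ---------------------------------------------------------------------------
# GC-matched background sampling
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    codes = encode_sequence(seq)
    return float(((codes == 1) | (codes == 2)).mean())


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` slots proportionally with largest-remainder rounding."""
    if weights.sum() == 0:
        return np.zeros_like(weights, dtype=int)
    quotas = weights / weights.sum() * total
    floors = np.floor(quotas).astype(int)
    remainder = total - floors.sum()
    order = np.argsort(-(quotas - floors))
    floors[order[:remainder]] += 1
    return floors


def sample_background(
    genome: Mapping[str, str],
    target_regions: Sequence[tuple[str, int, int]],
    ratio: int = DEFAULT_BG_RATIO,
    gc_bin: float = DEFAULT_GC_BIN,
    exclude: Sequence[tuple[str, int, int]] | None = None,
    seed: int = 0,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Draw GC- and length-matched background windows from the genome.

    Returns ``ratio * len(target_regions)`` non-overlapping windows (also
    avoiding ``exclude``, default the targets themselves) whose per-bin GC
    histogram matches the targets' (bin width ``gc_bin``, counts apportioned
    by largest remainder).  Deterministic given ``seed``.  If a bin cannot be
    filled after ``max_tries`` draws per window, a warning is issued and the
    shortfall is filled from the nearest available GC bin.
    """
    rng = np.random.default_rng(seed)
    if not target_regions:
        raise ValueError("no target regions")
    target_seqs = [genome[c][s:e] for c, s, e in target_regions]
    target_gc = np.array([gc_content(s) for s in target_seqs])
    bins = np.minimum((target_gc / gc_bin).astype(int), int(1 / gc_bin) - 1)
    n_bins = int(np.ceil(1 / gc_bin))
    bin_counts = np.bincount(bins, minlength=n_bins)
    quotas = _largest_remainder(bin_counts.astype(float), ratio * len(target_regions))

    occupied: dict[str, IntervalTree] = {}
    for c, s, e in list(exclude if exclude is not None else target_regions):
        occupied.setdefault(c, IntervalTree()).addi(s, e)

    chroms = list(genome)
    chrom_lens = np.array([len(genome[c]) for c in chroms], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    lengths_by_bin = {
        b: [e - s for (c, s, e), tb in zip(target_regions, bins) if tb == b]
        for b in range(n_bins)
    }
    reservoir: dict[int, list[tuple[str, int, int, str]]] = {b: [] for b in range(n_bins)}
    rows: list[tuple[str, int, int, str]] = []

    def claim(chrom: str, start: int, end: int) -> bool:
        tree = occupied.setdefault(chrom, IntervalTree())
        if tree.overlaps(start, end):
            return False
        tree.addi(start, end)
        return True

    for b in range(n_bins):
        need = int(quotas[b])
        if need == 0:
            continue
        lengths = lengths_by_bin[b]
        got = 0
        tries = 0
        while got < need and tries < max_tries * need:
            tries += 1
            length = lengths[got % len(lengths)]
            ci = rng.choice(len(chroms), p=chrom_p)
            chrom = chroms[ci]
            if len(genome[chrom]) < length:
                continue
            start = int(rng.integers(0, len(genome[chrom]) - length + 1))
            end = start + length
            if occupied.get(chrom, IntervalTree()).overlaps(start, end):
                continue
            seq = genome[chrom][start:end]
            if "N" in seq:
                continue
            wb = min(int(gc_content(seq) / gc_bin), n_bins - 1)
            if wb == b:
                occupied.setdefault(chrom, IntervalTree()).addi(start, end)
                rows.append((chrom, start, end, seq))
                got += 1
            else:
                reservoir[wb].append((chrom, start, end, seq))
        if got < need:
            warnings.warn(
                f"GC bin {b * gc_bin:.2f}-{(b + 1) * gc_bin:.2f}: sampled "
                f"{got}/{need} windows; filling from nearest bins"
            )
            for dist in range(1, n_bins):
                for nb in (b - dist, b + dist):
                    if not (0 <= nb < n_bins):
                        continue
                    while got < need and reservoir[nb]:
                        chrom, start, end, seq = reservoir[nb].pop()
                        if claim(chrom, start, end):
                            rows.append((chrom, start, end, seq))
                            got += 1
                if got >= need:
                    break
            if got < need:
                raise ValueError(
                    "genome too small to supply the requested background windows"
                )

    return pd.DataFrame(rows, columns=["chrom", "start", "end", "seq"])


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_tail(k: int, K: int, n: int, M: int) -> float:
    """Upper tail P(X >= k) of Hypergeometric(M, K, n), in log space.

    ``M`` sequences total, ``K`` of them motif-positive, ``n`` drawn (the
    target set), ``k`` motif-positive among the drawn.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= M and 0 <= n <= M):
        raise ValueError(
            f"inconsistent counts k={k}, K={K}, n={n}, M={M}"
        )
    if k == 0:
        return 1.0
    ks = np.arange(k, min(K, n) + 1)
    logp = hypergeom.logpmf(ks, M, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def enrich_tissue(
    target_seqs: Sequence[str],
    background_seqs: Sequence[str],
    motif_library: Sequence[Pwm],
    tissue: str = "",
    alpha: float = DEFAULT_ALPHA,
    background_freqs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Hypergeometric known-motif enrichment of targets vs. background.

    For each motif, k is the number of sequences containing at least one
    occurrence (both strands pooled; a sequence counts once).  The population
    is the union of target and background sets.  Fold enrichment is
    (k_t/n_t)/(k_b/n_b), capped at ``FOLD_CAP`` when the background has no
    occurrences.
    """
    if not target_seqs or not background_seqs:
        raise ValueError("target and background sets must be non-empty")
    n_t, n_b = len(target_seqs), len(background_seqs)
    rows = []
    for pwm in motif_library:
        thr = pwm.log_odds_threshold
        if thr <= 0:
            thr = default_threshold(pwm, background_freqs)
        k_t = sum(has_hit(s, pwm, background_freqs, thr) for s in target_seqs)
        k_b = sum(has_hit(s, pwm, background_freqs, thr) for s in background_seqs)
        p = hypergeom_tail(k_t, k_t + k_b, n_t, n_t + n_b)
        if k_b > 0:
            fold = (k_t / n_t) / (k_b / n_b)
        else:
            fold = 0.0 if k_t == 0 else FOLD_CAP
        rows.append(
            (pwm.name, tissue, n_t, k_t, n_b, k_b, p, fold, p < alpha)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "motif", "tissue", "n_target", "k_target",
            "n_background", "k_background", "p", "fold", "significant",
        ],
    )


def enrichment_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format enrichment records into a motif x tissue p matrix."""
    return records.pivot(index="motif", columns="tissue", values="p")


def unique_motifs(
    p_matrix: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Per-tissue uniquely significant motifs plus all intersection counts.

    Returns (unique, upset): ``unique`` maps each tissue to the motifs
    significant in that tissue only; ``upset`` has one row per non-empty
    tissue combination (2^N - 1 rows) with boolean membership columns and the
    count of motifs significant in exactly that combination.
    """
    sig = (p_matrix < alpha).fillna(False)
    tissues = list(p_matrix.columns)
    unique: dict[str, list[str]] = {t: [] for t in tissues}
    membership: dict[tuple[bool, ...], int] = {}
    for motif, row in sig.iterrows():
        key = tuple(bool(v) for v in row)
        if not any(key):
            continue
        membership[key] = membership.get(key, 0) + 1
        if sum(key) == 1:
            unique[tissues[key.index(True)]].append(motif)

    combos = []
    for mask in range(1, 2 ** len(tissues)):
        key = tuple(bool(mask & (1 << i)) for i in range(len(tissues)))
        combos.append(dict(zip(tissues, key), count=membership.get(key, 0)))
    upset = pd.DataFrame(combos)
    upset = upset.sort_values("count", ascending=False, kind="stable").reset_index(drop=True)
    for t in unique:
        unique[t].sort()
    return unique, upset


def rank_by_cv(
    score_matrix: pd.DataFrame,
    mean_min: float = 20.0,
    top_k: int = 50,
) -> pd.DataFrame:
    """Rank motifs by coefficient of variation of their enrichment scores.

    ``score_matrix`` holds -log10(p) per motif and tissue.  Motifs with mean
    score > ``mean_min`` are ranked by CV = sd/mean, descending; the top
    ``top_k`` are returned (all survivors, with a warning, if fewer).
    """
    means = score_matrix.mean(axis=1)
    sds = score_matrix.std(axis=1, ddof=1)
    kept = score_matrix.index[means > mean_min]
    if len(kept) < top_k:
        warnings.warn(
            f"only {len(kept)} motifs exceed mean score {mean_min}; "
            f"returning all of them"
        )
    cv = (sds[kept] / means[kept]).rename("cv")
    out = pd.DataFrame({"mean_score": means[kept], "cv": cv})
    out = out.sort_values("cv", ascending=False, kind="stable")
    return out.head(top_k)
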