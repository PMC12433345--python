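"""Shared fixtures: synthetic bundles, pipeline runs, and oracle helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from atacspec.consensus import ConsensusRegion
from atacspec.pipeline import InputData, PipelineConfig, run_all
from atacspec.synthio import SimConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """The full-scale study design: 6 tissues x 8 replicates, 3600 loci."""
    return generate_bundle(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return run_all(InputData.from_bundle(default_bundle), PipelineConfig(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    """A scaled-down bundle for fast structural tests."""
    cfg = SimConfig(
        seed=11, n_shared=300, n_specific=20, n_genes=100, chrom_len=400_000
    )
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    return run_all(
        InputData.from_bundle(small_bundle), PipelineConfig(seed=11)
    )


# ---------------------------------------------------------------------------
# Oracle helpers (kept independent of the implementation paths they check)
# ---------------------------------------------------------------------------

def brute_force_scan(seq: str, pwm, background=None, threshold=None):
    """Naive per-window PWM scorer over both strands.

    Returns a set of (position, strand, rounded score) triples; positions are
    forward-strand leftmost.
    """
    bg = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    if background is not None:
        bg = dict(zip("ACGT", background))
    if threshold is None:
        threshold = pwm.log_odds_threshold
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    L = pwm.length
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def score_window(window: str) -> float:
        total = 0.0
        for j, b in enumerate(window):
            if b == "N":
                total += -10.0
            else:
                p = max(pwm.probs[base_idx[b], j], 1e-3)
                total += np.log2(p / bg[b])
        return total

    hits = set()
    for pos in range(len(seq) - L + 1):
        s = score_window(seq[pos:pos + L])
        if s >= threshold:
            hits.add((pos, "+", round(s, 9)))
        rc = "".join(comp[b] for b in reversed(seq[pos:pos + L]))
        s = score_window(rc)
        if s >= threshold:
            hits.add((pos, "-", round(s, 9)))
    return hits


def match_regions_to_truth(regions, truth: pd.DataFrame,
                           min_overlap_frac: float = 0.5) -> dict[str, str]:
    """One-to-one map truth locus_id -> region_id by >=50% overlap.

    Regions are disjoint by construction, so containing the truth summit and
    overlapping at least half the truth interval identifies a unique match.
    """
    regs = pd.DataFrame(
        [(r.region_id, r.chrom, r.start, r.end) for r in regions],
        columns=["region_id", "chrom", "start", "end"],
    )
    matches: dict[str, str] = {}
    for chrom, grp in truth.reset_index().groupby("chrom"):
        sub = regs[regs["chrom"] == chrom].sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ids = sub["region_id"].to_numpy()
        for row in grp.itertuples():
            i = int(np.searchsorted(starts, row.summit, side="right")) - 1
            if i < 0 or row.summit >= ends[i]:
                continue
            overlap = min(ends[i], row.end) - max(starts[i], row.start)
            if overlap >= min_overlap_frac * (row.end - row.start):
                matches[row.locus_id] = ids[i]
    return matches


def toy_filter_matrix():
    """Six hand-built regions exercising every clause of the region filter.

    Two tissues (A, B) x 8 replicates.  Expected survivors: r1 (exactly 6/8
    replicated in A, total 120), r4 (fully replicated, huge total) and r5
    (replicated in B only).
    """
    from atacspec.consensus import CountMatrix

    samples = pd.DataFrame(
        {
            "tissue": ["A"] * 8 + ["B"] * 8,
            "replicate": list(range(1, 9)) * 2,
        },
        index=pd.Index([f"A_r{i}" for i in range(1, 9)]
                       + [f"B_r{i}" for i in range(1, 9)], name="sample_id"),
    )
    rows = {
        # 12 reads in 6 of 8 A samples (6 >= ceil(0.75*8)=6), total 120: kept
        "r1": [12] * 6 + [0] * 2 + [8] * 6 + [0] * 2,
        # >=10 reads in only 4/8 samples of each tissue, total huge: dropped (a)
        "r2": [50] * 4 + [0] * 4 + [50] * 4 + [0] * 4,
        # fully replicated in A but total only 99: dropped (b)
        "r3": [11] * 9 + [0] * 7,
        # replicated everywhere, large total: kept
        "r4": [40] * 16,
        # replicated only in tissue B: kept
        "r5": [0] * 8 + [20] * 8,
        # all zero: dropped by both clauses
        "r6": [0] * 16,
    }
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples.index)
    regions = [
        ConsensusRegion(
            region_id=rid, chrom="chr1", start=1000 * (i + 1),
            end=1000 * (i + 1) + 151, consensus_summit=1000 * (i + 1) + 75,
            n_support=2,
        )
        for i, rid in enumerate(counts.index)
    ]
    expected_kept = ["r1", "r4", "r5"]
    return CountMatrix(counts=counts, samples=samples, regions=regions), expected_kept
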