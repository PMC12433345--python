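"""Fixed-width consensus regions, fragment counting, and RPM normalization.

Per-sample peak calls are reduced to a single genome-wide set of fixed-width
intervals: every peak is replaced by its summit extended ``flank`` bp on each
side, the extended intervals are clustered by single-linkage overlap, and
each cluster supported by at least ``min_overlap`` distinct samples yields
one region re-centered on the median member summit.  Fragments are then
counted into the (disjoint) regions by midpoint containment, regions failing
the replication/total-count filters are dropped, and counts are scaled to
reads per million (RPM) using the in-matrix library size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import Peak

DEFAULT_FLANK = 75
DEFAULT_MIN_OVERLAP = 2
DEFAULT_MIN_COUNT = 10
DEFAULT_GROUP_FRACTION = 0.75
DEFAULT_MIN_TOTAL = 100


@dataclass(frozen=True)
class ConsensusRegion:
    """A fixed-width consensus interval centered on a cluster summit."""

    region_id: str
    chrom: str
    start: int
    end: int
    consensus_summit: int
    n_support: int

    def __post_init__(self) -> None:
        if not (self.start <= self.consensus_summit < self.end):
            raise ValueError(
                f"{self.region_id}: summit {self.consensus_summit} outside "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class CountMatrix:
    """Region x sample integer counts plus region and sample metadata.

    ``counts`` is indexed by region_id with one column per sample_id;
    ``samples`` is indexed by sample_id and must carry a ``tissue`` column.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    regions: list[ConsensusRegion]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("count matrix labels must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if "tissue" not in self.samples.columns:
            raise ValueError("sample sheet must carry a tissue column")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns do not match sample sheet")
        ids = [r.region_id for r in self.regions]
        if ids != list(self.counts.index):
            raise ValueError("count rows do not match region list")

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for t in self.samples["tissue"]:
            if t not in seen:
                seen.append(t)
        return seen


def extend_to_fixed_width(peak: Peak, flank: int = DEFAULT_FLANK,
                          chrom_len: int | None = None) -> tuple[int, int]:
    """Extend a peak's summit ``flank`` bp each way, clipping to the chromosome.

    Returns the 0-based half-open interval ``[summit - flank, summit + flank + 1)``
    (width ``2*flank + 1`` unless clipped).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    summit = peak.summit
    if summit < 0 or (chrom_len is not None and summit >= chrom_len):
        raise ValueError(
            f"summit {summit} outside chromosome {peak.chrom} (len {chrom_len})"
        )
    start = max(0, summit - flank)
    end = summit + flank + 1
    if chrom_len is not None:
        end = min(end, chrom_len)
    return start, end


def build_consensus(
    peaksets: Mapping[str, Sequence[Peak]],
    flank: int = DEFAULT_FLANK,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    chrom_lens: Mapping[str, int] | None = None,
) -> list[ConsensusRegion]:
    """Cluster summit-extended peaks across samples into consensus regions.

    Single-linkage clustering by >= 1 bp overlap of the extended intervals;
    a cluster contributes a region only if it contains peaks from at least
    ``min_overlap`` distinct samples.  The region is the median member summit
    (ties -> lower coordinate) re-extended ``+-flank`` and clipped.  Output is
    sorted by (chrom, start) with ids ``peak_000001`` onward; regions are
    guaranteed disjoint.
    """
    if len(peaksets) < min_overlap:
        raise ValueError(
            f"need at least min_overlap={min_overlap} peaksets, got {len(peaksets)}"
        )

    entries: list[tuple[str, int, int, int, str]] = []
    for sample_id, peaks in peaksets.items():
        for p in peaks:
            clen = chrom_lens.get(p.chrom) if chrom_lens is not None else None
            s, e = extend_to_fixed_width(p, flank, clen)
            entries.append((p.chrom, s, e, p.summit, sample_id))
    entries.sort(key=lambda t: (t[0], t[1], t[2]))

    raw: list[tuple[str, int, int]] = []  # (chrom, summit, n_support)
    i = 0
    while i < len(entries):
        chrom = entries[i][0]
        cluster_end = entries[i][2]
        j = i + 1
        while j < len(entries) and entries[j][0] == chrom and entries[j][1] < cluster_end:
            cluster_end = max(cluster_end, entries[j][2])
            j += 1
        members = entries[i:j]
        samples = {m[4] for m in members}
        if len(samples) >= min_overlap:
            summits = sorted(m[3] for m in members)
            median = summits[(len(summits) - 1) // 2]  # ties -> lower
            raw.append((chrom, median, len(samples)))
        i = j

    raw.sort()
    regions: list[ConsensusRegion] = []
    for k, (chrom, summit, n_support) in enumerate(raw, 1):
        clen = chrom_lens.get(chrom) if chrom_lens is not None else None
        start = max(0, summit - flank)
        end = summit + flank + 1
        if clen is not None:
            end = min(end, clen)
        regions.append(
            ConsensusRegion(
                region_id=f"peak_{k:06d}",
                chrom=chrom,
                start=start,
                end=end,
                consensus_summit=summit,
                n_support=n_support,
            )
        )
    return regions


def count_fragments(
    fragments: Mapping[str, pd.DataFrame],
    regions: Sequence[ConsensusRegion],
    samples: pd.DataFrame,
) -> CountMatrix:
    """Count fragments into disjoint regions by midpoint containment.

    ``fragments`` maps sample_id to a DataFrame with chrom/start/end columns
    (BED3).  A fragment is assigned to the single region containing
    ``floor((start + end) / 2)``; fragments whose midpoint falls outside all
    regions are ignored.
    """
    missing = [s for s in samples.index if s not in fragments]
    if missing:
        raise ValueError(f"no fragments supplied for samples {missing}")

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in regions}:
        idx = np.array([i for i, r in enumerate(regions) if r.chrom == chrom])
        starts = np.array([regions[i].start for i in idx])
        o = np.argsort(starts)
        idx = idx[o]
        starts = starts[o]
        ends = np.array([regions[i].end for i in idx])
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"regions on {chrom} overlap; counting needs disjoint regions")
        by_chrom[chrom] = (starts, ends, idx)

    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)
    for col, sample_id in enumerate(samples.index):
        frag = fragments[sample_id]
        if len(frag) == 0:
            continue
        starts_f = frag["start"].to_numpy()
        ends_f = frag["end"].to_numpy()
        if (ends_f <= starts_f).any():
            bad = int(np.argmax(ends_f <= starts_f))
            raise ValueError(
                f"sample {sample_id}: fragment with end <= start "
                f"({starts_f[bad]}-{ends_f[bad]})"
            )
        for chrom, grp in frag.groupby("chrom", sort=False):
            if chrom not in by_chrom:
                continue
            starts, ends, idx = by_chrom[chrom]
            m = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
            pos = np.searchsorted(starts, m, side="right") - 1
            ok = (pos >= 0) & (m < ends[np.clip(pos, 0, len(ends) - 1)])
            np.add.at(counts[:, col], idx[pos[ok]], 1)

    cdf = pd.DataFrame(
        counts, index=[r.region_id for r in regions], columns=list(samples.index)
    )
    return CountMatrix(counts=cdf, samples=samples.copy(), regions=list(regions))


def filter_regions(
    matrix: CountMatrix,
    min_count: int = DEFAULT_MIN_COUNT,
    min_group_fraction: float = DEFAULT_GROUP_FRACTION,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> CountMatrix:
    """Keep regions that replicate within a tissue and clear a total-count floor.

    A region is kept iff (a) in at least one tissue, at least
    ``ceil(min_group_fraction * n_replicates)`` of that tissue's samples have
    count >= ``min_count``, and (b) its total count over all samples is
    >= ``min_total``.  Region order is preserved.
    """
    if not (0 < min_group_fraction <= 1):
        raise ValueError("min_group_fraction must be in (0, 1]")

    counts = matrix.counts
    represented = counts >= min_count
    keep_a = pd.Series(False, index=counts.index)
    for tissue, cols in matrix.samples.groupby("tissue").groups.items():
        need = math.ceil(min_group_fraction * len(cols))
        keep_a |= represented[list(cols)].sum(axis=1) >= need
    keep_b = counts.sum(axis=1) >= min_total
    keep = keep_a & keep_b

    kept_regions = [r for r in matrix.regions if keep[r.region_id]]
    return CountMatrix(
        counts=counts.loc[keep].copy(),
        samples=matrix.samples.copy(),
        regions=kept_regions,
    )


def rpm_normalize(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Scale each sample's counts to reads per million of its in-matrix total."""
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    totals = counts.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count")
    return counts / totals * 1e6


def regions_to_bed(regions: Iterable[ConsensusRegion]) -> list[tuple]:
    return [(r.chrom, r.start, r.end, r.region_id) for r in regions]
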