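"""Readers and writers for the file formats the pipeline touches.

Internal coordinates are uniformly 0-based half-open, the native convention
of BED and narrowPeak.  GTF input (1-based, closed) is converted on read and
back on write.  FASTA sequences are uppercased on read; soft-masking is not
preserved.  All parsers raise :class:`FormatError` (naming the offending line
where applicable) rather than silently repairing structural problems.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """Structural problem in an input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class Peak:
    """One narrowPeak record (BED6+4) from one sample.

    ``summit_offset`` is the offset of the point of highest signal from
    ``start``; ``-1`` means the caller did not report a summit, in which case
    :attr:`summit` falls back to the interval midpoint.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    pvalue_nlog10: float = -1.0
    qvalue_nlog10: float = -1.0
    summit_offset: int = -1
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"peak {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise FormatError(
                f"peak {self.chrom}:{self.start}-{self.end}: summit offset "
                f"{self.summit_offset} outside interval"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def summit(self) -> int:
        """Absolute summit coordinate (midpoint if no summit was reported)."""
        if self.summit_offset == -1:
            return self.start + self.width // 2
        return self.start + self.summit_offset


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its exon structure and strand-aware TSS."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "other"
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        if not self.exons:
            raise FormatError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(sorted(self.exons))
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise FormatError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        object.__setattr__(self, "exons", exons)
        if not (self.start <= self.tss < self.end):
            raise FormatError(
                f"transcript {self.transcript_id}: TSS outside span"
            )

    @property
    def tss(self) -> int:
        """0-based transcription start site: span start on +, end-1 on -."""
        return self.start if self.strand == "+" else self.end - 1


_BIOTYPES = {"protein_coding", "lncRNA"}


@dataclass(frozen=True)
class Pwm:
    """Position probability matrix with a log-odds scanning threshold.

    ``probs`` has shape (4, length) in A, C, G, T row order; each column sums
    to one.  ``log_odds_threshold`` is in bits (log2 odds vs. background);
    windows scoring at or above it count as motif occurrences.
    """

    name: str
    tf_name: str
    probs: np.ndarray
    log_odds_threshold: float

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise FormatError(f"motif {self.name}: probs must be 4 x length")
        if probs.shape[1] < 4:
            raise FormatError(f"motif {self.name}: length must be >= 4")
        if (probs < 0).any():
            raise FormatError(f"motif {self.name}: negative probability")
        sums = probs.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise FormatError(f"motif {self.name}: columns must sum to 1")
        probs.flags.writeable = False
        object.__setattr__(self, "probs", probs)

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------

def read_narrowpeak(path: str | os.PathLike, sample_id: str = "") -> list[Peak]:
    """Read a MACS2 narrowPeak (BED6+4) file.

    Coordinates are kept 0-based half-open; column 10 is stored as the summit
    offset from ``start``.  Malformed lines raise :class:`FormatError` naming
    the line number.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                summit = int(fields[9])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate ({exc})"
                ) from None
            try:
                peaks.append(
                    Peak(
                        chrom=fields[0],
                        start=start,
                        end=end,
                        name=fields[3],
                        score=float(fields[4]),
                        strand=fields[5],
                        signal=float(fields[6]),
                        pvalue_nlog10=float(fields[7]),
                        qvalue_nlog10=float(fields[8]),
                        summit_offset=summit,
                        sample_id=sample_id,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t"
                f"{p.strand}\t{p.signal:g}\t{p.pvalue_nlog10:g}\t"
                f"{p.qvalue_nlog10:g}\t{p.summit_offset}\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript models from an Ensembl-dialect GTF.

    1-based closed GTF coordinates become 0-based half-open; the TSS is the
    span start on the + strand and span end - 1 on the - strand.  Unknown
    biotypes map to ``"other"``.  A transcript feature without exon children
    is treated as single-exon.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted internal errors
        raise FormatError(f"{path}: cannot parse GTF ({exc})") from exc

    transcripts: list[TranscriptModel] = []
    for feat in db.features_of_type("transcript", order_by=("seqid", "start")):
        if "transcript_id" not in feat.attributes:
            raise FormatError(
                f"{path}: transcript feature at {feat.seqid}:{feat.start} "
                "missing transcript_id attribute"
            )
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        biotype = feat.attributes.get(
            "transcript_biotype", feat.attributes.get("gene_biotype", ["other"])
        )[0]
        if biotype not in _BIOTYPES:
            biotype = "other"
        exons = [
            (e.start - 1, e.end)
            for e in db.children(feat, featuretype="exon", order_by="start")
        ]
        if not exons:
            exons = [(feat.start - 1, feat.end)]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,
                end=feat.end,
                biotype=biotype,
                exons=tuple(exons),
            )
        )
    return transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | os.PathLike,
              source: str = "atacspec") -> None:
    """Write transcript + exon features, converting back to 1-based closed."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{t.biotype}";'
            )
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# HOMER motif library
# ---------------------------------------------------------------------------

def read_homer_motifs(path: str | os.PathLike) -> list[Pwm]:
    """Read a HOMER ``.motif`` library.

    Each record is a ``>`` header (consensus, name, log-odds threshold)
    followed by one whitespace-separated A C G T probability row per motif
    position.  Rows off unity by at most 1e-3 are renormalized; larger
    deviations are rejected.
    """
    motifs: list[Pwm] = []
    header: tuple[str, str, float] | None = None
    rows: list[list[float]] = []
    header_line = 0

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if not rows:
            raise FormatError(
                f"{path}:{header_line}: motif {header[1]} has no matrix rows"
            )
        probs = np.array(rows, dtype=float).T  # -> (4, length)
        name = header[1]
        motifs.append(
            Pwm(
                name=name,
                tf_name=name.split("(")[0].split("/")[0],
                probs=probs,
                log_odds_threshold=header[2],
            )
        )
        header, rows = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split("\t")
                if len(fields) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: motif header needs consensus, "
                        "name and threshold fields"
                    )
                try:
                    thr = float(fields[2])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric threshold {fields[2]!r}"
                    ) from None
                header = (fields[0], fields[1], thr)
                header_line = lineno
                continue
            if header is None:
                raise FormatError(f"{path}:{lineno}: matrix row before header")
            vals = line.split()
            if len(vals) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 probabilities, got {len(vals)}"
                )
            try:
                row = [float(v) for v in vals]
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric probability"
                ) from None
            total = sum(row)
            if abs(total - 1.0) > 1e-3:
                raise FormatError(
                    f"{path}:{lineno}: probability row sums to {total:.4f}"
                )
            rows.append([v / total for v in row])
    flush()
    return motifs


def write_homer_motifs(motifs: Iterable[Pwm], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.consensus}\t{m.name}\t{m.log_odds_threshold:g}\n")
            for col in m.probs.T:
                fh.write("\t".join(f"{v:.3f}" for v in col) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into a chrom -> uppercase sequence mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED3/BED4+ into a DataFrame with chrom/start/end[/name] columns."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            dtype={0: str}, keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = names[: df.shape[1]] + list(df.columns[len(names):])
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    except (ValueError, TypeError):
        raise FormatError(f"{path}: non-integer BED coordinates") from None
    bad = df.index[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        raise FormatError(
            f"{path}: line {bad[0] + 1}: invalid interval "
            f"{df.loc[bad[0], 'start']}-{df.loc[bad[0], 'end']}"
        )
    return df


def write_bed(intervals: Iterable[Sequence], path: str | os.PathLike) -> None:
    """Write (chrom, start, end[, name, ...]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(v) for v in iv) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices and sample sheets
# ---------------------------------------------------------------------------

def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a labeled numeric matrix (header row, first column = row ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row label {dup!r}")
    if pd.Index(df.columns).has_duplicates:
        raise FormatError(f"{path}: duplicate column label")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | os.PathLike,
                     comments: Sequence[str] = ()) -> None:
    """Write a labeled matrix, optionally preceded by ``#`` comment lines."""
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t")


def read_samples_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sample sheet: sample_id, tissue, replicate columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    required = {"sample_id", "tissue"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: sample sheet needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id")
    return df.set_index("sample_id")
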