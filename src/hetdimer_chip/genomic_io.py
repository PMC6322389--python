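"""Shared genomic interval types and readers/writers for BED, bedGraph and GTF.

All coordinates are 0-based half-open (BED convention). GTF input (1-based,
inclusive) is converted on read. Chromosome names are matched by exact string
comparison; no alias table is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "SignalTrack",
    "GeneAnnotation",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_totals",
    "write_totals",
    "read_gtf",
    "write_gtf",
    "intersect",
    "cluster_intervals",
]

VALID_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """Raised when a genomic file line cannot be parsed."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional summit.

    The summit, when present, is an offset from ``start`` and must lie inside
    the interval. When absent, :attr:`summit_pos` falls back to the interval
    midpoint, ``start + (end - start) // 2``.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not 0 <= self.summit < self.length:
            raise ValueError(
                f"summit offset {self.summit} outside [0, {self.length})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def summit_pos(self) -> int:
        """Absolute summit position; midpoint when no summit was recorded."""
        if self.summit is not None:
            return self.start + self.summit
        return self.start + self.length // 2

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class PeakSet:
    """An ordered, duplicate-free collection of :class:`GenomicInterval`.

    Intervals are kept sorted by (chrom, start, end). ``provenance`` is a free
    mapping recording where the set came from (assay, condition, replicate).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        provenance: Mapping[str, str] | None = None,
    ) -> None:
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        seen: set[tuple[str, int, int]] = set()
        for iv in ivs:
            key = (iv.chrom, iv.start, iv.end)
            if key in seen:
                raise ValueError(f"duplicate interval {key}")
            seen.add(key)
        self.intervals: list[GenomicInterval] = ivs
        self.provenance: dict[str, str] = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.intervals == other.intervals

    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
                "summit": [iv.summit for iv in self.intervals],
            }
        )

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees for overlap queries."""
        trees: dict[str, IntervalTree] = {}
        for chrom, ivs in self.by_chrom().items():
            trees[chrom] = IntervalTree.from_tuples(
                (iv.start, iv.end, i) for i, iv in enumerate(ivs)
            )
        return trees


@dataclass
class GeneAnnotation:
    """Gene id -> (chrom, TSS position, strand), held as a DataFrame."""

    table: pd.DataFrame  # columns: gene_id, chrom, tss, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "tss", "strand"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_ids in annotation")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {
            str(chrom): sub.sort_values(["tss", "gene_id"]).reset_index(drop=True)
            for chrom, sub in self.table.groupby("chrom")
        }


class SignalTrack:
    """Run-length encoded per-base read coverage plus total mapped reads.

    Each chromosome stores parallel arrays (starts, ends, values) describing
    non-overlapping, sorted runs of constant per-base coverage. Positions not
    covered by any run have value 0.
    """

    def __init__(
        self,
        runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        total_mapped_reads: float,
    ) -> None:
        if total_mapped_reads < 0:
            raise ValueError("total_mapped_reads must be >= 0")
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError("ragged run arrays")
            if np.any(values < 0):
                raise ValueError(f"negative coverage on {chrom}")
            if np.any(ends <= starts):
                raise ValueError(f"empty run on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping runs on {chrom}")
            keep = values != 0
            self.runs[chrom] = (starts[keep], ends[keep], values[keep])
        self.total_mapped_reads = float(total_mapped_reads)

    @classmethod
    def from_dense(
        cls, dense: Mapping[str, np.ndarray], total_mapped_reads: float
    ) -> "SignalTrack":
        runs = {}
        for chrom, arr in dense.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size == 0:
                runs[chrom] = (np.empty(0, int), np.empty(0, int), np.empty(0))
                continue
            change = np.flatnonzero(np.diff(arr) != 0) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            values = arr[starts]
            runs[chrom] = (starts, ends, values)
        return cls(runs, total_mapped_reads)

    def sum_range(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base coverage over [start, end)."""
        if chrom not in self.runs:
            return 0.0
        starts, ends, values = self.runs[chrom]
        if starts.size == 0:
            return 0.0
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]))

    def dense(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base coverage over [start, end); positions < 0 are zero-padded."""
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self.runs:
            return out
        starts, ends, values = self.runs[chrom]
        lo = np.searchsorted(ends, max(start, 0), side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            a = max(s, start) - start
            b = min(e, end) - start
            if b > a:
                out[a:b] = v
        return out

    def total_in_track(self) -> float:
        tot = 0.0
        for starts, ends, values in self.runs.values():
            tot += float(np.sum((ends - starts) * values))
        return tot


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> PeakSet:
    """Read BED3/BED6/narrowPeak into a :class:`PeakSet`.

    The narrowPeak dialect (10 columns) is detected by column count; its 10th
    column is the summit offset from the interval start (-1 means absent).
    """
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                strand = fields[5] if len(fields) > 5 else "."
                summit: int | None = None
                if len(fields) >= 10:  # narrowPeak
                    s = int(fields[9])
                    summit = s if s >= 0 else None
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                ivs.append(
                    GenomicInterval(chrom, start, end, name, score, strand, summit)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(ivs)


def write_bed(peaks: PeakSet, path: str | Path, narrowpeak: bool = False) -> None:
    """Write sorted BED6 (or narrowPeak when summits should be preserved)."""
    with open(path, "w") as fh:
        for iv in peaks:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name,
                    repr(iv.score) if iv.score else "0", iv.strand]
            if narrowpeak:
                cols += ["-1", "-1", "-1",
                         str(iv.summit) if iv.summit is not None else "-1"]
            fh.write("\t".join(cols) + "\n")


def read_totals(path: str | Path) -> dict[str, float]:
    """Read a 2-column TSV mapping track label -> total mapped reads."""
    totals: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            totals[parts[0]] = float(parts[1])
    return totals


def write_totals(totals: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for label in sorted(totals):
            fh.write(f"{label}\t{totals[label]:.6g}\n")


def read_bedgraph(
    path: str | Path, totals_path: str | Path, label: str | None = None
) -> SignalTrack:
    """Read a sorted bedGraph plus its totals file into a :class:`SignalTrack`.

    ``label`` selects the entry in the totals file; by default the bedGraph
    file stem is used. A missing total is an error — there is no silent
    default, because CPM normalization would be meaningless without it.
    """
    totals = read_totals(totals_path)
    key = label if label is not None else Path(path).stem
    if key not in totals:
        raise KeyError(f"no total mapped reads recorded for track {key!r}")
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative coverage value")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    runs = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        values = np.array([r[2] for r in rows], dtype=np.float64)
        runs[chrom] = (starts, ends, values)
    return SignalTrack(runs, totals[key])


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            starts, ends, values = track.runs[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def read_gtf(path: str | Path) -> GeneAnnotation:
    """Read gene features from a GTF file into a :class:`GeneAnnotation`.

    GTF is 1-based inclusive; the TSS is converted to the 0-based coordinate
    of the first transcribed base (start-1 on '+', end-1 on '-').
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            if fields[2] != "gene":
                continue
            chrom, start, end, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            gene_id = None
            for attr in fields[8].split(";"):
                attr = attr.strip()
                if attr.startswith("gene_id"):
                    gene_id = attr.split(None, 1)[1].strip('"')
                    break
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: no gene_id attribute")
            tss = start - 1 if strand == "+" else end - 1
            rows.append((gene_id, chrom, tss, strand))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    )


def write_gtf(ann: GeneAnnotation, path: str | Path, gene_length: int = 1000) -> None:
    """Write gene features (a fixed nominal gene body downstream of each TSS)."""
    with open(path, "w") as fh:
        tab = ann.table.sort_values(["chrom", "tss", "gene_id"])
        for row in tab.itertuples():
            if row.strand == "+":
                start1, end1 = row.tss + 1, row.tss + gene_length
            else:
                start1, end1 = max(1, row.tss + 1 - gene_length + 1), row.tss + 1
            fh.write(
                f"{row.chrom}\tsim\tgene\t{start1}\t{end1}\t.\t{row.strand}\t.\t"
                f'gene_id "{row.gene_id}";\n'
            )


def write_tss_bed(ann: GeneAnnotation, path: str | Path) -> None:
    ivs = [
        GenomicInterval(row.chrom, row.tss, row.tss + 1, row.gene_id, 0.0, row.strand)
        for row in ann.table.itertuples()
    ]
    write_bed(PeakSet(ivs), path)


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------


def intersect(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> PeakSet:
    """Intervals of ``a`` overlapping any interval of ``b`` by >= min_overlap bases.

    ``a``'s coordinates are retained (the 1-bp-overlap replicate rule).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees = b.trees()
    b_by_chrom = b.by_chrom()
    kept = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            other = b_by_chrom[iv.chrom][hit.data]
            if iv.overlap(other) >= min_overlap:
                kept.append(iv)
                break
    return PeakSet(kept, provenance=dict(a.provenance))


def cluster_intervals(
    tagged: Sequence[tuple[GenomicInterval, object]], min_overlap: int = 1
) -> list[list[tuple[GenomicInterval, object]]]:
    """Single-linkage clustering of tagged intervals by >= min_overlap overlap.

    A sorted sweep: a new interval joins the open cluster while its start is
    <= (cluster max end - min_overlap), i.e. it shares at least min_overlap
    bases with the cluster span. Order of input does not affect the clusters.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    items = sorted(tagged, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    clusters: list[list[tuple[GenomicInterval, object]]] = []
    cur: list[tuple[GenomicInterval, object]] = []
    cur_chrom, cur_end = None, -1
    for iv, tag in items:
        if cur and iv.chrom == cur_chrom and iv.start <= cur_end - min_overlap:
            cur.append((iv, tag))
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                clusters.append(cur)
            cur = [(iv, tag)]
            cur_chrom, cur_end = iv.chrom, iv.end
    if cur:
        clusters.append(cur)
    return clusters
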