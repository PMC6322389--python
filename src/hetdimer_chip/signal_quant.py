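"""Normalized signal extraction at genomic intervals.

Signal is quantified as the sum of per-base coverage over each interval
(the ``bedcov`` semantics), normalized to counts per million mapped reads
(CPM) and, with length normalization, RPKM:

    CPM  = count * 1e6 / total_mapped_reads
    RPKM = CPM * 1e3 / interval_length

Also provides summit-centred heatmap matrices, random background sampling
from an accessible-region universe, and the background-baseline comparison
used to ask whether partner-subunit signal at candidate sites exceeds the
level seen at accessible sites not bound by the factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval, PeakSet, SignalTrack

__all__ = [
    "SiteSignalMatrix",
    "BackgroundSample",
    "quantify",
    "sample_background",
    "heatmap_matrix",
    "baseline_comparison",
]


@dataclass
class SiteSignalMatrix:
    """Sites x assays matrix of normalized signal.

    ``cpm`` and ``rpkm`` are DataFrames indexed by site_id with one column per
    assay label (the caller chooses labels such as ``alpha1/rep1``). ``sites``
    keeps the interval metadata aligned to the index.
    """

    sites: PeakSet
    cpm: pd.DataFrame
    rpkm: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        for df in (self.cpm, self.rpkm, self.counts):
            if (df.values < 0).any():
                raise ValueError("signals must be >= 0")
            if df.isna().any().any():
                raise ValueError("missing (site, assay) cells")

    @classmethod
    def empty(cls, sites: PeakSet) -> "SiteSignalMatrix":
        idx = pd.Index([iv.name for iv in sites], name="site_id")
        z = pd.DataFrame(index=idx)
        return cls(sites, z.copy(), z.copy(), z.copy())

    def add_column(self, label: str, col: pd.DataFrame) -> None:
        self.counts[label] = col["count"].values
        self.cpm[label] = col["cpm"].values
        self.rpkm[label] = col["rpkm"].values

    def assay_mean(self, labels: Sequence[str], units: str = "cpm") -> pd.Series:
        """Arithmetic mean of normalized signal across the given columns."""
        df = getattr(self, units)
        return df[list(labels)].mean(axis=1)

    def columns(self) -> list[str]:
        return list(self.cpm.columns)


@dataclass
class BackgroundSample:
    """Random non-overlapping fixed-width regions drawn from a universe."""

    regions: PeakSet
    universe_label: str
    counts: dict[str, np.ndarray] = field(default_factory=dict)


def quantify(track: SignalTrack, sites: PeakSet) -> pd.DataFrame:
    """Per-site coverage sum with CPM and RPKM normalization.

    Returns a DataFrame indexed by site name with columns count, cpm, rpkm.
    """
    if track.total_mapped_reads <= 0:
        raise ValueError("track has no mapped reads; CPM undefined")
    names, counts, lengths = [], [], []
    for iv in sites:
        if iv.length <= 0:
            raise ValueError(f"zero-length site {iv.name}")
        names.append(iv.name)
        counts.append(track.sum_range(iv.chrom, iv.start, iv.end))
        lengths.append(iv.length)
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    cpm = counts * 1e6 / track.total_mapped_reads
    rpkm = cpm * 1e3 / lengths
    return pd.DataFrame(
        {"count": counts, "cpm": cpm, "rpkm": rpkm},
        index=pd.Index(names, name="site_id"),
    )


def quantify_matrix(
    tracks: Mapping[str, SignalTrack], sites: PeakSet
) -> SiteSignalMatrix:
    """Quantify several labelled tracks over one site set."""
    mat = SiteSignalMatrix.empty(sites)
    for label in tracks:
        mat.add_column(label, quantify(tracks[label], sites))
    return mat


def sample_background(
    universe: PeakSet, n: int, width: int = 400, seed: int | np.random.Generator = 0
) -> BackgroundSample:
    """Draw n non-overlapping fixed-width regions from the universe.

    Each universe interval is partitioned into floor(length/width) disjoint
    slots and n slots are sampled uniformly without replacement, which keeps
    the sample non-overlapping by construction and deterministic under seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slots: list[tuple[str, int]] = []
    for iv in universe:
        for k in range(iv.length // width):
            slots.append((iv.chrom, iv.start + k * width))
    if n > len(slots):
        raise ValueError(
            f"cannot place {n} regions of width {width}: "
            f"universe supports at most {len(slots)}"
        )
    chosen = rng.choice(len(slots), size=n, replace=False)
    ivs = [
        GenomicInterval(slots[i][0], slots[i][1], slots[i][1] + width, f"bg{j:06d}")
        for j, i in enumerate(sorted(chosen))
    ]
    return BackgroundSample(PeakSet(ivs), universe_label="universe")


def heatmap_matrix(
    track: SignalTrack,
    sites: PeakSet,
    flank: int = 5000,
    bins: int = 100,
    order_by: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """CPM-normalized binned signal around each site summit.

    Rows are sites sorted descending by ``order_by`` (aligned to ``sites``
    order); columns are equal-width bins over [summit-flank, summit+flank).
    Windows truncated by the chromosome start are zero-padded. Returns the
    matrix and the row site names in plotted order.
    """
    if flank <= 0 or bins < 1:
        raise ValueError("flank must be > 0 and bins >= 1")
    if (2 * flank) % bins != 0:
        raise ValueError("2*flank must be divisible by bins")
    if track.total_mapped_reads <= 0:
        raise ValueError("track has no mapped reads")
    width = 2 * flank // bins
    n = len(sites)
    order = np.arange(n)
    if order_by is not None:
        order_by = np.asarray(order_by, dtype=float)
        if order_by.shape != (n,):
            raise ValueError("order_by must align with sites")
        order = np.argsort(-order_by, kind="stable")
    mat = np.zeros((n, bins))
    names = []
    for row, i in enumerate(order):
        iv = sites[i]
        centre = iv.summit_pos
        window = track.dense(iv.chrom, centre - flank, centre + flank)
        mat[row] = window.reshape(bins, width).mean(axis=1)
        names.append(iv.name)
    mat *= 1e6 / track.total_mapped_reads
    return mat, names


@dataclass
class BaselineComparison:
    baseline_mean: float
    fraction_above: float
    ranked_site_signal: np.ndarray  # sites sorted ascending, for line plots


def baseline_comparison(
    site_signal: np.ndarray, background_signal: np.ndarray
) -> BaselineComparison:
    """Compare partner-subunit signal at sites to the accessible-background mean.

    The baseline is the mean signal over accessible regions not bound by the
    factor; returns the fraction of sites strictly above it and the sorted
    per-rank series used for line plots.
    """
    site_signal = np.asarray(site_signal, dtype=float)
    background_signal = np.asarray(background_signal, dtype=float)
    if background_signal.size == 0:
        raise ValueError("empty background")
    if site_signal.size == 0:
        raise ValueError("empty site signal")
    baseline = float(np.mean(background_signal))
    frac = float(np.mean(site_signal > baseline))
    return BaselineComparison(baseline, frac, np.sort(site_signal))
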