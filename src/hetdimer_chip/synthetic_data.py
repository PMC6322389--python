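"""Ground-truthed synthetic ChIP-seq-like data for a heterodimeric factor.

The generator emulates the statistical structure the downstream analyses
assume for an alpha/beta heterodimeric transcription factor with two
alpha-isoforms:

- 1:1 alpha:beta site loading (configurable true ratio) with multiplicative
  log-normal replicate noise on the site mean followed by Poisson counts;
- site-wise isoform mixing: isoform-1-specific sites placed promoter-
  proximally (normal offset around a TSS), isoform-2-specific sites
  promoter-distally (uniform outside the proximal window), shared sites
  with an intermediate mixing parameter;
- graded global loading across conditions, with an optional site-wise
  progressive-loading component (a subset of sites responds more steeply
  to stimulus severity than the rest);
- knockout conditions (per-isoform multipliers, beta following the
  surviving alpha signal);
- cell-line repertoires with a conserved shared core: a ``shared_fraction``
  of sites is present in every cell line with the same mixing parameter,
  the remainder is cell-specific;
- a ranked gene-expression table in which genes nearest bound sites are
  upregulated.

One master seed drives everything; per-assay/condition/replicate streams
are derived by stable hashing of their labels, so adding an assay never
perturbs the draws of another.
"""

from __future__ import annotations

import bisect
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import (
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_gtf,
    write_totals,
    write_tss_bed,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "generate_annotation",
    "generate_sites",
    "simulate_site_counts",
    "simulate_coverage",
    "call_peaks_standin",
    "generate_expression",
    "background_universe",
    "accessible_universe",
    "motif_occurrences",
    "write_dataset",
]

ASSAYS = ("alpha1", "alpha2", "beta")


@dataclass
class SimConfig:
    """Parameters of the synthetic heterodimer ChIP experiment.

    Defaults describe a two-condition graded-stimulus experiment (severe
    stimulus at full loading, mild at half) on a 10 Mb single-chromosome
    genome with two replicates per assay.
    """

    genome_length: int = 10_000_000
    n_genes: int = 200
    n_sites_per_isoform: int = 150
    shared_fraction: float = 0.3
    alpha_beta_ratio: float = 1.0
    replicate_cv: float = 0.2
    depth_per_assay: float = 1_000_000
    condition_scales: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=lambda: {"severe": 1.0, "mild": 0.5}
    )
    progressive_fraction: float = 0.0
    progressive_exponent: float = 2.0
    isoform1_proximal_sd: float = 500.0
    isoform2_distal_range: float = 100_000.0
    proximal_window: float = 5_000.0
    min_separation: int = 1_000
    site_width: int = 400
    footprint_halfwidth: int = 150
    site_read_fraction: float = 0.5
    loading_log2_sd: float = 1.0
    ratio_log2_sd: float = 0.0        # site-wise systematic alpha:beta spread
    specific_mix: float = 0.9         # alpha1 share at isoform1-specific sites
    shared_mix_range: tuple[float, float] = (0.2, 0.8)
    n_cell_lines: int = 1
    effect_size: float = 2.0          # log2FC of genes nearest bound sites
    expression_null_sd: float = 0.25
    shared_placement: str = "proximal"  # proximal | distal | mixed
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shared_fraction", "progressive_fraction", "site_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        if not self.condition_scales:
            raise ValueError("condition_scales must be non-empty")
        if self.alpha_beta_ratio <= 0:
            raise ValueError("alpha_beta_ratio must be positive")
        if self.shared_placement not in ("proximal", "distal", "mixed"):
            raise ValueError("shared_placement must be proximal|distal|mixed")

    def assay_multiplier(self, condition: str, assay: str) -> tuple[float, float]:
        """(global scale, per-isoform multiplier) for a condition and assay."""
        spec = self.condition_scales[condition]
        if isinstance(spec, Mapping):
            scale = float(spec.get("global", 1.0))
            iso = float(spec.get(assay, 1.0))
        else:
            scale, iso = float(spec), 1.0
        return scale, iso


def _stream(seed: int, *labels: object) -> np.random.Generator:
    """Independent generator for a labelled stream, stable across runs."""
    digest = hashlib.sha256("/".join(map(str, labels)).encode()).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


@dataclass
class SimTruth:
    """Ground truth: one row per site, one row per gene."""

    sites: pd.DataFrame   # site_id, chrom, start, end, summit, category, mix,
                          # base_loading, progressive, tss_distance, nearest_gene, cells
    genes: pd.DataFrame   # gene_id, regulated

    def __post_init__(self) -> None:
        if self.sites["site_id"].duplicated().any():
            raise ValueError("duplicate site ids in truth")
        if (self.sites["base_loading"] <= 0).any():
            raise ValueError("loading values must be strictly positive")

    def peaks(self, cell: str | None = None) -> PeakSet:
        sub = self.sites
        if cell is not None:
            sub = sub[sub["cells"].map(lambda c: cell in c)]
        ivs = [
            GenomicInterval(
                r.chrom, int(r.start), int(r.end), name=r.site_id,
                score=float(r.base_loading), summit=int(r.summit),
            )
            for r in sub.itertuples()
        ]
        return PeakSet(ivs)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sites": self.sites.assign(
                cells=self.sites["cells"].map(list)
            ).to_dict(orient="records"),
            "genes": self.genes.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def generate_annotation(cfg: SimConfig) -> GeneAnnotation:
    """Uniformly spaced TSSs with jitter on a single synthetic chromosome."""
    if cfg.n_genes == 0:
        return GeneAnnotation(
            pd.DataFrame(columns=["gene_id", "chrom", "tss", "strand"])
        )
    spacing = cfg.genome_length / cfg.n_genes
    if spacing < 2000:
        raise ValueError(
            f"genome of {cfg.genome_length} bp too short for {cfg.n_genes} genes "
            "with non-overlapping promoters (need >= 2 kb spacing)"
        )
    rng = _stream(cfg.seed, "annotation")
    jitter = rng.uniform(0, 0.3 * spacing, size=cfg.n_genes)
    tss = (np.arange(cfg.n_genes) * spacing + 0.1 * spacing + jitter).astype(int)
    tss = np.clip(tss, 0, cfg.genome_length - 1)
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": [f"g{i:05d}" for i in range(cfg.n_genes)],
                "chrom": "chrS",
                "tss": tss,
                "strand": strands,
            }
        )
    )


def _place_proximal(rng, tss_pos, sd, genome_length, width):
    tss = tss_pos[rng.integers(len(tss_pos))]
    offset = rng.normal(0, sd)
    centre = int(np.clip(tss + offset, width, genome_length - width))
    return centre


def _place_distal(rng, tss_pos, proximal_window, distal_range, genome_length, width):
    # rejection-sample a centre whose nearest-TSS distance is outside the
    # proximal window but within the distal range
    for _ in range(1000):
        tss = tss_pos[rng.integers(len(tss_pos))]
        sign = rng.choice([-1, 1])
        offset = sign * rng.uniform(proximal_window, distal_range)
        centre = int(tss + offset)
        if width <= centre <= genome_length - width:
            d = np.abs(tss_pos - centre).min()
            if d >= proximal_window:
                return centre
    raise ValueError("could not place a distal site; genome too crowded")


def generate_sites(
    cfg: SimConfig, ann: GeneAnnotation
) -> tuple[PeakSet, SimTruth]:
    """Place ground-truth binding sites and draw their latent parameters.

    Per isoform, ``n_sites_per_isoform`` sites are generated of which a
    ``shared_fraction`` are shared between the isoforms (intermediate mixing,
    counted once). Shared sites are also the conserved core across cell
    lines; specific sites are assigned to a single cell line each.
    """
    if cfg.n_sites_per_isoform > 0 and len(ann) == 0:
        raise ValueError("cannot place sites on an empty annotation")
    rng = _stream(cfg.seed, "sites")
    tss_pos = np.sort(ann.table["tss"].values) if len(ann) else np.array([0])
    n_shared = round(cfg.shared_fraction * cfg.n_sites_per_isoform)
    n_spec = cfg.n_sites_per_isoform - n_shared
    half = cfg.site_width // 2

    plans: list[tuple[str, str]] = (
        [("isoform1", "proximal")] * n_spec
        + [("isoform2", "distal")] * n_spec
        + [("shared", cfg.shared_placement)] * n_shared
    )
    cells = [f"cell{i}" for i in range(cfg.n_cell_lines)]
    rows: list[dict] = []
    used: list[int] = []  # kept sorted; bisect gives the nearest neighbours

    def separated(centre: int) -> bool:
        j = bisect.bisect_left(used, centre)
        for k in (j - 1, j):
            if 0 <= k < len(used) and abs(centre - used[k]) < cfg.min_separation:
                return False
        return True

    for category, placement in plans:
        for _ in range(2000):
            if placement == "mixed":
                placement_i = "proximal" if rng.uniform() < 0.5 else "distal"
            else:
                placement_i = placement
            if placement_i == "proximal":
                centre = _place_proximal(
                    rng, tss_pos, cfg.isoform1_proximal_sd, cfg.genome_length, half
                )
            else:
                centre = _place_distal(
                    rng, tss_pos, cfg.proximal_window, cfg.isoform2_distal_range,
                    cfg.genome_length, half,
                )
            if separated(centre):
                break
        else:
            raise ValueError(
                "could not satisfy min_separation; genome too short for the "
                "requested number of sites"
            )
        bisect.insort(used, centre)
        if category == "isoform1":
            mix = cfg.specific_mix
        elif category == "isoform2":
            mix = 1.0 - cfg.specific_mix
        else:
            mix = rng.uniform(*cfg.shared_mix_range)
        site_cells = (
            frozenset(cells)
            if category == "shared"
            else frozenset([cells[rng.integers(cfg.n_cell_lines)]])
        )
        j = int(np.abs(tss_pos - centre).argmin())
        rows.append(
            {
                "site_id": f"s{len(rows):05d}",
                "chrom": "chrS",
                "start": centre - half,
                "end": centre + half,
                "summit": half,
                "category": category,
                "mix": mix,
                "progressive": rng.uniform() < cfg.progressive_fraction,
                "tss_distance": int(centre - tss_pos[j]),
                "base_loading": float(
                    2.0 ** rng.normal(0.0, cfg.loading_log2_sd)
                ),
                "ratio_log2_offset": float(rng.normal(0.0, cfg.ratio_log2_sd)),
                "cells": site_cells,
            }
        )
    sites = pd.DataFrame(
        rows,
        columns=[
            "site_id", "chrom", "start", "end", "summit", "category", "mix",
            "progressive", "tss_distance", "base_loading",
            "ratio_log2_offset", "cells",
        ],
    )
    if len(sites):
        # normalize loadings so expected total alpha site reads at scale 1
        # equal site_read_fraction * depth (left unscaled for empty libraries)
        target = cfg.site_read_fraction * cfg.depth_per_assay
        if target > 0:
            sites["base_loading"] *= target / sites["base_loading"].sum()
    genes = pd.DataFrame({"gene_id": ann.table["gene_id"], "regulated": False})
    truth = SimTruth(sites, genes)
    return truth.peaks(), truth


def expected_site_reads(
    cfg: SimConfig,
    truth: SimTruth,
    assay: str,
    condition: str,
    cell: str | None = None,
) -> np.ndarray:
    """Noise-free expected read count per truth site for one assay/condition.

    E[alpha1 + alpha2] / E[beta] equals ``alpha_beta_ratio`` at every site
    (modulated by any site-wise systematic ratio offset); in knockout
    conditions beta follows the sum of the surviving alpha signals.
    """
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}")
    if condition not in cfg.condition_scales:
        raise ValueError(f"unknown condition {condition!r}")
    if len(truth.sites) == 0:
        return np.zeros(0, dtype=float)
    sub = truth.sites
    scale, _ = cfg.assay_multiplier(condition, "beta")
    base = sub["base_loading"].values * scale
    if cfg.progressive_fraction > 0 and scale != 1.0:
        prog = sub["progressive"].values
        base = np.where(
            prog,
            sub["base_loading"].values * scale ** cfg.progressive_exponent,
            base,
        )
    mix = sub["mix"].values
    _, m1 = cfg.assay_multiplier(condition, "alpha1")
    _, m2 = cfg.assay_multiplier(condition, "alpha2")
    a1 = base * mix * m1
    a2 = base * (1 - mix) * m2
    ratio = cfg.alpha_beta_ratio * 2.0 ** sub["ratio_log2_offset"].values
    if assay == "alpha1":
        mu = a1
    elif assay == "alpha2":
        mu = a2
    else:
        mu = (a1 + a2) / ratio
    if cell is not None:
        present = sub["cells"].map(lambda c: cell in c).values
        mu = np.where(present, mu, 0.0)
    return mu


def simulate_site_counts(
    cfg: SimConfig,
    truth: SimTruth,
    assay: str,
    condition: str,
    replicate: int,
    cell: str | None = None,
) -> tuple[np.ndarray, float]:
    """Noisy per-site read counts for one assay x condition x replicate.

    The site mean is the expected count times a log-normal replicate factor
    (unit mean, coefficient of variation ``replicate_cv``); the count is then
    Poisson. Returns (counts per truth site, total mapped reads), where the
    total is the nominal ``depth_per_assay`` (background reads make up the
    remainder of the library).
    """
    mu = expected_site_reads(cfg, truth, assay, condition, cell)
    rng = _stream(cfg.seed, "counts", cell or "-", assay, condition, replicate)
    if cfg.replicate_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.replicate_cv**2))
        factors = rng.lognormal(-(sigma**2) / 2, sigma, size=mu.size)
    else:
        factors = np.ones_like(mu)
    counts = rng.poisson(mu * factors).astype(float)
    return counts, float(cfg.depth_per_assay)


def simulate_coverage(
    cfg: SimConfig,
    truth: SimTruth,
    assay: str,
    condition: str,
    replicate: int,
    cell: str | None = None,
    background_bin: int = 200,
) -> SignalTrack:
    """Lay simulated reads onto the genome as a per-base coverage track.

    Site reads are spread over a triangular footprint kernel (half-width
    ``footprint_halfwidth``) centred on the summit via a multinomial draw;
    uniform background reads (Poisson per ``background_bin``) fill the
    remainder of ``depth_per_assay``.
    """
    if cfg.depth_per_assay == 0:
        return SignalTrack({}, 0.0)
    counts, _ = simulate_site_counts(cfg, truth, assay, condition, replicate, cell)
    rng = _stream(cfg.seed, "coverage", cell or "-", assay, condition, replicate)
    L = cfg.genome_length
    dense = np.zeros(L, dtype=np.float64)
    hw = cfg.footprint_halfwidth
    kernel = hw - np.abs(np.arange(-hw, hw + 1))  # triangular, peak at summit
    kernel = np.maximum(kernel, 1).astype(float)
    kernel /= kernel.sum()
    for summit_abs, c in zip(
        truth.sites["start"].values + truth.sites["summit"].values, counts
    ):
        if c <= 0:
            continue
        reads = rng.multinomial(int(c), kernel)
        lo = int(summit_abs) - hw
        a, b = max(lo, 0), min(lo + kernel.size, L)
        dense[a:b] += reads[a - lo : b - lo]
    bg_total = max(cfg.depth_per_assay - counts.sum(), 0.0)
    n_bins = L // background_bin
    if bg_total > 0 and n_bins > 0:
        bg = rng.poisson(bg_total / n_bins, size=n_bins).astype(float)
        dense[: n_bins * background_bin] += np.repeat(
            bg / background_bin, background_bin
        )
    return SignalTrack.from_dense({"chrS": dense}, cfg.depth_per_assay)


def call_peaks_standin(
    track: SignalTrack, min_count: float, window: int = 101
) -> PeakSet:
    """Simple threshold peak caller for the synthetic pipeline.

    Smooths per-base counts with a centred moving average of ``window``
    bases and reports maximal runs where the smoothed count >= min_count;
    the summit is the argmax of the smoothed signal (first maximum on ties).
    Exists only so the synthetic pipeline runs end to end; it is not a model
    of any published peak caller.
    """
    if min_count <= 0 or window <= 0:
        raise ValueError("min_count and window must be positive")
    ivs = []
    n_peak = 0
    for chrom in sorted(track.runs):
        starts, ends, _ = track.runs[chrom]
        if starts.size == 0:
            continue
        span_end = int(ends[-1]) + window
        dense = track.dense(chrom, 0, span_end)
        # centred moving average via cumulative sums (window is odd-padded)
        hw = window // 2
        padded = np.concatenate(
            (np.zeros(hw), dense, np.zeros(window - hw))
        )
        csum = np.concatenate(([0.0], np.cumsum(padded)))
        smooth = (csum[window:] - csum[:-window])[: dense.size] / window
        above = smooth >= min_count
        if not above.any():
            continue
        padded = np.concatenate(([False], above, [False]))
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)
        for s, e in zip(run_starts, run_ends):
            summit = int(np.argmax(smooth[s:e]))
            ivs.append(
                GenomicInterval(
                    chrom, int(s), int(e), name=f"p{n_peak:06d}",
                    score=float(smooth[s:e].max()), summit=summit,
                )
            )
            n_peak += 1
    return PeakSet(ivs)


def background_universe(
    cfg: SimConfig, truth: SimTruth, margin: int = 500
) -> PeakSet:
    """Accessible-but-unbound universe: the genome minus site neighborhoods.

    Random background regions for the empirical percentile filter are drawn
    from here. At genome scale the overwhelming majority of accessible
    regions are unbound, so their count distribution is the null; on a short
    synthetic chromosome that property must be enforced by excluding the
    planted sites (with a safety margin covering the footprint kernel).
    """
    edges = [0]
    for r in truth.sites.sort_values("start").itertuples():
        lo = max(int(r.start) - margin, 0)
        hi = min(int(r.end) + margin, cfg.genome_length)
        edges.extend([lo, hi])
    edges.append(cfg.genome_length)
    ivs = []
    for i, (a, b) in enumerate(zip(edges[::2], edges[1::2])):
        if b - a >= 1:
            ivs.append(GenomicInterval("chrS", a, b, name=f"u{i:06d}"))
    return PeakSet(ivs)


def accessible_universe(
    cfg: SimConfig,
    truth: SimTruth,
    n_unbound: int = 2000,
    width: int = 400,
    margin: int = 500,
) -> PeakSet:
    """Accessible-region universe: truth sites plus random unbound regions.

    Emulates an open-chromatin catalogue for overlap-enrichment tests — it
    contains the bound sites as a minority among accessible regions.
    """
    rng = _stream(cfg.seed, "accessible")
    unbound = background_universe(cfg, truth, margin)
    slots = [
        (iv.start + k * width)
        for iv in unbound
        for k in range(iv.length // width)
    ]
    if n_unbound > len(slots):
        raise ValueError(f"cannot place {n_unbound} unbound regions")
    chosen = sorted(rng.choice(len(slots), size=n_unbound, replace=False))
    ivs = [
        GenomicInterval("chrS", int(r.start), int(r.end), name=f"acc_{r.site_id}")
        for r in truth.sites.itertuples()
    ] + [
        GenomicInterval("chrS", slots[i], slots[i] + width, name=f"acc_u{j:06d}")
        for j, i in enumerate(chosen)
    ]
    return PeakSet(ivs)


def motif_occurrences(
    cfg: SimConfig, truth: SimTruth, n_random: int = 2000, motif_width: int = 8
) -> PeakSet:
    """Motif positions: one under each site summit plus uniform random ones."""
    rng = _stream(cfg.seed, "motifs")
    ivs = []
    for r in truth.sites.itertuples():
        centre = int(r.start) + int(r.summit)
        ivs.append(
            GenomicInterval("chrS", centre - motif_width // 2,
                            centre + motif_width - motif_width // 2,
                            name=f"m_{r.site_id}")
        )
    pos = np.sort(
        rng.choice(cfg.genome_length - motif_width, size=n_random, replace=False)
    )
    for j, p in enumerate(pos):
        ivs.append(
            GenomicInterval("chrS", int(p), int(p) + motif_width, name=f"m_r{j:06d}")
        )
    dedup: dict[tuple[str, int, int], GenomicInterval] = {}
    for iv in ivs:
        dedup.setdefault((iv.chrom, iv.start, iv.end), iv)
    return PeakSet(dedup.values())


def generate_expression(
    cfg: SimConfig, truth: SimTruth, ann: GeneAnnotation
) -> tuple[pd.DataFrame, SimTruth]:
    """Ranked gene table: genes nearest bound sites are upregulated.

    Regulated genes get log2FC ~ Normal(effect_size, expression_null_sd) and
    small p-values (log-uniform in [1e-6, 1e-2]); the rest are null
    (Normal(0, sd), p uniform). Returns (table, truth with regulation flags).
    """
    if len(ann) == 0:
        raise ValueError("empty annotation")
    tss_pos = ann.table["tss"].values
    order = np.argsort(tss_pos)
    centres = truth.sites["start"].values + truth.sites["summit"].values
    regulated: set[str] = set()
    for c in centres:
        j = order[int(np.abs(tss_pos[order] - c).argmin())]
        regulated.add(ann.table["gene_id"].iloc[j])
    rng = _stream(cfg.seed, "expression")
    genes = ann.table["gene_id"].values
    is_reg = np.array([g in regulated for g in genes])
    phi = rng.normal(0.0, cfg.expression_null_sd, size=genes.size)
    phi[is_reg] = rng.normal(cfg.effect_size, cfg.expression_null_sd, size=is_reg.sum())
    pv = rng.uniform(0.0, 1.0, size=genes.size)
    pv = np.nextafter(pv, 1.0)  # keep p in (0, 1]
    pv[is_reg] = 10.0 ** rng.uniform(-6, -2, size=is_reg.sum())
    table = pd.DataFrame({"gene_id": genes, "log2fc": phi, "pvalue": pv})
    new_truth = SimTruth(
        truth.sites, pd.DataFrame({"gene_id": genes, "regulated": is_reg})
    )
    return table, new_truth


def site_signal_matrix(
    cfg: SimConfig,
    truth: SimTruth,
    condition: str,
    replicates: int = 2,
    cell: str | None = None,
    assays: Sequence[str] = ASSAYS,
):
    """Quantified site x assay matrix straight from per-site counts.

    Bypasses genome-coverage layout: per-site counts are drawn with
    :func:`simulate_site_counts` and normalized to CPM/RPKM against the
    nominal library depth. Columns are labelled ``{assay}_rep{r}``. Sites
    absent from ``cell`` (when given) have zero signal, matching what
    quantifying that cell's library at shared cluster coordinates yields.
    """
    from .signal_quant import SiteSignalMatrix

    peaks = truth.peaks()
    idx = pd.Index(truth.sites["site_id"].values, name="site_id")
    widths = (truth.sites["end"] - truth.sites["start"]).values.astype(float)
    cpm, rpkm, counts = {}, {}, {}
    for assay in assays:
        for rep in range(1, replicates + 1):
            c, total = simulate_site_counts(cfg, truth, assay, condition, rep, cell)
            label = f"{assay}_rep{rep}"
            counts[label] = c
            cpm[label] = c * 1e6 / total
            rpkm[label] = cpm[label] * 1e3 / widths
    return SiteSignalMatrix(
        peaks,
        pd.DataFrame(cpm, index=idx),
        pd.DataFrame(rpkm, index=idx),
        pd.DataFrame(counts, index=idx),
    )


def write_dataset(
    cfg: SimConfig,
    outdir: str | Path,
    replicates: int = 2,
    write_coverage: bool = True,
) -> SimTruth:
    """Emit the full synthetic dataset as plain-text files.

    Writes the gene annotation (GTF + TSS BED6), truth site BED6 (score =
    expected loading), per-assay x condition x replicate bedGraph coverage
    with a totals TSV, the ranked gene table, and a JSON truth file. Output
    is byte-identical for identical config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = generate_annotation(cfg)
    _, truth = generate_sites(cfg, ann)
    expr, truth = generate_expression(cfg, truth, ann)
    write_gtf(ann, outdir / "genes.gtf")
    write_tss_bed(ann, outdir / "tss.bed")
    write_bed(truth.peaks(), outdir / "truth_sites.bed", narrowpeak=True)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    totals: dict[str, float] = {}
    if write_coverage:
        for assay in ASSAYS:
            for condition in cfg.condition_scales:
                for rep in range(1, replicates + 1):
                    label = f"{assay}_{condition}_rep{rep}"
                    track = simulate_coverage(cfg, truth, assay, condition, rep)
                    write_bedgraph(track, outdir / f"{label}.bedgraph")
                    totals[label] = track.total_mapped_reads
        write_totals(totals, outdir / "totals.tsv")
    return truth
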