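"""Read-depth copy-number pipeline.

Coverage logratios are computed in overlapping 500 bp windows against the
mean of benign (BPH) controls, centred by subtracting the median of
per-chromosome histogram modes of median-filtered logratios (frequently
aberrant chromosomes 8, 22, X and Y are left out of the offset estimate),
summarized per gene with a 20 kb minimum span, and converted to purity- and
ploidy-corrected copy changes:

    raw = ploidy * 2**logratio - ploidy
    corrected = raw / purity          (purity 0.70 by default)

A gene is amplified or deleted when |corrected| exceeds 0.5 (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter as _ndimage_median_filter

from .genome import GeneModel, ReferenceModel

DEFAULT_WINDOW = 500
DEFAULT_STEP = 250
DEFAULT_EXCLUDED = frozenset({"8", "22", "X", "Y"})
DEFAULT_FILTER_LENGTH = 50
DEFAULT_BIN_WIDTH = 0.05
DEFAULT_MIN_SPAN = 20_000
DEFAULT_PURITY = 0.7
DEFAULT_THRESHOLD = 0.5


def _chrom_key(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class WindowGrid:
    """Overlapping fixed-size windows per chromosome (0-based half-open)."""

    window_size: int
    step: int
    windows: dict[str, list[tuple[int, int]]]

    @classmethod
    def from_lengths(cls, lengths: dict[str, int], window_size: int = DEFAULT_WINDOW,
                     step: int = DEFAULT_STEP) -> "WindowGrid":
        windows = {}
        for chrom, length in lengths.items():
            ws = []
            start = 0
            while start + window_size <= length:
                ws.append((start, start + window_size))
                start += step
            windows[chrom] = ws
        return cls(window_size, step, windows)

    @classmethod
    def from_reference(cls, ref: ReferenceModel, window_size: int = DEFAULT_WINDOW,
                       step: int = DEFAULT_STEP) -> "WindowGrid":
        return cls.from_lengths(ref.lengths, window_size, step)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.windows)

    def starts(self, chrom: str) -> np.ndarray:
        return np.array([s for s, _ in self.windows[chrom]], dtype=int)


@dataclass
class LogratioTrack:
    """Per-window log2 coverage ratios with the normalization offset kept so
    raw values stay recoverable."""

    grid: WindowGrid
    values: dict[str, np.ndarray]  # log2 ratios, NaN = masked
    normalization_offset: float = 0.0
    sample_id: str = "tumor"

    def copy(self) -> "LogratioTrack":
        return LogratioTrack(
            grid=self.grid,
            values={c: v.copy() for c, v in self.values.items()},
            normalization_offset=self.normalization_offset,
            sample_id=self.sample_id,
        )


@dataclass(frozen=True)
class CopyNumberCall:
    gene_id: str
    gene_logratio: float
    ploidy: int
    raw_change: float
    corrected_change: float
    status: str  # amplified / neutral / deleted / undefined


# --------------------------------------------------------------------------


def _table_to_arrays(table: pd.DataFrame, grid: WindowGrid) -> dict[str, np.ndarray]:
    out = {}
    for chrom in grid.chromosomes:
        sub = table[table["chromosome"] == chrom]
        expected = grid.starts(chrom)
        if len(sub) != len(expected) or not np.array_equal(sub["start"].to_numpy(), expected):
            raise ValueError(f"window table does not match grid on {chrom}")
        out[chrom] = sub["count"].to_numpy(dtype=float)
    return out


def compute_window_logratios(
    tumor_counts: pd.DataFrame,
    control_counts: Sequence[pd.DataFrame],
    grid: WindowGrid,
    sample_id: str = "tumor",
) -> LogratioTrack:
    """log2(tumor / mean-of-controls) per window; zero-control windows masked."""
    if not len(control_counts):
        raise ValueError("at least one control table required")
    tumor = _table_to_arrays(tumor_counts, grid)
    controls = [_table_to_arrays(c, grid) for c in control_counts]
    values = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for chrom in grid.chromosomes:
            ctl_mean = np.mean([c[chrom] for c in controls], axis=0)
            ratio = np.where(ctl_mean > 0, tumor[chrom] / ctl_mean, np.nan)
            lr = np.log2(ratio)
            lr[~np.isfinite(lr)] = np.nan
            values[chrom] = lr
    return LogratioTrack(grid=grid, values=values, sample_id=sample_id)


def median_filter(values: np.ndarray, length: int = DEFAULT_FILTER_LENGTH,
                  centered: bool = True) -> np.ndarray:
    """Running median with edge replication.

    An even requested length is widened to the next odd value when centered
    (length 50 -> effective 51); ``centered=False`` gives an exact trailing
    window of the requested length instead.
    """
    finite = np.isfinite(values)
    vals = values[finite]
    if vals.size == 0:
        return values.copy()
    if centered:
        eff = length if length % 2 == 1 else length + 1
        filtered = _ndimage_median_filter(vals, size=min(eff, vals.size), mode="nearest")
    else:
        s = pd.Series(vals)
        filtered = s.rolling(length, min_periods=1).median().to_numpy()
    out = np.full_like(values, np.nan)
    out[finite] = filtered
    return out


def histogram_mode(values: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH,
                   lo: float = -3.0, hi: float = 3.0) -> float:
    """Center of the densest histogram bin; ties resolved toward 0.

    The bin grid is aligned so that zero is a bin CENTER: a copy-neutral
    signal centred at 0 then yields a 0 mode instead of a systematic
    half-bin offset.
    """
    vals = values[np.isfinite(values)]
    if vals.size == 0:
        raise ValueError("no finite values for histogram mode")
    n_bins = int(round((hi - lo) / bin_width)) + 1
    lo_edge, hi_edge = lo - bin_width / 2, hi + bin_width / 2
    counts, edges = np.histogram(np.clip(vals, lo, hi), bins=n_bins,
                                 range=(lo_edge, hi_edge))
    centers = (edges[:-1] + edges[1:]) / 2
    best = counts.max()
    candidates = centers[counts == best]
    return float(candidates[np.argmin(np.abs(candidates))])


def normalize_logratios(
    track: LogratioTrack,
    excluded_chromosomes: frozenset[str] = DEFAULT_EXCLUDED,
    filter_length: int = DEFAULT_FILTER_LENGTH,
    bin_width: float = DEFAULT_BIN_WIDTH,
    centered_filter: bool = True,
) -> LogratioTrack:
    """Histogram-mode centering of a logratio track.

    Modes are computed on median-filtered logratios per non-excluded
    chromosome; the median of those modes is subtracted from ALL windows
    (excluded chromosomes included).  The offset is recorded on the track.
    """
    excluded = {_chrom_key(c) for c in excluded_chromosomes}
    modes = []
    for chrom in track.grid.chromosomes:
        if _chrom_key(chrom) in excluded:
            continue
        vals = track.values[chrom]
        if np.isfinite(vals).sum() == 0:
            continue
        filtered = median_filter(vals, filter_length, centered=centered_filter)
        modes.append(histogram_mode(filtered, bin_width))
    if not modes:
        raise ValueError("all chromosomes excluded from offset estimation")
    offset = float(np.median(modes))
    out = track.copy()
    for chrom in out.values:
        out.values[chrom] = out.values[chrom] - offset
    out.normalization_offset = track.normalization_offset + offset
    return out


def gene_logratio(
    track: LogratioTrack,
    gene: GeneModel,
    min_span: int = DEFAULT_MIN_SPAN,
    chrom_length: Optional[int] = None,
) -> float:
    """Median logratio of windows overlapping the gene, extending short genes
    symmetrically to a ``min_span`` total span (shifted inside chromosome
    bounds when clamped at an edge).  NaN when no unmasked window overlaps."""
    if gene.chromosome not in track.values:
        raise ValueError(f"chromosome {gene.chromosome} absent from track")
    start, end = gene.start, gene.end
    if end - start < min_span:
        pad = (min_span - (end - start)) / 2
        start = int(math.floor(gene.start - pad))
        end = int(math.ceil(gene.end + pad))
        if start < 0:
            end -= start
            start = 0
        if chrom_length is not None and end > chrom_length:
            start = max(0, start - (end - chrom_length))
            end = chrom_length
    windows = track.grid.windows[gene.chromosome]
    vals = track.values[gene.chromosome]
    sel = [v for (ws, we), v in zip(windows, vals) if ws < end and we > start]
    sel = [v for v in sel if np.isfinite(v)]
    if not sel:
        return float("nan")
    return float(np.median(sel))


def call_gene_copy_number(
    gene_id: str,
    logratio: float,
    ploidy: int,
    purity: float = DEFAULT_PURITY,
    threshold: float = DEFAULT_THRESHOLD,
) -> CopyNumberCall:
    """Purity-corrected copy-change call from a gene-level logratio."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if not np.isfinite(logratio):
        return CopyNumberCall(gene_id, logratio, ploidy, float("nan"), float("nan"), "undefined")
    raw = ploidy * 2.0 ** logratio - ploidy
    corrected = raw / purity
    # strict comparison, guarded so a corrected change equal to the
    # threshold up to float rounding (e.g. -0.35/0.7) stays neutral
    eps = 1e-9
    if corrected > threshold + eps:
        status = "amplified"
    elif corrected < -threshold - eps:
        status = "deleted"
    else:
        status = "neutral"
    return CopyNumberCall(gene_id, float(logratio), ploidy, float(raw), float(corrected), status)


def call_genes(
    track: LogratioTrack,
    genes: Sequence[GeneModel],
    ploidy_map: dict[str, int],
    chrom_lengths: Optional[dict[str, int]] = None,
    purity: float = DEFAULT_PURITY,
    threshold: float = DEFAULT_THRESHOLD,
    min_span: int = DEFAULT_MIN_SPAN,
) -> list[CopyNumberCall]:
    calls = []
    for gene in genes:
        lr = gene_logratio(
            track, gene, min_span,
            None if chrom_lengths is None else chrom_lengths.get(gene.chromosome),
        )
        calls.append(
            call_gene_copy_number(gene.gene_id, lr, ploidy_map[gene.chromosome],
                                  purity, threshold)
        )
    return calls


def calls_to_frame(calls: Sequence[CopyNumberCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "logratio": c.gene_logratio,
                "ploidy": c.ploidy,
                "raw_change": c.raw_change,
                "corrected_change": c.corrected_change,
                "status": c.status,
            }
            for c in calls
        ]
    )
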