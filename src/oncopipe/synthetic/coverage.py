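"""Windowed read-count simulation with planted copy-number segments.

Tumor counts mix tumor and admixed normal cells: within a segment of copy
change ``c`` on a chromosome of ploidy ``P``, the expected tumor count is

    depth * [purity * (P + c) + (1 - purity) * P] / P

so a hemizygous deletion at 70% purity yields a raw coverage logratio of
log2(0.65), exactly what the purity-corrected copy-number caller inverts.
Controls are drawn around ``depth`` (the germline ploidy).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..cnv import WindowGrid
from ..genome import ReferenceModel
from .config import SimulationConfig, nb_draw

CnvTruth = list[tuple[str, tuple[int, int], int]]  # (chromosome, interval, copy change)


def expected_tumor_factor(change: int, ploidy: int, purity: float) -> float:
    """Expected tumor/control coverage ratio inside a segment."""
    mixed = purity * (ploidy + change) + (1 - purity) * ploidy
    if mixed < 0:
        raise ValueError(f"copy change {change} makes mixed copy number negative")
    return mixed / ploidy


def simulate_coverage(
    ref: ReferenceModel,
    cnv_truth: CnvTruth,
    config: SimulationConfig,
    grid: WindowGrid | None = None,
) -> tuple[pd.DataFrame, list[pd.DataFrame], dict]:
    """Window-count tables for one tumor and ``n_bph_controls`` controls.

    Returns ``(tumor_table, control_tables, sidecar)``; tables have columns
    chromosome/start/end/count on the same grid the copy-number caller uses.
    """
    if grid is None:
        grid = WindowGrid.from_reference(ref)
    rng = np.random.default_rng(config.seed)

    frames = []
    for chrom in grid.chromosomes:
        windows = grid.windows[chrom]
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "start": [s for s, _ in windows],
                    "end": [e for _, e in windows],
                }
            )
        )
    base = pd.concat(frames, ignore_index=True)

    factor = np.ones(len(base))
    for chrom, (seg_start, seg_end), change in cnv_truth:
        ploidy = ref.ploidy_map[chrom]
        f = expected_tumor_factor(change, ploidy, config.purity)
        mask = (
            (base["chromosome"] == chrom)
            & (base["start"] < seg_end)
            & (base["end"] > seg_start)
        )
        factor[mask.to_numpy()] = f

    tumor = base.copy()
    tumor["count"] = nb_draw(rng, config.depth * factor, config.dispersion)
    controls = []
    for _ in range(config.n_bph_controls):
        ctl = base.copy()
        ctl["count"] = nb_draw(rng, np.full(len(base), config.depth), config.dispersion)
        controls.append(ctl)

    sidecar = {
        "purity": config.purity,
        "depth": config.depth,
        "segments": [
            {
                "chromosome": chrom,
                "start": s,
                "end": e,
                "change": change,
                "ploidy": ref.ploidy_map[chrom],
                "expected_logratio": float(
                    np.log2(expected_tumor_factor(change, ref.ploidy_map[chrom], config.purity))
                ),
            }
            for chrom, (s, e), change in cnv_truth
        ],
    }
    return tumor, controls, sidecar
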