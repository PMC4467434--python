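"""Gene x sample count matrices with planted overexpression and
RNA-isolation-method bias.

Counts follow  baseline_g * size_factor_s * bias_g[Trizol] * overexpression
with negative-binomial noise.  The design must contain at least two benign
(BPH) tissues extracted with BOTH Trizol and Qiagen — the paired samples
from which the batch-correction model is fitted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..genome import ReferenceModel
from .config import SimulationConfig, nb_draw


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    sample_class: str  # BPH / PC / CRPC
    isolation: str  # Trizol / Qiagen
    tissue_id: str | None = None  # shared by dual-extracted aliquots
    overexpressed: tuple[tuple[str, float], ...] = ()  # (gene_id, fold)

    def __post_init__(self) -> None:
        if self.sample_class not in {"BPH", "PC", "CRPC"}:
            raise ValueError("sample_class must be BPH, PC or CRPC")
        if self.isolation not in {"Trizol", "Qiagen"}:
            raise ValueError("isolation must be Trizol or Qiagen")


def example_design(n_tumors: int = 6, overexpress: dict[str, dict[str, float]] | None = None,
                   n_dual_bph: int = 6) -> list[SampleDesign]:
    """Benign controls (``n_dual_bph`` tissues, each extracted with both
    methods: 12 BPH libraries at the default) plus tumors alternating
    isolation methods.  ``overexpress`` maps sample_id -> {gene: fold}."""
    overexpress = overexpress or {}
    design = []
    for i in range(n_dual_bph):
        design.append(SampleDesign(f"BPH{i + 1}_T", "BPH", "Trizol", tissue_id=f"BPH{i + 1}"))
        design.append(SampleDesign(f"BPH{i + 1}_Q", "BPH", "Qiagen", tissue_id=f"BPH{i + 1}"))
    for i in range(n_tumors):
        sid = f"PC{i + 1}"
        design.append(
            SampleDesign(
                sid,
                "PC" if i % 2 == 0 else "CRPC",
                "Trizol" if i % 2 == 0 else "Qiagen",
                overexpressed=tuple(overexpress.get(sid, {}).items()),
            )
        )
    return design


def _check_dual_bph(design: list[SampleDesign]) -> list[str]:
    by_tissue: dict[str, set[str]] = {}
    for s in design:
        if s.sample_class == "BPH" and s.tissue_id is not None:
            by_tissue.setdefault(s.tissue_id, set()).add(s.isolation)
    dual = [t for t, methods in by_tissue.items() if methods == {"Trizol", "Qiagen"}]
    if len(dual) < 2:
        raise ValueError(
            "design must include >=2 BPH tissues extracted with both Trizol and "
            "Qiagen; batch correction is untestable without them"
        )
    return dual


def simulate_counts(
    ref: ReferenceModel,
    design: list[SampleDesign],
    config: SimulationConfig,
    n_extra_genes: int = 0,
    baseline_mean: float = 500.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Return ``(counts, sample_metadata, sidecar)``.

    ``counts`` is genes x samples; metadata has sample_id, sample_class,
    isolation, tissue_id columns.  Extra unnamed genes (G0001...) pad the
    matrix for normalization and batch-model fitting at realistic scale.
    """
    dual = _check_dual_bph(design)
    rng = np.random.default_rng(config.seed)

    gene_ids = [g.gene_id for g in ref.genes] + [f"G{i + 1:04d}" for i in range(n_extra_genes)]
    n_genes, n_samples = len(gene_ids), len(design)

    baseline = baseline_mean * rng.lognormal(0.0, 0.8, size=n_genes)
    size_factors = rng.lognormal(0.0, 0.15, size=n_samples)
    bias = np.array([config.batch_bias.get(g, 1.0) for g in gene_ids])

    mean = np.outer(baseline, size_factors)
    for j, s in enumerate(design):
        if s.isolation == "Trizol":
            mean[:, j] *= bias
        for gene_id, fold in s.overexpressed:
            mean[gene_ids.index(gene_id), j] *= fold

    counts = nb_draw(rng, mean, config.dispersion).astype(float)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=[s.sample_id for s in design])
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "sample_class": [s.sample_class for s in design],
            "isolation": [s.isolation for s in design],
            "tissue_id": [s.tissue_id or "" for s in design],
        }
    )
    sidecar = {
        "dual_bph_tissues": dual,
        "biased_genes": sorted(g for g in gene_ids if config.batch_bias.get(g, 1.0) != 1.0),
        "batch_bias": {g: config.batch_bias[g] for g in config.batch_bias},
        "size_factors": {s.sample_id: float(f) for s, f in zip(design, size_factors)},
        "overexpression": {
            s.sample_id: dict(s.overexpressed) for s in design if s.overexpressed
        },
    }
    return counts_df, meta, sidecar
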