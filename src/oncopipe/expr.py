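"""Expression normalization, isolation-method batch correction and
outlier-overexpression flagging.

The normalization chain is: median-of-ratios size factors (reference =
geometric mean across samples over genes with all-positive counts), then
division by each gene's total exon length in kilobases, then correction of
the Trizol/Qiagen isolation-method bias.  The batch model is fitted only on
benign (BPH) tissues extracted with both methods: per gene, the ratio of
Trizol to Qiagen median expression, with an unpaired two-tailed t-test;
genes at p < 0.0001 are deemed isolation-sensitive and Trizol samples are
divided by the ratio.  Subtype overexpression (ERG, ETV1, ETV4, SPINK1,
SKIL) is flagged per sample against the benign reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .subtype_stats import ttest_unpaired_two_tailed

STAGES = ("raw_counts", "normalized", "length_corrected", "batch_corrected")
SENSITIVITY_P = 1e-4
DEFAULT_SUBTYPE_GENES = ("ERG", "ETV1", "ETV4", "SPINK1", "SKIL")
DEFAULT_FOLD_MARGIN = 3.0


@dataclass
class ExpressionMatrix:
    """Genes x samples values with sample metadata and gene exon lengths.

    ``metadata`` must carry sample_id, sample_class (BPH/PC/CRPC) and
    isolation (Trizol/Qiagen) columns; ``exon_lengths_bp`` maps gene_id to
    total exon length.  ``stage`` advances monotonically through
    raw_counts -> normalized -> length_corrected -> batch_corrected.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    exon_lengths_bp: Optional[pd.Series] = None
    stage: str = "raw_counts"
    size_factors: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        meta_ids = list(self.metadata["sample_id"])
        if sorted(meta_ids) != sorted(self.values.columns):
            raise ValueError("metadata sample_ids must match matrix columns")

    def _advance(self, new_values: pd.DataFrame, new_stage: str, **kw) -> "ExpressionMatrix":
        # stage is monotone non-decreasing; normalization and length
        # correction commute gene-wise, so either order is accepted
        stage = STAGES[max(STAGES.index(new_stage), STAGES.index(self.stage))]
        out = ExpressionMatrix(new_values, self.metadata, self.exon_lengths_bp,
                               stage, self.size_factors)
        for k, v in kw.items():
            setattr(out, k, v)
        return out

    def samples_where(self, **conditions) -> list[str]:
        mask = pd.Series(True, index=self.metadata.index)
        for col, val in conditions.items():
            mask &= self.metadata[col] == val
        return list(self.metadata.loc[mask, "sample_id"])


@dataclass
class BatchCorrectionModel:
    """Per-gene Trizol/Qiagen ratio and t-test p over dual-extracted BPH."""

    ratios: pd.Series
    p_values: pd.Series
    sensitive_genes: set = field(default_factory=set)
    skipped_genes: list = field(default_factory=list)


# --------------------------------------------------------------------------


def normalize_median_of_ratios(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Median-of-ratios (DESeq-style) size-factor normalization.

    Reference profile = per-gene geometric mean across samples over genes
    with all-positive counts; each sample's size factor is the median of its
    count/reference ratios; counts are divided by the factor.
    """
    counts = matrix.values
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with nonzero counts in all samples")
    ref = np.exp(np.log(counts.loc[positive]).mean(axis=1))
    factors = counts.loc[positive].div(ref, axis=0).median(axis=0)
    normalized = counts.div(factors, axis=1)
    return matrix._advance(normalized, "normalized", size_factors=factors)


def length_correct(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene by its total exon length in kilobases."""
    if matrix.exon_lengths_bp is None:
        raise ValueError("exon lengths required for length correction")
    missing = [g for g in matrix.values.index if g not in matrix.exon_lengths_bp.index]
    if missing:
        raise ValueError(f"missing exon lengths for genes: {missing}")
    kb = matrix.exon_lengths_bp.loc[matrix.values.index] / 1000.0
    return matrix._advance(matrix.values.div(kb, axis=0), "length_corrected")


def fit_batch_correction(
    matrix: ExpressionMatrix,
    dual_bph_ids: Optional[Sequence[str]] = None,
    p_threshold: float = SENSITIVITY_P,
    welch: bool = False,
) -> BatchCorrectionModel:
    """Fit the isolation-method bias model on dual-extracted BPH samples.

    ``dual_bph_ids`` restricts the model to those samples; by default all
    BPH samples are used.  Genes whose Qiagen median is zero, or that are
    constant across both groups (t-test undefined), are skipped and listed.
    """
    meta = matrix.metadata.set_index("sample_id")
    ids = list(dual_bph_ids) if dual_bph_ids is not None else matrix.samples_where(sample_class="BPH")
    bph = meta.loc[ids]
    if (bph["sample_class"] != "BPH").any():
        raise ValueError("batch model must be fitted on BPH samples only")
    trizol = [s for s in ids if meta.loc[s, "isolation"] == "Trizol"]
    qiagen = [s for s in ids if meta.loc[s, "isolation"] == "Qiagen"]
    if len(trizol) < 2 or len(qiagen) < 2:
        raise ValueError("need >= 2 BPH samples per isolation group")

    tri = matrix.values[trizol]
    qia = matrix.values[qiagen]
    ratios, pvals, skipped = {}, {}, []
    tri_med = tri.median(axis=1)
    qia_med = qia.median(axis=1)
    for gene in matrix.values.index:
        if qia_med[gene] == 0:
            skipped.append(gene)
            continue
        a, b = tri.loc[gene].to_numpy(), qia.loc[gene].to_numpy()
        if np.ptp(np.concatenate([a, b])) == 0:
            skipped.append(gene)
            continue
        res = ttest_unpaired_two_tailed(a, b, welch=welch)
        if not res.defined:
            skipped.append(gene)
            continue
        ratios[gene] = tri_med[gene] / qia_med[gene]
        pvals[gene] = res.p
    ratios = pd.Series(ratios, dtype=float)
    pvals = pd.Series(pvals, dtype=float)
    sensitive = set(pvals.index[pvals < p_threshold])
    return BatchCorrectionModel(ratios, pvals, sensitive, skipped)


def apply_batch_correction(matrix: ExpressionMatrix, model: BatchCorrectionModel) -> ExpressionMatrix:
    """Divide Trizol samples' sensitive genes by the fitted ratio."""
    values = matrix.values.copy()
    trizol = matrix.samples_where(isolation="Trizol")
    genes = [g for g in model.sensitive_genes if g in values.index]
    for gene in genes:
        values.loc[gene, trizol] = values.loc[gene, trizol] / model.ratios[gene]
    return matrix._advance(values, "batch_corrected")


@dataclass
class OverexpressionMatrix:
    """Boolean gene x sample subtype-overexpression flags."""

    flags: pd.DataFrame  # genes x samples, bool
    thresholds: pd.Series  # per-gene cutoff used

    def positives(self, gene: str) -> list[str]:
        row = self.flags.loc[gene]
        return list(row.index[row])


def flag_overexpression(
    matrix: ExpressionMatrix,
    subtype_genes: Sequence[str] = DEFAULT_SUBTYPE_GENES,
    benign_reference: Optional[Sequence[str]] = None,
    fold_margin: float = DEFAULT_FOLD_MARGIN,
    method: str = "fold",
    z_cutoff: float = 5.0,
) -> OverexpressionMatrix:
    """Flag samples overexpressing subtype genes relative to benign tissue.

    Default rule: value > fold_margin * max(benign reference).  The z-score
    alternative (``method='zscore'``) flags values more than ``z_cutoff``
    benign standard deviations above the benign mean.  BPH samples are never
    flagged; a sample may be flagged for several genes (the matrix is not
    forced mutually exclusive).
    """
    missing = [g for g in subtype_genes if g not in matrix.values.index]
    if missing:
        raise ValueError(f"subtype genes missing from matrix: {missing}")
    if benign_reference is None:
        benign_reference = matrix.samples_where(sample_class="BPH")
    if not benign_reference:
        raise ValueError("benign reference samples required")
    bph_all = set(matrix.samples_where(sample_class="BPH"))

    sub = matrix.values.loc[list(subtype_genes)]
    ref = sub[list(benign_reference)]
    if method == "fold":
        thresholds = ref.max(axis=1) * fold_margin
    elif method == "zscore":
        thresholds = ref.mean(axis=1) + z_cutoff * ref.std(axis=1, ddof=1)
    else:
        raise ValueError("method must be 'fold' or 'zscore'")
    flags = sub.gt(thresholds, axis=0)
    for s in flags.columns:
        if s in bph_all:
            flags[s] = False
    return OverexpressionMatrix(flags=flags, thresholds=thresholds)
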