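"""Copy-number pipeline: logratio arithmetic, histogram-mode centering,
gene summarization with the 20 kb minimum span, purity/ploidy correction."""

import numpy as np
import pandas as pd
import pytest

from oncopipe import cnv
from oncopipe.genome import GeneModel
from oncopipe.synthetic import SimulationConfig, simulate_coverage, simulate_reference


def _grid(lengths, window=500, step=500):
    return cnv.WindowGrid.from_lengths(lengths, window, step)


def _table(grid, chrom_values):
    frames = []
    for chrom, values in chrom_values.items():
        starts = grid.starts(chrom)
        frames.append(pd.DataFrame({
            "chromosome": chrom,
            "start": starts,
            "end": starts + grid.window_size,
            "count": values,
        }))
    return pd.concat(frames, ignore_index=True)


def _flat_track(grid, level=0.0, per_chrom=None):
    values = {}
    for chrom in grid.chromosomes:
        n = len(grid.windows[chrom])
        values[chrom] = np.full(n, level if per_chrom is None else per_chrom[chrom], float)
    return cnv.LogratioTrack(grid=grid, values=values)


# --------------------------------------------------------------- logratios


def test_window_logratio_arithmetic():
    grid = _grid({"chr1": 2_000})
    tumor = _table(grid, {"chr1": [100, 50, 100, 0]})
    controls = [
        _table(grid, {"chr1": [80, 100, 0, 10]}),
        _table(grid, {"chr1": [90, 100, 0, 10]}),
        _table(grid, {"chr1": [110, 100, 0, 10]}),
        _table(grid, {"chr1": [120, 100, 0, 10]}),
    ]
    track = cnv.compute_window_logratios(tumor, controls, grid)
    vals = track.values["chr1"]
    assert vals[0] == pytest.approx(0.0)  # control mean 100
    assert vals[1] == pytest.approx(-1.0)
    assert np.isnan(vals[2])  # zero control mean masked
    assert np.isnan(vals[3])  # log2(0) masked


def test_grid_mismatch_rejected():
    grid = _grid({"chr1": 2_000})
    other = _grid({"chr1": 1_500})
    tumor = _table(other, {"chr1": [1, 1, 1]})
    ctl = _table(grid, {"chr1": [1, 1, 1, 1]})
    with pytest.raises(ValueError, match="grid"):
        cnv.compute_window_logratios(tumor, [ctl], grid)


# ----------------------------------------------------------- normalization


def test_constant_shift_recovered_as_offset():
    grid = _grid({"chr1": 60_000, "chr2": 60_000, "chr3": 60_000})
    track = _flat_track(grid, level=0.3)
    normalized = cnv.normalize_logratios(track)
    assert normalized.normalization_offset == pytest.approx(0.3, abs=cnv.DEFAULT_BIN_WIDTH / 2)
    for vals in normalized.values.values():
        assert np.allclose(vals, 0.0, atol=cnv.DEFAULT_BIN_WIDTH / 2)


def test_offset_is_median_of_per_chromosome_modes():
    grid = _grid({"chr1": 60_000, "chr2": 60_000, "chr3": 60_000})
    track = _flat_track(grid, per_chrom={"chr1": 0.3, "chr2": 0.3, "chr3": 1.3})
    normalized = cnv.normalize_logratios(track)
    assert normalized.normalization_offset == pytest.approx(0.3, abs=cnv.DEFAULT_BIN_WIDTH / 2)


def test_excluded_chromosomes_do_not_influence_offset():
    lengths = {"chr1": 60_000, "chr2": 60_000, "chr3": 60_000,
               "chr8": 60_000, "chrX": 60_000}
    grid = _grid(lengths)
    base = _flat_track(grid, level=0.0)
    shifted = _flat_track(grid, per_chrom={"chr1": 0.0, "chr2": 0.0, "chr3": 0.0,
                                           "chr8": 1.0, "chrX": -1.0})
    n_base = cnv.normalize_logratios(base)
    n_shift = cnv.normalize_logratios(shifted)
    assert n_shift.normalization_offset == pytest.approx(n_base.normalization_offset)
    # the excluded chromosomes are still shifted by the (unchanged) offset
    assert np.allclose(n_shift.values["chr8"],
                       1.0 - n_shift.normalization_offset)


def test_shift_equivariance_at_bin_multiples():
    rng = np.random.default_rng(42)
    grid = _grid({"chr1": 60_000, "chr2": 60_000, "chr3": 60_000})
    track = _flat_track(grid)
    for chrom in track.values:
        track.values[chrom] = rng.normal(0, 0.1, len(track.values[chrom]))
    shifted = track.copy()
    for chrom in shifted.values:
        shifted.values[chrom] = shifted.values[chrom] + 0.25  # 5 bins exactly
    n1 = cnv.normalize_logratios(track)
    n2 = cnv.normalize_logratios(shifted)
    assert n2.normalization_offset - n1.normalization_offset == pytest.approx(0.25)
    for chrom in n1.values:
        assert np.allclose(n1.values[chrom], n2.values[chrom])


def test_all_chromosomes_excluded_is_error():
    grid = _grid({"chr8": 60_000, "chrX": 60_000})
    with pytest.raises(ValueError, match="excluded"):
        cnv.normalize_logratios(_flat_track(grid))


def test_median_filter_preserves_length_and_masks():
    vals = np.array([0.0, 0.1, np.nan, 5.0, 0.2, 0.1, 0.0])
    out = cnv.median_filter(vals, 3)
    assert out.shape == vals.shape
    assert np.isnan(out[2])
    assert np.isfinite(out[np.isfinite(vals)]).all()


# ------------------------------------------------------- gene summarization


def test_gene_logratio_constant_and_extension():
    grid = _grid({"chr1": 100_000})
    vals = np.zeros(len(grid.windows["chr1"]))
    # windows covering [30 kb, 60 kb) get 0.5
    for i, (s, _) in enumerate(grid.windows["chr1"]):
        if 30_000 <= s < 60_000:
            vals[i] = 0.5
    track = cnv.LogratioTrack(grid=grid, values={"chr1": vals})
    long_gene = GeneModel("long", "chr1", "+", exons=((30_000, 60_000),))
    assert cnv.gene_logratio(track, long_gene) == pytest.approx(0.5)
    # 4 kb gene centred at 45 kb: 20 kb span [37 kb, 57 kb) stays inside 0.5
    short_gene = GeneModel("short", "chr1", "+", exons=((43_000, 47_000),))
    assert cnv.gene_logratio(track, short_gene) == pytest.approx(0.5)


def test_short_gene_span_extends_to_20kb():
    grid = _grid({"chr1": 100_000})
    starts = grid.starts("chr1")
    vals = np.where((starts >= 38_000) & (starts < 52_000), 1.0, 0.0)
    track = cnv.LogratioTrack(grid=grid, values={"chr1": vals.astype(float)})
    gene = GeneModel("g", "chr1", "+", exons=((44_000, 48_000),))
    # 20 kb span is [36 kb, 56 kb): 28 of 40 windows at 1.0 -> median 1.0
    assert cnv.gene_logratio(track, gene) == pytest.approx(1.0)


def test_gene_at_chromosome_start_clamps_span():
    grid = _grid({"chr1": 100_000})
    starts = grid.starts("chr1")
    vals = np.where(starts < 20_000, 1.0, 0.0).astype(float)
    track = cnv.LogratioTrack(grid=grid, values={"chr1": vals})
    gene = GeneModel("g", "chr1", "+", exons=((0, 4_000),))
    # clamped span = [0, 20 kb): all windows inside are 1.0
    assert cnv.gene_logratio(track, gene, chrom_length=100_000) == pytest.approx(1.0)


def test_gene_with_no_unmasked_windows_is_nan():
    grid = _grid({"chr1": 100_000})
    track = cnv.LogratioTrack(grid=grid, values={"chr1": np.full(200, np.nan)})
    gene = GeneModel("g", "chr1", "+", exons=((0, 30_000),))
    assert np.isnan(cnv.gene_logratio(track, gene))


# ----------------------------------------------------------- change calls


@pytest.mark.parametrize(
    "logratio, ploidy, purity, raw, corrected, status",
    [
        (0.0, 2, 0.7, 0.0, 0.0, "neutral"),
        (1.0, 2, 1.0, 2.0, 2.0, "amplified"),
        (np.log2(0.65), 2, 0.7, -0.7, -1.0, "deleted"),
        (np.log2(1 - 0.35 / 2), 2, 0.7, -0.35, -0.5, "neutral"),  # strict boundary
    ],
)
def test_copy_number_formula(logratio, ploidy, purity, raw, corrected, status):
    call = cnv.call_gene_copy_number("g", logratio, ploidy, purity)
    assert call.raw_change == pytest.approx(raw, abs=1e-9)
    assert call.corrected_change == pytest.approx(corrected, abs=1e-9)
    assert call.status == status


def test_nonfinite_logratio_is_undefined():
    call = cnv.call_gene_copy_number("g", float("nan"), 2)
    assert call.status == "undefined"


# -------------------------------------------------- planted-truth recovery


def test_recovers_planted_changes_through_full_chain():
    """Hemizygous deletion and single-copy gain planted at 70% purity are
    recovered after logratio computation, normalization and correction."""
    ref = simulate_reference(3, 150_000, gene_spec=[
        {"gene_id": "del", "chromosome": "chr1", "exons": [(50_000, 90_000)]},
        {"gene_id": "gain", "chromosome": "chr2", "exons": [(50_000, 90_000)]},
        {"gene_id": "flat", "chromosome": "chr3", "exons": [(50_000, 90_000)]},
    ], seed=50)
    cfg = SimulationConfig(seed=51, depth=100)
    segs = [("chr1", (45_000, 95_000), -1), ("chr2", (45_000, 95_000), 1)]
    tumor, controls, _ = simulate_coverage(ref, segs, cfg)
    grid = cnv.WindowGrid.from_reference(ref)
    track = cnv.normalize_logratios(cnv.compute_window_logratios(tumor, controls, grid))
    calls = {c.gene_id: c for c in cnv.call_genes(track, ref.genes, ref.ploidy_map, ref.lengths)}
    assert calls["del"].status == "deleted"
    assert calls["del"].corrected_change == pytest.approx(-1.0, abs=0.15)
    assert calls["gain"].status == "amplified"
    assert calls["gain"].corrected_change == pytest.approx(1.0, abs=0.15)
    assert calls["flat"].status == "neutral"
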