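"""Unit and property tests for the split-anchor rearrangement caller."""

import itertools

import pytest

from oncopipe import breakfast as bf
from oncopipe.samio import AlignmentRecord
from oncopipe.synthetic import SimulationConfig, simulate_reference
from oncopipe.synthetic.reads import default_fusion_truth, simulate_rearranged_alignments


def _rec(read_id, mate, chrom, pos, mapq=30, strand="+", dup=False, aligned=True, seq="A" * 90):
    return AlignmentRecord(read_id, mate, aligned, chrom if aligned else None,
                           pos if aligned else None, strand if aligned else None,
                           mapq, seq, dup)


# ----------------------------------------------------- discordant pairs


def test_separation_boundary_one_megabase():
    near = [_rec("r1", 1, "chr1", 0), _rec("r1", 2, "chr1", 999_999)]
    exact = [_rec("r2", 1, "chr1", 0), _rec("r2", 2, "chr1", 1_000_000)]
    assert bf.find_discordant_pairs(near) == []
    assert len(bf.find_discordant_pairs(exact)) == 1


def test_mapq_threshold_is_strict():
    at = [_rec("r", 1, "chr1", 0, mapq=16), _rec("r", 2, "chr2", 0, mapq=15)]
    above = [_rec("r", 1, "chr1", 0, mapq=16), _rec("r", 2, "chr2", 0, mapq=16)]
    assert bf.find_discordant_pairs(at) == []
    assert len(bf.find_discordant_pairs(above)) == 1


def test_duplicates_and_unaligned_excluded():
    dup = [_rec("r", 1, "chr1", 0, dup=True), _rec("r", 2, "chr2", 0)]
    half = [_rec("r", 1, "chr1", 0), _rec("r", 2, None, None, aligned=False)]
    assert bf.find_discordant_pairs(dup) == []
    assert bf.find_discordant_pairs(half) == []


def test_triplicate_read_id_is_malformed():
    records = [_rec("r", 1, "chr1", 0), _rec("r", 1, "chr1", 5), _rec("r", 2, "chr2", 0)]
    with pytest.raises(bf.MalformedInputError):
        bf.find_discordant_pairs(records)


def test_pair_enumeration_matches_brute_force_oracle():
    """Exhaustive check on a deterministic 50-read toy set: the caller's
    pair list equals a brute-force re-derivation of the rule."""
    records = []
    chroms = ["chr1", "chr2", "chr3"]
    for i in range(25):
        c1 = chroms[i % 3]
        c2 = chroms[(i * 2) % 3]
        records.append(_rec(f"r{i}", 1, c1, i * 137_003 % 2_000_000, mapq=10 + i))
        records.append(_rec(f"r{i}", 2, c2, (i * 911_001 + 13) % 2_000_000, mapq=40 - i))

    def oracle():
        keep = set()
        for i in range(25):
            m1, m2 = records[2 * i], records[2 * i + 1]
            if m1.mapq > 15 and m2.mapq > 15:
                if m1.chromosome != m2.chromosome or abs(m1.position - m2.position) >= 1_000_000:
                    keep.add(m1.read_id)
        return keep

    got = {p.mate1.read_id for p in bf.find_discordant_pairs(records)}
    assert got == oracle()


# ------------------------------------------------- anchor realignment


@pytest.fixture(scope="module")
def anchor_ref():
    return simulate_reference(2, 120_000, gene_spec=[
        {"gene_id": "A", "chromosome": "chr1", "exons": [(10_000, 30_000)]},
        {"gene_id": "B", "chromosome": "chr2", "exons": [(50_000, 70_000)]},
    ], seed=21)


def test_junction_read_yields_one_anchor_pair(anchor_ref):
    """Construct a read from two known reference substrings; placements are
    verified against a plain string-search oracle."""
    left = anchor_ref.fetch("chr1", 20_000 - 45, 20_000)
    right = anchor_ref.fetch("chr2", 60_000, 60_000 + 45)
    read = _rec("j", 2, None, None, aligned=False, seq=left + right)
    pairs = bf.split_and_realign_anchors([read], anchor_ref)
    assert len(pairs) == 1
    ap = pairs[0]
    assert anchor_ref.sequence("chr1").find((left + right)[:25]) == ap.anchor_start[1]
    assert anchor_ref.sequence("chr2").find((left + right)[-25:]) == ap.anchor_end[1]
    assert ap.implied_breakpoints[0] == ("chr1", 20_000 - 45 + 25)
    assert ap.implied_breakpoints[1] == ("chr2", 60_000 + 45 - 25)


def test_concordant_read_yields_no_anchor_pair(anchor_ref):
    seq = anchor_ref.fetch("chr1", 15_000, 15_090)
    read = _rec("c", 2, None, None, aligned=False, seq=seq)
    assert bf.split_and_realign_anchors([read], anchor_ref) == []


def test_ambiguous_anchor_is_discarded():
    """An exact planted repeat makes one anchor multi-mapping; a string
    oracle confirms two occurrences, and no anchor pair is produced."""
    base = simulate_reference(2, 120_000, gene_spec=[
        {"gene_id": "A", "chromosome": "chr1", "exons": [(10_000, 30_000)]}], seed=22)
    chroms = []
    repeat = base.fetch("chr1", 20_000, 20_025)
    for name, length, seq in base.chromosomes:
        if name == "chr2":  # plant an exact copy of the chr1 anchor
            seq = seq[:40_000] + repeat + seq[40_025:]
        chroms.append((name, length, seq))
    ref = type(base)(chromosomes=chroms, genes=base.genes)
    assert sum(s.count(repeat) for _, _, s in ref.chromosomes) == 2
    read_seq = repeat + ref.fetch("chr2", 80_000, 80_000 + 65)
    read = _rec("amb", 2, None, None, aligned=False, seq=read_seq)
    assert bf.split_and_realign_anchors([read], ref) == []


def test_one_mismatch_aligner_places_mutated_anchor(anchor_ref):
    exact = bf.UniqueExactAligner(anchor_ref)
    tolerant = bf.UniqueExactAligner(anchor_ref, max_mismatches=1)
    seq = anchor_ref.fetch("chr1", 20_000, 20_025)
    mutated = seq[:10] + ("A" if seq[10] != "A" else "C") + seq[11:]
    assert exact.align(mutated) is None
    assert tolerant.align(mutated) == ("chr1", 20_000, "+")
    assert tolerant.align(seq) == ("chr1", 20_000, "+")  # exact beats 1-mm


def test_short_mate_skipped_with_warning_count(anchor_ref):
    read = _rec("s", 2, None, None, aligned=False, seq="ACGT" * 10)
    assert bf.split_and_realign_anchors([read], anchor_ref) == []
    assert bf.split_and_realign_anchors.skipped_short == 1


# ----------------------------------------------------------- clustering


def _anchor(read_id, pos_a, pos_b, chrom_a="chr1", chrom_b="chr2"):
    return bf.AnchorPair(read_id, (chrom_a, pos_a, "+"), (chrom_b, pos_b, "+"),
                         ((chrom_a, pos_a + 25), (chrom_b, pos_b)))


def test_mixed_evidence_forms_single_cluster():
    anchors = [_anchor(f"a{i}", 1_000 + i * 40, 5_000 + i * 40) for i in range(5)]
    pair = bf.DiscordantPair(_rec("p", 1, "chr1", 900), _rec("p", 2, "chr2", 5_100, strand="-"), None)
    clusters = bf.cluster_evidence([pair], anchors, join_radius=1_000)
    assert len(clusters) == 1
    c = clusters[0]
    assert (c.n_paired_reads, c.n_anchor_pairs) == (1, 5)


def test_distant_junctions_stay_separate():
    near = [_anchor(f"a{i}", 1_000, 5_000) for i in range(3)]
    far = [_anchor(f"b{i}", 10_001_000, 5_000) for i in range(3)]
    clusters = bf.cluster_evidence([], near + far, join_radius=1_000)
    assert len(clusters) == 2


def test_clustering_invariant_under_input_order():
    """Permutation invariance, checked against a brute-force single-linkage
    oracle over all pairs of evidence items."""
    anchors = [_anchor(f"a{i}", 1_000 + 300 * i, 9_000 - 200 * i) for i in range(6)]
    anchors += [_anchor(f"c{i}", 40_000 + 10 * i, 70_000 + 10 * i) for i in range(3)]

    def oracle_partition(items):
        n = len(items)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(n), 2):
            ai, aj = items[i], items[j]
            if (abs(ai.anchor_start[1] - aj.anchor_start[1]) <= 1_000
                    and abs(ai.implied_breakpoints[1][1] - aj.implied_breakpoints[1][1]) <= 1_000):
                parent[find(i)] = find(j)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), set()).add(items[i].read_id)
        return {frozenset(g) for g in groups.values()}

    expected = oracle_partition(anchors)
    for perm_seed in range(4):
        import random

        shuffled = anchors[:]
        random.Random(perm_seed).shuffle(shuffled)
        clusters = bf.cluster_evidence([], shuffled, join_radius=1_000)
        got = {frozenset(c.members) for c in clusters}
        assert got == expected


def test_cluster_counts_conserved():
    anchors = [_anchor(f"a{i}", 1_000 + i, 5_000 + i) for i in range(4)]
    clusters = bf.cluster_evidence([], anchors, join_radius=1_000)
    assert sum(len(c.members) for c in clusters) == len(anchors)


def test_modal_breakpoint_tie_breaks_to_smallest():
    anchors = [_anchor("a", 1_000, 5_000), _anchor("b", 1_200, 5_000),
               _anchor("c", 1_000, 5_200), _anchor("d", 1_200, 5_200)]
    clusters = bf.cluster_evidence([], anchors, join_radius=1_000)
    assert clusters[0].breakpoint_estimate == (1_000 + 25, 5_000)


# -------------------------------------------------------------- filtering


@pytest.mark.parametrize(
    "pairs, anchors, kept",
    [
        (1, 5, True),
        (1, 4, False),
        (0, 5, False),
        (0, 19, False),
        (0, 20, True),
        (3, 0, False),
    ],
)
def test_support_filter_boundaries(pairs, anchors, kept):
    c = bf.RearrangementCluster(("chr1", (0, 1)), ("chr2", (0, 1)), pairs, anchors, (0, 0))
    assert (bf.filter_clusters([c]) == [c]) is kept


def test_filter_is_idempotent_and_order_preserving():
    cs = [
        bf.RearrangementCluster(("chr1", (0, 1)), ("chr2", (0, 1)), 1, 9, (0, 0)),
        bf.RearrangementCluster(("chr1", (5, 6)), ("chr2", (5, 6)), 0, 25, (5, 5)),
    ]
    once = bf.filter_clusters(cs)
    assert bf.filter_clusters(once) == once == cs


# -------------------------------------------------------------- annotation


def test_annotation_of_planted_promoter_swap(ref):
    truth = default_fusion_truth(ref)
    cfg = SimulationConfig(seed=30, n_straddling_pairs=1, n_spanning_mates=5,
                           n_background_pairs=30)
    records, _ = simulate_rearranged_alignments(ref, [truth], cfg)
    calls = bf.call_fusions(records, ref)
    assert len(calls) == 1
    call = calls[0]
    assert (call.gene5, call.gene3) == ("TMPRSS2L", "SKIL")
    assert call.promoter_class == "androgen_regulated"
    assert call.orientation == "sense"
    assert call.coding_disrupted is False


def test_annotation_antisense_case_still_emitted(ref):
    truth = default_fusion_truth(ref, orientation="antisense")
    cfg = SimulationConfig(seed=31, n_straddling_pairs=1, n_spanning_mates=5,
                           n_background_pairs=0)
    records, _ = simulate_rearranged_alignments(ref, [truth], cfg)
    calls = bf.call_fusions(records, ref)
    assert len(calls) == 1
    assert calls[0].orientation == "antisense"
    assert (calls[0].gene5, calls[0].gene3) == ("TMPRSS2L", "SKIL")


def test_breakpoint_inside_coding_region_flags_disruption(ref):
    skil = ref.gene("SKIL")
    cluster = bf.RearrangementCluster(
        locus_a=("chr1", (0, 100)),
        locus_b=(skil.chromosome, (skil.coding_region[0] + 10, skil.coding_region[0] + 100)),
        n_paired_reads=1, n_anchor_pairs=5,
        breakpoint_estimate=(50, skil.coding_region[0] + 50),
        prefix_side_votes=["a"],
    )
    call = bf.annotate_fusion(cluster, ref.genes, ref.lengths)
    assert call.coding_disrupted is True


def test_breakpoint_outside_reference_is_error(ref):
    cluster = bf.RearrangementCluster(("chrZ", (0, 1)), ("chr2", (0, 1)), 1, 5, (0, 0))
    with pytest.raises(ValueError, match="outside"):
        bf.annotate_fusion(cluster, ref.genes, ref.lengths)
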