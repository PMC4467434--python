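"""Split-anchor rearrangement calling from paired-end alignments.

The caller collects two evidence classes for genomic rearrangements:

* **discordant read pairs** — both mates aligned with MAPQ above a floor
  (default 15, strict) and either on different chromosomes or at least one
  megabase apart;
* **anchor pairs** — each unaligned mate is split into two 25 bp anchors
  taken from its ends; when both anchors realign uniquely and their
  placements are discordant by the same rule, the read spans a junction.

Evidence is clustered by single linkage on both loci, clusters are kept if
supported by at least 1 paired read and 5 anchor pairs, or by at least 20
anchor pairs, and surviving clusters are annotated against gene models:
5'/3' partner assignment, promoter class, sense/antisense juxtaposition and
whether the 3' partner's coding sequence is disrupted.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .genome import GeneModel, ReferenceModel, revcomp
from .samio import AlignmentRecord

DEFAULT_MIN_SEPARATION = 1_000_000
DEFAULT_MIN_MAPQ = 15
DEFAULT_ANCHOR_LEN = 25
DEFAULT_JOIN_RADIUS = 1_000

Placement = tuple[str, int, str]  # chromosome, 0-based leftmost, strand


class MalformedInputError(ValueError):
    pass


@dataclass(frozen=True)
class DiscordantPair:
    mate1: AlignmentRecord
    mate2: AlignmentRecord
    separation: Optional[int]  # None = interchromosomal

    @property
    def interchromosomal(self) -> bool:
        return self.separation is None


@dataclass(frozen=True)
class AnchorPair:
    read_id: str
    anchor_start: Placement  # from the read's first anchor_len bases
    anchor_end: Placement  # from the read's last anchor_len bases
    implied_breakpoints: tuple[tuple[str, int], tuple[str, int]]


@dataclass
class RearrangementCluster:
    locus_a: tuple[str, tuple[int, int]]
    locus_b: tuple[str, tuple[int, int]]
    n_paired_reads: int
    n_anchor_pairs: int
    breakpoint_estimate: tuple[int, int]
    members: list[str] = field(default_factory=list)
    # annotation hints harvested from the evidence
    anchor_strands: list[tuple[str, str]] = field(default_factory=list)
    pair_strands: list[tuple[str, str]] = field(default_factory=list)
    prefix_side_votes: list[str] = field(default_factory=list)  # 'a' or 'b'


@dataclass(frozen=True)
class FusionCall:
    gene5: str  # gene_id or 'intergenic'
    gene3: str
    cluster: RearrangementCluster
    coding_disrupted: bool
    promoter_class: str  # androgen_regulated / other_active / unknown
    orientation: str  # sense / antisense


# --------------------------------------------------------------------------
# discordant pairs


def _is_discordant(p1: Placement, p2: Placement, min_separation: int) -> bool:
    if p1[0] != p2[0]:
        return True
    return abs(p1[1] - p2[1]) >= min_separation


def find_discordant_pairs(
    alignments: Iterable[AlignmentRecord],
    min_separation: int = DEFAULT_MIN_SEPARATION,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[DiscordantPair]:
    """Collect pairs with both mates aligned, both MAPQ strictly above
    ``min_mapq``, and mates interchromosomal or >= ``min_separation`` apart.

    Duplicate-flagged records are excluded.  Three or more records sharing
    read_id + mate_index indicate malformed input.
    """
    by_read: dict[str, dict[int, AlignmentRecord]] = defaultdict(dict)
    for rec in alignments:
        slot = by_read[rec.read_id]
        if rec.mate_index in slot:
            raise MalformedInputError(
                f"multiple records for {rec.read_id}/{rec.mate_index}"
            )
        slot[rec.mate_index] = rec

    pairs = []
    for read_id in sorted(by_read):
        slot = by_read[read_id]
        if 1 not in slot or 2 not in slot:
            continue
        m1, m2 = slot[1], slot[2]
        if not (m1.aligned and m2.aligned):
            continue
        if m1.duplicate_flag or m2.duplicate_flag:
            continue
        if not (m1.mapq > min_mapq and m2.mapq > min_mapq):
            continue
        if m1.chromosome != m2.chromosome:
            pairs.append(DiscordantPair(m1, m2, None))
        else:
            sep = abs(m1.position - m2.position)
            if sep >= min_separation:
                pairs.append(DiscordantPair(m1, m2, sep))
    return pairs


# --------------------------------------------------------------------------
# anchor splitting and realignment


class UniqueExactAligner:
    """Places a short sequence at its unique exact match in the reference.

    Returns None when the sequence has zero matches or matches more than one
    location (counting both strands) — ambiguous anchors carry no evidence.
    With ``max_mismatches=1`` the best alignment within one mismatch is used
    instead, still requiring a unique optimum.
    """

    def __init__(self, ref: ReferenceModel, max_mismatches: int = 0):
        self.ref = ref
        self.max_mismatches = max_mismatches

    def _exact_hits(self, seq: str) -> list[Placement]:
        hits: list[Placement] = []
        for name, _, chrom_seq in self.ref.chromosomes:
            for query, strand in ((seq, "+"), (revcomp(seq), "-")):
                start = chrom_seq.find(query)
                while start != -1:
                    hits.append((name, start, strand))
                    if len(hits) > 2:
                        return hits
                    start = chrom_seq.find(query, start + 1)
        return hits

    def _edlib_hits(self, seq: str) -> list[Placement]:
        import edlib

        best_d = self.max_mismatches + 1
        hits: list[Placement] = []
        for name, _, chrom_seq in self.ref.chromosomes:
            for query, strand in ((seq, "+"), (revcomp(seq), "-")):
                res = edlib.align(query, chrom_seq, mode="HW", task="locations",
                                  k=self.max_mismatches)
                if res["editDistance"] < 0:
                    continue
                d = res["editDistance"]
                placements = [(name, loc[0], strand) for loc in res["locations"]]
                if d < best_d:
                    best_d, hits = d, placements
                elif d == best_d:
                    hits.extend(placements)
        return hits

    def align(self, seq: str) -> Optional[Placement]:
        hits = self._exact_hits(seq) if self.max_mismatches == 0 else self._edlib_hits(seq)
        return hits[0] if len(hits) == 1 else None


def _implied_breakpoint(placement: Placement, anchor_len: int, is_prefix: bool) -> tuple[str, int]:
    """Coordinate of the anchor end facing the junction."""
    chrom, pos, strand = placement
    if is_prefix:
        return (chrom, pos + anchor_len if strand == "+" else pos)
    return (chrom, pos if strand == "+" else pos + anchor_len)


def split_and_realign_anchors(
    unaligned_mates: Iterable[AlignmentRecord],
    ref: ReferenceModel,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    aligner=None,
) -> list[AnchorPair]:
    """Split each unaligned mate into terminal anchors, realign both and
    keep pairs whose placements are discordant.

    Mates shorter than two anchors are skipped; the skip count is exposed on
    the function attribute ``split_and_realign_anchors.skipped_short``.
    """
    if aligner is None:
        aligner = UniqueExactAligner(ref)
    out: list[AnchorPair] = []
    skipped = 0
    for rec in unaligned_mates:
        if rec.aligned:
            continue
        seq = rec.sequence
        if len(seq) < 2 * anchor_len:
            skipped += 1
            continue
        p_start = aligner.align(seq[:anchor_len])
        p_end = aligner.align(seq[-anchor_len:])
        if p_start is None or p_end is None:
            continue
        if not _is_discordant(p_start, p_end, min_separation):
            continue
        out.append(
            AnchorPair(
                read_id=rec.read_id,
                anchor_start=p_start,
                anchor_end=p_end,
                implied_breakpoints=(
                    _implied_breakpoint(p_start, anchor_len, is_prefix=True),
                    _implied_breakpoint(p_end, anchor_len, is_prefix=False),
                ),
            )
        )
    out_list = out
    # expose the warning count without changing the return type
    split_and_realign_anchors.skipped_short = skipped  # type: ignore[attr-defined]
    return out_list


# --------------------------------------------------------------------------
# clustering


@dataclass(frozen=True)
class _Evidence:
    kind: str  # 'pair' or 'anchor'
    read_id: str
    side_a: Placement
    side_b: Placement
    prefix_is_a: Optional[bool]  # anchors only


def _canonical(ev_kind: str, read_id: str, p1: Placement, p2: Placement,
               prefix_first: Optional[bool]) -> _Evidence:
    if (p1[0], p1[1]) <= (p2[0], p2[1]):
        return _Evidence(ev_kind, read_id, p1, p2, prefix_first)
    flipped = None if prefix_first is None else not prefix_first
    return _Evidence(ev_kind, read_id, p2, p1, flipped)


def _mode_smallest(values: Sequence[int]) -> int:
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def cluster_evidence(
    pairs: Sequence[DiscordantPair],
    anchors: Sequence[AnchorPair],
    join_radius: int = DEFAULT_JOIN_RADIUS,
) -> list[RearrangementCluster]:
    """Single-linkage clustering of evidence on both loci.

    Items merge transitively when their canonicalized locus pairs lie on the
    same chromosome pair and within ``join_radius`` on both sides.  Output is
    invariant under input order (evidence is canonically sorted first).
    """
    evidence: list[_Evidence] = []
    for p in pairs:
        m1, m2 = p.mate1, p.mate2
        evidence.append(
            _canonical("pair", m1.read_id,
                       (m1.chromosome, m1.position, m1.strand),
                       (m2.chromosome, m2.position, m2.strand), None)
        )
    for a in anchors:
        bp_a, bp_b = a.implied_breakpoints
        evidence.append(
            _canonical("anchor", a.read_id,
                       (bp_a[0], bp_a[1], a.anchor_start[2]),
                       (bp_b[0], bp_b[1], a.anchor_end[2]), True)
        )
    evidence.sort(key=lambda e: (e.side_a[0], e.side_b[0], e.side_a[1], e.side_b[1], e.read_id))

    # union-find restricted to identical chromosome pairs
    parent = list(range(len(evidence)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_chrom_pair: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, ev in enumerate(evidence):
        by_chrom_pair[(ev.side_a[0], ev.side_b[0])].append(i)
    for idxs in by_chrom_pair.values():
        for ii, i in enumerate(idxs):
            for j in idxs[ii + 1:]:
                ei, ej = evidence[i], evidence[j]
                if (abs(ei.side_a[1] - ej.side_a[1]) <= join_radius
                        and abs(ei.side_b[1] - ej.side_b[1]) <= join_radius):
                    parent[find(i)] = find(j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(evidence)):
        groups[find(i)].append(i)

    clusters = []
    for root in sorted(groups, key=lambda r: (evidence[r].side_a, evidence[r].side_b)):
        members = [evidence[i] for i in groups[root]]
        chrom_a = members[0].side_a[0]
        chrom_b = members[0].side_b[0]
        pos_a = [m.side_a[1] for m in members]
        pos_b = [m.side_b[1] for m in members]
        anchor_members = [m for m in members if m.kind == "anchor"]
        pair_members = [m for m in members if m.kind == "pair"]
        if anchor_members:
            est = (_mode_smallest([m.side_a[1] for m in anchor_members]),
                   _mode_smallest([m.side_b[1] for m in anchor_members]))
        else:
            # inner edges of paired reads: right end on '+', left end on '-'
            def inner(placement: Placement) -> int:
                _, pos, strand = placement
                return pos + 90 if strand == "+" else pos

            est = (int(sum(inner(m.side_a) for m in pair_members) / len(pair_members)),
                   int(sum(inner(m.side_b) for m in pair_members) / len(pair_members)))
        clusters.append(
            RearrangementCluster(
                locus_a=(chrom_a, (min(pos_a), max(pos_a) + 1)),
                locus_b=(chrom_b, (min(pos_b), max(pos_b) + 1)),
                n_paired_reads=len({m.read_id for m in pair_members}),
                n_anchor_pairs=len({m.read_id for m in anchor_members}),
                breakpoint_estimate=est,
                members=[m.read_id for m in members],
                anchor_strands=[(m.side_a[2], m.side_b[2]) for m in anchor_members],
                pair_strands=[(m.side_a[2], m.side_b[2]) for m in pair_members],
                prefix_side_votes=["a" if m.prefix_is_a else "b" for m in anchor_members],
            )
        )
    return clusters


def filter_clusters(clusters: Sequence[RearrangementCluster]) -> list[RearrangementCluster]:
    """Support filter: keep clusters with >=1 paired read and >=5 anchor
    pairs, or with >=20 anchor pairs.  Pure predicate; order preserved."""
    return [
        c for c in clusters
        if (c.n_paired_reads >= 1 and c.n_anchor_pairs >= 5) or c.n_anchor_pairs >= 20
    ]


# --------------------------------------------------------------------------
# annotation


def _gene_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.chromosome][g.start:g.end] = g
    return trees


def _gene_at(trees: dict[str, IntervalTree], chrom: str, pos: int) -> Optional[GeneModel]:
    hits = trees.get(chrom, IntervalTree())[pos]
    if not hits:
        return None
    return sorted(hits, key=lambda iv: iv.data.gene_id)[0].data


def _modal(items: Sequence) -> Optional[object]:
    if not items:
        return None
    counts = Counter(items)
    best = max(counts.values())
    return sorted(k for k, c in counts.items() if c == best)[0]


def annotate_fusion(
    cluster: RearrangementCluster,
    genes: Sequence[GeneModel],
    chrom_lengths: Optional[dict[str, int]] = None,
) -> FusionCall:
    """Interpret a cluster against gene models.

    5'/3' roles come from the anchor evidence when available (the prefix
    anchor of a junction-spanning read lies on the promoter-donating side);
    for pair-only clusters the androgen-regulated gene, if unambiguous, is
    taken as the 5' partner.  Orientation: anchors of one read map to the
    same strand for a sense junction and to opposite strands for an
    antisense one; straddling-pair mates behave the opposite way.
    """
    (chrom_a, _), (chrom_b, _) = cluster.locus_a, cluster.locus_b
    pos_a, pos_b = cluster.breakpoint_estimate
    if chrom_lengths is not None:
        for chrom, pos in ((chrom_a, pos_a), (chrom_b, pos_b)):
            if chrom not in chrom_lengths or not 0 <= pos <= chrom_lengths[chrom]:
                raise ValueError(f"breakpoint {chrom}:{pos} outside all chromosomes")

    trees = _gene_trees(genes)
    gene_a = _gene_at(trees, chrom_a, pos_a)
    gene_b = _gene_at(trees, chrom_b, pos_b)

    if cluster.anchor_strands:
        strands = _modal(cluster.anchor_strands)
        orientation = "sense" if strands[0] == strands[1] else "antisense"
    elif cluster.pair_strands:
        strands = _modal(cluster.pair_strands)
        orientation = "sense" if strands[0] != strands[1] else "antisense"
    else:
        orientation = "sense"

    prefix_side = _modal(cluster.prefix_side_votes)
    if prefix_side is None:
        flag_a = gene_a is not None and gene_a.androgen_regulated
        flag_b = gene_b is not None and gene_b.androgen_regulated
        prefix_side = "b" if (flag_b and not flag_a) else "a"

    if prefix_side == "a":
        g5, g3, pos3 = gene_a, gene_b, pos_b
    else:
        g5, g3, pos3 = gene_b, gene_a, pos_a

    coding_disrupted = False
    if g3 is not None and g3.coding_region is not None:
        cs, ce = g3.coding_region
        coding_disrupted = cs < pos3 < ce

    if g5 is None:
        promoter_class = "unknown"
    elif g5.androgen_regulated:
        promoter_class = "androgen_regulated"
    else:
        promoter_class = "other_active"

    return FusionCall(
        gene5=g5.gene_id if g5 else "intergenic",
        gene3=g3.gene_id if g3 else "intergenic",
        cluster=cluster,
        coding_disrupted=coding_disrupted,
        promoter_class=promoter_class,
        orientation=orientation,
    )


# --------------------------------------------------------------------------
# end-to-end convenience


def call_fusions(
    alignments: Iterable[AlignmentRecord],
    ref: ReferenceModel,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    join_radius: int = DEFAULT_JOIN_RADIUS,
    aligner=None,
) -> list[FusionCall]:
    records = list(alignments)
    pairs = find_discordant_pairs(records, min_separation, min_mapq)
    unaligned = [r for r in records if not r.aligned]
    anchors = split_and_realign_anchors(unaligned, ref, anchor_len, min_separation, aligner)
    clusters = filter_clusters(cluster_evidence(pairs, anchors, join_radius))
    lengths = ref.lengths
    return [annotate_fusion(c, ref.genes, lengths) for c in clusters]
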