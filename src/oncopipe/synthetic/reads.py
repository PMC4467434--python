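"""Paired-end alignment simulation with planted genomic rearrangements.

Three evidence classes are emitted, mirroring what a split-anchor
rearrangement caller consumes:

* concordant background pairs (both mates aligned, short insert);
* pairs straddling a planted junction — both mates aligned, far apart or on
  different chromosomes (discordant pairs);
* junction-spanning mates emitted as UNALIGNED records whose 90 bp sequence
  crosses the breakpoint, so the two 25 bp terminal anchors map to the two
  partner loci.

A sense junction joins the sequence left of ``breakpoint5`` to the sequence
right of ``breakpoint3``.  An antisense junction (the ACPP–SKIL geometry:
the 5' promoter placed downstream of the 3' gene in opposite orientation)
continues from ``breakpoint3`` leftward on the minus strand instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..genome import ReferenceModel, revcomp
from ..samio import AlignmentRecord
from .config import SimulationConfig

ANCHOR_LEN = 25


@dataclass(frozen=True)
class RearrangementTruth:
    partner5: str
    partner3: str
    breakpoint5: tuple[str, int]
    breakpoint3: tuple[str, int]
    orientation: str = "sense"  # or "antisense"
    disrupts_coding3: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in {"sense", "antisense"}:
            raise ValueError("orientation must be 'sense' or 'antisense'")

    def validate(self, ref: ReferenceModel) -> None:
        lengths = ref.lengths
        for chrom, pos in (self.breakpoint5, self.breakpoint3):
            if chrom not in lengths or not 0 <= pos < lengths[chrom]:
                raise ValueError(f"breakpoint {chrom}:{pos} outside reference")

    def to_dict(self) -> dict:
        return {
            "partner5": self.partner5,
            "partner3": self.partner3,
            "breakpoint5": list(self.breakpoint5),
            "breakpoint3": list(self.breakpoint3),
            "orientation": self.orientation,
            "disrupts_coding3": self.disrupts_coding3,
        }


def default_fusion_truth(ref: ReferenceModel, orientation: str = "sense") -> RearrangementTruth:
    """A TMPRSS2L->SKIL promoter-swap: breakpoint in the 5' gene's intron 3,
    partner breakpoint upstream of the SKIL-like coding start."""
    g5 = ref.gene("TMPRSS2L")
    g3 = ref.gene("SKIL")
    bp5 = (g5.chromosome, g5.exons[2][1] + 1_000)  # intron 3
    bp3 = (g3.chromosome, g3.coding_region[0] - 150)  # inside gene, upstream of CDS
    return RearrangementTruth(
        partner5=g5.gene_id,
        partner3=g3.gene_id,
        breakpoint5=bp5,
        breakpoint3=bp3,
        orientation=orientation,
        disrupts_coding3=False,
    )


def _junction_read(ref: ReferenceModel, truth: RearrangementTruth, split: int, read_length: int) -> str:
    """Read sequence crossing the junction; first ``split`` bases come from
    the 5' side, the rest from the 3' side."""
    c5, p5 = truth.breakpoint5
    c3, p3 = truth.breakpoint3
    left = ref.fetch(c5, p5 - split, p5)
    n = read_length - split
    if truth.orientation == "sense":
        right = ref.fetch(c3, p3, p3 + n)
    else:
        right = revcomp(ref.fetch(c3, p3 - n, p3))
    return left + right


def simulate_rearranged_alignments(
    ref: ReferenceModel,
    truths: list[RearrangementTruth],
    config: SimulationConfig,
) -> tuple[list[AlignmentRecord], list[dict]]:
    """Emit alignment records plus a per-read truth sidecar.

    Returns ``(records, sidecar)`` where each sidecar entry records the
    read's class (background / background_discordant / straddling /
    spanning), its planted coordinates and, for spanning mates, where each
    25 bp terminal anchor should realign.
    """
    for truth in truths:
        truth.validate(ref)
    if config.fragment_mean > min(ref.lengths.values()):
        raise ValueError("fragment size exceeds chromosome length")

    rng = np.random.default_rng(config.seed)
    L = config.read_length
    records: list[AlignmentRecord] = []
    sidecar: list[dict] = []
    lengths = ref.lengths
    names = ref.names
    weights = np.array([lengths[n] for n in names], dtype=float)
    weights /= weights.sum()

    def draw_mapq() -> int:
        return int(rng.integers(config.mapq_floor, 61))

    # --- concordant background -------------------------------------------
    for i in range(config.n_background_pairs):
        chrom = names[rng.choice(len(names), p=weights)]
        insert = max(2 * L + 10, int(rng.normal(config.fragment_mean, config.fragment_sd)))
        pos1 = int(rng.integers(0, lengths[chrom] - insert - 1))
        pos2 = pos1 + insert - L
        rid = f"bg{i:06d}"
        records.append(AlignmentRecord(rid, 1, True, chrom, pos1, "+", draw_mapq(), ref.fetch(chrom, pos1, pos1 + L)))
        records.append(AlignmentRecord(rid, 2, True, chrom, pos2, "-", draw_mapq(), revcomp(ref.fetch(chrom, pos2, pos2 + L))))
        sidecar.append({"read_id": rid, "class": "background", "truth_index": None})

    # --- background discordant noise -------------------------------------
    n_noise = rng.binomial(config.n_background_pairs, config.background_discordant_rate)
    for i in range(n_noise):
        c1, c2 = rng.choice(len(names), size=2, replace=False)
        chrom1, chrom2 = names[c1], names[c2]
        pos1 = int(rng.integers(0, lengths[chrom1] - L))
        pos2 = int(rng.integers(0, lengths[chrom2] - L))
        rid = f"nz{i:06d}"
        records.append(AlignmentRecord(rid, 1, True, chrom1, pos1, "+", draw_mapq(), ref.fetch(chrom1, pos1, pos1 + L)))
        records.append(AlignmentRecord(rid, 2, True, chrom2, pos2, "-", draw_mapq(), revcomp(ref.fetch(chrom2, pos2, pos2 + L))))
        sidecar.append({"read_id": rid, "class": "background_discordant", "truth_index": None})

    # --- planted junction evidence ----------------------------------------
    for t_idx, truth in enumerate(truths):
        c5, p5 = truth.breakpoint5
        c3, p3 = truth.breakpoint3

        for i in range(config.n_straddling_pairs):
            d1 = int(rng.integers(5, 80))
            d2 = int(rng.integers(5, 80))
            pos1 = p5 - d1 - L
            seq1 = ref.fetch(c5, pos1, pos1 + L)
            if truth.orientation == "sense":
                pos2, strand2 = p3 + d2, "-"
                seq2 = revcomp(ref.fetch(c3, pos2, pos2 + L))
            else:
                pos2, strand2 = p3 - d2 - L, "+"
                seq2 = ref.fetch(c3, pos2, pos2 + L)
            rid = f"str{t_idx}_{i:04d}"
            records.append(AlignmentRecord(rid, 1, True, c5, pos1, "+", draw_mapq(), seq1))
            records.append(AlignmentRecord(rid, 2, True, c3, pos2, strand2, draw_mapq(), seq2))
            sidecar.append({"read_id": rid, "class": "straddling", "truth_index": t_idx})

        for i in range(config.n_spanning_mates):
            split = int(rng.integers(ANCHOR_LEN + 5, L - ANCHOR_LEN - 5 + 1))
            seq = _junction_read(ref, truth, split, L)
            rid = f"spn{t_idx}_{i:04d}"
            # the spanning read's partner aligns normally on the 5' side
            d1 = int(rng.integers(5, 80))
            pos1 = p5 - split - d1 - L
            records.append(AlignmentRecord(rid, 1, True, c5, pos1, "+", draw_mapq(), ref.fetch(c5, pos1, pos1 + L)))
            records.append(AlignmentRecord(rid, 2, False, None, None, None, 0, seq))
            # expected anchor placements (0-based leftmost, strand)
            prefix = (c5, p5 - split, "+")
            n3 = L - split
            if truth.orientation == "sense":
                suffix = (c3, p3 + n3 - ANCHOR_LEN, "+")
            else:
                suffix = (c3, p3 - n3, "-")
            sidecar.append(
                {
                    "read_id": rid,
                    "class": "spanning",
                    "truth_index": t_idx,
                    "split": split,
                    "anchor_prefix": list(prefix),
                    "anchor_suffix": list(suffix),
                }
            )

    return records, sidecar
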