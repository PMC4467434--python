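"""Alignment records and SAM round-tripping.

The rearrangement caller consumes a minimal view of each paired-end record:
identity, mate index, coordinate (or unaligned status), strand, MAPQ,
sequence and the duplicate flag.  pysam handles the SAM dialect; internal
coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pysam

from .genome import ReferenceModel


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    mate_index: int  # 1 or 2
    aligned: bool
    chromosome: Optional[str]
    position: Optional[int]  # 0-based leftmost
    strand: Optional[str]
    mapq: int
    sequence: str
    duplicate_flag: bool = False

    def __post_init__(self) -> None:
        if self.mate_index not in (1, 2):
            raise ValueError("mate_index must be 1 or 2")
        if not 0 <= self.mapq <= 255:
            raise ValueError("mapq must be in [0, 255]")
        if self.aligned and (self.chromosome is None or self.position is None):
            raise ValueError("aligned record needs chromosome and position")
        if not self.aligned and (self.chromosome is not None or self.position is not None):
            raise ValueError("unaligned record must not carry a coordinate")


def write_sam(records: Iterable[AlignmentRecord], path: str, ref: ReferenceModel) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length, _ in ref.chromosomes],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.sequence
            a.mapping_quality = rec.mapq
            flag = 0x1  # paired
            flag |= 0x40 if rec.mate_index == 1 else 0x80
            if rec.duplicate_flag:
                flag |= 0x400
            if rec.aligned:
                if rec.strand == "-":
                    flag |= 0x10
                a.reference_id = out.header.get_tid(rec.chromosome)
                a.reference_start = rec.position
                a.cigarstring = f"{len(rec.sequence)}M"
            else:
                flag |= 0x4
            a.flag = flag
            out.write(a)


def read_sam(path: str) -> list[AlignmentRecord]:
    records = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            aligned = not a.is_unmapped
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    mate_index=2 if a.is_read2 else 1,
                    aligned=aligned,
                    chromosome=a.reference_name if aligned else None,
                    position=a.reference_start if aligned else None,
                    strand=("-" if a.is_reverse else "+") if aligned else None,
                    mapq=a.mapping_quality,
                    sequence=a.query_sequence or "",
                    duplicate_flag=a.is_duplicate,
                )
            )
    return records
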