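"""Reference genome and gene models.

All coordinates are 0-based half-open internally; SAM emission converts to
1-based per the standard.  The ploidy map reflects a male genome: autosomes
are diploid, X and Y haploid, and copy-number arithmetic downstream is done
per chromosome against this expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def chromosome_ploidy(name: str) -> int:
    """Default ploidy for a chromosome name (male genome: X/Y haploid)."""
    base = name[3:] if name.lower().startswith("chr") else name
    return 1 if base.upper() in {"X", "Y"} else 2


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure and optional coding region.

    ``exons`` are sorted, non-overlapping 0-based half-open intervals on
    ``chromosome``; ``coding_region`` (if present) lies within the gene span.
    ``androgen_regulated`` marks promoters under androgen-receptor control
    (TMPRSS2, SLC45A3, ACPP, MIPOL1 class) — the 5' partners of the
    promoter-swap fusions this package detects.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    coding_region: Optional[tuple[int, int]] = None
    androgen_regulated: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have at least one exon")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.gene_id}: empty exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = end
        if self.coding_region is not None:
            cs, ce = self.coding_region
            if not (self.start <= cs < ce <= self.end):
                raise ValueError(
                    f"{self.gene_id}: coding region [{cs}, {ce}) outside gene span"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def total_exon_length_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start <= position < self.end


@dataclass
class ReferenceModel:
    """A small multi-chromosome reference with gene models and a ploidy map."""

    chromosomes: list[tuple[str, int, str]]  # (name, length, sequence)
    genes: list[GeneModel] = field(default_factory=list)
    ploidy_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length, seq in self.chromosomes:
            if len(seq) != length:
                raise ValueError(f"{name}: sequence length {len(seq)} != {length}")
        lengths = self.lengths
        for gene in self.genes:
            if gene.chromosome not in lengths:
                raise ValueError(f"{gene.gene_id}: unknown chromosome {gene.chromosome}")
            if gene.end > lengths[gene.chromosome]:
                raise ValueError(
                    f"{gene.gene_id}: interval [{gene.start}, {gene.end}) exceeds "
                    f"{gene.chromosome} length {lengths[gene.chromosome]}"
                )
        for name in names:
            self.ploidy_map.setdefault(name, chromosome_ploidy(name))
        if any(p < 1 for p in self.ploidy_map.values()):
            raise ValueError("ploidy must be >= 1")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: length for name, length, _ in self.chromosomes}

    def sequence(self, chromosome: str) -> str:
        for name, _, seq in self.chromosomes:
            if name == chromosome:
                return seq
        raise KeyError(chromosome)

    def fetch(self, chromosome: str, start: int, end: int) -> str:
        seq = self.sequence(chromosome)
        if start < 0 or end > len(seq):
            raise ValueError(f"interval [{start}, {end}) outside {chromosome}")
        return seq[start:end]

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, _, seq in self.chromosomes:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_genes_tsv(self, path: str) -> None:
        write_genes_tsv(self.genes, path)


def write_genes_tsv(genes: Sequence[GeneModel], path: str) -> None:
    """Serialize gene models to a BED12-style TSV (block columns for exons)."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
                "coding_start": "" if g.coding_region is None else g.coding_region[0],
                "coding_end": "" if g.coding_region is None else g.coding_region[1],
                "androgen_regulated": int(g.androgen_regulated),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genes_tsv(path: str) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"coding_start": "Int64", "coding_end": "Int64"})
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        coding = None
        if pd.notna(row.coding_start) and pd.notna(row.coding_end):
            coding = (int(row.coding_start), int(row.coding_end))
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chromosome=str(row.chromosome),
                strand=str(row.strand),
                exons=tuple(zip(starts, ends)),
                coding_region=coding,
                androgen_regulated=bool(row.androgen_regulated),
            )
        )
    return genes


def read_fasta(path: str) -> list[tuple[str, int, str]]:
    chroms: list[tuple[str, int, str]] = []
    name, parts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seq = "".join(parts)
                    chroms.append((name, len(seq), seq))
                name, parts = line[1:].split()[0], []
            elif line:
                parts.append(line)
    if name is not None:
        seq = "".join(parts)
        chroms.append((name, len(seq), seq))
    return chroms
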