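"""Random reference genomes with planted gene models.

The default layout mimics the prostate-cancer setting: an androgen-regulated
5' partner gene (TMPRSS2-like) and a SKIL-like 3' target on different
chromosomes, plus ETS-family and SPINK1-like subtype genes used by the
expression stage.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from ..genome import GeneModel, ReferenceModel

_BASES = np.array(list("ACGT"))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _make_gene(spec: dict) -> GeneModel:
    return GeneModel(
        gene_id=spec["gene_id"],
        chromosome=spec["chromosome"],
        strand=spec.get("strand", "+"),
        exons=tuple(tuple(e) for e in spec["exons"]),
        coding_region=tuple(spec["coding_region"]) if spec.get("coding_region") else None,
        androgen_regulated=bool(spec.get("androgen_regulated", False)),
    )


def example_gene_spec(chrom_length: int = 2_000_000) -> list[dict]:
    """Seven genes over three chromosomes: two androgen-regulated 5'
    partners, a SKIL-like 3' gene, and the expression-subtype genes."""

    exon = 600
    intron = min(3_000, max(500, chrom_length // 200))
    unit = exon + intron

    def exons(start: int, n: int):
        return [(start + i * unit, start + i * unit + exon) for i in range(n)]

    def gene(gene_id, chrom, frac, n, androgen=False):
        start = int(chrom_length * frac)
        ex = exons(start, n)
        return {
            "gene_id": gene_id,
            "chromosome": chrom,
            "exons": ex,
            "coding_region": (start + exon // 2, ex[-1][1] - exon // 3),
            "androgen_regulated": androgen,
        }

    return [
        gene("TMPRSS2L", "chr1", 0.10, 8, androgen=True),
        gene("ACPPL", "chr1", 0.75, 6, androgen=True),
        gene("SKIL", "chr2", 0.15, 7),
        gene("ERG", "chr2", 0.70, 5),
        gene("ETV1", "chr3", 0.10, 5),
        gene("ETV4", "chr3", 0.40, 5),
        gene("SPINK1", "chr3", 0.68, 4),
    ]


def simulate_reference(
    n_chromosomes: int = 3,
    chrom_length: int = 2_000_000,
    gene_spec: Optional[Sequence[dict]] = None,
    seed: int = 0,
    chromosome_names: Optional[Sequence[str]] = None,
) -> ReferenceModel:
    """Generate a random reference with the requested gene models planted.

    Deterministic for a fixed seed.  Gene intervals beyond a chromosome end
    are rejected with a diagnostic (via ReferenceModel validation).
    """
    if chrom_length < 100_000:
        raise ValueError("chrom_length must be >= 100 kb")
    if chromosome_names is None:
        chromosome_names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    if len(chromosome_names) != n_chromosomes:
        raise ValueError("chromosome_names length mismatch")
    if gene_spec is None:
        gene_spec = example_gene_spec(chrom_length)
    if not gene_spec:
        raise ValueError("gene_spec must be nonempty")

    rng = np.random.default_rng(seed)
    chroms = [(name, chrom_length, _random_sequence(rng, chrom_length)) for name in chromosome_names]
    genes = [_make_gene(spec) for spec in gene_spec]
    return ReferenceModel(chromosomes=chroms, genes=genes)
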