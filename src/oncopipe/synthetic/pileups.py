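"""Per-site pileup tables with planted somatic and germline variants.

Germline sites appear in the tumor and in every benign (BPH) sample;
somatic sites only in the tumor.  Alt counts are binomial around the
planted allele fraction.  Sites may additionally be flagged as known
population polymorphisms for the downstream germline filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..genome import ReferenceModel
from .config import SimulationConfig

_ALT = {"A": "G", "C": "T", "G": "A", "T": "C"}


@dataclass(frozen=True)
class VariantTruth:
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    somatic: bool
    allele_fraction: float = 0.5
    in_population_list: bool = False

    def key(self) -> tuple:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "position": self.position,
            "ref_allele": self.ref_allele,
            "alt_allele": self.alt_allele,
            "somatic": self.somatic,
            "allele_fraction": self.allele_fraction,
            "in_population_list": self.in_population_list,
        }


def random_variant_truth(
    ref: ReferenceModel,
    n_somatic: int,
    n_germline: int,
    n_population: int,
    seed: int,
    somatic_fraction: float = 0.4,
    germline_fraction: float = 0.5,
) -> list[VariantTruth]:
    """Draw distinct variant sites across the reference.

    Population-polymorphism sites are germline sites additionally present in
    the user-supplied exclusion list.
    """
    rng = np.random.default_rng(seed)
    lengths = ref.lengths
    names = ref.names
    seen: set[tuple[str, int]] = set()
    out: list[VariantTruth] = []
    specs = (
        [("somatic", somatic_fraction)] * n_somatic
        + [("germline", germline_fraction)] * n_germline
        + [("population", germline_fraction)] * n_population
    )
    for kind, frac in specs:
        while True:
            chrom = names[rng.integers(0, len(names))]
            pos = int(rng.integers(0, lengths[chrom]))
            if (chrom, pos) not in seen:
                seen.add((chrom, pos))
                break
        base = ref.fetch(chrom, pos, pos + 1)
        out.append(
            VariantTruth(
                chromosome=chrom,
                position=pos,
                ref_allele=base,
                alt_allele=_ALT[base],
                somatic=kind == "somatic",
                allele_fraction=frac,
                in_population_list=kind == "population",
            )
        )
    return out


def simulate_pileups(
    ref: ReferenceModel,
    variant_truth: list[VariantTruth],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[pd.DataFrame], list[dict]]:
    """Build (tumor_pileup, bph_pileups, sidecar) tables.

    Depth is Poisson around ``config.depth``; alt counts binomial at the
    planted fraction (never exceeding depth by construction).
    """
    rng = np.random.default_rng(config.seed)

    def site_rows(truths, fraction_of) -> pd.DataFrame:
        rows = []
        for t in truths:
            depth = max(8, int(rng.poisson(config.depth)))
            alt = int(rng.binomial(depth, fraction_of(t)))
            rows.append(
                {
                    "chromosome": t.chromosome,
                    "position": t.position,
                    "ref_allele": t.ref_allele,
                    "alt_allele": t.alt_allele,
                    "alt_count": alt,
                    "total_count": depth,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["chromosome", "position", "ref_allele", "alt_allele", "alt_count", "total_count"],
        )

    tumor = site_rows(variant_truth, lambda t: t.allele_fraction)
    germline = [t for t in variant_truth if not t.somatic]
    bph_tables = [
        site_rows(germline, lambda t: t.allele_fraction) for _ in range(config.n_bph_controls)
    ]
    sidecar = [t.to_dict() for t in variant_truth]
    return tumor, bph_tables, sidecar


def population_site_table(variant_truth: list[VariantTruth]) -> pd.DataFrame:
    """The exclusion list a user would supply (1000 Genomes-style sites)."""
    rows = [
        {
            "chromosome": t.chromosome,
            "position": t.position,
            "ref_allele": t.ref_allele,
            "alt_allele": t.alt_allele,
        }
        for t in variant_truth
        if t.in_population_list
    ]
    return pd.DataFrame(rows, columns=["chromosome", "position", "ref_allele", "alt_allele"])
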