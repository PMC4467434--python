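"""RNA-seq somatic-variant heuristic with germline filtering.

Calling is asymmetric by sample role: a tumor (PC/CRPC) site is called when
at least 4 reads AND at least 15% of reads show the alternate allele;
benign (BPH) calling is deliberately more permissive — at least 2 reads and
at least 5% — so that germline variants are caught even at low coverage.
Tumor pileups are expected to be built after duplicate removal and with
low-quality alignments (MAPQ < 10) excluded; benign pileups use all
alignments.  Any tumor call seen in a benign sample or in a user-supplied
population site list (1000 Genomes / ESP6500 / SISU style) is filtered out;
the remainder are candidate somatic mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .genome import GeneModel
from .samio import AlignmentRecord

TUMOR_MIN_ALT = 4
TUMOR_MIN_FRACTION = 0.15
BENIGN_MIN_ALT = 2
BENIGN_MIN_FRACTION = 0.05
MIN_MAPQ_TUMOR = 10

SiteKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class PileupSite:
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    alt_count: int
    total_count: int
    sample_id: str = ""
    sample_role: str = "tumor"

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.total_count:
            raise ValueError("alt_count must lie in [0, total_count]")

    def key(self) -> SiteKey:
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class VariantCall:
    site: PileupSite
    alt_fraction: float
    called: bool
    somatic_status: Optional[str] = None  # candidate_somatic / germline_in_benign / population_polymorphism


def thresholds_for_role(role: str) -> tuple[int, float]:
    if role == "tumor":
        return TUMOR_MIN_ALT, TUMOR_MIN_FRACTION
    if role == "benign":
        return BENIGN_MIN_ALT, BENIGN_MIN_FRACTION
    raise ValueError("role must be 'tumor' or 'benign'")


def sites_from_frame(table: pd.DataFrame, sample_id: str = "", role: str = "tumor") -> list[PileupSite]:
    return [
        PileupSite(
            chromosome=str(r.chromosome),
            position=int(r.position),
            ref_allele=str(r.ref_allele),
            alt_allele=str(r.alt_allele),
            alt_count=int(r.alt_count),
            total_count=int(r.total_count),
            sample_id=sample_id,
            sample_role=role,
        )
        for r in table.itertuples(index=False)
    ]


def call_variants(pileup: Iterable[PileupSite], role: str) -> list[VariantCall]:
    """Apply the role-specific alt-count and alt-fraction thresholds
    (both inclusive).  Zero-depth sites are skipped."""
    min_alt, min_frac = thresholds_for_role(role)
    calls = []
    for site in pileup:
        if site.total_count == 0:
            continue
        frac = site.alt_count / site.total_count
        called = site.alt_count >= min_alt and frac >= min_frac
        if called:
            calls.append(VariantCall(site=site, alt_fraction=frac, called=True))
    return calls


def read_population_sites(path: str) -> set[SiteKey]:
    """Load a population-polymorphism exclusion list.

    Accepts a sites-only VCF (via pysam) or a TSV with columns
    chromosome/position/ref_allele/alt_allele (0-based positions).
    Malformed TSV rows raise with the offending line number.
    """
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        import pysam

        keys: set[SiteKey] = set()
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    keys.add((rec.chrom, rec.start, rec.ref, alt))
        return keys
    keys = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = ["chromosome", "position", "ref_allele", "alt_allele"]
        if any(c not in idx for c in required):
            raise ValueError(f"{path}:1: header must contain {required}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            try:
                keys.add((parts[idx["chromosome"]], int(parts[idx["position"]]),
                          parts[idx["ref_allele"]], parts[idx["alt_allele"]]))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed population site row") from exc
    return keys


def filter_germline(
    tumor_calls: Sequence[VariantCall],
    benign_calls: Sequence[VariantCall],
    population_sites: set[SiteKey] | Sequence[set[SiteKey]] = (),
) -> list[VariantCall]:
    """Remove tumor calls seen in any benign sample or population list;
    the survivors are returned tagged ``candidate_somatic``."""
    if isinstance(population_sites, set):
        population_sites = [population_sites]
    pop: set[SiteKey] = set().union(*population_sites) if population_sites else set()
    benign_keys = {c.site.key() for c in benign_calls}
    out = []
    for call in tumor_calls:
        key = call.site.key()
        if key in benign_keys:
            status = "germline_in_benign"
        elif key in pop:
            status = "population_polymorphism"
        else:
            status = "candidate_somatic"
        if status == "candidate_somatic":
            out.append(VariantCall(call.site, call.alt_fraction, True, status))
    return out


def deduplicate_alignments(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Coordinate+strand-keyed duplicate removal (samtools-rmdup-like),
    applied before pileup construction for tumor samples.  The first record
    at each (chromosome, position, strand, mate_index) key is kept."""
    seen = set()
    out = []
    for rec in records:
        if not rec.aligned:
            out.append(rec)
            continue
        key = (rec.chromosome, rec.position, rec.strand, rec.mate_index)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def classify_region(call: VariantCall, genes: Sequence[GeneModel]) -> str:
    """Optional gene-overlap annotation: coding / genic_noncoding / intergenic."""
    for g in genes:
        if g.contains(call.site.chromosome, call.site.position):
            if g.coding_region is not None:
                cs, ce = g.coding_region
                if cs <= call.site.position < ce:
                    return "coding"
            return "genic_noncoding"
    return "intergenic"


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chromosome": c.site.chromosome,
                "position": c.site.position,
                "ref_allele": c.site.ref_allele,
                "alt_allele": c.site.alt_allele,
                "alt_count": c.site.alt_count,
                "total_count": c.site.total_count,
                "alt_fraction": c.alt_fraction,
                "somatic_status": c.somatic_status or "",
            }
            for c in calls
        ],
        columns=["chromosome", "position", "ref_allele", "alt_allele", "alt_count",
                 "total_count", "alt_fraction", "somatic_status"],
    )
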