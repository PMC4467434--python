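"""End-to-end orchestration over file-based stage contracts.

The orchestrator adds nothing computational: each stage (rearrangement
calling, copy number, somatic variants, expression) is independently
runnable, and ``run_all`` simply executes the stages whose inputs are
configured, in dependency order, collecting per-sample reports.  Reports
are regenerable byte-identically from inputs + config + seed; the resolved
config and its hash are recorded in every artifact.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from . import breakfast as bf
from . import cnv as cnvmod
from . import expr as exprmod
from . import rnavar
from .genome import ReferenceModel, read_fasta, read_genes_tsv
from .samio import read_sam

_KNOWN_KEYS = {
    "seed", "sample_id", "output_dir", "reference", "fusion", "cnv", "rnavar", "expr",
}
_KNOWN_SUBKEYS = {
    "reference": {"fasta", "genes"},
    "fusion": {"sam", "min_separation", "min_mapq", "anchor_len", "join_radius"},
    "cnv": {"tumor_counts", "control_counts", "purity", "window_size", "step",
            "filter_length", "bin_width", "threshold", "excluded_chromosomes"},
    "rnavar": {"tumor_pileup", "benign_pileups", "population_sites"},
    "expr": {"counts", "metadata", "fold_margin", "sensitivity_p", "subtype_genes"},
}

_DEFAULTS = {
    "fusion": {"min_separation": 1_000_000, "min_mapq": 15, "anchor_len": 25,
               "join_radius": 1_000},
    "cnv": {"purity": 0.7, "window_size": 500, "step": 250, "filter_length": 50,
            "bin_width": 0.05, "threshold": 0.5,
            "excluded_chromosomes": ["8", "22", "X", "Y"]},
    "expr": {"fold_margin": 3.0, "sensitivity_p": 1e-4,
             "subtype_genes": list(exprmod.DEFAULT_SUBTYPE_GENES)},
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration with every default resolved."""

    raw: dict
    seed: int
    sample_id: str
    output_dir: str

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, subkeys in _KNOWN_SUBKEYS.items():
            if section in data:
                bad = set(data[section]) - subkeys
                if bad:
                    raise ConfigError(f"unknown keys in '{section}': {sorted(bad)}")
        if "reference" not in data:
            raise ConfigError("config requires a 'reference' section")
        resolved = dict(data)
        for section, defaults in _DEFAULTS.items():
            if section in resolved:
                merged = dict(defaults)
                merged.update(resolved[section])
                resolved[section] = merged
        return cls(
            raw=resolved,
            seed=int(data.get("seed", 0)),
            sample_id=str(data.get("sample_id", "tumor")),
            output_dir=str(data.get("output_dir", "oncopipe_out")),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def section(self, name: str) -> Optional[dict]:
        return self.raw.get(name)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


FUSION_COLUMNS = ["locus_a", "locus_b", "n_paired_reads", "n_anchor_pairs",
                  "breakpoint_a", "breakpoint_b", "gene5", "gene3",
                  "coding_disrupted", "promoter_class", "orientation"]
CNV_COLUMNS = ["gene_id", "logratio", "ploidy", "raw_change", "corrected_change", "status"]
SOMATIC_COLUMNS = ["chromosome", "position", "ref_allele", "alt_allele", "alt_count",
                   "total_count", "alt_fraction", "somatic_status"]


@dataclass
class SampleReport:
    sample_id: str
    fusions: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FUSION_COLUMNS))
    copy_number: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CNV_COLUMNS))
    somatic: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=SOMATIC_COLUMNS))
    overexpression: pd.DataFrame = field(default_factory=pd.DataFrame)
    provenance: dict = field(default_factory=dict)


def _load_reference(config: RunConfig) -> ReferenceModel:
    sect = config.section("reference")
    chroms = read_fasta(sect["fasta"])
    genes = read_genes_tsv(sect["genes"]) if sect.get("genes") else []
    return ReferenceModel(chromosomes=chroms, genes=genes)


def _fusion_stage(config: RunConfig, ref: ReferenceModel) -> pd.DataFrame:
    sect = config.section("fusion")
    records = read_sam(sect["sam"])
    calls = bf.call_fusions(
        records, ref,
        min_separation=int(sect["min_separation"]),
        min_mapq=int(sect["min_mapq"]),
        anchor_len=int(sect["anchor_len"]),
        join_radius=int(sect["join_radius"]),
    )
    rows = []
    for call in calls:
        c = call.cluster
        rows.append(
            {
                "locus_a": f"{c.locus_a[0]}:{c.locus_a[1][0]}-{c.locus_a[1][1]}",
                "locus_b": f"{c.locus_b[0]}:{c.locus_b[1][0]}-{c.locus_b[1][1]}",
                "n_paired_reads": c.n_paired_reads,
                "n_anchor_pairs": c.n_anchor_pairs,
                "breakpoint_a": c.breakpoint_estimate[0],
                "breakpoint_b": c.breakpoint_estimate[1],
                "gene5": call.gene5,
                "gene3": call.gene3,
                "coding_disrupted": call.coding_disrupted,
                "promoter_class": call.promoter_class,
                "orientation": call.orientation,
            }
        )
    return pd.DataFrame(rows, columns=FUSION_COLUMNS)


def _cnv_stage(config: RunConfig, ref: ReferenceModel) -> pd.DataFrame:
    sect = config.section("cnv")
    grid = cnvmod.WindowGrid.from_reference(ref, int(sect["window_size"]), int(sect["step"]))
    tumor = pd.read_csv(sect["tumor_counts"], sep="\t")
    controls = [pd.read_csv(p, sep="\t") for p in sect["control_counts"]]
    track = cnvmod.compute_window_logratios(tumor, controls, grid)
    track = cnvmod.normalize_logratios(
        track,
        excluded_chromosomes=frozenset(str(c) for c in sect["excluded_chromosomes"]),
        filter_length=int(sect["filter_length"]),
        bin_width=float(sect["bin_width"]),
    )
    calls = cnvmod.call_genes(track, ref.genes, ref.ploidy_map, ref.lengths,
                              purity=float(sect["purity"]), threshold=float(sect["threshold"]))
    return cnvmod.calls_to_frame(calls)


def _rnavar_stage(config: RunConfig) -> pd.DataFrame:
    sect = config.section("rnavar")
    tumor = rnavar.sites_from_frame(pd.read_csv(sect["tumor_pileup"], sep="\t"), role="tumor")
    tumor_calls = rnavar.call_variants(tumor, "tumor")
    benign_calls = []
    for path in sect.get("benign_pileups", []):
        sites = rnavar.sites_from_frame(pd.read_csv(path, sep="\t"), role="benign")
        benign_calls.extend(rnavar.call_variants(sites, "benign"))
    pop_sites = [rnavar.read_population_sites(p) for p in sect.get("population_sites", [])]
    somatic = rnavar.filter_germline(tumor_calls, benign_calls, pop_sites)
    return rnavar.calls_to_frame(somatic)


def _expr_stage(config: RunConfig, ref: ReferenceModel) -> pd.DataFrame:
    sect = config.section("expr")
    counts = pd.read_csv(sect["counts"], sep="\t", index_col=0)
    meta = pd.read_csv(sect["metadata"], sep="\t").fillna({"tissue_id": ""})
    lengths = pd.Series({g.gene_id: g.total_exon_length_bp for g in ref.genes})
    lengths = lengths.reindex(counts.index, fill_value=1000)
    matrix = exprmod.ExpressionMatrix(counts, meta, lengths)
    matrix = exprmod.normalize_median_of_ratios(matrix)
    matrix = exprmod.length_correct(matrix)
    model = exprmod.fit_batch_correction(matrix, p_threshold=float(sect["sensitivity_p"]))
    matrix = exprmod.apply_batch_correction(matrix, model)
    subtype = [g for g in sect["subtype_genes"] if g in matrix.values.index]
    flags = exprmod.flag_overexpression(matrix, subtype, fold_margin=float(sect["fold_margin"]))
    return flags.flags


def run_all(config: RunConfig) -> list[SampleReport]:
    """Execute configured stages in dependency order; abort on stage failure
    with the stage name in the error."""
    ref = _load_reference(config)
    provenance = {"config_hash": config.config_hash, "seed": config.seed}
    report = SampleReport(sample_id=config.sample_id, provenance=provenance)
    stages = [
        ("fusion", lambda: _fusion_stage(config, ref), "fusions"),
        ("cnv", lambda: _cnv_stage(config, ref), "copy_number"),
        ("rnavar", lambda: _rnavar_stage(config), "somatic"),
        ("expr", lambda: _expr_stage(config, ref), "overexpression"),
    ]
    for name, fn, attr in stages:
        if config.section(name) is None:
            continue
        try:
            setattr(report, attr, fn())
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    return [report]


def write_report(reports: list[SampleReport], output_dir: str) -> list[str]:
    """Per-sample TSVs plus a cohort alteration matrix (samples x categories)."""
    if not reports:
        raise ValueError("reports must be nonempty")
    os.makedirs(output_dir, exist_ok=True)
    written = []
    cohort_rows = []
    for rep in reports:
        base = os.path.join(output_dir, rep.sample_id)
        for label, frame in (("fusions", rep.fusions), ("copy_number", rep.copy_number),
                             ("somatic", rep.somatic)):
            path = f"{base}.{label}.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written.append(path)
        path = f"{base}.overexpression.tsv"
        rep.overexpression.to_csv(path, sep="\t", float_format="%.6g")
        written.append(path)
        with open(f"{base}.provenance.json", "w") as fh:
            json.dump(rep.provenance, fh, sort_keys=True, indent=2)
        written.append(f"{base}.provenance.json")

        samples = list(rep.overexpression.columns) or [rep.sample_id]
        for s in samples:
            row = {"sample_id": s}
            if s == rep.sample_id or len(samples) == 1:
                fus = rep.fusions
                row["fusion"] = ";".join(
                    f"{r.gene5}-{r.gene3}" for r in fus.itertuples(index=False)
                ) if len(fus) else ""
                cn = rep.copy_number
                if len(cn):
                    row["amplified"] = ";".join(cn.loc[cn["status"] == "amplified", "gene_id"])
                    row["deleted"] = ";".join(cn.loc[cn["status"] == "deleted", "gene_id"])
                else:
                    row["amplified"] = row["deleted"] = ""
                row["n_somatic"] = len(rep.somatic)
            else:
                row["fusion"] = row["amplified"] = row["deleted"] = ""
                row["n_somatic"] = 0
            for gene in rep.overexpression.index:
                row[f"overexpr_{gene}"] = bool(rep.overexpression.loc[gene, s]) if s in rep.overexpression.columns else False
            cohort_rows.append(row)
    cohort = pd.DataFrame(cohort_rows)
    cohort_path = os.path.join(output_dir, "cohort_matrix.tsv")
    cohort.to_csv(cohort_path, sep="\t", index=False)
    written.append(cohort_path)
    return written
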