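"""Readers, writers and configuration for every pipeline file format.

Plain-text formats only: dosing and covariate tables are CSV keyed by
subject_id, genotypes travel as VCF (GT field, biallelic SNPs) or a TSV
matrix (one SNP per row, one subject per column, cells 0/1/2 or empty),
phenotypes and association results are CSV/TSV, and the truth record of the
synthetic generator is JSON.  Missing values are empty fields in CSV/TSV and
"./." in VCF.  Coordinates are 1-based; chromosomes are labelled "1".."22"
and "X".  On load the coded allele is re-oriented to the in-sample minor
allele, with a log entry whenever a swap occurs — no record is ever dropped
silently.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assoc import DEFAULT_COVARIATES, GenotypeMatrix
from .mec import DEFAULT_WINDOWS_H, SITES, MECRecord
from .pk import ConcProfile, DoseEvent, DosingHistory, PKParameters

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "default_pk_parameters",
    "load_pk_parameters",
    "read_dosing_csv",
    "write_dosing_csv",
    "write_profile_csv",
    "read_covariates_csv",
    "write_covariates_csv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "write_truth_json",
    "load_config",
]


# ---------------------------------------------------------------------------
# PK parameter sets


def _builtin_param_text() -> str:
    return (importlib.resources.files("mecgwas") / "data" / "pk_params.yaml").read_text()


def load_pk_parameters(path: str | Path | None, name: str = "shafer_fentanyl") -> PKParameters:
    """Load a named PK parameter block from a YAML file (or the built-in)."""
    text = Path(path).read_text() if path is not None else _builtin_param_text()
    blocks = yaml.safe_load(text)
    if name not in blocks:
        raise KeyError(f"no PK parameter set named {name!r}; available: {sorted(blocks)}")
    return PKParameters(**blocks[name])


def default_pk_parameters(name: str = "shafer_fentanyl") -> PKParameters:
    return load_pk_parameters(None, name)


# ---------------------------------------------------------------------------
# dosing and profiles


def read_dosing_csv(path: str | Path, observation_end_min: float = 1440.0) -> list[DosingHistory]:
    """Dosing CSV: subject_id,time_min,dose_ug,kind — one event per row."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"subject_id", "time_min", "dose_ug", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"dosing CSV must have columns {sorted(required)}")
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_min", kind="stable")
        events = [
            DoseEvent(float(r.time_min), float(r.dose_ug), str(r.kind))
            for r in grp.itertuples()
        ]
        out.append(DosingHistory(str(sid), events, observation_end_min))
    return out


def write_dosing_csv(histories: list[DosingHistory], path: str | Path) -> None:
    rows = [
        {"subject_id": h.subject_id, "time_min": e.time_min,
         "dose_ug": e.dose_ug, "kind": e.kind}
        for h in histories
        for e in h.events
    ]
    pd.DataFrame(rows, columns=["subject_id", "time_min", "dose_ug", "kind"]).to_csv(
        path, index=False, float_format="%.17g")


def write_profile_csv(profiles: list[ConcProfile], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"subject_id": p.subject_id, "time_min": p.times,
                      "cp_ng_ml": p.cp, "ce_ng_ml": p.ce})
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# covariates


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip").set_index("subject_id")
    missing = [c for c in DEFAULT_COVARIATES if c not in df.columns]
    if missing:
        raise ValueError(f"covariate CSV missing columns {missing}")
    return df


def write_covariates_csv(covars: pd.DataFrame, path: str | Path,
                         sex: np.ndarray | None = None) -> None:
    out = covars.copy()
    if sex is not None:
        out["sex"] = sex
    out.to_csv(path, index_label="subject_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# phenotypes


def _pheno_columns() -> list[str]:
    cols = ["subject_id"]
    cols += [f"n_demands_{h}h" for h in DEFAULT_WINDOWS_H]
    for h in DEFAULT_WINDOWS_H:
        for site in SITES:
            cols.append(f"mec_{site}_0_{h}h")
    for h in DEFAULT_WINDOWS_H:
        for site in SITES:
            cols.append(f"log_mec_{site}_0_{h}h")
    return cols


def write_phenotypes_csv(records: list[MECRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row: dict = {"subject_id": rec.subject_id}
        for h in DEFAULT_WINDOWS_H:
            row[f"n_demands_{h}h"] = rec.n_demands(h)
        for h in DEFAULT_WINDOWS_H:
            for site in SITES:
                row[f"mec_{site}_0_{h}h"] = rec.window_means.get((h, site))
                row[f"log_mec_{site}_0_{h}h"] = rec.log_values.get((h, site))
        rows.append(row)
    pd.DataFrame(rows, columns=_pheno_columns()).to_csv(path, index=False)


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("subject_id")


# ---------------------------------------------------------------------------
# genotypes


def _orient_minor(calls: np.ndarray, snps: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Swap alleles wherever the coded allele is not the in-sample minor."""
    freq = np.nanmean(calls, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        for j in np.where(flip)[0]:
            logger.info("allele swap at %s: coded-allele frequency %.3f > 0.5",
                        snps["id"].iloc[j], freq[j])
        calls = calls.copy()
        calls[:, flip] = 2.0 - calls[:, flip]
        snps = snps.copy()
        minor = snps["minor"].to_numpy().copy()
        major = snps["major"].to_numpy().copy()
        minor[flip], major[flip] = major[flip].copy(), minor[flip].copy()
        snps["minor"], snps["major"] = minor, major
    return calls, snps


def read_genotypes(
    path: str | Path,
    fmt: str | None = None,
    sex: dict[str, str] | np.ndarray | None = None,
) -> GenotypeMatrix:
    """Load a genotype matrix from VCF or TSV, minor-allele oriented.

    ``fmt`` defaults from the file suffix.  Multiallelic and non-SNP VCF
    records are skipped with counts logged; half-calls become missing;
    duplicate SNP ids raise.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        geno = _read_vcf(path)
    elif fmt == "tsv":
        geno = _read_tsv(path)
    else:
        raise ValueError("format must be 'vcf' or 'tsv'")
    if geno.snps["id"].duplicated().any():
        dups = geno.snps["id"][geno.snps["id"].duplicated()].tolist()
        raise ValueError(f"duplicate SNP ids: {dups[:5]}")
    calls, snps = _orient_minor(geno.calls, geno.snps)
    sex_arr = None
    if sex is not None:
        if isinstance(sex, dict):
            sex_arr = np.array([sex.get(s, "F") for s in geno.subjects])
        else:
            sex_arr = np.asarray(sex)
    return GenotypeMatrix(geno.subjects, snps.reset_index(drop=True), calls, sex_arr)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    rows, calls, skipped = [], [], 0
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        g = np.empty(len(subjects))
        for s, gt in enumerate(var.genotypes):
            a = gt[:-1]  # final entry is the phased flag
            g[s] = np.nan if any(x < 0 for x in a) else float(sum(1 for x in a if x == 1))
        rows.append({
            "id": var.ID or f"{var.CHROM}:{var.POS}",
            "chrom": str(var.CHROM), "pos": int(var.POS),
            "minor": var.ALT[0], "major": var.REF,
        })
        calls.append(g)
    if skipped:
        logger.info("read_genotypes: skipped %d multiallelic/non-SNP records", skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    return GenotypeMatrix(subjects, pd.DataFrame(rows), np.array(calls).T)


def _read_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["id", "chrom", "pos", "minor", "major"]
    if df.columns[:5].tolist() != meta_cols:
        raise ValueError(f"genotype TSV must start with columns {meta_cols}")
    subjects = df.columns[5:].tolist()
    snps = df[meta_cols].copy()
    calls = df[subjects].to_numpy(dtype=float).T
    return GenotypeMatrix(subjects, snps, calls)


def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    out = geno.snps.copy()
    mat = geno.calls.T  # SNP-major rows
    for s, sid in enumerate(geno.subjects):
        col = pd.array(mat[:, s], dtype="float64")
        out[sid] = pd.Series(col).astype("Int64")  # empty cell for missing
    out.to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 writer: GT-only, REF=major, ALT=minor, ./. missing."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.subjects) + "\n")
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, row in enumerate(geno.snps.itertuples()):
            gts = [
                "./." if np.isnan(v) else code[v]
                for v in geno.calls[:, j]
            ]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.major}\t{row.minor}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


def write_truth_json(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, loadable from YAML."""

    genotypes: str
    covariates: str
    dosing: str
    out_dir: str = "out"
    genotype_format: str | None = None
    pk_param_file: str | None = None
    pk_param_set: str = "shafer_fentanyl"
    phenotype_site: str = "plasma"
    phenotype_window_h: int = 6
    n_stages: int = 3
    alpha: float = 0.05
    prune_r2: float = 0.8
    q_threshold: float = 0.05
    stage_split: str = "contiguous"  # or "random"
    covariate_mode: str = "screened"  # or "all"
    models: tuple[str, ...] = ("additive", "dominant", "recessive")
    observation_end_min: float = 1440.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for thr in (self.alpha, self.prune_r2, self.q_threshold):
            if not 0 < thr <= 1:
                raise ValueError("thresholds must lie in (0, 1]")
        if self.phenotype_site not in SITES:
            raise ValueError(f"phenotype_site must be one of {SITES}")
        if self.phenotype_window_h not in DEFAULT_WINDOWS_H:
            raise ValueError(f"phenotype_window_h must be one of {DEFAULT_WINDOWS_H}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "models" in raw:
        raw["models"] = tuple(raw["models"])
    return PipelineConfig(**raw)
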