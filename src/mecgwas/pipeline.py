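"""End-to-end pipeline: dosing -> MEC phenotypes -> staged GWAS -> outputs.

``run_pipeline`` wires the stages together for one phenotype choice
(site x window): simulate concentrations for every dosing history, extract
windowed MEC phenotypes, screen the clinical covariates, run the staged
association scan under each genetic model, LD-prune and FDR-correct the
survivors, and write the association table, phenotype table, QQ data and a
machine-readable run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (
    DEFAULT_COVARIATES,
    AssocRecord,
    StagePlan,
    qq_data,
    staged_gwas,
)
from .io import (
    PipelineConfig,
    load_pk_parameters,
    read_covariates_csv,
    read_dosing_csv,
    read_genotypes,
    write_phenotypes_csv,
)
from .mec import extract_mec
from .power import covariate_screen

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "association_frame"]


def association_frame(records: list[AssocRecord], n_stages: int) -> pd.DataFrame:
    """Flatten association records into the output table."""
    rows = []
    for rec in records:
        row: dict = {"snp": rec.snp, "chrom": rec.chrom, "pos": rec.pos, "model": rec.model}
        for s in range(1, n_stages + 1):
            res = rec.stage_results.get(s)
            row[f"stage{s}_beta"] = res.beta if res else None
            row[f"stage{s}_p"] = res.p if res else None
        fin = rec.combined_final
        row["combined_beta"] = fin.beta if fin else None
        row["combined_p"] = fin.p if fin else None
        row["q"] = rec.q
        row["survived"] = rec.survived_all
        row["pruned_by"] = rec.pruned_by
        row["significant"] = rec.genome_wide_significant
        rows.append(row)
    return pd.DataFrame(rows)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis chain; returns the run report dict.

    Any stage failure aborts with a message tagged by the stage name.
    Output files land in ``config.out_dir``: phenotypes.csv,
    association.tsv, qq_<model>.tsv, report.json.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "mecgwas_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "counts": {},
    }

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        name = stage("load_inputs")
        params = load_pk_parameters(config.pk_param_file, config.pk_param_set)
        covars = read_covariates_csv(config.covariates)
        sex = None
        if "sex" in covars.columns:
            sex = {sid: str(v) for sid, v in covars["sex"].items()}
        geno = read_genotypes(config.genotypes, config.genotype_format, sex=sex)
        histories = read_dosing_csv(config.dosing, config.observation_end_min)
        report["counts"]["subjects_genotyped"] = geno.n_subjects
        report["counts"]["snps_loaded"] = geno.n_snps
        report["counts"]["subjects_dosed"] = len(histories)

        name = stage("mec_phenotype")
        mec_records = [extract_mec(h, params) for h in histories]
        write_phenotypes_csv(mec_records, out / "phenotypes.csv")
        key = (config.phenotype_window_h, config.phenotype_site)
        pheno_by_subject = {r.subject_id: r.log_values.get(key) for r in mec_records}
        pheno = np.array(
            [np.nan if pheno_by_subject.get(s) is None else pheno_by_subject[s]
             for s in geno.subjects], dtype=float)
        n_missing = int(np.isnan(pheno).sum())
        report["counts"]["subjects_missing_phenotype"] = n_missing
        report["counts"]["subjects_analyzed"] = geno.n_subjects - n_missing

        name = stage("covariate_screen")
        clin = covars.loc[geno.subjects, list(DEFAULT_COVARIATES)]
        ok = ~np.isnan(pheno)
        screen = covariate_screen(pheno[ok], clin.loc[ok])
        if config.covariate_mode == "screened":
            used = [r.name for r in screen if r.flagged]
        else:
            used = list(DEFAULT_COVARIATES)
        report["covariate_screen"] = [
            {"variable": r.name, "beta": r.value, "p": r.p, "flagged": r.flagged}
            for r in screen
        ]
        report["covariates_used"] = used
        C = clin[used].to_numpy() if used else None

        name = stage("staged_gwas")
        n_analyzed = int(ok.sum())
        if config.stage_split == "contiguous":
            plan = StagePlan.contiguous(
                n_analyzed, config.n_stages, alpha=config.alpha,
                prune_r2=config.prune_r2, q_threshold=config.q_threshold)
        else:
            plan = StagePlan.random(
                n_analyzed, config.n_stages, seed=config.seed, alpha=config.alpha,
                prune_r2=config.prune_r2, q_threshold=config.q_threshold)
        frames = []
        for model in config.models:
            records = staged_gwas(geno, pheno, C, plan, model)
            frames.append(association_frame(records, plan.n_stages))
            stage1_p = np.array([
                r.stage_results[1].p for r in records
                if r.stage_results.get(1) is not None])
            exp, obs = qq_data(stage1_p[np.isfinite(stage1_p)])
            pd.DataFrame({"expected_neglog10_p": exp, "observed_neglog10_p": obs}).to_csv(
                out / f"qq_{model}.tsv", sep="\t", index=False)
            report["counts"][f"survivors_{model}"] = int(
                sum(1 for r in records if r.survived_all))
            report["counts"][f"significant_{model}"] = int(
                sum(1 for r in records if r.genome_wide_significant))
        assoc = pd.concat(frames, ignore_index=True)
        assoc.to_csv(out / "association.tsv", sep="\t", index=False)

        name = stage("report")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        return report
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        raise RuntimeError(f"pipeline failed in stage '{name}': {exc}") from exc
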