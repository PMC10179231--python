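"""Per-SNP regression and the multi-stage association procedure.

Each SNP is tested by ordinary least squares of the log-transformed MEC
phenotype on a genotype coding (additive = minor-allele count, dominant =
carrier indicator, recessive = homozygous-minor indicator) together with the
clinical covariates.  Subjects are partitioned into consecutive stages
(default three of 117); a SNP advances past stage k only if its stage-k
p-value and the pooled analysis of stages 1..k are both below the stage
alpha.  Final-stage survivors are greedily pruned at an r^2 threshold so only
the most significant SNP of an LD-redundant set remains, and
Benjamini-Hochberg q-values over the pruned survivors define genome-wide
significance (q < 0.05).

Chromosome-X markers are fitted in females only; males are excluded from
every stage for those SNPs.

The bulk fitting path residualizes phenotype and genotypes on the covariates
once per subject set (Frisch-Waugh), which reproduces the full OLS
coefficient, standard error and t-test for the genotype term exactly while
scaling to genome-wide SNP panels.  SNPs with missing calls fall back to a
per-SNP complete-case fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .popgen import ld_em

logger = logging.getLogger(__name__)

__all__ = [
    "MODELS",
    "GenotypeMatrix",
    "RegressionResult",
    "StagePlan",
    "AssocRecord",
    "encode_genotype",
    "encode_genotypes",
    "snp_regression",
    "combine_stages",
    "staged_gwas",
    "ld_prune",
    "fdr_qvalues",
    "qq_data",
]

MODELS = ("additive", "dominant", "recessive")

#: clinical covariates carried into every per-SNP fit by default
DEFAULT_COVARIATES = (
    "age_years",
    "remi_rate_ug_kg_min",
    "endsurg_fentanyl_ug",
    "pain2h_score",
)


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele counts with SNP metadata.

    ``calls`` is float with NaN for missing; ``snps`` has columns
    id/chrom/pos/minor/major; ``sex`` is 'M'/'F' per subject (used only to
    exclude males at chromosome-X markers).
    """

    subjects: list[str]
    snps: pd.DataFrame
    calls: np.ndarray
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.subjects), len(self.snps)):
            raise ValueError("calls shape must be (n_subjects, n_snps)")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype calls must be 0/1/2 or missing")
        if self.sex is None:
            self.sex = np.array(["F"] * len(self.subjects))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def maf(self) -> np.ndarray:
        """In-sample minor allele frequency per SNP."""
        return np.nanmean(self.calls, axis=0) / 2.0


@dataclass(frozen=True)
class RegressionResult:
    beta: float
    se: float
    t_stat: float
    p: float
    n_used: int


@dataclass
class StagePlan:
    """Partition of analyzed subjects into consecutive stages plus thresholds."""

    assignment: np.ndarray  # stage index 1..S per analyzed subject
    alpha: float = 0.05
    prune_r2: float = 0.8
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.min() != 1:
            raise ValueError("stages must be numbered from 1")
        for thr in (self.alpha, self.prune_r2, self.q_threshold):
            if not 0 < thr <= 1:
                raise ValueError("thresholds must lie in (0, 1]")

    @property
    def n_stages(self) -> int:
        return int(self.assignment.max())

    @classmethod
    def contiguous(cls, n_subjects: int, n_stages: int = 3, **kw) -> "StagePlan":
        """Default split: consecutive blocks in input order, near-equal sizes
        (117/117/117 for the default cohort of 351)."""
        sizes = np.full(n_stages, n_subjects // n_stages)
        sizes[: n_subjects % n_stages] += 1
        return cls(np.repeat(np.arange(1, n_stages + 1), sizes), **kw)

    @classmethod
    def random(cls, n_subjects: int, n_stages: int = 3, seed: int = 0, **kw) -> "StagePlan":
        plan = cls.contiguous(n_subjects, n_stages, **kw)
        rng = np.random.default_rng(seed)
        rng.shuffle(plan.assignment)
        return plan


@dataclass
class AssocRecord:
    """Stage-wise association results for one SNP under one genetic model."""

    snp: str
    chrom: str
    pos: int
    model: str
    stage_results: dict[int, RegressionResult | None] = field(default_factory=dict)
    combined_results: dict[int, RegressionResult | None] = field(default_factory=dict)
    survived_stage: dict[int, bool] = field(default_factory=dict)
    pruned: bool = False
    pruned_by: str | None = None
    q: float | None = None
    genome_wide_significant: bool = False

    @property
    def survived_all(self) -> bool:
        return bool(self.survived_stage) and all(self.survived_stage.values())

    @property
    def combined_final(self) -> RegressionResult | None:
        if not self.combined_results:
            return None
        return self.combined_results[max(self.combined_results)]


def encode_genotype(count: float, model: str):
    """Code a minor-allele count under a genetic model; missing propagates."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if count is None or (isinstance(count, float) and np.isnan(count)):
        return np.nan
    if count not in (0, 1, 2):
        raise ValueError("genotype count must be 0, 1 or 2")
    if model == "additive":
        return float(count)
    if model == "dominant":
        return 1.0 if count >= 1 else 0.0
    return 1.0 if count == 2 else 0.0


def encode_genotypes(calls: np.ndarray, model: str) -> np.ndarray:
    """Vectorized :func:`encode_genotype` over an array (NaN preserved)."""
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    calls = np.asarray(calls, dtype=float)
    if model == "additive":
        return calls.copy()
    if model == "dominant":
        out = (calls >= 1).astype(float)
    else:
        out = (calls == 2).astype(float)
    out[np.isnan(calls)] = np.nan
    return out


# ---------------------------------------------------------------------------
# least-squares core


def _design(covars: np.ndarray | None, n: int) -> np.ndarray:
    if covars is None:
        return np.ones((n, 1))
    covars = np.atleast_2d(np.asarray(covars, dtype=float))
    if covars.shape[0] != n:
        covars = covars.T
    return np.column_stack([np.ones(n), covars])


def _fit_one(y: np.ndarray, g: np.ndarray, X: np.ndarray) -> RegressionResult | None:
    """Full OLS of y on [X | g]; returns the genotype-term inference."""
    n, k = X.shape
    df = n - k - 1
    if df < 1:
        return None
    if np.ptp(g) == 0:
        return None  # monomorphic in the fitted subjects
    Q, _ = np.linalg.qr(X)
    ey = y - Q @ (Q.T @ y)
    eg = g - Q @ (Q.T @ g)
    gg = float(eg @ eg)
    if gg <= 1e-10 * n * max(np.var(g), 1e-30):
        return None  # collinear with covariates
    beta = float(ey @ eg) / gg
    rss = float(ey @ ey) - beta * beta * gg
    sigma2 = max(rss, 0.0) / df
    se = np.sqrt(sigma2 / gg)
    t = beta / se if se > 0 else np.inf
    p = 2 * float(stats.t.sf(abs(t), df))
    return RegressionResult(beta, float(se), float(t), p, n)


def snp_regression(
    pheno: np.ndarray,
    codes: np.ndarray,
    covars: np.ndarray | pd.DataFrame | None = None,
    subjects: np.ndarray | None = None,
) -> RegressionResult | None:
    """Covariate-adjusted OLS for one coded SNP.

    ``pheno``/``codes``/``covars`` are aligned arrays; ``subjects`` is an
    optional boolean/index mask restricting the fit.  Rows with any missing
    value are dropped (per-SNP complete case).  Returns None — with a log
    entry — for a monomorphic or covariate-collinear genotype.
    """
    y = np.asarray(pheno, dtype=float)
    g = np.asarray(codes, dtype=float)
    C = np.asarray(covars, dtype=float) if covars is not None else None
    if subjects is not None:
        y, g = y[subjects], g[subjects]
        if C is not None:
            C = C[subjects]
    ok = ~(np.isnan(y) | np.isnan(g))
    if C is not None:
        C2 = np.atleast_2d(C)
        if C2.shape[0] != len(y):
            C2 = C2.T
        ok &= ~np.isnan(C2).any(axis=1)
        C = C2[ok]
    y, g = y[ok], g[ok]
    X = _design(C, len(y))
    n_pred = X.shape[1]  # intercept + covariates (+ genotype below)
    if len(y) < n_pred + 2:
        logger.info("snp_regression skipped: %d complete cases < predictors+2", len(y))
        return None
    res = _fit_one(y, g, X)
    if res is None:
        logger.info("snp_regression skipped: monomorphic/collinear genotype")
    return res


def _bulk_fit(
    y: np.ndarray,
    G: np.ndarray,
    covars: np.ndarray | None,
) -> dict[str, np.ndarray]:
    """Vectorized genotype-term OLS across SNP columns sharing one subject set.

    Complete-genotype columns share a single covariate projection; columns
    with missing calls are refitted per SNP with their own complete cases.
    """
    n, m = G.shape
    X = _design(covars, n)
    k = X.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tval = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    n_used = np.zeros(m, dtype=int)
    df = n - k - 1
    has_nan = np.isnan(G).any(axis=0)
    full = ~has_nan
    if full.any() and df >= 1:
        Q, _ = np.linalg.qr(X)
        ey = y - Q @ (Q.T @ y)
        Gf = G[:, full]
        EG = Gf - Q @ (Q.T @ Gf)
        gg = np.einsum("ij,ij->j", EG, EG)
        span = np.ptp(Gf, axis=0)
        ok = (span > 0) & (gg > 1e-10 * n * np.maximum(np.var(Gf, axis=0), 1e-30))
        b = np.where(gg > 0, (ey @ EG) / np.where(gg > 0, gg, 1.0), np.nan)
        rss = float(ey @ ey) - b * b * gg
        s = np.sqrt(np.maximum(rss, 0.0) / df / np.where(gg > 0, gg, np.nan))
        t = b / s
        p = 2 * stats.t.sf(np.abs(t), df)
        cols = np.where(full)[0]
        beta[cols[ok]] = b[ok]
        se[cols[ok]] = s[ok]
        tval[cols[ok]] = t[ok]
        pval[cols[ok]] = p[ok]
        n_used[cols[ok]] = n
    for j in np.where(has_nan)[0]:
        res = snp_regression(y, G[:, j], covars)
        if res is not None:
            beta[j], se[j], tval[j], pval[j], n_used[j] = (
                res.beta, res.se, res.t_stat, res.p, res.n_used)
    return {"beta": beta, "se": se, "t": tval, "p": pval, "n": n_used}


def combine_stages(
    pheno: np.ndarray,
    codes: np.ndarray,
    covars: np.ndarray | None,
    stage_mask: np.ndarray,
) -> RegressionResult | None:
    """Pooled OLS over the subjects of the given stages.

    The pooled analysis refits one regression on the concatenated subject
    set with the same covariates and no stage indicator, matching a single
    "combined beta/p" per SNP.
    """
    return snp_regression(pheno, codes, covars, subjects=stage_mask)


# ---------------------------------------------------------------------------
# staged procedure


def staged_gwas(
    geno: GenotypeMatrix,
    pheno: np.ndarray | pd.Series,
    covars: pd.DataFrame | np.ndarray | None,
    plan: StagePlan,
    model: str = "additive",
) -> list[AssocRecord]:
    """Run the multi-stage association scan for one genetic model.

    ``pheno`` and ``covars`` are aligned with ``geno.subjects``; subjects
    with a missing phenotype or covariate are excluded before the plan is
    applied.  Stage 1 keeps SNPs with stage-1 p < alpha; each later stage k
    requires both its own p < alpha and the pooled stages-1..k p < alpha.
    ``genome_wide_significant`` means survived all stages, not pruned, and
    q below the plan threshold.

    Multiple-testing correction follows the staged design: the q-values are
    computed by BH over the candidate set selected after the penultimate
    stage (all SNPs, for a single-stage plan) once that set has been
    LD-pruned, and a SNP is genome-wide significant only if it additionally
    survived the final stage.
    """
    y = np.asarray(pheno, dtype=float)
    C = None
    if covars is not None:
        C = np.asarray(covars, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    analyzed = ~np.isnan(y)
    if C is not None:
        analyzed &= ~np.isnan(C).any(axis=1)
    idx_analyzed = np.where(analyzed)[0]
    if len(plan.assignment) != len(idx_analyzed):
        raise ValueError(
            f"stage plan covers {len(plan.assignment)} subjects but "
            f"{len(idx_analyzed)} have complete phenotype/covariates"
        )
    sex = np.asarray(geno.sex)[idx_analyzed]
    y_a = y[idx_analyzed]
    C_a = C[idx_analyzed] if C is not None else None

    codes_all = encode_genotypes(geno.calls[idx_analyzed], model)
    is_x = geno.snps["chrom"].astype(str).str.upper().eq("X").to_numpy()

    records = [
        AssocRecord(
            snp=row.id, chrom=str(row.chrom), pos=int(row.pos), model=model)
        for row in geno.snps.itertuples()
    ]
    alive = np.arange(geno.n_snps)
    n_stages = plan.n_stages
    candidates = np.array([], dtype=int)  # set entering the final stage
    for s in range(1, n_stages + 1):
        if alive.size == 0:
            break
        if s == n_stages:
            candidates = alive  # the FDR stratum (all SNPs when S = 1)
        stage_mask = plan.assignment == s
        pooled_mask = plan.assignment <= s
        keep = []
        for x_flag in (False, True):
            sel = alive[is_x[alive] == x_flag]
            if sel.size == 0:
                continue
            sub_stage = stage_mask & ((sex == "F") if x_flag else True)
            sub_pool = pooled_mask & ((sex == "F") if x_flag else True)
            res_s = _bulk_fit(y_a[sub_stage], codes_all[np.ix_(sub_stage, sel)],
                              C_a[sub_stage] if C_a is not None else None)
            res_c = res_s if s == 1 else _bulk_fit(
                y_a[sub_pool], codes_all[np.ix_(sub_pool, sel)],
                C_a[sub_pool] if C_a is not None else None)
            for j, snp_i in enumerate(sel):
                rec = records[snp_i]
                rec.stage_results[s] = _row_result(res_s, j)
                rec.combined_results[s] = _row_result(res_c, j)
                p_s = res_s["p"][j]
                p_c = res_c["p"][j]
                ok = np.isfinite(p_s) and p_s < plan.alpha
                if s > 1:
                    ok = ok and np.isfinite(p_c) and p_c < plan.alpha
                rec.survived_stage[s] = bool(ok)
                if ok:
                    keep.append(snp_i)
        alive = np.array(sorted(keep), dtype=int)

    cand_recs = [records[i] for i in candidates
                 if records[i].combined_final is not None]
    if cand_recs:
        kept, dropped_by = ld_prune(cand_recs, geno, idx_analyzed, plan.prune_r2)
        for rec in cand_recs:
            if rec.snp in dropped_by:
                rec.pruned = True
                rec.pruned_by = dropped_by[rec.snp]
        qs = fdr_qvalues(np.array([r.combined_final.p for r in kept]))
        for rec, q in zip(kept, qs):
            rec.q = float(q)
            rec.genome_wide_significant = bool(
                rec.survived_all and not rec.pruned and q < plan.q_threshold)
    return records


def _row_result(res: dict[str, np.ndarray], j: int) -> RegressionResult | None:
    if not np.isfinite(res["p"][j]):
        return None
    return RegressionResult(
        float(res["beta"][j]), float(res["se"][j]), float(res["t"][j]),
        float(res["p"][j]), int(res["n"][j]))


def ld_prune(
    records: list[AssocRecord],
    geno: GenotypeMatrix,
    subject_idx: np.ndarray | None = None,
    r2_threshold: float = 0.8,
) -> tuple[list[AssocRecord], dict[str, str]]:
    """Greedy LD pruning of survivor SNPs by combined p.

    Records are visited in ascending combined p (ties broken by position
    then id); a SNP is kept iff its r^2 with every already-kept SNP stays
    below the threshold.  Returns (kept records, dropped snp -> index snp).
    """
    snp_col = {sid: i for i, sid in enumerate(geno.snps["id"])}
    calls = geno.calls if subject_idx is None else geno.calls[subject_idx]

    def sort_key(rec: AssocRecord):
        return (rec.combined_final.p, rec.pos, rec.snp)

    ordered = sorted(records, key=sort_key)
    kept: list[AssocRecord] = []
    dropped: dict[str, str] = {}
    for rec in ordered:
        g1 = calls[:, snp_col[rec.snp]]
        index_snp = None
        for k in kept:
            g2 = calls[:, snp_col[k.snp]]
            ld = ld_em(g1, g2)
            if ld.defined and ld.r2 >= r2_threshold:
                index_snp = k.snp
                break
        if index_snp is None:
            kept.append(rec)
        else:
            dropped[rec.snp] = index_snp
    return kept, dropped


def fdr_qvalues(
    pvalues: np.ndarray,
    strata: np.ndarray | None = None,
) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced).

    With ``strata`` given, q-values are computed within each stratum
    separately (stratified FDR); default is a single stratum.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if strata is None:
        return multipletests(p, method="fdr_bh")[1]
    strata = np.asarray(strata)
    q = np.empty_like(p)
    for s in np.unique(strata):
        m = strata == s
        q[m] = multipletests(p[m], method="fdr_bh")[1]
    return q


def qq_data(
    pvalues: np.ndarray,
    floor: float = 1e-300,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p for a QQ plot.

    Observed p sorted ascending pair with uniform-order-statistic medians
    approximated by i/(m+1).  Zero p-values are clipped at ``floor`` with a
    warning.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("qq_data: %d zero p-values clipped at %g", int((p == 0).sum()), floor)
        p = np.maximum(p, floor)
    m = len(p)
    obs = -np.log10(np.sort(p))
    exp = -np.log10(np.arange(1, m + 1) / (m + 1))
    return exp, obs
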