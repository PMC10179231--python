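"""Synthetic cohort generator: genotypes, covariates, latent MECs, dosing.

No patient-level data accompany the analysis this package implements, so the
generator produces inputs with the statistical structure the pipeline
assumes and a truth record for recovery tests:

* genotypes drawn in Hardy-Weinberg proportions at per-SNP minor allele
  frequencies, with optional LD blocks built from correlated latent
  Gaussians thresholded to preserve the marginal frequencies;
* clinical covariates on realistic postoperative ranges (age 20-85 y,
  remifentanil infusion rate around the 0.25 ug/kg/min protocol rate,
  end-of-surgery fentanyl topping out a 100 ug bolus, 0-10 pain score);
* a latent per-subject minimum effective concentration, log-linear in the
  causal SNP minor-allele counts and the covariates plus Gaussian noise;
* a closed-loop PCA dosing history: the subject demands a 20 ug dose
  whenever the simulated effect-site concentration falls back to their
  latent MEC, subject to the pump rules (5-min lockout, at most 12 demands
  in any rolling hour, 1000 ug reservoir).

Demand instants are located by bracketed root search on the closed-form
concentration curve, so with zero behavioral noise the pre-demand effect-site
concentration of an unconstrained demand equals the latent MEC to solver
precision — the basis of the pipeline's round-trip tests.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assoc import DEFAULT_COVARIATES, GenotypeMatrix
from .pk import DoseEvent, DosingHistory, PKParameters, SuperpositionState, hybrid_constants

__all__ = [
    "PCASettings",
    "CohortSpec",
    "LatentPhenotype",
    "CohortData",
    "gen_genotypes",
    "gen_covariates",
    "gen_latent_mec",
    "gen_dosing",
    "gen_cohort",
]


@dataclass(frozen=True)
class PCASettings:
    """Pump program: demand dose, lockout, rolling-hour cap, reservoir."""

    demand_dose_ug: float = 20.0
    lockout_min: float = 5.0
    max_per_hour: int = 12
    capacity_ug: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.demand_dose_ug, self.lockout_min, self.max_per_hour, self.capacity_ug) <= 0:
            raise ValueError("all pump settings must be positive")
        if self.capacity_ug < self.demand_dose_ug:
            raise ValueError("reservoir must hold at least one demand dose")


@dataclass
class CohortSpec:
    """Generative conditions for one synthetic cohort."""

    n_subjects: int = 351
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    #: optional LD blocks as (block size, latent within-block correlation),
    #: occupying consecutive SNPs from index 0
    ld_blocks: list[tuple[int, float]] | None = None
    #: number of trailing SNPs placed on chromosome X
    x_snps: int = 0
    #: (snp index, per-copy effect on log latent effect-site MEC)
    causal_snps: list[tuple[int, float]] = field(default_factory=list)
    #: pin specific SNPs to an exact MAF (e.g. a planted causal variant)
    snp_maf_overrides: dict[int, float] = field(default_factory=dict)
    #: log-scale coefficients of the clinical covariates (signs as screened)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age_years": 0.004,
            "remi_rate_ug_kg_min": 0.409,
            "endsurg_fentanyl_ug": 0.001,
            "pain2h_score": 0.019,
        }
    )
    #: optional covariate distribution overrides: name -> ("constant", v)
    #: or ("uniform", lo, hi) or ("normal", mu, sd)
    covariate_dists: dict[str, tuple] = field(default_factory=dict)
    intercept: float = -0.75
    noise_sd: float = 0.2
    pca: PCASettings = field(default_factory=PCASettings)
    initial_bolus_ug: float = 100.0
    #: lognormal sd of the per-demand multiplicative threshold noise
    behavior_noise_sd: float = 0.0
    observation_end_min: float = 1440.0
    #: concentration the demand trigger watches; opioids act at the effect
    #: site, so that is the default (plasma available for sensitivity runs)
    trigger_site: str = "effect"
    prop_male: float = 218 / 351
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie in (0, 0.5]")
        for i, _ in self.causal_snps:
            if not 0 <= i < self.n_snps:
                raise ValueError("causal SNP index out of range")
        if self.trigger_site not in ("effect", "plasma"):
            raise ValueError("trigger_site must be 'effect' or 'plasma'")


@dataclass
class LatentPhenotype:
    """Generative truth for one subject's effect-site MEC (ng/mL)."""

    subject_id: str
    latent_mec: float
    genetic: float
    covariate: float
    residual: float

    @property
    def log_components_sum(self) -> float:
        return self.genetic + self.covariate + self.residual


@dataclass
class CohortData:
    geno: GenotypeMatrix
    covariates: pd.DataFrame
    latents: list[LatentPhenotype]
    histories: list[DosingHistory]
    truth: dict


def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _latent_correlation(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation producing allele-indicator correlation
    ``target_r`` after thresholding at the MAF quantile."""
    if target_r >= 1.0:
        return 1.0
    c = stats.norm.ppf(maf)

    def allele_corr(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf([c, c], mean=[0, 0],
                                            cov=[[1, rho], [rho, 1]])
        return (p11 - maf * maf) / (maf * (1 - maf))

    if allele_corr(0.9999) <= target_r:
        return 0.9999
    return float(optimize.brentq(lambda r: allele_corr(r) - target_r, 0.0, 0.9999,
                                 xtol=1e-6))


def gen_genotypes(spec: CohortSpec, seed: int | None = None) -> GenotypeMatrix:
    """Draw the marker panel.

    Independent SNPs are binomial(2, MAF) per subject (HWE by construction).
    An LD block shares one MAF across its SNPs (tightly linked variants have
    near-identical frequencies) and draws each haplotype from a correlated
    latent Gaussian vector thresholded at the normal quantile of that MAF.
    The block's correlation parameter is the target allele-level correlation
    r (so pairwise LD r^2 ~ r^2 squared at the haplotype level); the latent
    Gaussian correlation is calibrated upward to undo the attenuation the
    thresholding introduces.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, m = spec.n_subjects, spec.n_snps
    mafs = rng.uniform(*spec.maf_range, size=m)
    for idx, maf in spec.snp_maf_overrides.items():
        mafs[idx] = maf
    calls = np.empty((n, m))

    block_cols: list[tuple[int, int, float]] = []
    j = 0
    for size, rho in spec.ld_blocks or []:
        if j + size > m:
            raise ValueError("LD blocks exceed the SNP panel")
        block_cols.append((j, j + size, rho))
        j += size
    in_block = np.zeros(m, dtype=bool)
    for a, b, _ in block_cols:
        in_block[a:b] = True

    free = ~in_block
    calls[:, free] = rng.binomial(2, mafs[free], size=(n, free.sum()))
    for a, b, target_r in block_cols:
        size = b - a
        maf = float(mafs[a])  # one frequency per block
        mafs[a:b] = maf
        rho = _latent_correlation(target_r, maf)
        cov = np.full((size, size), rho)
        np.fill_diagonal(cov, 1.0)
        L = np.linalg.cholesky(cov)
        thr = stats.norm.ppf(maf)
        g = np.zeros((n, size))
        for _hap in range(2):
            z = rng.standard_normal((n, size)) @ L.T
            g += (z < thr).astype(float)
        calls[:, a:b] = g

    chrom = np.array(["1"] * m, dtype=object)
    if spec.x_snps:
        chrom[m - spec.x_snps:] = "X"
    snps = pd.DataFrame(
        {
            "id": [f"snp{k + 1:05d}" for k in range(m)],
            "chrom": chrom,
            "pos": (np.arange(m) + 1) * 10_000,
            "minor": ["G"] * m,
            "major": ["A"] * m,
        }
    )
    sex = np.where(rng.random(n) < spec.prop_male, "M", "F")
    return GenotypeMatrix(_subject_ids(n), snps, calls, sex)


_DEFAULT_DISTS: dict[str, tuple] = {
    "age_years": ("uniform", 20.0, 85.0),
    "remi_rate_ug_kg_min": ("normal", 0.25, 0.05),
    "endsurg_fentanyl_ug": ("increments", 100.0, 50.0, 1.0),
    "pain2h_score": ("pain", 10, 0.3),
}


def gen_covariates(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Clinical covariate table (one row per subject).

    Defaults: age uniform on 20-85 y; remifentanil rate normal around the
    0.25 ug/kg/min protocol rate (clipped at 0.05); end-of-surgery fentanyl
    a 100 ug bolus plus Poisson-many 50 ug increments; 2-h pain score
    binomial on the 0-10 scale.
    """
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    n = spec.n_subjects
    data: dict[str, np.ndarray] = {}
    for name in DEFAULT_COVARIATES:
        dist = spec.covariate_dists.get(name, _DEFAULT_DISTS[name])
        kind = dist[0]
        if kind == "constant":
            col = np.full(n, float(dist[1]))
        elif kind == "uniform":
            col = rng.uniform(dist[1], dist[2], size=n)
        elif kind == "normal":
            col = np.clip(rng.normal(dist[1], dist[2], size=n), 0.05, None)
        elif kind == "increments":
            col = dist[1] + dist[2] * rng.poisson(dist[3], size=n)
        elif kind == "pain":
            col = rng.binomial(dist[1], dist[2], size=n).astype(float)
        else:
            raise ValueError(f"unknown covariate distribution {kind!r}")
        data[name] = col
    return pd.DataFrame(data, index=pd.Index(_subject_ids(n), name="subject_id"))


def gen_latent_mec(
    geno: GenotypeMatrix,
    covars: pd.DataFrame,
    spec: CohortSpec,
    seed: int | None = None,
) -> list[LatentPhenotype]:
    """Latent log effect-site MEC = intercept + genetics + covariates + noise."""
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 2)
    n = geno.n_subjects
    genetic = np.zeros(n)
    for idx, beta in spec.causal_snps:
        genetic += beta * np.nan_to_num(geno.calls[:, idx])
    covariate = np.zeros(n)
    for name, beta in spec.covariate_effects.items():
        covariate += beta * covars[name].to_numpy()
    residual = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    log_mec = spec.intercept + genetic + covariate + residual
    return [
        LatentPhenotype(sid, float(np.exp(lm)), float(g), float(c), float(r))
        for sid, lm, g, c, r in zip(geno.subjects, log_mec, genetic, covariate, residual)
    ]


def _next_downward_crossing(
    conc, thr: float, t_from: float, horizon: float, coarse: float = 0.5
) -> float | None:
    """First t in (t_from, horizon] where the curve falls through thr.

    The curve is scanned in expanding chunks at ``coarse`` resolution and
    the crossing is then polished by bracketed root search.
    """
    chunk = 120.0
    start = t_from
    while start < horizon - 1e-9:
        end = min(start + chunk, horizon)
        ts = np.arange(start, end, coarse)
        ts = np.append(ts, end)
        vals = np.asarray(conc(ts))
        hits = np.where((vals[:-1] > thr) & (vals[1:] <= thr))[0]
        if hits.size:
            i = int(hits[0])
            return float(optimize.brentq(
                lambda t: float(conc(np.array([t]))[0]) - thr,
                ts[i], ts[i + 1], xtol=1e-10))
        start = end
        chunk *= 2
    return None


def gen_dosing(
    latent: LatentPhenotype,
    params: PKParameters,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> tuple[DosingHistory, dict]:
    """Closed-loop PCA simulation for one subject.

    The initial bolus is placed at t=0.  A demand is placed at the first
    time the trigger-site concentration falls to the subject's (noise
    multiplied) threshold; if the pump rules forbid delivery at that moment
    the demand is delivered at the earliest allowed time instead and flagged
    as constrained.  Returns the history and an info dict with per-demand
    constrained flags and a ``bolus_only`` flag when the threshold is never
    reached from above.
    """
    if latent.latent_mec <= 0:
        raise ValueError("latent MEC must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    pump = spec.pca
    hybrid = hybrid_constants(params)
    state = SuperpositionState(hybrid)
    events = [DoseEvent(0.0, spec.initial_bolus_ug, "initial_bolus")]
    state.add_dose(0.0, spec.initial_bolus_ug)
    conc = state.ce if spec.trigger_site == "effect" else state.cp

    demand_times: list[float] = []
    constrained: list[bool] = []
    cum = 0.0
    horizon = spec.observation_end_min
    t_search = 0.0
    while cum + pump.demand_dose_ug <= pump.capacity_ug:
        thr = latent.latent_mec
        if spec.behavior_noise_sd > 0:
            thr *= float(np.exp(rng.normal(0.0, spec.behavior_noise_sd)))
        t_lock = demand_times[-1] + pump.lockout_min if demand_times else 0.0
        t_cap = 0.0
        if len(demand_times) >= pump.max_per_hour:
            t_cap = demand_times[-pump.max_per_hour] + 60.0
        t_allowed = max(t_lock, t_cap, t_search)
        if t_allowed >= horizon:
            break
        ce_allowed = float(conc(np.array([t_allowed]))[0])
        if demand_times and ce_allowed <= thr:
            # threshold was crossed while the pump rules forbade delivery
            td, was_constrained = t_allowed, ce_allowed < thr * (1 - 1e-9)
        else:
            cross = _next_downward_crossing(conc, thr, t_allowed, horizon)
            if cross is None:
                break
            td, was_constrained = cross, False
        if td > horizon:
            break
        events.append(DoseEvent(td, pump.demand_dose_ug, "pca_demand"))
        state.add_dose(td, pump.demand_dose_ug)
        demand_times.append(td)
        constrained.append(bool(was_constrained))
        cum += pump.demand_dose_ug
        t_search = td

    history = DosingHistory(latent.subject_id, events, horizon)
    info = {
        "constrained": constrained,
        "n_demands": len(demand_times),
        "bolus_only": len(demand_times) == 0,
        "exhausted": cum + pump.demand_dose_ug > pump.capacity_ug,
    }
    return history, info


def gen_cohort(spec: CohortSpec, params: PKParameters | None = None) -> CohortData:
    """Compose genotypes, covariates, latent MECs and dosing histories.

    The truth record lists the causal SNPs with their effects, every latent
    MEC, and the per-subject dosing flags needed by recovery tests.
    """
    if params is None:
        from .io import default_pk_parameters

        params = default_pk_parameters()
    geno = gen_genotypes(spec)
    covars = gen_covariates(spec)
    latents = gen_latent_mec(geno, covars, spec)
    rngs = _spawn(spec.seed + 3, spec.n_subjects)
    histories = []
    infos = []
    for latent, rng in zip(latents, rngs):
        h, info = gen_dosing(latent, params, spec, rng)
        histories.append(h)
        infos.append(info)
    truth = {
        "seed": spec.seed,
        "causal_snps": [
            {"index": int(i), "id": geno.snps["id"].iloc[i], "beta_per_copy": float(b)}
            for i, b in spec.causal_snps
        ],
        "latent_mec": {lat.subject_id: lat.latent_mec for lat in latents},
        "dosing": {
            h.subject_id: {
                "n_demands": info["n_demands"],
                "n_constrained": int(sum(info["constrained"])),
                "constrained": info["constrained"],
                "bolus_only": info["bolus_only"],
                "exhausted": info["exhausted"],
            }
            for h, info in zip(histories, infos)
        },
    }
    return CohortData(geno, covars, latents, histories, truth)
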