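"""Synthetic two-sample GWAS summary statistics and multi-compound trial data.

The generator emulates the statistical structure a cis drug-target MR
consumes: a protein exposure instrumented by variants in one LD block
(AR(1) correlation), optional downstream mediators, an outcome affected by
the protein either directly or only through mediators, and three strictly
non-overlapping samples (exposure GWAS, outcome GWAS, LD reference panel)
so the two-sample assumptions hold by construction.  Genotypes default to
continuous multivariate-normal dosage surrogates, which reproduce the
covariance structure that summary statistics inherit; a discrete mode
rounds to {0, 1, 2} via liability thresholds matching each variant's MAF.

Trial datasets mimic a compound-stratified RCT literature: each compound
carries true percent-change effects on biomarkers and true log odds ratios
on clinical events (allowing planted off-target effects), and each trial
reports a noisy mean difference with its 95% CI, or binomial event counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from targetmr.gwas_io import SummaryTable, SUMMARY_COLUMNS
from targetmr.instruments import LDMatrix
from targetmr.trial_meta import TRIAL_COLUMNS, Z95

# non-palindromic allele pairs only, so default fixtures never hit the
# strand-ambiguity path unless a test plants palindromes deliberately
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]


@dataclass
class SimConfig:
    """Generating parameters for one two-sample summary-statistics dataset.

    ``gamma`` holds per-variant effects on the protein (missing entries are
    zero); when None, ``n_causal`` variants evenly spaced across the region
    receive effects of size ``gamma_scale``.  ``mediation`` maps mediator
    name -> (alpha, beta_med): protein -> mediator slope and mediator ->
    outcome slope.  With mediators present the outcome depends on the
    protein only through them; otherwise ``theta`` is the direct protein ->
    outcome effect.  ``outcome_prevalence`` switches the outcome to a
    liability-thresholded binary trait analyzed by logistic regression.
    """

    m: int = 50
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exposure: int = 10_000
    n_outcome: int = 50_000
    n_reference: int = 5_000
    gamma: np.ndarray | None = None
    n_causal: int = 5
    gamma_scale: float = 0.25
    theta: float = 0.2
    mediation: dict[str, tuple[float, float]] = field(default_factory=dict)
    mediator_direct_scale: float = 0.15
    outcome_prevalence: float | None = None
    discrete_dosages: bool = False
    scramble_outcome_alleles: bool = True
    chrom: str = "16"
    pos_start: int = 56_961_923
    pos_step: int = 480
    seed: int = 0

    def __post_init__(self):
        if min(self.n_exposure, self.n_outcome, self.n_reference) < 2:
            raise ValueError("all sample sizes must be >= 2")
        if not abs(self.ld_rho) < 1:
            raise ValueError("|ld_rho| must be < 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.outcome_prevalence is not None and not (0 < self.outcome_prevalence < 1):
            raise ValueError("outcome_prevalence must lie in (0, 1)")


@dataclass
class TrialSimConfig:
    """Generating parameters for a multi-compound trial dataset.

    ``compounds`` maps compound name -> {"md": {outcome: true % MD},
    "logor": {outcome: true log-OR}}.  Defaults emulate a four-compound
    CETP-inhibitor literature: two potent compounds with large HDL-C
    raising / LDL-C lowering action, one with attenuated lipid effects,
    and one with an off-target harmful event effect.
    """

    compounds: dict = field(default_factory=lambda: {
        "potent_a": {"md": {"HDL-C": 130.0, "LDL-C": -38.0, "SBP": 0.7},
                      "logor": {"CVD": np.log(0.93)}},
        "potent_b": {"md": {"HDL-C": 132.0, "LDL-C": -37.0, "SBP": 0.9},
                      "logor": {"CVD": np.log(0.96)}},
        "offtarget": {"md": {"HDL-C": 52.0, "LDL-C": -20.0, "SBP": 4.6},
                       "logor": {"CVD": np.log(1.22)}},
        "weak": {"md": {"HDL-C": 29.0, "LDL-C": -1.0, "SBP": -0.5},
                  "logor": {"CVD": 0.0}},
    })
    trials_per_compound: dict | int = field(default_factory=lambda: {
        "potent_a": 6, "potent_b": 1, "offtarget": 4, "weak": 4,
    })
    arm_size: int = 1_300
    control_risk: float = 0.10
    md_sd: float = 18.0  # per-subject SD of percent change from baseline
    followup_months: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.arm_size < 10:
            raise ValueError("arm sizes must be >= 10")
        if not (0 < self.control_risk < 1):
            raise ValueError("control_risk must lie in (0, 1)")


def gen_ld_ar1(m: int, ld_rho: float, keys: list[str] | None = None) -> LDMatrix:
    """AR(1) LD: r[i, j] = ld_rho^|i - j|; positive definite for |rho| < 1."""
    if not abs(ld_rho) < 1:
        raise ValueError("|ld_rho| must be < 1")
    idx = np.arange(m)
    r = ld_rho ** np.abs(idx[:, None] - idx[None, :])
    return LDMatrix(keys if keys is not None else [f"v{i}" for i in range(m)], r)


def _default_gamma(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    gamma = np.zeros(cfg.m)
    idx = np.linspace(0, cfg.m - 1, num=min(cfg.n_causal, cfg.m)).round().astype(int)
    gamma[idx] = cfg.gamma_scale * rng.choice([1.0, -1.0], size=idx.size) * rng.uniform(
        0.8, 1.2, size=idx.size
    )
    return gamma


def _draw_genotypes(
    rng: np.random.Generator, n: int, chol: np.ndarray, mafs: np.ndarray, discrete: bool
) -> np.ndarray:
    """Standardized genotype scores with the target LD.

    Continuous mode returns the MVN scores directly; discrete mode
    thresholds two latent haplotypes per individual at the MAF quantile and
    standardizes the resulting {0,1,2} dosage.
    """
    if not discrete:
        return rng.standard_normal((n, chol.shape[0])) @ chol.T
    cut = stats.norm.ppf(mafs)
    h1 = rng.standard_normal((n, chol.shape[0])) @ chol.T < cut
    h2 = rng.standard_normal((n, chol.shape[0])) @ chol.T < cut
    d = (h1.astype(float) + h2.astype(float))
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    return (d - d.mean(axis=0)) / sd


def _marginal_linear(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple linear regression of y on g (vectorized)."""
    n = y.size
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    beta = sxy / sxx
    syy = float(yc @ yc)
    resid_var = np.clip(syy - beta * sxy, 0.0, None) / (n - 2)
    se = np.sqrt(resid_var / sxx)
    tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    return beta, se, np.clip(p, np.finfo(float).tiny, 1.0)


def _marginal_logistic(
    g: np.ndarray, y: np.ndarray, n_iter: int = 30
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column logistic regression (intercept + dosage), batched Newton."""
    n, m = g.shape
    ybar = y.mean()
    b0 = np.full(m, np.log(ybar / (1 - ybar)))
    b1 = np.zeros(m)
    for _ in range(n_iter):
        eta = b0[None, :] + g * b1[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        r = y[:, None] - p
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", g, r)
        h00 = w.sum(axis=0)
        h01 = np.einsum("ij,ij->j", g, w)
        h11 = np.einsum("ij,ij,ij->j", g, g, w)
        det = h00 * h11 - h01**2
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        b0 += db0
        b1 += db1
        if max(np.abs(db0).max(), np.abs(db1).max()) < 1e-10:
            break
    eta = b0[None, :] + g * b1[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    h00 = w.sum(axis=0)
    h01 = np.einsum("ij,ij->j", g, w)
    h11 = np.einsum("ij,ij,ij->j", g, g, w)
    se = np.sqrt(h00 / (h00 * h11 - h01**2))
    z = b1 / se
    pval = 2 * stats.norm.sf(np.abs(z))
    return b1, se, np.clip(pval, np.finfo(float).tiny, 1.0)


def _make_table(
    meta: pd.DataFrame, beta, se, p, n: int, name: str, trait_type: str, unit: str,
) -> SummaryTable:
    df = meta.copy()
    df["beta"] = beta
    df["se"] = se
    df["pvalue"] = p
    df["n"] = n
    return SummaryTable(name, trait_type, unit, "GRCh38", df[SUMMARY_COLUMNS].reset_index(drop=True))


def gen_two_sample_summary(cfg: SimConfig):
    """Simulate exposure/mediator/outcome summary statistics plus a reference.

    Returns ``(exposure_tables, outcome_table, reference_dosages, truth)``:
    exposure_tables is a dict with the protein table under "protein" plus
    one table per mediator; reference_dosages is an individuals x variants
    DataFrame whose columns are variant keys; truth records every
    generating parameter including the LD-smeared expected marginal
    exposure betas (R @ gamma).

    The three samples are drawn from disjoint random streams and never share
    individuals.  When ``scramble_outcome_alleles`` is on, a random subset
    of outcome records is re-expressed on the opposite effect allele
    (labels swapped, beta negated, EAF complemented) so harmonization has
    real work to do.
    """
    rng = np.random.default_rng(cfg.seed)
    # independent child streams: the two-sample guarantee by construction
    r_exp, r_out, r_ref, r_misc = rng.spawn(4)

    mafs = r_misc.uniform(*cfg.maf_range, size=cfg.m)
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(cfg.m)]
    pos = cfg.pos_start + cfg.pos_step * np.arange(cfg.m)
    meta = pd.DataFrame(
        {
            "variant_id": [f"rs{100000 + i}" for i in range(cfg.m)],
            "chrom": cfg.chrom,
            "pos": pos,
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "eaf": mafs,
        }
    )

    ld = gen_ld_ar1(cfg.m, cfg.ld_rho)
    chol = np.linalg.cholesky(ld.r)
    gamma = np.asarray(cfg.gamma, dtype=float) if cfg.gamma is not None else _default_gamma(cfg, r_misc)
    if gamma.shape != (cfg.m,):
        raise ValueError("gamma must have length m")

    # each mediator also carries its own sparse direct cis effects (distinct
    # variants per mediator) so that mediator beta profiles are not exactly
    # proportional — without this, multivariable MR would be unidentifiable
    deltas: dict[str, np.ndarray] = {}
    for j, name in enumerate(cfg.mediation):
        delta = np.zeros(cfg.m)
        idx = (np.arange(max(1, cfg.m // 10)) * 7 + 3 * j + 1) % cfg.m
        delta[np.unique(idx)] = cfg.mediator_direct_scale * r_misc.choice(
            [1.0, -1.0], size=np.unique(idx).size
        )
        deltas[name] = delta

    def protein_and_mediators(g: np.ndarray, rstream: np.random.Generator):
        x = g @ gamma + rstream.standard_normal(g.shape[0])
        meds = {
            name: alpha * x + g @ deltas[name] + rstream.standard_normal(g.shape[0])
            for name, (alpha, _) in cfg.mediation.items()
        }
        return x, meds

    # exposure sample: protein + mediator GWAS
    g_e = _draw_genotypes(r_exp, cfg.n_exposure, chol, mafs, cfg.discrete_dosages)
    x_e, meds_e = protein_and_mediators(g_e, r_exp)
    exposure_tables: dict[str, SummaryTable] = {}
    beta, se, p = _marginal_linear(g_e, x_e)
    exposure_tables["protein"] = _make_table(
        meta, beta, se, p, cfg.n_exposure, "protein", "continuous", "ug/ml"
    )
    for name, vals in meds_e.items():
        beta, se, p = _marginal_linear(g_e, vals)
        exposure_tables[name] = _make_table(
            meta, beta, se, p, cfg.n_exposure, name, "continuous", "SD"
        )

    # outcome sample
    g_o = _draw_genotypes(r_out, cfg.n_outcome, chol, mafs, cfg.discrete_dosages)
    x_o, meds_o = protein_and_mediators(g_o, r_out)
    if cfg.mediation:
        liability = sum(b * meds_o[n] for n, (_, b) in cfg.mediation.items())
    else:
        liability = cfg.theta * x_o
    liability = liability + r_out.standard_normal(cfg.n_outcome)
    if cfg.outcome_prevalence is None:
        beta, se, p = _marginal_linear(g_o, liability)
        outcome = _make_table(
            meta, beta, se, p, cfg.n_outcome, "outcome", "continuous", "SD"
        )
    else:
        cut = np.quantile(liability, 1 - cfg.outcome_prevalence)
        y = (liability > cut).astype(float)
        if y.sum() < 10 or y.sum() > cfg.n_outcome - 10:
            raise ValueError("infeasible outcome prevalence for this sample size")
        beta, se, p = _marginal_logistic(g_o, y)
        outcome = _make_table(
            meta, beta, se, p, cfg.n_outcome, "outcome", "binary", "logOR"
        )

    if cfg.scramble_outcome_alleles:
        flip = r_misc.random(cfg.m) < 0.5
        odf = outcome.df
        ea = odf.loc[flip, "effect_allele"].copy()
        odf.loc[flip, "effect_allele"] = odf.loc[flip, "other_allele"].to_numpy()
        odf.loc[flip, "other_allele"] = ea.to_numpy()
        odf.loc[flip, "beta"] = -odf.loc[flip, "beta"]
        odf.loc[flip, "eaf"] = 1.0 - odf.loc[flip, "eaf"]

    # reference panel: dosage-like scores centered at 1 per variant
    g_r = _draw_genotypes(r_ref, cfg.n_reference, chol, mafs, cfg.discrete_dosages)
    from targetmr.gwas_io import variant_keys

    keys = list(variant_keys(meta.assign(pos=meta["pos"].astype(int))))
    reference = pd.DataFrame(1.0 + g_r, columns=keys)

    truth = {
        "gamma": gamma,
        "theta": cfg.theta if not cfg.mediation else None,
        "mediation": dict(cfg.mediation),
        "mediator_direct": deltas,
        "expected_marginal_bx": ld.r @ gamma,
        "ld": ld,
        "mafs": mafs,
        "config": cfg,
    }
    return exposure_tables, outcome, reference, truth


def gen_trialset(cfg: TrialSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a compound-stratified trial table in the pooling CSV schema.

    Continuous outcomes: each trial reports md ~ N(true MD, se^2) with
    se = md_sd * sqrt(2 / arm_size), and a 95% CI consistent with that SE.
    Binary outcomes: control events ~ Binomial(arm, control_risk); treated
    events ~ Binomial(arm, p1) where odds(p1) = odds(control) * exp(logOR).
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for compound, effects in cfg.compounds.items():
        k = (
            cfg.trials_per_compound
            if isinstance(cfg.trials_per_compound, int)
            else cfg.trials_per_compound.get(compound, 1)
        )
        for t in range(k):
            study = f"{compound}_trial{t + 1}"
            for outcome, true_md in effects.get("md", {}).items():
                se = cfg.md_sd * np.sqrt(2.0 / cfg.arm_size)
                md = rng.normal(true_md, se)
                rows.append(
                    dict(
                        study_id=study, compound=compound, outcome=outcome,
                        type="continuous", md=md,
                        ci_low=md - Z95 * se, ci_high=md + Z95 * se,
                        followup_months=cfg.followup_months,
                    )
                )
            for outcome, logor in effects.get("logor", {}).items():
                p0 = cfg.control_risk
                odds1 = p0 / (1 - p0) * np.exp(logor)
                p1 = odds1 / (1 + odds1)
                rows.append(
                    dict(
                        study_id=study, compound=compound, outcome=outcome,
                        type="binary",
                        t_events=int(rng.binomial(cfg.arm_size, p1)),
                        t_total=cfg.arm_size,
                        c_events=int(rng.binomial(cfg.arm_size, p0)),
                        c_total=cfg.arm_size,
                        followup_months=cfg.followup_months,
                    )
                )
    df = pd.DataFrame(rows)
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[TRIAL_COLUMNS]
    truth = {"compounds": cfg.compounds, "config": cfg}
    return df, truth
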