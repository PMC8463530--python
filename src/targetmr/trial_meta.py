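"""Compound-stratified meta-analysis of randomized-trial effects.

Binary endpoints are pooled as log odds ratios extracted from 2x2 event
tables (0.5 continuity correction to all four cells of any zero-cell table;
double-zero trials are excluded).  Continuous endpoints are pooled as the
between-group difference in percentage change from baseline, on the reported
percent scale, with the SE back-transformed from a 95% CI when that is what
a trial reports.  Fixed-effect pooling is inverse-variance weighting;
random-effects uses the DerSimonian-Laird moment estimator of tau^2.
Between-compound heterogeneity treats each compound's pooled estimate as
one unit in a Cochran Q test — the signal that distinguishes compound
failure from target failure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from targetmr.gwas_io import ExclusionRecord

Z95 = 1.959964  # normal quantile for all 95% CI back-transforms

TRIAL_COLUMNS = [
    "study_id", "compound", "outcome", "type",
    "t_events", "t_total", "c_events", "c_total",
    "md", "ci_low", "ci_high", "se", "followup_months",
]


@dataclass
class TrialOutcome:
    """One study x outcome record extracted from a trial report."""

    study_id: str
    compound: str
    outcome: str
    type: str  # "binary" | "continuous"
    t_events: int | None = None
    t_total: int | None = None
    c_events: int | None = None
    c_total: int | None = None
    md: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    se: float | None = None
    followup_months: float | None = None

    def __post_init__(self):
        if self.type == "binary":
            cells = (self.t_events, self.t_total, self.c_events, self.c_total)
            if any(c is None for c in cells):
                raise ValueError(f"{self.study_id}: binary outcome needs all four counts")
            if self.t_events > self.t_total or self.c_events > self.c_total:
                raise ValueError(f"{self.study_id}: events exceed arm total")
        elif self.type == "continuous":
            if self.md is None:
                raise ValueError(f"{self.study_id}: continuous outcome needs md")
            has_ci = self.ci_low is not None and self.ci_high is not None
            if not has_ci and self.se is None:
                raise ValueError(f"{self.study_id}: continuous outcome needs a CI or an SE")
            if has_ci and self.ci_low >= self.ci_high:
                raise ValueError(f"{self.study_id}: ci_low must be below ci_high")
        else:
            raise ValueError(f"outcome type must be binary/continuous, got {self.type!r}")


@dataclass
class PointEstimate:
    """A single trial's effect on a common scale (log-OR or % MD)."""

    study_id: str
    compound: str
    outcome: str
    effect: float
    se: float
    scale: str  # "logOR" | "MD%"

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.study_id}: SE must be positive")


@dataclass
class MetaEstimate:
    """Pooled effect for one compound x outcome (or an overall pool)."""

    compound: str
    outcome: str
    effect: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    Q_within: float
    df: int
    tau2: float
    k_studies: int
    model: str  # "fixed" | "random"
    scale: str = ""

    @property
    def odds_ratio(self) -> float:
        if self.scale != "logOR":
            raise ValueError("odds_ratio only defined on the logOR scale")
        return math.exp(self.effect)


def effect_from_trial(t: TrialOutcome) -> PointEstimate | ExclusionRecord:
    """Per-trial effect and SE on the pooling scale.

    Binary: log-OR = ln(a d / (b c)), se = sqrt(1/a + 1/b + 1/c + 1/d),
    with 0.5 added to all four cells whenever any cell is zero; trials with
    zero events in both arms carry no information about the OR and are
    returned as an exclusion record instead of an estimate.  Continuous:
    the reported mean difference, with se = (ci_high - ci_low) / (2 * 1.959964)
    when only a 95% CI is given.
    """
    if t.type == "binary":
        if t.t_events == 0 and t.c_events == 0:
            return ExclusionRecord(t.study_id, "effect", "double-zero-events")
        a = float(t.t_events)
        b = float(t.t_total - t.t_events)
        c = float(t.c_events)
        d = float(t.c_total - t.c_events)
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        log_or = math.log(a * d / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        return PointEstimate(t.study_id, t.compound, t.outcome, log_or, se, "logOR")
    se = t.se if t.se is not None else (t.ci_high - t.ci_low) / (2 * Z95)
    return PointEstimate(t.study_id, t.compound, t.outcome, float(t.md), float(se), "MD%")


def se_from_or_ci(ci_low: float, ci_high: float) -> float:
    """SE of a log odds ratio back-transformed from its reported 95% CI."""
    return (math.log(ci_high) - math.log(ci_low)) / (2 * Z95)


def _check_scale(estimates: list[PointEstimate]) -> str:
    scales = {e.scale for e in estimates}
    if len(scales) > 1:
        raise ValueError(f"cannot pool mixed scales: {sorted(scales)}")
    return estimates[0].scale


def pool_fixed(estimates: list[PointEstimate], label: str = "") -> MetaEstimate:
    """Fixed-effect inverse-variance pooling with within-group Cochran Q."""
    if not estimates:
        raise ValueError("nothing to pool")
    scale = _check_scale(estimates)
    e = np.array([x.effect for x in estimates])
    w = np.array([1.0 / x.se**2 for x in estimates])
    pooled = float(np.sum(w * e) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (e - pooled) ** 2))
    k = len(estimates)
    z = pooled / se
    return MetaEstimate(
        compound=label or _common(estimates, "compound"),
        outcome=_common(estimates, "outcome"),
        effect=pooled,
        se=se,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        p=float(2 * stats.norm.sf(abs(z))),
        Q_within=q,
        df=k - 1,
        tau2=0.0,
        k_studies=k,
        model="fixed",
        scale=scale,
    )


def pool_random(estimates: list[PointEstimate], label: str = "") -> MetaEstimate:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) from the fixed-
    effect weights, then re-pool with weights 1/(se^2 + tau^2).  When
    Q <= df, tau^2 = 0 and the result coincides with the fixed-effect pool.
    """
    if not estimates:
        raise ValueError("nothing to pool")
    scale = _check_scale(estimates)
    if len(estimates) == 1:
        warnings.warn("single study: random-effects pool equals the study, tau2 = 0")
        fe = pool_fixed(estimates, label)
        fe.model = "random"
        return fe
    fixed = pool_fixed(estimates, label)
    w = np.array([1.0 / x.se**2 for x in estimates])
    df = len(estimates) - 1
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (fixed.Q_within - df) / c)
    e = np.array([x.effect for x in estimates])
    w_star = 1.0 / (np.array([x.se**2 for x in estimates]) + tau2)
    pooled = float(np.sum(w_star * e) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    z = pooled / se
    return MetaEstimate(
        compound=fixed.compound,
        outcome=fixed.outcome,
        effect=pooled,
        se=se,
        ci_low=pooled - Z95 * se,
        ci_high=pooled + Z95 * se,
        p=float(2 * stats.norm.sf(abs(z))),
        Q_within=fixed.Q_within,
        df=df,
        tau2=float(tau2),
        k_studies=len(estimates),
        model="random",
        scale=scale,
    )


def between_compound_q(compound_estimates: list[MetaEstimate]) -> tuple[float, int, float]:
    """Cochran Q across compounds, one unit per compound.

    Each compound's pooled estimate enters with weight 1/se^2 against the
    fixed pool of the compound estimates; Q ~ chi-square(#compounds - 1)
    under compound homogeneity.  A small p indicates that the compounds do
    not share one effect — evidence of compound-specific (off-target or
    potency) differences.
    """
    if len(compound_estimates) < 2:
        raise ValueError("between-compound heterogeneity needs >= 2 compounds")
    scales = {m.scale for m in compound_estimates}
    outcomes = {m.outcome for m in compound_estimates}
    if len(scales) > 1 or len(outcomes) > 1:
        raise ValueError("compound estimates must share one outcome and scale")
    e = np.array([m.effect for m in compound_estimates])
    w = np.array([1.0 / m.se**2 for m in compound_estimates])
    overall = np.sum(w * e) / np.sum(w)
    q = float(np.sum(w * (e - overall) ** 2))
    df = len(compound_estimates) - 1
    return q, df, float(stats.chi2.sf(q, df))


def meta_regress(
    estimates: list[PointEstimate],
    covariate: np.ndarray,
) -> dict:
    """Random-effects meta-regression of trial effects on one covariate.

    Weighted least squares with weights 1/(se_i^2 + tau^2); tau^2 by method
    of moments on the WLS residuals (floored at zero).  Returns slope,
    intercept, their SEs and a two-sided normal p for the slope.  The slope
    is invariant to centering the covariate.
    """
    if len(estimates) < 3:
        raise ValueError("meta-regression needs >= 3 trials")
    x = np.asarray(covariate, dtype=float)
    if x.size != len(estimates):
        raise ValueError("covariate length must match estimates")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    _check_scale(estimates)
    y = np.array([e.effect for e in estimates])
    v = np.array([e.se**2 for e in estimates])
    X = np.column_stack([np.ones_like(x), x])
    k, p_dim = X.shape

    def wls(tau2):
        w = 1.0 / (v + tau2)
        A = X.T @ (X * w[:, None])
        beta = np.linalg.solve(A, X.T @ (w * y))
        return beta, w, A

    beta, w, A = wls(0.0)
    resid = y - X @ beta
    q = float(np.sum(w * resid**2))
    # method-of-moments: E[Q] = (k - p) + tau2 * (tr(P) ...) with P the
    # weight projection; the standard DL-style denominator
    W = np.diag(w)
    P = W - W @ X @ np.linalg.solve(A, X.T @ W)
    denom = float(np.trace(P))
    tau2 = max(0.0, (q - (k - p_dim)) / denom) if denom > 0 else 0.0
    beta, w, A = wls(tau2)
    cov = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    z = beta[1] / se[1]
    return {
        "slope": float(beta[1]),
        "slope_se": float(se[1]),
        "intercept": float(beta[0]),
        "intercept_se": float(se[0]),
        "tau2": float(tau2),
        "p": float(2 * stats.norm.sf(abs(z))),
        "k": k,
    }


def funnel_coords(
    estimates: list[PointEstimate],
    pooled: MetaEstimate,
    n_grid: int = 50,
) -> dict[str, pd.DataFrame]:
    """Scatter and pseudo-95% funnel boundary for small-study inspection.

    The boundary traces pooled +/- 1.959964 * se over an SE grid from 0 to
    the largest observed SE; at se = 0 both boundary arms meet at the
    pooled estimate.
    """
    pts = pd.DataFrame(
        {
            "study_id": [e.study_id for e in estimates],
            "effect": [e.effect for e in estimates],
            "se": [e.se for e in estimates],
        }
    )
    se_grid = np.linspace(0.0, max(e.se for e in estimates), n_grid)
    boundary = pd.DataFrame(
        {
            "se": se_grid,
            "low": pooled.effect - Z95 * se_grid,
            "high": pooled.effect + Z95 * se_grid,
        }
    )
    return {"points": pts, "boundary": boundary}


def _common(estimates: list[PointEstimate], attr: str) -> str:
    vals = {getattr(e, attr) for e in estimates}
    return vals.pop() if len(vals) == 1 else "mixed"


def read_trials(path) -> list[TrialOutcome]:
    """Read a trial-effects CSV (columns per :data:`TRIAL_COLUMNS`; unused
    cells empty) into validated records."""
    return trials_from_frame(pd.read_csv(path))


def trials_from_frame(df: pd.DataFrame) -> list[TrialOutcome]:
    """Validate an in-memory trial-effects frame into records."""
    missing = [c for c in ("study_id", "compound", "outcome", "type") if c not in df.columns]
    if missing:
        raise KeyError(f"trials file lacks columns: {missing}")
    out = []
    for row in df.to_dict("records"):
        kwargs = {k: row.get(k) for k in TRIAL_COLUMNS if k in row}
        for k in ("t_events", "t_total", "c_events", "c_total"):
            v = kwargs.get(k)
            kwargs[k] = int(v) if v is not None and not _na(v) else None
        for k in ("md", "ci_low", "ci_high", "se", "followup_months"):
            v = kwargs.get(k)
            kwargs[k] = float(v) if v is not None and not _na(v) else None
        out.append(TrialOutcome(**kwargs))
    return out


def _na(v) -> bool:
    return isinstance(v, float) and math.isnan(v)


def compound_meta(
    trials: list[TrialOutcome],
    outcome: str,
    model: str = "fixed",
) -> tuple[dict[str, MetaEstimate], list[ExclusionRecord]]:
    """Pool one outcome per compound; returns the per-compound estimates
    and the exclusion records (double-zero trials)."""
    pool = pool_fixed if model == "fixed" else pool_random
    by_compound: dict[str, list[PointEstimate]] = {}
    exclusions: list[ExclusionRecord] = []
    for t in trials:
        if t.outcome != outcome:
            continue
        res = effect_from_trial(t)
        if isinstance(res, ExclusionRecord):
            exclusions.append(res)
        else:
            by_compound.setdefault(t.compound, []).append(res)
    return {c: pool(ests, label=c) for c, ests in sorted(by_compound.items())}, exclusions
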