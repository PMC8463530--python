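"""Correlated-instrument GLS-IVW estimation, heterogeneity, and pruning.

Genetic associations with an outcome are regressed on genetic associations
with the exposure (drug-target protein concentration or a downstream
biomarker) through the origin, with residual LD between instruments modeled
by generalized least squares:

    Omega = diag(s_y) . rho . diag(s_y)
    theta = (X' Omega^-1 X)^-1 X' Omega^-1 b_y

where X is the vector b_x (univariable) or the matrix B_x (multivariable).
Under no horizontal pleiotropy the slope estimates the causal effect of the
exposure on the outcome per unit of exposure.  Exposure standard errors are
carried but not propagated: in the two-sample design residual weak-instrument
error attenuates the slope toward the null, so the first-order Omega is
conservative.

Heterogeneity is quantified by the generalized Cochran Q on the GLS
residuals; instruments exerting undue influence are removed by iterated
leverage/outlier pruning in the whitened design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from targetmr.instruments import InstrumentSet, LDMatrix, nearest_psd


@dataclass
class MRInput:
    """Univariable GLS design: m instruments for one exposure/outcome pair."""

    b_x: np.ndarray
    s_x: np.ndarray
    b_y: np.ndarray
    s_y: np.ndarray
    rho: np.ndarray
    variant_keys: list[str] = field(default_factory=list)
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    exposure_unit: str = ""
    outcome_unit: str = ""

    def __post_init__(self):
        for name in ("b_x", "s_x", "b_y", "s_y"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        m = self.b_x.size
        if not (self.s_x.size == self.b_y.size == self.s_y.size == m):
            raise ValueError("b_x, s_x, b_y, s_y must share length")
        if self.rho.shape != (m, m):
            raise ValueError("rho must be m x m")
        if np.any(self.s_y <= 0):
            raise ValueError("outcome SEs must be positive")
        if not self.variant_keys:
            self.variant_keys = [f"v{i}" for i in range(m)]

    @property
    def m(self) -> int:
        return self.b_x.size

    @property
    def design(self) -> np.ndarray:
        return self.b_x[:, None]

    @property
    def k(self) -> int:
        return 1

    @classmethod
    def from_instrument_set(cls, inst: InstrumentSet) -> "MRInput":
        df = inst.pairs.df
        return cls(
            b_x=df["b_x"].to_numpy(),
            s_x=df["s_x"].to_numpy(),
            b_y=df["b_y"].to_numpy(),
            s_y=df["s_y"].to_numpy(),
            rho=inst.ld.r,
            variant_keys=list(df["key"]),
            exposure_name=inst.pairs.exposure_name,
            outcome_name=inst.pairs.outcome_name,
            exposure_unit=inst.pairs.exposure_unit,
            outcome_unit=inst.pairs.outcome_unit,
        )


@dataclass
class MVMRInput:
    """Multivariable design: m instruments for k jointly modeled exposures."""

    B_x: np.ndarray
    exposure_names: list[str]
    b_y: np.ndarray
    s_y: np.ndarray
    rho: np.ndarray
    variant_keys: list[str] = field(default_factory=list)
    outcome_name: str = "outcome"
    outcome_unit: str = ""
    condition_max: float = 1e8

    def __post_init__(self):
        self.B_x = np.atleast_2d(np.asarray(self.B_x, dtype=float))
        if self.B_x.shape[0] == 1 and len(self.exposure_names) == 1 and self.B_x.shape[1] > 1:
            self.B_x = self.B_x.T
        self.b_y = np.atleast_1d(np.asarray(self.b_y, dtype=float))
        self.s_y = np.atleast_1d(np.asarray(self.s_y, dtype=float))
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        m, k = self.B_x.shape
        if k != len(self.exposure_names):
            raise ValueError("exposure_names must match B_x columns")
        if k >= m:
            raise ValueError(f"need more instruments ({m}) than exposures ({k})")
        if np.any(self.s_y <= 0):
            raise ValueError("outcome SEs must be positive")
        if np.linalg.cond(self.B_x) > self.condition_max:
            raise ValueError(
                f"exposure beta columns are collinear: {self.exposure_names}"
            )
        if not self.variant_keys:
            self.variant_keys = [f"v{i}" for i in range(m)]

    @property
    def m(self) -> int:
        return self.B_x.shape[0]

    @property
    def design(self) -> np.ndarray:
        return self.B_x

    @property
    def k(self) -> int:
        return self.B_x.shape[1]


@dataclass
class MRResult:
    """Slope estimate(s), Wald inference, heterogeneity and provenance."""

    exposure_names: list[str]
    outcome_name: str
    theta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    Q: float
    df_Q: int
    p_Q: float | None
    m_used: int
    excluded: list = field(default_factory=list)
    orientation: str = "raw"
    conditional_f: np.ndarray | None = None
    overdispersion: bool = False

    def single(self) -> tuple[float, float, float]:
        """(theta, se, p) for a univariable result."""
        return float(self.theta[0]), float(self.se[0]), float(self.p[0])


def _omega_inverse(s_y: np.ndarray, rho: np.ndarray) -> np.ndarray:
    rho_psd, _ = nearest_psd(rho)
    omega = np.outer(s_y, s_y) * rho_psd
    try:
        w, v = np.linalg.eigh(omega)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise np.linalg.LinAlgError(f"Omega eigendecomposition failed: {err}")
    if w.min() <= 1e-8 * w.max():
        raise np.linalg.LinAlgError(
            "Omega is singular beyond regularization tolerance; "
            "clump instruments at a lower r2 threshold"
        )
    return (v / w) @ v.T


def _gls_fit(X: np.ndarray, b_y: np.ndarray, s_y: np.ndarray, rho: np.ndarray):
    oi = _omega_inverse(s_y, rho)
    xtoi = X.T @ oi
    A = xtoi @ X
    Ainv = np.linalg.inv(A)
    theta = Ainv @ (xtoi @ b_y)
    return theta, Ainv, oi


def heterogeneity_q(inp: MRInput | MVMRInput, theta: np.ndarray) -> tuple[float, int, float | None]:
    """Generalized Cochran Q of the GLS residuals.

    Q = (b_y - X theta)' Omega^-1 (b_y - X theta), chi-square with m - k
    degrees of freedom under homogeneity.  With df < 1 the statistic is
    still returned but the p-value is withheld.
    """
    X = inp.design
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    oi = _omega_inverse(inp.s_y, inp.rho)
    resid = inp.b_y - X @ theta
    q = float(resid @ oi @ resid)
    df = inp.m - inp.k
    p = float(stats.chi2.sf(q, df)) if df >= 1 else None
    return q, df, p


def gls_ivw(inp: MRInput, overdispersion: bool = False) -> MRResult:
    """Correlated-instrument inverse-variance-weighted slope by GLS.

    With rho the identity this reduces to textbook IVW (weighted least
    squares through the origin with weights 1/s_y^2); with a single
    instrument it is the Wald ratio b_y/b_x.  ``overdispersion`` optionally
    inflates the SE by sqrt(max(1, Q/(m - 1))).
    """
    if inp.m < 1:
        raise ValueError("need at least one instrument")
    theta, Ainv, _ = _gls_fit(inp.design, inp.b_y, inp.s_y, inp.rho)
    se = np.sqrt(np.diag(Ainv))
    q, df, p_q = heterogeneity_q(inp, theta)
    if overdispersion and df >= 1:
        se = se * np.sqrt(max(1.0, q / df))
    z = theta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return MRResult(
        exposure_names=[inp.exposure_name],
        outcome_name=inp.outcome_name,
        theta=theta,
        se=se,
        z=z,
        p=p,
        Q=q,
        df_Q=df,
        p_Q=p_q,
        m_used=inp.m,
        overdispersion=overdispersion,
    )


def mvmr_gls(inp: MVMRInput, overdispersion: bool = False) -> MRResult:
    """Multivariable GLS-IVW: joint slopes for k candidate mediators.

    Per-exposure SEs come from the diagonal of (B_x' Omega^-1 B_x)^-1.
    Conditional instrument strength is reported per exposure as the
    conditional F-like statistic from regressing each exposure's betas on
    the others' in the whitened design.
    """
    theta, Ainv, oi = _gls_fit(inp.design, inp.b_y, inp.s_y, inp.rho)
    se = np.sqrt(np.diag(Ainv))
    q, df, p_q = heterogeneity_q(inp, theta)
    if overdispersion and df >= 1:
        se = se * np.sqrt(max(1.0, q / df))
    z = theta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return MRResult(
        exposure_names=list(inp.exposure_names),
        outcome_name=inp.outcome_name,
        theta=theta,
        se=se,
        z=z,
        p=p,
        Q=q,
        df_Q=df,
        p_Q=p_q,
        m_used=inp.m,
        conditional_f=_conditional_strength(inp, oi),
        overdispersion=overdispersion,
    )


def _conditional_strength(inp: MVMRInput, oi: np.ndarray) -> np.ndarray:
    """Mean whitened residual sum of squares of each exposure's betas given
    the other exposures — low values flag conditionally weak exposures."""
    w, v = np.linalg.eigh(oi)
    w_half = (v * np.sqrt(np.clip(w, 0, None))) @ v.T
    Xw = w_half @ inp.B_x
    m, k = Xw.shape
    out = np.empty(k)
    for j in range(k):
        if k == 1:
            out[j] = float(Xw[:, 0] @ Xw[:, 0]) / m
            continue
        others = np.delete(Xw, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, Xw[:, j], rcond=None)
        resid = Xw[:, j] - others @ coef
        out[j] = float(resid @ resid) / (m - (k - 1))
    return out


def whitened_diagnostics(inp: MRInput | MVMRInput) -> tuple[np.ndarray, np.ndarray]:
    """Hat values and standardized residuals in the whitened GLS design.

    Pre-multiplying by a symmetric square root of Omega^-1 turns the GLS
    problem into OLS with unit error variance, where the classical
    leverage h_i and residual r_i = e_i / sqrt(1 - h_i) apply; r_i^2 is
    approximately chi-square(1) under the model.
    """
    oi = _omega_inverse(inp.s_y, inp.rho)
    w, v = np.linalg.eigh(oi)
    w_half = (v * np.sqrt(np.clip(w, 0, None))) @ v.T
    Xw = w_half @ inp.design
    yw = w_half @ inp.b_y
    A = Xw.T @ Xw
    H = Xw @ np.linalg.solve(A, Xw.T)
    h = np.clip(np.diag(H), 0.0, 1.0)
    resid = yw - H @ yw
    denom = np.sqrt(np.clip(1.0 - h, 1e-12, None))
    return h, resid / denom


def prune_leverage_outliers(
    inp: MRInput,
    leverage_mult: float = 3.0,
    alpha: float = 0.05,
    max_iter: int = 50,
) -> tuple[MRInput, list]:
    """Iteratively drop instruments with large leverage or outlier statistics.

    Per pass, flags variants with hat value above ``leverage_mult * k / m``
    or whose squared standardized residual has a chi-square(1) upper-tail
    probability below the Bonferroni level ``alpha / m``; the worst flagged
    variant is removed and the model re-fit.  Never prunes below
    max(3, k + 1) instruments.
    """
    if inp.m < 3:
        raise ValueError("pruning requires at least 3 instruments")
    floor = max(3, inp.k + 1)
    excluded: list[tuple[str, str, float]] = []
    cur = inp
    for _ in range(max_iter):
        if cur.m <= floor:
            break
        h, r = whitened_diagnostics(cur)
        lev_cut = leverage_mult * cur.k / cur.m
        out_p = stats.chi2.sf(r**2, 1)
        flags_lev = h > lev_cut
        flags_out = out_p < alpha / cur.m
        if not (flags_lev.any() or flags_out.any()):
            break
        # remove the single worst offender, preferring the outlier criterion
        if flags_out.any():
            i = int(np.argmax(np.where(flags_out, r**2, -np.inf)))
            excluded.append((cur.variant_keys[i], "outlier", float(r[i] ** 2)))
        else:
            i = int(np.argmax(np.where(flags_lev, h, -np.inf)))
            excluded.append((cur.variant_keys[i], "leverage", float(h[i])))
        keep = np.ones(cur.m, dtype=bool)
        keep[i] = False
        cur = _subset_input(cur, keep)
    else:  # pragma: no cover
        warnings.warn("pruning hit the iteration cap")
    if cur.m <= floor and inp.m > floor:
        h, r = whitened_diagnostics(cur)
        if (h > leverage_mult * cur.k / cur.m).any() or (
            stats.chi2.sf(r**2, 1) < alpha / cur.m
        ).any():
            warnings.warn("pruning stopped at the instrument floor with flags remaining")
    return cur, excluded


def _subset_input(inp: MRInput, keep: np.ndarray) -> MRInput:
    return MRInput(
        b_x=inp.b_x[keep],
        s_x=inp.s_x[keep],
        b_y=inp.b_y[keep],
        s_y=inp.s_y[keep],
        rho=inp.rho[np.ix_(keep, keep)],
        variant_keys=[k for k, f in zip(inp.variant_keys, keep) if f],
        exposure_name=inp.exposure_name,
        outcome_name=inp.outcome_name,
        exposure_unit=inp.exposure_unit,
        outcome_unit=inp.outcome_unit,
    )


def orient_canonical(result: MRResult, direction_spec: dict[str, str]) -> MRResult:
    """Re-sign estimates toward the canonical drug-target direction.

    For an exposure whose canonical pharmacological direction is
    "decrease" (e.g. circulating CETP or PCSK9 concentration, LDL-C, TG)
    the raw per-unit-higher slope is negated so the report reads per unit
    *lower* exposure; "increase" (HDL-C) leaves the sign unchanged.
    Orienting twice with the same spec is the identity.
    """
    signs = []
    for name in result.exposure_names:
        if name not in direction_spec:
            raise KeyError(f"no canonical direction for exposure {name!r}")
        d = direction_spec[name]
        if d not in ("increase", "decrease"):
            raise ValueError(f"direction must be increase/decrease, got {d!r}")
        signs.append(-1.0 if d == "decrease" else 1.0)
    s = np.asarray(signs)
    if result.orientation == "canonical":
        return result
    return replace(
        result,
        theta=result.theta * s,
        z=result.z * s,
        orientation="canonical",
    )
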