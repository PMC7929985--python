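"""Clonogenic-assay statistics: plating efficiency, survival fractions,
maximum-likelihood linear-quadratic fits, curve comparison and
radioenhancement metrics.

Model
-----
Colony counts are modelled as Poisson with mean

    mu = cells_seeded * PE * SF(D),    SF(D) = exp(-(alpha*D + beta*D**2))

i.e. a Poisson log-linear model with offset log(cells_seeded):

    log mu = log(cells_seeded) + c - alpha*D - beta*D**2,   PE = exp(c).

By default the plating efficiency is estimated inside the fit as the
intercept ``c`` (identified by the dose-0 dishes); an externally measured PE
may be supplied instead, in which case only (alpha, beta) are estimated.
alpha, beta >= 0 is enforced by default (the linear-quadratic interpretation
requires non-negative coefficients); the constraint can be switched off.

Standard errors come from the observed information (inverse Hessian of the
negative log-likelihood at the optimum). Two fitted curves are compared with
a deviance-based F-test: the joint model shares (alpha, beta) across arms
while keeping per-arm intercepts, and

    F = [(Dev_joint - Dev_sep) / df_num] / [Dev_sep / df_den]

with df_num = 2 extra parameters and df_den = n_obs - k_separate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ClonogenicTable",
    "LQFit",
    "CurveComparison",
    "EnhancementMetrics",
    "SurvivalBand",
    "plating_efficiency",
    "survival_fraction",
    "fit_lq",
    "compare_curves",
    "ser_at_dose",
    "def_at_level",
    "survival_band",
]

REQUIRED_COLUMNS = ("arm", "dose_gy", "cells_seeded", "colonies", "dish_id")


@dataclass
class ClonogenicTable:
    """Per-dish colony-count records.

    Wraps a DataFrame with columns ``arm, dose_gy, cells_seeded, colonies,
    dish_id``. Colony counts are validated non-negative but may be
    fractional, so idealized (expected-value) data can be represented and
    refit exactly.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        for row, (dose, cells, col) in enumerate(
            zip(df["dose_gy"], df["cells_seeded"], df["colonies"])
        ):
            if not np.isfinite(dose) or dose < 0:
                raise ValueError(f"row {row}: dose_gy must be a non-negative number, got {dose!r}")
            if not np.isfinite(cells) or cells < 1:
                raise ValueError(f"row {row}: cells_seeded must be >= 1, got {cells!r}")
            if not np.isfinite(col) or col < 0:
                raise ValueError(f"row {row}: colonies must be >= 0, got {col!r}")

    @property
    def arms(self) -> list[str]:
        return sorted(self.data["arm"].unique())

    def arm(self, name: str) -> pd.DataFrame:
        sub = self.data[self.data["arm"] == name]
        if sub.empty:
            raise ValueError(f"no records for arm {name!r}; available: {self.arms}")
        return sub

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class LQFit:
    """A fitted linear-quadratic survival curve.

    ``alpha`` (1/Gy) scales directly lethal lesions, ``beta`` (1/Gy^2)
    accumulated sublethal lesions; ``alpha_beta_ratio`` (Gy) is their
    quotient, defined only when beta > 0. May also be constructed directly
    from published coefficients for metric calculations.
    """

    alpha: float
    beta: float
    se_alpha: float | None = None
    se_beta: float | None = None
    cov_alpha_beta: float | None = None
    log_likelihood: float | None = None
    alpha_beta_ratio: float | None = None
    n_obs: int = 0
    pe: float | None = None
    deviance: float | None = None
    arm: str | None = None

    def __post_init__(self) -> None:
        if self.alpha_beta_ratio is None and self.beta > 0:
            self.alpha_beta_ratio = self.alpha / self.beta

    def sf(self, dose) -> np.ndarray | float:
        """Survival fraction SF(D) under this fit."""
        dose = np.asarray(dose, dtype=float)
        out = np.exp(-(self.alpha * dose + self.beta * dose**2))
        return float(out) if out.ndim == 0 else out


@dataclass
class CurveComparison:
    """Deviance F-test of two survival curves sharing vs splitting (alpha, beta)."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    model_joint_loglik: float
    model_separate_loglik: float


@dataclass
class EnhancementMetrics:
    """Radioenhancement summary comparing a treated to a control curve."""

    ser_at_dose: float
    ref_dose: float
    def_at_level: float
    ref_level: float


@dataclass
class SurvivalBand:
    """Central SF(D) curve with an uncertainty envelope on a dose grid."""

    dose_gy: np.ndarray
    central: np.ndarray
    lower: np.ndarray
    upper: np.ndarray


def plating_efficiency(table: ClonogenicTable, arm: str) -> float:
    """Plating efficiency: pooled colonies / cells seeded over dose-0 dishes.

    Raises if the arm has no unirradiated dishes or if no colonies formed
    (PE = 0 would leave every survival fraction undefined).
    """
    sub = table.arm(arm)
    d0 = sub[sub["dose_gy"] == 0]
    if d0.empty:
        raise ValueError(f"arm {arm!r} has no dose-0 dishes; supply an external PE")
    total_col = float(d0["colonies"].sum())
    total_seed = float(d0["cells_seeded"].sum())
    if total_col <= 0:
        raise ValueError(f"arm {arm!r}: zero colonies at dose 0, PE undefined")
    return total_col / total_seed


def survival_fraction(colonies: float, cells_seeded: float, pe: float) -> float:
    """SF = colonies / (PE * cells seeded). May exceed 1 by sampling noise."""
    if pe <= 0 or pe > 1:
        raise ValueError("plating efficiency must be in (0, 1]")
    if cells_seeded < 1:
        raise ValueError("cells_seeded must be >= 1")
    return colonies / (pe * cells_seeded)


# ---------------------------------------------------------------------------
# Poisson ML machinery


def _nll(theta, X, off, y):
    eta = X @ theta + off
    mu = np.exp(eta)
    return float(np.sum(mu - y * eta))


def _grad(theta, X, off, y):
    mu = np.exp(X @ theta + off)
    return X.T @ (mu - y)


def _hess(theta, X, off, y):
    mu = np.exp(X @ theta + off)
    return (X * mu[:, None]).T @ X


def _poisson_loglik(y, mu):
    return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1.0)))


def _poisson_deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def _fit_poisson(X, off, y, bounds, x0):
    """Bounded Poisson ML: L-BFGS-B then Newton polish on inactive coordinates."""
    res = optimize.minimize(
        _nll,
        x0,
        args=(X, off, y),
        jac=_grad,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
    )
    theta = res.x.copy()
    # Newton refinement: parameter tolerance 1e-9, respecting active bounds
    for _ in range(50):
        g = _grad(theta, X, off, y)
        H = _hess(theta, X, off, y)
        free = np.ones(len(theta), dtype=bool)
        for i, (lo, hi) in enumerate(bounds):
            if lo is not None and theta[i] <= lo + 1e-12 and g[i] > 0:
                free[i] = False
            if hi is not None and theta[i] >= hi - 1e-12 and g[i] < 0:
                free[i] = False
        if not free.any():
            break
        try:
            step = np.linalg.solve(H[np.ix_(free, free)], g[free])
        except np.linalg.LinAlgError:
            break
        new = theta.copy()
        new[free] -= step
        for i, (lo, hi) in enumerate(bounds):
            if lo is not None:
                new[i] = max(new[i], lo)
            if hi is not None:
                new[i] = min(new[i], hi)
        if not np.isfinite(_nll(new, X, off, y)):
            break
        moved = np.max(np.abs(new - theta))
        theta = new
        if moved < 1e-9:
            break
    if not np.all(np.isfinite(theta)):
        raise RuntimeError(f"Poisson ML fit did not converge: {res.message}")
    return theta


def _design(doses, arm_codes=None, n_arms=1, with_intercepts=True):
    cols = []
    if with_intercepts:
        for a in range(n_arms):
            cols.append((arm_codes == a).astype(float) if arm_codes is not None else np.ones_like(doses))
    cols.append(-doses)
    cols.append(-(doses**2))
    return np.column_stack(cols)


def fit_lq(
    table: ClonogenicTable,
    arm: str | None = None,
    pe: float | None = None,
    constrain: bool = True,
) -> LQFit:
    """Maximum-likelihood linear-quadratic fit to one arm's colony counts.

    Maximizes the Poisson likelihood of the dish counts with mean
    ``cells_seeded * PE * exp(-(alpha*D + beta*D^2))``. With ``pe=None``
    (default) PE enters the fit as a free intercept, identified by the
    dose-0 dishes; pass a measured ``pe`` to fix it. ``constrain=True``
    enforces alpha, beta >= 0.

    Raises on degenerate designs (fewer distinct doses than free dose
    parameters, or all doses zero) and on optimizer failure.
    """
    sub = table.arm(arm) if arm is not None else table.data
    doses = sub["dose_gy"].to_numpy(dtype=float)
    y = sub["colonies"].to_numpy(dtype=float)
    cells = sub["cells_seeded"].to_numpy(dtype=float)
    n_distinct = len(np.unique(doses))
    n_params = 2 + (1 if pe is None else 0)
    if n_distinct < max(n_params, 3):
        raise ValueError(
            f"need >= {max(n_params, 3)} distinct doses to fit, got {n_distinct}"
        )
    if np.all(doses == 0):
        raise ValueError("all doses are zero: alpha and beta are unidentifiable")
    if pe is not None and not (0 < pe <= 1):
        raise ValueError("pe must be in (0, 1]")

    if pe is None:
        off = np.log(cells)
        X = _design(doses, with_intercepts=True)
        bounds = [(None, None), (0.0 if constrain else None, None), (0.0 if constrain else None, None)]
        x0 = np.array([_seed_intercept(sub), *_seed_ab(sub, None)])
    else:
        off = np.log(cells * pe)
        X = _design(doses, with_intercepts=False)
        bounds = [(0.0 if constrain else None, None)] * 2
        x0 = np.array(_seed_ab(sub, pe))
    if constrain:
        x0[-2:] = np.clip(x0[-2:], 0.0, None)

    theta = _fit_poisson(X, off, y, bounds, x0)
    mu = np.exp(X @ theta + off)
    H = _hess(theta, X, off, y)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("singular observed information; fit not identifiable") from exc
    ia, ib = len(theta) - 2, len(theta) - 1
    alpha, beta = float(theta[ia]), float(theta[ib])
    return LQFit(
        alpha=alpha,
        beta=beta,
        se_alpha=float(np.sqrt(max(cov[ia, ia], 0.0))),
        se_beta=float(np.sqrt(max(cov[ib, ib], 0.0))),
        cov_alpha_beta=float(cov[ia, ib]),
        log_likelihood=_poisson_loglik(y, mu),
        alpha_beta_ratio=alpha / beta if beta > 0 else None,
        n_obs=len(y),
        pe=float(np.exp(theta[0])) if pe is None else pe,
        deviance=_poisson_deviance(y, mu),
        arm=arm,
    )


def _seed_intercept(sub: pd.DataFrame) -> float:
    d0 = sub[sub["dose_gy"] == 0]
    if not d0.empty and d0["colonies"].sum() > 0:
        return math.log(d0["colonies"].sum() / d0["cells_seeded"].sum())
    return math.log(0.5)


def _seed_ab(sub: pd.DataFrame, pe: float | None) -> tuple[float, float]:
    """Least-squares seed on -log(per-dose mean SF) vs (D, D^2)."""
    pe0 = pe if pe is not None else max(_safe_pe(sub), 1e-6)
    grp = sub.groupby("dose_gy").apply(
        lambda g: g["colonies"].sum() / (pe0 * g["cells_seeded"].sum()),
        include_groups=False,
    )
    d = grp.index.to_numpy(dtype=float)
    sf = np.clip(grp.to_numpy(dtype=float), 1e-12, None)
    keep = d > 0
    if keep.sum() >= 2:
        A = np.column_stack([d[keep], d[keep] ** 2])
        coef, *_ = np.linalg.lstsq(A, -np.log(sf[keep]), rcond=None)
        return float(coef[0]), float(coef[1])
    return 0.3, 0.03


def _safe_pe(sub: pd.DataFrame) -> float:
    d0 = sub[sub["dose_gy"] == 0]
    if d0.empty or d0["colonies"].sum() <= 0:
        return 0.5
    return float(d0["colonies"].sum() / d0["cells_seeded"].sum())


def compare_curves(
    table: ClonogenicTable,
    arm_a: str,
    arm_b: str,
    constrain: bool = True,
) -> CurveComparison:
    """Deviance-based ML F-test: one shared (alpha, beta) vs one per arm.

    Both models keep per-arm intercepts (plating efficiencies); the joint
    model constrains the two dose-response coefficient pairs to be equal.
    Identical data in both arms gives F = 0, p = 1.
    """
    fit_a = fit_lq(table, arm_a, constrain=constrain)
    fit_b = fit_lq(table, arm_b, constrain=constrain)
    dev_sep = fit_a.deviance + fit_b.deviance
    ll_sep = fit_a.log_likelihood + fit_b.log_likelihood

    sub = pd.concat([table.arm(arm_a), table.arm(arm_b)])
    doses = sub["dose_gy"].to_numpy(dtype=float)
    y = sub["colonies"].to_numpy(dtype=float)
    cells = sub["cells_seeded"].to_numpy(dtype=float)
    arm_codes = (sub["arm"] == arm_b).to_numpy().astype(int)
    X = _design(doses, arm_codes=arm_codes, n_arms=2, with_intercepts=True)
    off = np.log(cells)
    c = 0.0 if constrain else None
    bounds = [(None, None), (None, None), (c, None), (c, None)]
    x0 = np.array(
        [
            _seed_intercept(table.arm(arm_a)),
            _seed_intercept(table.arm(arm_b)),
            (fit_a.alpha + fit_b.alpha) / 2,
            (fit_a.beta + fit_b.beta) / 2,
        ]
    )
    theta = _fit_poisson(X, off, y, bounds, x0)
    mu = np.exp(X @ theta + off)
    dev_joint = _poisson_deviance(y, mu)
    ll_joint = _poisson_loglik(y, mu)

    df_num = 2
    df_den = len(y) - 6  # separate model: 2 intercepts + 2 (alpha, beta) pairs
    if df_den <= 0:
        raise ValueError("not enough observations for the F-test denominator")
    num = max(dev_joint - dev_sep, 0.0)
    # numerical tie tolerance: the two optimizations agree only to ~1e-11
    # on identical data; a difference this small is zero extra deviance
    if num <= 1e-7 * max(1.0, dev_sep):
        num = 0.0
    if dev_sep <= 0:
        f_stat = 0.0 if num == 0 else math.inf
    else:
        f_stat = (num / df_num) / (dev_sep / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den)) if math.isfinite(f_stat) else 0.0
    return CurveComparison(
        f_statistic=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        model_joint_loglik=ll_joint,
        model_separate_loglik=ll_sep,
    )


def ser_at_dose(fit_ctrl: LQFit, fit_treat: LQFit, dose: float = 2.0) -> float:
    """Sensitizer enhancement ratio: % reduction of SF at the reference dose.

    SER = 100 * (1 - SF_treat(D) / SF_ctrl(D)); 0 for identical curves,
    positive when the treated curve falls below the control.
    """
    return 100.0 * (1.0 - fit_treat.sf(dose) / fit_ctrl.sf(dose))


def _dose_at_level(fit: LQFit, level: float) -> float:
    """Positive root of alpha*D + beta*D^2 = -ln(level)."""
    target = -math.log(level)
    if fit.beta > 0:
        disc = fit.alpha**2 + 4.0 * fit.beta * target
        return (-fit.alpha + math.sqrt(disc)) / (2.0 * fit.beta)
    if fit.alpha <= 0:
        raise ValueError("dose at survival level undefined when alpha = beta = 0")
    return target / fit.alpha


def def_at_level(fit_ctrl: LQFit, fit_treat: LQFit, level: float = 0.10) -> float:
    """Dose enhancement factor: D_ctrl / D_treat at equal survival ``level``.

    Solves SF(D) = level on both curves (quadratic formula; linear limit
    when beta = 0). 1 for identical curves, > 1 when the treated curve
    reaches the level at a lower dose.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    return _dose_at_level(fit_ctrl, level) / _dose_at_level(fit_treat, level)


def enhancement_metrics(
    fit_ctrl: LQFit, fit_treat: LQFit, ref_dose: float = 2.0, ref_level: float = 0.10
) -> EnhancementMetrics:
    """Bundle SER at ``ref_dose`` and DEF at ``ref_level`` into one record."""
    return EnhancementMetrics(
        ser_at_dose=ser_at_dose(fit_ctrl, fit_treat, ref_dose),
        ref_dose=ref_dose,
        def_at_level=def_at_level(fit_ctrl, fit_treat, ref_level),
        ref_level=ref_level,
    )


def survival_band(fit: LQFit, dose_grid) -> SurvivalBand:
    """Central SF(D) with an envelope from the coefficient standard errors.

    The envelope is the pointwise min/max of the LQ law evaluated at the
    four corner pairs (alpha +/- se_alpha, beta +/- se_beta), following the
    convention of shading survival curves by the standard deviations of the
    two coefficients. With missing standard errors the band collapses to
    the central curve (a warning is emitted).
    """
    dose_grid = np.asarray(dose_grid, dtype=float)
    central = fit.sf(dose_grid)
    if fit.se_alpha is None or fit.se_beta is None:
        import warnings

        warnings.warn("fit has no standard errors; returning central curve only")
        return SurvivalBand(dose_grid, central, central.copy(), central.copy())
    corners = [
        LQFit(alpha=fit.alpha + sa * fit.se_alpha, beta=fit.beta + sb * fit.se_beta).sf(dose_grid)
        for sa in (-1.0, 1.0)
        for sb in (-1.0, 1.0)
    ]
    corners = np.asarray(corners)
    return SurvivalBand(
        dose_gy=dose_grid,
        central=central,
        lower=np.minimum(corners.min(axis=0), central),
        upper=np.maximum(corners.max(axis=0), central),
    )
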