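"""Constrained logistic dose-response fitting and the asymptote/fit tests.

The response (percentage of plants surviving or of normal phenotype) is
modelled by a declining log-logistic curve that passes exactly through 100%
at dose zero:

    y(x) = A + (100 - A) / (1 + (x / m)^b)

with lower asymptote A (%), rate b > 0 and midpoint m (mM) — the dose at
which y is halfway between 100 and A, so y(m) = (100 + A) / 2.  Fitting is
unweighted nonlinear least squares on percentages with a multistart grid;
the need for the lower asymptote and lack of fit are assessed with
extra-sum-of-squares F tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "logistic_decline",
    "LogisticFit",
    "FTestResult",
    "LackOfFitResult",
    "DoseReport",
    "prepare_table",
    "fit",
    "asymptote_test",
    "lack_of_fit_test",
    "report_doses",
]

UPPER_ASYMPTOTE = 100.0


def logistic_decline(x, A, b, m):
    """Evaluate y(x) = A + (100 - A) / (1 + (x/m)^b); exactly 100 at x = 0."""
    x = np.asarray(x, dtype=float)
    if m <= 0:
        raise ValueError(f"midpoint m must be positive, got {m}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(x > 0, (x / m) ** b, 0.0)
    out = A + (UPPER_ASYMPTOTE - A) / (1.0 + ratio)
    return out if out.ndim else float(out)


@dataclass
class LogisticFit:
    """Fitted constrained logistic (upper asymptote fixed at 100%).

    ``lower_asymptote_estimated`` records whether A was free (full model) or
    pinned at 0 (reduced model).  ``covariance`` is the asymptotic (A, b, m)
    — or (b, m) — covariance from the Gauss-Newton approximation, or None
    when the Jacobian is singular.  ``identifiable`` is False for degenerate
    data (no dose effect), in which case the parameters are NaN.
    """

    A: float
    b: float
    m: float
    residual_ss: float
    n_obs: int
    n_params: int
    lower_asymptote_estimated: bool
    converged: bool
    identifiable: bool = True
    covariance: np.ndarray | None = None
    n_starts: int = 0
    upper: float = UPPER_ASYMPTOTE

    @property
    def df_residual(self) -> int:
        return self.n_obs - self.n_params

    def predict(self, x):
        """Fitted response (%) at dose x."""
        return logistic_decline(x, self.A, self.b, self.m)


def prepare_table(table: pd.DataFrame) -> pd.DataFrame:
    """Normalise a dose-response table to columns (dose, percent).

    Accepts either a ``percent`` column or ``responders``/``total`` counts.
    """
    table = table.copy()
    if "percent" not in table.columns:
        if not {"responders", "total"} <= set(table.columns):
            raise ValueError(
                "table needs either a 'percent' column or "
                "'responders' and 'total' columns"
            )
        if (table["total"] <= 0).any():
            raise ValueError("'total' must be positive")
        table["percent"] = 100.0 * table["responders"] / table["total"]
    if "dose" not in table.columns:
        raise ValueError("table needs a 'dose' column")
    if (table["dose"] < 0).any():
        raise ValueError("doses must be non-negative")
    return table


def _validate_design(doses: np.ndarray) -> None:
    positive = np.unique(doses[doses > 0])
    if 0.0 not in doses or positive.size < 2:
        raise ValueError(
            "fit needs observations at dose 0 and at >= 2 distinct positive doses"
        )


def _multistart(residual_fn, starts, bounds):
    best = None
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residual_fn, x0, bounds=bounds, method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=500 * len(x0),
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    return best


def _covariance(sol, rss: float, df: int) -> np.ndarray | None:
    if df <= 0:
        return None
    J = sol.jac
    try:
        JtJ_inv = np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        return None
    return JtJ_inv * (rss / df)


def fit(table: pd.DataFrame, estimate_lower_asymptote: bool = True) -> LogisticFit:
    """Fit the constrained logistic by multistart nonlinear least squares.

    Minimises sum((observed% - y(dose))^2).  Starts span a grid of rates
    {0.5, 1, 2, 4} x positive-dose quartiles for m, with A initialised at the
    smallest observed response (full model) or fixed at 0 (reduced model).
    Raises RuntimeError if no start converges.
    """
    table = prepare_table(table)
    doses = table["dose"].to_numpy(dtype=float)
    y = table["percent"].to_numpy(dtype=float)
    _validate_design(doses)
    n = len(y)

    if np.ptp(y) < 1e-8:
        # Flat response: the curve shape (and A in particular) is not
        # identifiable from the data.
        return LogisticFit(
            A=np.nan, b=np.nan, m=np.nan,
            residual_ss=0.0, n_obs=n,
            n_params=3 if estimate_lower_asymptote else 2,
            lower_asymptote_estimated=estimate_lower_asymptote,
            converged=False, identifiable=False,
        )

    pos = np.unique(doses[doses > 0])
    m_starts = np.quantile(pos, [0.25, 0.5, 0.75])
    b_starts = (0.5, 1.0, 2.0, 4.0)
    a0 = float(np.clip(y.min(), 0.0, UPPER_ASYMPTOTE - 1.0))

    if estimate_lower_asymptote:
        def residual(theta):
            A, b, m = theta
            return y - logistic_decline(doses, A, b, m)

        starts = [np.array([a0, b, m]) for b in b_starts for m in m_starts]
        bounds = ([0.0, 1e-6, 1e-9],
                  [UPPER_ASYMPTOTE - 1e-9, np.inf, np.inf])
        n_params = 3
    else:
        def residual(theta):
            b, m = theta
            return y - logistic_decline(doses, 0.0, b, m)

        starts = [np.array([b, m]) for b in b_starts for m in m_starts]
        bounds = ([1e-6, 1e-9], [np.inf, np.inf])
        n_params = 2

    sol = _multistart(residual, starts, bounds)
    if sol is None:
        raise RuntimeError(
            "nonlinear least squares failed to converge from every start "
            f"({len(starts)} starts tried)"
        )
    rss = float(2.0 * sol.cost)
    if estimate_lower_asymptote:
        A, b, m = (float(v) for v in sol.x)
    else:
        A = 0.0
        b, m = (float(v) for v in sol.x)
    return LogisticFit(
        A=A, b=b, m=m, residual_ss=rss, n_obs=n, n_params=n_params,
        lower_asymptote_estimated=estimate_lower_asymptote,
        converged=True, covariance=_covariance(sol, rss, n - n_params),
        n_starts=len(starts),
    )


@dataclass
class FTestResult:
    """Extra-sum-of-squares F test between nested fits."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    degenerate: bool = False


def asymptote_test(fit_with_A: LogisticFit, fit_without_A: LogisticFit) -> FTestResult:
    """Is the lower asymptote needed?  F test of the A-free vs A=0 fits.

    F = ((RSS0 - RSS1) / 1) / (RSS1 / df1) where RSS1/df1 come from the full
    (A estimated) model.  RSS1 = 0 is reported as degenerate rather than an
    exception.
    """
    if fit_with_A.n_obs != fit_without_A.n_obs:
        raise ValueError("nested fits must use identical data")
    if not fit_with_A.lower_asymptote_estimated or (
        fit_without_A.lower_asymptote_estimated
    ):
        raise ValueError(
            "expected fit_with_A with A estimated and fit_without_A with A fixed"
        )
    rss1, rss0 = fit_with_A.residual_ss, fit_without_A.residual_ss
    df1 = fit_with_A.df_residual
    df_num = fit_with_A.n_params - fit_without_A.n_params
    if rss1 <= 0 or df1 <= 0:
        return FTestResult(np.inf if rss0 > rss1 else 0.0, df_num, df1,
                           np.nan, degenerate=True)
    f = max(rss0 - rss1, 0.0) / df_num / (rss1 / df1)
    p = float(stats.f.sf(f, df_num, df1))
    return FTestResult(float(f), df_num, df1, p)


@dataclass
class LackOfFitResult:
    """Lack-of-fit F test against pure replicate error."""

    f_statistic: float
    df_lack_of_fit: int
    df_pure_error: int
    p_value: float
    lack_of_fit_ss: float
    pure_error_ss: float
    n_obs: int
    n_doses: int


def lack_of_fit_test(fitted: LogisticFit, table: pd.DataFrame) -> LackOfFitResult:
    """Partition the residual SS into lack-of-fit and pure replicate error.

    Pure-error SS is the sum of squared deviations of replicates about their
    dose means (df = N - n_doses); lack-of-fit SS is the remainder of the
    model residual SS (df = n_doses - n_params).  Requires replicated doses.
    """
    table = prepare_table(table)
    doses = table["dose"].to_numpy(dtype=float)
    y = table["percent"].to_numpy(dtype=float)
    n = len(y)
    unique_doses = np.unique(doses)
    n_doses = unique_doses.size
    if n == n_doses:
        raise ValueError("lack-of-fit test requires replicated doses")
    dose_means = {d: y[doses == d].mean() for d in unique_doses}
    pure_error_ss = float(sum(
        ((y[doses == d] - dose_means[d]) ** 2).sum() for d in unique_doses
    ))
    lof_ss = max(fitted.residual_ss - pure_error_ss, 0.0)
    df_lof = n_doses - fitted.n_params
    df_pe = n - n_doses
    if df_lof <= 0:
        # Saturated model: no dof left to detect lack of fit.
        return LackOfFitResult(np.nan, df_lof, df_pe, np.nan,
                               lof_ss, pure_error_ss, n, n_doses)
    if pure_error_ss <= 0:
        f = np.inf if lof_ss > 0 else 0.0
        p = 0.0 if lof_ss > 0 else 1.0
    else:
        f = (lof_ss / df_lof) / (pure_error_ss / df_pe)
        p = float(stats.f.sf(f, df_lof, df_pe))
    return LackOfFitResult(float(f), df_lof, df_pe, p,
                           lof_ss, pure_error_ss, n, n_doses)


@dataclass
class DoseReport:
    """Doses of practical interest derived from a fitted curve.

    ``dose_at_absolute_50`` solves y(x) = 50 (None when A >= 50 makes 50%
    unreachable); ``half_reduction_dose`` is the midpoint m, the dose
    removing half the total possible reduction from 100% down to A; the
    response there is (100 + A) / 2.
    """

    dose_at_absolute_50: float | None
    half_reduction_dose: float
    survival_at_half_reduction: float


def report_doses(fitted: LogisticFit) -> DoseReport:
    """Report the absolute-50% dose and the half-reduction (midpoint) dose."""
    if not fitted.identifiable or not np.isfinite(fitted.m):
        raise ValueError("cannot report doses for a non-identifiable fit")
    A, b, m = fitted.A, fitted.b, fitted.m
    if A < 50.0:
        # Solve A + (100 - A)/(1 + (x/m)^b) = 50  =>  (x/m)^b = 50/(50 - A).
        dose50 = m * (50.0 / (50.0 - A)) ** (1.0 / b)
    else:
        dose50 = None
    return DoseReport(
        dose_at_absolute_50=dose50,
        half_reduction_dose=m,
        survival_at_half_reduction=float(fitted.predict(m)),
    )
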