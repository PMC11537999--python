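"""Four-parameter Hill (4PL) concentration-response fitting.

The model is

    a(c) = a0 + (a_inf - a0) * c**n / (k**n + c**n)

with ``a0`` the activity at zero concentration, ``a_inf`` the activity at
infinite concentration, ``k`` the half-maximal concentration (IC50 for an
inhibitor) and ``n`` the Hill coefficient.  Efficacy is ``a_inf - a0``.

Fitting is bounded nonlinear least squares with a small set of
deterministic starting points, so results are fully reproducible.  A
single gross outlier may be masked and the fit repeated once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ConcentrationResponse",
    "HillFit",
    "hill_eval",
    "fit_hill",
    "derive_icx",
    "fit_table",
]

# Hill-coefficient box; potency box is data-driven (see fit_hill).
N_MIN, N_MAX = 0.3, 8.0


@dataclass(frozen=True)
class ConcentrationResponse:
    """A per-compound response series for one readout.

    Concentrations are in µM and must be strictly positive and strictly
    increasing; ``response`` is % activity (vehicle = 0, full effect of the
    positive control = -100).  ``mask`` flags points included in the fit.
    """

    compound_id: str
    concentration: np.ndarray
    response: np.ndarray
    readout: str = "activity"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        c = np.asarray(self.concentration, dtype=float)
        a = np.asarray(self.response, dtype=float)
        if c.shape != a.shape or c.ndim != 1:
            raise ValueError("concentration and response must be equal-length 1-D arrays")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        m = self.mask
        m = np.ones(c.shape, dtype=bool) if m is None else np.asarray(m, dtype=bool)
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "response", a)
        object.__setattr__(self, "mask", m)

    @property
    def n_points(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class HillFit:
    """Fitted 4PL parameters plus fit quality."""

    a0: float
    a_inf: float
    k: float  # IC50/EC50, µM
    n: float  # Hill coefficient
    r_squared: float
    converged: bool

    @property
    def efficacy(self) -> float:
        """Maximal response relative to baseline, a_inf - a0 (%)."""
        return self.a_inf - self.a0


NO_FIT = HillFit(a0=0.0, a_inf=0.0, k=np.nan, n=np.nan, r_squared=np.nan, converged=False)


def hill_eval(fit: HillFit, c) -> np.ndarray | float:
    """Evaluate the fitted Hill curve at concentration(s) ``c`` (µM, >= 0)."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        frac = np.where(c > 0, c**fit.n / (fit.k**fit.n + c**fit.n), 0.0)
    out = fit.a0 + (fit.a_inf - fit.a0) * frac
    return float(out) if out.ndim == 0 else out


def _residuals(theta, c, a):
    a0, ainf, logk, n = theta
    k = np.exp(logk)
    return a0 + (ainf - a0) * c**n / (k**n + c**n) - a


def _solve(c, a, k_lo, k_hi, fix_n=None):
    """Bounded least squares from deterministic starts; returns best solution."""
    a_lo, a_hi = a.min() - 50.0, a.max() + 50.0
    a0_init = float(a[0])
    ainf_init = float(a[-1])
    half = (a0_init + ainf_init) / 2.0
    k_mid = float(c[int(np.argmin(np.abs(a - half)))])
    k_mid = min(max(k_mid, k_lo), k_hi)
    starts = [k_mid, np.sqrt(k_lo * k_hi), np.sqrt(k_mid * k_hi)]
    best = None
    for k0 in starts:
        if fix_n is None:
            x0 = [a0_init, ainf_init, np.log(k0), 1.0]
            lb = [a_lo, a_lo, np.log(k_lo), N_MIN]
            ub = [a_hi, a_hi, np.log(k_hi), N_MAX]
            fun = _residuals
        else:
            x0 = [a0_init, ainf_init, np.log(k0)]
            lb = [a_lo, a_lo, np.log(k_lo)]
            ub = [a_hi, a_hi, np.log(k_hi)]
            fun = lambda th, c_, a_: _residuals([th[0], th[1], th[2], fix_n], c_, a_)
        try:
            sol = least_squares(fun, x0, bounds=(lb, ub), args=(c, a), method="trf")
        except Exception:
            continue
        cost = float(sol.cost)
        k_val = float(np.exp(sol.x[2]))
        # ties broken toward the smaller k for reproducibility
        if best is None or cost < best[0] - 1e-12 or (abs(cost - best[0]) <= 1e-12 and k_val < best[1]):
            best = (cost, k_val, sol)
    return best


def _fit_once(c, a, k_lo, k_hi):
    fix_n = 1.0 if len(c) < 4 else None
    best = _solve(c, a, k_lo, k_hi, fix_n=fix_n)
    if best is None:
        return None
    _, k_val, sol = best
    a0, ainf = float(sol.x[0]), float(sol.x[1])
    n = 1.0 if fix_n is not None else float(sol.x[3])
    resid = sol.fun
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-10 else 0.0)
    return HillFit(a0=a0, a_inf=ainf, k=k_val, n=n, r_squared=r2, converged=bool(sol.success)), resid


def fit_hill(cr: ConcentrationResponse, mask_outlier: bool = True) -> HillFit:
    """Fit the 4PL model to a concentration-response series.

    With fewer than 4 usable points the Hill coefficient is fixed at 1 and
    three parameters are fitted.  The potency ``k`` is constrained to
    [c_min/10, c_max*10].  If one residual exceeds 3 robust SDs, that point
    is masked and the fit repeated once.  Failure returns a non-converged
    result rather than raising.
    """
    keep = cr.mask
    if keep.sum() < 2:
        return NO_FIT
    c = cr.concentration[keep]
    a = cr.response[keep]
    k_lo, k_hi = c.min() / 10.0, c.max() * 10.0
    out = _fit_once(c, a, k_lo, k_hi)
    if out is None:
        return NO_FIT
    fit, resid = out
    if mask_outlier and len(c) >= 5:
        # judge the worst point against the spread of the remaining residuals,
        # since a gross outlier can drag the fit toward itself
        cand = int(np.argmax(np.abs(resid)))
        others = np.delete(resid, cand)
        robust_sd = 1.4826 * np.median(np.abs(others - np.median(others)))
        if robust_sd > 0 and abs(resid[cand]) > 3.0 * robust_sd:
            keep2 = np.ones(len(c), dtype=bool)
            keep2[cand] = False
            out2 = _fit_once(c[keep2], a[keep2], k_lo, k_hi)
            if out2 is not None and out2[0].converged:
                fit = out2[0]
    return fit


def derive_icx(fit: HillFit, x: float) -> float:
    """Concentration producing x% of the fitted maximal effect.

    Closed form: ``k * (x / (100 - x))**(1/n)``.  Requires a converged fit
    with nonzero efficacy and 0 < x < 100.
    """
    if not 0 < x < 100:
        raise ValueError("x must lie strictly between 0 and 100")
    if not fit.converged or fit.efficacy == 0 or not np.isfinite(fit.k):
        raise ValueError("ICx undefined for a flat or non-converged fit")
    return float(fit.k * (x / (100.0 - x)) ** (1.0 / fit.n))


def fit_table(responses: pd.DataFrame, mask_outlier: bool = True) -> pd.DataFrame:
    """Fit every (compound_id, readout) series in a long-format table.

    Expects columns compound_id, readout, concentration_um, percent_activity.
    Returns one row per series with the fitted parameters.
    """
    rows = []
    for (cid, readout), grp in responses.groupby(["compound_id", "readout"], sort=True):
        grp = grp.sort_values("concentration_um")
        cr = ConcentrationResponse(
            compound_id=str(cid),
            concentration=grp["concentration_um"].to_numpy(),
            response=grp["percent_activity"].to_numpy(),
            readout=str(readout),
        )
        f = fit_hill(cr, mask_outlier=mask_outlier)
        rows.append(
            {
                "compound_id": cid,
                "readout": readout,
                "a0": f.a0,
                "ainf": f.a_inf,
                "ic50_um": f.k,
                "hill_n": f.n,
                "efficacy": f.efficacy,
                "r2": f.r_squared,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
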