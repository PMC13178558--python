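"""Population noise statistics, exact Spearman test, exponential-decay fits.

Conventions:

* noise CV^2 = sigma^2 / mu^2, burstiness Fano F = sigma^2 / mu with the
  sample (n-1) standard deviation; Fano = 1 is the Poisson (non-bursty) line;
* "silent" means count 0, "on" means count >= 1;
* a group with mu = 0 has undefined CV^2 and Fano (reported as NaN, never 0/0);
* the Spearman p-value is an exact two-sided permutation test over all n!
  rank permutations for n <= 8 (>= in the tail count, so perfectly monotone
  n = 4 data gives p = 2/24 ~ 0.08), with a t-approximation fallback beyond;
* the one-phase exponential decay model is
  y(x) = (y0 - plateau) exp(-k x) + plateau with k >= 0.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import least_squares

from ._exceptions import DataError, FitError
from .datasets import validate_counts

__all__ = [
    "NoiseSummary",
    "summarize_counts",
    "summaries_frame",
    "SpearmanResult",
    "spearman_exact",
    "ExpDecayFit",
    "fit_exp_decay",
]

logger = logging.getLogger(__name__)

EXACT_SPEARMAN_LIMIT = 8  # full n! enumeration up to here


@dataclass(frozen=True)
class NoiseSummary:
    """Per-group count statistics (one strain x condition group)."""

    strain: str
    condition_uM: float
    n_cells: int
    mu: float
    sigma: float
    cv2: float  # NaN when mu == 0
    fano: float  # NaN when mu == 0
    frac_silent: float
    frac_on: float


def summarize_counts(
    counts: pd.DataFrame,
    group_by: Sequence[str] = ("strain", "condition_uM"),
) -> List[NoiseSummary]:
    """Noise summaries per (strain, condition) group, sorted by group key.

    sigma is the sample standard deviation (n-1 denominator; 0 for a single
    cell). Groups with mu = 0 get NaN for cv2 and fano.
    """
    counts = validate_counts(counts, source="<counts>")
    out: List[NoiseSummary] = []
    for key, g in counts.groupby(list(group_by), sort=True):
        c = g["count"].to_numpy(dtype=float)
        n = len(c)
        mu = float(c.mean())
        sigma = float(c.std(ddof=1)) if n > 1 else 0.0
        var = sigma * sigma
        if mu > 0:
            cv2, fano = var / (mu * mu), var / mu
        else:
            cv2 = fano = float("nan")
        frac_silent = float((c == 0).mean())
        strain, cond = key
        out.append(
            NoiseSummary(
                strain=str(strain),
                condition_uM=float(cond),
                n_cells=n,
                mu=mu,
                sigma=sigma,
                cv2=cv2,
                fano=fano,
                frac_silent=frac_silent,
                frac_on=1.0 - frac_silent,
            )
        )
    return out


def summaries_frame(summaries: List[NoiseSummary]) -> pd.DataFrame:
    """Tidy one-row-per-group DataFrame of NoiseSummary fields."""
    return pd.DataFrame([s.__dict__ for s in summaries])


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_two_sided: float
    n: int
    method: str  # "exact" (full permutation) or "t-approx"


def spearman_exact(x, y) -> SpearmanResult:
    """Spearman rank correlation with an exact small-sample permutation p.

    rho is the Pearson correlation of (average) ranks. For n <= 8 the
    two-sided p-value is computed over all n! permutations of the y ranks as
    the fraction with |rho_perm| >= |rho_observed|; beyond that the usual
    t-approximation is used and a notice is logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError(f"x and y must be equal-length 1-D, got {x.shape} and {y.shape}")
    n = len(x)
    if n < 3:
        raise DataError(f"need at least 3 pairs, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("x and y must be finite")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise DataError("rank correlation is undefined for a constant input")
    rxc = rx - rx.mean()
    rho = float(np.dot(rxc, ry - ry.mean()) / (n * sx * sy))
    if n <= EXACT_SPEARMAN_LIMIT:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        rhos = (ry[perms] - ry.mean()) @ rxc / (n * sx * sy)
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "exact"
    else:
        logger.info(
            "n = %d exceeds the exact-permutation limit (%d); using the t-approximation",
            n,
            EXACT_SPEARMAN_LIMIT,
        )
        p = float(scipy.stats.spearmanr(x, y).pvalue)
        method = "t-approx"
    return SpearmanResult(rho=rho, p_two_sided=p, n=n, method=method)


@dataclass(frozen=True)
class ExpDecayFit:
    """One-phase exponential decay y(x) = (y0 - plateau) exp(-k x) + plateau."""

    y0: float
    plateau: float
    k: float
    r_squared: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.y0 - self.plateau) * np.exp(-self.k * x) + self.plateau


def fit_exp_decay(x, y, max_nfev: int = 20000) -> ExpDecayFit:
    """Least-squares one-phase exponential decay with k >= 0.

    Initialisation: plateau0 = min(y), y0_0 = max(y), k0 from a log-linear
    regression of y - plateau0 against x (robust for monotone decay data).
    Constant y is returned directly as plateau = y with r_squared = 1 (the
    zero-SS_tot convention). Non-convergence raises FitError carrying the
    best-so-far parameters.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length 1-D arrays")
    if len(np.unique(x)) < 4:
        raise DataError(f"need >= 4 distinct x values, got {len(np.unique(x))}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("x and y must be finite")

    if np.ptp(y) == 0.0:
        return ExpDecayFit(y0=float(y[0]), plateau=float(y[0]), k=0.0, r_squared=1.0)

    plateau0 = float(y.min())
    y00 = float(y.max())
    xspan = float(np.ptp(x)) or 1.0
    resid0 = y - plateau0
    mask = resid0 > 0
    if mask.sum() >= 2 and len(np.unique(x[mask])) >= 2:
        slope = scipy.stats.linregress(x[mask], np.log(resid0[mask])).slope
        k0 = max(-float(slope), 1e-3 / xspan)
    else:
        k0 = 1.0 / xspan

    def residuals(theta):
        y0, plateau, k = theta
        return (y0 - plateau) * np.exp(-k * x) + plateau - y

    res = least_squares(
        residuals,
        x0=[y00, plateau0, k0],
        bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=max_nfev,
    )
    if not res.success:
        raise FitError(
            f"exponential-decay fit did not converge: {res.message}", params=res.x
        )
    y0, plateau, k = map(float, res.x)
    ss_res = float(np.sum(residuals(res.x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ExpDecayFit(y0=y0, plateau=plateau, k=k, r_squared=r2)
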