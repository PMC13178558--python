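"""Spot-intensity calibration and copy-number quantification.

The conversion from per-spot integrated intensities to per-cell mRNA counts
follows the standard smFISH recipe:

1. a false-positive threshold is set at the 99.9th percentile of spot
   intensities observed in a no-target (probe-deletion) negative control;
2. the surviving spot-intensity distribution is fitted with a Gaussian
   mixture; because spots are quantal, the components sit near integer
   multiples of the single-molecule intensity and the mean of the first
   (lowest-mean) component is the intensity of one mRNA molecule;
3. each cell's total surviving intensity is divided by the single-molecule
   intensity and rounded to the nearest integer to give its copy number.

Rounding to the nearest integer (the division rule alone leaves this open) is
unbiased for symmetric intensity noise; the percentile uses the
linear-interpolation convention (position (n-1) q) for bit-exactness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.mixture import GaussianMixture

from ._exceptions import DataError, FitError, ParameterError
from .datasets import COUNT_COLUMNS, SpotTable

__all__ = [
    "fp_threshold",
    "fit_intensity_mixture",
    "IntensityCalibration",
    "quantify_counts",
    "IntensityCalibrator",
]

FP_PERCENTILE = 99.9  # false-positive cut: 99.9th percentile of the control


def fp_threshold(control_intensities, percentile: float = FP_PERCENTILE) -> float:
    """False-positive intensity threshold from a negative-control spot list.

    Returns the ``percentile``-th percentile (default 99.9) under the
    linear-interpolation convention: the value at position (n-1) * q of the
    sorted sample, interpolating between neighbours.
    """
    a = np.asarray(control_intensities, dtype=float)
    if a.size == 0:
        raise DataError("control intensity list is empty")
    return float(np.percentile(a, percentile))


def fit_intensity_mixture(
    intensities,
    n_components: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> List[Tuple[float, float, float]]:
    """Maximum-likelihood Gaussian mixture of spot intensities via EM.

    Returns [(weight, mean, sd), ...] sorted by ascending mean; the first
    component's mean is the single-molecule unit intensity. The fit runs on
    raw intensities (bin-free), initialised k-means++-style with a fixed seed,
    so it is deterministic. Raises FitError if EM does not converge within
    ``max_iter`` iterations and DataError with fewer than 10 points per
    component.
    """
    a = np.asarray(intensities, dtype=float).reshape(-1, 1)
    if n_components < 1:
        raise ParameterError(f"n_components must be >= 1, got {n_components}")
    if len(a) < 10 * n_components:
        raise DataError(
            f"need at least {10 * n_components} intensities for "
            f"{n_components} components, got {len(a)}"
        )
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="full",
        tol=tol,
        max_iter=max_iter,
        n_init=1,
        init_params="k-means++",
        random_state=seed,
        reg_covar=1e-8,
    ).fit(a)
    if not gm.converged_:
        raise FitError(
            f"EM did not converge within {max_iter} iterations "
            f"(log-likelihood lower bound {gm.lower_bound_:.6g})",
            params=[(float(w), float(m), float(np.sqrt(c)))
                    for w, m, c in zip(gm.weights_, gm.means_.ravel(), gm.covariances_.ravel())],
        )
    comps = sorted(
        zip(gm.weights_.ravel(), gm.means_.ravel(), np.sqrt(gm.covariances_.ravel())),
        key=lambda t: t[1],
    )
    return [(float(w), float(m), float(s)) for w, m, s in comps]


@dataclass
class IntensityCalibration:
    """A fitted spot-intensity calibration.

    fp_threshold   : intensity cut from the negative control (a.u., >= 0)
    unit_intensity : mean of the lowest-mean mixture component (a.u., > 0)
    mixture        : [(weight, mean, sd)] sorted by ascending mean
    """

    fp_threshold: float
    unit_intensity: float
    mixture: List[Tuple[float, float, float]]

    def __post_init__(self):
        if self.fp_threshold < 0:
            raise ParameterError("fp_threshold must be >= 0")
        if not (self.unit_intensity > 0):
            raise ParameterError("unit_intensity must be > 0")
        if self.mixture:
            w = sum(c[0] for c in self.mixture)
            if abs(w - 1.0) > 1e-9:
                raise ParameterError(f"mixture weights must sum to 1, got {w}")
            means = [c[1] for c in self.mixture]
            if means != sorted(means):
                raise ParameterError("mixture components must be sorted by mean")
            if not math.isclose(self.unit_intensity, means[0], rel_tol=1e-12):
                raise ParameterError("unit_intensity must equal the first component mean")

    def to_json(self) -> str:
        return json.dumps(
            {
                "fp_threshold": self.fp_threshold,
                "unit_intensity": self.unit_intensity,
                "components": [
                    {"weight": w, "mean": m, "sd": s} for w, m, s in self.mixture
                ],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "IntensityCalibration":
        d = json.loads(text)
        return cls(
            fp_threshold=float(d["fp_threshold"]),
            unit_intensity=float(d["unit_intensity"]),
            mixture=[(float(c["weight"]), float(c["mean"]), float(c["sd"]))
                     for c in d["components"]],
        )


def quantify_counts(
    spots: Union[SpotTable, pd.DataFrame],
    calib: IntensityCalibration,
) -> pd.DataFrame:
    """Convert a spot table into a per-cell count table.

    Spots with intensity <= fp_threshold are discarded as false positives;
    per cell, count = round(sum of surviving intensities / unit_intensity),
    floored at 0. Cells on the roster (or appearing in the spot table) with no
    surviving spots get count 0.
    """
    if not (calib.unit_intensity > 0):
        raise ParameterError("unit_intensity must be > 0")
    if isinstance(spots, SpotTable):
        spots_df, roster = spots.spots, spots.cells
    else:
        spots_df, roster = spots, None

    surviving = spots_df[spots_df["intensity"] > calib.fp_threshold]
    totals = surviving.groupby("cell_id")["intensity"].sum()
    counts = np.floor(totals / calib.unit_intensity + 0.5).clip(lower=0).astype(np.int64)

    if roster is not None:
        out = roster.copy()
    else:
        out = pd.DataFrame({"cell_id": pd.unique(spots_df["cell_id"])})
        out["strain"] = "na"
        out["condition_uM"] = 0.0
    out["count"] = out["cell_id"].map(counts).fillna(0).astype(np.int64)
    return out[COUNT_COLUMNS].reset_index(drop=True)


class IntensityCalibrator(TransformerMixin, BaseEstimator):
    """Scikit-learn-style transformer from spot tables to count tables.

    ``fit`` learns the false-positive threshold (from the control population)
    and the single-molecule unit intensity (from the Gaussian mixture over
    surviving spot intensities); ``transform`` applies the total-intensity /
    unit-intensity rule per cell.

    Parameters
    ----------
    n_components : number of Gaussian components in the intensity mixture
    percentile : control percentile for the false-positive threshold
    tol, max_iter : EM stopping rule
    random_state : EM initialisation seed (fit is deterministic given it)
    """

    def __init__(self, n_components: int = 3, percentile: float = FP_PERCENTILE,
                 tol: float = 1e-8, max_iter: int = 500, random_state: int = 0):
        self.n_components = n_components
        self.percentile = percentile
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None, control: Optional[Sequence[float]] = None):
        """Fit on spot intensities.

        X may be a SpotTable (its control population is used) or a 1-D array
        of spot intensities with ``control`` passed separately; with no
        control the threshold is 0 (keep everything).
        """
        if isinstance(X, SpotTable):
            control = X.control_intensities if control is None else control
            intensities = X.spots["intensity"].to_numpy(dtype=float)
        else:
            intensities = np.asarray(X, dtype=float).ravel()
        thr = fp_threshold(control, self.percentile) if control is not None and len(control) else 0.0
        surviving = intensities[intensities > thr]
        mixture = fit_intensity_mixture(
            surviving,
            n_components=self.n_components,
            seed=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.fp_threshold_ = thr
        self.mixture_ = mixture
        self.unit_intensity_ = mixture[0][1]
        self.calibration_ = IntensityCalibration(
            fp_threshold=thr, unit_intensity=self.unit_intensity_, mixture=mixture
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        """Quantify a SpotTable (or raw spot DataFrame) into per-cell counts."""
        if not hasattr(self, "calibration_"):
            raise FitError("IntensityCalibrator is not fitted")
        return quantify_counts(X, self.calibration_)
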