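"""Synthetic data generators: ZINB counts, telegraph-model counts, spot tables.

These generators produce every input the downstream stages consume, emulating
the structure of smFISH data from a tryptophan-operon reporter experiment:
zero-inflated, overdispersed single-cell mRNA count distributions across a
tryptophan condition ladder, and per-spot integrated intensities that are
quantal (Gaussian components at integer multiples of the single-molecule unit
intensity) together with a low-intensity background population standing in for
a probe-target-deletion negative control.

The telegraph simulator is mechanistic and shares no code with the ZINB model;
it serves as an independent oracle for the bursty negative-binomial regime.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._exceptions import ParameterError
from .datasets import CELL_COLUMNS, COUNT_COLUMNS, SpotTable
from .params import TelegraphParams, ZINBParams

__all__ = ["sample_zinb", "simulate_telegraph", "generate_spot_table"]


def _counts_frame(counts: np.ndarray, strain: str, condition_uM: float, cell_prefix: str) -> pd.DataFrame:
    n = len(counts)
    return pd.DataFrame(
        {
            "cell_id": [f"{cell_prefix}{i:06d}" for i in range(n)],
            "strain": strain,
            "condition_uM": float(condition_uM),
            "count": np.asarray(counts, dtype=np.int64),
        },
        columns=COUNT_COLUMNS,
    )


def sample_zinb(
    params: ZINBParams,
    n_cells: int,
    seed: int,
    strain: str = "synthetic",
    condition_uM: float = 0.0,
    cell_prefix: str = "c",
) -> pd.DataFrame:
    """Draw a per-cell count table from the zero-inflated negative binomial.

    With probability ``omega`` a cell is in the repressed state and reports 0;
    otherwise its count follows NB(r, p) with pmf
    C(k+r-1, k) p**k (1-p)**r. Reproducible for a fixed ``seed``.
    """
    if not isinstance(params, ZINBParams):
        params = ZINBParams(*params)
    if n_cells < 0:
        raise ParameterError(f"n_cells must be >= 0, got {n_cells}")
    rng = np.random.default_rng(seed)
    if n_cells == 0:
        return _counts_frame(np.empty(0, dtype=np.int64), strain, condition_uM, cell_prefix)
    repressed = rng.random(n_cells) < params.omega
    # numpy's negative_binomial counts failures with success prob q, pmf
    # C(k+r-1,k) q**r (1-q)**k -- so q = 1 - p under our convention.
    active = rng.negative_binomial(params.r, 1.0 - params.p, size=n_cells)
    counts = np.where(repressed, 0, active)
    return _counts_frame(counts, strain, condition_uM, cell_prefix)


def simulate_telegraph(
    params: TelegraphParams,
    n_cells: int,
    t_end: float,
    seed: int,
    strain: str = "telegraph",
    condition_uM: float = 0.0,
    cell_prefix: str = "c",
) -> pd.DataFrame:
    """Exact steady-state-bound sampling of the two-state promoter model.

    For each cell the ON/OFF promoter trajectory on [0, t_end] is simulated
    exactly (exponential holding times, promoter initialised from its
    stationary law). Given that trajectory, transcription is a Poisson process
    of rate k_tx during ON intervals and each transcript decays independently
    at rate k_deg, so the surviving count at t_end is Poisson with mean

        k_tx * integral over ON intervals of exp(-k_deg (t_end - s)) ds.

    This conditional-Poisson draw is identical in law to running the full
    event-by-event stochastic simulation and reading the count at t_end, but
    costs only one event per promoter switch. Cells start with zero mRNA, so
    ``t_end`` must be several mRNA lifetimes (1/k_deg) for stationarity.
    """
    if not isinstance(params, TelegraphParams):
        params = TelegraphParams(*params)
    if n_cells < 0:
        raise ParameterError(f"n_cells must be >= 0, got {n_cells}")
    if not (t_end > 0):
        raise ParameterError(f"t_end must be > 0, got {t_end}")
    rng = np.random.default_rng(seed)
    k_on, k_off, k_tx, k_deg = params.k_on, params.k_off, params.k_tx, params.k_deg
    total_switch = k_on + k_off
    p_on = k_on / total_switch if total_switch > 0 else 0.0
    counts = np.empty(n_cells, dtype=np.int64)
    for i in range(n_cells):
        t = 0.0
        on = rng.random() < p_on
        integral = 0.0  # integral of exp(-k_deg (t_end - s)) over ON time
        while t < t_end:
            rate = k_off if on else k_on
            if rate <= 0.0:
                t_next = t_end
            else:
                t_next = min(t + rng.exponential(1.0 / rate), t_end)
            if on:
                integral += math.exp(-k_deg * (t_end - t_next)) - math.exp(
                    -k_deg * (t_end - t)
                )
            t = t_next
            on = not on
        counts[i] = rng.poisson(k_tx * integral / k_deg)
    return _counts_frame(counts, strain, condition_uM, cell_prefix)


def generate_spot_table(
    unit_intensity: float,
    intensity_cv: float,
    counts: pd.DataFrame,
    n_control: int,
    control_scale: float,
    seed: int,
    coloc_prob: float = 0.15,
) -> SpotTable:
    """Emit a quantal spot-intensity table for a count table.

    Each cell with count k distributes its k molecules over diffraction-limited
    spots: successive molecules co-localize with the current spot with
    probability ``coloc_prob`` (else start a new spot), so a spot holding m
    molecules draws its integrated intensity from
    N(m * unit_intensity, m * (intensity_cv * unit_intensity)**2). The cell's
    total intensity therefore has mean k * unit_intensity and standard
    deviation intensity_cv * unit_intensity * sqrt(k) regardless of grouping.
    Silent cells emit no spots but stay on the cell roster.

    Control (no-target) intensities are half-normal with scale
    ``control_scale``, emulating sub-threshold background spots.
    """
    if not (unit_intensity > 0):
        raise ParameterError(f"unit_intensity must be > 0, got {unit_intensity}")
    if not (0.0 < intensity_cv < 0.5):
        raise ParameterError(f"intensity_cv must lie in (0, 0.5), got {intensity_cv}")
    if control_scale < 0:
        raise ParameterError(f"control_scale must be >= 0, got {control_scale}")
    if n_control < 0:
        raise ParameterError(f"n_control must be >= 0, got {n_control}")
    if not (0.0 <= coloc_prob < 1.0):
        raise ParameterError(f"coloc_prob must lie in [0, 1), got {coloc_prob}")

    from .datasets import validate_counts

    counts = validate_counts(counts, source="<counts for spot generation>")
    rng = np.random.default_rng(seed)
    spot_sd = intensity_cv * unit_intensity

    spot_ids, cell_ids, intensities = [], [], []
    sid = 0
    for cell_id, k in zip(counts["cell_id"], counts["count"]):
        if k == 0:
            continue
        # sequential grouping of molecules into spots
        mult = [1]
        for _ in range(int(k) - 1):
            if rng.random() < coloc_prob:
                mult[-1] += 1
            else:
                mult.append(1)
        for m in mult:
            inten = rng.normal(m * unit_intensity, math.sqrt(m) * spot_sd)
            spot_ids.append(f"s{sid:07d}")
            cell_ids.append(cell_id)
            intensities.append(max(inten, 0.0))
            sid += 1

    intensities = np.asarray(intensities, dtype=float)
    # peak height is carried as metadata only; a fixed fraction of the
    # integrated intensity with mild multiplicative noise is realistic enough
    peak = 0.35 * intensities * np.clip(1.0 + 0.1 * rng.standard_normal(len(intensities)), 0.1, None)
    spots = pd.DataFrame(
        {
            "spot_id": spot_ids,
            "cell_id": cell_ids,
            "intensity": intensities,
            "peak_height": peak,
        },
        columns=["spot_id", "cell_id", "intensity", "peak_height"],
    )
    control = np.abs(rng.normal(0.0, control_scale, size=n_control)) if n_control else np.empty(0)
    cells = counts[CELL_COLUMNS].reset_index(drop=True)
    return SpotTable(spots=spots, control_intensities=control, cells=cells)
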