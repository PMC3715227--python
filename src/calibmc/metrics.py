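"""Accuracy indices between calibrated estimates and reference glucose.

The indices standard in the diabetes community, computed over the paired
(RBG g_i, estimate ĝ_i) samples of a session:

    RMSE = sqrt(mean_i (g_i − ĝ_i)²)          [mg/dL]
    MAD  = mean_i |g_i − ĝ_i|                 [mg/dL]
    MARD = mean_i |g_i − ĝ_i| / g_i × 100     [%]

Pairs are formed at the RBG instants at or after the initial calibration
instant, with ĝ taken at the nearest grid sample.  Aggregation across
sessions treats sessions (independent study days) as the units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glucose_model import CalibrationPlan
from .session_io import Session

__all__ = ["AccuracyIndices", "session_accuracy", "aggregate", "INDEX_NAMES"]

INDEX_NAMES = ("rmse", "mad", "mard")


@dataclass
class AccuracyIndices:
    rmse: float  # mg/dL
    mad: float  # mg/dL
    mard: float  # percent
    n_pairs: int

    def __post_init__(self) -> None:
        if min(self.rmse, self.mad, self.mard) < 0 or self.n_pairs < 1:
            raise ValueError("indices must be ≥ 0 over ≥ 1 pair")

    def as_dict(self) -> dict[str, float]:
        return {"rmse": self.rmse, "mad": self.mad, "mard": self.mard}


def accuracy_from_pairs(g: np.ndarray, g_hat: np.ndarray) -> AccuracyIndices:
    """Indices from matched reference/estimate arrays."""
    g = np.asarray(g, dtype=float)
    g_hat = np.asarray(g_hat, dtype=float)
    if g.size == 0:
        raise ValueError("no evaluable pairs")
    err = g - g_hat
    return AccuracyIndices(
        rmse=float(np.sqrt(np.mean(err**2))),
        mad=float(np.mean(np.abs(err))),
        mard=float(np.mean(np.abs(err) / g) * 100.0),
        n_pairs=int(g.size),
    )


def session_accuracy(
    session: Session,
    calibrated: np.ndarray,
    plan: CalibrationPlan,
    include_cal_points: bool = True,
) -> AccuracyIndices:
    """Index the calibrated series against the session's RBG samples.

    Pairs run over RBG instants at or after the plan's initial calibration
    instant.  With ``include_cal_points=False`` the instants used for
    (re)calibration are excluded — their error contribution is zero by the
    shift-to-match contract, so including them (the default) scores the
    benefit of each extra RBG point exactly as the Monte Carlo null does.
    """
    mask = session.rbg_times >= plan.t0
    if not include_cal_points:
        on_plan = np.isclose(session.rbg_times[:, None], plan.times[None, :]).any(
            axis=1
        )
        mask &= ~on_plan
    times = session.rbg_times[mask]
    if times.size == 0:
        raise ValueError("no evaluable RBG pairs after the initial calibration")
    g_hat = calibrated[session.nearest_index(times)]
    if np.any(~np.isfinite(g_hat)):
        raise ValueError("calibrated series undefined at an evaluation instant")
    return accuracy_from_pairs(session.rbg_values[mask], g_hat)


def aggregate(per_session: list[AccuracyIndices]) -> pd.DataFrame:
    """Mean and sample (n−1) standard deviation of each index over sessions."""
    if not per_session:
        raise ValueError("no sessions to aggregate")
    df = pd.DataFrame([ix.as_dict() for ix in per_session])
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
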