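"""Population glucose-estimation model and baseline calibration.

The device estimates glucose through a static population-level multivariate
linear regression over the C multi-sensor channels,

    g_hat_uncal(t) = beta · x(t) + intercept ,

with beta identified by L1-regularised (LASSO) least squares on pooled
(x, RBG) pairs from the identification sessions.  Per-session usage then
applies a *baseline calibration*: at a calibration instant t_cal with
reference g(t_cal),

    b = g_hat_uncal(t_cal) − g(t_cal) ,
    g_hat(t) = g_hat_uncal(t) − b          for t ≥ t_cal,

i.e. the estimated profile is shifted so it passes through the reference
value, and b is held fixed until the next calibration instant (if any).

Identification removes per-session means (a fixed-effects / within
transformation, equivalent to unpenalised per-session intercepts) before
the penalised fit: session baselines live inside the glucose-related
channels and would otherwise attenuate beta; they are exactly what the
calibration parameter b absorbs at deployment.  Channels are standardised
on the identification data.  Lambda is chosen by cross-validation grouped
by session, scoring within-session-centred residuals (the error that
survives calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import warnings

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

from .session_io import Session

__all__ = [
    "RegressionModel",
    "CalibrationPlan",
    "fit_model",
    "predict_uncalibrated",
    "compute_baseline",
    "apply_calibration",
    "DEFAULT_LAMBDA_GRID",
    "EQUILIBRATION_S",
]

#: default initial-calibration delay: 75 min of sensor–skin equilibration
EQUILIBRATION_S = 75 * 60.0

#: default L1 penalty grid (sklearn ``alpha`` scale, mg/dL response units)
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 1.5, 12))

#: RBG-to-grid pairing tolerance factor (× dt) and compute_baseline window
BASELINE_TOL_S = 300.0


@dataclass
class RegressionModel:
    """Population sparse linear model: ``beta · x + intercept`` (mg/dL)."""

    beta: np.ndarray
    intercept: float
    lam: float
    channel_count: int

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.channel_count,):
            raise ValueError("beta length must equal channel_count")

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(
                f"# intercept={float(self.intercept)!r} lambda={float(self.lam)!r}\n"
            )
            fh.write("channel,beta\n")
            for c, b in enumerate(self.beta):
                fh.write(f"{c},{float(b)!r}\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RegressionModel":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(
                kv.split("=") for kv in header.lstrip("# ").strip().split(" ")
            )
            df = pd.read_csv(fh, float_precision="round_trip")
        beta = df["beta"].to_numpy(float)
        return cls(
            beta=beta,
            intercept=float(meta["intercept"]),
            lam=float(meta["lambda"]),
            channel_count=beta.size,
        )


@dataclass
class CalibrationPlan:
    """Ordered calibration instants with the baseline b active after each.

    The segment from each calibration time to the next uses that entry's b;
    before the first entry the calibrated estimate is undefined.
    """

    times: np.ndarray
    b_values: np.ndarray
    scheme: str = "single"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.times.size == 0:
            raise ValueError("calibration plan needs at least one entry")
        if self.times.shape != self.b_values.shape:
            raise ValueError("times/b_values length mismatch")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("calibration times must be strictly increasing")

    @property
    def t0(self) -> float:
        return float(self.times[0])

    def b_active(self, t: np.ndarray) -> np.ndarray:
        """Baseline in force at each time (NaN before the first entry)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        b = np.where(idx >= 0, self.b_values[np.maximum(idx, 0)], np.nan)
        return b


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------

def _paired_design(
    session: Session, reference: tuple[np.ndarray, np.ndarray] | None
) -> tuple[np.ndarray, np.ndarray]:
    """(x, g) pairs at reference instants, x at the nearest grid sample."""
    if reference is None:
        times, values = session.rbg_times, session.rbg_values
    else:
        times, values = (np.asarray(a, dtype=float) for a in reference)
    if times.size == 0:
        raise ValueError(f"no reference samples for session {session.session_id}")
    idx = session.nearest_index(times)
    if np.any(np.abs(session.t[idx] - times) > session.dt):
        raise ValueError("reference instant farther than dt from the grid")
    return session.X[:, idx].T, values


def fit_model(
    sessions: Sequence[Session],
    reference: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    cv_folds: int = 5,
    seed: int = 0,
) -> RegressionModel:
    """Identify the population model by grouped-CV LASSO.

    Parameters
    ----------
    sessions
        Identification sessions (≥2).
    reference
        Optional map ``session_id -> (times_s, glucose_mgdl)`` overriding
        each session's RBG series as the regression target (e.g. simulator
        ground truth in tests).  Default: RBG instants only.
    lambda_grid
        Candidate L1 strengths (sklearn ``alpha``); the grid is searched by
        session-grouped cross-validation and ties prefer the larger lambda.
    cv_folds, seed
        Number of folds and the seed for the fold assignment shuffle.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 identification sessions")
    lambda_grid = sorted(float(a) for a in lambda_grid)
    if not lambda_grid:
        raise ValueError("empty lambda_grid")
    C = sessions[0].n_channels
    Xs, ys = [], []
    for s in sessions:
        if s.n_channels != C:
            raise ValueError("sessions have inconsistent channel counts")
        ref = reference.get(s.session_id) if reference is not None else None
        x, g = _paired_design(s, ref)
        Xs.append(x)
        ys.append(g)
    # within-session centring (session fixed effects)
    Xc = [x - x.mean(axis=0) for x in Xs]
    yc = [g - g.mean() for g in ys]
    pooled = np.vstack(Xc)
    if np.all(pooled.std(axis=0) < 1e-12):
        raise ValueError("degenerate design: all channels constant")

    n_sessions = len(sessions)
    n_folds = min(cv_folds, n_sessions)
    order = np.random.default_rng(seed).permutation(n_sessions)
    fold_of = np.empty(n_sessions, dtype=int)
    fold_of[order] = np.arange(n_sessions) % n_folds

    def _fit(alpha: float, rows_X: np.ndarray, rows_y: np.ndarray) -> np.ndarray:
        scale = rows_X.std(axis=0)
        scale[scale < 1e-12] = 1.0
        est = Lasso(alpha=alpha, fit_intercept=False, max_iter=50_000, tol=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(rows_X / scale, rows_y)
        return est.coef_ / scale

    cv_mse = np.zeros(len(lambda_grid))
    for fold in range(n_folds):
        train = [i for i in range(n_sessions) if fold_of[i] != fold]
        val = [i for i in range(n_sessions) if fold_of[i] == fold]
        Xtr = np.vstack([Xc[i] for i in train])
        ytr = np.concatenate([yc[i] for i in train])
        for j, alpha in enumerate(lambda_grid):
            beta = _fit(alpha, Xtr, ytr)
            err = np.concatenate([yc[i] - Xc[i] @ beta for i in val])
            cv_mse[j] += np.sum(err**2)
    # tie-break toward larger lambda (sparser model)
    best = int(np.flatnonzero(cv_mse <= cv_mse.min() * (1 + 1e-12))[-1])
    lam = float(lambda_grid[best])
    beta = _fit(lam, np.vstack(Xc), np.concatenate(yc))
    mean_x = np.vstack(Xs).mean(axis=0)
    mean_y = float(np.concatenate(ys).mean())
    intercept = mean_y - float(beta @ mean_x)
    return RegressionModel(beta=beta, intercept=intercept, lam=lam, channel_count=C)


# ---------------------------------------------------------------------------
# prediction and calibration
# ---------------------------------------------------------------------------

def predict_uncalibrated(model: RegressionModel, session: Session) -> np.ndarray:
    """Uncalibrated estimate ``beta·x(t) + intercept`` on the session grid."""
    if session.n_channels != model.channel_count:
        raise ValueError(
            f"session has {session.n_channels} channels, model expects "
            f"{model.channel_count}"
        )
    return model.beta @ session.X + model.intercept


def compute_baseline(
    model: RegressionModel,
    session: Session,
    t_cal: float,
    tol_s: float = BASELINE_TOL_S,
) -> float:
    """Calibration parameter b at ``t_cal``: model output minus reference.

    Uses the RBG sample nearest to ``t_cal`` (within ``tol_s``) and the
    channel vector at the grid sample nearest that RBG instant.
    """
    if session.rbg_times.size == 0:
        raise ValueError("session has no RBG samples")
    k = int(np.argmin(np.abs(session.rbg_times - t_cal)))
    if abs(session.rbg_times[k] - t_cal) > tol_s:
        raise ValueError(f"no RBG within {tol_s} s of t_cal={t_cal}")
    idx = int(session.nearest_index(session.rbg_times[k]))
    pred = float(model.beta @ session.X[:, idx] + model.intercept)
    return pred - float(session.rbg_values[k])


def apply_calibration(
    model: RegressionModel, session: Session, plan: CalibrationPlan
) -> np.ndarray:
    """Calibrated series: model output minus the baseline active at each t.

    At every calibration instant the result equals the reference used there
    (shift-to-match contract); before the first instant it is NaN and must
    be excluded from all accuracy metrics.  Each plan entry takes effect at
    the grid sample nearest its calibration instant — the same sample its
    baseline was computed from.
    """
    switch = session.t[session.nearest_index(plan.times)]
    idx = np.searchsorted(switch, session.t, side="right") - 1
    b = np.where(idx >= 0, plan.b_values[np.maximum(idx, 0)], np.nan)
    return predict_uncalibrated(model, session) - b
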