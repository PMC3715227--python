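"""Construction of calibration plans for every strategy under comparison.

All strategies share the same initial calibration: the first RBG at or
after the 75-min equilibration (sensor–skin adaptation) sets the baseline
b that every scheme starts from.  On top of it:

* ``single_baseline_plan``  — nothing else (the device's standard rule);
* ``event_triggered_plan``  — one recalibration at the first RBG after
  each detected sweat event;
* ``scheduled_plan``        — recalibrations at fixed delays Tc after the
  initial instant (e.g. the Tc = 1 h, 4 h schedule);
* ``random_plan``           — Ns recalibrations at RBG instants drawn
  uniformly without replacement, the building block of the Monte Carlo
  null distribution.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .glucose_model import (
    EQUILIBRATION_S,
    CalibrationPlan,
    RegressionModel,
    compute_baseline,
)
from .session_io import Session
from .sweat_detector import SweatEvent

__all__ = [
    "single_baseline_plan",
    "event_triggered_plan",
    "scheduled_plan",
    "random_plan",
    "eligible_recalibration_times",
]


def single_baseline_plan(
    model: RegressionModel,
    session: Session,
    equilibration_s: float = EQUILIBRATION_S,
) -> CalibrationPlan:
    """Initial calibration only: first RBG at or after the equilibration."""
    eligible = session.rbg_times[session.rbg_times >= equilibration_s]
    if eligible.size == 0:
        raise ValueError(
            f"no RBG at or after {equilibration_s} s in {session.session_id}"
        )
    t0 = float(eligible[0])
    return CalibrationPlan(
        times=[t0], b_values=[compute_baseline(model, session, t0)], scheme="single"
    )


def _extend(
    model: RegressionModel,
    session: Session,
    base: CalibrationPlan,
    extra_times: Sequence[float],
    scheme: str,
) -> CalibrationPlan:
    """Add recalibration instants after t0, collapsing duplicates."""
    times = [base.t0]
    for tc in sorted(set(float(t) for t in extra_times)):
        if tc > base.t0 and tc not in times:
            times.append(tc)
    b = [float(base.b_values[0])] + [
        compute_baseline(model, session, tc) for tc in times[1:]
    ]
    return CalibrationPlan(times=times, b_values=b, scheme=scheme)


def event_triggered_plan(
    model: RegressionModel,
    session: Session,
    events: Sequence[SweatEvent],
    equilibration_s: float = EQUILIBRATION_S,
) -> CalibrationPlan:
    """Recalibrate at the first RBG after each detected sweat event.

    Events with no subsequent RBG contribute nothing; several events ahead
    of the same RBG collapse to a single recalibration; instants not
    strictly after the initial calibration are dropped.
    """
    base = single_baseline_plan(model, session, equilibration_s)
    extra = [
        e.first_rbg_after_s for e in events if e.first_rbg_after_s is not None
    ]
    return _extend(model, session, base, extra, "sweat")


def scheduled_plan(
    model: RegressionModel,
    session: Session,
    tc_list_s: Sequence[float],
    equilibration_s: float = EQUILIBRATION_S,
) -> CalibrationPlan:
    """Recalibrate at the first RBG ≥ t0 + Tc for each scheduled delay.

    Delays falling beyond the session end are skipped; duplicates collapse.
    """
    base = single_baseline_plan(model, session, equilibration_s)
    extra = []
    for tc in tc_list_s:
        later = session.rbg_times[session.rbg_times >= base.t0 + float(tc)]
        if later.size:
            extra.append(float(later[0]))
    return _extend(model, session, base, extra, "schedule")


def eligible_recalibration_times(
    session: Session, t0: float
) -> np.ndarray:
    """RBG instants strictly after the initial calibration instant."""
    return session.rbg_times[session.rbg_times > t0]


def random_plan(
    model: RegressionModel,
    session: Session,
    n_recal: int,
    rng: np.random.Generator,
    equilibration_s: float = EQUILIBRATION_S,
) -> CalibrationPlan:
    """Initial calibration plus Ns random recalibration instants.

    The initial entry is identical to the single-baseline plan and fixed;
    the Ns recalibration instants are drawn uniformly *without replacement*
    from the RBG instants strictly after t0 (drawing one twice would be a
    no-op anyway).
    """
    base = single_baseline_plan(model, session, equilibration_s)
    if n_recal == 0:
        return base
    pool = eligible_recalibration_times(session, base.t0)
    if pool.size < n_recal:
        raise ValueError(
            f"only {pool.size} eligible RBG instants for Ns={n_recal} "
            f"in {session.session_id}"
        )
    chosen = rng.choice(pool, size=n_recal, replace=False)
    return _extend(model, session, base, chosen, "random")
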