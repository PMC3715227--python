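"""Monte Carlo assessment of calibration schemes.

A proposed calibration scheme (recalibrating after sweat events, or on a
fixed schedule Tc after the initial calibration) may look better than the
single initial calibration simply because it consumes more RBG points.
The Monte Carlo null controls for exactly that: in each of N iterations
every test session is recalibrated at Ns RBG instants drawn at random (the
initial calibration stays fixed), the across-session mean of each accuracy
index is stored, and the scheme under test is located inside the resulting
null distribution.  ``percent_better`` — the percentage of iterations with
a strictly smaller mean index than the scheme — is the headline statistic:
small values mean the scheme beats random recalibration with the same RBG
budget; central values mean the apparent benefit is just the extra points.

Scheme-vs-scheme significance uses the two-sample Student t-test when both
groups pass a Kolmogorov–Smirnov normality check (at the sample's own
mean/sd), and the Wilcoxon rank-sum test otherwise, treating sessions
(independent study days) as independent units.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration_schemes import (
    event_triggered_plan,
    random_plan,
    scheduled_plan,
    single_baseline_plan,
)
from .glucose_model import (
    EQUILIBRATION_S,
    CalibrationPlan,
    RegressionModel,
    apply_calibration,
    predict_uncalibrated,
)
from .metrics import INDEX_NAMES, AccuracyIndices, accuracy_from_pairs, session_accuracy
from .session_io import Session
from .sweat_detector import SweatEvent

__all__ = [
    "MCResult",
    "SchemeAssessment",
    "choose_ns",
    "run_mc",
    "percent_better",
    "compare_schemes",
    "assess_scheme",
    "full_assessment",
    "write_assessment",
]


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class MCResult:
    """Null distribution of mean accuracy indices under random recalibration."""

    null_means: pd.DataFrame  # N rows × (rmse, mad, mard)
    n_iterations: int
    n_recal: int  # Ns
    seed: int
    scheme_means: dict[str, float] | None = None
    single_means: dict[str, float] | None = None

    @property
    def percent_better(self) -> dict[str, float]:
        """% of iterations strictly better (smaller) than the scheme under test."""
        if self.scheme_means is None:
            raise ValueError("no scheme under test attached")
        return {
            k: percent_better(self.null_means[k].to_numpy(), self.scheme_means[k])
            for k in INDEX_NAMES
        }


@dataclass
class SchemeAssessment:
    """One scenario: scheme under test located inside its Monte Carlo null."""

    name: str
    per_session: pd.DataFrame  # session_id + indices for the scheme
    single_per_session: pd.DataFrame
    mc: MCResult
    comparison: dict[str, tuple[str, float, float]]  # index -> (test, stat, p)


# ---------------------------------------------------------------------------
# Ns choice and the percentile statistic
# ---------------------------------------------------------------------------

def choose_ns(event_counts: Sequence[int]) -> int:
    """Ns = mean event count over test sessions, rounded half away from zero.

    Any event at all forces Ns ≥ 1; no events anywhere gives 0.
    """
    counts = np.asarray(list(event_counts), dtype=float)
    if counts.size == 0 or np.all(counts == 0):
        return 0
    return max(1, int(np.floor(counts.mean() + 0.5)))


def percent_better(distribution: np.ndarray, scheme_value: float) -> float:
    """Percentage of null iterations strictly smaller than the scheme value.

    Ties count as not-better (conservative for the scheme under test).
    """
    d = np.asarray(distribution, dtype=float)
    if d.size == 0:
        raise ValueError("empty distribution")
    return float(100.0 * np.mean(d < scheme_value))


# ---------------------------------------------------------------------------
# fast per-session evaluation used inside the MC loop
# ---------------------------------------------------------------------------

@dataclass
class _SessionCache:
    """Everything the MC loop needs, precomputed once per session."""

    session_id: str
    t0: float
    b0: float
    pool_times: np.ndarray  # eligible recalibration instants (> t0)
    pool_b: np.ndarray  # baseline value were we to recalibrate there
    eval_times: np.ndarray  # RBG instants ≥ t0
    eval_pred: np.ndarray  # uncalibrated model output at those instants
    eval_g: np.ndarray  # RBG values there

    @classmethod
    def build(
        cls,
        model: RegressionModel,
        session: Session,
        equilibration_s: float = EQUILIBRATION_S,
    ) -> "_SessionCache":
        base = single_baseline_plan(model, session, equilibration_s)
        pred = predict_uncalibrated(model, session)
        rbg_pred = pred[session.nearest_index(session.rbg_times)]
        pool_mask = session.rbg_times > base.t0
        eval_mask = session.rbg_times >= base.t0
        return cls(
            session_id=session.session_id,
            t0=base.t0,
            b0=float(base.b_values[0]),
            pool_times=session.rbg_times[pool_mask],
            pool_b=(rbg_pred - session.rbg_values)[pool_mask],
            eval_times=session.rbg_times[eval_mask],
            eval_pred=rbg_pred[eval_mask],
            eval_g=session.rbg_values[eval_mask],
        )

    def evaluate(
        self, chosen: np.ndarray, include_cal_points: bool = True
    ) -> AccuracyIndices:
        """Indices for the plan {t0} ∪ pool[chosen] (indices into the pool)."""
        chosen = np.sort(np.asarray(chosen, dtype=int))
        times = np.concatenate(([self.t0], self.pool_times[chosen]))
        bs = np.concatenate(([self.b0], self.pool_b[chosen]))
        seg = np.searchsorted(times, self.eval_times, side="right") - 1
        g_hat = self.eval_pred - bs[seg]
        g = self.eval_g
        if not include_cal_points:
            keep = ~np.isin(self.eval_times, times)
            g, g_hat = g[keep], g_hat[keep]
        return accuracy_from_pairs(g, g_hat)


def _stream_seed(seed: int, iteration: int, session_id: str) -> np.random.SeedSequence:
    """One RNG stream per (seed, iteration, session): parallel-safe determinism."""
    h = zlib.crc32(session_id.encode()) & 0x7FFFFFFF
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, iteration, h])


def run_mc(
    model: RegressionModel,
    sessions: Sequence[Session],
    n_recal: int,
    n_iterations: int,
    seed: int,
    include_cal_points: bool = True,
    equilibration_s: float = EQUILIBRATION_S,
) -> MCResult:
    """Build the null distribution of mean indices under random recalibration.

    Each iteration draws, independently per session, ``n_recal`` (Ns)
    recalibration instants uniformly without replacement from the RBG
    instants after the fixed initial calibration, scores every session and
    stores the across-session mean of RMSE/MAD/MARD.  Deterministic given
    ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    caches = [_SessionCache.build(model, s, equilibration_s) for s in sessions]
    for c in caches:
        if c.pool_times.size < n_recal:
            raise ValueError(
                f"only {c.pool_times.size} eligible RBG instants for "
                f"Ns={n_recal} in {c.session_id}"
            )
    rows = np.empty((n_iterations, len(INDEX_NAMES)))
    for i in range(n_iterations):
        acc = np.zeros(len(INDEX_NAMES))
        for cache in caches:
            if n_recal:
                rng = np.random.default_rng(_stream_seed(seed, i, cache.session_id))
                chosen = rng.choice(cache.pool_times.size, n_recal, replace=False)
            else:
                chosen = np.empty(0, dtype=int)
            ix = cache.evaluate(chosen, include_cal_points)
            acc += [ix.rmse, ix.mad, ix.mard]
        rows[i] = acc / len(caches)
    return MCResult(
        null_means=pd.DataFrame(rows, columns=list(INDEX_NAMES)),
        n_iterations=n_iterations,
        n_recal=n_recal,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# significance testing between schemes
# ---------------------------------------------------------------------------

def _looks_normal(x: np.ndarray, alpha: float) -> bool:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return False
    return stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue > alpha


def compare_schemes(
    indices_a: Sequence[float],
    indices_b: Sequence[float],
    alpha: float = 0.05,
) -> tuple[str, float, float]:
    """Two-sided test between per-session index values of two schemes.

    Student's t-test when both groups pass the KS normality gate at
    ``alpha`` (parameters estimated from each sample — the Lilliefors
    caveat applies), the Wilcoxon rank-sum test otherwise.  Groups are
    treated as independent.  Returns (test name, statistic, p-value).
    """
    a = np.asarray(list(indices_a), dtype=float)
    b = np.asarray(list(indices_b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 sessions per group")
    if _looks_normal(a, alpha) and _looks_normal(b, alpha):
        res = stats.ttest_ind(a, b)
        return "t-test", float(res.statistic), float(res.pvalue)
    res = stats.ranksums(a, b)
    return "wilcoxon-rank-sum", float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# full scenario assessment
# ---------------------------------------------------------------------------

def _scheme_table(
    model: RegressionModel,
    sessions: Sequence[Session],
    plans: Mapping[str, CalibrationPlan],
    include_cal_points: bool,
) -> pd.DataFrame:
    rows = []
    for s in sessions:
        plan = plans[s.session_id]
        ix = session_accuracy(
            s, apply_calibration(model, s, plan), plan, include_cal_points
        )
        rows.append(
            {
                "session_id": s.session_id,
                "scheme": plan.scheme,
                "n_pairs": ix.n_pairs,
                **ix.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def assess_scheme(
    name: str,
    model: RegressionModel,
    sessions: Sequence[Session],
    plans: Mapping[str, CalibrationPlan],
    n_recal: int,
    n_iterations: int,
    seed: int,
    include_cal_points: bool = True,
    equilibration_s: float = EQUILIBRATION_S,
) -> SchemeAssessment:
    """Locate one scheme inside its Monte Carlo null and test it vs single."""
    table = _scheme_table(model, sessions, plans, include_cal_points)
    single_plans = {
        s.session_id: single_baseline_plan(model, s, equilibration_s)
        for s in sessions
    }
    single_table = _scheme_table(model, sessions, single_plans, include_cal_points)
    mc = run_mc(
        model,
        sessions,
        n_recal,
        n_iterations,
        seed,
        include_cal_points,
        equilibration_s,
    )
    mc.scheme_means = {k: float(table[k].mean()) for k in INDEX_NAMES}
    mc.single_means = {k: float(single_table[k].mean()) for k in INDEX_NAMES}
    comparison = {
        k: compare_schemes(table[k], single_table[k]) for k in INDEX_NAMES
    }
    return SchemeAssessment(
        name=name,
        per_session=table,
        single_per_session=single_table,
        mc=mc,
        comparison=comparison,
    )


def full_assessment(
    model: RegressionModel,
    test_sessions: Sequence[Session],
    events: Mapping[str, Sequence[SweatEvent]] | None = None,
    tc_grid_s: Sequence[float] = tuple(h * 3600.0 for h in range(1, 8)),
    combined_tc_s: Sequence[float] = (3600.0, 4 * 3600.0),
    n_iterations: int = 1000,
    seed: int = 0,
    include_cal_points: bool = True,
    equilibration_s: float = EQUILIBRATION_S,
) -> dict[str, SchemeAssessment]:
    """Run every configured scenario against its Monte Carlo null.

    Scenarios: ``sweat`` (event-triggered recalibration, Ns = rounded mean
    detected-event count) when ``events`` is given; one ``tc_{h}h`` scenario
    per scheduled delay in ``tc_grid_s`` (Ns = 1); and the combined schedule
    (Ns = number of delays).  Each scenario gets its own derived seed.
    """
    def scenario_seed(name: str) -> int:
        return (int(seed) * 1_000_003 + zlib.crc32(name.encode())) & 0x7FFFFFFF

    results: dict[str, SchemeAssessment] = {}
    if events is not None:
        counts = [len(events.get(s.session_id, [])) for s in test_sessions]
        ns = choose_ns(counts)
        plans = {
            s.session_id: event_triggered_plan(
                model, s, events.get(s.session_id, []), equilibration_s
            )
            for s in test_sessions
        }
        results["sweat"] = assess_scheme(
            "sweat", model, test_sessions, plans, ns, n_iterations,
            scenario_seed("sweat"), include_cal_points, equilibration_s,
        )
    for tc in tc_grid_s:
        name = f"tc_{tc / 3600.0:g}h"
        plans = {
            s.session_id: scheduled_plan(model, s, [tc], equilibration_s)
            for s in test_sessions
        }
        results[name] = assess_scheme(
            name, model, test_sessions, plans, 1, n_iterations,
            scenario_seed(name), include_cal_points, equilibration_s,
        )
    if combined_tc_s:
        name = "tc_" + "_".join(f"{tc / 3600.0:g}h" for tc in combined_tc_s)
        plans = {
            s.session_id: scheduled_plan(model, s, combined_tc_s, equilibration_s)
            for s in test_sessions
        }
        results[name] = assess_scheme(
            name, model, test_sessions, plans, len(combined_tc_s), n_iterations,
            scenario_seed(name), include_cal_points, equilibration_s,
        )
    return results


def write_assessment(
    results: Mapping[str, SchemeAssessment],
    out_dir: str | Path,
    plots: bool = False,
) -> Path:
    """Write summary.csv plus per-scenario null distributions (and histograms)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, res in results.items():
        sub = out / name
        sub.mkdir(exist_ok=True)
        for k in INDEX_NAMES:
            res.mc.null_means[[k]].to_csv(
                sub / f"null_distribution_{k}.csv", index=False
            )
        res.per_session.to_csv(sub / "per_session.csv", index=False)
        pb = res.mc.percent_better
        for k in INDEX_NAMES:
            test_name, statistic, p = res.comparison[k]
            rows.append(
                {
                    "scheme": name,
                    "index": k,
                    "scheme_mean": res.mc.scheme_means[k],
                    "scheme_sd": float(res.per_session[k].std(ddof=1)),
                    "single_mean": res.mc.single_means[k],
                    "single_sd": float(res.single_per_session[k].std(ddof=1)),
                    "percent_better": pb[k],
                    "test": test_name,
                    "statistic": statistic,
                    "p_value": p,
                    "n_iterations": res.mc.n_iterations,
                    "n_recal": res.mc.n_recal,
                }
            )
        if plots:
            _plot_histograms(res, sub)
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    return out


def _plot_histograms(res: SchemeAssessment, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    for ax, k in zip(axes, INDEX_NAMES):
        ax.hist(res.mc.null_means[k], bins=30, color="0.7")
        ax.axvline(res.mc.scheme_means[k], color="red", label="scheme")
        ax.axvline(res.mc.single_means[k], color="green", label="single")
        ax.set_title(k.upper())
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(out_dir / "null_histograms.png", dpi=120)
    plt.close(fig)
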