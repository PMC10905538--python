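"""Kaplan-Meier survivability, control normalization, log-rank comparison,
and responder classification for per-trap event tables.

One trap is one subject; a death is an NK-mediated tumor apoptosis event at
a frame time; traps without an event are right-censored at the imaging
horizon (24 h).  The product-limit estimator

    S(t) = prod_{t_i <= t} (n_i - d_i) / n_i

uses the standard convention: censored traps leave the risk set at their
censoring time but never count as events.  With censoring only at the
horizon, S(horizon) = survivors / n0 exactly.

Experimental curves are normalized against the tumor-only on-chip control:

    S_norm(t) = (S_exp(t) - min S_cont) / (max S_cont - min S_cont)

which removes background on-chip death; a control with no deaths makes the
denominator zero, in which case the experimental curve is returned
unchanged with a degenerate-control flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvivalCurve:
    """Product-limit step function with risk/event bookkeeping."""

    times: np.ndarray       # ascending, first entry 0
    S: np.ndarray           # survival probability at each time
    n_risk: np.ndarray      # at risk entering each time
    d: np.ndarray           # events at each time
    c: np.ndarray           # censored at each time
    n0: int

    def at(self, t: float) -> float:
        """Step-function value: S at the last time <= t."""
        idx = np.searchsorted(self.times, t + 1e-12) - 1
        return float(self.S[max(idx, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "S": self.S,
                             "n_risk": self.n_risk, "d": self.d,
                             "c": self.c})


def _event_arrays(events: pd.DataFrame, horizon_h: float):
    status = events["status_code"].to_numpy()
    t = events["event_time_h"].to_numpy(dtype=float)
    times = np.where(status == 1, t, horizon_h)
    observed = status == 1
    if np.any(times[observed] > horizon_h + 1e-9):
        raise ValueError("event times beyond horizon")
    return times, observed


def km_estimate(events: pd.DataFrame, horizon_h: float = 24.0) -> SurvivalCurve:
    """Kaplan-Meier estimate for one population's event table.

    ``events`` rows carry status_code 1 (death at event_time_h) or
    2 (no event; censored at the horizon).
    """
    if len(events) == 0:
        raise ValueError("no traps in population")
    times, observed = _event_arrays(events, horizon_h)
    n0 = len(times)
    uniq = np.unique(times)
    out_t, out_s, out_r, out_d, out_c = [0.0], [1.0], [n0], [0], [0]
    s = 1.0
    for t in uniq:
        at_risk = int(np.sum(times >= t - 1e-12))
        d_t = int(np.sum(observed & np.isclose(times, t)))
        c_t = int(np.sum(~observed & np.isclose(times, t)))
        if d_t > 0:
            s *= (at_risk - d_t) / at_risk
        out_t.append(float(t))
        out_s.append(s)
        out_r.append(at_risk)
        out_d.append(d_t)
        out_c.append(c_t)
    return SurvivalCurve(np.array(out_t), np.array(out_s),
                         np.array(out_r), np.array(out_d),
                         np.array(out_c), n0)


def pool_runs(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine duplicate-run event tables for one cell line.

    Trap identity becomes (run_id, trap_id).  Mixing cell lines is an
    error, as is pooling tables that share a run_id (which would silently
    double-count traps; relabel run_id first if that is really intended).
    """
    if not tables:
        raise ValueError("no tables to pool")
    lines = {t["line_id"].iloc[0] for t in tables if len(t)}
    if len(lines) > 1:
        raise ValueError(f"mixed line_ids: {sorted(lines)}")
    run_ids = [t["run_id"].iloc[0] for t in tables if len(t)]
    if len(run_ids) != len(set(run_ids)):
        raise ValueError("duplicate run_id across pooled tables")
    return pd.concat(tables, ignore_index=True)


@dataclass
class NormalizedCurve:
    times: np.ndarray
    S_norm: np.ndarray
    control_id: str = "0:1"
    degenerate_control: bool = False


def normalize_survival(S_exp: SurvivalCurve,
                       S_cont: SurvivalCurve,
                       control_id: str = "0:1") -> NormalizedCurve:
    """Rescale an experimental curve by the control curve's range.

    Values may leave [0, 1] when the experimental curve drops below the
    control's minimum; they are reported as-is with a warning.
    """
    lo = float(S_cont.S.min())
    hi = float(S_cont.S.max())
    if hi - lo <= 1e-12:
        return NormalizedCurve(S_exp.times.copy(), S_exp.S.copy(),
                               control_id, degenerate_control=True)
    norm = (S_exp.S - lo) / (hi - lo)
    if norm.min() < -1e-12 or norm.max() > 1 + 1e-12:
        warnings.warn("normalized survivability outside [0, 1]")
    return NormalizedCurve(S_exp.times.copy(), norm, control_id)


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    groups: tuple[str, str] = ("a", "b")


def logrank_test(events_a: pd.DataFrame, events_b: pd.DataFrame,
                 horizon_h: float = 24.0,
                 groups: tuple[str, str] = ("a", "b")) -> LogRankResult:
    """Two-group log-rank test (1 df) with hypergeometric variance.

    Symmetric under group swap; with no events in either group the
    statistic is 0 and p = 1 (with a warning).
    """
    if len(events_a) == 0 or len(events_b) == 0:
        raise ValueError("both groups must be non-empty")
    ta, oa = _event_arrays(events_a, horizon_h)
    tb, ob = _event_arrays(events_b, horizon_h)
    times = np.concatenate([ta, tb])
    observed = np.concatenate([oa, ob])
    group = np.concatenate([np.zeros(len(ta), bool), np.ones(len(tb), bool)])
    event_times = np.unique(times[observed])
    if len(event_times) == 0:
        warnings.warn("no events in either group; log-rank undefined")
        return LogRankResult(0.0, 1.0, groups)
    O1 = E1 = V = 0.0
    for t in event_times:
        at_risk = times >= t - 1e-12
        n = at_risk.sum()
        n1 = (at_risk & ~group).sum()
        d = (observed & np.isclose(times, t)).sum()
        d1 = (observed & np.isclose(times, t) & ~group).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V <= 0:
        warnings.warn("zero log-rank variance")
        return LogRankResult(0.0, 1.0, groups)
    chi2 = (O1 - E1) ** 2 / V
    return LogRankResult(float(chi2), float(stats.chi2.sf(chi2, df=1)),
                         groups)


@dataclass
class ResponseCall:
    line_id: str
    S_at_24h: float
    threshold: float
    label: str                  # "responder" | "nonresponder"


def classify_response(events_or_curve, line_id: str | None = None,
                      threshold: float = 0.75, ratio: str = "1:1",
                      horizon_h: float = 24.0) -> ResponseCall:
    """Responder iff 24-h survivability of the given E:T population is
    strictly below the threshold (read at the last step time <= 24 h)."""
    if isinstance(events_or_curve, SurvivalCurve):
        curve = events_or_curve
        line = line_id or "unknown"
    else:
        table = events_or_curve
        sub = table[table["population"] == ratio]
        curve = km_estimate(sub, horizon_h)
        line = line_id or str(table["line_id"].iloc[0])
    s24 = curve.at(24.0)
    label = "responder" if s24 < threshold else "nonresponder"
    return ResponseCall(line, s24, threshold, label)


def survival_curves_table(table: pd.DataFrame, horizon_h: float = 24.0,
                          ) -> pd.DataFrame:
    """Long-format per-population curves for one (possibly pooled) table."""
    frames = []
    for (line, pop), sub in table.groupby(["line_id", "population"]):
        curve = km_estimate(sub, horizon_h)
        df = curve.to_frame()
        df.insert(0, "population", pop)
        df.insert(0, "line_id", line)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
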