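"""Visuo-motor integration analysis.

Quantifies, for each ROI, how activity relates to running speed (RS) and
optic-flow speed (OF) during uncoupled (replay) sessions: lagged Pearson
cross-correlations over +-1 s, a population median best lag (m_Lag), mean
coefficients R_RS / R_OF in a 250 ms window around m_Lag, the full-quadrant
interaction angle theta of the (R_RS, R_OF) vector (0 deg = positively
RS-coupled only, 90 deg = positively OF-coupled only, 180/270 their
negative counterparts), and a selectivity index
(|R_OF| - |R_RS|) / (|R_OF| + |R_RS|) in [-1, 1].  ROIs enter the angle
analysis only when |R| = sqrt(R_RS^2 + R_OF^2) >= 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import BehaviorSession, RoiRecording

R_MAG_THRESHOLD = 0.1
SKEWNESS_THRESHOLD = 1.0
MIN_RUN_SPEED = 3.0       # cm/s, median-RS session inclusion gate
WINDOW_S = 0.25           # averaging window around m_Lag


def responsive_by_skewness(recording: RoiRecording) -> bool:
    """Transient-rich traces are right-skewed; gate at skewness > 1."""
    trace = recording.dff
    if np.std(trace) == 0:
        return False
    return bool(stats.skew(trace) > SKEWNESS_THRESHOLD)


def lag_grid(frame_rate: float) -> np.ndarray:
    """Lag grid in frames: -floor(fr) .. +floor(fr)-1 (60 lags at 30 Hz)."""
    L = int(np.floor(frame_rate))
    return np.arange(-L, L)


def lagged_crosscorr(activity: np.ndarray, variable: np.ndarray,
                     frame_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Pearson coefficient at each lag of the +-1 s grid.

    Positive lag means the activity lags the behavioral variable (the
    coefficient pairs activity[t] with variable[t - lag]); only the
    overlapping segment contributes.  Returns (lags_frames, coefficients),
    with undefined (zero-variance) lags masked as NaN.
    """
    activity = np.asarray(activity, dtype=float)
    variable = np.asarray(variable, dtype=float)
    if len(activity) != len(variable):
        raise ValueError("traces must be aligned and equal length")
    lags = lag_grid(frame_rate)
    if len(activity) < 4 * (2 * len(lags) // 2):
        raise ValueError("trace too short for the lag span")
    coeffs = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag > 0:
            a, v = activity[lag:], variable[:-lag]
        elif lag < 0:
            a, v = activity[:lag], variable[-lag:]
        else:
            a, v = activity, variable
        if np.std(a) == 0 or np.std(v) == 0:
            coeffs[k] = np.nan
            continue
        coeffs[k] = np.corrcoef(a, v)[0, 1]
    return lags, coeffs


def best_lag(lags: np.ndarray, coeffs: np.ndarray) -> int:
    """Lag (frames) with the highest absolute coefficient."""
    finite = np.where(np.isfinite(coeffs), np.abs(coeffs), -np.inf)
    return int(lags[int(np.argmax(finite))])


def population_median_lag(best_lags: np.ndarray,
                          frame_rate: float) -> float:
    """m_Lag in seconds: median over ROIs of per-ROI best lags."""
    if len(best_lags) == 0:
        raise ValueError("need at least one responsive ROI")
    return float(np.median(np.asarray(best_lags, dtype=float)) / frame_rate)


def mean_corr_in_window(lags: np.ndarray, coeffs: np.ndarray,
                        m_lag: float, frame_rate: float,
                        window: float = WINDOW_S) -> float:
    """Mean coefficient over lags within +-window/2 of m_Lag (inclusive)."""
    lag_s = lags / frame_rate
    sel = np.abs(lag_s - m_lag) <= window / 2.0 + 1e-9
    if not sel.any():
        warnings.warn("window off the lag grid; truncated", RuntimeWarning)
        return np.nan
    vals = coeffs[sel]
    return float(np.nanmean(vals))


def interaction_angle(r_rs: float, r_of: float) -> float:
    """Full-quadrant angle (degrees, [0, 360)) of the (R_RS, R_OF) vector.

    R_RS spans the 0 deg axis and R_OF the 90 deg axis, so 0 deg means
    positively running-coupled only and 90 deg positively optic-flow-
    coupled only.
    """
    if r_rs == 0 and r_of == 0:
        raise ValueError("zero vector: interaction angle undefined")
    return float(np.degrees(np.arctan2(r_of, r_rs)) % 360.0)


def selectivity_index(r_rs: float, r_of: float) -> float:
    """(|R_OF| - |R_RS|) / (|R_OF| + |R_RS|), in [-1, 1]."""
    denom = abs(r_of) + abs(r_rs)
    if denom == 0:
        raise ValueError("zero denominator: selectivity index undefined")
    return float((abs(r_of) - abs(r_rs)) / denom)


@dataclass
class VisuomotorStats:
    roi: int
    r_rs: float
    r_of: float
    r_mag: float
    theta: float | None
    si: float | None
    included: bool
    best_lag_rs: int = 0
    best_lag_of: int = 0


def session_circular_median(stats_list: list[VisuomotorStats]) -> float:
    """theta_pop: angle of the (median R_RS, median R_OF) vector."""
    inc = [s for s in stats_list if s.included]
    if not inc:
        raise ValueError("no included ROI")
    med_rs = float(np.median([s.r_rs for s in inc]))
    med_of = float(np.median([s.r_of for s in inc]))
    return interaction_angle(med_rs, med_of)


def session_qc(behavior: BehaviorSession) -> bool:
    """Include the session iff median running speed >= 3 cm/s."""
    return bool(np.median(behavior.running_speed) >= MIN_RUN_SPEED)


def analyze_session(behavior: BehaviorSession,
                    recordings: list[RoiRecording],
                    responsiveness: str = "skewness",
                    threshold: float = R_MAG_THRESHOLD
                    ) -> tuple[list[VisuomotorStats], dict]:
    """Full per-session pipeline.

    1. Gate ROIs by dF/F skewness (or take all, for synthetic traces whose
       generative model is linear rather than transient-rich).
    2. Lagged cross-correlation of each responsive ROI with RS and OF.
    3. m_Lag per variable from the population of best lags.
    4. R_RS / R_OF per ROI as the window mean around the m_Lag.
    5. |R| gate, interaction angle and selectivity index.

    Returns per-ROI stats and a session summary dict (m_lag_rs, m_lag_of
    in seconds, theta_pop, median SI over included ROIs).
    """
    if responsiveness not in ("skewness", "all"):
        raise ValueError("responsiveness must be 'skewness' or 'all'")
    fr = behavior.frame_rate
    responsive = [rec for rec in recordings
                  if responsiveness == "all" or responsive_by_skewness(rec)]
    profiles = {}
    for rec in responsive:
        prof = {}
        for name, var in (("rs", behavior.running_speed),
                          ("of", behavior.optic_flow_speed)):
            lags, coeffs = lagged_crosscorr(rec.rate, var, fr)
            prof[name] = (lags, coeffs, best_lag(lags, coeffs))
        profiles[rec.roi_id] = prof
    if not profiles:
        return [], {"n_responsive": 0}

    m_lag = {name: population_median_lag(
        np.array([profiles[r][name][2] for r in profiles]), fr)
        for name in ("rs", "of")}

    out = []
    for rec in responsive:
        prof = profiles[rec.roi_id]
        r_rs = mean_corr_in_window(*prof["rs"][:2], m_lag["rs"], fr)
        r_of = mean_corr_in_window(*prof["of"][:2], m_lag["of"], fr)
        r_mag = float(np.hypot(r_rs, r_of))
        included = bool(r_mag >= threshold)
        theta = si = None
        if included and r_mag > 0:
            theta = interaction_angle(r_rs, r_of)
            si = selectivity_index(r_rs, r_of)
        out.append(VisuomotorStats(
            roi=rec.roi_id, r_rs=r_rs, r_of=r_of, r_mag=r_mag, theta=theta,
            si=si, included=included, best_lag_rs=prof["rs"][2],
            best_lag_of=prof["of"][2]))

    summary = {"n_responsive": len(responsive),
               "n_included": sum(s.included for s in out),
               "m_lag_rs": m_lag["rs"], "m_lag_of": m_lag["of"]}
    inc = [s for s in out if s.included]
    if inc:
        summary["theta_pop"] = session_circular_median(out)
        summary["si_median"] = float(np.median([s.si for s in inc]))
    return out, summary


def stats_to_frame(stats_list: list[VisuomotorStats]) -> pd.DataFrame:
    return pd.DataFrame([
        {"roi": s.roi, "r_rs": s.r_rs, "r_of": s.r_of, "r_mag": s.r_mag,
         "theta": s.theta, "si": s.si, "included": s.included}
        for s in stats_list])


def polar_histogram(stats_list: list[VisuomotorStats],
                    bin_deg: float = 15.0) -> pd.DataFrame:
    """Counts of included-ROI interaction angles per angular bin."""
    edges = np.arange(0.0, 360.0 + bin_deg, bin_deg)
    angles = [s.theta for s in stats_list if s.included and s.theta is not None]
    counts, _ = np.histogram(angles, bins=edges)
    return pd.DataFrame({"bin_start_deg": edges[:-1], "count": counts})


# ---------------------------------------------------------------------------
# Circular statistics

def _circ_dist(a: np.ndarray, b: float) -> np.ndarray:
    """Signed circular distance in (-pi, pi]."""
    return np.angle(np.exp(1j * (a - b)))


def circular_median(angles: np.ndarray) -> float:
    """Circular median (radians): minimizes mean absolute circular distance."""
    angles = np.asarray(angles, dtype=float)
    cands = np.concatenate([angles, angles + np.pi])
    diffs = np.angle(np.exp(1j * (angles[None, :] - cands[:, None])))
    costs = np.mean(np.abs(diffs), axis=1)
    best = cands[np.argmin(costs)]
    return float(np.mod(best, 2 * np.pi))


def circular_median_test(groups: list[np.ndarray], method: str = "chi2",
                         n_permutations: int = 2000,
                         seed: int = 0) -> float:
    """Nonparametric multi-sample test for a common circular median.

    Counts, per group, the observations falling on the negative side of the
    pooled circular median and refers the resulting statistic

        P = N^2/(M(N-M)) * sum_i m_i^2/n_i - N*M/(N-M)

    to chi-square with k-1 degrees of freedom (``method='chi2'``), or to a
    label-permutation null (``method='permutation'``).  Angles in radians.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 5 for g in groups):
        raise ValueError("each group needs at least 5 angles")
    pooled = np.concatenate(groups)
    if np.allclose(_circ_dist(pooled, pooled[0]), 0.0):
        return 1.0  # degenerate: all angles identical

    def statistic(gs):
        all_ = np.concatenate(gs)
        med = circular_median(all_)
        n = np.array([len(g) for g in gs], dtype=float)
        m = np.array([np.sum(_circ_dist(g, med) < 0) for g in gs], dtype=float)
        N, M = n.sum(), m.sum()
        if M == 0 or M == N:
            return 0.0
        return float(N * N / (M * (N - M)) * np.sum(m * m / n)
                     - N * M / (N - M))

    P = statistic(groups)
    k = len(groups)
    if method == "chi2":
        return float(stats.chi2.sf(P, k - 1))
    if method == "permutation":
        rng = np.random.default_rng(seed)
        sizes = np.cumsum([len(g) for g in groups])[:-1]
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if statistic(np.split(perm, sizes)) >= P - 1e-12:
                count += 1
        return float((count + 1) / (n_permutations + 1))
    raise ValueError("method must be 'chi2' or 'permutation'")
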