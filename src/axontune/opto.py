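"""Optogenetic suppression statistics.

For each ROI, the stimuli that reliably drive it (GP-predicted SNR > 2 and
amplitude at least two thirds of the best response, laser off) are pooled
and control vs. laser trials compared with a two-sided Wilcoxon rank-sum
test.  An ROI counts as suppressed when the test is significant AND the
laser-trial mean is below the control mean — a deliberately literal
implementation of the published convention, whose one-directional null
rate is therefore about alpha/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gp import (SNR_THRESHOLD, TuningFit,
                 find_preferred_stimulus, predict, transform_features)

DRIVE_FRACTION = 2.0 / 3.0


def select_driving_stimuli(fit: TuningFit,
                           conditions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Grid conditions that drive the ROI, evaluated at laser = 0.

    ``conditions`` defaults to the distinct laser-off training conditions of
    the fit.  A condition qualifies when its predicted SNR exceeds 2 and its
    predicted mean reaches 2/3 of the best response.  Raises if nothing
    qualifies (the ROI is then excluded upstream).
    """
    if conditions is None:
        mask = np.isclose(fit.features[:, 4], 0.0)
        F = fit.features[mask].copy()
        F[:, 4] = 0.0
        cond = pd.DataFrame({
            "sf": 2.0 ** F[:, 0], "tf": 2.0 ** F[:, 1],
            "direction": F[:, 2]})
    else:
        cond = conditions.reset_index(drop=True)
        F = transform_features(cond["sf"], cond["tf"], cond["direction"],
                               np.full(len(cond), np.expm1(fit.s_ref)),
                               np.zeros(len(cond)))
    mean, var = fit.predict_features(F)
    r_best = predict(fit, find_preferred_stimulus(fit, laser_value=0))[0]
    snr = np.where(var > 0, mean / np.sqrt(var), np.inf)
    keep = (snr > SNR_THRESHOLD) & (mean >= DRIVE_FRACTION * r_best)
    if not keep.any():
        raise ValueError("no condition drives this ROI; excluded")
    return cond[keep].reset_index(drop=True)


@dataclass
class SuppressionResult:
    roi: int
    included_stimuli: pd.DataFrame
    p_value: float
    suppressed: bool
    control_mean: float
    laser_mean: float
    pct_change: float


def test_suppression(control: np.ndarray, laser: np.ndarray,
                     alpha: float = 0.05, roi: int = 0,
                     included_stimuli: pd.DataFrame | None = None) -> SuppressionResult:
    """Rank-sum comparison of pooled control vs. laser trial responses."""
    control = np.asarray(control, dtype=float)
    laser = np.asarray(laser, dtype=float)
    if len(control) == 0 or len(laser) == 0:
        raise ValueError("both trial arms must be non-empty")
    p = float(stats.mannwhitneyu(control, laser, alternative="two-sided",
                                 method="auto").pvalue)
    c_mean, l_mean = float(control.mean()), float(laser.mean())
    suppressed = bool(p < alpha and l_mean < c_mean)
    pct = 100.0 * (c_mean - l_mean) / c_mean if c_mean != 0 else np.nan
    return SuppressionResult(
        roi=roi, included_stimuli=included_stimuli if included_stimuli is not None
        else pd.DataFrame(), p_value=p, suppressed=suppressed,
        control_mean=c_mean, laser_mean=l_mean, pct_change=pct)


def analyze_roi(fit: TuningFit, responses: pd.DataFrame, alpha: float = 0.05,
                roi: int = 0) -> SuppressionResult:
    """Select driving stimuli from the fit, pool trials and test."""
    included = select_driving_stimuli(fit)
    key = set(map(tuple, np.round(
        included[["sf", "tf", "direction"]].to_numpy(), 9)))
    trial_key = [tuple(v) for v in np.round(
        responses[["sf", "tf", "direction"]].to_numpy(), 9)]
    in_set = np.array([k in key for k in trial_key])
    control = responses.loc[in_set & (responses["laser"] == 0), "response"]
    laser = responses.loc[in_set & (responses["laser"] == 1), "response"]
    return test_suppression(control.to_numpy(), laser.to_numpy(), alpha=alpha,
                            roi=roi, included_stimuli=included)


@dataclass
class SessionSummary:
    n_rois: int
    pct_suppressed: float
    pct_change_median: float
    pct_change_iqr: float
    mean_amplitude_decrease: float


def session_summary(results: list[SuppressionResult]) -> SessionSummary:
    """Session-level suppression metrics across analyzed ROIs.

    The mean amplitude decrease averages each ROI's laser/control mean
    ratio first and the ROIs second (ROI-then-session averaging).
    """
    if not results:
        raise ValueError("need at least one analyzed ROI")
    pct = np.array([r.pct_change for r in results], dtype=float)
    sup = np.array([r.suppressed for r in results], dtype=bool)
    q75, q25 = np.nanpercentile(pct, [75, 25])
    ratios = np.array([r.laser_mean / r.control_mean for r in results
                       if r.control_mean != 0])
    return SessionSummary(
        n_rois=len(results),
        pct_suppressed=100.0 * float(sup.mean()),
        pct_change_median=float(np.nanmedian(pct)),
        pct_change_iqr=float(q75 - q25),
        mean_amplitude_decrease=100.0 * (1.0 - float(ratios.mean())),
    )


@dataclass
class CenteredCurves:
    offsets_octaves: np.ndarray
    control: np.ndarray
    laser: np.ndarray
    dimension: str


def centered_tuning_curves(fit: TuningFit, dimension: str,
                           span_octaves: float = 2.0,
                           n: int = 41) -> CenteredCurves:
    """Control/laser tuning curves re-indexed around the control peak.

    Requires significant responsiveness (SNR > 2 at the preferred stimulus)
    in both laser conditions; raises otherwise.  Curves are predicted at the
    control-preferred direction and complementary frequency, at offsets in
    octaves relative to the control-preferred SF or TF.
    """
    if dimension not in ("sf", "tf"):
        raise ValueError("dimension must be 'sf' or 'tf'")
    prefs = {}
    for L in (0, 1):
        p = find_preferred_stimulus(fit, laser_value=L)
        mean, var = predict(fit, p)
        snr = mean / np.sqrt(var) if var > 0 else np.inf
        if snr <= SNR_THRESHOLD:
            raise ValueError(f"ROI not significantly responsive at laser={L}")
        prefs[L] = p
    at = prefs[0]
    center = np.log2(at.sf if dimension == "sf" else at.tf)
    offsets = np.linspace(-span_octaves, span_octaves, n)
    curves = {}
    for L in (0, 1):
        F = transform_features(
            np.full(n, at.sf), np.full(n, at.tf), np.full(n, at.direction),
            np.full(n, at.run_speed), np.full(n, float(L)))
        F[:, 0 if dimension == "sf" else 1] = center + offsets
        mean, _ = fit.predict_features(F, include_noise=False)
        curves[L] = mean
    return CenteredCurves(offsets_octaves=offsets, control=curves[0],
                          laser=curves[1], dimension=dimension)


def results_to_frame(results: list[SuppressionResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"roi": r.roi, "p": r.p_value, "suppressed": r.suppressed,
         "control_mean": r.control_mean, "laser_mean": r.laser_mean,
         "pct_change": r.pct_change} for r in results])
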