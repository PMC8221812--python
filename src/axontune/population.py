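"""Population response matrices and group statistics.

Trial responses are Z-scored per ROI against that ROI's whole inferred-rate
trace, averaged per (SF, TF) grid cell at each ROI's preferred drift
direction, and pooled into a population response matrix whose similarity
across sources is a Pearson correlation over cells.  Group comparisons use
two-sided Wilcoxon rank-sum tests at the ROI level and on per-session
medians, with Bonferroni adjustment for an explicitly declared family size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gp import TuningFit
from .synthetic import RoiRecording


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p (exact for small untied samples)."""
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="auto").pvalue)


def zscore_responses(recording: RoiRecording,
                     trial_responses: pd.DataFrame) -> pd.DataFrame:
    """Z-score one ROI's trial responses against its inferred-rate trace."""
    mu = float(recording.rate.mean())
    sd = float(recording.rate.std())
    if sd == 0:
        warnings.warn(f"ROI {recording.roi_id} has zero trace SD; excluded",
                      RuntimeWarning)
        return trial_responses.iloc[0:0].assign(z=[])
    out = trial_responses.copy()
    out["z"] = (out["response"] - mu) / sd
    return out


@dataclass
class ResponseMatrix:
    """Mean Z-scored population responses on the SF x TF grid."""

    values: np.ndarray          # rows = SF levels, columns = TF levels
    sf_levels: np.ndarray
    tf_levels: np.ndarray
    n_rois: int
    source: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sf_levels,
                            columns=self.tf_levels)


def _roi_matrix(table: pd.DataFrame, pref_direction: float):
    """One ROI's repeat-averaged Z-response grid at its preferred direction."""
    sfs = np.sort(table["sf"].unique())
    tfs = np.sort(table["tf"].unique())
    dirs = np.sort(table["direction"].unique())
    d = dirs[np.argmin(np.abs((dirs - pref_direction + 180.0) % 360.0
                              - 180.0))]
    sub = table[np.isclose(table["direction"], d)]
    if "laser" in sub:
        sub = sub[sub["laser"] == 0]
    cell = sub.groupby(["sf", "tf"])["z"].mean()
    M = np.full((len(sfs), len(tfs)), np.nan)
    for (sf, tf), v in cell.items():
        M[np.searchsorted(sfs, sf), np.searchsorted(tfs, tf)] = v
    return M, sfs, tfs


def _stack_matrices(per_roi, sf_levels, tf_levels, source):
    if not per_roi:
        raise ValueError("no responsive ROIs; response matrix undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(np.stack(per_roi), axis=0)
    return ResponseMatrix(values=values, sf_levels=sf_levels,
                          tf_levels=tf_levels, n_rois=len(per_roi),
                          source=source)


def response_matrix(fits: Sequence[TuningFit],
                    z_responses: Sequence[pd.DataFrame],
                    source: str = "",
                    responsive_only: bool = True) -> ResponseMatrix:
    """Average per-ROI Z-response at each (SF, TF) cell, preferred direction.

    For each (responsive) ROI the repeats at the grid direction nearest its
    preferred direction are averaged first, so ROIs — not trials — carry
    equal weight in the population mean.
    """
    per_roi = []
    sf_levels = tf_levels = None
    for fit, table in zip(fits, z_responses):
        if responsive_only and not fit.responsive:
            continue
        if len(table) == 0:
            continue
        M, sfs, tfs = _roi_matrix(table, fit.best_stimulus.direction)
        if sf_levels is None:
            sf_levels, tf_levels = sfs, tfs
        per_roi.append(M)
    return _stack_matrices(per_roi, sf_levels, tf_levels, source)


def response_matrix_from_table(z_table: pd.DataFrame,
                               source: str = "") -> ResponseMatrix:
    """Population matrix from a tidy table of Z-scored responses.

    ``z_table`` needs columns roi, sf, tf, direction, z and
    preferred_direction (one value per ROI); an optional boolean
    ``responsive`` column gates ROIs.  This is the file-based entry point
    used by the command line.
    """
    per_roi = []
    sf_levels = tf_levels = None
    for _, table in z_table.groupby("roi"):
        if "responsive" in table and not bool(table["responsive"].iloc[0]):
            continue
        M, sfs, tfs = _roi_matrix(table,
                                  float(table["preferred_direction"].iloc[0]))
        if sf_levels is None:
            sf_levels, tf_levels = sfs, tfs
        per_roi.append(M)
    return _stack_matrices(per_roi, sf_levels, tf_levels, source)


def matrix_similarity(a: ResponseMatrix, b: ResponseMatrix) -> float:
    """Pearson correlation between two matrices over paired finite cells."""
    va, vb = a.values.ravel(), b.values.ravel()
    if va.shape != vb.shape:
        raise ValueError("matrices must share the SF x TF grid")
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < 3:
        raise ValueError("need at least 3 finite paired cells")
    if np.std(va[ok]) == 0 or np.std(vb[ok]) == 0:
        warnings.warn("constant matrix; similarity undefined", RuntimeWarning)
        return np.nan
    return float(stats.pearsonr(va[ok], vb[ok])[0])


@dataclass
class GroupComparison:
    p_roi: float
    p_session: float | None
    significant_roi: bool
    significant_session: bool | None
    alpha_adjusted: float
    n_a: int
    n_b: int
    notice: str = ""


def compare_distributions(group_a: Sequence[float], group_b: Sequence[float],
                          sessions_a: Sequence | None = None,
                          sessions_b: Sequence | None = None,
                          family_size: int = 1,
                          alpha: float = 0.05) -> GroupComparison:
    """Two-sided rank-sum comparison at ROI and session level.

    ``family_size`` is the declared Bonferroni family; significance flags
    compare raw p-values against alpha/family_size.  The session-level test
    runs on per-session medians and is skipped (with a notice) when either
    side has fewer than two sessions.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    p_roi = _ranksum_p(a, b)
    alpha_adj = alpha / family_size

    p_sess = sig_sess = None
    notice = ""
    if sessions_a is not None and sessions_b is not None:
        med_a = pd.Series(a).groupby(list(sessions_a)).median().to_numpy()
        med_b = pd.Series(b).groupby(list(sessions_b)).median().to_numpy()
        if len(med_a) >= 2 and len(med_b) >= 2:
            p_sess = _ranksum_p(med_a, med_b)
            sig_sess = bool(p_sess < alpha_adj)
        else:
            notice = "fewer than 2 sessions per group; session test skipped"
    return GroupComparison(p_roi=p_roi, p_session=p_sess,
                           significant_roi=bool(p_roi < alpha_adj),
                           significant_session=sig_sess,
                           alpha_adjusted=alpha_adj, n_a=len(a), n_b=len(b),
                           notice=notice)
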