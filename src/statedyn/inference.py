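"""Group-level statistics: paired condition contrasts with BH correction,
Pearson correlations of metric changes with behavior and receptor
availability (ROI level, and voxel level with a cluster-extent filter),
and covariate (IQ) adjustment via partial correlation.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .types import DynamicMetrics, SubjectRecord, VoxelMap

#: The five metric-state changes carried into the receptor correlations:
#: the features with significant condition differences in the contrasts.
DEFAULT_SELECTED_FEATURES: tuple[tuple[str, str], ...] = (
    ("dwell_time", "FPN+"),
    ("fractional_occupancy", "FPN+"),
    ("dwell_time", "VIS-"),
    ("fractional_occupancy", "VIS-"),
    ("fractional_occupancy", "SOM+"),
)

_METRIC_ATTRS = {
    "fractional_occupancy": "fractional_occupancy",
    "dwell_time": "dwell_time",
    "appearance_rate": "appearance_rate",
}


def bh_correct(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted p-values (min_{j>=i} m p_(j)/j,
    capped at 1) and rejection flags at ``alpha``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def paired_t(diff: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t on per-subject differences (one-sample t vs 0).

    Degenerate zero-variance differences: t=0/p=1 when all differences are
    zero; otherwise the p -> 0 limit is reported with a warning.
    """
    diff = np.asarray(diff, dtype=float)
    n = len(diff)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero differences; p reported as 0 limit")
        return float(np.inf * np.sign(diff.mean())), 0.0
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def paired_contrast(
    metrics_pl: list[DynamicMetrics],
    metrics_mp: list[DynamicMetrics],
    state_names: list[str],
    which: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    bh_family: str = "per_metric",
) -> pd.DataFrame:
    """Paired MP-vs-PL t tests across subjects for metric x state cells.

    Rows of the returned table: (metric, state, mean_diff, t_statistic,
    p_value, p_adjusted, significant_uncorrected, significant_bh). BH
    correction is applied within each metric family (all states of one
    metric) by default, or globally with ``bh_family='global'``.
    """
    pl_by_id = {m.subject_id: m for m in metrics_pl}
    mp_by_id = {m.subject_id: m for m in metrics_mp}
    unmatched = sorted(set(pl_by_id) ^ set(mp_by_id))
    if unmatched:
        raise ValueError(f"unmatched subjects across conditions: {unmatched}")
    ids = sorted(pl_by_id)
    if len(ids) < 3:
        raise ValueError("need at least 3 matched subjects")
    if which is None:
        which = [(metric, s) for metric in _METRIC_ATTRS for s in state_names]
    rows = []
    for metric, state in which:
        s = state_names.index(state)
        attr = _METRIC_ATTRS[metric]
        diff = np.array([
            getattr(mp_by_id[i], attr)[s] - getattr(pl_by_id[i], attr)[s] for i in ids
        ])
        t, p = paired_t(diff)
        rows.append((metric, state, float(diff.mean()), t, p))
    table = pd.DataFrame(rows, columns=["metric", "state", "mean_diff", "t_statistic", "p_value"])
    table["p_adjusted"] = np.nan
    table["significant_bh"] = False
    if bh_family == "per_metric":
        for metric, grp in table.groupby("metric"):
            p_adj, rej = bh_correct(grp["p_value"].to_numpy(), alpha)
            table.loc[grp.index, "p_adjusted"] = p_adj
            table.loc[grp.index, "significant_bh"] = rej
    elif bh_family == "global":
        p_adj, rej = bh_correct(table["p_value"].to_numpy(), alpha)
        table["p_adjusted"] = p_adj
        table["significant_bh"] = rej
    else:
        raise ValueError(f"unknown bh_family {bh_family!r}")
    table["significant_uncorrected"] = table["p_value"] < alpha
    return table


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must share length n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def adjust_for_covariate(x: np.ndarray, y: np.ndarray, covariate: np.ndarray) -> tuple[float, float]:
    """Partial correlation of x and y given one covariate: residualize
    both on [intercept | covariate] and correlate the residuals, with the
    two-sided p on df = n - 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = len(x)
    if not (len(y) == len(z) == n) or n < 4:
        raise ValueError("need matched vectors with n >= 4")
    if z.std() == 0:
        warnings.warn("constant covariate; falling back to plain correlation")
        return pearson_with_p(x, y)
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # a variable fully explained by the covariate leaves nothing to correlate
    if rx.std() < 1e-12 * max(1.0, x.std()) or ry.std() < 1e-12 * max(1.0, y.std()):
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return r, p


# ---------------------------------------------------------------------------
# metric changes and receptor correlations

def metric_delta_table(
    metrics_pl: list[DynamicMetrics],
    metrics_mp: list[DynamicMetrics],
    state_names: list[str],
    features: tuple[tuple[str, str], ...] = DEFAULT_SELECTED_FEATURES,
) -> pd.DataFrame:
    """Per-subject MP-PL changes for selected (metric, state) features,
    one column per feature named like ``dwell_time:FPN+``."""
    pl_by_id = {m.subject_id: m for m in metrics_pl}
    mp_by_id = {m.subject_id: m for m in metrics_mp}
    ids = sorted(set(pl_by_id) & set(mp_by_id))
    data = {"subject_id": ids}
    for metric, state in features:
        s = state_names.index(state)
        attr = _METRIC_ATTRS[metric]
        data[f"{metric}:{state}"] = [
            float(getattr(mp_by_id[i], attr)[s] - getattr(pl_by_id[i], attr)[s]) for i in ids
        ]
    return pd.DataFrame(data).set_index("subject_id")


def roi_correlation_table(
    subjects: list[SubjectRecord],
    deltas: pd.DataFrame,
    receptor: str = "d1r",
) -> pd.DataFrame:
    """Pearson r and p of each striatal ROI's receptor availability against
    each metric-change column. Subjects missing from ``deltas`` or with
    NaN changes are dropped pairwise; the used n is reported per row."""
    if receptor not in ("d1r", "d2r_pl", "d2r_mp"):
        raise ValueError(f"unknown receptor measure {receptor!r}")
    by_id = {s.subject_id: s for s in subjects}
    rows = []
    n_rois = len(getattr(subjects[0], receptor))
    for col in deltas.columns:
        series = deltas[col].dropna()
        ids = [i for i in series.index if i in by_id]
        y = series.loc[ids].to_numpy(dtype=float)
        for roi in range(n_rois):
            x = np.array([getattr(by_id[i], receptor)[roi] for i in ids])
            r, p = pearson_with_p(x, y)
            rows.append((roi, col, r, p, len(ids)))
    return pd.DataFrame(rows, columns=["roi", "metric", "r", "p", "n"])


# ---------------------------------------------------------------------------
# voxel-level correlation with cluster-extent threshold

def voxelwise_correlation_clusters(
    maps: list[VoxelMap],
    target: np.ndarray,
    p_thresh: float = 0.05,
    min_cluster: int = 30,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, np.ndarray]:
    """Per-voxel Pearson correlation against a subject-level scalar,
    thresholded at uncorrected ``p < p_thresh`` and filtered to connected
    components (26-connectivity) of at least ``min_cluster`` voxels.

    Positive- and negative-correlation voxels are clustered separately.
    Returns (labeled cluster map with integer labels, cluster table with
    size/sign/peak r, r map, p map). Outside-mask voxels are NaN in the r
    and p maps and 0 in the label map.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 subjects")
    target = np.asarray(target, dtype=float)
    if len(target) != len(maps):
        raise ValueError("target length must equal the number of maps")
    shape, mask = maps[0].values.shape, maps[0].mask
    for m in maps[1:]:
        if m.values.shape != shape or not np.array_equal(m.mask, mask):
            raise ValueError("all maps must share grid shape and mask")
    V = np.stack([m.values[mask] for m in maps])  # n_subjects x n_voxels
    n = V.shape[0]
    Vc = V - V.mean(axis=0)
    tc = target - target.mean()
    denom = np.linalg.norm(Vc, axis=0) * np.linalg.norm(tc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Vc.T @ tc) / denom
    r = np.where(denom > 0, r, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)

    r_map = np.full(shape, np.nan)
    p_map = np.full(shape, np.nan)
    r_map[mask] = r
    p_map[mask] = p

    structure = np.ones((3, 3, 3), dtype=int)  # 26-connectivity
    label_map = np.zeros(shape, dtype=int)
    rows = []
    next_label = 1
    for sign, sign_name in ((1, "positive"), (-1, "negative")):
        binary = np.zeros(shape, dtype=bool)
        binary[mask] = (p < p_thresh) & (np.sign(r) == sign)
        comp, n_comp = ndimage.label(binary, structure=structure)
        for c in range(1, n_comp + 1):
            voxels = comp == c
            size = int(voxels.sum())
            if size < min_cluster:
                continue
            peak = float(r_map[voxels][np.argmax(np.abs(r_map[voxels]))])
            label_map[voxels] = next_label
            rows.append((next_label, sign_name, size, peak))
            next_label += 1
    table = pd.DataFrame(rows, columns=["label", "sign", "size", "peak_r"])
    return label_map, table, r_map, p_map
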