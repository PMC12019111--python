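"""Per-scan dynamic metrics from frame-level state labels.

Four summaries per scan and state: fractional occupancy (share of kept
frames), dwell time (mean maximal-run length in seconds), appearance rate
(runs per minute of kept time) and the row-stochastic transition matrix
(self-transitions on the diagonal). Censoring gaps break temporal
adjacency: a run never bridges a gap, and frame pairs spanning a gap
contribute no transition count.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ClusteringResult, DynamicMetrics, StateSequence


def split_labels_by_scan(result: ClusteringResult) -> list[StateSequence]:
    """Split concatenated labels back into per-scan state sequences.

    ``gap_after[i]`` is set wherever kept frames i and i+1 of a scan were
    not adjacent in the original acquisition (a censored frame between
    them).
    """
    idx = result.scan_index
    if len(idx) != len(result.labels):
        raise ValueError("scan_index does not cover all labels")
    seqs = []
    # TR is not carried by ClusteringResult; sequences get tr=nan here and
    # callers attach it, or use split_labels_by_scan_with_tr.
    for scan_id, grp in idx.groupby("scan", sort=True):
        frames = grp["frame"].to_numpy()
        if not np.all(np.diff(frames) > 0):
            raise ValueError(f"scan {scan_id} frames are not strictly increasing")
        gap_after = np.zeros(len(frames), dtype=bool)
        gap_after[:-1] = np.diff(frames) > 1
        seqs.append(StateSequence(
            states=result.labels[grp.index.to_numpy()],
            gap_after=gap_after,
            tr_seconds=float("nan"),
            subject_id=str(grp["subject_id"].iloc[0]),
            condition=str(grp["condition"].iloc[0]),
        ))
    return seqs


def split_labels_by_scan_with_tr(result: ClusteringResult, tr_seconds: float) -> list[StateSequence]:
    seqs = split_labels_by_scan(result)
    for s in seqs:
        s.tr_seconds = tr_seconds
    return seqs


def _run_segments(seq: StateSequence) -> list[tuple[int, int]]:
    """Maximal runs as (state, length); runs are broken by censoring gaps."""
    runs = []
    states, gaps = seq.states, seq.gap_after
    start = 0
    for t in range(len(states)):
        last = t == len(states) - 1
        if last or states[t + 1] != states[t] or gaps[t]:
            runs.append((int(states[start]), t - start + 1))
            start = t + 1
    return runs


def fractional_occupancy(seq: StateSequence, k: int) -> np.ndarray:
    """count(state == s) / kept frames, per state."""
    counts = np.bincount(seq.states, minlength=k).astype(float)
    return counts / len(seq.states)


def dwell_time(seq: StateSequence, k: int) -> np.ndarray:
    """Mean maximal-run length per state, in seconds; 0 for absent states."""
    runs = _run_segments(seq)
    out = np.zeros(k)
    for s in range(k):
        lens = [ln for st, ln in runs if st == s]
        if lens:
            out[s] = float(np.mean(lens)) * seq.tr_seconds
    return out


def appearance_rate(seq: StateSequence, k: int) -> np.ndarray:
    """Number of maximal runs per state, per minute of kept scan time."""
    minutes = len(seq.states) * seq.tr_seconds / 60.0
    if minutes <= 0:
        raise ValueError("observation span must be positive")
    runs = _run_segments(seq)
    out = np.zeros(k)
    for st, _ in runs:
        out[st] += 1.0
    return out / minutes


def transition_matrix(seq: StateSequence, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized counts of adjacent (t, t+1) state pairs, excluding
    pairs spanning a censoring gap. Returns (matrix, row_defined); rows
    with no observed departure are all-zero and flagged undefined."""
    if len(seq.states) < 2:
        raise ValueError("need at least 2 kept frames")
    counts = np.zeros((k, k))
    s, g = seq.states, seq.gap_after
    valid = ~g[:-1]
    np.add.at(counts, (s[:-1][valid], s[1:][valid]), 1.0)
    row = counts.sum(axis=1)
    defined = row > 0
    tm = np.zeros((k, k))
    tm[defined] = counts[defined] / row[defined, None]
    return tm, defined


def offdiagonal_transition_matrix(tm: np.ndarray) -> np.ndarray:
    """Persistence-free view: zero the diagonal and renormalize rows with
    off-diagonal mass (rows without any stay all-zero)."""
    out = tm.copy()
    np.fill_diagonal(out, 0.0)
    row = out.sum(axis=1)
    nz = row > 0
    out[nz] /= row[nz, None]
    return out


def compute_metrics(seq: StateSequence, k: int) -> DynamicMetrics:
    """All four dynamic metrics for one scan."""
    tm, defined = transition_matrix(seq, k)
    return DynamicMetrics(
        fractional_occupancy=fractional_occupancy(seq, k),
        dwell_time=dwell_time(seq, k),
        appearance_rate=appearance_rate(seq, k),
        transition_matrix=tm,
        row_defined=defined,
        n_frames_kept=len(seq.states),
        subject_id=seq.subject_id,
        condition=seq.condition,
    )


def metrics_table(metrics: list[DynamicMetrics], state_names: list[str] | None = None) -> pd.DataFrame:
    """Tidy long table (subject, condition, state, metric, value)."""
    rows = []
    for m in metrics:
        k = len(m.fractional_occupancy)
        names = state_names if state_names is not None else [str(s) for s in range(k)]
        for s in range(k):
            for metric, vec in (("fractional_occupancy", m.fractional_occupancy),
                                ("dwell_time", m.dwell_time),
                                ("appearance_rate", m.appearance_rate)):
                rows.append((m.subject_id, m.condition, names[s], metric, float(vec[s])))
    return pd.DataFrame(rows, columns=["subject_id", "condition", "state", "metric", "value"])
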