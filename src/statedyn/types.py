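"""Core data containers shared across the pipeline stages.

All containers are plain dataclasses holding numpy arrays / pandas frames;
they carry no behaviour beyond validation, so every stage can be tested in
isolation and serialized to flat text formats.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

#: The eight resting-state networks used throughout: seven cortical plus one
#: subcortical (SUB).
NETWORKS: tuple[str, ...] = ("FPN", "LIM", "VAT", "DAT", "SOM", "VIS", "DMN", "SUB")

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
TISSUE_COLUMNS = ("white_matter", "csf", "global_signal")
CONFOUND_COLUMNS = MOTION_COLUMNS + TISSUE_COLUMNS


@dataclass
class RoiTimeSeries:
    """One scan: a frames x ROIs BOLD matrix plus acquisition metadata.

    Attributes
    ----------
    data : (T, N) float array
        BOLD amplitude per frame and ROI (arbitrary units).
    tr_seconds : float
        Repetition time in seconds.
    subject_id, condition : str
        Scan identity; condition is "PL" or "MP".
    confounds : (T, 9) DataFrame or None
        Six rigid-body motion parameters (translations in mm, rotations in
        rad) followed by three tissue regressors (WM, CSF, global signal).
    censor_mask : (T,) bool array
        True = frame kept. Defaults to all kept.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    condition: str = ""
    confounds: Optional[pd.DataFrame] = None
    censor_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("data must be a T x N matrix with T >= 2")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.n_frames, dtype=bool)
        else:
            self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
            if self.censor_mask.shape != (self.n_frames,):
                raise ValueError("censor_mask length must equal the number of frames")
        if self.confounds is not None and len(self.confounds) != self.n_frames:
            raise ValueError("confounds must have one row per frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_kept(self) -> int:
        return int(self.censor_mask.sum())

    def copy_with(self, data: np.ndarray, censor_mask: Optional[np.ndarray] = None) -> "RoiTimeSeries":
        return RoiTimeSeries(
            data=np.array(data, dtype=float),
            tr_seconds=self.tr_seconds,
            subject_id=self.subject_id,
            condition=self.condition,
            confounds=None if self.confounds is None else self.confounds.copy(),
            censor_mask=self.censor_mask.copy() if censor_mask is None else np.asarray(censor_mask, dtype=bool),
        )


@dataclass
class ScrubbingReport:
    """Per-frame motion/intensity summaries and the censoring outcome."""

    fd: np.ndarray
    dvars: np.ndarray
    n_censored: int
    fd_thresh: float
    dvars_thresh: float


@dataclass
class NetworkTemplates:
    """Assignment of each ROI to one of the eight resting-state networks."""

    roi_network: np.ndarray  # (N,) array of network labels

    def __post_init__(self) -> None:
        self.roi_network = np.asarray(self.roi_network, dtype=object)
        unknown = set(self.roi_network) - set(NETWORKS)
        if unknown:
            raise ValueError(f"unknown network labels: {sorted(unknown)}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_network)

    def indicator(self, network: str) -> np.ndarray:
        """Binary membership vector for one network."""
        if network not in NETWORKS:
            raise ValueError(f"unknown network {network!r}")
        return (self.roi_network == network).astype(float)

    def sizes(self) -> dict[str, int]:
        return {net: int((self.roi_network == net).sum()) for net in NETWORKS}


@dataclass
class ClusteringResult:
    """Output of correlation-distance k-means over concatenated frames."""

    k: int
    centroids: np.ndarray            # (k, N), zero-mean rows
    labels: np.ndarray               # (F,) ints in 0..k-1
    scan_index: pd.DataFrame         # columns: scan, subject_id, condition, frame
    inertia: float                   # total within-cluster correlation distance
    explained_variance: float

    @property
    def n_frames(self) -> int:
        return len(self.labels)


@dataclass
class StateCatalog:
    """Names for the k states plus the full cosine-similarity table."""

    names: list[str]
    similarity_table: np.ndarray  # (k, 8, 2): cosine of (positive, negative) part

    def index_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class ElbowResult:
    """Elbow selection outcome; ``fell_back`` flags the k_max fallback."""

    k: int
    fell_back: bool = False


@dataclass
class StateSequence:
    """Kept-frame state labels for one scan.

    ``gap_after[i]`` marks position i as followed by a censoring gap, i.e.
    kept frames i and i+1 were not adjacent in the original acquisition.
    """

    states: np.ndarray        # (T_kept,) ints in 0..k-1
    gap_after: np.ndarray     # (T_kept,) bool
    tr_seconds: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        self.gap_after = np.asarray(self.gap_after, dtype=bool)
        if self.states.size == 0:
            raise ValueError("state sequence is empty")
        if self.gap_after.shape != self.states.shape:
            raise ValueError("gap_after must match states length")


@dataclass
class DynamicMetrics:
    """Per-scan dynamic summaries of a state sequence."""

    fractional_occupancy: np.ndarray  # (k,) sums to 1
    dwell_time: np.ndarray            # (k,) seconds; 0 where state absent
    appearance_rate: np.ndarray       # (k,) runs per minute of kept time
    transition_matrix: np.ndarray     # (k, k) row-stochastic where defined
    row_defined: np.ndarray           # (k,) bool: row had >=1 observed departure
    n_frames_kept: int
    subject_id: str = ""
    condition: str = ""


@dataclass
class SubjectRecord:
    """Per-subject receptor, behavioral and covariate measures."""

    subject_id: str
    d1r: np.ndarray       # per striatal ROI, binding units
    d2r_pl: np.ndarray
    d2r_mp: np.ndarray
    rt_2ball_pl: float
    rt_2ball_mp: float
    rt_3ball_pl: float
    rt_3ball_mp: float
    acc_2ball_pl: float
    acc_2ball_mp: float
    acc_3ball_pl: float
    acc_3ball_mp: float
    iq: float

    def __post_init__(self) -> None:
        for name in ("acc_2ball_pl", "acc_2ball_mp", "acc_3ball_pl", "acc_3ball_mp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("rt_2ball_pl", "rt_2ball_mp", "rt_3ball_pl", "rt_3ball_mp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class VoxelMap:
    """A small 3D scalar map with an in-region mask (e.g. striatal voxels)."""

    values: np.ndarray  # 3D grid
    mask: np.ndarray    # 3D bool, same shape
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 3:
            raise ValueError("values and mask must be 3D grids of equal shape")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("non-finite values inside mask")


@dataclass
class MediationResult:
    """Simple mediation fit (x -> m -> y) with bootstrap inference."""

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    p_indirect: float
    n_boot: int
    seed: int
    n_degenerate_redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "c_prime": self.c_prime,
            "indirect": self.indirect, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_indirect": self.p_indirect, "n_boot": self.n_boot, "seed": self.seed,
            "n_degenerate_redraws": self.n_degenerate_redraws,
        }
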