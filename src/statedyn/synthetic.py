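"""Synthetic cohort generator with planted brain-state structure.

Emulates a placebo-controlled crossover resting-state fMRI study: each of
``n_subjects`` subjects contributes one scan per condition (PL = placebo,
MP = methylphenidate). Latent brain states follow a first-order Markov
chain over co-activation patterns; under MP the persistence of the FPN+
and VIS- states is boosted by an amount that scales with a subject-level
sensitivity driven by striatal D1 receptor availability, and entry into
SOM+ is proportionally reduced. Behavioral response time is linked to the
realized FPN+ dwell-time change through a planted mediation path, so the
full downstream pipeline (postprocessing, clustering, dynamic metrics,
contrasts, correlations, mediation) can be validated against known truth.

Randomness: every operation draws from a child of a single root
``numpy.random.SeedSequence``; spawned streams are keyed by a fixed
(subject, condition, purpose) ordering, so one integer seed reproduces
the entire cohort bit-for-bit.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .types import (
    CONFOUND_COLUMNS,
    NETWORKS,
    DynamicMetrics,
    NetworkTemplates,
    RoiTimeSeries,
    SubjectRecord,
)

#: Networks used for centroid +/- pairs, in order of preference.
CENTROID_NETWORK_ORDER: tuple[str, ...] = ("FPN", "SOM", "VIS", "DMN", "DAT", "VAT", "LIM", "SUB")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with defaults mirroring the
    emulated acquisition (TR 0.891 s, 520 frames, 200 cortical + 32
    subcortical ROIs, 37 subjects, six latent states).

    ``mediation_a`` gates the D1R -> state-sensitivity path (path a);
    ``mediation_b`` is the magnitude of the dwell-time -> response-time
    path (path b, applied with a negative sign: larger FPN+ dwell-time
    gain shortens response time). ``sensitivity_slope`` is a unitless
    overall scaling of the D1R link.
    """

    n_subjects: int = 37
    n_rois: int = 232
    n_frames: int = 520
    tr_seconds: float = 0.891
    k_true: int = 6
    base_persistence: float = 0.95
    mp_persistence_boost: float = 0.02
    sensitivity_slope: float = 1.0
    mediation_a: float = 0.5
    mediation_b: float = 0.05
    noise_sd: float = 0.5
    drift_amp: float = 1.0
    drift_period_s: float = 300.0
    ar_coeff: float = 0.3
    spike_rate: float = 0.02
    seed: int = 7
    # secondary knobs (held fixed across the study)
    amplitude: float = 1.0
    spike_amplitude: float = 3.0
    sensitivity_noise_sd: float = 0.3
    rt_noise_sd: float = 0.3
    d1r_mean: float = 2.0
    d1r_between_sd: float = 0.25
    d1r_within_sd: float = 0.10
    acc_probe_p: dict = field(default_factory=lambda: {
        ("2ball", "PL"): 0.903, ("2ball", "MP"): 0.970,
        ("3ball", "PL"): 0.890, ("3ball", "MP"): 0.948,
    })
    n_probes: int = 15  # 3 cycles x 5 response intervals per task scan

    def __post_init__(self) -> None:
        if not 0.0 < self.base_persistence < 1.0:
            raise ValueError("base_persistence must lie in (0, 1)")
        if not 0.0 <= self.spike_rate < 1.0:
            raise ValueError("spike_rate must lie in [0, 1)")
        if not 0.0 <= self.mp_persistence_boost < 1.0:
            raise ValueError("mp_persistence_boost must be in [0, 1)")
        if self.base_persistence + self.mp_persistence_boost >= 1.0:
            raise ValueError("base_persistence + mp_persistence_boost must be < 1")
        if self.n_frames * self.tr_seconds <= 60.0:
            raise ValueError("scan must span more than 60 s (appearance rate is per minute)")
        if self.drift_period_s <= 100.0:
            raise ValueError("drift_period_s must exceed 100 s (below the analysis band)")
        if self.k_true % 2 != 0:
            raise ValueError("k_true must be even (states come in +/- pairs)")
        if self.k_true > 2 * len(NETWORKS):
            raise ValueError("k_true exceeds 2 x number of networks")
        if self.n_subjects < 1 or self.n_rois < 16 or self.n_frames < 3:
            raise ValueError("n_subjects >= 1, n_rois >= 16, n_frames >= 3 required")


@dataclass
class CohortTruth:
    """Ground truth planted by the generator, keyed by (subject, condition)."""

    state_names: list[str]
    sequences: dict          # (subject_id, condition) -> (n_frames,) int array
    kernels: dict            # (subject_id, condition) -> (k, k) transition kernel
    sensitivity: dict        # subject_id -> float
    metrics: dict            # (subject_id, condition) -> DynamicMetrics
    delta_dwell_fpn_plus: dict  # subject_id -> MP-PL dwell-time difference (s)


@dataclass
class SyntheticCohort:
    scans: list               # RoiTimeSeries, 2 per subject; [] if BOLD skipped
    templates: NetworkTemplates
    centroids: np.ndarray     # (k_true, n_rois) planted patterns
    truth: CohortTruth
    subjects: list            # SubjectRecord
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# templates and centroids

def generate_network_templates(n_rois: int = 232, seed: int = 0) -> NetworkTemplates:
    """Assign ``n_rois`` ROIs to the eight resting-state networks.

    The subcortical network (SUB) receives ``round(n_rois * 32/232)`` ROIs
    (exactly 32 at the default 232, mirroring a 200-cortical + 32-subcortical
    parcellation); the seven cortical networks split the remainder as evenly
    as possible. ROI order is shuffled deterministically by ``seed`` so
    network membership is not a function of ROI index.
    """
    if n_rois < 16:
        raise ValueError("n_rois must be >= 16 to give all 8 networks >= 2 ROIs")
    n_sub = max(2, round(n_rois * 32 / 232))
    n_cort = n_rois - n_sub
    base, extra = divmod(n_cort, 7)
    sizes = [base + (1 if i < extra else 0) for i in range(7)] + [n_sub]
    if min(sizes) < 2:
        raise ValueError("n_rois too small for 8 networks of >= 2 ROIs")
    labels = np.repeat(np.array(NETWORKS, dtype=object), sizes)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return NetworkTemplates(roi_network=labels)


def generate_centroids(templates: NetworkTemplates, k_true: int = 6) -> np.ndarray:
    """Planted co-activation patterns as +/- pairs over selected networks.

    For each of the first ``k_true // 2`` networks in
    :data:`CENTROID_NETWORK_ORDER` (FPN, SOM, VIS at the default k=6), one
    centroid elevates that network's ROIs and its negation suppresses them.
    Each centroid is exactly zero-mean across ROIs, consistent with demeaned
    BOLD amplitudes. Ordering is [NET1+, NET1-, NET2+, NET2-, ...].
    """
    if k_true % 2 != 0:
        raise ValueError("k_true must be even")
    if k_true > 2 * len(NETWORKS):
        raise ValueError("k_true exceeds 2 x number of networks")
    n = templates.n_rois
    centroids = np.empty((k_true, n))
    for i, net in enumerate(CENTROID_NETWORK_ORDER[: k_true // 2]):
        ind = templates.indicator(net)
        pattern = ind - ind.mean()
        centroids[2 * i] = pattern
        centroids[2 * i + 1] = -pattern
    return centroids


def centroid_state_names(k_true: int = 6) -> list[str]:
    """Names of the planted states, in centroid order (e.g. FPN+, FPN-, ...)."""
    names = []
    for net in CENTROID_NETWORK_ORDER[: k_true // 2]:
        names.extend([f"{net}+", f"{net}-"])
    return names


# ---------------------------------------------------------------------------
# latent Markov dynamics

def build_transition_kernel(
    subject_sensitivity: float, condition: str, config: GeneratorConfig
) -> np.ndarray:
    """Row-stochastic transition kernel for one subject and condition.

    Under PL the kernel is symmetric: ``base_persistence`` on the diagonal,
    the remainder spread uniformly. Under MP the self-transition of FPN+
    and VIS- is raised by ``sensitivity x mp_persistence_boost`` (other
    entries in those rows rescaled), and every row's entry probability into
    SOM+ is reduced by the same relative amount, the removed mass being
    redistributed proportionally over the row's other off-diagonal targets.
    """
    if condition not in ("PL", "MP"):
        raise ValueError(f"condition must be 'PL' or 'MP', got {condition!r}")
    k = config.k_true
    p0 = config.base_persistence
    kernel = np.full((k, k), (1.0 - p0) / (k - 1))
    np.fill_diagonal(kernel, p0)
    if condition == "PL" or config.mp_persistence_boost == 0.0:
        return kernel

    names = centroid_state_names(k)
    boosted = [i for i, nm in enumerate(names) if nm in ("FPN+", "VIS-")]
    reduced = [i for i, nm in enumerate(names) if nm == "SOM+"]
    boost = subject_sensitivity * config.mp_persistence_boost
    for i in boosted:
        new_diag = p0 + boost
        if new_diag >= 1.0:
            raise ValueError(
                f"self-transition {new_diag:.4f} >= 1; subject sensitivity too large"
            )
        if new_diag < 0.0:
            raise ValueError("negative self-transition; sensitivity too negative")
        off = kernel[i].copy()
        off[i] = 0.0
        kernel[i] = off * (1.0 - new_diag) / off.sum()
        kernel[i, i] = new_diag
    rel = boost / (1.0 - p0)
    factor = min(max(1.0 - rel, 0.0), 2.0)
    for j in reduced:
        for i in range(k):
            if i == j:
                continue
            removed = kernel[i, j] * (1.0 - factor)
            kernel[i, j] *= factor
            others = [c for c in range(k) if c != i and c != j]
            kernel[i, others] += removed * kernel[i, others] / kernel[i, others].sum()
    np.testing.assert_allclose(kernel.sum(axis=1), 1.0, atol=1e-12)
    return kernel


def simulate_state_sequence(
    subject_sensitivity: float,
    condition: str,
    config: GeneratorConfig,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one scan's latent state sequence (values in 0..k_true-1)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kernel = build_transition_kernel(subject_sensitivity, condition, config)
    cum = np.cumsum(kernel, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    T = config.n_frames
    u = rng.random(T)
    seq = np.empty(T, dtype=int)
    seq[0] = int(rng.integers(config.k_true))
    for t in range(1, T):
        seq[t] = int(np.searchsorted(cum[seq[t - 1]], u[t], side="right"))
    return seq


# ---------------------------------------------------------------------------
# BOLD signal synthesis

def simulate_roi_timeseries(
    sequence: np.ndarray,
    centroids: np.ndarray,
    config: GeneratorConfig,
    seed: int | np.random.Generator = 0,
    subject_id: str = "",
    condition: str = "",
) -> RoiTimeSeries:
    """Render a state sequence into a frames x ROIs BOLD matrix.

    Frame t = amplitude * centroid[state_t] + AR(1) noise + a slow
    sinusoidal drift (period > 100 s, below the analysis band) + sparse
    large-amplitude motion-spike artifacts. Six motion regressors (slow
    random walk plus a displacement at each spike frame large enough that
    framewise displacement exceeds 0.5 mm there) and three tissue
    regressors (drift-locked WM/CSF traces and the global signal) are
    emitted alongside.
    """
    sequence = np.asarray(sequence, dtype=int)
    if sequence.min() < 0 or sequence.max() >= centroids.shape[0]:
        raise ValueError("sequence values must index valid centroids")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T, n = len(sequence), centroids.shape[1]

    data = config.amplitude * centroids[sequence]

    if config.noise_sd > 0:
        innov = rng.normal(0.0, config.noise_sd, size=(T, n))
        data = data + lfilter([1.0], [1.0, -config.ar_coeff], innov, axis=0)
    else:
        rng.normal(0.0, 1.0, size=(T, n))  # keep stream alignment

    t_sec = np.arange(T) * config.tr_seconds
    phase = rng.uniform(0.0, 2.0 * np.pi)
    loadings = rng.uniform(0.5, 1.5, size=n)
    drift_wave = np.sin(2.0 * np.pi * t_sec / config.drift_period_s + phase)
    if config.drift_amp > 0:
        data = data + config.drift_amp * np.outer(drift_wave, loadings)

    spike_frames = rng.random(T) < config.spike_rate
    spike_frames[0] = False  # frame 0 has no predecessor; FD there is 0 by convention
    n_spikes = int(spike_frames.sum())
    if n_spikes:
        data[spike_frames] += rng.normal(0.0, config.spike_amplitude, size=(n_spikes, n))

    # motion: slow random walk (translations mm, rotations rad) + spike jumps
    motion = np.cumsum(rng.normal(0.0, 0.004, size=(T, 6)), axis=0)
    motion[:, 3:] *= 0.02  # rotations ~1e-4 rad steps
    motion[spike_frames, 0] += 0.8  # transient 0.8 mm displacement
    wm = 0.5 * config.drift_amp * drift_wave + rng.normal(0.0, 0.1, size=T)
    csf = 0.3 * config.drift_amp * drift_wave + rng.normal(0.0, 0.1, size=T)
    gs = data.mean(axis=1)
    confounds = pd.DataFrame(
        np.column_stack([motion, wm, csf, gs]), columns=list(CONFOUND_COLUMNS)
    )
    return RoiTimeSeries(
        data=data,
        tr_seconds=config.tr_seconds,
        subject_id=subject_id,
        condition=condition,
        confounds=confounds,
    )


# ---------------------------------------------------------------------------
# ground-truth metrics (independent simple counting, used for the truth
# tables so the analysis-side implementations can be validated against it)

def _runs(seq: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    start = 0
    for t in range(1, len(seq)):
        if seq[t] != seq[t - 1]:
            runs.append((int(seq[start]), t - start))
            start = t
    runs.append((int(seq[start]), len(seq) - start))
    return runs


def truth_metrics(seq: np.ndarray, k: int, tr_seconds: float,
                  subject_id: str = "", condition: str = "") -> DynamicMetrics:
    """Dynamic metrics of a ground-truth sequence by direct run counting."""
    seq = np.asarray(seq, dtype=int)
    T = len(seq)
    fo = np.array([(seq == s).sum() / T for s in range(k)])
    runs = _runs(seq)
    dwell = np.zeros(k)
    rate = np.zeros(k)
    minutes = T * tr_seconds / 60.0
    for s in range(k):
        lens = [ln for st, ln in runs if st == s]
        if lens:
            dwell[s] = float(np.mean(lens)) * tr_seconds
            rate[s] = len(lens) / minutes
    counts = np.zeros((k, k))
    for t in range(T - 1):
        counts[seq[t], seq[t + 1]] += 1
    row = counts.sum(axis=1)
    defined = row > 0
    tm = np.zeros((k, k))
    tm[defined] = counts[defined] / row[defined, None]
    return DynamicMetrics(
        fractional_occupancy=fo, dwell_time=dwell, appearance_rate=rate,
        transition_matrix=tm, row_defined=defined, n_frames_kept=T,
        subject_id=subject_id, condition=condition,
    )


# ---------------------------------------------------------------------------
# full cohort

def generate_cohort(config: GeneratorConfig, include_bold: bool = True) -> SyntheticCohort:
    """Generate the full synthetic study.

    Per subject i: striatal D1R is a subject-level mean plus per-ROI noise;
    state sensitivity = 1 + mediation_a * sensitivity_slope * z(mean D1R_i)
    + noise (unit mean, so the average subject receives exactly
    ``mp_persistence_boost``); response-time change in the 2-ball task =
    -mediation_b * (true MP-PL FPN+ dwell-time difference) + noise. The
    3-ball response-time change carries no planted path, and IQ is
    independent of everything. Accuracy is 15 Bernoulli probes per task
    scan (3 cycles x 5 response intervals).

    ``include_bold=False`` skips BOLD/confound synthesis (scans list empty)
    for studies of the latent dynamics and downstream statistics only.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    ss_templates, ss_subjects, ss_scans, ss_behavior = root.spawn(4)

    templates = generate_network_templates(cfg.n_rois, seed=ss_templates.generate_state(1)[0] % (2**31))
    centroids = generate_centroids(templates, cfg.k_true)
    names = centroid_state_names(cfg.k_true)
    fpn_plus = names.index("FPN+")

    rng_sub = np.random.default_rng(ss_subjects)
    n_striatal = templates.sizes()["SUB"]
    subj_ids = [f"sub-{i + 1:02d}" for i in range(cfg.n_subjects)]
    d1r_means = rng_sub.normal(cfg.d1r_mean, cfg.d1r_between_sd, size=cfg.n_subjects)
    d1r = d1r_means[:, None] + rng_sub.normal(0.0, cfg.d1r_within_sd, size=(cfg.n_subjects, n_striatal))
    d2r_pl = rng_sub.normal(2.5, 0.3, size=(cfg.n_subjects, n_striatal))
    d2r_mp = 0.8 * d2r_pl + rng_sub.normal(0.0, 0.1, size=(cfg.n_subjects, n_striatal))
    z = (d1r_means - d1r_means.mean()) / d1r_means.std() if cfg.n_subjects > 1 else np.zeros(1)
    sensitivity = (
        1.0
        + cfg.mediation_a * cfg.sensitivity_slope * z
        + rng_sub.normal(0.0, cfg.sensitivity_noise_sd, size=cfg.n_subjects)
    )
    # keep every subject's MP kernel valid: |sensitivity x boost| must stay
    # inside the (1 - base_persistence) headroom
    if cfg.mp_persistence_boost > 0:
        s_cap = 0.9 * (1.0 - cfg.base_persistence) / cfg.mp_persistence_boost
        sensitivity = np.clip(sensitivity, -s_cap, s_cap)

    scans: list[RoiTimeSeries] = []
    sequences: dict = {}
    kernels: dict = {}
    metrics: dict = {}
    delta_dwell: dict = {}
    scan_seeds = ss_scans.spawn(cfg.n_subjects)
    for i, sid in enumerate(subj_ids):
        seq_ss, bold_ss = scan_seeds[i].spawn(2)
        seq_rngs = {c: np.random.default_rng(s) for c, s in zip(("PL", "MP"), seq_ss.spawn(2))}
        bold_rngs = {c: np.random.default_rng(s) for c, s in zip(("PL", "MP"), bold_ss.spawn(2))}
        for cond in ("PL", "MP"):
            seq = simulate_state_sequence(sensitivity[i], cond, cfg, seq_rngs[cond])
            sequences[(sid, cond)] = seq
            kernels[(sid, cond)] = build_transition_kernel(sensitivity[i], cond, cfg)
            metrics[(sid, cond)] = truth_metrics(seq, cfg.k_true, cfg.tr_seconds, sid, cond)
            if include_bold:
                scans.append(
                    simulate_roi_timeseries(seq, centroids, cfg, bold_rngs[cond], sid, cond)
                )
        delta_dwell[sid] = float(
            metrics[(sid, "MP")].dwell_time[fpn_plus] - metrics[(sid, "PL")].dwell_time[fpn_plus]
        )

    rng_beh = np.random.default_rng(ss_behavior)
    subjects: list[SubjectRecord] = []
    for i, sid in enumerate(subj_ids):
        rt2_pl = max(0.2, rng_beh.normal(0.6, 0.08))
        d_rt2 = -cfg.mediation_b * delta_dwell[sid] + rng_beh.normal(0.0, cfg.rt_noise_sd)
        rt3_pl = max(0.2, rng_beh.normal(0.75, 0.10))
        d_rt3 = rng_beh.normal(0.0, cfg.rt_noise_sd)
        acc = {
            key: rng_beh.binomial(cfg.n_probes, p) / cfg.n_probes
            for key, p in cfg.acc_probe_p.items()
        }
        subjects.append(SubjectRecord(
            subject_id=sid,
            d1r=d1r[i], d2r_pl=d2r_pl[i], d2r_mp=d2r_mp[i],
            rt_2ball_pl=rt2_pl, rt_2ball_mp=max(0.05, rt2_pl + d_rt2),
            rt_3ball_pl=rt3_pl, rt_3ball_mp=max(0.05, rt3_pl + d_rt3),
            acc_2ball_pl=acc[("2ball", "PL")], acc_2ball_mp=acc[("2ball", "MP")],
            acc_3ball_pl=acc[("3ball", "PL")], acc_3ball_mp=acc[("3ball", "MP")],
            iq=rng_beh.normal(115.0, 12.0),
        ))

    truth = CohortTruth(
        state_names=names, sequences=sequences, kernels=kernels,
        sensitivity={sid: float(sensitivity[i]) for i, sid in enumerate(subj_ids)},
        metrics=metrics, delta_dwell_fpn_plus=delta_dwell,
    )
    return SyntheticCohort(
        scans=scans, templates=templates, centroids=centroids,
        truth=truth, subjects=subjects, config=cfg,
    )
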