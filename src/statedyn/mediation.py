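"""Simple three-variable mediation with bootstrap inference.

Paths: a (x -> m), b (m -> y controlling x), c (total x -> y), c' (direct
x -> y controlling m); indirect effect = a x b. All regressions are OLS
with intercepts, so c = c' + a x b holds exactly on a common sample.
Inference on the indirect effect uses a nonparametric subject-level
bootstrap (rows resampled jointly) with a percentile confidence interval
and a tail-symmetric two-sided p-value.
"""
from __future__ import annotations

import numpy as np

from .types import MediationResult


def _as_vectors(x, m, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("x, m, y must share length")
    if len(x) < 5:
        raise ValueError("need n >= 5 observations")
    if x.std() == 0 or m.std() == 0:
        raise ValueError("x and m must be nonconstant")
    return x, m, y


def fit_paths(x, m, y) -> tuple[float, float, float, float]:
    """OLS path coefficients (a, b, c, c_prime), intercepts included.

    a: slope of m ~ x; c: slope of y ~ x; (c_prime, b): slopes of
    y ~ x + m. Raises on near-collinear x and m, reporting the design's
    condition number.
    """
    x, m, y = _as_vectors(x, m, y)
    n = len(x)
    one = np.ones(n)
    Xa = np.column_stack([one, x])
    a = np.linalg.lstsq(Xa, m, rcond=None)[0][1]
    c = np.linalg.lstsq(Xa, y, rcond=None)[0][1]
    Xb = np.column_stack([one, x, m])
    cond = np.linalg.cond(Xb)
    if cond > 1e10:
        raise ValueError(f"x and m are collinear (design condition number {cond:.3g})")
    coef = np.linalg.lstsq(Xb, y, rcond=None)[0]
    c_prime, b = coef[1], coef[2]
    return float(a), float(b), float(c), float(c_prime)


def _boot_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorized a*b over bootstrap index matrix (n_boot, n).

    Uses the closed-form two-regressor OLS on centered resamples; rows
    with a degenerate design (zero variance or collinear) return NaN.
    """
    xb, mb, yb = x[idx], m[idx], y[idx]
    xc = xb - xb.mean(axis=1, keepdims=True)
    mc = mb - mb.mean(axis=1, keepdims=True)
    yc = yb - yb.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    smm = np.einsum("ij,ij->i", mc, mc)
    sxm = np.einsum("ij,ij->i", xc, mc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    smy = np.einsum("ij,ij->i", mc, yc)
    det = sxx * smm - sxm**2
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sxm / sxx
        b = (sxx * smy - sxm * sxy) / det
        ab = a * b
    bad = (sxx <= 0) | (smm <= 0) | (det <= np.finfo(float).eps * sxx * smm)
    ab[bad] = np.nan
    return ab


def bootstrap_indirect(x, m, y, n_boot: int = 1000, seed: int = 0) -> MediationResult:
    """Bootstrap the indirect effect a x b.

    Subjects are resampled with replacement ``n_boot`` times; degenerate
    resamples (constant x or collinear design) are redrawn and counted.
    The 95% CI is the 2.5/97.5 percentile of the bootstrap distribution;
    p = 2 min(#{ab* <= 0}, #{ab* >= 0}) / n_boot, floored at 2 / n_boot.
    Deterministic under a fixed seed.
    """
    x, m, y = _as_vectors(x, m, y)
    a, b, c, c_prime = fit_paths(x, m, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    ab = np.empty(n_boot)
    filled = 0
    n_redraws = 0
    while filled < n_boot:
        draw = min(n_boot - filled, n_boot)
        idx = rng.integers(0, n, size=(draw, n))
        vals = _boot_paths(x, m, y, idx)
        ok = np.isfinite(vals)
        n_redraws += int((~ok).sum())
        take = vals[ok]
        ab[filled:filled + len(take)] = take
        filled += len(take)
    lo, hi = np.percentile(ab, [2.5, 97.5])
    p = 2.0 * min((ab <= 0).sum(), (ab >= 0).sum()) / n_boot
    p = max(p, 2.0 / n_boot)
    p = min(p, 1.0)
    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, indirect=a * b,
        ci_low=float(lo), ci_high=float(hi), p_indirect=float(p),
        n_boot=n_boot, seed=seed, n_degenerate_redraws=n_redraws,
    )


def residualize_on(covariate, *vectors) -> list[np.ndarray]:
    """Residualize each vector on [intercept | covariate]; used to adjust
    the mediation triplet for IQ before fitting."""
    z = np.asarray(covariate, dtype=float)
    design = np.column_stack([np.ones(len(z)), z])
    out = []
    for v in vectors:
        v = np.asarray(v, dtype=float)
        out.append(v - design @ np.linalg.lstsq(design, v, rcond=None)[0])
    return out
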