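"""Normalization tracks: probe-level intensities -> probeset-level log2 expression.

Four independently implemented tracks mirror the classic Affymetrix
preprocessing families:

* ``RMA``    — background shift, log2, quantile normalization, median-polish
  summarization (natively log scale);
* ``MAS5``   — ideal-mismatch subtraction, Tukey-biweight signal, trimmed-mean
  scaling (natively linear, log2-transformed on output);
* ``LiWong`` — invariant-set normalization to a pseudo-median reference and a
  multiplicative model-based expression index (natively linear, logged);
* ``VSN``    — affine calibration plus generalized-log (arcsinh) transform,
  median-polish summarization (natively variance-stabilized, not re-logged).

A registry keyed by track name accepts plugin tracks with the same contract,
so further algorithms (e.g. sequence-aware background models) can be slotted
in without touching the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .synthgen import ProbeIntensityMatrix

log = logging.getLogger(__name__)

LN2 = np.log(2.0)


@dataclass
class ProbesetExpressionMatrix:
    """Probeset x sample expression on log2 (or glog2) scale for one study."""

    study_id: str
    track: str
    values: pd.DataFrame            # index probeset_id, columns sample_ids
    #: True when the track natively produced linear values that were
    #: subsequently log2-transformed
    scale_note: bool = False
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")


# ---------------------------------------------------------------------------
# shared primitives


def quantile_normalize(matrix):
    """Force every column onto the across-column mean empirical distribution.

    Each column's sorted values become the mean of the columns' sorted values;
    within-column rank order is preserved and ties receive the mean of the
    tied target quantiles.  Accepts an array or DataFrame (returned as given).
    """
    df_index = df_cols = None
    if isinstance(matrix, pd.DataFrame):
        df_index, df_cols = matrix.index, matrix.columns
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("need a 2-D matrix with at least one column")
    if not np.isfinite(x).all():
        raise ValueError("missing/non-finite values are not supported")

    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        # average the target quantiles within tie groups
        _, inv, counts = np.unique(col[order], return_inverse=True,
                                   return_counts=True)
        group_means = np.bincount(inv, weights=target) / counts
        out[order, j] = group_means[inv]
    if df_index is not None:
        return pd.DataFrame(out, index=df_index, columns=df_cols)
    return out


@dataclass
class MedianPolishFit:
    overall: float | np.ndarray
    probe_effects: np.ndarray
    sample_effects: np.ndarray
    residuals: np.ndarray

    @property
    def summary(self):
        """Summarized expression per sample: overall + sample effects."""
        return self.overall + self.sample_effects


def median_polish(block, tol: float = 1e-8, max_iter: int = 100) -> MedianPolishFit:
    """Tukey median polish of an additive probe x sample model.

    Alternately removes row (probe) and column (sample) medians, sweeping
    effect medians into the overall term, until the largest removed median is
    below ``tol`` or ``max_iter`` is reached.  Also accepts a stacked 3-D array
    of blocks (block x probe x sample), polished jointly for speed.
    """
    x = np.asarray(block, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("median polish requires finite input")
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None, :, :]
    resid = x.copy()
    overall = np.zeros(x.shape[0])
    rows = np.zeros(x.shape[:2])
    cols = np.zeros((x.shape[0], x.shape[2]))
    for _ in range(max_iter):
        rdelta = np.median(resid, axis=2)
        resid -= rdelta[:, :, None]
        rows += rdelta
        d = np.median(cols, axis=1)
        cols -= d[:, None]
        overall += d
        cdelta = np.median(resid, axis=1)
        resid -= cdelta[:, None, :]
        cols += cdelta
        d = np.median(rows, axis=1)
        rows -= d[:, None]
        overall += d
        if max(np.abs(rdelta).max(), np.abs(cdelta).max()) < tol:
            break
    if squeeze:
        return MedianPolishFit(float(overall[0]), rows[0], cols[0], resid[0])
    return MedianPolishFit(overall, rows, cols, resid)


def tukey_biweight(x: np.ndarray, axis: int = 0, c: float = 5.0,
                   epsilon: float = 1e-4) -> np.ndarray:
    """One-step Tukey biweight location estimate along ``axis``."""
    x = np.asarray(x, dtype=float)
    med = np.median(x, axis=axis, keepdims=True)
    s = np.median(np.abs(x - med), axis=axis, keepdims=True)
    u = (x - med) / (c * s + epsilon)
    w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
    return (w * x).sum(axis=axis) / w.sum(axis=axis)


# ---------------------------------------------------------------------------
# RMA-style track


def normalize_rma(raw: ProbeIntensityMatrix, bg_quantile: float = 0.05,
                  **_) -> ProbesetExpressionMatrix:
    """Background shift, log2, quantile normalization, median polish.

    The background step subtracts each array's ``bg_quantile`` intensity and
    floors the result at 1 (a deliberate simplification of the usual
    normal+exponential convolution fit: downstream analysis uses only
    variance ranking, for which a location shift suffices).
    """
    n_ps, p, n = raw.pm.shape
    pm2d = raw.pm.reshape(n_ps * p, n)
    bg = np.quantile(pm2d, bg_quantile, axis=0)
    v = np.log2(np.maximum(pm2d - bg[None, :], 1.0))
    v = quantile_normalize(v)
    fit = median_polish(v.reshape(n_ps, p, n))
    values = fit.overall[:, None] + fit.sample_effects
    return ProbesetExpressionMatrix(
        raw.study_id, "RMA",
        pd.DataFrame(values, index=raw.probeset_ids, columns=raw.sample_ids),
        scale_note=False, params={"bg_quantile": bg_quantile},
    )


# ---------------------------------------------------------------------------
# MAS5-style track


def mas5_signal(pm: np.ndarray, mm: np.ndarray, c: float = 5.0,
                epsilon: float = 1e-4, contrast_tau: float = 0.03,
                floor: float = 2.0 ** -20) -> np.ndarray:
    """Unscaled MAS5-style log2 signal per probeset and sample.

    The ideal mismatch equals MM where MM < PM; otherwise PM is shrunk by the
    probeset's specific background SB = biweight of log2(PM/MM), floored at
    ``contrast_tau`` so the subtraction never removes the whole signal.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(pm / np.maximum(mm, 1e-300))
    sb = tukey_biweight(ratio, axis=1, c=c, epsilon=epsilon)
    sb = np.maximum(sb, contrast_tau)
    im = np.where(mm < pm, mm, pm / np.exp2(sb)[:, None, :])
    pv = np.maximum(pm - im, floor)
    return tukey_biweight(np.log2(pv), axis=1, c=c, epsilon=epsilon)


def normalize_mas5(raw: ProbeIntensityMatrix, target: float = 500.0,
                   c: float = 5.0, epsilon: float = 1e-4,
                   contrast_tau: float = 0.03, trim: float = 0.02,
                   **_) -> ProbesetExpressionMatrix:
    """Ideal-mismatch subtraction, biweight signal, trimmed-mean scaling.

    After scaling, every array's ``trim``-trimmed mean of linear signals
    equals ``target``.  Output is reported on log2 scale (scale_note=True).
    """
    if raw.mm is None:
        raise ValueError(
            "MAS5 requires mismatch (MM) intensities; use an MM-free track "
            "such as RMA, LiWong or VSN"
        )
    sig = mas5_signal(raw.pm, raw.mm, c=c, epsilon=epsilon,
                      contrast_tau=contrast_tau)
    linear = np.exp2(sig)
    tm = np.array([stats.trim_mean(linear[:, j], trim)
                   for j in range(linear.shape[1])])
    values = sig + np.log2(target / tm)[None, :]
    return ProbesetExpressionMatrix(
        raw.study_id, "MAS5",
        pd.DataFrame(values, index=raw.probeset_ids, columns=raw.sample_ids),
        scale_note=True,
        params={"target": target, "c": c, "contrast_tau": contrast_tau},
    )


# ---------------------------------------------------------------------------
# Li-Wong-style track (invariant set + multiplicative model)


def invariant_set(values: np.ndarray, reference: np.ndarray,
                  thresholds: tuple[float, float] = (0.003, 0.007)) -> np.ndarray:
    """Probes whose ranks agree between an array and the reference.

    A probe is invariant when its rank-difference proportion is below
    ``t0 + t1 * (average rank / n)`` — a small/large-rank interpolation of the
    tolerance.
    """
    n = len(values)
    r_a = stats.rankdata(values)
    r_ref = stats.rankdata(reference)
    prd = np.abs(r_a - r_ref) / n
    avg = (r_a + r_ref) / 2.0
    t0, t1 = thresholds
    return prd < t0 + t1 * (avg / n)


def _running_median_map(x: np.ndarray, y: np.ndarray, window_frac: float = 0.02):
    """Monotone running-median smoother through (x, y), returned as knots."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    w = max(5, int(window_frac * len(xs)) | 1)
    smooth = ndimage.median_filter(ys, size=w, mode="nearest")
    smooth = np.maximum.accumulate(smooth)
    return xs, smooth


def fit_multiplicative_model(blocks: np.ndarray, tol: float = 1e-10,
                             max_iter: int = 200):
    """Alternating least squares for PM_ij ~= theta_j * phi_i per probeset.

    ``blocks`` is (probeset, probe, sample); the probe-affinity vector is
    constrained to ||phi||^2 = P.  Returns (theta, phi) with shapes
    (probeset, sample) and (probeset, probe).  On exact rank-1 input the
    factors are recovered to numerical precision.
    """
    n_ps, p, _ = blocks.shape
    phi = np.ones((n_ps, p))
    theta = np.einsum("spn,sp->sn", blocks, phi) / (phi ** 2).sum(1, keepdims=True)
    for _ in range(max_iter):
        prev = theta
        phi = np.einsum("spn,sn->sp", blocks, theta) / (theta ** 2).sum(1, keepdims=True)
        phi *= np.sqrt(p / (phi ** 2).sum(1, keepdims=True))
        theta = np.einsum("spn,sp->sn", blocks, phi) / (phi ** 2).sum(1, keepdims=True)
        if np.abs(theta - prev).max() < tol * max(1.0, np.abs(theta).max()):
            break
    return theta, phi


def normalize_liwong(raw: ProbeIntensityMatrix,
                     thresholds: tuple[float, float] = (0.003, 0.007),
                     tol: float = 1e-10, max_iter: int = 200,
                     window_frac: float = 0.02,
                     **_) -> ProbesetExpressionMatrix:
    """Invariant-set normalization plus multiplicative model expression index.

    Without background correction: each array is normalized to the pseudo-
    median reference array by a monotone running-median curve fitted over the
    invariant probe set, then each probeset block is fitted with the
    multiplicative model PM_ij ~= theta_j * phi_i by alternating least squares
    under the ||phi||^2 = P constraint; expression is log2(theta).
    """
    n_ps, p, n = raw.pm.shape
    if n < 2:
        raise ValueError("Li-Wong normalization needs at least 2 samples")
    pm2d = raw.pm.reshape(n_ps * p, n)
    reference = np.median(pm2d, axis=1)

    normed = np.empty_like(pm2d)
    for j in range(n):
        inv = invariant_set(pm2d[:, j], reference, thresholds)
        if not inv.any():
            log.warning("study %s array %s: no invariant probes; using all",
                        raw.study_id, raw.sample_ids[j])
            inv = np.ones(len(reference), dtype=bool)
        xs, ys = _running_median_map(pm2d[inv, j], reference[inv], window_frac)
        normed[:, j] = np.interp(pm2d[:, j], xs, ys)
    normed = np.maximum(normed, 1e-6).reshape(n_ps, p, n)
    theta, _ = fit_multiplicative_model(normed, tol=tol, max_iter=max_iter)
    values = np.log2(np.maximum(theta, 1e-6))
    return ProbesetExpressionMatrix(
        raw.study_id, "LiWong",
        pd.DataFrame(values, index=raw.probeset_ids, columns=raw.sample_ids),
        scale_note=True, params={"thresholds": thresholds},
    )


# ---------------------------------------------------------------------------
# VSN-style track (affine calibration + generalized log)


def _trimmed_affine_fit(x: np.ndarray, y: np.ndarray, trim_fraction: float,
                        iters: int = 5) -> tuple[float, float]:
    """Least-trimmed-squares-style affine fit y ~= alpha + beta * x."""
    keep = np.ones(len(x), dtype=bool)
    alpha = beta = 0.0
    for _ in range(iters):
        xk, yk = x[keep], y[keep]
        beta, alpha = np.polyfit(xk, yk, 1)
        resid = np.abs(alpha + beta * x - y)
        cutoff = np.quantile(resid, 1.0 - trim_fraction)
        keep = resid <= cutoff
    return float(alpha), float(beta)


def vsn_calibrate(pm2d: np.ndarray, trim_fraction: float = 0.1):
    """Affine calibration + glog transform of a probe x sample matrix.

    Each array s gets h_s(x) = arcsinh(a_s + b_s x) / ln 2.  The affine part
    is estimated by trimmed least-squares agreement of the array's sorted
    quantiles with the pseudo-median reference array's; the shared glog scale
    is set from the data's additive (low-intensity, absolute) and
    multiplicative (high-intensity, relative) noise components so that the
    transform equalizes variance across the intensity range.

    Returns (transformed matrix, a per array, b per array).
    """
    n_probes, n = pm2d.shape
    if n < 2:
        raise ValueError("VSN calibration needs at least 2 samples")
    med = np.median(pm2d, axis=0)
    ref = int(np.argsort(med, kind="stable")[len(med) // 2])
    ref_sorted = np.sort(pm2d[:, ref])

    alpha = np.empty(n)
    beta = np.empty(n)
    for j in range(n):
        a, b = _trimmed_affine_fit(np.sort(pm2d[:, j]), ref_sorted, trim_fraction)
        if b <= 0:
            raise ValueError(
                f"VSN calibration failed: non-positive scale for array {j}"
            )
        alpha[j], beta[j] = a, b
    calibrated = alpha[None, :] + beta[None, :] * pm2d

    probe_med = np.median(calibrated, axis=1)
    q25, q75 = np.quantile(probe_med, [0.25, 0.75])
    low = calibrated[probe_med <= q25]
    high = calibrated[probe_med >= q75]
    sigma_add = float(np.median(low.std(axis=1)))
    sigma_mult = float(np.median(np.std(np.log(np.maximum(high, 1e-9)), axis=1)))
    if sigma_add > 1e-12 and sigma_mult > 1e-12:
        lam = sigma_add / sigma_mult
    else:  # degenerate (e.g. identical arrays): any positive scale works
        lam = max(float(np.median(calibrated)) / 50.0, 1e-6)
    x0 = float(np.quantile(calibrated, 0.05))

    h = np.arcsinh((calibrated - x0) / lam) / LN2
    a_eff = (alpha - x0) / lam
    b_eff = beta / lam
    return h, a_eff, b_eff


def normalize_vsn(raw: ProbeIntensityMatrix, trim_fraction: float = 0.1,
                  **_) -> ProbesetExpressionMatrix:
    """Variance-stabilizing calibration + glog, median-polish summarization.

    Output values are already on a variance-stabilized log2-like scale and are
    not logged again (scale_note=False).
    """
    n_ps, p, n = raw.pm.shape
    pm2d = raw.pm.reshape(n_ps * p, n)
    h, a_eff, b_eff = vsn_calibrate(pm2d, trim_fraction)
    fit = median_polish(h.reshape(n_ps, p, n))
    values = fit.overall[:, None] + fit.sample_effects
    return ProbesetExpressionMatrix(
        raw.study_id, "VSN",
        pd.DataFrame(values, index=raw.probeset_ids, columns=raw.sample_ids),
        scale_note=False,
        params={"a": a_eff.tolist(), "b": b_eff.tolist(),
                "trim_fraction": trim_fraction},
    )


# ---------------------------------------------------------------------------
# track registry

TRACKS: dict[str, callable] = {
    "RMA": normalize_rma,
    "MAS5": normalize_mas5,
    "LiWong": normalize_liwong,
    "VSN": normalize_vsn,
}


def register_track(name: str, fn) -> None:
    """Register a plugin normalization track with the standard contract."""
    TRACKS[name] = fn


def run_track(name: str, raw: ProbeIntensityMatrix, **cfg) -> ProbesetExpressionMatrix:
    if name not in TRACKS:
        raise KeyError(f"unknown track {name!r}; available: {sorted(TRACKS)}")
    return TRACKS[name](raw, **cfg)
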