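"""Reference relaxometry fitters and evaluation statistics.

The inversion-recovery spin-echo reference fits the 3-parameter model
S(TI) = A - B exp(-TI / T1); the spin-echo T2 reference fits the
mono-exponential S(TE) = S0 exp(-TE / T2).  ROI statistics, Bland-Altman
agreement and the coefficient of variation (sample SD; technique CV as the
root mean square of per-ROI CVs) mirror standard phantom-evaluation
practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ROISpec",
    "fit_ir_t1",
    "fit_monoexp_t2",
    "roi_stats",
    "bland_altman",
    "BlandAltman",
    "coefficient_of_variation",
]


# ---------------------------------------------------------------------------
# reference fits
# ---------------------------------------------------------------------------

def _ir_model(ti, a, b, t1):
    return a - b * np.exp(-ti / t1)


def fit_ir_t1(signals, ti, magnitude: bool = False):
    """3-parameter inversion-recovery fit S(TI) = A - B exp(-TI/T1).

    With ``magnitude=True`` the signal polarity is restored by trying every
    sign-flip split of the (TI-sorted) points and keeping the best fit.
    Returns (A, B, T1).
    """
    signals = np.asarray(signals, float)
    ti = np.asarray(ti, float)
    if signals.size != ti.size or signals.size < 4:
        raise ValueError("need at least 4 (signal, TI) pairs")
    order = np.argsort(ti)
    ti_s, sig_s = ti[order], signals[order]

    def _fit(sig):
        a0 = sig[-1]
        b0 = a0 - sig[0]
        if abs(b0) < 1e-12 * max(1.0, abs(a0)):
            raise ValueError("no inversion contrast: T1 unidentifiable (B = 0)")
        t1_0 = max(ti_s[len(ti_s) // 2], 1e-3)
        popt, _ = curve_fit(
            _ir_model, ti_s, sig, p0=[a0, b0, t1_0], maxfev=20000
        )
        resid = float(np.sum((_ir_model(ti_s, *popt) - sig) ** 2))
        return popt, resid

    if not magnitude:
        popt, _ = _fit(sig_s)
        return float(popt[0]), float(popt[1]), float(popt[2])
    best = None
    for split in range(len(ti_s) + 1):
        sig = sig_s.copy()
        sig[:split] = -sig[:split]
        try:
            popt, resid = _fit(sig)
        except (ValueError, RuntimeError):
            continue
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise ValueError("inversion-recovery fit failed for all polarities")
    popt = best[0]
    return float(popt[0]), float(popt[1]), float(popt[2])


def fit_monoexp_t2(signals, te, log_linear: bool = True):
    """Mono-exponential fit S(TE) = S0 exp(-TE/T2); returns (S0, T2)."""
    signals = np.asarray(signals, float)
    te = np.asarray(te, float)
    if signals.size != te.size or signals.size < 2:
        raise ValueError("need at least 2 (signal, TE) pairs")
    if log_linear:
        if np.any(signals <= 0):
            raise ValueError("log-linear fit needs positive signals")
        coef = np.polyfit(te, np.log(signals), 1)
        slope, intercept = coef[0], coef[1]
        if slope >= 0:
            raise ValueError("non-decaying signal: T2 fit failed")
        return float(np.exp(intercept)), float(-1.0 / slope)
    popt, _ = curve_fit(
        lambda t, s0, t2: s0 * np.exp(-t / t2), te, signals,
        p0=[signals.max(), max(te.mean(), 1e-3)], maxfev=20000,
    )
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# ROI and agreement statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROISpec:
    """Cubic ROI: center voxel coordinates and edge length in mm."""

    center: tuple
    size_mm: float = 12.0
    voxel_size: float = 3.0

    @property
    def side_voxels(self) -> int:
        return max(1, int(round(self.size_mm / self.voxel_size)))


def roi_stats(volume: np.ndarray, roi: ROISpec, mask: np.ndarray | None = None):
    """(mean, sample SD, n) over the cubic ROI, optionally masked."""
    volume = np.asarray(volume)
    side = roi.side_voxels
    sl = []
    for ax, c in enumerate(roi.center):
        start = int(c) - side // 2
        stop = start + side
        if start < 0 or stop > volume.shape[ax]:
            raise ValueError("ROI extends outside the volume")
        sl.append(slice(start, stop))
    vals = volume[tuple(sl)]
    if mask is not None:
        vals = vals[mask[tuple(sl)]]
    vals = np.asarray(vals, float).ravel()
    if vals.size == 0:
        raise ValueError("ROI empty after masking")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, int(vals.size)


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    pearson_r: float


def bland_altman(series_a, series_b) -> BlandAltman:
    """Bland-Altman agreement of paired series (differences a - b)."""
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length series with >= 2 entries")
    d = a - b
    md = float(d.mean())
    sd = float(np.std(d, ddof=1))
    if np.std(a) > 0 and np.std(b) > 0:
        r = float(np.corrcoef(a, b)[0, 1])
    else:
        r = np.nan
    return BlandAltman(
        mean_difference=md, sd_difference=sd,
        loa_lower=md - 1.96 * sd, loa_upper=md + 1.96 * sd, pearson_r=r,
    )


def coefficient_of_variation(measurements) -> tuple:
    """Per-ROI CV% across repeats and the technique CV (RMS of per-ROI CVs).

    ``measurements``: (n_rois, n_repeats) array-like, >= 2 repeats per ROI.
    """
    m = np.asarray(measurements, float)
    if m.ndim == 1:
        m = m[None, :]
    if m.shape[1] < 2:
        raise ValueError("need >= 2 repeats per ROI")
    means = m.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("zero mean in a ROI: CV undefined")
    cvs = np.std(m, axis=1, ddof=1) / np.abs(means) * 100.0
    technique = float(np.sqrt(np.mean(cvs**2)))
    return cvs, technique
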