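"""Digital water-fat vial phantom and forward k-space simulator.

This module is the scanner stand-in: a cylindrical-vial phantom with known
(T1, T2, fat fraction, B0) per vial, synthetic coil sensitivities, a
periodic respiratory surrogate, and a profile-by-profile forward model of
the four-block Look-Locker acquisition producing multi-echo multi-coil
k-space data along the CASPR schedule.

Forward signal model per voxel, profile n (cycle timeline index j) and echo e:

    s = PD * [ (1 - FF) * w_j  +  FF * c_e * f_j ] * exp(i 2 pi B0 TE_e)

where w and f are the Bloch steady-state timelines of the water and fat
components (fat simulated with its own T1/T2 so that the linearity of the
water/fat amplitudes in the subspace is exercised rather than assumed),
c_e the multi-peak fat dephasing at echo e, and B0 the voxel off-resonance.
The fat component's preparation-pulse response is simulated at the voxel's
water off-resonance; the chemical-shift dephasing enters through c_e only.

Respiratory motion is a rigid feet-head (readout-axis) translation of the
coil-weighted object, applied as a per-profile linear phase on the readout
k-line.  The readout axis is fully sampled with 2x oversampling; bipolar
acquisition misalignment is emulated by sampling the second echo's readout
at a configurable fractional-sample offset, and two opposite-polarity DC
calibration lines are produced for its estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import BlochDictionary, SequenceTiming, bloch_simulate
from .trajectory import CASPRSampling
from .waterfat import FatSpectrum

__all__ = [
    "DigitalPhantom",
    "MotionTrace",
    "KSpaceData",
    "make_vial_phantom",
    "make_coil_maps",
    "make_motion_trace",
    "simulate_kspace",
]


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigitalPhantom:
    """Label volume plus per-label tissue table and auxiliary maps.

    ``tissue_table`` is a structured array over labels 0..n_labels-1 with
    fields t1, t2, fat_fraction, proton_density, b0 (label 0 = empty
    background, proton_density 0)."""

    label_map: np.ndarray
    tissue_table: np.ndarray
    coil_maps: np.ndarray
    voxel_size: float = 3.0

    def __post_init__(self):
        tt = self.tissue_table
        if np.any((tt["fat_fraction"] < 0) | (tt["fat_fraction"] > 1)):
            raise ValueError("fat_fraction must lie in [0, 1]")
        if np.any(np.abs(tt["b0"]) > 300.0):
            raise ValueError("b0 offsets must stay within the +-300 Hz matching range")

    @property
    def shape(self) -> tuple:
        return self.label_map.shape

    @property
    def n_coils(self) -> int:
        return self.coil_maps.shape[0]

    def map_of(self, name: str) -> np.ndarray:
        """Voxelwise ground-truth map of a tissue-table field."""
        return self.tissue_table[name][self.label_map]

    @property
    def b0_map(self) -> np.ndarray:
        return self.map_of("b0")


_TISSUE_DTYPE = np.dtype([
    ("t1", float), ("t2", float), ("fat_fraction", float),
    ("proton_density", float), ("b0", float),
])


def make_coil_maps(shape, n_coils: int = 4, seed: int = 0) -> np.ndarray:
    """Smooth synthetic complex coil sensitivities, (n_coils, *shape).

    Gaussian magnitude profiles centered outside the FOV on alternating
    sides, with a smooth linear phase; loosely mimics a surround array."""
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    maps = np.empty((n_coils,) + tuple(shape), np.complex128)
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils
        cy, cz = 1.4 * np.cos(ang), 1.4 * np.sin(ang)
        r2 = (y - cy) ** 2 + (z - cz) ** 2 + 0.3 * x**2
        mag = np.exp(-r2 / 2.0)
        ph = (rng.uniform(-1, 1) * x + rng.uniform(-1, 1) * y
              + rng.uniform(-1, 1) * z + rng.uniform(0, 2 * np.pi))
        maps[c] = mag * np.exp(1j * ph)
    return maps


def make_vial_phantom(
    matrix,
    n_vials: int = 8,
    t1_range=(300.0, 1500.0),
    t2_range=(15.0, 100.0),
    ff_values=(0.0, 0.0, 0.05, 0.12, 0.25),
    b0_profile="zero",
    b0_max: float = 240.0,
    background=None,
    n_coils: int = 4,
    voxel_size: float = 3.0,
    seed: int = 0,
) -> DigitalPhantom:
    """Cylindrical-vial water-fat phantom with known ground truth.

    Vials are cylinders along the z axis, arranged on a ring in the x-y
    plane inside a water background cylinder.  T1 and T2 vary
    across vials over ``t1_range``/``t2_range``; fat fractions cycle through
    ``ff_values``.  ``b0_profile`` is "zero", "per_vial" (seeded uniform
    offsets up to b0_max) or an explicit per-label array.
    """
    nx, ny, nz = matrix
    rng = np.random.default_rng(seed)
    labels = np.zeros(matrix, np.int32)
    # vials are cylinders along z (the thin axis); cross-sections live in the
    # (x, y) plane so the rigid feet-head (x) motion crosses vial edges
    xx, yy = np.meshgrid(np.arange(nx) - nx / 2.0 + 0.5,
                         np.arange(ny) - ny / 2.0 + 0.5, indexing="ij")
    rx, ry = 0.46 * nx, 0.46 * ny
    bg = (xx / rx) ** 2 + (yy / ry) ** 2 <= 1.0
    z_core = slice(int(0.08 * nz), int(np.ceil(0.92 * nz)))
    labels[bg, z_core] = 1
    # vials (labels 2..): one centered, the rest on a ring
    vial_r = 0.11 * min(nx, ny)
    centers = [(0.0, 0.0)]
    ring = 0.30 * min(nx, ny)
    for i in range(n_vials - 1):
        ang = 2.0 * np.pi * i / (n_vials - 1)
        centers.append((ring * np.cos(ang), ring * np.sin(ang)))
    for i, (cx, cy) in enumerate(centers[:n_vials]):
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= vial_r**2
        if not mask.any():
            raise ValueError("vial does not cover any voxel; matrix too small")
        if np.any(~bg[mask]):
            raise ValueError("vial placed outside the phantom background")
        labels[mask, z_core] = 2 + i

    n_labels = 2 + n_vials
    tt = np.zeros(n_labels, _TISSUE_DTYPE)
    if background is None:
        background = dict(t1=2800.0, t2=100.0, fat_fraction=0.0, proton_density=0.6)
    tt[1] = (background["t1"], background["t2"], background["fat_fraction"],
             background["proton_density"], 0.0)
    t1s = np.linspace(t1_range[0], t1_range[1], n_vials)
    t2s = np.linspace(t2_range[0], t2_range[1], n_vials)
    # spread the requested fat fractions over the vials so that every listed
    # value (in particular the extremes) appears even when n_vials differs
    # from len(ff_values)
    if n_vials == 1:
        ffs = [ff_values[0]]
    else:
        ffs = [ff_values[int(round(i * (len(ff_values) - 1) / (n_vials - 1)))]
               for i in range(n_vials)]
    for i in range(n_vials):
        tt[2 + i] = (t1s[i], t2s[i], ffs[i], 1.0, 0.0)
    if isinstance(b0_profile, str):
        if b0_profile == "per_vial":
            tt["b0"][1:] = np.round(rng.uniform(-b0_max, b0_max, n_labels - 1))
        elif b0_profile != "zero":
            raise ValueError(f"unknown b0_profile {b0_profile!r}")
    else:
        tt["b0"] = np.asarray(b0_profile, float)
    coil_maps = make_coil_maps(matrix, n_coils, seed)
    return DigitalPhantom(label_map=labels, tissue_table=tt,
                          coil_maps=coil_maps, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# respiratory surrogate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionTrace:
    """Surrogate respiratory amplitude vs time (ms)."""

    amplitude: np.ndarray
    sample_times: np.ndarray

    def at(self, t_ms) -> np.ndarray:
        return np.interp(t_ms, self.sample_times, self.amplitude)


def make_motion_trace(
    duration: float,
    period: float = 3.7,
    amplitude: float = 1.0,
    drift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    rate_hz: float = 25.0,
    plateau_power: int = 3,
) -> MotionTrace:
    """Asymmetric periodic breathing surrogate with an end-expiration plateau.

    m(t) = amplitude * sin(pi t / period)^(2 p) + drift * t + noise: the
    trace dwells near 0 (end-expiration, the histogram mode) with short
    inspiration peaks of height ``amplitude``.  ``duration``/``period`` in
    seconds, ``drift`` in units/min.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    rng = np.random.default_rng(seed)
    n = max(2, int(duration * rate_hz))
    t_s = np.arange(n) / rate_hz
    m = amplitude * np.sin(np.pi * t_s / period) ** (2 * plateau_power)
    m = m + drift * t_s / 60.0
    if noise_sd > 0:
        m = m + rng.normal(0.0, noise_sd, n)
    return MotionTrace(amplitude=m, sample_times=t_s * 1e3)


# ---------------------------------------------------------------------------
# k-space simulation
# ---------------------------------------------------------------------------

@dataclass
class KSpaceData:
    """Profile-stream multi-echo multi-coil k-space container.

    ``data``: (n_profiles, n_echoes, n_coils, n_readout) complex64 in
    acquisition order aligned with ``sampling``; ``calibration``: two DC
    readouts of opposite gradient polarity, (2, n_coils, n_readout).
    """

    data: np.ndarray
    sampling: CASPRSampling
    timing: SequenceTiming
    calibration: np.ndarray
    noise_covariance: np.ndarray
    motion_amplitude: np.ndarray
    times: np.ndarray
    readout_oversampling: int = 2
    nx: int = 0
    voxel_size: float = 3.0
    weights: np.ndarray | None = None

    @property
    def n_profiles(self) -> int:
        return self.data.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[1]

    @property
    def n_coils(self) -> int:
        return self.data.shape[2]

    @property
    def n_readout(self) -> int:
        return self.data.shape[3]


def _fractional_kx_shift(lines: np.ndarray, delta: float) -> np.ndarray:
    """Resample k-lines at kx + delta (fractional samples), last axis."""
    n = lines.shape[-1]
    img = np.fft.ifft(np.fft.ifftshift(lines, axes=-1), axis=-1)
    x = np.arange(n)
    ramp = np.exp(-2j * np.pi * delta * x / n)
    return np.fft.fftshift(np.fft.fft(img * ramp, axis=-1), axes=-1)


def simulate_kspace(
    phantom: DigitalPhantom,
    timing: SequenceTiming,
    sampling: CASPRSampling,
    fat_spectrum: FatSpectrum,
    motion: MotionTrace | None = None,
    motion_gain: float = 5.0,
    noise_sd: float = 0.0,
    noise_covariance: np.ndarray | None = None,
    seed: int = 0,
    readout_oversampling: int = 2,
    fat_t1: float = 350.0,
    fat_t2: float = 50.0,
    echo_shift: float = 0.0,
    dictionary: BlochDictionary | None = None,
    time_step: float = 0.01,
) -> KSpaceData:
    """Forward-simulate the full accelerated acquisition.

    ``motion_gain`` converts surrogate units to mm of feet-head shift;
    ``echo_shift`` is the bipolar misalignment of echo 2 in k-space samples
    (also encoded in the opposite-polarity calibration pair).  If a
    ``dictionary`` is supplied, water timelines are looked up from their
    nearest atom instead of simulated directly (requires on-grid tissues).
    """
    nx, ny, nz = phantom.shape
    rng = np.random.default_rng(seed)
    nxo = nx * readout_oversampling
    n_echo = timing.n_echoes
    tt = phantom.tissue_table
    n_labels = tt.shape[0]
    if np.any((tt["t1"] <= 0) & (tt["proton_density"] > 0)) or np.any(
        (tt["t2"] <= 0) & (tt["proton_density"] > 0)
    ):
        raise ValueError("tissue relaxation times must be positive")

    # per-label timelines over one cycle
    n_prof_cycle = timing.n_profiles
    w_tl = np.zeros((n_labels, n_prof_cycle))
    f_tl = np.zeros((n_labels, n_prof_cycle))
    for lab in range(1, n_labels):
        if tt["proton_density"][lab] == 0:
            continue
        if dictionary is not None:
            idx = dictionary.atom_index(tt["t1"][lab], tt["t2"][lab], tt["b0"][lab])
            w_tl[lab] = dictionary.atoms[idx]
        else:
            w_tl[lab] = bloch_simulate(
                timing, tt["t1"][lab], tt["t2"][lab], tt["b0"][lab],
                time_step=time_step,
            ).values.real
        if tt["fat_fraction"][lab] > 0:
            f_tl[lab] = bloch_simulate(
                timing, fat_t1, fat_t2, tt["b0"][lab], time_step=time_step
            ).values.real

    # per-coil, per-label k-space basis volumes (x zero-padded for oversampling)
    x0 = (nxo - nx) // 2
    n_coils = phantom.n_coils
    G = np.zeros((n_coils, n_labels, nxo, ny, nz), np.complex64)
    for lab in range(1, n_labels):
        ind = (phantom.label_map == lab).astype(float)
        if not ind.any():
            continue
        for c in range(n_coils):
            vol = np.zeros((nxo, ny, nz), np.complex128)
            vol[x0:x0 + nx] = phantom.coil_maps[c] * ind
            G[c, lab] = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol)))

    coords = sampling.profile_coords
    cyc = sampling.cycle_profile_index()
    times = sampling.profile_times(timing)
    m_amp = motion.at(times) if motion is not None else np.zeros(times.size)

    c_e = np.array([fat_spectrum.dephasing(te) for te in timing.te])
    b0_ph = np.exp(
        2j * np.pi * tt["b0"][None, :, None] * 1e-3 * np.asarray(timing.te)[None, None, :]
    )  # (1, n_labels, n_echoes)
    pd = tt["proton_density"]
    ff = tt["fat_fraction"]
    # per-profile per-label per-echo complex amplitude
    amp = (
        pd[None, :, None]
        * ((1.0 - ff)[None, :, None] * w_tl.T[cyc][:, :, None]
           + ff[None, :, None] * c_e[None, None, :] * f_tl.T[cyc][:, :, None])
        * b0_ph
    )  # (n_profiles, n_labels, n_echoes)

    iy = coords[:, 0] + ny // 2
    iz = coords[:, 1] + nz // 2
    # gather k-lines: (n_coils, n_labels, n_profiles, nxo) -> weighted sum
    lines = G[:, :, :, iy, iz]  # (n_coils, n_labels, nxo, n_profiles)
    data = np.einsum("clxn,nle->necx", lines, amp).astype(np.complex64)

    # rigid feet-head shift: linear phase along the oversampled readout
    if motion is not None and motion_gain != 0.0:
        kx = np.arange(nxo) - nxo // 2
        fov_x = nxo * phantom.voxel_size
        shift_mm = m_amp * motion_gain
        ramp = np.exp(-2j * np.pi * kx[None, :] * shift_mm[:, None] / fov_x)
        data *= ramp[:, None, None, :].astype(np.complex64)

    # bipolar echo misalignment on echo 2
    if echo_shift != 0.0 and n_echo > 1:
        data[:, 1] = _fractional_kx_shift(data[:, 1], echo_shift)

    # opposite-polarity DC calibration pair (equilibrium-weighted, echo-1 TE)
    dc_amp = pd * ((1.0 - ff) + ff * c_e[0]) * np.exp(
        2j * np.pi * tt["b0"] * 1e-3 * timing.te[0]
    ) * np.sin(np.deg2rad(timing.flip_deg))
    cal_line = np.einsum(
        "clx,l->cx", G[:, :, :, ny // 2, nz // 2], dc_amp
    )
    calibration = np.stack([cal_line, _fractional_kx_shift(cal_line, echo_shift)])

    if noise_covariance is None:
        noise_covariance = np.eye(n_coils) * noise_sd**2
    noise_covariance = np.asarray(noise_covariance, complex)
    if noise_sd > 0 or np.any(noise_covariance != 0):
        L = np.linalg.cholesky(noise_covariance + 1e-30 * np.eye(n_coils))
        shp = (sampling.n_profiles, n_echo, n_coils, nxo)
        white = rng.normal(size=shp) + 1j * rng.normal(size=shp)
        data = data + np.einsum("ij,nejx->neix", L, white).astype(np.complex64)
        wc = rng.normal(size=(2, n_coils, nxo)) + 1j * rng.normal(size=(2, n_coils, nxo))
        calibration = calibration + np.einsum("ij,pjx->pix", L, wc)

    return KSpaceData(
        data=data,
        sampling=sampling,
        timing=timing,
        calibration=calibration.astype(np.complex64),
        noise_covariance=noise_covariance,
        motion_amplitude=m_amp,
        times=times,
        readout_oversampling=readout_oversampling,
        nx=nx,
        voxel_size=phantom.voxel_size,
    )
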