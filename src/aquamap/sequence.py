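"""Pulse-sequence timing, mBIR-4 waveform synthesis and Bloch dictionary simulation.

The acquisition interleaves four 3-s blocks, each consisting of an adiabatic
mBIR-4 preparation pulse followed by a Look-Locker train of seven spoiled
gradient-echo shots (60 profiles per shot, TR 3.4 ms, two bipolar echoes).
Blocks differ in the total preparation-pulse duration (gaps inserted into the
10-ms active waveform lengthen transverse-relaxation exposure and hence the T2
weighting) and in the pulse angle: blocks 1-3 use the pulse as an adiabatic
inversion (180 deg), block 4 as a T2prep (0 deg net rotation).  Block 1 adds an
extra 200-ms delay (TD1) between preparation and readout; the remainder of each
block is a recovery pause (TD2).

The Bloch engine propagates the full RF amplitude/phase modulation of the
mBIR-4 pulse with hard-pulse steps (default 10 us) and closed-form relaxation
between events, assuming ideally spoiled readouts and no T2* decay.  Because
transverse magnetization is spoiled every TR, the recorded per-profile signal
is real (sin(alpha) * Mz at excitation); the constant per-echo off-resonance
phase exp(i 2 pi B0 TE) is applied by the forward model and the water-fat
stage, not stored in the dictionary.

The periodic steady state of the 12-s four-block cycle is obtained exactly:
the cycle acts on the longitudinal magnetization as a scalar affine map
Mz -> a*Mz + b, whose fixed point b/(1-a) is the steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence as _Seq

import numba
import numpy as np

__all__ = [
    "SequenceTiming",
    "RFWaveform",
    "DictionaryGrid",
    "SignalTimeline",
    "BlochDictionary",
    "build_timing",
    "mbir4_waveform",
    "bloch_simulate",
    "build_dictionary",
    "prep_propagator",
]

# gyromagnetic ratio of 1H, kHz per microtesla (42.577 Hz/uT)
GAMMA_KHZ_PER_UT = 42.5774688e-3

# mBIR-4 waveform design: printed hardware limits ...
MBIR4_PEAK_UT = 13.5       # peak B1 amplitude, uT
MBIR4_SWEEP_HZ = 3700.0    # maximum frequency-modulation offset, Hz
MBIR4_ACTIVE_MS = 10.0     # active (non-gap) duration, ms
# ... and the canonical tanh/tan modulation shape parameters (zeta = 10,
# tan(kappa) = 10), which keep the pulse adiabatic down to B1 scales of ~0.6
# at the 13.5 uT peak amplitude.
MBIR4_ZETA = 10.0
MBIR4_TAN_ARG = 10.0
MBIR4_KAPPA = float(np.arctan(MBIR4_TAN_ARG))

DEFAULT_TIME_STEP_MS = 0.01  # hard-pulse integration step during RF


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceTiming:
    """Block/shot/TR timing of the four-block Look-Locker acquisition (ms)."""

    n_blocks: int = 4
    block_duration: float = 3000.0
    prep_durations: tuple = (10.9, 25.9, 40.9, 55.9)
    prep_angles: tuple = (180.0, 180.0, 180.0, 0.0)
    td1: float = 200.0
    prep_to_readout_gap: float = 6.0
    shots_per_block: int = 7
    profiles_per_shot: int = 60
    tr: float = 3.4
    te: tuple = (1.0, 2.1)
    flip_deg: float = 3.0
    n_repetitions: int = 8

    def __post_init__(self):
        if len(self.prep_durations) != self.n_blocks:
            raise ValueError("prep_durations must have one entry per block")
        if len(self.prep_angles) != self.n_blocks:
            raise ValueError("prep_angles must have one entry per block")
        if min(self.prep_durations) <= 0 or self.tr <= 0 or self.block_duration <= 0:
            raise ValueError("durations must be positive")
        if self.td1 < 0 or self.prep_to_readout_gap < 0:
            raise ValueError("delays must be non-negative")
        if any(t <= 0 for t in self.te) or max(self.te) >= self.tr:
            raise ValueError("echo times must lie inside the TR")
        for b in range(self.n_blocks):
            if self.recovery_pause(b) < 0:
                raise ValueError(
                    f"block {b + 1}: readout train does not fit into the "
                    f"{self.block_duration} ms block (negative recovery pause)"
                )

    @property
    def n_echoes(self) -> int:
        return len(self.te)

    @property
    def shot_duration(self) -> float:
        """Duration of one shot's readout train, ms."""
        return self.profiles_per_shot * self.tr

    @property
    def profiles_per_block(self) -> int:
        return self.shots_per_block * self.profiles_per_shot

    @property
    def n_profiles(self) -> int:
        """Profiles in one four-block cycle (the dictionary timeline length)."""
        return self.n_blocks * self.profiles_per_block

    def pre_readout_delay(self, block: int) -> float:
        """Delay between preparation end and first excitation (0-based block)."""
        return self.prep_to_readout_gap + (self.td1 if block == 0 else 0.0)

    def recovery_pause(self, block: int) -> float:
        """TD2: pause filling the block to block_duration, ms (0-based block)."""
        return (
            self.block_duration
            - self.prep_durations[block]
            - self.pre_readout_delay(block)
            - self.shots_per_block * self.shot_duration
        )

    def inversion_times(self, block: int) -> np.ndarray:
        """TI of each shot: delay from preparation end to the shot's k-space
        center (= first) profile, ms (0-based block)."""
        s = np.arange(self.shots_per_block)
        return self.pre_readout_delay(block) + s * self.shot_duration

    def profile_times(self) -> np.ndarray:
        """Excitation time of every profile in one cycle, ms from cycle start."""
        t = np.empty(self.n_profiles)
        j = np.arange(self.profiles_per_block)
        for b in range(self.n_blocks):
            start = (
                b * self.block_duration
                + self.prep_durations[b]
                + self.pre_readout_delay(b)
            )
            t[b * self.profiles_per_block:(b + 1) * self.profiles_per_block] = (
                start + j * self.tr
            )
        return t


def build_timing(config: dict | None = None) -> SequenceTiming:
    """Build a validated :class:`SequenceTiming` from a configuration mapping.

    Unknown keys are rejected; timings are independent of the matrix size.
    """
    config = dict(config or {})
    known = {f for f in SequenceTiming.__dataclass_fields__}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown sequence config keys: {sorted(unknown)}")
    for key in ("prep_durations", "prep_angles", "te"):
        if key in config:
            config[key] = tuple(config[key])
    return SequenceTiming(**config)


# ---------------------------------------------------------------------------
# mBIR-4 waveform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFWaveform:
    """Sampled RF waveform: amplitude (uT), phase (rad) and gap mask."""

    time_step: float
    amplitude: np.ndarray
    phase: np.ndarray
    gap_mask: np.ndarray

    @property
    def duration(self) -> float:
        return self.amplitude.size * self.time_step

    @property
    def active_duration(self) -> float:
        return float((~self.gap_mask).sum()) * self.time_step


def _mbir4_segments(time_step: float, pulse_angle: float):
    """Amplitude (uT) and phase (rad) samples of the four active segments.

    Returns (amp1, ph1), (amp23, ph23), (amp4, ph4) with the two middle
    segments merged (they are contiguous; the gaps sit at the outer segment
    boundaries, where the amplitude modulation passes through zero).
    """
    seg_ms = MBIR4_ACTIVE_MS / 4.0
    n = seg_ms / time_step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"time_step {time_step} ms does not evenly tile the "
            f"{seg_ms} ms segment duration"
        )
    n = int(round(n))
    # midpoint sampling of the normalized segment coordinate x in [0, 1]
    x = (np.arange(n) + 0.5) / n
    z, k = MBIR4_ZETA, MBIR4_KAPPA
    a_fall = np.tanh(z * (1.0 - x))          # 1 -> 0
    a_rise = np.tanh(z * x)                  # 0 -> 1
    f_up = np.tan(k * x) / np.tan(k)         # 0 -> +1
    f_dn = np.tan(k * (x - 1.0)) / np.tan(k)  # -1 -> 0
    # BIR-4 inter-segment phase jumps realise the net rotation angle
    dphi = np.pi + np.deg2rad(pulse_angle) / 2.0

    amp = MBIR4_PEAK_UT * np.concatenate([a_fall, a_rise, a_fall, a_rise])
    freq = np.concatenate([f_up, f_dn, f_up, f_dn])
    # frequency modulation integrated to a phase that accumulates continuously
    # over the whole active waveform (the phase register holds during gaps);
    # midpoint rule to match the midpoint amplitude sampling
    f_khz = MBIR4_SWEEP_HZ * 1e-3 * freq
    ph = 2.0 * np.pi * (np.cumsum(f_khz) - 0.5 * f_khz) * time_step
    ph[n:3 * n] += dphi  # inner segment pair phase jump (undone before seg 4)
    return (amp[:n], ph[:n]), (amp[n:3 * n], ph[n:3 * n]), (amp[3 * n:], ph[3 * n:])


def mbir4_waveform(
    total_duration: float,
    pulse_angle: float,
    time_step: float = DEFAULT_TIME_STEP_MS,
) -> RFWaveform:
    """Synthesize the gapped mBIR-4 waveform.

    The active tanh/tan-modulated BIR-4 waveform lasts 10 ms; two equal gaps
    (RF off, free relaxation/precession) are inserted at the outer segment
    boundaries so the total duration equals ``total_duration``, providing the
    T2 weighting of the preparation.
    """
    if total_duration < MBIR4_ACTIVE_MS:
        raise ValueError("total_duration must be at least the 10 ms active duration")
    if pulse_angle not in (0.0, 180.0, 0, 180):
        raise ValueError("pulse_angle must be 0 or 180 degrees")
    (a1, p1), (a23, p23), (a4, p4) = _mbir4_segments(time_step, float(pulse_angle))
    gap_total = total_duration - MBIR4_ACTIVE_MS
    n_gap = int(round(gap_total / 2.0 / time_step))
    zeros = np.zeros(n_gap)
    amp = np.concatenate([a1, zeros, a23, zeros, a4])
    ph = np.concatenate([p1, zeros, p23, zeros, p4])
    gap = np.concatenate(
        [
            np.zeros(a1.size, bool),
            np.ones(n_gap, bool),
            np.zeros(a23.size, bool),
            np.ones(n_gap, bool),
            np.zeros(a4.size, bool),
        ]
    )
    return RFWaveform(time_step=time_step, amplitude=amp, phase=ph, gap_mask=gap)


# ---------------------------------------------------------------------------
# dictionary grid
# ---------------------------------------------------------------------------

def _default_t1_grid() -> np.ndarray:
    return np.concatenate([np.arange(105.0, 1500.0 + 1e-9, 15.0),
                           np.arange(1550.0, 3000.0 + 1e-9, 50.0)])


def _default_t2_grid() -> np.ndarray:
    return np.arange(9.0, 120.0 + 1e-9, 1.5)


@dataclass(frozen=True)
class DictionaryGrid:
    """(T1, T2, B0) grid over which the dictionary is simulated."""

    t1_values: np.ndarray = field(default_factory=_default_t1_grid)
    t2_values: np.ndarray = field(default_factory=_default_t2_grid)
    b0_values: np.ndarray = field(default_factory=lambda: np.arange(-200.0, 201.0, 20.0))
    b1_scale: float = 1.0

    def __post_init__(self):
        for name in ("t1_values", "t2_values", "b0_values"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        if np.any(self.t1_values <= 0) or np.any(self.t2_values <= 0):
            raise ValueError("relaxation times must be positive")

    @classmethod
    def default_mapping(cls) -> "DictionaryGrid":
        """Grid used to learn the subspace basis (B0 in +-200 Hz)."""
        return cls()

    @classmethod
    def default_matching(cls) -> "DictionaryGrid":
        """Extended-B0 grid (+-300 Hz) used for B0-specific matching."""
        return cls(b0_values=np.arange(-300.0, 301.0, 20.0))

    @property
    def n_atoms(self) -> int:
        return self.t1_values.size * self.t2_values.size * self.b0_values.size

    def params(self) -> np.ndarray:
        """(n_atoms, 3) table of (T1, T2, B0), lexicographic over (B0, T1, T2)."""
        b0, t1, t2 = np.meshgrid(
            self.b0_values, self.t1_values, self.t2_values, indexing="ij"
        )
        return np.column_stack([t1.ravel(), t2.ravel(), b0.ravel()])


# ---------------------------------------------------------------------------
# Bloch engine
# ---------------------------------------------------------------------------

@numba.njit(cache=True, fastmath=True)
def _propagate_affine(rot, e1, e2):  # pragma: no cover - exercised via callers
    """Propagate the affine spin map M -> A M + c through a hard-pulse train.

    rot: (n_b0, n_steps, 3, 3) per-step rotations; e1/e2: (n_pairs,) per-step
    relaxation factors.  Returns (n_b0, n_pairs, 3, 4) with columns 0..2 = A
    and column 3 = c.
    """
    n_b0, n_steps = rot.shape[0], rot.shape[1]
    n_p = e1.shape[0]
    out = np.empty((n_b0, n_p, 3, 4))
    for ib in range(n_b0):
        r = rot[ib]
        for ip in range(n_p):
            E1 = e1[ip]
            E2 = e2[ip]
            rec = 1.0 - E1
            m = np.zeros((3, 4))
            m[0, 0] = 1.0
            m[1, 1] = 1.0
            m[2, 2] = 1.0
            for it in range(n_steps):
                r00 = r[it, 0, 0]; r01 = r[it, 0, 1]; r02 = r[it, 0, 2]
                r10 = r[it, 1, 0]; r11 = r[it, 1, 1]; r12 = r[it, 1, 2]
                r20 = r[it, 2, 0]; r21 = r[it, 2, 1]; r22 = r[it, 2, 2]
                for j in range(4):
                    x = m[0, j]; y = m[1, j]; z = m[2, j]
                    m[0, j] = (r00 * x + r01 * y + r02 * z) * E2
                    m[1, j] = (r10 * x + r11 * y + r12 * z) * E2
                    m[2, j] = (r20 * x + r21 * y + r22 * z) * E1
                m[2, 3] += rec
            out[ib, ip] = m
    return out


def _step_rotations(amp_ut, phase, b0_hz, b1_scale, dt_ms):
    """Rodrigues rotation matrices for each (b0, RF sample)."""
    w1 = 2.0 * np.pi * GAMMA_KHZ_PER_UT * b1_scale * amp_ut  # rad/ms
    wz = 2.0 * np.pi * np.asarray(b0_hz, float)[:, None] * 1e-3  # rad/ms
    n_b0 = wz.shape[0]
    n_s = amp_ut.shape[0]
    wxb = np.broadcast_to(w1 * np.cos(phase), (n_b0, n_s))
    wyb = np.broadcast_to(w1 * np.sin(phase), (n_b0, n_s))
    wzb = np.broadcast_to(wz, (n_b0, n_s))
    mag = np.sqrt(wxb**2 + wyb**2 + wzb**2)
    ang = -mag * dt_ms  # left-handed precession convention
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(mag > 0, wxb / np.where(mag > 0, mag, 1.0), 0.0)
        uy = np.where(mag > 0, wyb / np.where(mag > 0, mag, 1.0), 0.0)
        uz = np.where(mag > 0, wzb / np.where(mag > 0, mag, 1.0), 0.0)
    c, s = np.cos(ang), np.sin(ang)
    one_c = 1.0 - c
    R = np.empty((n_b0, n_s, 3, 3))
    R[..., 0, 0] = c + ux * ux * one_c
    R[..., 0, 1] = ux * uy * one_c - uz * s
    R[..., 0, 2] = ux * uz * one_c + uy * s
    R[..., 1, 0] = uy * ux * one_c + uz * s
    R[..., 1, 1] = c + uy * uy * one_c
    R[..., 1, 2] = uy * uz * one_c - ux * s
    R[..., 2, 0] = uz * ux * one_c - uy * s
    R[..., 2, 1] = uz * uy * one_c + ux * s
    R[..., 2, 2] = c + uz * uz * one_c
    return R


def _relax_factors(t1, t2, dt):
    e1 = np.exp(-dt / np.asarray(t1, float))
    e2 = np.exp(-dt / np.asarray(t2, float))
    return e1, e2


def _free_precession_affine(b0_hz, tau_ms, t1, t2):
    """Closed-form affine (A, c) for free precession + relaxation over tau.

    Shapes: A (n_b0, n_p, 3, 3), c (n_b0, n_p, 3)."""
    n_b0 = np.asarray(b0_hz, float).size
    n_p = np.asarray(t1, float).size
    e1, e2 = _relax_factors(t1, t2, tau_ms)
    phi = 2.0 * np.pi * np.asarray(b0_hz, float) * 1e-3 * tau_ms
    # left-handed convention to match _step_rotations
    cph, sph = np.cos(-phi), np.sin(-phi)
    A = np.zeros((n_b0, n_p, 3, 3))
    A[..., 0, 0] = cph[:, None] * e2[None, :]
    A[..., 0, 1] = -sph[:, None] * e2[None, :]
    A[..., 1, 0] = sph[:, None] * e2[None, :]
    A[..., 1, 1] = cph[:, None] * e2[None, :]
    A[..., 2, 2] = e1[None, :] * np.ones((n_b0, 1))
    c = np.zeros((n_b0, n_p, 3))
    c[..., 2] = 1.0 - e1[None, :]
    return A, c


def _compose(A2, c2, A1, c1):
    """(A2, c2) o (A1, c1): first apply 1, then 2."""
    A = np.einsum("...ij,...jk->...ik", A2, A1)
    c = np.einsum("...ij,...j->...i", A2, c1) + c2
    return A, c


_SEGMENT_CACHE: dict = {}


def _segment_affines(angle, t1, t2, b0_hz, b1_scale, time_step):
    """Affine maps of the three active mBIR-4 chunks (seg1, seg2+3, seg4)."""
    (a1, p1), (a23, p23), (a4, p4) = _mbir4_segments(time_step, angle)
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    e1, e2 = _relax_factors(t1, t2, time_step)
    out = []
    for amp, ph in ((a1, p1), (a23, p23), (a4, p4)):
        rot = _step_rotations(amp, ph, b0_hz, b1_scale, time_step)
        aff = _propagate_affine(np.ascontiguousarray(rot), e1, e2)
        out.append((np.ascontiguousarray(aff[..., :3]), np.ascontiguousarray(aff[..., 3])))
    return out


def prep_propagator(
    total_duration: float,
    pulse_angle: float,
    t1,
    t2,
    b0_hz,
    b1_scale: float = 1.0,
    time_step: float = DEFAULT_TIME_STEP_MS,
):
    """Affine map (A, c) of one gapped mBIR-4 preparation, M -> A M + c.

    ``t1``/``t2`` are parallel arrays of relaxation-time pairs (use np.inf to
    disable relaxation); ``b0_hz`` an array of off-resonance values.  Returns
    A with shape (n_b0, n_pairs, 3, 3) and c with shape (n_b0, n_pairs, 3).
    """
    t1 = np.atleast_1d(np.asarray(t1, float))
    t2 = np.atleast_1d(np.asarray(t2, float))
    b0_hz = np.atleast_1d(np.asarray(b0_hz, float))
    (A1, c1), (A23, c23), (A4, c4) = _segment_affines(
        float(pulse_angle), t1, t2, b0_hz, b1_scale, time_step
    )
    gap = (total_duration - MBIR4_ACTIVE_MS) / 2.0
    if gap < -1e-9:
        raise ValueError("total_duration shorter than the active pulse")
    Ag, cg = _free_precession_affine(b0_hz, max(gap, 0.0), t1, t2)
    A, c = _compose(Ag, cg, A1, c1)
    A, c = _compose(A23, c23, A, c)
    A, c = _compose(Ag, cg, A, c)
    A, c = _compose(A4, c4, A, c)
    return A, c


# ---------------------------------------------------------------------------
# timeline simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalTimeline:
    """Per-profile complex transverse signal over one four-block cycle."""

    values: np.ndarray
    profile_times: np.ndarray


def _simulate_timelines(
    timing: SequenceTiming,
    t1,
    t2,
    b0_hz,
    b1_scale: float = 1.0,
    time_step: float = DEFAULT_TIME_STEP_MS,
    ideal_prep: bool = False,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate steady-state timelines for all (b0 x (t1, t2)) combinations.

    Returns (or fills ``out`` with) an array of shape
    (n_profiles, n_b0 * n_pairs) holding sin(alpha) * Mz at each excitation.
    """
    t1 = np.atleast_1d(np.asarray(t1, float))
    t2 = np.atleast_1d(np.asarray(t2, float))
    b0_hz = np.atleast_1d(np.asarray(b0_hz, float))
    n_p, n_b0 = t1.size, b0_hz.size
    n_atoms = n_b0 * n_p

    alpha = np.deg2rad(timing.flip_deg * b1_scale)
    cosa, sina = np.cos(alpha), np.sin(alpha)
    e1_tr = np.exp(-timing.tr / t1)                      # (n_p,)
    a_tr = e1_tr * cosa
    b_tr = 1.0 - e1_tr

    # longitudinal prep response per block: Mz -> a_prep Mz + b_prep
    a_prep = np.empty((timing.n_blocks, n_b0, n_p))
    b_prep = np.empty((timing.n_blocks, n_b0, n_p))
    if ideal_prep:
        for b in range(timing.n_blocks):
            a_prep[b] = np.cos(np.deg2rad(timing.prep_angles[b]))
            b_prep[b] = 0.0
    else:
        for b in range(timing.n_blocks):
            A, c = prep_propagator(
                timing.prep_durations[b],
                timing.prep_angles[b],
                t1,
                t2,
                b0_hz,
                b1_scale,
                time_step,
            )
            a_prep[b] = A[..., 2, 2]
            b_prep[b] = c[..., 2]

    def delay_op(tau):
        e = np.exp(-tau / t1)[None, :]
        return e, 1.0 - e

    n_tr = timing.profiles_per_block
    # n-fold composition of the constant TR map
    a_train = a_tr**n_tr
    with np.errstate(divide="ignore", invalid="ignore"):
        geo = np.where(np.abs(1.0 - a_tr) > 1e-14,
                       (1.0 - a_train) / (1.0 - a_tr), float(n_tr))
    b_train = b_tr * geo

    # compose the full cycle map Mz -> a_cyc Mz + b_cyc
    a_cyc = np.ones((n_b0, n_p))
    b_cyc = np.zeros((n_b0, n_p))

    def apply(a_op, b_op):
        nonlocal a_cyc, b_cyc
        a_cyc = a_op * a_cyc
        b_cyc = a_op * b_cyc + b_op

    for b in range(timing.n_blocks):
        apply(a_prep[b], b_prep[b])
        apply(*delay_op(timing.pre_readout_delay(b)))
        apply(a_train[None, :], b_train[None, :])
        apply(*delay_op(timing.recovery_pause(b)))

    with np.errstate(divide="ignore", invalid="ignore"):
        mz0 = b_cyc / (1.0 - a_cyc)
    mz0 = np.where(np.abs(1.0 - a_cyc) > 1e-14, mz0, 0.0)

    # record one cycle from the steady state
    if out is None:
        out = np.empty((timing.n_profiles, n_atoms), np.float64)
    mz = mz0.reshape(-1).copy()
    a_tr_f = np.broadcast_to(a_tr, (n_b0, n_p)).reshape(-1)
    b_tr_f = np.broadcast_to(b_tr, (n_b0, n_p)).reshape(-1)
    n = 0
    for b in range(timing.n_blocks):
        mz = (a_prep[b] * mz.reshape(n_b0, n_p) + b_prep[b]).reshape(-1)
        e, r = delay_op(timing.pre_readout_delay(b))
        mz = (e * mz.reshape(n_b0, n_p) + r).reshape(-1)
        for _ in range(n_tr):
            out[n] = sina * mz
            mz = a_tr_f * mz + b_tr_f
            n += 1
        e, r = delay_op(timing.recovery_pause(b))
        mz = (e * mz.reshape(n_b0, n_p) + r).reshape(-1)
    return out


def bloch_simulate(
    timing: SequenceTiming,
    t1: float,
    t2: float,
    b0: float = 0.0,
    b1: float = 1.0,
    time_step: float = DEFAULT_TIME_STEP_MS,
    ideal_prep: bool = False,
) -> SignalTimeline:
    """Steady-state signal timeline for a single (T1, T2, B0, B1) combination.

    One complex value per profile (real-valued here: spoiled readout, echo
    phase applied downstream), taken immediately after each excitation.
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("t1 and t2 must be positive")
    sig = _simulate_timelines(
        timing, [t1], [t2], [b0], b1, time_step, ideal_prep=ideal_prep
    )[:, 0]
    if not np.all(np.isfinite(sig)):
        raise RuntimeError("Bloch simulation produced non-finite values")
    return SignalTimeline(values=sig.astype(complex), profile_times=timing.profile_times())


# ---------------------------------------------------------------------------
# dictionary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlochDictionary:
    """Simulated signal timelines over a (T1, T2, B0) grid.

    ``atoms`` has shape (n_atoms, n_profiles); rows are ordered
    lexicographically over (B0, T1, T2) as produced by
    :meth:`DictionaryGrid.params`.  Atoms are stored as float32 (see module
    docstring for why timelines are real).
    """

    atoms: np.ndarray
    params: np.ndarray
    grid: DictionaryGrid
    timing: SequenceTiming

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    def atom_index(self, t1: float, t2: float, b0: float = 0.0) -> int:
        i1 = int(np.argmin(np.abs(self.grid.t1_values - t1)))
        i2 = int(np.argmin(np.abs(self.grid.t2_values - t2)))
        ib = int(np.argmin(np.abs(self.grid.b0_values - b0)))
        n1, n2 = self.grid.t1_values.size, self.grid.t2_values.size
        return (ib * n1 + i1) * n2 + i2


def build_dictionary(
    grid: DictionaryGrid,
    timing: SequenceTiming,
    time_step: float = DEFAULT_TIME_STEP_MS,
    dtype=np.float32,
) -> BlochDictionary:
    """Bloch-simulate the full dictionary over ``grid``.

    Deterministic for a fixed configuration.  The (T1, T2) pair grid is
    simulated jointly for all B0 values; B0 enters the preparation-pulse
    propagation and the downstream echo phase only.
    """
    t1g, t2g = np.meshgrid(grid.t1_values, grid.t2_values, indexing="ij")
    t1p, t2p = t1g.ravel(), t2g.ravel()
    n_profiles = timing.n_profiles
    sig = np.empty((n_profiles, grid.n_atoms), dtype)
    buf = _simulate_timelines(
        timing, t1p, t2p, grid.b0_values, grid.b1_scale, time_step,
        out=np.empty((n_profiles, grid.n_atoms), np.float64),
    )
    if not np.all(np.isfinite(buf)):
        bad = np.argwhere(~np.isfinite(buf))
        atom = bad[0, 1]
        params = grid.params()[atom]
        raise RuntimeError(
            f"non-finite Bloch simulation at (T1, T2, B0) = {tuple(params)}"
        )
    sig[:] = buf
    return BlochDictionary(atoms=sig.T, params=grid.params(), grid=grid, timing=timing)
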