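"""Golden-step CASPR profile ordering on the Cartesian ky-kz grid.

Each shot acquires 60 phase-encode profiles that walk outward from the
k-space center along an approximately Archimedean spiral inside an elliptical
shutter; the spiral's start angle advances by the golden angle from shot to
shot, so the 28 contrasts (4 blocks x 7 shots) accumulate complementary,
largely non-overlapping profile sets over the repetitions.  The
frequency-encoding (readout) direction is fully sampled and is the feet-head
axis; sampling here concerns (ky, kz) only.

Spiral construction: candidate shutter points are claimed greedily - for each
of the 60 radial steps the grid point nearest (in shutter
normalized coordinates) to the continuous spiral that has not yet been
claimed by this shot is taken, ties broken toward the smaller angle and then
the smaller radius.  Profiles are then ordered by non-decreasing radius, so
every shot starts at the k-space center (its k-space-center profile defines
the shot's inversion time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import SequenceTiming

__all__ = ["CASPRSampling", "generate_sampling", "density_compensation"]

GOLDEN_ANGLE_RAD = 2.0 * np.pi * (1.0 - 2.0 / (1.0 + np.sqrt(5.0)))
DEFAULT_TURNS = 1.0  # spiral turns from center to shutter edge per shot


@dataclass(frozen=True)
class CASPRSampling:
    """Ordered profile schedule.

    ``coords``: (n_shots, profiles_per_shot, 2) integer (ky, kz);
    per-shot metadata arrays are parallel to the first axis.  Shots are in
    acquisition order: repetition-major, then block, then shot-in-block.
    """

    coords: np.ndarray
    block_index: np.ndarray
    shot_index: np.ndarray
    repetition: np.ndarray
    golden_index: np.ndarray
    grid_shape: tuple
    acceleration: float
    n_repetitions: int
    shots_per_block: int

    @property
    def n_shots(self) -> int:
        return self.coords.shape[0]

    @property
    def profiles_per_shot(self) -> int:
        return self.coords.shape[1]

    @property
    def n_profiles(self) -> int:
        return self.n_shots * self.profiles_per_shot

    @property
    def n_contrasts(self) -> int:
        return int(self.block_index.max() + 1) * self.shots_per_block

    @property
    def contrast_index(self) -> np.ndarray:
        """Contrast (block, shot) label of every shot."""
        return self.block_index * self.shots_per_block + self.shot_index

    @property
    def profile_coords(self) -> np.ndarray:
        """(n_profiles, 2) coordinates in acquisition order."""
        return self.coords.reshape(-1, 2)

    @property
    def profile_contrast(self) -> np.ndarray:
        return np.repeat(self.contrast_index, self.profiles_per_shot)

    def profile_times(self, timing: SequenceTiming) -> np.ndarray:
        """Acquisition (excitation) time of every profile, ms from scan start."""
        cycle = timing.profile_times()
        per_block = timing.profiles_per_block
        t = np.empty(self.n_profiles)
        p = self.profiles_per_shot
        for i in range(self.n_shots):
            base = self.repetition[i] * timing.n_blocks * timing.block_duration
            j = self.block_index[i] * per_block + self.shot_index[i] * p
            t[i * p:(i + 1) * p] = base + cycle[j:j + p]
        return t

    def cycle_profile_index(self) -> np.ndarray:
        """Index of every profile into the one-cycle dictionary timeline."""
        p = self.profiles_per_shot
        base = (self.block_index * self.shots_per_block + self.shot_index) * p
        return (base[:, None] + np.arange(p)[None, :]).reshape(-1)


def _shutter_points(ny: int, nz: int) -> np.ndarray:
    ky = np.arange(-(ny // 2), (ny + 1) // 2)
    kz = np.arange(-(nz // 2), (nz + 1) // 2)
    gy, gz = np.meshgrid(ky, kz, indexing="ij")
    r = (gy / (ny / 2.0)) ** 2 + (gz / (nz / 2.0)) ** 2
    mask = r <= 1.0 + 1e-12
    return np.column_stack([gy[mask], gz[mask]])


def shutter_area(ny: int, nz: int) -> int:
    """Number of grid points inside the elliptical shutter."""
    return _shutter_points(ny, nz).shape[0]


def _spiral_shot(points_n, angles, radii, theta0, turns, p):
    """Claim p grid points along the spiral starting at angle theta0.

    points_n: (m, 2) shutter points in normalized coordinates; angles/radii
    their polar representation.  Returns indices into the shutter table.
    """
    m = points_n.shape[0]
    claimed = np.zeros(m, bool)
    out = np.empty(p, np.int64)
    # linear radial progression: denser near the center, matching the
    # profile ordering's deliberate oversampling of the k-space center
    rho = np.arange(p) / (p - 1.0)
    theta = theta0 + 2.0 * np.pi * turns * rho
    tx = rho * np.cos(theta)
    ty = rho * np.sin(theta)
    for j in range(p):
        d2 = (points_n[:, 0] - tx[j]) ** 2 + (points_n[:, 1] - ty[j]) ** 2
        d2[claimed] = np.inf
        dmin = d2.min()
        cand = np.flatnonzero(d2 <= dmin + 1e-12)
        if cand.size > 1:  # tie: smaller angle, then smaller radius
            order = np.lexsort((radii[cand], angles[cand]))
            pick = cand[order[0]]
        else:
            pick = cand[0]
        claimed[pick] = True
        out[j] = pick
    return out


def generate_sampling(
    ny: int,
    nz: int,
    timing: SequenceTiming,
    r: float = 7.5,
    n_repetitions: int | None = None,
    turns: float = DEFAULT_TURNS,
) -> CASPRSampling:
    """Generate the deterministic golden-step CASPR schedule.

    The number of repetitions N defaults to ceil(shutter_area / (R * profiles
    per shot)) so that each of the contrasts samples approximately
    shutter_area / R distinct profiles (duplicate sampling of low-frequency
    profiles across repetitions is expected and handled by the density
    compensation).
    """
    if ny < 8 or nz < 8:
        raise ValueError("grid too small (need ny, nz >= 8)")
    p = timing.profiles_per_shot
    pts = _shutter_points(ny, nz)
    if pts.shape[0] < p:
        raise ValueError(f"shutter holds {pts.shape[0]} points < {p} profiles per shot")
    if n_repetitions is None:
        n_repetitions = max(1, int(np.ceil(pts.shape[0] / (r * p))))
    pts_n = pts / np.array([ny / 2.0, nz / 2.0])
    angles = np.mod(np.arctan2(pts_n[:, 1], pts_n[:, 0]), 2.0 * np.pi)
    radii = np.hypot(pts_n[:, 0], pts_n[:, 1])

    n_shots = n_repetitions * timing.n_blocks * timing.shots_per_block
    coords = np.empty((n_shots, p, 2), np.int32)
    block = np.empty(n_shots, np.int32)
    shot = np.empty(n_shots, np.int32)
    rep = np.empty(n_shots, np.int32)
    gold = np.arange(n_shots, dtype=np.int32)
    i = 0
    for rr in range(n_repetitions):
        for b in range(timing.n_blocks):
            for s in range(timing.shots_per_block):
                idx = _spiral_shot(pts_n, angles, radii, gold[i] * GOLDEN_ANGLE_RAD,
                                   turns, p)
                # order by non-decreasing radius (stable in claim order)
                order = np.argsort(radii[idx], kind="stable")
                coords[i] = pts[idx[order]]
                block[i], shot[i], rep[i] = b, s, rr
                i += 1
    return CASPRSampling(
        coords=coords,
        block_index=block,
        shot_index=shot,
        repetition=rep,
        golden_index=gold,
        grid_shape=(ny, nz),
        acceleration=float(r),
        n_repetitions=n_repetitions,
        shots_per_block=timing.shots_per_block,
    )


def density_compensation(sampling: CASPRSampling) -> np.ndarray:
    """Per-profile density-compensation weight, binned per contrast.

    Within each contrast, the duplicates of a sampled (ky, kz) location share
    unit total weight (each gets 1 / multiplicity)."""
    ny, nz = sampling.grid_shape
    coords = sampling.profile_coords
    flat = (coords[:, 0] + ny // 2) * nz + (coords[:, 1] + nz // 2)
    key = sampling.profile_contrast.astype(np.int64) * (ny * nz) + flat
    _, inverse, counts = np.unique(key, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]
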