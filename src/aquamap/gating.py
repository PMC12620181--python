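"""Respiratory motion states and soft-gating weights.

A surrogate respiratory amplitude m[n] is recorded per k-space profile.  Four
motion states are found by 1-D k-medoids clustering; the reference state
m_ref is the medoid of the most-populated cluster (the end-expiration
plateau dominates occupancy).  Profiles are then down-weighted - never
discarded - with a Gaussian in the distance from the reference,

    w[n] = exp(-(m[n] - m_ref)^2 / (2 sigma^2)),

whose full width at half maximum equals the distance from the reference to
the second-closest motion state m_ref2:

    sigma = |m_ref2 - m_ref| / (2 sqrt(2 ln 2)).

The effective acceleration after gating counts each k-space location at its
accumulated weight, capped at 1 for oversampled locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import CASPRSampling, shutter_area

__all__ = [
    "MotionStates",
    "SoftGatingWeights",
    "kmedoids_states",
    "softgating_weights",
    "effective_acceleration",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class MotionStates:
    """k-medoid motion states of a 1-D respiratory amplitude trace."""

    medoids: np.ndarray
    reference: float
    second_closest: float
    sigma: float
    degenerate: bool = False

    @property
    def fwhm(self) -> float:
        return abs(self.second_closest - self.reference)


@dataclass(frozen=True)
class SoftGatingWeights:
    """Per-profile soft-gating weights in (0, 1]."""

    weights: np.ndarray
    states: MotionStates


def _assign(values: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    return np.argmin(np.abs(values[:, None] - medoids[None, :]), axis=1)


def _cluster_medoid(values: np.ndarray) -> float:
    """Point of ``values`` minimizing the summed absolute distance.

    In 1-D this is the lower median, which is itself a data point."""
    v = np.sort(values)
    return float(v[(v.size - 1) // 2])


def kmedoids_states(trace, k: int = 4, seed: int = 0, max_iter: int = 100) -> MotionStates:
    """Cluster the 1-D amplitude trace into ``k`` motion states.

    Voronoi-style k-medoids (assignment / in-cluster medoid update, exact in
    1-D via the cluster median) from a seeded k-means++-like initialization.
    The reference state is the medoid of the largest cluster; the
    second-closest state is the medoid with the second-smallest distance to
    the reference.
    """
    values = np.asarray(getattr(trace, "amplitude", trace), float).ravel()
    if values.size < k:
        raise ValueError(f"trace length {values.size} < k = {k}")
    uniq = np.unique(values)
    if uniq.size == 1:
        return MotionStates(
            medoids=uniq, reference=float(uniq[0]), second_closest=float(uniq[0]),
            sigma=0.0, degenerate=True,
        )
    k_eff = min(k, uniq.size)
    rng = np.random.default_rng(seed)
    # seeded farthest-point-style init on the unique amplitudes
    medoids = [uniq[rng.integers(uniq.size)]]
    while len(medoids) < k_eff:
        d = np.min(np.abs(uniq[:, None] - np.array(medoids)[None, :]), axis=1)
        medoids.append(uniq[int(np.argmax(d))])
    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        labels = _assign(values, medoids)
        new = medoids.copy()
        for j in range(k_eff):
            sel = values[labels == j]
            if sel.size:
                new[j] = _cluster_medoid(sel)
        new = np.sort(new)
        if np.array_equal(new, medoids):
            break
        medoids = new
    labels = _assign(values, medoids)
    counts = np.bincount(labels, minlength=k_eff)
    ref = float(medoids[int(np.argmax(counts))])
    order = np.argsort(np.abs(medoids - ref), kind="stable")
    if medoids.size < 2 or medoids[order[1]] == ref:
        return MotionStates(
            medoids=medoids, reference=ref, second_closest=ref, sigma=0.0,
            degenerate=True,
        )
    second = float(medoids[order[1]])
    sigma = abs(second - ref) / _FWHM
    return MotionStates(
        medoids=medoids, reference=ref, second_closest=second, sigma=sigma
    )


def softgating_weights(trace, states: MotionStates) -> SoftGatingWeights:
    """Gaussian soft-gating weight of every profile.

    With a degenerate (zero-width) state set the gate collapses to
    all-or-nothing: weight 1 at the reference amplitude, 0 elsewhere."""
    values = np.asarray(getattr(trace, "amplitude", trace), float).ravel()
    if states.sigma <= 0:
        w = np.where(values == states.reference, 1.0, 0.0)
        return SoftGatingWeights(weights=w, states=states)
    w = np.exp(-((values - states.reference) ** 2) / (2.0 * states.sigma**2))
    return SoftGatingWeights(weights=w, states=states)


def effective_acceleration(
    weights: SoftGatingWeights | np.ndarray, sampling: CASPRSampling
) -> float:
    """Effective acceleration R_eff after soft-gating.

    Per contrast, each sampled location contributes its accumulated weight
    capped at 1 (oversampled profiles cannot count more than once); R_eff is
    shutter_area over that sum, averaged over contrasts."""
    w = np.asarray(getattr(weights, "weights", weights), float).ravel()
    if w.size != sampling.n_profiles:
        raise ValueError("weights not aligned with the sampling schedule")
    ny, nz = sampling.grid_shape
    area = shutter_area(ny, nz)
    coords = sampling.profile_coords
    flat = (coords[:, 0] + ny // 2) * nz + (coords[:, 1] + nz // 2)
    key = sampling.profile_contrast.astype(np.int64) * (ny * nz) + flat
    uniq, inverse = np.unique(key, return_inverse=True)
    acc = np.zeros(uniq.size)
    np.add.at(acc, inverse, w)
    capped = np.minimum(acc, 1.0)
    contrast_of_loc = uniq // (ny * nz)
    r_eff = []
    for c in range(sampling.n_contrasts):
        tot = capped[contrast_of_loc == c].sum()
        r_eff.append(area / tot if tot > 0 else np.inf)
    return float(np.mean(r_eff))
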