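"""SVD subspace basis of the Bloch dictionary and projection utilities.

Image reconstruction operates on k coefficient images in the joint T1/T2
relaxation subspace spanned by the first k right singular vectors of the
dictionary's atom matrix.  The basis is shared between the two echoes (the
dictionary carries no T2* decay, so the temporal evolution is echo
independent up to the constant off-resonance echo phase).

The SVD is computed economically from the 1680 x 1680 Gram matrix of the atom
matrix; singular values are the square roots of its eigenvalues and the
captured "signal variability" is the cumulative squared-singular-value
(energy) fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import BlochDictionary

__all__ = ["SubspaceBasis", "compute_basis", "project", "project_dictionary",
           "CompressedDictionary"]


@dataclass(frozen=True)
class SubspaceBasis:
    """Orthonormal temporal basis Phi (n_profiles x k).

    ``singular_values`` holds the full singular spectrum of the dictionary;
    ``alpha`` the normalized singular values of the retained columns
    (alpha_1 = 1), used to scale the TV regularization per coefficient image.
    """

    phi: np.ndarray
    singular_values: np.ndarray
    k: int

    def __post_init__(self):
        if self.phi.shape[1] != self.k:
            raise ValueError("phi must have k columns")

    @property
    def n_profiles(self) -> int:
        return self.phi.shape[0]

    @property
    def alpha(self) -> np.ndarray:
        s = self.singular_values[: self.k]
        return s / s[0]

    def energy(self, k: int | None = None) -> float:
        """Fraction of squared-singular-value energy captured by k columns."""
        k = self.k if k is None else k
        s2 = self.singular_values**2
        return float(s2[:k].sum() / s2.sum())


def compute_basis(dictionary: BlochDictionary, k: int = 5) -> SubspaceBasis:
    """Compute the rank-k SVD basis of the dictionary atom matrix.

    Uses the eigendecomposition of the (n_profiles x n_profiles) Gram matrix,
    which is exact for the right singular vectors and far cheaper than a full
    SVD of the tall atom matrix.  Column signs follow the convention that each
    column's largest-magnitude entry is positive.
    """
    atoms = dictionary.atoms
    if atoms.size == 0:
        raise ValueError("empty dictionary")
    if not 1 <= k <= atoms.shape[1]:
        raise ValueError("k must be in [1, n_profiles]")
    gram = (atoms.T @ atoms).astype(np.float64)
    try:
        evals, evecs = np.linalg.eigh(gram)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise RuntimeError("SVD of the dictionary failed") from err
    evals = np.clip(evals[::-1], 0.0, None)
    evecs = evecs[:, ::-1]
    sv = np.sqrt(evals)
    phi = evecs[:, :k].copy()
    # deterministic sign convention
    for j in range(k):
        i = int(np.argmax(np.abs(phi[:, j])))
        if phi[i, j] < 0:
            phi[:, j] = -phi[:, j]
    return SubspaceBasis(phi=phi, singular_values=sv, k=k)


def project(signal: np.ndarray, basis: SubspaceBasis) -> np.ndarray:
    """Subspace coefficients Phi^T s of a profile-time signal (or stack).

    ``signal`` may be (n_profiles,) or (..., n_profiles); coefficients are
    returned along the last axis.
    """
    signal = np.asarray(signal)
    if signal.shape[-1] != basis.n_profiles:
        raise ValueError(
            f"signal length {signal.shape[-1]} does not match basis rows "
            f"{basis.n_profiles}"
        )
    return signal @ basis.phi


def reconstruct(coeffs: np.ndarray, basis: SubspaceBasis) -> np.ndarray:
    """Expand subspace coefficients back to profile-time signals (Phi c)."""
    return np.asarray(coeffs) @ basis.phi.T


@dataclass(frozen=True)
class CompressedDictionary:
    """Dictionary atoms projected into the subspace (n_atoms x k) plus norms."""

    coeffs: np.ndarray
    norms: np.ndarray
    params: np.ndarray
    basis: SubspaceBasis

    @property
    def n_atoms(self) -> int:
        return self.coeffs.shape[0]


def project_dictionary(
    dictionary: BlochDictionary, basis: SubspaceBasis
) -> CompressedDictionary:
    """Project every atom into the subspace for compressed matching."""
    if dictionary.atoms.shape[1] != basis.n_profiles:
        raise ValueError("dictionary and basis profile counts differ")
    coeffs = (basis.phi.T @ dictionary.atoms.T).T.astype(np.float64)
    norms = np.linalg.norm(coeffs, axis=1)
    return CompressedDictionary(
        coeffs=coeffs, norms=norms, params=dictionary.params, basis=basis
    )
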