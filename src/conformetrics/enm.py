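"""Anisotropic network model (ANM) normal-mode analysis.

The ANM places a harmonic spring of uniform stiffness γ between every pair
of Cα nodes closer than a cutoff distance.  The 3N×3N Hessian of that
potential has six zero eigenvalues (rigid translations/rotations of a
connected network); its lowest nonzero eigenpairs are the global modes that
drive all the samplers in :mod:`conformetrics.samplers`.

The model object follows a fit/results split:

>>> model = AnisotropicNetworkModel(structure, cutoff=15.0)
>>> res = model.fit(n_modes=10)
>>> res.eigenvalues, res.modes   # ascending λ_k, orthonormal columns
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .structures import Structure

DEFAULT_CUTOFF = 15.0  # Å, conventional Cα-ANM choice
DEFAULT_GAMMA = 1.0


class DegenerateGeometryError(ValueError):
    """Two network nodes coincide; spring direction undefined."""


class DisconnectedNetworkWarning(UserWarning):
    """More than six near-zero modes: the network has several components."""


def build_hessian(coords: np.ndarray, cutoff: float = DEFAULT_CUTOFF,
                  gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Assemble the 3N×3N ANM Hessian.

    For each contacting pair (i, j) with separation vector r and distance
    d ≤ cutoff, the off-diagonal 3×3 super-element is −γ/d² · r rᵀ; the
    diagonal super-element is minus the sum of the off-diagonals in its
    block row.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    diff = coords[:, None, :] - coords[None, :, :]  # r_i - r_j
    dist2 = np.sum(diff * diff, axis=2)
    contact = (dist2 <= cutoff * cutoff)
    np.fill_diagonal(contact, False)
    if np.any(dist2[contact] == 0.0):
        raise DegenerateGeometryError("coincident nodes within cutoff")
    hess = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(contact)
    sel = ii < jj
    for i, j in zip(ii[sel], jj[sel]):
        r = coords[j] - coords[i]
        block = -gamma / dist2[i, j] * np.outer(r, r)
        hess[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
        hess[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
        hess[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        hess[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return hess


def _fix_mode_signs(modes: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude component of each mode is
    positive (stabilizes comparisons across eigensolvers)."""
    idx = np.argmax(np.abs(modes), axis=0)
    signs = np.sign(modes[idx, np.arange(modes.shape[1])])
    signs[signs == 0] = 1.0
    return modes * signs


@dataclass(frozen=True)
class ANMResults:
    """ANM spectrum: zero modes discarded, nonzero modes ascending.

    ``modes`` holds orthonormal 3N-dimensional eigenvectors as columns;
    ``eigenvalues[k]`` is λ of ``modes[:, k]``.
    """

    coords: np.ndarray
    cutoff: float
    gamma: float
    eigenvalues: np.ndarray
    modes: np.ndarray
    n_zero_modes: int

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def mode_as_displacement(self, k: int) -> np.ndarray:
        """Mode k reshaped to (N, 3)."""
        return self.modes[:, k].reshape(-1, 3)

    def summary(self) -> str:
        lines = [
            "Anisotropic Network Model Results",
            "=================================",
            f"nodes:       {self.n_nodes}",
            f"cutoff:      {self.cutoff:.1f} Å   gamma: {self.gamma:g}",
            f"zero modes:  {self.n_zero_modes}",
            f"modes kept:  {self.n_modes}",
            "lowest eigenvalues: "
            + ", ".join(f"{v:.4g}" for v in self.eigenvalues[:6]),
        ]
        return "\n".join(lines)

    def export_modes(self, path) -> None:
        """Plain-text export, one 3N mode vector per row (ascending λ)."""
        header = ("eigenvalues: "
                  + " ".join(f"{v:.8g}" for v in self.eigenvalues))
        np.savetxt(str(path), self.modes.T, fmt="%.8g", header=header)

    def export_nmd(self, path, title: str = "conformetrics ANM") -> None:
        """NMD-style export for mode viewers (one `mode` line per mode)."""
        with open(str(path), "w") as fh:
            fh.write(f"title {title}\n")
            fh.write("coordinates "
                     + " ".join(f"{c:.3f}" for c in self.coords.ravel()) + "\n")
            for k in range(self.n_modes):
                fh.write(f"mode {k + 1} {self.eigenvalues[k]:.6g} "
                         + " ".join(f"{c:.6f}" for c in self.modes[:, k]) + "\n")


class AnisotropicNetworkModel:
    """Cα elastic network model of a single structure.

    Parameters
    ----------
    structure : Structure or (N, 3) array
        Node coordinates in Å.
    cutoff : float
        Spring cutoff distance in Å (default 15).
    gamma : float
        Uniform spring constant (default 1; arbitrary units).
    """

    def __init__(self, structure, cutoff: float = DEFAULT_CUTOFF,
                 gamma: float = DEFAULT_GAMMA):
        if isinstance(structure, Structure):
            self.coords = structure.coords.copy()
        else:
            self.coords = np.asarray(structure, float)
        self.cutoff = float(cutoff)
        self.gamma = float(gamma)

    def hessian(self) -> np.ndarray:
        return build_hessian(self.coords, self.cutoff, self.gamma)

    def fit(self, n_modes: int | None = 20,
            zero_tol_factor: float = 1e-8) -> ANMResults:
        """Diagonalize the Hessian and return the nonzero-mode spectrum.

        Eigenvalues below ``zero_tol_factor * max(λ)`` count as zero modes
        (six for a connected network).  ``n_modes=None`` keeps all nonzero
        modes.
        """
        hess = self.hessian()
        evals, evecs = eigh(hess)
        tol = zero_tol_factor * float(evals[-1])
        n_zero = int(np.sum(evals < tol))
        if n_zero > 6:
            warnings.warn(
                f"{n_zero} near-zero modes: network appears disconnected "
                f"({(n_zero // 6)} rigid components?)",
                DisconnectedNetworkWarning)
        nz_vals = evals[n_zero:]
        nz_vecs = evecs[:, n_zero:]
        if n_modes is not None:
            nz_vals = nz_vals[:n_modes]
            nz_vecs = nz_vecs[:, :n_modes]
        return ANMResults(self.coords.copy(), self.cutoff, self.gamma,
                          nz_vals.copy(), _fix_mode_signs(nz_vecs),
                          n_zero_modes=n_zero)


# ---------------------------------------------------------------------------
# Mode-combination utilities shared by the samplers
# ---------------------------------------------------------------------------

def random_combination(k: int, rng: np.random.Generator) -> np.ndarray:
    """Unit coefficient vector uniform on the (k−1)-sphere, sign included."""
    if k <= 0:
        raise ValueError("k must be positive")
    while True:
        c = rng.standard_normal(k)
        norm = np.linalg.norm(c)
        if norm > 1e-12:
            return c / norm


def scale_to_rmsd(displacement: np.ndarray, target_rmsd: float,
                  n_nodes: int) -> np.ndarray:
    """Scale a 3N displacement so that applying it moves N nodes by exactly
    ``target_rmsd`` (Å): scale = target · √N / ‖displacement‖."""
    displacement = np.asarray(displacement, float)
    if target_rmsd == 0.0:
        return np.zeros_like(displacement)
    norm = np.linalg.norm(displacement)
    if norm == 0.0:
        raise ValueError("cannot scale a zero displacement")
    return displacement * (target_rmsd * np.sqrt(n_nodes) / norm)


def combine_modes(model: ANMResults, coefficients: np.ndarray,
                  mode_indices=None) -> np.ndarray:
    """Linear combination of modes as a 3N displacement vector."""
    coefficients = np.asarray(coefficients, float)
    if mode_indices is None:
        mode_indices = np.arange(len(coefficients))
    return model.modes[:, mode_indices] @ coefficients
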