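"""Synthetic structures and ensembles with known ground truth.

Every pipeline stage in this package can be exercised without any
downloaded structure using three generators:

* :func:`toy_structure` — deterministic Cα geometries: an ideal α-helix, a
  compact self-avoiding chain (globular-protein stand-in), or a two-domain
  dumbbell joined by a short linker (hinge-bending test bed);
* :func:`gaussian_ensemble` — conformers drawn from a Gaussian whose
  covariance is built from a prescribed orthonormal mode set, so the true
  principal components and their variances are known exactly — this
  emulates a densely sampled, unimodal ensemble;
* :func:`two_state_ensemble` — an open/closed mixture with isotropic
  per-atom jitter, emulating bimodal experimental ensembles (two crystal
  forms of a hinged enzyme); with small jitter it reduces to the
  crystal-like, narrowly distributed regime.

Conventions shared with the samplers: a mode with ANM eigenvalue λ gets
thermal-like variance ``scale / λ``, so softer modes fluctuate more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Ensemble, Structure

BOND_LENGTH = 3.8          # Å, consecutive Cα distance
HELIX_RISE = 1.5           # Å per residue
HELIX_TWIST = 100.0        # degrees per residue
HELIX_RADIUS = 2.3         # Å


def _keys(n: int, chain: str = "A"):
    return tuple((chain, i + 1, "") for i in range(n))


def _helix(n: int) -> np.ndarray:
    t = np.arange(n)
    ang = np.deg2rad(HELIX_TWIST) * t
    return np.column_stack([HELIX_RADIUS * np.cos(ang),
                            HELIX_RADIUS * np.sin(ang),
                            HELIX_RISE * t])


def _compact_chain(n: int, rng: np.random.Generator,
                   center: np.ndarray | None = None,
                   start: np.ndarray | None = None,
                   min_dist: float = 3.4) -> np.ndarray:
    """Self-avoiding random walk with 3.8 Å bonds confined to a
    protein-density sphere around ``center``."""
    radius = 3.0 * n ** (1.0 / 3.0)
    center = np.zeros(3) if center is None else np.asarray(center, float)
    pts = [center.copy() if start is None else np.asarray(start, float)]
    while len(pts) < n:
        last = pts[-1]
        placed = False
        for _ in range(200):
            d = rng.standard_normal(3)
            # bias back toward the center when drifting out of the sphere
            excess = np.linalg.norm(last - center) / radius
            if excess > 1.0:
                d += 2.0 * (excess - 1.0 + 0.5) * (center - last) / np.linalg.norm(center - last)
            d = BOND_LENGTH * d / np.linalg.norm(d)
            cand = last + d
            prev = np.asarray(pts[:-1])
            if len(prev) == 0 or np.min(np.linalg.norm(prev - cand, axis=1)) >= min_dist:
                pts.append(cand)
                placed = True
                break
        if not placed:            # loosen self-avoidance rather than fail
            d = rng.standard_normal(3)
            pts.append(last + BOND_LENGTH * d / np.linalg.norm(d))
    return np.asarray(pts)


def _two_domain(n: int, rng: np.random.Generator) -> np.ndarray:
    n_linker = 4
    n_a = (n - n_linker) // 2
    n_b = n - n_linker - n_a
    lobe_a = _compact_chain(n_a, rng, center=np.zeros(3))
    exit_a = lobe_a[-1]
    direction = exit_a - lobe_a.mean(axis=0)
    direction /= np.linalg.norm(direction)
    linker = np.asarray([exit_a + (i + 1) * BOND_LENGTH * direction
                         for i in range(n_linker)])
    r_b = 3.0 * n_b ** (1.0 / 3.0)
    center_b = linker[-1] + (0.6 * r_b) * direction
    lobe_b = _compact_chain(n_b, rng, center=center_b, start=linker[-1]
                            + BOND_LENGTH * direction)
    return np.vstack([lobe_a, linker, lobe_b])


def toy_structure(n_residues: int = 50, topology: str = "helix",
                  seed: int = 0, label: str | None = None) -> Structure:
    """Deterministic toy Cα structure.

    ``topology``: ``"helix"`` (ideal α-helix: 1.5 Å rise, 100°/residue),
    ``"compact-chain"`` (globular self-avoiding walk), or ``"two-domain"``
    (two compact lobes joined by a 4-residue linker; its lowest ANM mode is
    inter-lobe hinge motion).
    """
    if n_residues < 10:
        raise ValueError("toy structures need n_residues >= 10")
    rng = np.random.default_rng(seed)
    if topology == "helix":
        coords = _helix(n_residues)
    elif topology == "compact-chain":
        coords = _compact_chain(n_residues, rng)
    elif topology == "two-domain":
        coords = _two_domain(n_residues, rng)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    if label is None:
        label = f"{topology}-{n_residues}"
    return Structure(label, _keys(n_residues), coords)


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for a Gaussian ensemble.

    ``modes`` are the orthonormal 3N directions used (columns);
    ``variances`` their per-mode variances (Å², descending = the true PCA
    eigenvalues); ``covariance()`` reconstructs Σ = U diag(var) Uᵀ.
    """

    modes: np.ndarray        # (3N, k), descending-variance order
    variances: np.ndarray    # (k,)
    mean: np.ndarray         # (N, 3)

    def covariance(self) -> np.ndarray:
        return (self.modes * self.variances) @ self.modes.T


def gaussian_ensemble(mean: Structure, modes: np.ndarray,
                      eigenvalues: np.ndarray, scale: float = 1.0,
                      n_conformers: int = 100, seed: int = 0,
                      ) -> tuple[Ensemble, GroundTruth]:
    """Gaussian ensemble over a prescribed mode basis.

    Each conformer is ``mean + Σ_k c_k u_k`` with ``c_k ~ N(0, scale/λ_k)``
    (variance), mimicking thermal occupancy of harmonic modes: soft modes
    (small λ) dominate.  Returns the ensemble and the exact ground truth
    (modes reordered by descending variance — the true PCs).
    """
    modes = np.asarray(modes, float)
    eigenvalues = np.asarray(eigenvalues, float)
    if np.any(eigenvalues <= 0):
        raise ValueError("eigenvalues must be positive")
    gram = modes.T @ modes
    if not np.allclose(gram, np.eye(modes.shape[1]), atol=1e-8):
        raise ValueError("modes must be orthonormal columns")
    rng = np.random.default_rng(seed)
    n = mean.n_residues
    k = modes.shape[1]
    variances = scale / eigenvalues
    if scale == 0:
        coords = np.repeat(mean.coords[None], n_conformers, axis=0)
    else:
        c = rng.standard_normal((n_conformers, k)) * np.sqrt(variances)
        coords = mean.coords[None] + (c @ modes.T).reshape(n_conformers, n, 3)
    order = np.argsort(variances)[::-1]
    truth = GroundTruth(modes[:, order], variances[order], mean.coords.copy())
    labels = [f"{mean.label}|g{i + 1}" for i in range(n_conformers)]
    return Ensemble(labels, mean.residue_keys, coords), truth


def two_state_ensemble(open_state: Structure, closed_state: Structure,
                       populations: tuple[float, float] = (0.5, 0.5),
                       noise: float = 0.3, n_conformers: int = 100,
                       seed: int = 0) -> Ensemble:
    """Open/closed mixture with isotropic per-atom Gaussian jitter.

    Emulates a bimodal experimental ensemble (two crystal forms); state
    labels are recorded in ``meta["state"]``.
    """
    import pandas as pd

    if open_state.residue_keys != closed_state.residue_keys:
        raise ValueError("open and closed structures must share a residue frame")
    populations = np.asarray(populations, float)
    if populations.min() < 0 or not np.isclose(populations.sum(), 1.0):
        raise ValueError("populations must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    states = rng.choice(2, size=n_conformers, p=populations)
    bases = [open_state.coords, closed_state.coords]
    n = open_state.n_residues
    coords = np.empty((n_conformers, n, 3))
    for i, s in enumerate(states):
        coords[i] = bases[s] + noise * rng.standard_normal((n, 3))
    labels = [f"two-state|{'oc'[s]}{i + 1}" for i, s in enumerate(states)]
    meta = pd.DataFrame({"state": np.where(states == 0, "open", "closed")})
    return Ensemble(labels, open_state.residue_keys, coords, meta=meta)
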