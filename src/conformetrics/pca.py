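"""Principal component analysis of conformational ensembles.

PCA here is the eigendecomposition of the 3N×3N covariance of superposed
Cα coordinates about the ensemble mean, with 1/M (population)
normalization — so the sum of all eigenvalues equals the sum of squared
per-residue RMSFs (trace conservation), and projecting the source ensemble
onto its own components gives per-component score variances equal to the
eigenvalues.

Experimental-ensemble components are conventionally called ePCs and
simulated-ensemble components sPCs; cross-projections (simulated conformers
scored on ePCs) first superpose each conformer onto the PC model's mean
structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .enm import _fix_mode_signs
from .structures import Ensemble, ResidueKey, kabsch_superpose, superpose_to_mean


@dataclass(frozen=True)
class PCAResults:
    """Fitted principal components of one ensemble.

    ``components`` is (k, 3N) with orthonormal rows in descending-eigenvalue
    order; ``eigenvalues`` are in Å².
    """

    mean_coords: np.ndarray           # (N, 3)
    eigenvalues: np.ndarray           # (k,) descending, Å²
    components: np.ndarray            # (k, 3N) orthonormal rows
    residue_keys: tuple[ResidueKey, ...]
    label: str = ""
    total_variance: float = 0.0       # trace of the full covariance, Å²

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_residues(self) -> int:
        return self.mean_coords.shape[0]

    def fraction_of_variance(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance

    def summary(self) -> str:
        frac = self.fraction_of_variance()
        lines = [
            f"Ensemble PCA Results{f' — {self.label}' if self.label else ''}",
            "=" * 40,
            f"residues:        {self.n_residues}",
            f"components kept: {self.n_components}",
            f"total variance:  {self.total_variance:.4f} Å²",
            "",
            "  PC   eigenvalue (Å²)   % variance   cumulative %",
        ]
        cum = 0.0
        for i, (ev, f) in enumerate(zip(self.eigenvalues, frac), 1):
            cum += 100 * f
            lines.append(f"  {i:<4d} {ev:<17.4f} {100 * f:<12.2f} {cum:.2f}")
        return "\n".join(lines)

    def export(self, eigenvalues_path, components_path) -> None:
        """TSV eigenvalues + plain-text component matrix (one PC per row)."""
        with open(str(eigenvalues_path), "w") as fh:
            fh.write("pc\teigenvalue\tfraction\n")
            for i, (ev, f) in enumerate(zip(self.eigenvalues,
                                            self.fraction_of_variance()), 1):
                fh.write(f"{i}\t{ev:.8g}\t{f:.8g}\n")
        np.savetxt(str(components_path), self.components, fmt="%.8g")


class EnsemblePCA:
    """PCA model of a conformational ensemble.

    The ensemble is superposed onto its iterative mean first if it is not
    already.  ``fit`` returns a :class:`PCAResults`.
    """

    def __init__(self, ensemble: Ensemble, label: str | None = None):
        if not ensemble.superposed:
            ensemble = superpose_to_mean(ensemble)
        self.ensemble = ensemble
        self.label = label if label is not None else ""

    def fit(self, n_components: int | None = None) -> PCAResults:
        ens = self.ensemble
        m, n = ens.n_conformers, ens.n_residues
        if m < 2:
            raise ValueError("PCA needs at least 2 conformers")
        flat = ens.coords.reshape(m, 3 * n)
        mean = flat.mean(axis=0)
        centered = flat - mean
        # population covariance via SVD: eigenvalues = s² / M
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        evals = s ** 2 / m
        total = float(evals.sum())
        rank = min(m - 1, 3 * n)
        if n_components is None:
            k = rank
        else:
            k = n_components
            if k > rank:
                warnings.warn(f"requested {k} components but covariance rank "
                              f"is at most {rank}; truncating", UserWarning)
                k = rank
        comps = _fix_mode_signs(vt[:k].T).T
        return PCAResults(mean.reshape(n, 3), evals[:k].copy(), comps,
                          ens.residue_keys, label=self.label,
                          total_variance=total)


def compute_pcs(ensemble: Ensemble, n_components: int | None = None,
                label: str = "") -> PCAResults:
    """Functional shorthand for ``EnsemblePCA(ensemble, label).fit(...)``."""
    return EnsemblePCA(ensemble, label=label).fit(n_components)


@dataclass(frozen=True)
class Projection:
    """Per-conformer scores on selected PCs (Å)."""

    scores: np.ndarray                # (M, k)
    pc_indices: tuple[int, ...]       # 0-based PC indices
    source_label: str = ""
    pc_label: str = ""

    def to_tsv(self, path, labels=None) -> None:
        with open(str(path), "w") as fh:
            fh.write("conformer\t" + "\t".join(f"PC{i + 1}"
                                               for i in self.pc_indices) + "\n")
            for m in range(self.scores.shape[0]):
                name = labels[m] if labels is not None else str(m)
                fh.write(name + "\t"
                         + "\t".join(f"{v:.6f}" for v in self.scores[m]) + "\n")


def project(ensemble: Ensemble, pcs: PCAResults,
            k: int | None = None) -> Projection:
    """Score conformers on a PC model.

    Each conformer is superposed onto the PC model's mean structure first,
    so cross-ensemble projections (e.g. simulated conformers onto
    experimental PCs) are well defined.  ``score_i = p_i · (x − mean)``.
    """
    if ensemble.residue_keys != pcs.residue_keys:
        from .structures import AlignmentError
        raise AlignmentError("ensemble and PC model use different residue frames")
    if k is None:
        k = pcs.n_components
    k = min(k, pcs.n_components)
    mean_flat = pcs.mean_coords.ravel()
    scores = np.empty((ensemble.n_conformers, k))
    for m in range(ensemble.n_conformers):
        fitted, _ = kabsch_superpose(ensemble.coords[m], pcs.mean_coords)
        scores[m] = pcs.components[:k] @ (fitted.ravel() - mean_flat)
    return Projection(scores, tuple(range(k)))


def variance_along_pcs(ensemble: Ensemble, pcs: PCAResults,
                       n: int = 10) -> np.ndarray:
    """Standard deviation of conformer scores along the first ``n`` PCs.

    The deviation is taken about the PC model's own mean structure (score
    zero), not the projected ensemble's centroid — this is the dispersion
    of a computed ensemble measured in the experimental frame.
    """
    proj = project(ensemble, pcs, k=n)
    return np.sqrt(np.mean(proj.scores ** 2, axis=0))


def rmsf(ensemble: Ensemble) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the mean position."""
    if not ensemble.superposed:
        ensemble = superpose_to_mean(ensemble)
    if ensemble.n_conformers == 1:
        warnings.warn("single-conformer ensemble: RMSF is identically zero",
                      UserWarning)
        return np.zeros(ensemble.n_residues)
    mean = ensemble.coords.mean(axis=0)
    dev = ensemble.coords - mean
    return np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))


def kde_density(scores_2d: np.ndarray, bandwidth: str | float = "scott",
                grid_size: int = 80, padding: float = 0.1):
    """Gaussian-KDE density of 2-D PC scores on a regular grid.

    Returns (xx, yy, density) suitable for contour plotting of the
    conformational landscape.  Bandwidth follows Scott's rule by default.
    """
    pts = np.asarray(scores_2d, float).T  # (2, M)
    kde = gaussian_kde(pts, bw_method=bandwidth)
    lo = pts.min(axis=1)
    hi = pts.max(axis=1)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo -= padding * span
    hi += padding * span
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    xx, yy = np.meshgrid(xs, ys)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return xx, yy, dens
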