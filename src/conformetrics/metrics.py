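"""Comparison statistics for pairs/collections of conformational ensembles.

The comparison toolkit mirrors how generated ensembles are benchmarked
against experimentally resolved ones:

* **overlap matrix** — absolute correlation cosines |p_i · q_j| between two
  sets of principal components;
* **RWSIP** — root-weighted square inner product between two PC subspaces,

  .. math::

     \\mathrm{RWSIP} = \\left[\\frac{\\sum_{i,j\\le n} \\lambda_i^u
     \\lambda_j^v (u_i\\cdot v_j)^2}{\\sum_{i\\le n} \\lambda_i^u
     \\lambda_i^v}\\right]^{1/2}

  which equals 1 for identical subspaces with identical spectra and 0 for
  mutually orthogonal ones (eigenvalues paired by descending rank in the
  denominator; n = 4 by convention);
* **RMSF Pearson matrix** — pairwise correlation of per-residue
  fluctuation profiles;
* **distance observables** — per-conformer inter-residue or
  inter-selection centroid distances (flap opening, loop closure,
  domain-closure distances), computed in each conformer's native frame;
* **ComparisonReport** — closest distances of approach, minimum RMSD to a
  target (e.g. closed) structure, and all the matrices above, exportable as
  JSON/TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pca import PCAResults
from .structures import (AlignmentError, Ensemble, SelectionError, Structure,
                         rmsd_profile)

DEFAULT_N_PCS = 4


def overlap_matrix(a: PCAResults, b: PCAResults,
                   k: int = DEFAULT_N_PCS) -> np.ndarray:
    """k×k matrix of absolute correlation cosines |p_i^a · p_j^b|."""
    if a.residue_keys != b.residue_keys:
        raise AlignmentError("PC models use different residue frames")
    ka = min(k, a.n_components)
    kb = min(k, b.n_components)
    return np.abs(a.components[:ka] @ b.components[:kb].T)


def rwsip(a: PCAResults, b: PCAResults, n: int = DEFAULT_N_PCS) -> float:
    """Root-weighted square inner product of two PC subspaces.

    Weighted by both spectra so the most collective (largest-eigenvalue)
    components dominate; bounded in [0, 1] with 1 iff the two models share
    both subspace and spectrum shape over the first ``n`` components.
    """
    if a.n_components < n or b.n_components < n:
        raise ValueError(f"both PC models need >= {n} components")
    lam_a = a.eigenvalues[:n]
    lam_b = b.eigenvalues[:n]
    dots = a.components[:n] @ b.components[:n].T
    num = float(np.sum(np.outer(lam_a, lam_b) * dots ** 2))
    den = float(np.sum(lam_a * lam_b))
    if den <= 0.0:
        raise ValueError("degenerate spectra: zero RWSIP denominator")
    return float(np.sqrt(num / den))


def rmsf_pearson(profiles: list[np.ndarray],
                 labels: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of per-residue RMSF profiles.

    Zero-variance profiles give NaN entries (flagged, not raised).
    """
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise ValueError("profiles have unequal lengths")
    if labels is None:
        labels = [f"profile{i + 1}" for i in range(len(profiles))]
    arr = np.asarray(profiles, float)
    stds = arr.std(axis=1)
    k = len(profiles)
    mat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if stds[i] == 0 or stds[j] == 0:
                mat[i, j] = mat[j, i] = np.nan
            else:
                mat[i, j] = mat[j, i] = float(np.corrcoef(arr[i], arr[j])[0, 1])
    for i in range(k):
        if stds[i] == 0:
            mat[i, i] = np.nan
    return pd.DataFrame(mat, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Distance observables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceSeries:
    """Per-conformer distance observable (Å), native-frame (superposition
    independent)."""

    name: str
    values: np.ndarray

    @property
    def closest_approach(self) -> float:
        return float(self.values.min())

    @property
    def farthest(self) -> float:
        return float(self.values.max())

    def histogram(self, bins="fd"):
        return np.histogram(self.values, bins=bins)


def pair_distance(ensemble: Ensemble, residue_a, residue_b,
                  name: str | None = None) -> DistanceSeries:
    """Cα–Cα distance between two residues, per conformer."""
    ia = ensemble.index_of(tuple(residue_a))
    ib = ensemble.index_of(tuple(residue_b))
    d = np.linalg.norm(ensemble.coords[:, ia] - ensemble.coords[:, ib], axis=1)
    if name is None:
        name = f"{residue_a}-{residue_b}"
    return DistanceSeries(name, d)


def _selection_indices(ensemble: Ensemble, ranges) -> list[int]:
    """Resolve a list of (chain, first, last) residue ranges to indices."""
    idx = []
    for chain, first, last in ranges:
        for i, (ch, num, _ic) in enumerate(ensemble.residue_keys):
            if ch == chain and first <= num <= last:
                idx.append(i)
    if not idx:
        raise SelectionError(f"selection {ranges!r} matches no residues")
    return sorted(set(idx))


def com_distance(ensemble: Ensemble, ranges_a, ranges_b,
                 name: str = "com") -> DistanceSeries:
    """Distance between unweighted Cα centroids of two residue-range
    selections, per conformer.

    Each selection is a list of ``(chain, first_resnum, last_resnum)``
    tuples — e.g. a two-segment "fingers" subdomain.
    """
    ia = _selection_indices(ensemble, ranges_a)
    ib = _selection_indices(ensemble, ranges_b)
    ca = ensemble.coords[:, ia].mean(axis=1)
    cb = ensemble.coords[:, ib].mean(axis=1)
    return DistanceSeries(name, np.linalg.norm(ca - cb, axis=1))


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Everything needed for a method-comparison table.

    ``overlaps[(a, b)]`` holds the k×k overlap matrix between PC sets a and
    b; ``rwsip_table`` is a symmetric DataFrame with unit diagonal;
    ``distance_summary`` rows give closest/farthest approach per ensemble
    and observable; ``min_rmsd_to_target`` rows give the minimum superposed
    RMSD from each ensemble to each registered target structure.
    """

    overlaps: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    rwsip_table: pd.DataFrame | None = None
    rmsf_pearson: pd.DataFrame | None = None
    variance_along_pcs: pd.DataFrame | None = None
    distance_summary: pd.DataFrame | None = None
    min_rmsd_to_target: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {"notes": list(self.notes)}
        out["overlaps"] = {f"{a}|{b}": m.tolist()
                           for (a, b), m in self.overlaps.items()}
        for name in ("rwsip_table", "rmsf_pearson", "variance_along_pcs",
                     "distance_summary", "min_rmsd_to_target"):
            df = getattr(self, name)
            out[name] = None if df is None else json.loads(
                df.to_json(orient="split"))
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(str(path), "w") as fh:
                fh.write(text + "\n")
        return text

    def write_tsv_tables(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("rwsip_table", "rmsf_pearson", "variance_along_pcs",
                     "distance_summary", "min_rmsd_to_target"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(d / f"{name}.tsv", sep="\t")

    def summary(self) -> str:
        parts = ["Ensemble Comparison Report", "=" * 40]
        if self.rwsip_table is not None:
            parts += ["", "RWSIP (eigenvalue-weighted subspace agreement):",
                      self.rwsip_table.round(3).to_string()]
        if self.rmsf_pearson is not None:
            parts += ["", "RMSF Pearson correlations:",
                      self.rmsf_pearson.round(3).to_string()]
        if self.distance_summary is not None:
            parts += ["", "Distance observables (Å):",
                      self.distance_summary.round(2).to_string()]
        if self.min_rmsd_to_target is not None:
            parts += ["", "Minimum RMSD to target structures (Å):",
                      self.min_rmsd_to_target.round(2).to_string()]
        if self.notes:
            parts += ["", "Notes:"] + [f"- {n}" for n in self.notes]
        return "\n".join(parts)


def summarize(ensembles: dict[str, Ensemble],
              pc_models: dict[str, PCAResults] | None = None,
              observables: dict[str, dict] | None = None,
              targets: dict[str, Structure] | None = None,
              rmsf_profiles: dict[str, np.ndarray] | None = None,
              reference_pcs: str | None = None,
              n_pcs: int = DEFAULT_N_PCS) -> ComparisonReport:
    """Assemble a ComparisonReport from registered inputs.

    ``observables`` maps an observable name to either
    ``{"pair": (key_a, key_b)}`` or ``{"com": (ranges_a, ranges_b)}``.
    ``targets`` maps a target name to a Structure; the minimum superposed
    RMSD from every ensemble to every target is tabulated.  When
    ``reference_pcs`` names one of the PC models, per-PC standard
    deviations of every ensemble along that model's components are added.
    Missing/failed pieces are noted and skipped, not fatal.
    """
    report = ComparisonReport()
    pc_models = pc_models or {}
    names = list(pc_models)
    if pc_models:
        mat = np.eye(len(names))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    report.overlaps[(a, b)] = overlap_matrix(
                        pc_models[a], pc_models[b], k=n_pcs)
                if i <= j:
                    try:
                        val = rwsip(pc_models[a], pc_models[b], n=n_pcs)
                    except ValueError as exc:
                        report.notes.append(f"rwsip({a},{b}) failed: {exc}")
                        val = np.nan
                    mat[i, j] = mat[j, i] = val
        report.rwsip_table = pd.DataFrame(mat, index=names, columns=names)
    if rmsf_profiles:
        report.rmsf_pearson = rmsf_pearson(list(rmsf_profiles.values()),
                                           list(rmsf_profiles))
    if reference_pcs is not None and reference_pcs in pc_models:
        from .pca import variance_along_pcs as _var
        rows = {}
        ref = pc_models[reference_pcs]
        n_var = min(10, ref.n_components)
        for ens_name, ens in ensembles.items():
            try:
                rows[ens_name] = _var(ens, ref, n=n_var)
            except Exception as exc:  # frame mismatch etc.
                report.notes.append(
                    f"variance_along_pcs skipped for {ens_name}: {exc}")
        if rows:
            report.variance_along_pcs = pd.DataFrame(
                rows, index=[f"PC{i + 1}" for i in range(n_var)]).T
    if observables:
        rows = []
        for obs_name, spec_ in observables.items():
            for ens_name, ens in ensembles.items():
                try:
                    if "pair" in spec_:
                        series = pair_distance(ens, *spec_["pair"], name=obs_name)
                    else:
                        series = com_distance(ens, *spec_["com"], name=obs_name)
                except SelectionError as exc:
                    report.notes.append(
                        f"observable {obs_name} skipped for {ens_name}: {exc}")
                    continue
                rows.append(dict(observable=obs_name, ensemble=ens_name,
                                 closest=series.closest_approach,
                                 farthest=series.farthest,
                                 mean=float(series.values.mean())))
        if rows:
            report.distance_summary = pd.DataFrame(rows)
    if targets:
        rows = []
        for tgt_name, tgt in targets.items():
            for ens_name, ens in ensembles.items():
                try:
                    profile = rmsd_profile(ens, tgt)
                except AlignmentError as exc:
                    report.notes.append(
                        f"target {tgt_name} skipped for {ens_name}: {exc}")
                    continue
                rows.append(dict(target=tgt_name, ensemble=ens_name,
                                 min_rmsd=float(profile.min())))
        if rows:
            report.min_rmsd_to_target = pd.DataFrame(rows)
    return report
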