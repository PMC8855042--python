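"""Structures, ensembles, and superposition primitives.

A :class:`Structure` is one conformer reduced to its Cα trace: an ordered
list of residue keys ``(chain, resnum, icode)`` and an ``(N, 3)`` coordinate
array in Å.  An :class:`Ensemble` stacks M conformers that share a residue
frame.  All downstream analysis (elastic network models, PCA, comparison
metrics) operates on these two containers.

PDB reading/writing is delegated to biotite; the optimal rigid-body
superposition (Kabsch) is delegated to
:func:`scipy.spatial.transform.Rotation.align_vectors`, which guarantees a
proper rotation (det = +1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]


class FormatError(ValueError):
    """Raised when a file cannot be interpreted as a Cα structure."""


class SelectionError(KeyError):
    """Raised when a requested chain/residue selection is absent."""


class AlignmentError(ValueError):
    """Raised when residue frames of two objects cannot be reconciled."""


@dataclass(frozen=True)
class Structure:
    """One conformer: labeled Cα coordinates.

    Parameters
    ----------
    label : str
        Free-form identifier (e.g. the PDB id or a conformer tag).
    residue_keys : tuple of (chain, resnum, icode)
        Unique, ordered residue identifiers (PDB author numbering).
    coords : (N, 3) ndarray
        Cα positions in Å.
    """

    label: str
    residue_keys: tuple[ResidueKey, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        if coords.shape[0] < 2:
            raise ValueError("a structure needs at least 2 residues")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        if len(self.residue_keys) != coords.shape[0]:
            raise ValueError("residue_keys and coords length mismatch")
        if len(set(self.residue_keys)) != len(self.residue_keys):
            raise ValueError("residue_keys must be unique")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        return replace(self, coords=np.asarray(coords, float),
                       label=self.label if label is None else label)

    def index_of(self, key: ResidueKey) -> int:
        try:
            return self.residue_keys.index(key)
        except ValueError:
            raise SelectionError(f"residue {key} not in structure {self.label!r}")


@dataclass
class Ensemble:
    """M aligned conformers over a common residue frame.

    ``meta`` is an optional per-conformer table (lineage, state labels, ...)
    carried along by the samplers and generators.
    """

    labels: list[str]
    residue_keys: tuple[ResidueKey, ...]
    coords: np.ndarray  # (M, N, 3) Å
    superposed: bool = False
    reference_mean: np.ndarray | None = None
    meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (M, N, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one conformer")
        if self.coords.shape[1] != len(self.residue_keys):
            raise ValueError("residue_keys and coords N mismatch")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("labels and coords M mismatch")

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def structure(self, i: int) -> Structure:
        """Extract conformer ``i`` as a Structure."""
        return Structure(self.labels[i], self.residue_keys, self.coords[i].copy())

    def mean_structure(self, label: str = "mean") -> Structure:
        return Structure(label, self.residue_keys, self.coords.mean(axis=0))

    def index_of(self, key: ResidueKey) -> int:
        try:
            return self.residue_keys.index(key)
        except ValueError:
            raise SelectionError(f"residue {key} not in ensemble")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _atom_array_to_structure(atoms, label: str, chain: str | None) -> Structure:
    ca = atoms[(atoms.atom_name == "CA") & (atoms.element == "C")]
    if chain is not None:
        if chain not in set(atoms.chain_id):
            raise SelectionError(f"chain {chain!r} not present in {label!r}")
        ca = ca[ca.chain_id == chain]
    if ca.array_length() == 0:
        raise FormatError(f"no Cα atoms found in {label!r}")
    keys, coords, seen = [], [], set()
    for i in range(ca.array_length()):
        key = (str(ca.chain_id[i]), int(ca.res_id[i]), str(ca.ins_code[i]).strip())
        if key in seen:
            logger.warning("duplicate Cα for residue %s in %s; keeping first", key, label)
            continue
        seen.add(key)
        keys.append(key)
        coords.append(ca.coord[i])
    return Structure(label, tuple(keys), np.asarray(coords, float))


def read_structure(path, chain: str | None = None, model: int | None = None,
                   label: str | None = None) -> Structure:
    """Read one Cα structure from a PDB file.

    Altlocs resolve to the highest-occupancy location (ties broken by
    altloc id, which biotite applies via its ``occupancy`` policy).
    ``model`` is 1-based; default is the first model.
    """
    pdbf = PDBFile.read(str(path))
    atoms = pdbf.get_structure(model=model if model is not None else 1,
                               altloc="occupancy")
    if label is None:
        label = str(path)
    return _atom_array_to_structure(atoms, label, chain)


def read_ensemble_pdb(path, chain: str | None = None, label: str | None = None) -> Ensemble:
    """Read a multi-model PDB (MODEL/ENDMDL) into an Ensemble."""
    pdbf = PDBFile.read(str(path))
    n_models = pdbf.get_model_count()
    base = label if label is not None else str(path)
    structures = [
        _atom_array_to_structure(
            pdbf.get_structure(model=m, altloc="occupancy"), f"{base}#{m}", chain)
        for m in range(1, n_models + 1)
    ]
    return build_ensemble(structures)


def write_ensemble_pdb(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a Cα-only multi-model PDB."""
    n = ensemble.n_residues
    template = struc.AtomArray(n)
    for i, (ch, num, icode) in enumerate(ensemble.residue_keys):
        template.chain_id[i] = ch
        template.res_id[i] = num
        template.ins_code[i] = icode
        template.res_name[i] = "GLY"
        template.atom_name[i] = "CA"
        template.element[i] = "C"
        template.hetero[i] = False
    stack = struc.stack([template] * ensemble.n_conformers)
    stack.coord = np.round(ensemble.coords, 3)
    pdbf = PDBFile()
    pdbf.set_structure(stack)
    pdbf.write(str(path))


def write_structure_pdb(structure: Structure, path) -> None:
    ens = Ensemble([structure.label], structure.residue_keys,
                   structure.coords[None, :, :])
    write_ensemble_pdb(ens, path)


def write_coordinate_table(ensemble: Ensemble, path) -> None:
    """Whitespace-delimited M×3N coordinate table (one conformer per row)."""
    flat = ensemble.coords.reshape(ensemble.n_conformers, -1)
    np.savetxt(str(path), flat, fmt="%.6f")


def read_coordinate_table(path, residue_keys=None, label: str = "table") -> Ensemble:
    flat = np.atleast_2d(np.loadtxt(str(path)))
    if flat.shape[1] % 3:
        raise FormatError("coordinate table width is not a multiple of 3")
    n = flat.shape[1] // 3
    if residue_keys is None:
        residue_keys = tuple(("A", i + 1, "") for i in range(n))
    coords = flat.reshape(flat.shape[0], n, 3)
    labels = [f"{label}#{i + 1}" for i in range(flat.shape[0])]
    return Ensemble(labels, tuple(residue_keys), coords)


# ---------------------------------------------------------------------------
# Ensemble construction and superposition
# ---------------------------------------------------------------------------

def build_ensemble(structures: list[Structure],
                   mapping: str | dict = "intersection") -> Ensemble:
    """Assemble structures into an ensemble over their common residue core.

    ``mapping="intersection"`` keeps residues present in every structure,
    ordered as in the first one.  Alternatively pass an explicit key map:
    ``{structure_label: {common_key: that_structure's_key}}`` for homologs
    whose numbering differs.
    """
    if not structures:
        raise ValueError("need at least one structure")
    if mapping == "intersection":
        common = set(structures[0].residue_keys)
        for s in structures[1:]:
            common &= set(s.residue_keys)
        if not common:
            raise AlignmentError("residue-key intersection is empty")
        keys = tuple(k for k in structures[0].residue_keys if k in common)
        coords = np.empty((len(structures), len(keys), 3))
        for m, s in enumerate(structures):
            idx = [s.residue_keys.index(k) for k in keys]
            coords[m] = s.coords[idx]
    else:
        keymap: dict = mapping
        keys = tuple(next(iter(keymap.values())).keys())
        coords = np.empty((len(structures), len(keys), 3))
        for m, s in enumerate(structures):
            smap = keymap[s.label]
            idx = [s.index_of(smap[k]) for k in keys]
            coords[m] = s.coords[idx]
    labels = [s.label for s in structures]
    return Ensemble(labels, keys, coords, superposed=False)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed coordinates and the minimized RMSD (Å).  The
    rotation is always proper (no reflection).
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
    mob_c = np.average(mobile, axis=0, weights=w)
    ref_c = np.average(reference, axis=0, weights=w)
    with warnings.catch_warnings():
        # align_vectors warns for exact (noise-free) alignments
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(reference - ref_c, mobile - mob_c,
                                           weights=w)
    moved = rot.apply(mobile - mob_c) + ref_c
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - reference) ** 2) / np.sum(w)))
    return moved, rmsd


def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = True) -> float:
    """RMSD between two coordinate sets, optimally superposed by default."""
    if superpose:
        return kabsch_superpose(a, b)[1]
    d = np.asarray(a, float) - np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def superpose_to_mean(ensemble: Ensemble, max_iter: int = 20,
                      tol: float = 1e-4) -> Ensemble:
    """Iteratively superpose all conformers onto their running mean.

    Stops when the mean structure shifts by less than ``tol`` Å RMSD between
    iterations.  Returns a new superposed Ensemble with ``reference_mean``
    set.
    """
    coords = ensemble.coords.copy()
    mean = coords[0].copy()
    for _ in range(max_iter):
        for m in range(coords.shape[0]):
            coords[m], _ = kabsch_superpose(coords[m], mean)
        new_mean = coords.mean(axis=0)
        shift = rmsd(new_mean, mean, superpose=False)
        mean = new_mean
        if shift < tol:
            break
    else:
        logger.warning("superpose_to_mean: no convergence in %d iterations "
                       "(last mean shift %.2e Å)", max_iter, shift)
    return Ensemble(list(ensemble.labels), ensemble.residue_keys, coords,
                    superposed=True, reference_mean=mean, meta=ensemble.meta)


def rmsd_profile(ensemble: Ensemble, reference: Structure) -> np.ndarray:
    """Per-conformer RMSD to a reference, each independently superposed."""
    if ensemble.residue_keys != reference.residue_keys:
        common = [k for k in reference.residue_keys if k in set(ensemble.residue_keys)]
        if not common:
            raise AlignmentError("ensemble and reference share no residues")
        ei = [ensemble.residue_keys.index(k) for k in common]
        ri = [reference.residue_keys.index(k) for k in common]
        ens_coords = ensemble.coords[:, ei]
        ref_coords = reference.coords[ri]
    else:
        ens_coords = ensemble.coords
        ref_coords = reference.coords
    return np.array([kabsch_superpose(c, ref_coords)[1] for c in ens_coords])
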