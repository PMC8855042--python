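"""ENM-based conformer generation schemes.

Three generation schemes, reduced to their geometric/ENM cores (no
force-field relaxation, no MD engine):

* ``clustenm_sample`` — iterative generations of mode deformations at a
  target RMSD, hierarchical clustering of the children, and propagation of
  cluster medoids as the next generation's parents.  Two deformation
  flavours: deterministic ± single-mode steps, or random unit combinations
  of the low modes.
* ``comd_anmmc_sample`` — ANM Monte-Carlo walking: single modes are drawn
  with probability ∝ 1/λ (soft modes dominate), each applied as a small
  fixed-RMSD step, accumulating until a per-cycle RMSD target is reached;
  every cycle-end conformer is accepted (pure exploration regime) and the
  modes are recomputed at the start of each cycle.
* ``mdenm_directions`` — RMSD-filtered random combinations of the lowest
  modes: a candidate direction is accepted only if its 1 Å deformation lies
  farther than a threshold RMSD from every previously accepted deformation,
  maximizing directional coverage.

All samplers are deterministic under a seed.  Instead of the original
methods' energy minimization, a structure can be relaxed on a
parent-anchored elastic potential with a soft-sphere clash term
(``relax_conformer``); by default conformers are left unrelaxed and the
lineage table records this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .enm import AnisotropicNetworkModel, combine_modes, random_combination, scale_to_rmsd
from .structures import Ensemble, Structure, kabsch_superpose, rmsd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    """Parameters of the three generation schemes.

    Defaults follow the common protocol of the hybrid-method benchmarks:
    3 lowest nonzero modes, 1 Å deformation RMSD, 5 generations, 3 runs for
    the cluster-based scheme; 0.1 Å per-mode step, a 1.0–1.5 Å per-cycle
    RMSD window and 50 cycles for the mode-walking scheme.
    """

    n_modes: int = 3
    deformation_rmsd: float = 1.0       # Å per generation / per child
    n_generations: int = 5
    n_runs: int = 3
    representatives: int = 4            # cluster medoids passed on per generation
    children_per_parent: int = 6        # random-combination children (ClustENMD mode)
    anm_cutoff: float = 15.0
    anm_gamma: float = 1.0
    relax: str = "none"                 # "none" | "elastic"
    # coMD / ANM-MC
    comd_step_rmsd: float = 0.1         # Å per accepted mode step
    comd_cycle_rmsd: tuple[float, float] = (1.0, 1.5)  # per-cycle RMSD window
    comd_n_cycles: int = 50
    comd_max_substeps: int = 5000
    comd_prob_exponent: float = 1.0     # selection probability ∝ λ^-exponent
    # MDeNM
    mdenm_n_replicas: int = 12
    mdenm_rmsd_threshold: float = 1.0   # Å between accepted deformed structures
    mdenm_displacement: float = 1.0     # Å deformation per direction
    mdenm_max_attempts: int | None = None  # default: 200 × n_replicas
    seed: int = 0

    def __post_init__(self):
        for name in ("n_modes", "n_generations", "n_runs", "representatives",
                     "children_per_parent", "comd_n_cycles", "mdenm_n_replicas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.deformation_rmsd <= 0 or self.comd_step_rmsd <= 0:
            raise ValueError("deformation RMSDs must be positive")
        lo, hi = self.comd_cycle_rmsd
        if not (0 < lo <= hi):
            raise ValueError("comd_cycle_rmsd window must satisfy 0 < lo <= hi")


def _anm_modes(coords: np.ndarray, config: SamplerConfig):
    model = AnisotropicNetworkModel(coords, cutoff=config.anm_cutoff,
                                    gamma=config.anm_gamma)
    return model.fit(n_modes=config.n_modes)


# ---------------------------------------------------------------------------
# Elastic relaxation stand-in
# ---------------------------------------------------------------------------

def relax_conformer(conformer: np.ndarray, parent: np.ndarray,
                    mode: str = "none", cutoff: float = 15.0,
                    gamma: float = 1.0, clash_distance: float = 3.5,
                    clash_k: float = 10.0, force_tol: float = 1e-3,
                    max_steps: int = 500) -> np.ndarray:
    """Relax a conformer on a parent-anchored harmonic network.

    ``mode="none"`` returns the input unchanged.  ``mode="elastic"`` runs
    steepest descent on V = ½γ Σ_contacts (r_ij − r⁰_ij)² plus a soft-sphere
    penalty k(d_clash − r_ij)² for non-contact pairs closer than
    ``clash_distance`` Å, until the max force component drops below
    ``force_tol``.  Steps are halved on energy increase.
    """
    if mode == "none":
        return conformer.copy()
    if mode != "elastic":
        raise ValueError(f"unknown relaxation mode {mode!r}")
    x = np.asarray(conformer, float).copy()
    parent = np.asarray(parent, float)
    n = x.shape[0]
    pdiff = parent[:, None, :] - parent[None, :, :]
    pdist = np.sqrt(np.sum(pdiff * pdiff, axis=2))
    contact = (pdist <= cutoff)
    np.fill_diagonal(contact, False)

    def energy_forces(coords):
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt(np.sum(diff * diff, axis=2))
        np.fill_diagonal(dist, np.inf)
        e = 0.0
        f = np.zeros_like(coords)
        # harmonic springs at parent rest lengths
        dr = np.where(contact, dist - pdist, 0.0)
        e += 0.25 * gamma * np.sum(dr * dr)  # pairs counted twice
        coef = np.where(contact, -gamma * dr / dist, 0.0)
        f += np.einsum("ij,ijk->ik", coef, diff)
        # soft-sphere clash among non-contact pairs
        clash = (~contact) & (dist < clash_distance)
        if np.any(clash):
            pen = np.where(clash, clash_distance - dist, 0.0)
            e += 0.5 * clash_k * np.sum(pen * pen)
            ccoef = np.where(clash, clash_k * pen / dist, 0.0)
            f += np.einsum("ij,ijk->ik", ccoef, diff)
        return e, f

    step = 0.05
    e, f = energy_forces(x)
    for _ in range(max_steps):
        if np.max(np.abs(f)) < force_tol:
            break
        trial = x + step * f
        e_t, f_t = energy_forces(trial)
        if e_t <= e:
            x, e, f = trial, e_t, f_t
            step = min(step * 1.2, 0.5)
        else:
            step *= 0.5
            if step < 1e-8:
                logger.warning("relax_conformer: step underflow, stopping")
                break
    else:
        logger.warning("relax_conformer: force tolerance not reached in "
                       "%d steps", max_steps)
    drift = rmsd(x, conformer, superpose=False)
    logger.debug("relaxation drift %.3f Å", drift)
    return x


# ---------------------------------------------------------------------------
# ClustENM / ClustENMD
# ---------------------------------------------------------------------------

def _cluster_medoids(coords: list[np.ndarray], n_clusters: int) -> list[int]:
    """Average-linkage clustering on the pairwise-RMSD matrix; returns the
    medoid index of each cluster."""
    m = len(coords)
    if m <= n_clusters:
        return list(range(m))
    dmat = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dmat[i, j] = dmat[j, i] = rmsd(coords[i], coords[j])
    z = linkage(squareform(dmat, checks=False), method="average")
    assignment = fcluster(z, t=n_clusters, criterion="maxclust")
    medoids = []
    for c in np.unique(assignment):
        members = np.nonzero(assignment == c)[0]
        within = dmat[np.ix_(members, members)]
        medoids.append(int(members[np.argmin(within.sum(axis=1))]))
    return sorted(medoids)


def clustenm_sample(start: Structure, config: SamplerConfig | None = None,
                    variant: str = "clustenmd") -> Ensemble:
    """Iterative generate→cluster→propagate sampling from one structure.

    ``variant="clustenm"`` deforms each parent by ±1 target-RMSD step along
    each of the ``n_modes`` lowest modes (2·n_modes children per parent);
    ``variant="clustenmd"`` draws ``children_per_parent`` random unit
    combinations of those modes instead.  ANM modes are recomputed for every
    parent in every generation.  All children of all ``n_runs`` runs
    accumulate into the returned ensemble; the ``meta`` table records run,
    generation, parent and RMSD-to-parent/start lineage.
    """
    if config is None:
        config = SamplerConfig()
    if variant not in ("clustenm", "clustenmd"):
        raise ValueError(f"unknown variant {variant!r}")
    n = start.n_residues
    all_coords = [start.coords.copy()]
    meta_rows = [dict(conformer=0, run=-1, generation=0, parent=-1,
                      rmsd_to_parent=0.0, rmsd_to_start=0.0, relaxed=False)]
    labels = [f"{start.label}|start"]
    for run in range(config.n_runs):
        rng = np.random.default_rng(config.seed + run)
        parents = [start.coords.copy()]
        parent_ids = [0]
        for gen in range(1, config.n_generations + 1):
            children, child_meta = [], []
            for p_coords, p_id in zip(parents, parent_ids):
                anm = _anm_modes(p_coords, config)
                k = min(config.n_modes, anm.n_modes)
                if variant == "clustenm":
                    combos = []
                    for mode_i in range(k):
                        for sign in (+1.0, -1.0):
                            c = np.zeros(k)
                            c[mode_i] = sign
                            combos.append(c)
                else:
                    combos = [random_combination(k, rng)
                              for _ in range(config.children_per_parent)]
                for c in combos:
                    disp = combine_modes(anm, c)
                    disp = scale_to_rmsd(disp, config.deformation_rmsd, n)
                    child = p_coords + disp.reshape(n, 3)
                    relaxed = relax_conformer(child, p_coords, config.relax,
                                              cutoff=config.anm_cutoff,
                                              gamma=config.anm_gamma)
                    children.append(relaxed)
                    child_meta.append(dict(
                        run=run, generation=gen, parent=p_id,
                        rmsd_to_parent=rmsd(child, p_coords, superpose=False),
                        rmsd_to_start=rmsd(relaxed, start.coords),
                        relaxed=config.relax != "none"))
            if not children:
                raise ValueError("generation produced no children; check config")
            first_new = len(all_coords)
            for cc, cm in zip(children, child_meta):
                cm["conformer"] = len(all_coords)
                all_coords.append(cc)
                meta_rows.append(cm)
                labels.append(f"{start.label}|r{run}g{cm['generation']}"
                              f"c{cm['conformer']}")
            reps = _cluster_medoids(children, config.representatives)
            if not reps:
                raise ValueError("clustering produced no representatives")
            parents = [children[i] for i in reps]
            parent_ids = [first_new + i for i in reps]
    ens = Ensemble(labels, start.residue_keys, np.asarray(all_coords),
                   meta=pd.DataFrame(meta_rows))
    return ens


# ---------------------------------------------------------------------------
# coMD-style ANM-MC walking
# ---------------------------------------------------------------------------

def _mode_probabilities(eigenvalues: np.ndarray, exponent: float) -> np.ndarray:
    w = eigenvalues.astype(float) ** (-exponent)
    return w / w.sum()


def comd_anmmc_sample(start: Structure, config: SamplerConfig | None = None) -> Ensemble:
    """ANM-MC exploration: one conformer per cycle per run.

    Each cycle recomputes the ANM at the cycle's starting conformer, then
    repeatedly draws one of the ``n_modes`` lowest modes with probability
    ∝ λ^−1 (softer modes more probable) and applies a ±0.1 Å RMSD step
    along it until the conformer's RMSD from the cycle start reaches a
    per-cycle target drawn uniformly from the configured window (default
    1.0–1.5 Å).  The final sub-step is shrunk by bisection so the cycle-end
    RMSD meets the target to ~1e−8 Å.  Every cycle end is accepted
    (Metropolis acceptance probability 1: exploration, not transition
    pathing).
    """
    if config is None:
        config = SamplerConfig()
    n = start.n_residues
    all_coords: list[np.ndarray] = []
    labels: list[str] = []
    meta_rows: list[dict] = []
    lo, hi = config.comd_cycle_rmsd
    for run in range(config.n_runs):
        rng = np.random.default_rng(config.seed + run)
        current = start.coords.copy()
        # each run contributes its starting snapshot (cycle 0)
        meta_rows.append(dict(conformer=len(all_coords), run=run, cycle=0,
                              rmsd_to_cycle_start=0.0, rmsd_to_start=0.0,
                              substeps=0))
        labels.append(f"{start.label}|r{run}start")
        all_coords.append(current.copy())
        for cycle in range(1, config.comd_n_cycles + 1):
            anm = _anm_modes(current, config)
            probs = _mode_probabilities(anm.eigenvalues, config.comd_prob_exponent)
            cycle_start = current.copy()
            target = float(rng.uniform(lo, hi))
            substeps = 0
            while substeps < config.comd_max_substeps:
                k = int(rng.choice(anm.n_modes, p=probs))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                step = scale_to_rmsd(sign * anm.modes[:, k],
                                     config.comd_step_rmsd, n).reshape(n, 3)
                trial = current + step
                substeps += 1
                if rmsd(trial, cycle_start, superpose=False) >= target:
                    # bisect the final sub-step amplitude onto the target
                    s_lo, s_hi = 0.0, 1.0
                    for _ in range(60):
                        s = 0.5 * (s_lo + s_hi)
                        r = rmsd(current + s * step, cycle_start,
                                 superpose=False)
                        if r < target:
                            s_lo = s
                        else:
                            s_hi = s
                    current = current + s_hi * step
                    break
                current = trial
            else:
                logger.warning("coMD run %d cycle %d: target %.2f Å not "
                               "reached in %d sub-steps; cycle truncated",
                               run, cycle, target, substeps)
            meta_rows.append(dict(
                conformer=len(all_coords), run=run, cycle=cycle,
                rmsd_to_cycle_start=rmsd(current, cycle_start, superpose=False),
                rmsd_to_start=rmsd(current, start.coords), substeps=substeps))
            labels.append(f"{start.label}|r{run}cyc{cycle}")
            all_coords.append(current.copy())
    return Ensemble(labels, start.residue_keys, np.asarray(all_coords),
                    meta=pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# MDeNM excitation directions
# ---------------------------------------------------------------------------

def mdenm_directions(start: Structure, config: SamplerConfig | None = None
                     ) -> tuple[np.ndarray, Ensemble]:
    """RMSD-filtered random excitation directions.

    Draws random unit combinations of the ``n_modes`` lowest modes of the
    start structure's ANM, deforms the start by ``mdenm_displacement`` Å
    along each, and accepts a candidate only if its deformed structure is
    more than ``mdenm_rmsd_threshold`` Å (superposed RMSD) from every
    previously accepted one.  Stops at ``mdenm_n_replicas`` accepted
    directions or when the attempt budget is exhausted (warning).

    Returns the accepted unit coefficient vectors (stacked rows) and the
    ensemble of deformed structures.
    """
    if config is None:
        config = SamplerConfig()
    if config.mdenm_rmsd_threshold >= 2 * config.mdenm_displacement:
        logger.warning("rmsd_threshold >= 2×displacement: at most two "
                       "antipodal directions can be accepted")
    rng = np.random.default_rng(config.seed)
    anm = _anm_modes(start.coords, config)
    k = min(config.n_modes, anm.n_modes)
    n = start.n_residues
    budget = (config.mdenm_max_attempts if config.mdenm_max_attempts
              else 200 * config.mdenm_n_replicas)
    accepted_coeffs: list[np.ndarray] = []
    deformed: list[np.ndarray] = []
    attempts = 0
    while len(accepted_coeffs) < config.mdenm_n_replicas and attempts < budget:
        attempts += 1
        c = random_combination(k, rng)
        disp = scale_to_rmsd(combine_modes(anm, c), config.mdenm_displacement, n)
        cand = start.coords + disp.reshape(n, 3)
        if all(rmsd(cand, prev) > config.mdenm_rmsd_threshold
               for prev in deformed):
            accepted_coeffs.append(c)
            deformed.append(cand)
    if len(accepted_coeffs) < config.mdenm_n_replicas:
        logger.warning("mdenm_directions: budget of %d attempts exhausted; "
                       "returning %d of %d directions", budget,
                       len(accepted_coeffs), config.mdenm_n_replicas)
    labels = [f"{start.label}|dir{i + 1}" for i in range(len(deformed))]
    meta = pd.DataFrame(dict(conformer=np.arange(len(deformed)),
                             rmsd_to_start=[rmsd(d, start.coords, superpose=False)
                                            for d in deformed]))
    ens = Ensemble(labels, start.residue_keys, np.asarray(deformed), meta=meta)
    return np.asarray(accepted_coeffs), ens
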