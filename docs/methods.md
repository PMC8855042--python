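# Methods

## Structural model and containers

All analysis operates on Cα traces.  A `Structure` is an ordered list of
residue keys `(chain, author residue number, insertion code)` with an
`(N, 3)` coordinate array in Å; an `Ensemble` stacks M conformers over a
common residue frame.  Ensembles built from heterogeneous structures keep
only the intersection of residue keys (ordered as in the first structure);
missing residues therefore shrink the common core rather than being
imputed.  Homologs whose numbering differs are mapped with an explicit
user-supplied key map — no sequence aligner is embedded, because the
intended inputs are pre-aligned ensembles.  Altloc conflicts resolve to
the highest-occupancy location (ties by altloc id); residues without a Cα
are skipped with a warning.

Superposition is the unweighted Kabsch fit over all common Cα
(per-residue weights are accepted as an option), computed with
`scipy.spatial.transform.Rotation.align_vectors`, which returns the
globally optimal proper rotation (det = +1, never a reflection).
`superpose_to_mean` iterates fit-to-running-mean until the mean moves less
than 1e-4 Å RMSD (default), which converges in a handful of passes for
anything unimodal and is the standard preprocessing before PCA and RMSF.

## Anisotropic network model

The ANM treats the Cα trace as nodes joined by identical harmonic springs
(force constant γ) for every pair within a cutoff `r_c`.  The potential
`V = ½γ Σ_{d⁰_ij ≤ r_c} (d_ij − d⁰_ij)²` yields the 3N×3N Hessian with
off-diagonal super-elements `−γ/d² · r rᵀ` and diagonal blocks equal to
minus the sum of their row.  Defaults are `r_c = 15 Å` and `γ = 1`
(arbitrary units) — the conventional single-parameter Cα-ANM choice; both
are configurable, and spring constants are deliberately not
distance-weighted.  A connected network has exactly six zero eigenvalues
(rigid translations and rotations); eigenvalues below `1e-8 × λ_max`
are counted as zero modes, and more than six triggers a
disconnected-network warning.  "The three lowest modes" always means the
three lowest *nonzero* modes after discarding the rigid-body six.

Diagonalization is dense (`scipy.linalg.eigh`), adequate up to ~2000
residues; mode signs follow the convention that each mode's
largest-magnitude component is positive, which stabilizes regression
comparisons (all overlap/RWSIP quantities use squared or absolute inner
products, so the convention never changes results).

## Samplers

All three samplers share two primitives: uniform sampling of unit
coefficient vectors on the k-sphere (normalized Gaussian draws) and exact
RMSD scaling of a 3N displacement (`scale = target·√N/‖d‖`).  Every
sampler is bit-reproducible given a seed; parallel runs derive their
generators as `seed + run_index`.

**Generation–clustering scheme (ClustENM/ClustENMD style).**  Per
generation, the ANM is recomputed for each parent; children are produced
either as deterministic ± deformations along each of the 3 lowest modes
(enumerative variant) or as random unit combinations (default variant,
6 children per parent), each scaled to exactly 1.0 Å RMSD from its
parent.  Children are pooled, clustered by average-linkage hierarchical
clustering on the pairwise superposed-RMSD matrix
(`scipy.cluster.hierarchy`, cut to the configured number of clusters),
and cluster medoids (minimum summed within-cluster RMSD) become the next
generation's parents.  Defaults: 5 generations, 3 runs, 4
representatives.  All children from all generations accumulate into the
output ensemble, with a lineage table (run, generation, parent, RMSD to
parent and to start).  The original methods relax conformers by energy
minimization or short MD in a force field; here relaxation is either off
(default — the lineage records conformers as unrelaxed) or an elastic
stand-in: steepest descent on a parent-anchored harmonic network plus a
soft-sphere clash penalty for non-contact pairs closer than 3.5 Å, with
step halving on energy increase.

**Mode-walking scheme (coMD/ANM-MC style).**  Each cycle recomputes the
ANM at the cycle's starting conformer and then repeatedly: draws one of
the 3 lowest modes with probability ∝ λ^−1 (the thermal-amplitude
ordering — the softest mode is the most probable; the exponent is
configurable), picks a random sign, and steps 0.1 Å RMSD along it.  The
cycle ends when the conformer's RMSD from the cycle start reaches a
target drawn uniformly from [1.0, 1.5] Å; because steps are discrete, the
final sub-step's amplitude is bisected so the cycle-end RMSD meets the
target to ~1e-8 Å.  Every cycle end is accepted — the Metropolis
acceptance probability is set to 1, i.e. free exploration around the
start rather than biased transition pathing (two-endpoint pathing with
rejection is out of scope).  One conformer per cycle per run, plus each
run's starting snapshot, gives `runs × (cycles + 1)` conformers — e.g.
9 runs × 50 cycles → 459.

**Excitation-direction scheme (MDeNM style, directions only).**  From a
single ANM of the start, random unit combinations of the 3 lowest modes
are drawn; each candidate deforms the start by 1 Å RMSD, and is accepted
only if the deformed structure lies more than a threshold RMSD
(superposed) from every previously accepted deformation.  This maximizes
directional coverage of the soft-mode subspace.  The default threshold of
1.0 Å gives roughly 50% acceptance on the toy systems (pairwise RMSD
between two independent 1 Å deformations averages ≈ 1.2 Å); the attempt
budget defaults to 200 × the requested replica count, and exhaustion
returns fewer directions with a warning.  The subsequent kinetic
excitation and MD relaxation of the original method are not modelled.

## Ensemble PCA and comparison metrics

PCA eigendecomposes the covariance of superposed Cα coordinates about the
ensemble mean with **1/M (population) normalization** — chosen so the
trace identities hold exactly: Σ all eigenvalues = total coordinate
variance = Σ per-residue RMSF².  Conformers are unweighted (no
occupancy/resolution weighting).  Cross-ensemble projections superpose
each conformer onto the PC model's mean structure before scoring, so a
simulated ensemble can be scored in an experimental ePC frame; per-PC
standard deviations are computed about the PC model's mean (score zero),
not the projected ensemble's own centroid, because they measure the
dispersion of one ensemble in another's frame.

RWSIP pairs eigenvalues by descending rank in the denominator
(`Σ_i λ_i^u λ_i^v`), uses absolute/squared cosines throughout, and is
symmetric, bounded in [0, 1] (Cauchy–Schwarz), exactly 1 on
self-comparison, and equals |u₁·v₁| at n = 1.  Overlap matrices report
absolute correlation cosines; signed variants carry no extra information
under the sign convention above.  The default subspace size is n = 4
components (5 suits strongly hinge-dominated systems and is
configurable).

Distance observables (residue-pair distances, inter-domain centroid
distances) are computed in each conformer's native frame and are
therefore superposition-independent.  Centroids are unweighted Cα
centroids; mass-weighted all-atom centers are not modelled because the
data model is Cα-only, which can shift inter-domain distances by a few
tenths of an Å relative to all-atom centers of mass.  Multi-segment
selections (e.g. a "fingers" subdomain of two sequence ranges) are lists
of (chain, first, last) ranges.  Distance/RMSD histograms default to
Freedman–Diaconis binning; landscape densities use Gaussian KDE with
Scott's-rule bandwidth (both configurable).

## Synthetic data: what it emulates, and what it does not

`toy_structure` builds an ideal α-helix (1.5 Å rise, 100°/residue,
2.3 Å radius), a compact self-avoiding chain with 3.8 Å bonds confined
to a sphere of protein-like density (radius 3.0·N^⅓ Å), or a two-domain
dumbbell of two compact lobes joined by a 4-residue linker whose lowest
ANM mode is inter-lobe hinge motion.  Dumbbells below ~50 residues have
lobes too small to brace the linker and can show a near-zero seventh mode;
the recovery experiments therefore use 50–100 residues.

`gaussian_ensemble` draws conformers `mean + Σ_k c_k u_k` with
`c_k ~ N(0, scale/λ_k)` over an orthonormal mode basis — the same
eigenvalue-to-amplitude convention the mode-walking sampler uses — and
returns the exact ground truth (modes reordered by descending variance =
the true PCs).  `two_state_ensemble` mixes an open and a closed structure
with given populations plus isotropic per-atom Gaussian jitter (a
crystal-noise stand-in; correlated ENM noise can be layered on by feeding
the states through `gaussian_ensemble`).

These generators emulate the *statistical shapes* of experimental
ensembles — unimodal Gaussian clouds, bimodal open/closed sets, narrow
crystal-like distributions — but not their physics: no side chains, no
sequence, no crystal-contact anisotropy, no resolution-dependent noise.
Tests passing on them certify the estimators and samplers
(PCA recovers a known covariance; RWSIP/overlap identities; sampler
geometric contracts), not the biological accuracy of any generated
ensemble.

## Numerical choices and degenerate inputs

* Zero-mode tolerance `1e-8 × λ_max`; coincident nodes within the cutoff
  raise a degenerate-geometry error.
* Kabsch on noise-free congruent sets returns RMSD at machine precision;
  N ≥ 3 non-collinear points are required for a unique rotation.
* PCA requested beyond covariance rank (M−1) truncates with a warning;
  single-conformer RMSF warns and returns zeros.
* Mixture populations must sum to 1; Gaussian mode variances require
  λ > 0; zero displacement cannot be RMSD-scaled.
* Clustering of fewer children than requested representatives returns all
  children; the medoid tie-break is the lowest index.

## Problem sizes

The test suite and the acceptance script run on 30–100-residue toys with
ensembles of up to 5000 conformers — sizes at which the recovery
experiments (truth-vs-recovered RWSIP > 0.98, PC1 overlap > 0.95,
eigenvalue ratios within 10%) are comfortably converged while the full
suite completes in well under a minute of CPU for any single module.
Real proteins of a few hundred residues pose no difficulty for the dense
eigensolver; multi-thousand-residue systems would want a partial sparse
solver, which is a known limitation, as are: no mmCIF input, no
trajectory formats beyond multi-model PDB and plain coordinate tables, no
mass-weighting, Cα-only centroids, and samplers without force-field
relaxation.
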