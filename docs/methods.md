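# Methods

This note records the models implemented in `voltgate`, the assumptions
behind them, the parameters that matter, and the choices made where the
design was genuinely open.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Gating-charge free energies

The gating charge translocated by a voltage-sensor residue is computed
from charging free energies: ΔG_s(V, qᵢ) is the cost of growing the charge
of residue i from 0 to qᵢ in state s under membrane voltage V, estimated by
thermodynamic integration over a charging parameter λ with windows at
0, 0.1, …, 1.0.  The coupling fraction f_s(i) is the difference quotient of
ΔG at two voltages divided by qᵢ(V₂ − V₁) (free energies converted to eV
with 1 kcal/mol = 0.0433641 eV so qV is in e·V; the inverse constant is
derived from this one so unit round-trips are exact in floating point).
Per-residue contributions are Δqᵢ = qᵢ(f_c − f_o); the total is their exact
sum.

Numerical choices:

- **Quadrature** is the trapezoid on the λ grid found in the data — exact
  for constant and linear mean-force profiles, and with the familiar O(h²)
  bias otherwise (the 3λ² test profile integrates to 1.005 rather than
  1.000 on 11 windows).  No higher-order rule is used: 11 noisy points do
  not justify one.
- **Errors**: per-window standard errors come from block averaging
  (sd of block means / √n_blocks, ddof = 1) and are propagated through the
  trapezoid weights in quadrature, then through the coupling-fraction and
  ΔQ arithmetic in quadrature.
- **Defaults**: voltage pair V₁ = 0, V₂ = +0.75 V (the simulated activation
  potential); the seven BK voltage-sensor residues D153, R167, D186, R207,
  R210, R213, E219 with formal charges ±1 ship as the default set, and any
  set is accepted.
- The published per-residue contributions for the Core-MT BK construct are
  shipped as reference data (`BK_VSD_CONTRIBUTIONS_E`); routing them
  through the accumulator gives a full-precision total of 0.462 e, of
  which R210+R213 carry 0.44 e (95.2 % of the raw sum; 97.8 % of the
  one-decimal 0.45 e total).  The package reports full-precision sums and
  leaves the rounding discrepancy visible rather than matching any single
  rounded figure.

The linear-slab validation system plants f = depth exactly (a uniform
field makes the charging Hamiltonian linear in λ, so every window's mean
force is the constant qVd).  The sign convention follows the ΔQ definition
(closed minus open): a positive charge moving to a larger depth fraction
contributes negatively.

## Smeared-charge Poisson electrostatics

Charges are smeared as spherical Gaussians with inverse width
β = 0.25 Å⁻¹ on a 1 Å periodic grid; the density is accumulated with the
Gaussian truncated at 1e−10 of its peak (r ≈ 19.2 Å at the default β).
Periodic images are summed per axis using the separability of the
Gaussian, which remains exact when the box is smaller than the truncation
diameter.  The potential solves ∇²φ = −4πρ spectrally; the k = 0 mode is
zeroed, which fixes the mean-zero gauge and implicitly neutralises any net
charge with a uniform background (flagged on the result).  Internal
potential units are e/Å; 1 e/Å = 14.39964 V.

The membrane voltage is a separate linear ramp with total drop V across
L_z, kept apart from the charge-generated field so the protein's own field
remains inspectable; it is added at export.  The sign convention is
parameterised and defaults to depolarising-positive: potential higher on
the low-z (intracellular) face.  At β = 0.25 Å⁻¹ and 1 Å spacing the
Gaussian is resolved to ~1e−17 at the Nyquist frequency, so the spectral
solve is effectively exact for the smeared density; the remaining
difference from the real-space erf image-sum oracle (≤ ~0.4 % at probes
≥ 2 Å from charges in the 100 Å test box) is dominated by trilinear
interpolation off grid nodes.

Grid dimensions are the ceiling of box/spacing — the spacing is honoured
exactly and the effective box padded virtually to n·h.

## Structural descriptors

- Helix axes are the dominant singular vector of centered Cα coordinates,
  oriented N→C; tilt is the angle to +z folded into [0°, 90°].  An ideal
  discrete helix's principal axis deviates slightly from its geometric
  axis when the residue count is not a whole number of turns, which is why
  the construction contract is ±0.5°.
- RMSD superposes on a separate selection (default: the same selection;
  for pore RMSD the restrained filter region is the natural anchor) via
  Kabsch, then measures over the analysis selection.
- Pore hydration counts water oxygens inside an axial slab whose bounds
  are fixed z values or per-frame selection centers-of-mass, within a
  radial cutoff (default 8 Å — the "inside the pore" radius is not
  sharply defined physically, so it is configurable).  The pore axis
  defaults to the (x, y) center of a chosen anchor selection (the
  selectivity-filter backbone is the stable choice when the filter is
  restrained).
- The pore-radius profile is a simplified axial profiler: per z-slice the
  minimum over nearby atoms (|z_atom − z| ≤ slab_half, default dz) of
  (axis distance − vdW radius), clamped at 0; empty slices report the
  configured maximum probe radius and are flagged.  It is not a
  Monte-Carlo sphere-squeezing profiler.
- Permeation events require a full two-boundary traversal: enter through
  one slab face, exit through the other, without first returning through
  the entry face.  Partial crossings never count; a step jumping the whole
  slab counts as an instantaneous traversal.  Time reversal exactly swaps
  up/down counts.
- Conductance is g = N_net·e/(V·T) with N_net counted along the field.
- Displacements subtract a reference frame with no whole-protein drift
  correction (appropriate when an anchor region is restrained); running
  averages use a centered window (default 100 frames) with edge shrinkage,
  and per-subunit averaging is keyed on chain id.

## Dynamic networks

Contacts: minimum heavy-atom distance ≤ 5 Å in ≥ 75 % of frames;
sequence-adjacent residues are excluded by default (neighbor_exclusion = 1,
set 0 to keep them) to avoid trivial backbone shortcuts.  Correlations use
full 3-D displacement dot products normalised by the per-node fluctuation
magnitudes.  Edge weights are w = −ln |C|: the absolute value extends the
weighting to anti-correlated pairs (a −log of a negative number is
undefined), and the natural-log base only rescales lengths without
changing any path ranking.  Zero-correlation contact edges are dropped
with a warning (infinite length).

Optimal paths use Floyd–Warshall all-pairs distances with greedy
reconstruction that always takes the smallest-labelled neighbour
consistent with the distances — the lexicographically smallest shortest
path, making tie-breaks deterministic.  Suboptimal paths are all simple
paths with length strictly below (1 + tolerance) × optimum (tolerance
0.5), enumerated by depth-first search pruned with the remaining-distance
bound, capped (default 1000) with a truncation flag.  The boundary is
strict: a path at exactly 1.5× the optimum is excluded.

Communities are Girvan–Newman divisive clustering with weighted edge
betweenness (weights as distances) and deterministic tie-breaking (the
lexicographically smallest of the tied edges is removed); the partition —
including the undivided one — maximising modularity on edge strengths
(|C|) is returned.  A caveat the planted-partition tests reflect: on a
*complete* contact graph every shortest path is its direct edge, so edge
betweenness cannot separate blocks regardless of the correlation
structure.  Planted two-block recovery is therefore exercised on the
two-clique-plus-bridge contact topology (each block internally connected,
one inter-block contact), where recovery of 16-node, r = 0.6 vs 0.1
ensembles at 10⁴ frames is exact across seeds.

## Information flow

Node fluctuations are x_t = |r_t − ⟨r⟩| (distance to the equilibrium
position), so x ≥ 0.  Differential entropies come from a Gaussian mixture
fit with the component count selected by BIC over 1–5 components (fixed
seed, 3 restarts) and H = −(1/N)Σ ln ρ̂(xₙ); the joint entropy uses a 2-D
mixture on paired samples, the natural extension of the 1-D estimator.
Entropies and MI are reported in nats.  Three restarts were adopted after
profiling: at the n = 10⁵ sample sizes the closed-form Gaussian oracles
are reproduced to the same tolerance as with ten restarts at a third of
the cost.  Densities with a hard support edge (e.g. exponential) converge
slowly in the mixture size; the BIC keeps selecting the cap and the
estimate carries a positive bias of a few hundredths of a nat at 5
components, so callers needing such densities should raise
`max_components` (the exponential oracle test uses 10).

Estimator contracts: series with fewer than 50 samples or zero range are
rejected; numerically perfectly dependent pairs saturate at a configured
20 nats with a degeneracy flag (the continuous MI diverges); small
negative MI estimates are clamped to 0 and flagged.

The flow network multiplies the boolean contact mask into the MI matrix
(the contact map here is a mask, distinct from the correlation matrix of
the path analysis — the two are never coerced).  With L = D − A, sink
rows/columns are removed, sink potentials are 0, and b injects one unit at
the source; fᵢ = ½Σⱼ|Pᵢ − Pⱼ|A_ij.  Identities maintained by construction
and asserted in tests: Laplacian row sums 0; unit current out of the
source and into the sinks (Kirchhoff, to 1e−10); f at a sole source or
sink exactly 0.5; f invariant under uniform scaling of A; agreement with a
pseudoinverse-based current-flow computation on random graphs.

## Synthetic data and what passing tests show

The generators emulate the statistical structure the analyses consume,
not the physics that produces it:

- Harmonic ensembles draw i.i.d. frames from a planted multivariate
  normal (node-level covariance applied per Cartesian component, or a
  full 3n × 3n covariance).  All in-scope network statistics are
  functions of the stationary distribution, so the absence of kinetics is
  immaterial to them — but nothing here validates autocorrelated-sampling
  effects on real trajectories.
- TI profiles are polynomials in λ with closed-form integrals; noise is
  optional (default 0 so integrals are exact in tests) and the block
  series is constructed so the block-averaged SE estimates the injected
  noise.
- The slab system realises the coupling-fraction bookkeeping exactly
  (f = depth), which validates the arithmetic, not the convergence of
  real charging simulations.
- Ion tracks plant exact full-crossing counts with jitter and
  same-side-retreat distractor tracks that must not count.
- Helix bundles are ideal α-helices (1.5 Å rise, 100° twist, 2.3 Å
  radius) with CA/CB atoms plus sidechain proxy atoms for charged residue
  names, at prescribed tilts.

Every generator is seed-deterministic and returns its ground truth with
the data.  Passing the suite therefore demonstrates correctness of the
estimators and bookkeeping on data satisfying their assumptions; it does
not demonstrate force-field realism, sampling convergence, or robustness
to the non-stationarity of real activation trajectories.

Problem sizes used by the default test and acceptance runs were chosen as
the smallest at which the statistical tolerances are comfortably
resolved: 10⁵ frames for scalar-estimator closed forms, 10⁴ frames for
community recovery, 16-node planted partitions, 200 random graphs (≤ 12
nodes) for path enumeration, 100 for flow conservation, 20 seeds for the
noisy-slab bias check, and a 100 Å box at 1 Å spacing for the Poisson
oracle.

## Known limitations

- The Poisson solver has no dielectric heterogeneity or mobile-ion
  screening; it is the vacuum (uniform-dielectric) smeared-charge map.
- The pore profiler is axial-clearance only (no off-axis probe path).
- GMM-based MI is biased upward for small samples and near support edges;
  the bias decreases with n (asserted on Gaussian fixtures) but is not
  corrected analytically.
- PDB is the only structure dialect; topologies (PSF/TOP), velocities and
  forces are out of scope.  Charges and radii come from the sidecar table,
  never from a force field.
- Girvan–Newman is O(E²·N log N)-ish with weighted betweenness; it is
  meant for residue-scale networks (hundreds of nodes), not atom-scale
  graphs.
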