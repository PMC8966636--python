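# Methods

## Model

The protein is reduced to a two-bead coarse-grained model: one backbone site
per residue at the unweighted centroid of the N, CA, C, O heavy atoms, and one
side-chain site at the centroid of the side-chain heavy atoms (glycine has
none).  Hydrogens are ignored.  Mass-weighting is irrelevant here because the
only quantity taken from normal-mode analysis is the equal-time equilibrium
covariance of a harmonic system, C = k_B·T·H⁺, which does not depend on the
masses.  Centroid placement (rather than CA/CB representative atoms) is the
package's choice; it makes the mapping linear in the atomic coordinates, so it
is exactly equivariant under rigid motions.

The elastic network carries a harmonic potential Σ ½k_ij(l_ij − l_ij⁰)² over
all site pairs whose ensemble-mean distance lies within a cutoff (default
10 Å, configurable).  At the reference geometry each spring contributes
k·êêᵀ blocks to the 3N×3N Hessian (transverse terms vanish at l = l⁰).
Eigenvalues below 10⁻⁸ × the largest are treated as the rigid-body null
space; a graph with more than 6 such modes is flagged as floppy or
disconnected.  Units are kcal mol⁻¹, Å, K with
k_B = 0.0019872 kcal mol⁻¹ K⁻¹.

## Fluctuation matching

Each window's observed statistic is the population variance of the
inter-site distance series, ⟨δl²⟩_obs; the model prediction is the
*linearized* bond-length variance êᵀ(C_ii + C_jj − 2C_ij)ê.  The update

    k′ = k · (⟨δl²⟩_NMA / ⟨δl²⟩_obs)^α ,  clipped to k ≥ k_min

has its fixed point exactly at variance match, respects the inverse
proportionality of stiffness and fluctuation (equipartition), is scale-free
in k, and recovers an isolated spring in a single α = 1 step.  Defaults:
α = 0.3, tolerance 10⁻³ on the maximum relative variance mismatch, 200
iterations, k_init = 1, k_min = 10⁻⁶.  On densely coupled networks the last
decade of mismatch decays slowly, so runs can end unconverged at the default
budget; the result is still accurate (the spring constants move little after
the first ~50 iterations) and the convergence flag, iteration count and final
mismatch are always recorded in the fit report — never silently dropped.
Pairs with zero observed variance (possible only for degenerate synthetic
input) are assigned a capped constant (10³) and flagged rather than allowed to
diverge.

Two deliberate asymmetries of the observable are worth noting.  The *target*
is the variance of the actual distance |x_i − x_j|, which is what an
ensemble provides; the *prediction* is the linearized projection on the
reference bond direction.  These differ at order (σ⊥²/l⁰)², so the fitted k
absorbs a small anharmonic correction; the windowing exists precisely to keep
such anharmonicity small.  Consistency checks between sampling and NMA
therefore compare like with like: the sampled variance of the *projected*
separation, which is exactly Gaussian with the predicted variance.

l⁰ is the window-mean distance and is held fixed across iterations within a
window; the reference geometry is the window-mean structure.  Only internal
distances enter, so the fit is invariant under rigid motion of the input and
no trajectory superposition is performed.

Window defaults: 2000 frames per window with 50 % overlap (stride 1000).  For
a trajectory saved every 1 ps this corresponds to overlapping windows of a
few ns, the scale on which the harmonic approximation holds per window while
leaving enough windows (≈ 9 per 10⁴ frames) for persistence statistics.

## Rigidity graphs

k_IJ sums the constants of all springs joining residues I ≠ J whose site
kinds match the category (BB, BS with both orientations, SS).  To keep the
graphs non-covalent, BB entries at sequence separation ≤ 1 (the peptide bond)
and SS entries across declared disulfides (SG–SG < 2.5 Å) are forced to zero;
the BB separation is configurable since the minimal covalent reading
(separation 1) is a design choice.  Degrees are row sums; the handshake
identity Σd_I = 2Σ_{I<J}k_IJ is a tested invariant.  Window graphs are
averaged elementwise into the mean graph.

## Prominent modes

Mechanically strong modes are eigenvalue outliers by the Tukey boxplot rule
(λ > Q3 + 1.5·IQR) — a standard, parameter-light outlier definition.
Persistence is scored by the mean-mode content r_nα = max_β|ν_nβ·ν_α|
(invariant to window-mode ordering and sign) averaged over windows, and a
mode is persistent when ⟨r_α⟩ exceeds the quantile of a normal distribution
fitted (mean, sd) to the ⟨r_α⟩ sample.  The CDF cutoff defaults to 0.8: with
only as many modes as residues, and a genuinely persistent cluster that can
be a third of the sample, a 0.95 normal quantile frequently lands above the
sample maximum and selects nothing; 0.8 keeps the persistence filter
meaningful while the eigenvalue criterion — intersected to form Π — supplies
the specificity.  Both thresholds are recorded with every selection.
Strongly coupled pairs take all residues with ν²_{α,I} ≥ ν_c² = 0.1 in some
α ∈ Π and keep pairs that are actual graph edges (k̄_IJ > 0) — residues that
merely co-occur in a mode without a direct coupling are not paired.

## Two-state comparison

Δk_IJ = k_resp − k_ref over the union of the two states' pair lists
(reference = the state taken as baseline, e.g. the complex).  The prominent
responses are the top quartile of |Δk|: the threshold is the m-th largest
value with m = ceil(percentile/100 · N), ties included — deterministic and
order-independent.  On/off switches require exact absence (k ≤ zero_tol,
default 0) in one state.  Relay routes pool prominent and on/off pairs across
the three categories (responses mix backbone and side-chain couplings) and
connect two pairs when any residue of one is within seq_gap (default 2,
hard maximum 4) of any residue of the other; connected components with ≥ 2
members are routes.  Whether route linking should demand *both* residues
nearby is not decidable from the method description; the any-residue relation
is the documented default.

## Synthetic data and what it does (not) show

The generator grows a compact self-avoiding chain (3.8 Å spacing, side-chain
sites offset 2 Å), places springs on all pairs within the cutoff plus a
sampled set of beyond-cutoff contacts, and draws k uniformly from
k_range = (0.2, 1.0) kcal mol⁻¹ Å⁻² — a weak, diffuse background.  Ensembles
are sampled exactly from the harmonic Boltzmann distribution (mode-wise
Gaussian with variance k_B·T/λ, rigid-body modes excluded), which is the
correct null model for the learning stage since that stage only consumes
distance-fluctuation statistics.

The two-state benchmark plants, on shared geometry: a route of SS springs
between consecutive residues of a contiguous chain at 12 × the background
maximum, multiplied by the change factor (default 4) in the response state;
four equally stiff *anchor* SS springs left unchanged in both states, so both
states own prominent modes and the union list is non-trivial; and one pruned
plus one added stiff spring as on/off ground truth.  The order-of-magnitude
contrast between planted and background couplings mirrors the sparse,
heavy-tailed coupling distributions seen in real rigidity graphs, and makes
the planted chain's path-graph modes (whose second mode carries the chain
ends at weight² 0.25, safely above ν_c²) the dominant, persistent spectral
features.  The background springs incident to the route's side-chain sites
are additionally raised to 4 × the background maximum in *both* states: a
stiff spring with transversely floppy endpoints acquires a linearization
bias that compresses its learned constant (an estimator property discussed
above), and rigid route side chains keep the benchmark a test of the
comparison machinery rather than of that bias.  Consecutive route side
chains are required to sit 3.5–8 Å apart — nearly coincident sites make the
spring direction, and hence the constant, unidentifiable.

What passing these tests shows: the estimator, spectral selection and
comparison machinery are correct and self-consistent under the model's own
assumptions, at realistic sampling noise.  What they do not show: robustness
to anharmonicity beyond the windowed-harmonic regime, to conformational
change between states (the benchmark holds geometry fixed to isolate the Δk
machinery), to multi-chain proteins, or to force-field/solvent effects —
real MD input remains the user's responsibility.

## Numerical choices

- Eigendecompositions symmetrize the input, sort eigenvalues descending, and
  fix signs (largest-magnitude component positive) for bit-reproducibility.
- Mean-mode contents are clipped to [0, 1] against round-off.
- TSV outputs use `%.17g` and are re-read with round-trip float parsing, so
  bundles reproduce in-memory objects exactly; manifests are written last and
  act as the bundle's commit marker.
- All generators are driven by explicit integer seeds (NumPy `default_rng` /
  `SeedSequence`); identical configuration and seed give byte-identical
  outputs.

## Problem sizes

Default test and acceptance workloads use 30-residue systems (≈ 57 sites),
10³–3×10⁴ frames, and 9 windows per state — sizes chosen so a full two-state
analysis completes in roughly two minutes on one core while leaving the
sampling noise (≈ 3 % per-window variance error at 2000 frames) realistic
enough to exercise the persistence statistics.

## Known limitations

- The absolute k scale is defined by the fluctuation-match itself; no
  independent calibration against experimental elastic moduli is attempted.
- Single chains only; relay contiguity assumes sequence-linear residue
  indexing.
- Slow tail convergence on dense networks (see above); raise `max_iter` or
  `alpha` if strict tolerance matters more than wall time.
- Nucleic acids, ligands and ions have no CG representation.
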