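# Methods

This note documents the models, algorithms, parameter conventions, and known
limitations of `pda`. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## The density contract

A density model supplies ln p(**R**) *up to an additive constant* and its
gradient with respect to all 3n electron coordinates, batched over
configurations. Every downstream operation — Metropolis acceptance ratios,
descent of −ln p, basin counting — uses differences of ln p only, so |Ψ|² is
never normalized. At wavefunction nodes ln p is reported as a large negative
floor (−10³⁰⁰) and gradients as non-finite; the samplers and maximizers treat
such points as infinitely unlikely. Spin enters as a fixed label vector
(mₛ = ±½ per electron): the built-in two-electron singlet densities are
spatially symmetric, while the generic Slater determinant partitions electrons
into α and β blocks by their labels. Permutation invariance (same-spin swaps
exact; opposite-spin swaps exact when the mₛ labels are swapped along) is
asserted by property tests for every model.

## H₂ in the minimal Slater basis

The correlated reference model is the two-configuration expansion
Ψ = c₁ σ_g² + c₂ σ_u² over the bonding/antibonding combinations of 1s Slater
orbitals φ(r) = √(ζ³/π) e^(−ζr) on the two protons. Defaults: bond length
R = 1.4 a₀ (equilibrium) and ζ = 1.0 (the unscaled, conventional minimal-basis
exponent). The CI coefficients are determined variationally from the 2×2
eigenproblem over the σ_g² and σ_u² configurations; at the defaults
c = (0.99386, −0.11065), E(CAS) = −1.10656 Ha versus E(RHF) = −1.09094 Ha.
Setting c = (1, 0) yields the restricted Hartree–Fock model, whose density
factorizes into independent one-electron densities.

One-electron two-center integrals use the standard closed forms. The
two-electron repulsion integrals are evaluated through an exact-L2 projection
of the 1s Slater radial profile onto 24 even-tempered normalized s Gaussians
(the projection solves analytic normal equations; L2 residual ≈ 1e−10), after
which every integral is a closed-form Gaussian integral requiring only the
Boys function F₀. The engine is validated in the test suite against the closed
forms for S, T, V, (AA|AA) = 5ζ/8 and the two-center Coulomb integral
(agreement ~1e−7); the hybrid and exchange integrals then come from the same
validated engine. This choice trades the error-prone special-function closed
forms of the exchange integral for a uniformly accurate numerical route.

**Exponent convention.** The printed reference weights for this system
(2×49% covalent, 2×1.3% ionic) correspond to ζ = 1.0: the model's converged
basin probabilities at the defaults are 48.64% per covalent and 1.36% per
ionic maximum (estimated from three independent 10⁵-sample runs; the printed
values are the 2-significant-figure roundings). The CAS-variationally optimal
exponent ζ ≈ 1.20 instead gives 2×44.2% / 2×5.9% and is clearly not the
published convention, so ζ = 1.0 stays the default. The ~0.35 / 0.06
percentage-point offsets between the model-consistent values and the printed
ones are inherited from the unspecified parameters behind the published
numbers; the acceptance tests assert against the model-consistent values, and
the printed values lie inside the same bands.

## Sampling

A plain Metropolis random walk targets p: every step displaces *all*
electrons by isotropic Gaussians of width `step` and accepts with
min(1, p'/p). Defaults: burn-in 1000 steps, thinning 1, a single walker, and
automatic step tuning to 50% acceptance (geometric bisection on a pilot
chain). The same seed reproduces a sample set bit for bit; a chain whose
acceptance falls below 1% aborts with a diagnostic naming the step size.

Independent parallel walkers (`walkers > 1`) draw from the same stationary
distribution and are interleaved round-robin in the record; they serve two
purposes: vectorized evaluation, and an honest error estimate — the
across-walker spread of any basin fraction is its true Monte Carlo standard
error including within-chain autocorrelation. Large-scale runs in the tests
and the acceptance script use N = 100,000 with thinning 10 and 50 walkers.
These sizes keep a full analysis around a minute on one CPU; the published
setting of 10⁶ samples changes only the error bars.

A caveat the walker-resolved errors make visible: observables that
distinguish configurations *only by their spin labelling* (e.g. which of the
two covalent H₂ maxima a sample belongs to) decorrelate only when the chain
swaps the labels — a rare collective move — so their effective sample size is
far below N even though label-symmetric totals converge at the iid rate.

## Local maximization and basin attribution

−ln p is minimized in two phases:

1. **Capped steepest descent.** Monotone gradient ascent on ln p with the
   per-electron step length capped at `max_step` = 0.1 a₀ and a per-sample
   adaptive backtracking line search (a step is accepted only if ln p does not
   decrease). The cap keeps the minimization local: a sample cannot jump over
   a ridge or node into a neighboring basin. Electron–nucleus cusps are
   handled by capture: an electron entering `capture_radius` = 0.05 a₀ of a
   nucleus with its ascent direction pointing at it is snapped onto the
   nucleus and frozen (maxima with electrons exactly at nuclei are expected —
   H₂, core electrons). Each capture restarts the latency clock.
2. **Trust-boxed quasi-Newton refinement.** After `latency` = 20 descent steps
   without a capture, the free electrons are refined with L-BFGS-B, frozen
   electrons fixed. Each refinement round is bounded to a per-coordinate box
   of half-width `trust_radius` = 0.05 a₀ around its entry point: an
   *unbounded* line search can step across a nodal surface of Ψ (an
   infinitely thin spike of −ln p) into a higher-p neighboring basin, which
   was measured to misattribute ~20% of the H₂ ionic basin. Rounds that end on
   their box, or stall at a cusp outside the capture radius, hand back to a
   renewed descent phase; the cycle repeats up to 12 times.

Convergence requires all electrons frozen, or a free-electron gradient
max-norm ≤ 1e−6 (step max-norm ≤ 1e−8 also terminates). Because a vanishing
gradient also occurs at saddle points — whose basins have measure zero — every
converged sample with free electrons is probed by deterministic axis nudges
(h = 0.02 a₀, ±x/±y/±z per electron); a strict ln p improvement sends the
sample back into descent. The probe only accepts improvements, so the
recorded −ln p trajectory is non-increasing across all phases, which the test
suite asserts pathwise. Samples that exhaust all cycles unconverged are
flagged and excluded from basin counts with a warning.

Per-sample maxima are unified by greedy spherical pre-clustering
(radius 0.01 a₀): maxima are processed by decreasing p and merged
first-fit. *Identity* of two maxima is spin-resolved — they merge only if a
spin-preserving permutation (independent assignment within each spin channel)
brings them within the radius. Maxima that differ by an opposite-spin
permutation (the two covalent H₂ maxima) are genuinely distinct points of the
spin-labelled configuration space and must survive to the clustering stage,
which is what makes the covalent cluster's spin correlation meaningful.

## Metric, clustering, and local clustering

The spinposition distance ignores spin; the configuration metric D is the
maximal single-electron distance under the sum-cost-minimal permutation
(Hungarian algorithm, certified against exhaustive enumeration for n ≤ 6 in
the tests). Single-linkage clustering at threshold d_sim (default 0.2 a₀,
sensible range 0.1–0.4 a₀) is implemented directly as connected components of
the D ≤ d_sim graph — equivalent to DBSCAN at minPts = 1 but using the
best-match metric verbatim. Members of a cluster are index-aligned to the
member with the highest p via best match; an optional `spin_aware` assignment
mode breaks exact cost ties (within 1e−10 a₀) toward fewer spin-label
mismatches, a guard for symmetric molecules where the spatial assignment is
arbitrary and would otherwise scramble spin correlations. Choosing d_sim
follows the standard guideline — separate maxima with different per-nucleus
electron counts, merge spin permutations — and the report's per-cluster
`nucleus_electron_counts` diagnostic shows exactly this.

Local clustering restricts every configuration to the k electrons nearest a
chosen center (ties to the lower index) before any distance is computed,
yielding marginal ("local") cluster probabilities; with k = n it reproduces
global clustering exactly, and merged local clusters carry the sum of their
constituents' global probabilities (asserted on fixtures). Fixed-k selection
keeps the two compared subsets equal-sized so D stays defined.

## Spin correlation and motifs

For an aligned cluster, c_ij = 4⟨mₛ,ᵢ mₛ,ⱼ⟩_C with basin-probability weights;
the diagonal is identically 1 and |c_ij| ≤ 1. Electrons with c_ij ≤ −1 + ε
are spin-coupled; motifs are the connected components of the coupling graph.
ε defaults to 0.05: finite-sample weights make exact ±1 unreachable, and the
empirical distribution of c_ij is strongly tri-modal at {−1, 0, +1} with a gap
around the extremes, so a small tolerance is safe. Within a motif the implied
±-sign pattern is checked for consistency (same-sign pairs must show
c_ij ≥ 1 − ε); non-two-colorable components are flagged rather than split.
Intermediate correlations are reported (and histogrammed, weighted by P_C) but
never form motifs. Dot structures draw edges only between −1 pairs, and spin
colors are canonicalized per motif (first electron spin-up) because only
relative spins within a motif carry information.

## Synthetic data and what the tests show

The Gaussian-mixture fixtures (independent per-electron mixtures, or
symmetrized joint modes) have analytically known maxima, basin boundaries, and
moments; they validate the sampler (closed-form moments, Kolmogorov–Smirnov
against the exact marginal), the maximizer (fixed points, basin boundaries at
symmetry midplanes, binomial basin splits), and the clustering bookkeeping.
They are smooth, low-dimensional, and node-free, so passing them says nothing
about fermionic nodal surfaces or cusps — those are exercised by the H₂ CAS /
RHF models and the Slater-determinant fixture, which carry real cusps, a node,
and near-degenerate basins. None of the built-in models has the
dimensionality, Jastrow correlation, or heavy-atom shell structure of
production wavefunctions; conclusions about large molecules rest on the
algorithms, not on these models. The synthetic "methanol-like" maxima archive
used to exercise local re-clustering is labelled synthetic and encodes its
53/47 bond split by construction.

## Numerical choices and degenerate inputs

- All lengths in bohr internally; XYZ input defaults to angstrom
  (1 Å = 1.8897261258369282 a₀) unless the file or caller declares bohr.
- Ties: pre-clustering processes equal-p maxima in stable input order;
  subset selection breaks distance ties toward the lower electron index;
  representative selection breaks value ties toward the stable member order.
- Maxima archives store exact float64 positions; report YAML is emitted with
  deterministic key order so equal-seed runs are byte-identical.
- Degenerate requests fail loudly as contract errors: mismatched spin counts,
  k larger than n, non-positive radii, d_sim ≤ pre-clustering radius,
  starting a maximization on a node.

## Known limitations

- No production wavefunctions: Slater–Jastrow ansätze, basis-set machinery,
  and DFT/SCF beyond the H₂ 2×2 CI are out of scope; the generic determinant
  accepts only s-type Slater orbitals.
- Basin attribution is approximate near basin boundaries: any finite-step
  scheme can cross a finite ridge. The step cap, trust box, and saddle probe
  bound the effect (measured ≤ 0.05 percentage points on the H₂ ionic weight
  against a descent-only reference) but do not eliminate it.
- The importer for externally deposited maxima reads this package's
  self-describing HDF5 layout; proprietary QMC binary layouts are not parsed.
- Automatic symmetry detection is not attempted; for symmetric molecules the
  `spin_aware` assignment mode and a reduced d_sim are the provided remedies.
- No interactive 3-D visualization; dot structures are exported as YAML and
  extended XYZ for external viewers.
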