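# pda — probability density analysis of many-electron densities

`pda` analyzes the all-electron probability density p(**R**) = |Ψ(**R**)|² of a
molecule through its *local maxima*: the most likely arrangements of all n
electrons at once. Each maximum R\* owns a basin of attraction Ω(R\*), and the
probability

P(R\*) = ∫<sub>Ω(R\*)</sub> p(**R**) d**R** ≈ N(R\*)/N

of finding the electrons inside that basin is estimated by Monte Carlo
counting: sample N configurations from p, maximize each one locally, and count
how many land in each basin. Maxima that differ only by electron permutations
or small displacements are grouped by single-linkage clustering under the
best-match metric

D(A, B) = max<sub>i</sub> |a<sub>π(i)</sub> − b<sub>i</sub>|,
  π = argmin Σ<sub>i</sub> |a<sub>π(i)</sub> − b<sub>i</sub>| (Hungarian algorithm),

and each cluster C gets a probability P<sub>C</sub> = Σ P(R\*) and a spin-correlation
matrix c<sub>ij</sub> = 4⟨m<sub>s,i</sub> m<sub>s,j</sub>⟩<sub>C</sub> ∈ [−1, 1]. Pairs with
c<sub>ij</sub> = −1 ("spin-coupled") are joined into *electron motifs* — the
generalization of the Lewis electron pair — and a cluster's representative
maximum annotated with spins and motif edges is its *ab initio dot structure*.
For H₂ this machinery recovers the three Lewis structures (H–H, H⁻ H⁺, H⁺ H⁻)
with quantitative weights; the same pipeline applies to any density model that
can report ln p and its gradient.

The package is aimed at quantum Monte Carlo / electronic-structure researchers
who want basin probabilities, cluster weights, and spin-coupling motifs from a
wavefunction, plus re-clustering of externally produced maxima archives.

## What is included

- **wavefunctions** — the density-model contract (batched ln p and ∇ln p up to
  a constant) with built-in models: H₂ CAS(2,2) in the minimal 1s Slater basis
  with variationally determined CI coefficients, the H₂ restricted
  Hartree–Fock determinant, a generic Slater determinant over user-supplied
  s-type orbitals, and analytic Gaussian-mixture fixtures.
- **sampling** — Metropolis random walk (variational-Monte-Carlo style) with
  step tuning, burn-in/thinning, and optional parallel independent walkers.
- **maximization** — two-phase minimization of −ln p: step-capped monotone
  steepest descent with nuclear-capture handling of the electron–nucleus cusp,
  then trust-boxed L-BFGS-B refinement; basin attribution and counting.
- **assignment / clustering** — best-match permutation metric, greedy
  spherical pre-clustering, single-linkage clustering at threshold d_sim,
  local (bond-restricted) clustering with marginal probabilities.
- **motifs** — spin-correlation matrices, motif extraction, dot-structure
  assembly, correlation histograms.
- **io / CLI** — XYZ input, HDF5 sample/maxima archives, YAML reports,
  extended-XYZ dot-structure export, `pda run` and `pda recluster`.

## Worked example

Analyze the correlated H₂ ground state (bond length 1.4 a₀, ζ = 1.0) with
20,000 samples, clustering maxima at d_sim = 1.0 a₀:

```bash
$ pda run --model h2_cas --samples 20000 --seed 1 --dsim 1.0 --out h2_demo
4 maxima, 3 clusters -> h2_demo/report.yaml
```

The report (`h2_demo/report.yaml`) contains, per cluster, the probability,
members, representative configuration, per-nucleus electron counts, the
spin-correlation matrix and the motifs. For this run:

| cluster | P_C | members | electrons per nucleus | electron z-positions (a₀) | c₀₁ |
|---|---|---|---|---|---|
| covalent | 0.9707 | 2 | [1, 1] | −0.7, +0.7 | −1.0 |
| ionic (left) | 0.0158 | 1 | [2, 0] | −0.7, −0.7 | −1.0 |
| ionic (right) | 0.0136 | 1 | [0, 2] | +0.7, +0.7 | −1.0 |

All four maxima place both electrons exactly on the nuclei. The covalent
cluster holds the two maxima that differ only in which spin sits on which
proton; its spin correlation c₀₁ = −1 marks the two electrons as spin-coupled,
so they form a single two-electron motif — the Lewis bond pair. The dot
structure is written both as YAML and as extended XYZ with electrons as
pseudo-atoms `X`:

```
4
units=bohr Properties=species:S:1:pos:R:3:spin:R:1 probability=0.97065
H 0.0000000000 0.0000000000 -0.7000000000 0.0
H 0.0000000000 0.0000000000 0.7000000000 0.0
X 0.0000000000 0.0000000000 -0.7000000000 +0.5
X 0.0000000000 0.0000000000 0.7000000000 -0.5
```

Archived maxima (`h2_demo/maxima.h5`) can be re-clustered without re-sampling,
including locally around a bond center (the k nearest electrons only):

```bash
pda recluster h2_demo/maxima.h5 --dsim 0.2 --local 0,0,0:2 --out h2_re
```

The same pipeline is available as a library:

```python
import pda

model = pda.build_h2_cas(1.4, 1.0)           # c = (0.9939, -0.1106), variational
samples = pda.sample(model, 20_000, seed=1)
maxima = pda.attribute_samples(model, samples)
clusters = pda.single_linkage(maxima, pda.ClusteringParams(d_sim=1.0),
                              n_total=len(samples))
matrix = pda.spin_correlation(clusters[0])   # c_01 = -1
```

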