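# soletrace

Dual-tracer analysis of fine-scale fish population structure, combining SNP
genotypes (an evolutionary-timescale tracer) and otolith shape (an
ecological-timescale tracer). The package targets the situation of a weakly
structured marine stock — such as common sole sampled from three putative
subunits (SW, NE, UK) of a single management area — where each tracer alone
gives a subtle signal and the question is how their discriminatory powers
compare. It is written for fisheries and population-genetics researchers who
want the whole chain, from raw outlines and genotype matrices to assignment
matrices, as reusable, tested Python.

Because studies of this kind rarely deposit raw fish data, the package ships
a first-class synthetic-data generator that reproduces the statistical
structure the analysis assumes (unbalanced three-subunit sampling, weak
differentiation, confounded shape effects), so every stage is testable and
every result below is reproducible from a seed.

## What it computes

**Otolith shape.** Closed outlines are expanded in elliptical Fourier
descriptors: harmonic *k* carries coefficients (a_k, b_k, c_k, d_k), and the
expansion is normalized on the first harmonic for size, rotation and
starting-point invariance (left otoliths are mirrored into the right-side
frame first). The harmonic count n_j per otolith is the smallest n with
cumulative Fourier power

F(n) = Σ_{k≤n} (a_k² + b_k² + c_k² + d_k²)/2

reaching 99.9% of the total at K_max = 99, and the sample is described with
n = max_j(n_j) harmonics. Harmonics 2..n form a descriptor matrix reduced by
centered PCA to the fewest components explaining ≥ 99% of variance (the shape
matrix S). Alongside, five scalar indices are computed from otolith length
L0, width l0, perimeter P0 and area A0: ellipticity (L0−l0)/(L0+l0),
circularity P0²/A0, rectangularity A0/(L0·l0), roundness 4A0/(πL0²) and form
coefficient 4πA0/P0², with a pairwise-correlation redundancy screen.

**Shape statistics.** A redundancy analysis S ~ Subunit + Length + Side +
Sex + Year with marginal permutation F-tests (Freedman–Lane residual
permutation), and per-index Gaussian linear models with Type III ANOVA
(sum-to-zero contrasts) plus Tukey HSD post hoc comparisons between
subunits. `residualize` strips the Length/Sex/Side confounds from descriptors
ahead of assignment.

**Population genetics.** Weir–Cockerham (1984) θ, global and pairwise, as a
multilocus ratio of variance-component sums, with percentile bootstrap
(over loci) 95% CIs; a configurable genotype QC (MAF, missingness, exact HWE
test); and DAPC — PCA reduction of centered genotypes followed by LDA — with
its stratified-holdout cross-validation of the retained-PC count.

**Assignment framework.** Tracer-agnostic supervised assignment: stratified
K-fold cross-validation (default K = 3), fold-internal preprocessing (PCA for
genotypes, confound residualization for otolith indices; fitted on training
rows only), pooled-covariance LDA membership probabilities, and a sampling ×
predicted subunit assignment matrix with mean ± sd across all tests.

## Worked example

```python
from soletrace.popgen import bootstrap_fst_ci
from soletrace.simulate import SimulationConfig, simulate_genotypes

g = simulate_genotypes(SimulationConfig(seed=11))   # 47/31/42 fish, 2902 loci
res = bootstrap_fst_ci(g, n_boot=1000, seed=11)
lo, hi = res.global_ci
print(f"global theta = {res.global_theta:.4f}  95% CI [{lo:.4f}, {hi:.4f}]"
      + ("  *" if res.global_significant else ""))
```

prints (this is the opening of `examples/04_genetic_structure.py`)

```
global theta = 0.0049  95% CI [0.0043, 0.0056]  *
```

— the multilocus Weir–Cockerham estimate recovers the generator's weak
differentiation (target F = 0.0045) and its bootstrap CI excludes zero, i.e.
the differentiation is small but statistically detectable. Running
`python examples/05_assignment.py` then shows the two tracers side by side:

```
genetic tracer ... mean self-assignment: 0.68 (chance level 0.33)
otolith shape tracer ... mean self-assignment: 0.39 (chance level 0.33)
```

so under the same sampling design the genetic tracer discriminates subunits
better than otolith shape, and both matrices lean toward the largest
subunit — the characteristic unbalanced-sampling artifact of supervised
assignment. The other scripts in `examples/` walk through the shape analysis
(`02`), the confound-adjusted statistics (`03`) and the genetic structure
analysis (`04`); each prints the numbers it computes with a line on what
they mean.

A thin CLI wraps the same library: `soletrace pipeline --seed 1 --out-dir out`
runs simulate → Fourier analysis → indices → statistics → F_ST → DAPC →
assignment and writes a single `report.json` juxtaposing both tracers; the
stage subcommands (`simulate`, `efa`, `indices`, `fst`, `dapc`, `stats`,
`assign`) operate on files (VCF / 0/1/2 CSV genotypes, long-format contour
CSV).

## Scope

The package starts from genotype matrices and digitized outlines: read-level
sequencing, variant calling, image segmentation, linkage structure and
larval-dispersal modelling are out of scope.
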