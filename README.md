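# myofibspat

Spatial statistics for muscle fiber-type distributions on histological
cross-sections.

Skeletal muscles mix "slow" (type I) and "fast" (type II) fibers, and the
spatial arrangement of the two types across a muscle belly changes with age
and neuromuscular disease: denervation–reinnervation cycles produce
conspicuous clusters of like-type fibers ("fiber-type grouping").  Most
published descriptions of this phenomenon are qualitative.  `myofibspat`
gives physiologists and biostatisticians a quantitative toolkit that starts
from the minimal digitized representation of a stained section — one CSV row
per fiber with centroid coordinates `(x, y)` and a type label — and provides:

* **Geometry** — a neighbor network from the pruned Delaunay triangulation of
  the fiber centroids, an alpha-shape boundary polygon, and the clipped
  Voronoi tessellation used for plotting.
* **Summary tests** on the neighbor network:
  * *mean cluster size* of the less prevalent type against a 95% permutation
    envelope (attraction / repulsion / random verdicts);
  * *unlike neighbor pairs* — a join-count test using the exact mean and
    variance of the number of slow–fast edges under random labeling with
    fixed type counts, `z = (U − E[U]) / √Var[U]`;
  * *abnormally grouped fibers* — the fraction of target-type fibers in
    clusters containing adjacent fibers whose like-type neighbor count
    exceeds one standard deviation above its null (hypergeometric) mean.
* **Binary Markov random field (BMRF)** — the Ising-type model
  `Pr(Z = z) ∝ exp{α Σᵢ zᵢ + β Σ_{i∼j} zᵢ zⱼ}` with slow = −1, fast = +1;
  `α` measures type balance and `β` the neighbor interaction (β > 0:
  like-type attraction; β < 0: repulsion).  Estimation is maximum
  pseudolikelihood (equivalent to a logistic regression of fiber type on the
  neighbor spin sum), with a permutation envelope for `β`.
* **Logistic GAM** — the log odds of a fiber being fast as a penalized
  thin-plate-spline smooth of position,
  `log(p/(1−p)) = β₀ + β₁x + β₂y + Σₖ βₖ bₖ(x, y)`, with REML/GCV selection
  of the smoothing parameter λ, yielding gridded type-probability surfaces;
  plus a multinomial extension for three or more fiber types.
* **Synthetic sections** — jittered-lattice fiber packings labeled either by
  a Gibbs sampler of the BMRF or independently from a smooth probability
  surface, so every method is testable against known ground truth.
* **Cohort tools** — batch BMRF fits over a manifest of sections and
  two-group comparison of the per-section `(α̂, β̂)` estimates (Welch t and
  Mann–Whitney U).

## Input format

A UTF-8 CSV with a header and columns `x`, `y`, `type` (other names via
`column_map` / CLI config).  Coordinates are unitless — every statistic is
invariant to translation, rotation and uniform scaling.  Label matching is
case-insensitive; the mapping of labels to "fast" is always explicit
(`--fast-labels IIA`), never guessed.

## Worked example

Simulate a soleus-like section (1600 fibers, slow majority, weak like-type
attraction β = 0.06) and analyze it:

```sh
myofibspat --seed 1 simulate --mode bmrf --rows 40 --cols 40 \
    --alpha -0.2 --beta 0.06 --out sim.csv
myofibspat --seed 1 tests sim.csv --fast-labels fast --n-perm 999
```

```
Mean cluster size                 5.54
Envelope                          (4.31, 5.65)
Conclusion (mean cluster size)    random
Expected unlike neighbor pairs    2151.8
Observed unlike neighbor pairs    1990
p-value                           4.271e-07
Conclusion (unlike pairs)         attraction
% abnormally grouped slow fibers  97.5%
% abnormally grouped fast fibers  63.9%
```

The join-count test sees far fewer slow–fast neighbor pairs (1990) than the
2151.8 expected under randomness — significant like-type attraction — while
the mean cluster size of the minority (fast) type stays inside its envelope:
the two classical tests can disagree on the same section, which is exactly
why the model-based view matters.  The abnormal-grouping percentages are
descriptive only and strongly depend on the overall type proportions.

```sh
myofibspat --seed 1 bmrf sim.csv --fast-labels fast --n-perm 999
```

```
alpha = -0.1755
beta = 0.06978
envelope for beta=0: (-0.03162, 0.02735)
conclusion: attraction
```

The fitted `α̂ = −0.18` recovers the slow majority and `β̂ = 0.070` lies far
above the randomness envelope — like-type attraction, close to the
generating β = 0.06.

For a section whose fast-fiber probability rises radially from 0.2 (center)
to 0.8 (edge):

```sh
myofibspat --seed 2 simulate --mode surface --surface radial \
    --rows 40 --cols 40 --p-lo 0.2 --p-hi 0.8 --out radial.csv
myofibspat --seed 2 gam radial.csv --fast-labels fast --grid 100 \
    --plot surface.png
```

```
lambda = 4.654, edf = 13.49, converged = True
```

REML picks a finite λ (13.5 effective degrees of freedom, i.e. a genuinely
curved surface) and writes the gridded probability map as `surface.csv` plus
a heatmap with the fibers overlaid.  On a section with no spatial trend the
same command drives λ to the upper boundary and the surface collapses to the
plane fit (edf ≈ 3).

Batch workflows use a `(path, group)` manifest:

```sh
myofibspat batch manifest.csv --fast-labels fast
myofibspat compare batch_fits.csv --parameter beta --plot groups.png
```

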