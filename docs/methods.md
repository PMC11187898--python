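# Methods

`edmix` quantifies the composition of a crystalline powder from an automated
electron-diffraction campaign: thousands of sub-micron grains are exposed one
by one, each either yields an indexed unit cell or fails in a recorded way,
and the indexed cells are matched against a library of known crystal forms.
This note documents the models, algorithms, numerical choices and known
limitations, module by module.

## Lattice model and Niggli reduction

A unit cell is six parameters (a, b, c in Å; α, β, γ in degrees, open
interval (0, 180)).  Validity additionally requires the triclinic volume
discriminant `1 − cos²α − cos²β − cos²γ + 2cosα·cosβ·cosγ` to exceed 1e-6:
the discriminant equals (V/abc)², so this rejects near-coplanar axis triples
that are numerically legal but physically degenerate.  Angles are stored in
degrees throughout (the convention of crystallographic file formats);
radians appear only inside trigonometric calls.

Setting-independent comparison uses the canonical Niggli cell, computed by
the iterative Krivý–Gruber reduction on the 3×3 lattice metric
G (G_ij = e_i·e_j).  Inequality comparisons use a relative tolerance of
1e-5 (`edmix.cells.NIGGLI_EPS_REL`, exposed as an argument), the standard
choice that prevents cycling between nearly-equal branches; the iteration is
bounded at 1000 steps and raises `ReductionError` beyond that (never
observed in practice — typical cells converge in under 20 steps).
`niggli_reduce` also returns the accumulated integer transformation matrix
M (det ±1).  Transformations follow the **column-vector basis convention**:
the reduced basis is `(a b c)·M`, equivalently `G_reduced = Mᵀ·G·M`; this is
asserted by round-trip tests.  Volume is preserved exactly up to floating
point (relative 1e-6 tested).

## Cell matching

An observed cell matches a reference compound iff, after sorting lengths
ascending (each angle following its opposite axis), all three length
deviations are ≤ tol_len and all three angle deviations are ≤ tol_ang.  The
defaults, 1 Å and 10°, are deliberately generous relative to the cell-noise
level of automated processing (σ well below 0.2 Å / 1°), so identification
hinges on the library being separated by much more than the tolerance — the
shipped amino-acid library satisfies this with a large margin (tested).
When several compounds fall within tolerance the smallest normalised
distance (mean of the six deviations, each scaled by its tolerance) wins and
the result is flagged `ambiguous`; ties break by lexicographic name, so
assignment is independent of library order.  Ambiguous matches count toward
their assigned compound by default and can be dropped by configuration.

Two comparison modes exist.  `canonicalize=True` (default) Niggli-reduces
both cells first, which is robust to the processing software indexing the
same lattice in different settings.  `canonicalize=False` compares the
as-given parameters (after length sorting) and reproduces naive
per-parameter comparison.

One subtlety of canonicalisation: the Niggli form is discontinuous at the
boundary between its all-acute and all-obtuse types.  A monoclinic reference
with β = 99.8° and the other angles exactly 90° reduces to the obtuse
branch, but measurement noise on the 90° angles flips the reduced cell of an
observed lattice into the acute branch, where the same β appears as
180° − β.  Canonicalised comparison therefore folds every angle to its acute
equivalent (θ → min(θ, 180° − θ)) before taking deviations, making the
comparison continuous across the boundary.  The fold can in principle
conflate two genuinely different lattices that share lengths and
supplementary angles; with libraries separated on lengths (as here) this has
no practical effect.

## Composition statistics

* counting ratio: `100·n_comp/n_identified`, reported to one decimal;
* area-corrected ratio: `100·S_comp/S_total`, with both sums over
  *identified* crystals only; crystals whose area could not be measured
  contribute to counting but not to area sums;
* identification rate: `100·n_identified/n_selected`, reported to the
  nearest integer percent;
* formulation (tablet-style) ratio: numerator is the compound's crystal
  count; the denominator policy is explicit.  `identified_plus_nondiffracting`
  divides by identified + non-diffracting grains and leaves
  weakly/undefined-diffracting grains out entirely — appropriate when a
  large amorphous fraction is expected and a weak pattern cannot be
  attributed to either phase.  `identified_only` (default) divides by
  identified crystals.

Raw double-precision ratios are always retained alongside the rounded
presentation values.  `compare_to_input` reports observed − input per
compound (percentage points) and the sample standard deviation (ddof = 1) of
the per-compound counting − area differences, a scalar summary of how much
the area correction changes the answer.

Campaign accounting is three-way: `n_selected` counts every acquisition,
`n_identified` counts crystals assigned to a compound, and indexed crystals
that match nothing count toward `n_selected` only.

## Area estimation

Images are binarised at a global threshold — user-supplied, or Otsu's
between-class variance maximisation for `"auto"` (flagged in the
measurement, since a manually tuned threshold has no objective criterion to
emulate).  The default dark-field convention takes intensity ≥ threshold as
foreground; `invert` selects the opposite.  Connected components (4- or
8-connectivity, default 8) below `min_particle_px` (default 10) are
discarded.  The measured crystal is, by default, the particle whose centroid
is nearest the image centre (the acquisition centres its target), with
`largest` and `sum` as alternatives; equidistant ties break deterministically
by smallest label index.  Pixel counts convert to µm² via pixel_size².
A size filter flags particles whose equivalent-circle diameter falls outside
a configurable 0.2–1.5 µm window, mirroring the beam-limited picking range
of the acquisition.  Thickness is not estimated; only projected area enters
the composition, never a volume model.

## Merging statistics and subset search

Reflections are mapped to a canonical orbit representative (the
lexicographically greatest symmetry-equivalent index) under the Laue group's
operators plus Friedel inversion.  Operator sets for the eleven Laue groups
are generated by closing small generator sets under multiplication; group
orders (2, 4, 8, 8, 16, 6, 12, 12, 24, 24, 48) are asserted in tests.
Hexagonal/trigonal groups use hexagonal axes with the −3m convention's
two-fold along [110]; monoclinic uses unique axis b.

Inter-dataset scaling is the minimal physical model: one multiplicative
factor per dataset, fit by iterated least squares against current group
means (tolerance 1e-6, ≤ 100 iterations), first dataset fixed to scale 1.
Scales are constrained positive (an anti-correlated dataset pins near zero
rather than sign-flipping into spurious agreement) and clipped to
[1e-8, 1e8] to keep pathological fits finite.  Each dataset must share ≥ 3
unique reflections with the reference or `UnmergeablePairError` is raised.

Statistics over merged groups (multiplicity ≥ 2 groups only, for both
numerators and denominators, following standard practice):

* `R_merge = Σ_hkl Σ_i |I_i − ⟨I⟩| / Σ_hkl Σ_i |I_i|` (the absolute value in
  the denominator only matters for pathological negative data);
* `R_meas` adds the `sqrt(n/(n−1))` multiplicity correction per group;
* CC₁/₂ is the Pearson correlation between mean intensities of two random
  half-splits of each group, split by a seeded permutation (`cc_seed`) for
  reproducibility.  Degenerate cases: element-wise equal halves give exactly
  1 (noise-free data), otherwise a constant half-vector gives 0;
* completeness = observed unique / theoretically possible unique within the
  d_min sphere.  The theoretical count enumerates all integer triples with
  |h_i| ≤ a_i/d_min directly and maps them to the asymmetric unit — slower
  than an analytic multiplicity formula but unambiguous at desk scale
  (d_min ≥ 0.7 Å, cells up to a few tens of Å; guarded at index range 200).

The composite score is `w₀·completeness/100 + w₁·CC₁/₂ − w₂·R_meas` with
weights (1, 1, 1) by default.  The exact scoring used by merging programs in
the wild is not standardised; this surrogate is declared and configurable.
`best_subset` evaluates every combination of ≤ k_max datasets (within a
configurable budget, default 10⁶; beyond it `BudgetExceededError` instructs
the greedy fallback) or grows the subset greedily by best marginal addition.
Ties break by smaller subset, then lexicographic ids.  Datasets may carry
alternative processing variants; the search picks at most one variant per
dataset, representing a processing-parameter sweep without re-implementing
spot finding.  Subsets whose members cannot be pairwise scaled are skipped
with score −∞ rather than aborting the search.

## Synthetic campaigns

The generator emulates the study conditions of a well-behaved nine-compound
amino-acid mixture:

| parameter | default | rationale |
|---|---|---|
| compounds, fractions | 9 amino acids, 5.0–23.0 % | shipped library with CSD-style reference cells (fixture values) |
| cell noise (σ_len, σ_ang) | 0.1 Å, 0.3° | automated indexing scatters well inside the 1 Å / 10° tolerances |
| p(no diffraction / weak / multi-lattice / smeared) | 0.15 / 0.05 / 0.03 / 0.02 | ≈75 % indexing success, the upper range of automated campaigns |
| area distribution | log-normal(µ = ln 0.3, σ = 0.6) µm², truncated [0.05, 1.8] | crystals picked in a 0.2–1.5 µm size window |
| image rendering | 256 px frames, 0.01 µm/px, bg 40 / fg 200, noise σ 10 | ≥ 5× contrast-to-noise, the regime where global thresholding is reliable |
| reflections | exponential (Wilson-like) true intensities, mean 100; wedge observes ≈ `wedge_fraction·N` uniques 1–2× each; I_obs = scale·I_true·(1+ε), ε ~ N(0, noise_frac) | short-wedge partiality with per-dataset scale offsets |

Failure statuses draw independently of compound by default; a per-compound
failure multiplier can emulate hygroscopic components that index less often.
Every stream derives from a single integer seed (per-compound intensity
seeds default to a CRC of the compound name, so wedges of one compound share
ground truth); identical seeds give bit-identical campaigns.

What the generator does *not* emulate — and what passing tests therefore do
not show about real data: indexing errors that produce a *wrong* (rather
than noisy) cell, correlated noise between cell parameters, crystal clumps
and overlapping lattices in images (each image holds one crystal plus
optional specks), background gradients, beam damage, and any dependence of
diffraction quality on crystal size or orientation.  Recovery numbers on
synthetic campaigns are therefore upper bounds on real-campaign accuracy.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale by choice:
campaigns of 120–1000 crystals, reflection sets at d_min 1.2–1.5 Å for cells
under 20 Å (a few hundred unique reflections), subset searches over 5
datasets, and 80–200 cells for the reduction cross-checks.  The brute-force
reduction oracle enumerates all 3×3 integer matrices with entries in {−2..2}
and det ±1 (135 408 of them); this enumeration is exhaustive only for
modestly skewed inputs, so oracle comparisons draw cells with angles in
80–100° and a single random shear — for such cells the reducing
transformation provably stays inside the enumerated range (verified
empirically over thousands of cells), while arbitrary valid cells are still
covered by the permutation/re-basing invariance tests.  All randomness is
seeded; re-running any pipeline with the same configuration reproduces
byte-identical reports.

## Known limitations

* Compounds with (near-)identical reduced cells cannot be separated; the
  principled fallback — discriminating by reflection-intensity correlation —
  is future work.  Overlaps are at least flagged via `ambiguous`.
* The acute-angle fold (above) trades a vanishing false-match risk for
  robustness at the Niggli type boundary.
* Scaling is a single multiplicative factor per dataset: no resolution-
  dependent (B-factor), absorption or decay terms.
* Densities are metadata only; no mass/volume conversion is performed, since
  it would inherit unstated density values.
* Completeness counts the full sphere's asymmetric unit; no systematic-
  absence handling (space-group-level extinctions are unknown at the Laue
  stage).
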