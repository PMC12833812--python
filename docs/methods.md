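# Methods

## Descriptor model

**Percent buried volume.** The active site of a Brønsted acid
organocatalyst is annotated by a probe-center atom index (there is no
reliable automatic rule for which atom defines "the active site" across
scaffold families — P vs the acidic O/H of a phosphoric acid, for
instance — so the annotation is a required input, never an inference).
Occupancy is the union of atomic van der Waals spheres using Bondi (1964)
radii scaled by 1.17, the convention of the buried-volume literature; the
radii table is a swappable input so alternative sets can be tested. The
probe-center atom is excluded from occupancy — it defines the origin a
substrate approaches, not congestion — and the acidic proton is excluded
when annotated; both choices are recorded in result metadata. Hydrogens
are included by default because the sterics directly around an acidic site
depend on them. %V_bur is evaluated over a radius scan
{2.5, 3.0, 3.5, 4.0, 4.5, 5.0} Å (no single radius is canonical; the
downstream best-variant-by-Q² selection absorbs the choice) on a cubic
grid of spacing 0.05 Å. At that spacing the grid agrees with the analytic
ratio-of-cubes value for a centered atom to ~0.01 percentage points and
with a 2×10⁵-sample Monte-Carlo oracle to ≲0.2 points; halving the spacing
moves values by <0.3 points. The Monte-Carlo estimator (uniform sampling in
the ball via radial inverse-CDF, binomial standard error reported) exists
purely as an independent oracle.

**Sterimol.** L, B1, B5 follow the standard rotational-projection
definitions on an annotated (attachment → root) axis, vdW-augmented with
unscaled Bondi radii. L carries no +0.40 Å historical bond correction —
stated here to avoid cross-tool confusion. B1 is minimized over
perpendicular directions scanned at 1° (production) with a 0.1° scan
reserved for oracle comparisons; the coarse scan can overshoot the true
minimum by at most max|p_i|·Δθ, which the tests bound explicitly.

**Ensembles.** Per-conformer values collapse by Boltzmann weighting
(w ∝ exp(−ΔE/RT), R = 1.98720×10⁻³ kcal mol⁻¹ K⁻¹, default 298.15 K) when
relative energies are present, plus ensemble-min and ensemble-max; absent
energies disable the Boltzmann variant rather than guessing weights.

Electronic descriptors (partial charges, pKa) are never computed — they
are ingested as external CSV columns with provenance `ingested`.

## Statistical model

Observed ee converts to ΔΔG‡ = RT ln[(1+ee)/(1−ee)] at each record's own
temperature; a catalyst's records across substrate combinations are
arithmetically averaged after conversion. The dataset's reference
enantiomer defines positive ee, so selectivity-inverting catalysts carry
negative ΔΔG. |ee| = 1 entries (">99% ee") are clamped to 0.995
(configurable) with a logged warning, since ΔΔG diverges at |ee| = 1.

Each (dataset × family × variant) is fit by univariate OLS. Reported per
fit: slope, intercept, R², MAE, two-sided slope-t p-value (n−2 df; for
univariate OLS this is identical to the model F-test, so no separate
choice arises), and leave-one-out Q² = 1 − PRESS/TSS with PRESS from the
leverage identity e₍ᵢ₎ = eᵢ/(1−hᵢᵢ) — exact, verified against explicit
n-refit LOO to 1e-10. Only the variant with the largest Q² represents a
family on a dataset; ties break by smaller MAE, then lexicographic variant
id, so selection is deterministic and column-order-independent. Catalysts
missing a value for one variant are dropped from that variant's fit only
(pairwise deletion, per-variant n recorded). Minimum n is 4 (two df for
the t-test); smaller datasets are reported unscreenable. "Meaningful at
>95 % confidence" means p < 0.05 on the selected variant (0.10/0.05/0.01
grid); no multiple-testing correction is applied because confidence is
reported nominally per dataset.

Numerical degeneracies: a constant predictor — including one whose spread
is below ~1e-10 of its magnitude, which arises when a descriptor is
constant up to floating-point noise and would otherwise yield a
meaningless ~1e14 slope — raises a degenerate-predictor error and the
variant is skipped; a constant response returns a degenerate result with
MAE only (R², p, Q² undefined as NaN).

**Meta-analysis.** Proportions of significant models per family are over
all screened datasets (a family with no usable variant on a dataset counts
as not significant there). Averages of R²/MAE are unweighted across
datasets (a size-weighted option exists, off by default). Diversity
classification: a catalyst "differs beyond the modular substituent" when
its backbone or active-site class differs from the dataset's modal values;
≤1 such catalyst (default threshold) ⇒ `limited`, else `significant`. The
threshold is exposed and a per-dataset override table is honored, because
the printed criterion is applied with judgment in practice. Family ranking
sorts by proportion significant at the strictest alpha, then average R²,
then average MAE — deterministic.

The dummy baseline predicts every catalyst's ΔΔG by the dataset mean.
OLS dominates this baseline in sum of squared errors by construction, but
not, as a theorem, in MAE: a near-null family's selected fit can exceed
the baseline MAE by a float-level margin. The packaged invariant is
therefore stated for each dataset's overall selected model (largest Q²
across families), where it holds with a wide margin whenever any real
signal exists.

## Synthetic data

Shell catalysts are geometric stand-ins, not molecules: a dummy carbon at
the origin (the excluded probe center) surrounded by carbons placed on a
golden-spiral lattice at 2.5 Å and angularly jittered (SD 5°, to avoid
exact-symmetry artifacts in B1). Carbon shells keep a single radii entry
dominant. A series of n catalysts uses 1, 2, …, n shell atoms, giving a
strictly increasing %V_bur spanning ≥20 percentage points at 3.5 Å.
Fixture descriptor evaluation uses a 0.1 Å grid — shells are smooth
near-spherical occupancies for which 0.1 Å is converged far below any
tolerance the fixtures' consumers assert — with ensemble-min aggregation
(single-conformer fixtures make the choice inert).

Reaction data follow ΔΔG_i = β₀ + β₁·x_i + ε, ε ~ N(0, σ²), with x the
generative descriptor column, then convert to ee at 298.15 K. Defaults
emulate the statistical shape of curated literature collections: 11
catalysts per dataset (typical curated size), β₀ = 0.2 kcal/mol,
β₁ = 0.02 kcal/mol per %V_bur point (spans ≈1.6 kcal/mol over a default
series while keeping every implied |ee| below the 0.995 limit), σ = 0.15
kcal/mol so realized per-dataset MAEs land in the 0.05–0.3 kcal/mol range
seen in practice. Records whose implied |ee| would reach 0.995 are clamped
(or redrawn under the `regenerate` policy) with a log message. One root
seed spawns per-dataset `SeedSequence` streams; the manifest records each
derived seed so any dataset is reproducible in isolation, and the whole
fixture tree is byte-identical across runs.

What the fixtures do **not** emulate: real bonding/valence, conformer
multiplicity, correlated descriptor families beyond what shared geometry
induces, heteroscedastic or temperature-varying noise, and curation
artifacts of literature data. Passing tests therefore demonstrate the
pipeline's statistical and geometric correctness, not that buried volume
correlates with any particular real reaction.

## Problem sizes in the packaged checks

The test suite and `scripts/acceptance.py` run entirely on synthetic
inputs: 20 random six-atom clusters for the grid-vs-Monte-Carlo and
sterimol-vs-fine-scan comparisons (2×10⁵ MC samples each), 25 random fits
for the LOO identity, 4–10 simulated datasets of 11 catalysts for
end-to-end recovery and screening, and 1000 null replicates for type-I
calibration. These sizes put Monte-Carlo error well below the asserted
tolerances while keeping a full run to a couple of minutes.

## Known limitations

- No conformer generation, geometry optimization, or quantum chemistry;
  structures and energies are inputs.
- No quadrant/octant buried-volume decomposition.
- Univariate OLS only — multivariate and regularized models are
  deliberately out of scope.
- SDF support is V2000 only (V3000 is rejected explicitly).
- Diversity classification requires scaffold labels; unlabeled catalysts
  make a dataset unclassifiable rather than silently defaulting.
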