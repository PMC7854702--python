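# Methods

## Conventions

The scattering vector length is S = 2 sin θ / λ in Å⁻¹ everywhere; the
classic q = 4π sin θ / λ equals 2πS, so every Fourier kernel (Debye sinc,
Guinier exponent) carries a 2π relative to q-convention formulas.
`read_profile(..., q_convention="q")` converts q-gridded data on input.
The Guinier slope of ln I vs S² is −(4π²/3)Rg².

## SAXS analysis (saxs_core)

**Guinier fit.**  Error-weighted linear regression of ln I on S² over a
window in S², default [4 × 10⁻⁶, 2 × 10⁻⁵] Å⁻² (the window used for the
phytochrome dilution series; always user-overridable, never searched
automatically).  Weights are (I/σ)², the delta-method variance of ln I.
Standard errors come from the regression covariance scaled by the reduced
χ²; a positive slope more than two standard errors above zero is rejected
as "no Guinier region" rather than reported as an imaginary Rg.

**Dilution series.**  KC/I(0) and Rg² are fit against concentration by
ordinary (unweighted) least squares — the per-point errors of derived
Guinier parameters are strongly correlated, and no defensible weighting
scheme exists at that level.  Intercepts give 1/M_W and Rg²(0); slopes
give 2A₂ and −B_if.  A non-positive 1/M_W or negative Rg²(0) intercept is
an error ("extrapolation invalid").  K defaults to 1 (arbitrary intensity
units); with absolute calibration the caller supplies K.

**Population estimation.**  How the 0.39/0.61 Pr/Pfr split is best
obtained from spectra is genuinely open; the package's choice is
non-negative least squares of the steady-state spectrum against the two
reference spectra over a configurable window (default 550–800 nm, where
the red/far-red bands live), with weights renormalised to sum to one and
the window, point count and residual RMS recorded in
`MixtureWeights.method`.  Reference spectra with condition number above
10⁸ are rejected as ill-posed.

**Decomposition.**  The two-component inversion is applied point-wise on
the shared S grid (linear interpolation onto the overlap when grids
differ; extrapolation is forbidden).  Errors propagate as
σ_Pfr = √(σ_steady² + w²σ_Pr²)/w_PfrPfr.  Negative output intensities are
retained and counted in a logged diagnostic: clipping would bias averages
and break the linearity the mix/decompose identity tests rely on.

## Bead models and Debye scattering (bead_models)

Dummy residues are treated as identical point scatterers (radius 3.8 Å is
carried as metadata; an optional uniform-sphere form factor can be
switched on).  The Debye sum I(S) = ΣΣ sinc(2πS·r_ij) is evaluated either
exactly (all pairs, streamed in bounded-memory chunks) or via a pair-
distance histogram with 0.5 Å bins, which agrees with the exact sum to
better than 0.2% for S ≤ 0.02 Å⁻¹ and makes N = 20 000 beads tractable in
seconds.  I(0) = N² exactly in exact mode.  χ² uses the closed-form
optimal scale α* = Σ(I_e I_m/σ²)/Σ(I_m²/σ²); no numerical search.

Parametric shapes (rod, bent rod, crossed two-fold dimer, sphere,
ellipsoid) are filled by rejection sampling with a seeded generator —
fixed seed gives bitwise-identical models, and a 180° bend reproduces the
straight rod bead for bead.  Bead overlap is not prevented: DR models are
interpenetrating by construction.

## Ensemble classification (shape_classify)

Alignment maps each model's inertia eigenvectors to x, y, z in
ascending-eigenvalue order (long axis on x) with det = +1.  The remaining
four proper sign flips — and, when enantiomer handling is on, the mirror
image, since shapes reconstructed from orientationally averaged data carry
no handedness — are resolved by maximising binary voxel overlap with the
reference; without a reference a canonical rule is used (third moment
positive on the first two axes, third sign fixed by det = +1).

Voxelisation uses a cubic 6 Å grid anchored at the corner of a bounding
box shared by the whole ensemble (union of aligned models plus a one-voxel
margin) so all density vectors live in one space; bins are half-open, a
bead on a face belongs to the higher-index voxel, and Σ density × volume
equals the bead count exactly.

PCA is mean-centred covariance PCA computed through the M × M Gram matrix
(M models ≪ voxel count), which yields the full variance spectrum cheaply;
only the two leading components are mapped back to voxel space, and their
signs are fixed by making the largest-magnitude loading positive.
Clustering is scikit-learn K-means (k-means++ seeding, best of 50
restarts, fixed seed); k = 10 by default.  Empty clusters are reported,
not re-seeded.  Group averaging re-superimposes every member on the member
nearest the cluster centroid in PC space (enantiomer handling on) and
takes the fraction of members occupying each voxel; the representative
mask applies an occupancy threshold of 0.5 (configurable — no published
value exists).  The tool ranks groups by size but never auto-selects a
"correct" morphology: that judgement requires external evidence
(microscopy, homologous structures).

The dummy-residue count survey evaluates a pluggable reconstruction engine
over counts 900–1200 in steps of 25, averaging χ² over 14 seeded repeats
per count (the survey design used for the phytochrome ensembles), and
returns the argmin with ties broken toward fewer beads.  Engine models up
to 2000 beads are scored with exact-mode Debye sums: histogram quantisation
(0.5 Å) can alias fine distance differences that mock engines and small
models legitimately produce.

## Elastic network modes (enm_nma)

The network is the anisotropic (directional-spring) model: uniform force
constant, unit masses, contacts at pair distance ≤ cutoff (inclusive).
Each contact contributes −k·r̂r̂ᵀ off-diagonal blocks; diagonal blocks make
block rows sum to zero, so rigid translations are exact zero modes.  Modes
come from a full symmetric eigendecomposition; eigenvalues below
10⁻¹⁰ × λ_max count as zero modes (six for a connected, non-collinear
structure).  B-factors are the pseudo-inverse diagonal summed per residue,
B_i ∝ Σ_m λ_m⁻¹ |v_{m,i}|².  Cutoff calibration scans 6–15 Å in 0.5 Å
steps, maximising the Pearson correlation with experimental B-factors
(ties toward the smaller cutoff; disconnected grids are skipped with a
warning); the force constant is then scaled so ΣB_pred = ΣB_exp, which
leaves the correlation unchanged.  Mode rendering follows the convention
of magnifying displacements three-fold, "first mode" meaning the lowest
non-zero eigenvalue.

A caveat for very extended structures: a filament several hundred Å long
has bending modes whose eigenvalues fall below the relative zero
tolerance, so the reported zero-mode count can exceed six for physical
reasons (near-degeneracy with rigid-body motion), not numerical error.
Zero-mode checks in the tests therefore use compact globular fixtures.

## Sequence comparison (seq_compare)

Affine-gap Smith–Waterman with EMBOSS-Water conventions: a gap of length L
costs open + (L−1)·extend (defaults BLOSUM62, 10, 0.5); identity and
similarity percentages divide by the full alignment length including gap
columns; similarity counts columns with a positive substitution score.
Traceback starts at the maximum-score cell (smallest end coordinates among
ties) and prefers diagonal, then gap-in-the-second-sequence, then
gap-in-the-first.  Residues absent from the matrix (e.g. O, U) score 0
with a warning.  The implementation is checked against an independently
written dictionary-based DP oracle and against Biopython's
`PairwiseAligner` with matching gap scores.

## Synthetic data: what it emulates, and what it does not

`synthetic_data` provides every input class with planted ground truth:

- **Dilution series** — the Debye curve of a chosen shape, rescaled per
  concentration so I(0, C) and Rg(C) follow the ideal-dilution laws with
  planted M_W, A₂, Rg(0), B_if (defaults: M_W 250 kDa, the five
  concentrations 0.5/1.5/2.0/3.0/4.0 mg/mL of the phytochrome series).
  Interparticle effects are injected analytically at Guinier level
  relative to the base curve's own window fit, so a noise-free series
  inverts exactly; no structure-factor model is attempted.  Noise-free
  profiles carry constant relative errors (uniform ln-fit weights); noisy
  ones use σ ∝ √I/√C.
- **Photosteady mixtures** — the exact two-component sum at a planted
  w_PrPr (default 0.39) with optional Gaussian noise.
- **Spectra** — Gaussian bands near the classical red (667 nm) and
  far-red (730 nm) absorbance maxima with a tunable overlap; band
  parameters are configuration defaults, not measurements.
- **Model ensembles** — three families of crossed rod dimers ("twisted
  tubes", "cross", "butterfly") mimicking reconstructed phytochrome
  morphologies: 175 Å rods at distinct crossing angles, 4000 beads per
  dimer (2000 per subunit, the surveyed DR scale; the rod girth is 35 Å so
  the bead packing density — roughly one DR per residue volume — matches
  real reconstructions).  Members get per-bead jitter (default 2 Å),
  random rigid motions, random handedness flips, ±5% bead resampling;
  outliers are protein-sized Gaussian blobs.  Real reconstruction
  ensembles differ in ways this generator does not model: chain-like bead
  connectivity, data-driven shape variation correlated with χ², and
  ambiguity families of unequal abundance.  Passing the classification
  tests therefore shows the protocol separates distinct morphologies under
  realistic jitter and handedness ambiguity — not that it reproduces any
  particular published grouping.
- **ENM structures** — helix / hairpin / two-domain Cα traces with exact
  3.8 Å virtual bonds (two helical domains with a 6 Å lateral offset by
  default, so the contact network stays connected across the calibration
  grid and the fluctuation profile actually discriminates cutoffs — a
  single ideal helix is too dynamically homogeneous for calibration to be
  identifiable).  B-factors are the network's own prediction at the
  planted cutoff (default 9 Å), scaled to a mean of 30 Å², with
  multiplicative noise.

Every generator is a pure function of (parameters, seed).

## Numerical choices and degenerate inputs

- Missing error columns default to σ = max(10⁻⁶, √I) with a logged warning.
- Interpolation between S grids is linear in I on the overlap only.
- Voxel-boundary sensitivity: beads within numerical alignment error
  (~10⁻⁶ Å) of a voxel face can hop bins between otherwise identical
  runs; pipeline equivariance holds to ~10⁻³ in PC coordinates rather
  than machine precision, and averaged occupancies of identical rigid
  copies are binary up to a ≲2% voxel fraction.
- Near-spherical models have a degenerate inertia tensor; alignment then
  falls back to the canonical sign rule with a warning.  Collinear models
  are rejected.
- K-means determinism is per (seed, restart count); empty clusters are
  flagged, never silently re-seeded.

## Problem sizes

The test suite and acceptance script run at desk scale: 560-model
ensembles of 4000-bead models, 20 000-bead Debye oracles, 120-residue
calibration structures (50 noisy trials), and a 500-residue eigensolve —
sizes chosen so every check completes in about a minute while still
exercising the same code paths as full-scale data.

## Known limitations

- The pipeline consumes DR models from any source but includes no
  reconstruction engine (the survey takes a pluggable callable); the
  shipped engines are test mocks.
- No indirect-transform P(r), ambiguity scoring, hydration-shell or
  excluded-volume corrections; the Debye forward model is point-scatterer.
- Group-II-style manual realignment of anisotropic shapes is approximated
  by overlap-maximising re-superimposition; it is a stated proxy for human
  curation, not a reproduction of it.
- The ENM is Cα-only with uniform springs and unit masses; no mass
  weighting, solvent, or all-atom force field.
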