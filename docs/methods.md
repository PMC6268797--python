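# Methods

## Scientific setting

Flexible oligosaccharides populate ensembles of conformers rather than a
single structure.  One way to validate a proposed conformational ensemble is
lanthanide-assisted paramagnetic NMR: a metal-chelating tag at the reducing
end induces pseudocontact shifts (PCSs) in every nucleus, and because the PCS
depends on the nucleus's distance and orientation relative to the metal's
magnetic-susceptibility anisotropy (Δχ) tensor, the ensemble-averaged,
back-calculated PCSs can be compared quantitatively with the measured ones.
`glycopcs` implements that workflow for the branched GM2-ganglioside
tetrasaccharide βGalNAc-(1-4)-[αNeu5Ac-(2-3)]-βGal-(1-4)-βGlc: PCS
extraction from paired shift tables, metal placement by glucose-ring
alignment, Δχ-tensor fitting, Q-factor scoring, and clustering of the three
glycosidic (Φ, ψ) torsion distributions.

## The PCS model

For a nucleus at polar position (r, θ, φ) in the principal frame of the
traceless symmetric Δχ tensor,

    Δδ[ppm] = 10⁴/(12π r³) · [Δχ_ax (3cos²θ − 1) + 3/2 · Δχ_rh sin²θ cos2φ]

with r in Å and Δχ_ax, Δχ_rh in 10⁻³² m³.  The prefactor 10⁴/(12π) is the
standard one making these three units consistent.  The frame-independent form
used internally is Δδ = 10⁴/(4π) · vᵀχv / r⁵ with v the metal→nucleus
vector; the two are equal after eigendecomposition (verified to 1e-12 in the
tests).  Ensemble predictions are population-weighted sums Σᵢ pᵢ Δδᵢ with
fixed uniform weights pᵢ = 1/N (0.0005 at the study size N = 2000); the
populations are never fitted.

Agreement is scored by Q = rms(Δδ_calc − Δδ_obs)/rms(Δδ_obs), pooled
unweighted over all matched ¹H and ¹³C nuclei, so one Q describes the
combined correlation.

## Tensor fitting

The PCS is linear in the five independent components of χ, so fitting one
tensor to ≥ 5 observed PCSs under fixed populations is linear least squares.
The design matrix holds the ensemble-averaged geometric coefficients per
observed nucleus; the solve is a rank-revealing SVD with a relative
singular-value cutoff of 1e-10 — geometry that cannot resolve all five
components (rank < 5) is an error, not a silently regularized answer.  The
metal position is fixed per conformer by superposing a six-atom glucose-ring
template (C1, C2, C3, C4, C5, O5, the minimal unambiguous "glucose ring")
with the Kabsch algorithm (proper-rotation correction: the sign of the
smallest singular vector is flipped if det < 0) and carrying a fixed
metal-offset vector along.  The averaged tag-metal coordinates from the
original tag study are unpublished, so the template ships as a configurable
object; the default places the metal 8 Å from the ring centroid along the
anomeric-substituent direction, preserving the geometry of a reducing-end
tag.  Observation-level k-fold cross-validation (seeded, deterministic) is
provided as a robustness check; conformer-level bootstrap is out of scope.

Principal-frame conventions: eigenvalues are assigned |χ_zz| ≥ |χ_yy| ≥
|χ_xx| (exact ties broken by descending signed value), Δχ_ax = χ_zz −
(χ_xx + χ_yy)/2, Δχ_rh = χ_xx − χ_yy, and eigenvectors are oriented
deterministically (first nonzero component positive, right-handed frame,
ZYZ Euler angles).  Per-metal fits are independent; no joint anisotropy
constraint across Tm³⁺/Tb³⁺ is imposed.

## Torsion statistics and clustering

Glycosidic torsions follow the carbohydrate conventions Φ = H1–C1–O′4–C′4,
ψ = C1–O′4–C′4–H′4 for the hexose–hexose linkages and Φ = C1–C2–O′3–C′3,
ψ = C2–O′3–C′3–H′3 for the sialyl linkage, with the signed IUPAC dihedral
(right-hand rule about the central bond, range (−180°, 180°]).

Circular means use the atan2 of mean sine/cosine; the circular SD is
√(−2 ln R̄) with R̄ the mean resultant length (an arithmetic SD of wrapped
deviations is available as an option; the two agree within ~0.2° for the
concentrated σ ≤ 15–20° clusters relevant here).

Clustering works on a periodic 2-D histogram (default 5° bins) smoothed with
a wrapped Gaussian (σ = 1 bin): local maxima are candidate peaks; maxima
below 5% of the strongest peak's smoothed height are discarded as sampling
noise (without this floor, isolated far-tail bins of a broad cluster can
seed spurious clusters at n ≈ 2000); peaks within a 60° wrapped-Euclidean
basin radius of a stronger peak are suppressed; points are assigned to the
nearest surviving peak within the basin radius; clusters below a 2%
population fraction are dropped and their members counted as unassigned.
Populations plus the unassigned fraction sum to 1 exactly.  All thresholds
are exposed as parameters.  Coincident mixture components merge into one
cluster by construction.

## Synthetic ensemble generator

The MD trajectories behind the experimental study are not deposited, so the
generator is the test bed standing in for them.  What it emulates:

- three glycosidic linkages sampling wrapped-Gaussian (Φ, ψ) mixtures whose
  default means and SDs are the published cluster statistics
  (GalNAc–Gal: one cluster (30° ± 12°, 17° ± 13°); Neu5Ac–Gal:
  (−174° ± 11°, −32° ± 11°) and (−69° ± 10°, −6° ± 14°); Gal–Glc:
  (−34° ± 15°, −32° ± 17°), (40° ± 11°, −4° ± 20°), (37° ± 21°, −167° ± 19°)).
  Cluster populations are not published; the defaults (1.0; 0.65/0.35;
  0.5/0.3/0.2) order clusters as listed, major first, consistent with the
  sialyl clusters being described as major and metastable.  Φ and ψ are
  sampled independently (only marginal ± values are published);
- 2000 conformers with uniform weight 0.0005, matching the subsampling
  protocol (10 × 12 ns runs, 1 ps snapshots, first 2 ns discarded, every
  50 ps retained);
- a known ground-truth Δχ tensor (default Δχ_ax = −20, Δχ_rh = −5 in
  10⁻³² m³ — placeholder magnitudes, flagged as such in the ground-truth
  record, since the tag's actual Δχ values are unpublished);
- additive Gaussian observation noise (default 0.01 ppm).

Conformers are built by articulating rigid idealized ⁴C₁-like pyranose
fragments (and a simplified Neu5Ac with its C7–C9 arm) at the requested
torsions; placement uses internal-coordinate construction of the anomeric
carbon (1.41 Å C–O bond, tetrahedral angle) followed by an axial spin, so
the requested Φ/ψ are reproduced by the built coordinates to ≲ 1e-12°
(tested at 1e-6°).  The fragments are chemically approximate but
geometrically exact for every atom the pipeline touches.

What the generator does *not* emulate: solvation, energetics, Φ–ψ
covariance, inter-residue hydrogen bonding, steric exclusion between
branches, and realistic PCS magnitudes (with the default tensor and the 8 Å
metal offset the synthetic PCS range is wider than the experimental one).
Passing tests therefore demonstrate the correctness of the computational
pipeline — extraction, geometry, forward model, fit, statistics — not the
physical realism of any particular ensemble.

## Numerical choices and degenerate inputs

- Dihedrals: coincident consecutive points or collinear triples are errors
  (tolerance 1e-10 on the cross-product norms).
- Superposition: exact for rigid copies (rmsd < 1e-9 Å); rmsd above a 0.5 Å
  threshold warns and flags the conformer.
- Q-factor: all-zero observations or zero matched assignments are errors.
- Tensor validation: symmetry and tracelessness to 1e-9 relative; the stored
  matrix is re-symmetrized and trace-removed to rounding.
- PDB I/O carries 3 decimals (1e-3 Å); exact-closure experiments are run on
  in-memory ensembles, and file round-trip tests use 1e-3 Å tolerances.
- All stochastic stages take explicit integer seeds; reports and outputs are
  byte-identical across runs apart from timing fields.

## Problem sizes

Analyses and acceptance checks run at the study size (2000 conformers,
30 fitted nuclei, 100 noise replicates, n = 2000 per linkage for
clustering); unit tests use 1–80-conformer ensembles.

## Known limitations

- The Tm³⁺/Tb³⁺ Δχ magnitudes and the tag-metal offset are placeholders;
  fitted tensors from synthetic data validate the estimator, not the tag.
- The Gal/Neu5Ac/GalNAc columns of the packaged shift table are printed with
  fewer decimals than the published PCS table implies, so their PCS
  arithmetic agrees only to 0.03 ppm (the published PCS table was evidently
  computed from unrounded shifts); the Glc column agrees to 0.01 ppm.
- Cluster SDs are biased slightly low when basins truncate broad clusters
  (≲ 1° at the study conditions).
- Only multi-model PDB ensembles are read; binary trajectory formats are out
  of scope.
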