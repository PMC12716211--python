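# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Geometry and conventions

The laboratory frame puts the incident beam along +z and the flat detector
perpendicular to it at `distance_mm`. The goniometer tilt axis lies in the
detector plane, by default along +x (the detector fast axis) with a
configurable azimuth; neither the axis direction nor the rotation sense is a
physical constant of the method, so both are configuration. Pixels are
0-based continuous `(fast, slow)` coordinates. Reciprocal space carries no
factor of 2π (|s| = 1/d).

The electron wavelength is the relativistic de Broglie formula
λ = h/√(2 m e V (1 + eV/2mc²)) with CODATA constants; 0.019687 Å at 300 kV,
0.025079 Å at 200 kV. The default beam is 200 kV, a common setting for the
detector class emulated here; it is a config field, not an assumption the
algorithms depend on.

The `B` matrix is the inverse of the canonical direct matrix (cell vector
`a` along +x, `b` in the x–y plane), so its columns are a*, b*, c* and
`c*` ends up along +z; `det(B) = 1/V` holds identically. Orientations are
proper rotations; `CrystalModel.from_ub` recovers U by polar projection of
UB·B⁻¹ onto SO(3), which absorbs the asymmetry of least-squares UBs.

`map_spot_to_reciprocal` keeps the exact Ewald construction,
s = R(−θ)·(p̂ − ẑ)/λ. The flat-sphere picture is only a limit: the mapped
point sits on the sphere, displaced from the plane z = 0 by s²λ/2, which
stays below the default acceptance half-width only for s ≲ 0.45 Å⁻¹ at
300 kV. Tests of the "flat" property therefore run at moderate resolution;
the processing chain itself never relies on flatness.

## Niggli reduction and the comparison form

Reduction is delegated to gemmi's Gruber-vector implementation with
change-of-basis tracking, so a reduced `CrystalModel` provably spans the
same lattice (the basis transform is checked to be unimodular).

The Niggli cell is discontinuous where an angle crosses 90°: noise on a
cell with right angles flips the reduction between the acute and the obtuse
variant (γ versus 180° − γ), which would split one phase into two clusters
under a plain Euclidean cell distance. `niggli_comparison_cell` therefore
snaps angles within 1° of 90° to exactly 90° and flips remaining acute
angles to their obtuse partners whenever a basis-vector sign change permits
it (an even number of acute angles, or an exact 90° available to pair
with). Genuinely acute (Type I) cells are untouched. All cells entering the
clustering stage pass through this form. A residual knife edge remains when
two reduced lengths are nearly equal (the ordering can swap and move the
unique angle between the α/β/γ slots); a metric that is continuous across
reduction boundaries (e.g. NCDist-style) would remove it, but the plain
six-parameter Euclidean distance is kept as the default because it is the
simplest rule that supports the dendrogram analysis.

## The synthetic experiment

The generator emulates the statistical structure of a screening experiment,
not its physics in detail:

* **Schedule** — batch-by-batch: all positions at one angle, then the next;
  default 7 angles from −30° to +30° in 10° steps (the acquisition table of
  a real experiment is instrument-specific; this default is an assumption
  and is configurable).
* **Positions** — each draws a phase from the mixture fractions
  (multinomial); a `failure_fraction` (default 0.1) of positions is
  amorphous (background-only frames); an `aggregate_fraction` (default
  0.15) carries 2 or 3 independent lattices with probability 0.7/0.3, each
  with an independently drawn phase — the multi-crystal patterns that
  defeat single-still indexers.
* **Orientations** — uniform on SO(3) via the normalized-quaternion method;
  one seeded generator drives everything, so runs are bit-reproducible.
* **Reflections** — every hkl inside the resolution sphere whose exact
  excitation error satisfies |ε| ≤ `eps_max` is rendered as a 2D Gaussian
  blob (σ = 1.2 px) with integral `scale · I(hkl) · exp(−ε²/2σ_e²)` over a
  flat background, then Poisson-counted. Defaults `eps_max = 0.002 Å⁻¹`,
  `σ_e = 0.001 Å⁻¹` put typical partialities in (0.1, 1.0).
* **Intensities** — Wilson-like: symmetry-unique reflections draw i.i.d.
  exponential means and Laue mates share the mean. This gives merging
  statistics the correct correlation structure; real structure factors,
  dynamical scattering and detector point-spread are deliberately absent,
  so passing tests validate the *processing*, not electron-scattering
  physics.
* **Drift** — the pattern center performs a per-position random walk
  (step σ = 0.7 px, clipped at ±5 px), moving spots and direct beam
  together, as beam-tracking does in practice.

Two study scenarios intentionally widen the rocking half-width above the
default. A still samples a slab of thickness 2ε through reciprocal space,
and the union coverage of N slabs is roughly 1 − (1 − ε/s)^N, so near-
complete data from 20 crystals × 7 angles requires ε/s ≳ 3/140 ≈ 0.02;
the completeness scenario therefore uses ε = 0.015 Å⁻¹ at d_min = 2.0 Å
(mosaic nanocrystals). Likewise the six-phase mixture demo uses
ε = 0.008 Å⁻¹ (with σ_e = 0.004) because the smallest demo cell
(V ≈ 310 Å³) yields only ~2 excited reflections per frame at the default
width — too few points for any Fourier autoindexer. Both values follow
from node-count arithmetic (excited spots/frame ≈ 2π s² ε V), and match
the reflection-per-dataset counts typical of real mosaic nanocrystal data.
The `eps_max` and `σ_e` knobs are always set together: σ_e = eps_max/2
keeps the partiality at the acceptance edge at exp(−2) ≈ 0.135.

The six demo phases use reduced cells of common molecular solids (amino
acids, a vitamin, metal acetates, a sweetener) with their approximate
densities; one cell was given clearly distinct short axes (6.10/6.60 Å
instead of two nearly equal ones) so the demo does not sit on the
length-ordering knife edge described above. All are treated as Laue -1
(P1 intensity statistics); space-group absences are out of scope.

## Spot finding

Extended dispersion threshold: a pixel is signal when it exceeds the local
mean by `k_sigma` (default 6) local standard deviations in a 15×15 window.
The background statistics are estimated robustly — seeded from the global
median/MAD and refined three times with flagged regions (dilated by 3 px to
cover spot wings) excluded — and are built with a fixed internal multiplier
(4.0) so that the final `k_sigma` threshold produces nested pixel sets:
raising `k_sigma` can only shrink spots. Connected components of at least
`min_pixels = 3` become spots with background-subtracted intensity-weighted
centroids; a disk around the direct beam is masked.

## Drift correction

Integer-pixel registration (the drift is a few pixels; sub-pixel
registration buys nothing for 3 px integration masks) by FFT
cross-correlation of a central 128×128 crop against each position's
reference frame. When the nominal beam center is known, the reference frame
is additionally anchored to it through the direct-beam centroid — estimated
after Gaussian smoothing at the beam-blob width with the peak search
restricted to the plausible drift range, so a strong Bragg reflection near
the center cannot capture the anchor. Without the anchor the whole series
inherits the reference frame's own drift, which rotates differently into
each frame's reciprocal mapping and distorts the cloud enough to break
small-cell indexing.

## Autoindexing

1. **Cloud** — all spot centroids of a tilt series mapped to the zero-tilt
   crystal frame.
2. **FFT basis search** — the cloud is histogrammed on a 128³ grid
   (half-extent auto-sized to the farthest point; the real-space range then
   covers basis vectors up to ~30–45 Å); peaks of the FFT magnitude above
   0.15 × point count, at real-space lengths in [3, 50] Å, are refined by
   per-axis parabolic interpolation, deduplicated up to sign and ranked by
   height with ties broken by shorter length.
3. **Triplet selection** — over the top 30 candidates, the triplet indexing
   the largest fraction of points to integers (tolerance 0.10 per index)
   wins; among triplets within 2% of the best score the smallest cell
   volume is chosen. Two guards matter in practice: a minimum volume
   (30 Å³) and a coplanarity floor (normalized scalar triple product
   ≥ 0.05) — near-coplanar triplets of true lattice vectors index 100% of
   points with spuriously small volume and would otherwise win the volume
   tie-break.
4. **Primitivization** — FFT candidate lists are dominated by long
   combination vectors, so the winning triplet may generate a sublattice
   (a 2× or 3× supercell) that still indexes every point with all-even or
   otherwise non-primitive indices. Fractional combinations (c·T)/m for
   m ∈ {2, 3} that index the points equally well reveal the missing lattice
   vectors; accepted replacements divide the volume by m, iterated to a
   fixed point. This is a data-driven analogue of cell reduction and is
   what makes small-cell recovery reliable.
5. **Refinement** — iterated least squares of UB against the indexed
   points, re-indexed on the Niggli-reduced basis; `refine_cell` keeps the
   Miller indices fixed (so its residual cannot increase) and propagates
   parameter standard deviations through a finite-difference Jacobian of
   the six cell parameters with respect to the UB elements.
6. **Multi-lattice peeling** — accept a lattice, remove its points, repeat
   on the remainder. The single-lattice acceptance threshold (fraction
   ≥ 0.4) cannot apply per pass — in a three-lattice aggregate each lattice
   owns only ~1/3 of the points — so each pass accepts at ≥ 0.25 of the
   *remaining* points and at least 12 absolute points, and peeling stops
   when fewer than 10% of the original points (or 15 points) remain.
   Unindexed datasets are retained and counted: they form the denominator
   of the indexing rate.

## Integration and partiality

Each still is treated as an independent crystal with
UB(θ) = R(axis, θ)·UB(0). Prediction enumerates every hkl with d ≥ d_min
and |ε| ≤ eps_max from the exact Ewald construction ((0,0,0) excluded) and
projects along the diffracted-beam direction. Integration is
background-subtracted summation: disk of radius 3 px (config), background
median in a 5–8 px annulus, σ from Poisson counts in the peak plus the
variance of the median estimator (π/2 · var/n). The recorded fraction is
modelled as an isotropic Gaussian rocking profile P = exp(−ε²/2σ_e²) — a
deliberate simplification of anisotropic ellipsoidal mosaicity models; the
isotropic width can be re-estimated per dataset by truncated-Gaussian
maximum likelihood on matched excitation errors (`estimate_sigma_e`).
Corrected intensities are I/P with P clamped at 0.05; observations below
the clamp or with the peak off the detector are discarded and counted. No
Lorentz factor is applied (stills have no rotation sweep) and no
polarization correction (electron beam).

## Scaling, ambiguity and merging

Per-still multiplicative scales minimize Σ w (I/k − ⟨I⟩)² with w = 1/σ² by
alternating least squares to a relative change of 1e-6; the first frame of
each connected component of the frame/reflection graph fixes the gauge, and
disconnected components scale independently with a warning. Merohedral
indexing ambiguity is resolved by correlating each dataset's per-unique
means with a running reference (first dataset seeds it; two passes), which
is deterministic in the dataset order. Merging maps hkl to the
lexicographically largest image under the Laue group (operator tables
generated from representative centrosymmetric space groups, so Friedel
mates always merge), takes 1/σ²-weighted means, and reports R_merge,
R_meas, R_pim over uniques of multiplicity ≥ 2, plus CC½ and R_split on
half-datasets assigned alternately in frame-id order (deterministic, no
RNG; unweighted within-half means). Completeness counts observed uniques
against a brute-force enumeration of the resolution sphere. All statistics
are descriptive outputs — still-shot data with partiality corrections can
show R_merge far above 100% and still refine — nothing gates on them.
Export is fixed-width SHELX HKLF4 (3I4, 2F8.2) with global rescaling on
field overflow and the 0 0 0 terminator.

## Phase analysis

Each indexed lattice contributes one Niggli comparison cell; aggregates
contribute once per resolved lattice (the method counts lattices, not
volumes). Average-linkage hierarchical clustering (single/complete
available) on the raw six-parameter Euclidean distance is cut at a
threshold (default 1.5; the demo phases are ≥ 5 apart); flat clusters with
fewer than `min_members = 2` datasets are outliers and leave the
denominators. Volume fractions are count ratios; weight fractions multiply
by per-cluster densities and renormalize, and are omitted with a warning
when any density is missing. Percentages print at one decimal,
rounded half away from zero. Because indexed *lattices* can outnumber
collected *datasets* (aggregates), reports always carry both denominators.

## Problem sizes and determinism

Simulations run on a 256² detector (0.1 mm pixels, 650 mm camera length);
population studies use 100 single-crystal series and the mixture demo 72
positions — sizes chosen so every study is a single-CPU, minutes-scale
computation. One integer seed drives each study; identical (config, seed)
pairs reproduce `report.json` byte for byte.

## Known limitations

* The partiality model is isotropic; anisotropic (ellipsoidal) mosaicity,
  dynamical scattering and precession integration are out of scope.
* The cell comparison metric is the raw Euclidean distance on reduced
  parameters; cells whose reduced lengths nearly tie can still scatter
  between angle slots (see the comparison-form section).
* The intensity model is statistical (Wilson-like), so structure solution
  downstream of the exported HKL files is not meaningful on synthetic data.
* Indexing of very small cells (V ≲ 400 Å³) needs either a broad effective
  rocking width or more tilt angles; at the default 0.002 Å⁻¹ half-width
  such datasets are data-starved by design, mirroring the real trade-off
  between dose and sampling.
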