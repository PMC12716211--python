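# tserialed

Batch-by-batch serial electron diffraction (still-shot ED with tilt)
processing: simulation, autoindexing, still integration, scaling/merging and
quantitative phase analysis for multi-phase nanocrystal mixtures.

## The problem

Phase analysis of beam-sensitive polycrystalline materials — pharmaceutical
formulations, molecular solids, porous frameworks — is hard for powder
diffraction when phases are minor, peaks overlap, or cells are similar.
Serial electron diffraction records one still pattern per nanocrystal, but a
single still of a small-cell crystal carries too few reflections to index
without prior knowledge, and the nearly flat Ewald sphere of high-energy
electrons (λ = 0.0197 Å at 300 kV) removes the information along the beam.

The batch-by-batch approach resolves this: every crystal position on the
grid is visited at a short list of goniometer angles — all positions at one
angle, then the stage rotates once to the next angle.  Regrouping the frames
per position gives each crystal a *discrete tilt series*, i.e. a genuinely
3D sampling of its reciprocal lattice, which is indexable ab initio, while
each frame individually remains a still that serial-crystallography
integration handles with a partiality model.  Counting indexed lattices per
unit-cell cluster then quantifies the phase composition, and merging each
cluster's partiality-corrected intensities yields data for structure
solution.

## What the package does

| stage | module | method |
|---|---|---|
| simulate | `tserialed.synthetic_data` | ground-truth-annotated frame stacks: multinomial phase draws, uniform SO(3) orientations, exact Ewald construction, Gaussian-rocking partiality P = exp(−ε²/2σ_e²), Poisson noise, beam-center drift, aggregates and amorphous positions |
| preprocess | `tserialed.preprocessing` | integer-pixel drift correction by cross-correlation anchored on the direct beam; regrouping into per-crystal tilt series |
| index | `tserialed.indexing` | extended dispersion-threshold spot finding; 3D reciprocal cloud; FFT basis search; triplet selection by indexed fraction with data-driven primitivization; iterative multi-lattice peeling for aggregates; least-squares cell refinement with Niggli reduction |
| integrate | `tserialed.integration` | per-still orientation UB(θ) = R(axis, θ)·UB(0); exact excitation errors; background-subtracted summation; 1/P partiality correction |
| merge | `tserialed.merging` | indexing-ambiguity resolution, per-still scaling, Laue merging with R_merge/R_meas/R_pim/R_split/CC½, completeness, SHELX HKLF4 export |
| phase | `tserialed.phase_analysis` | average-linkage clustering of Niggli cells by 6-parameter Euclidean distance, outlier exclusion, lattice-count volume fractions, density-weighted weight fractions |
| orchestrate | `tserialed.pipeline` / `tserialed` CLI | one reproducible run from a config + seed |

## Worked example

Index 20 independent synthetic single-crystal discrete tilt series of a
fixed triclinic cell (7 stills from −30° to +30°, 0.3 px centroid noise) and
look at the population statistics:

```python
import numpy as np
from tserialed.experiments import cell_recovery_study

study = cell_recovery_study(n_datasets=20, seed=1)
print("indexed %d of %d series" % (study.n_indexed, study.n_datasets))
print("true cell:", study.true_cell)
print("mean cell:", np.round(study.cells.mean(axis=0), 3))
print("RSD %:   ", np.round(study.rsd_percent, 3))
```

prints

```
indexed 20 of 20 series
true cell: (11.1, 12.7, 14.4, 95.0, 98.5, 103.2)
mean cell: [ 11.1    12.702  14.404  94.992  98.512 103.183]
RSD %:    [0.112 0.08  0.08  0.065 0.075 0.089]
```

Every series indexes without any prior cell knowledge, and the spread of
each refined cell parameter across the population is about 0.1% — length and
angle precision well below the 0.5% level at which chemically distinct
phases separate in the dendrogram.

The same arithmetic that turns cluster counts into phase fractions:

```python
from tserialed.phase_analysis import indexing_rate
indexing_rate(495, 902)   # -> 54.9  (percent of collected datasets indexed)
```

A full simulated experiment from the shell:

```bash
tserialed run --seed 11 --out run1/        # simulate -> ... -> report.json
tserialed simulate --seed 3 --out raw/ --format smv-like
tserialed preprocess --in raw/ --out corr/
tserialed index --in corr/frames.h5 --out cells.csv
tserialed phase --cells cells.csv --threshold 1.5 --out report.json
```

`run1/report.json` contains the indexing rate, the unit-cell clusters with
volume/weight percentages, per-cluster merging statistics, and the complete
parameter echo for provenance.

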