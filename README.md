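# cytomech

Cell-mechanics and cytoskeleton quantitation toolkit. Reusable, tested
implementations of five quantitative workflows common in tumor-cell
mechanobiology, each exercisable end to end on synthetic data with known
ground truth:

* **Constrained traction force microscopy** — Boussinesq forward solution
  on an elastic half-space, Fourier-transform traction cytometry (FTTC)
  with Tikhonov regularization and L-curve selection, and an iterative
  cell-contour-constrained inversion (`cytomech.elastics`).
* **Traction read-outs** — RMS traction, first-order moment matrix, net
  contractile moment, polarity ellipse and orientation
  (`cytomech.tracmetrics`).
* **Microtubule length dynamics** — maximum length-change percentage,
  per-cell longest-MT aggregation, exact/asymptotic Mann-Whitney
  comparison (`cytomech.mtdyn`).
* **3-D perinuclear quantitation** — quadratic detector-gain calibration
  and inversion, nuclear/cytoplasmic/perinuclear-shell segmentation with
  anisotropy-aware distance transforms, per-cell mean intensities, plus
  densitometric fold-change and ratio normalizations
  (`cytomech.quant3d`).
* **Interactome enrichment and cohort survival** — pseudo-counted fold
  enrichment with threshold filtering and category fractions
  (`cytomech.enrich`); expression-quartile dichotomization, Kaplan-Meier
  estimation, log-rank and Fisher exact tests (`cytomech.cohort`).

`cytomech.synthio` generates every input with known ground truth
(contractile traction dipoles on 1/11/26 kPa gels, MT length traces with
tunable dynamicity, two-channel confocal stacks with gain distortion,
two-arm survival cohorts, bait/control intensity tables); all generators
are seeded and bit-reproducible. `cytomech.shell_io` provides CSV/TIFF
I/O with provenance headers, validated pipeline configuration and the
`run` driver.

## Command line

```sh
cytomech simulate tfm   --seed 1 --out scene/           # dipole scene
cytomech tfm invert     --displacements scene/displacement.csv \
                        --mask scene/contour.csv --gel-kpa 11 \
                        --reg-lambda auto --out traction.csv
cytomech tfm metrics    --traction traction.csv --mask scene/contour.csv \
                        --out metrics.csv
cytomech simulate mt     --seed 1 --out traces.csv --dynamicity 0.1
cytomech mtdyn stats     --traces traces.csv --group-col condition
cytomech simulate stack  --seed 1 --out stack.tif --enrichment 2
cytomech quant3d run     --stack stack.tif --out shell_means.csv
cytomech enrich deps     --table intensities.csv --threshold 2 --pseudo auto
cytomech simulate cohort --seed 1 --out cohort.csv --hazard-ratio 2
cytomech cohort km       --table cohort.csv --out-prefix results/km
cytomech run             --config pipeline.yaml   # simulate -> invert -> metrics
```

All tabular formats are plain CSV with unit-suffixed columns
(`x_um`, `tx_Pa`, `ncm_pNum`, ...); stacks are multi-channel TIFF with
channel names and voxel sizes in the image description.

## Conventions worth knowing

* Units: µm for lengths, Pa for traction, pN for force (1 Pa·µm² = 1 pN).
* Poisson ratio defaults to 0.5 (incompressible) and is overridable.
* Traction polarity is defined as |λ1| / (|λ1| + |λ2|) of the moment
  matrix eigenvalues, i.e. 0.5 for isotropic traction and 1.0 for a pure
  uniaxial dipole, avoiding an unbounded raw eigenvalue ratio.
* Net contractile moment is the trace of the moment matrix; it is
  negative for contractile cells.
* Quartile dichotomization labels values strictly below the 25th
  percentile (linear interpolation) as "low"; threshold ties go to
  "high".

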