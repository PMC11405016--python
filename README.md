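# evquant

Quantification of extracellular-vesicle (EV) experiments from microscopy
images: vesicle morphometry in electron micrographs, per-micrograph membrane
area, and bead-based fluorescence co-immunopurification — together with the
synthetic ground-truth generators used to validate every stage.

## What it is for

Membrane-bending proteins such as Prominin 1 (Prom1) and Tweety Homology 1
(Ttyh1) drive the release of small EVs (< ~250 nm) from cultured cells.
Comparing such proteins quantitatively requires a handful of image-derived
numbers:

* **per-vesicle shape** from cryo-TEM (vesicles appear as bilayer-rim
  annuli) and negative-stain TEM (dark stain-excluding bodies): the
  area-equivalent diameter `d = 2·sqrt(A/π)`, moment-ellipse axes,
  minimum/maximum caliper (Feret) diameters, and the roundness
  `4A/(π·major²)` (equal to minor/major for an ellipse). A vesicle with
  roundness strictly below 0.6 is classified *tubular* — the morphology that
  distinguishes Ttyh1 EVs and cholesterol-depleted Prom1 EVs from spherical
  ones;
* **membrane yield** as the fraction of micrograph pixels occupied by
  membrane features, compared between conditions as a fold difference of
  means with first-order error propagation and an unpaired Mann–Whitney
  test;
* **bound-fluorophore ratios** on Strep-resin beads: beads are segmented on
  the blue reference channel, artifacts (bright in the target channel only)
  are excluded by rule with an audit trail, and the background-subtracted
  target/reference ratio is averaged per condition relative to a control;
* **statistics** exactly as used in this kind of study: pooled-variance
  Student t tests (two-tailed, unpaired), exact small-sample Mann–Whitney,
  Bonferroni-adjusted thresholds with conservative display rounding;
* **topology curation** of candidate prominin-family sequences: exactly five
  transmembrane helices in a 2+2+1 arrangement with two extracellular loops
  > 300 aa and two intracellular loops < 25 aa (strict inequalities).

Because real micrographs come without ground truth, the package includes a
first-class synthetic generator (`evquant.synthetic`) that renders
cryo-style rim annuli, negative-stain-style rough dark bodies, capsule-shaped
tubules (optionally bent), and two-channel bead montages — all with exact
analytic truth, explicit seeds, and bit-reproducible output.

## Worked example

```python
from evquant import detect, morphometry, synthetic

spec = synthetic.standard_benchmark(seed=11)   # 200 spheres + 20 tubules, SNR 5
micrograph, truths = synthetic.render_micrograph(spec)
detections = detect.segment_vesicles(micrograph)
metrics = [morphometry.measure_detection(d) for d in detections]
summary = morphometry.summarize_condition(metrics, "benchmark")
print(len(detections), round(summary.mean_diameter_nm, 1),
      round(summary.tubular_fraction, 4))
```

prints `220 139.3 0.0909`: all 220 generated vesicles are recovered (the
scene contains 20 capsules of width 42 nm among 200 spheres of 40–250 nm),
the mean area-equivalent diameter is 139.3 ± 58.2 nm, and 9.09 % of the
completely visible vesicles classify as tubular — exactly the generated
fraction. Running the numbered drivers reproduces the full analysis:

```bash
python analysis/01_simulate_benchmark.py    # render the scene + truth table
python analysis/02_vesicle_morphometry.py   # precision 1.000, recall 1.000,
                                            # mean |diameter error| 0.75 %
python analysis/03_membrane_area.py         # fold 5.48 ± 0.24 (truth 5.52),
                                            # Mann-Whitney p = 3.1e-09
python analysis/04_bead_assay.py            # 5/5 artifacts excluded,
                                            # relative binding 1.971 (truth 2.0)
python analysis/05_stats_calibration.py     # type-I rate 0.0522; displays 0.0045 / 0.007
python analysis/06_topology_curation.py     # 2/8 panel sequences pass
```

Each driver writes its tables under `results/` (large regenerable images go
to `scratch/`). A command-line interface mirrors the same stages
(`evquant simulate|detect|measure|membrane-area|bead-assay|compare|filter-topology|run`);
real micrographs are read from MRC (pixel size in the header, Å converted to
nm) or TIFF (resolution tags or an explicit Å override).

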