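# mzflow

Modular LC-MS data processing for metabolomics and proteomics profiling:
scan-level mass detection (centroiding), chromatogram building and
deconvolution, deisotoping, peak-list alignment across samples, and
compound identification against a local database — plus a synthetic
benchmark that scores alignment quality against known ground truth.

## The problem

Liquid chromatography–mass spectrometry produces, per sample, a stack of
mass spectra over retention time (RT). Turning raw scans into a table of
quantified molecular features requires centroiding each spectrum,
connecting m/z traces across scans into chromatograms, resolving those
into individual chromatographic peaks, collapsing isotopologues, and —
the hard part in multi-sample studies — matching corresponding peaks
across samples whose retention times drift non-linearly from run to run.

The core algorithm here is the **RANSAC aligner**. A naive (Join)
aligner matches each sample's peaks to a growing master list `L` inside
a fixed window `|Δm/z| ≤ rm₀, |ΔRT| ≤ tolerance`; it cannot cope with
non-linear RT drift. The RANSAC aligner corrects the drift first. For
each sample S against the master list:

1. For every master row *i* (average m/z *mᵢ*, average RT *rᵢ*), mark
   every peak of S inside the RANSAC window
   `RWᵢ = [mᵢ ± rm₀] × [rᵢ ± rr₀]` as a candidate alignment `(rᵢ, r)`.
2. Run RANSAC on the candidate scatter: repeatedly draw 4 candidates,
   fit a cubic (non-linear mode) or line through them, count candidates
   within the inlier threshold *t* seconds; keep the model with the most
   inliers (a local-optimisation pass then grows the consensus set
   against the smoothed curve).
3. Smooth the inlier set with LOESS to obtain the RT-correction
   function *r* ↦ *r′*.
4. Recenter each row's alignment window at the corrected RT:
   `AWᵢ = [mᵢ ± rm₀] × [r′ᵢ ± ar₀]`.
5. Join the sample into the master list inside these corrected windows.

Alignment quality is measured pairwise against generator ground truth:
**precision** = true aligned pairs / all aligned pairs produced,
**recall** = true aligned pairs / all true pairs in the data.

## Worked example

Generate the standard synthetic benchmark — one seed list of 200 peaks
(m/z 100–1000 Da, RT 60–1200 s) duplicated into 20 samples, each copy
RT-warped by a random smooth non-linear function bounded by 40 s — and
realign it:

```python
import mzflow as mz

pls, truth = mz.generate_synthetic_dataset(mz.SyntheticParams(seed=1))
aligned = mz.ransac_align(pls, mz.RansacParams(k=500, seed=1))
precision, recall = mz.evaluate_alignment(aligned, truth)
print(f"rows: {len(aligned.rows)}  samples: {len(aligned.samples)}")
print(f"precision: {100*precision:.1f}%  recall: {100*recall:.1f}%")
```

```
rows: 200  samples: 20
precision: 100.0%  recall: 100.0%
```

All 4000 features collapse back into exactly 200 rows of 20 members —
every cross-sample pair correct. The same comparison from the CLI, RANSAC
versus the Join aligner at three RT tolerances:

```sh
mzflow benchmark --n-samples 6 --n-peaks 60 --seed 1 --iterations 500 \
    --out report.csv
```

```
 aligner  precision   recall  seconds
  ransac        1.0 1.000000 0.173218
 join_5s        1.0 0.180000 0.004143
join_20s        1.0 0.707778 0.002277
join_50s        1.0 1.000000 0.001748
```

With drift up to 40 s, a 5 s Join window recovers only 18% of the true
pairs; RANSAC recovers all of them after RT correction. (A 50 s Join
window also succeeds here because the benchmark contains no decoy peaks
to mismatch; its precision degrades as soon as near-isobaric
interferents exist.)

A full raw-data pipeline (mzML in, aligned CSV out) is driven by a YAML
config:

```yaml
inputs: [a.mzML, b.mzML]
seed: 7
mass_detector: {name: exact_mass, noise_level: 100}
chromatogram: {mz_tolerance: 0.01, min_time_span: 10, min_height: 500}
resolver: {name: local_minimum, min_height: 500, min_relative_height: 0.05,
           min_ratio: 2, min_duration: 10, search_window: 30}
deisotope: {enabled: true, mz_tolerance: 0.008, rt_tolerance: 5}
aligner: {method: ransac, mz_tolerance: 0.05, rt_tolerance: "0:50",
          rt_tolerance_after_correction: "0:25"}
export: {csv: aligned.csv}
```

```sh
mzflow run --config pipeline.yaml
```

Subcommands `detect`, `align`, `identify` and `benchmark` expose the
individual stages; RT tolerances accept `m:ss` / `hh:mm:ss` notation.

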