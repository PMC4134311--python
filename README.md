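# icanet

Group spatial ICA of 4D brain time series: a tested, reusable pipeline for
comparing intrinsic connectivity networks between two groups, exercised end
to end on synthetic cohorts with planted ground truth.

The package covers the full analysis chain of a two-group movie-viewing fMRI
study:

1. **Synthetic cohort generation** (`icanet.synthdata`) — two groups of 4D
   volumes built from planted spatial networks (Gaussian node bumps times
   band-limited time courses), WM/CSF nuisance signals, linear drift and
   Gaussian noise, plus 100-Hz physiological traces (penile tumescence cuff
   pressure, cardiac R-peak events, respiratory belt) and behavioural scores.
   Every planted quantity is recorded as ground truth; all randomness fans
   out deterministically from one master seed.
2. **Physiological reduction** (`icanet.physio`) — TR-locked tumescence
   percent change (block-mean down-sampling, mean-preserving detrend,
   first-10-s baseline), instantaneous cardiac and respiratory rates, and
   pooled-variance two-tailed group t-tests.
3. **Preprocessing** (`icanet.preprocess`) — scan trimming, half-a-voxel
   motion QC, voxel-wise linear detrending, 6-mm Gaussian smoothing, and
   WM/CSF nuisance regression.
4. **Per-subject spatial ICA** (`icanet.ica`) — temporal PCA whitening (30
   components) followed by FastICA with deflation and the tanh contrast;
   Z-scaled spatial maps, flagged non-convergence, skewness-based sign
   orientation.
5. **Group network identification** (`icanet.group_networks`) — constrained
   average-linkage clustering of all subjects' components on spatial
   similarity (one component per subject per cluster) and greedy one-to-one
   template matching (|r| >= 0.25).
6. **Group statistics** (`icanet.stats`) — voxel-wise one-way ANOVA between
   groups on network Z maps, Monte Carlo cluster-extent thresholding
   (voxel p < 0.005, FWHM 1.842 voxels, 5000 iterations, familywise
   alpha 0.05), ROI t-tests, behavioural t-tests, and brain-behaviour
   Pearson correlations.
7. **Orchestration** (`icanet.pipeline`, `icanet.cli`) — a reproducible
   `simulate -> preprocess -> ica -> group -> stats -> report` pipeline with
   YAML configs and a JSON report.

See `docs/methods.md` for the complete methodological description and the
conventions adopted where the underlying protocol leaves choices open.

## Quick start

Run the packaged tiny end-to-end demonstration (8 subjects, coarse grid,
about half a minute on one CPU):

```sh
icanet run --size tiny --seed 0 --out runs/tiny
cat runs/tiny/report.json
```

Full-size study conditions (16 + 19 subjects, 210 volumes, 3-mm grid,
30 components; several minutes):

```sh
icanet run --size demo --seed 0 --out runs/demo
```

Individual stages are exposed as subcommands operating on files:

```sh
icanet simulate --out data/cohort --seed 1            # write a synthetic cohort
icanet physio data/cohort --out physio.tsv            # TR-locked physio summaries
icanet preprocess data/cohort/EDp01/bold.nii \
    --wm-mask data/cohort/EDp01/wm_mask.nii \
    --csf-mask data/cohort/EDp01/csf_mask.nii --out pre.nii
icanet ica pre.nii --n-components 30 --out ica_out/   # per-subject FastICA
icanet stats --iterations 5000 --seed 0               # Monte Carlo cluster extent
icanet fixtures --size tiny --out fixtures/           # dataset with ground truth
```

As a library:

```python
from icanet.pipeline import RunConfig, run_pipeline
from icanet.synthdata import CohortConfig

cfg = RunConfig(cohort=CohortConfig(master_seed=7))
report = run_pipeline(cfg, "runs/seed7")
print(report["networks_matched"], report["thresholds"])
```

## Testing

```sh
python -m pytest            # full suite, including slow end-to-end tests
python -m pytest -m "not slow"   # fast subset (~2 min)
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(behavioural statistics recomputation, Monte Carlo threshold, network
identification, group-difference recovery, ICA correctness against an
independent reference, error calibration, physiological recovery).

The standalone acceptance target runner:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

reports the Monte Carlo minimum cluster extent (5000 iterations) on the
whole-brain 3-mm mask together with the mask's voxel count.

## Layout

```
src/icanet/       library modules (volume, networks, synthdata, physio,
                  preprocess, ica, group_networks, stats, pipeline, cli)
tests/            pytest suite (unit + property + acceptance)
scripts/          acceptance target runner
docs/methods.md   methodological description and conventions
```
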