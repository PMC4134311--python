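# Methods

This document describes the generator, the analysis pipeline, and the
statistical conventions implemented by `icanet`, including the choices made
where a standard protocol leaves details open. Everything below is verified
by the test suite; module names in parentheses point at the implementation.

## Spatial frame

All volumes live on an axis-aligned grid (`icanet.volume.Grid`) with
isotropic voxels. The default analysis grid uses 3-mm voxels spanning
x in [-60, 60], y in [-90, 70], z in [-40, 75] mm, shape (41, 54, 39).
The whole-brain mask (`brain_mask`) is a super-ellipsoid
(exponent 3, centre (0, -12, 12) mm, semi-axes (62, 80, 58) mm) chosen to
contain every network node with margin; on the default grid it holds
60,153 voxels, matching the scale of a whole-brain 3-mm analysis mask.
Volumes round-trip through NIfTI-1 via nibabel with the grid encoded in the
affine.

## Synthetic cohort generator (`icanet.synthdata`)

Each subject's 4D data is a low-rank signal model plus structured nuisance
plus Gaussian noise:

- **Networks.** Seven canonical networks are specified by node coordinates
  (`icanet.networks.default_networks`): DMN, FPN, SN and VN are planted in
  the data; AN, CEN and SMN exist only as templates and must come out
  absent. Each node is an isotropic Gaussian bump with SD = radius/2
  (default radius 8 mm; visual-cortex node 12 mm); a network map is the
  max-normalised sum of its node bumps.
- **Time courses.** Each planted network gets an independent unit-variance
  time course, band-limited below 0.1 Hz (random Fourier phases), so network
  signals resemble slow intrinsic fluctuations.
- **Group effects.** A group effect multiplies a node's loading in one group
  (`default_group_effects`: DMN mPFC/PCC/left-IPL reduced in EDp to 0.6;
  SN right-AI/IFG reduced to 0.6 and dACC raised to 1.4 in EDp).
  Per-subject loadings add N(0, 0.2) variability, clipped at 0.
- **Nuisance and noise.** WM and CSF compartments carry their own random
  time courses; a rank-1 linear drift (amplitude 1) and i.i.d. Gaussian
  noise (SD 0.5) complete the model.
- **Physiology.** Tumescence is a cuff-pressure trace: 80 mmHg baseline,
  logistic rise (midpoint 20 s, time constant 3 s) to a plateau given as a
  percent amplitude, plus sensor noise. Cardiac activity is an R-peak event
  train with 3 % inter-beat-interval jitter around the target rate.
  Respiration is a sinusoid at the target frequency plus noise.
  Default group parameters: tumescence +10 % (HC) vs +1 % (EDp),
  cardiac 74.0 vs 75.4 bpm, respiration 0.25 vs 0.30 Hz.
- **Behaviour.** Twelve questionnaire/score columns are drawn per subject
  from group-specific normal distributions.
- **Determinism.** One master seed fans out through
  `numpy.random.SeedSequence`; all derived seeds are < 2^31. Re-running a
  simulation writes byte-identical manifests.

## Physiological reduction (`icanet.physio`)

- **Tumescence percent change**: the 100-Hz trace is block-averaged to one
  value per TR, its least-squares linear trend is removed *mean-preservingly*
  (so the run-mean percent change stays interpretable as an amplitude), and
  values are expressed as percent change against the mean of the first 10 s
  of the down-sampled raw trace. Consequence (verified in closed form by the
  tests): an added linear trend is not perfectly cancelled — its effect
  enters only through the baseline window and is negligible for realistic
  drifts.
- **Cardiac rate**: 60 / inter-beat interval, assigned to interval
  midpoints and linearly interpolated to TR midpoints.
- **Respiratory rate**: the belt trace is low-pass smoothed (zero-phase
  Gaussian, SD 0.15 s — far below any plausible respiratory period) so
  sensor noise cannot create spurious crossings, then cycle times are taken
  as sub-sample-interpolated rising zero crossings and converted to
  cycles/min on the TR grid.
- **Group tests**: classical pooled-variance two-tailed t-tests, also
  available directly from printed summary statistics
  (`pooled_ttest_from_summaries`).

## Preprocessing (`icanet.preprocess`)

Applied per subject, in order: discard the first 2 volumes; motion QC
(excursion = translation plus rotation arc at a 65-mm head radius; fail
above half a voxel); voxel-wise linear detrending (mean-preserving);
isotropic Gaussian smoothing at FWHM 6 mm (reflect boundary); nuisance
regression of the WM and CSF mean series (demeaned covariates, least
squares; a |r| > 0.999 collinear pair drops CSF with a warning).

## Per-subject spatial ICA (`icanet.ica`)

- **Whitening**: voxel-wise (row) demeaning, temporal PCA via SVD, retain
  30 components (capped at the data rank with a warning), scale to identity
  covariance. The `WhiteningRecord` retains everything needed to
  reconstruct.
- **FastICA**: deflation with the tanh (log-cosh) contrast. Each unit is
  estimated by the fixed-point iteration
  `w <- E[x g(w'x)] - E[g'(w'x)] w`, Gram-Schmidt-orthogonalised against
  previously found units, declared converged when
  `|<w_new, w_old>| > 1 - tol`, with up to 5 random restarts; a unit that
  never converges is flagged (iteration count -1) but retained.
- **Outputs**: spatial maps Z-scaled (zero mean, unit variance over voxels),
  signs oriented so each map has non-negative skewness, and time courses
  scaled so that map (x) time course reconstructs the demeaned data.
- **Validation**: the test suite checks source recovery on super-Gaussian
  toys, orthonormality of the unmixing rows (1e-6), reconstruction identity,
  voxel-permutation equivariance, determinism, and agreement with
  scikit-learn's independent FastICA implementation on identical whitened
  input (|r| > 0.99 per matched component). scikit-learn is used only as an
  oracle in tests, never at run time.

## Group network identification (`icanet.group_networks`)

- **Self-organising clustering of ICs (sogICA-style)**: pool all subjects'
  components; distance 1 - |spatial r| within the mask; weighted
  average-linkage agglomeration under the constraint that no cluster may
  contain two components of the same subject; deterministic tie-breaking;
  member signs aligned to the first member before averaging.
- **Template matching**: cluster mean maps are matched one-to-one to the
  seven canonical templates greedily by descending |r|, accepting matches
  with |r| >= 0.25 and aligning signs. Templates without an acceptable
  cluster are reported absent.
- **Subject network maps**: each matched cluster yields one Z map per
  contributing subject (sign-aligned); subjects missing from a cluster are
  reported with a warning.

## Group statistics (`icanet.stats`)

- **Voxel-wise test**: one-way two-group ANOVA on subject network Z maps;
  F = t^2 with df (1, n1 + n2 - 2). Zero-variance voxels are flagged and
  excluded with a warning.
- **Cluster-extent threshold (Monte Carlo)**: iterate (default 5000 times):
  draw Gaussian noise on the grid, smooth with a Gaussian of FWHM
  1.842 voxels, standardise within the mask, threshold at the *one-class*
  critical value z = Phi^-1(1 - p_voxel) (p_voxel = 0.005), label clusters
  with 26-connectivity, record the maximum cluster size. The minimum
  cluster extent is the smallest k with P(max >= k) <= alpha = 0.05.
  One-class exceedance is used because the thresholded statistic is an
  F map (direction-less); this matches the convention of standard
  AlphaSim-style simulators and yields ~22 voxels on the default 60k-voxel
  3-mm mask.
- **Applying the threshold** (`threshold_and_label`): the observed map is
  thresholded per sign at the two-tailed t critical value
  t_{1 - p_voxel/2, df} — equal-or-stricter than the simulated null — and
  surviving clusters are labelled per sign with 26-connectivity, discarding
  clusters below the Monte Carlo minimum extent. Cluster tables report
  peak voxel, peak mm coordinates, signed peak t and extent.
- **ROI, behaviour, correlation**: ROI means compared by pooled t-test;
  behavioural columns by pooled t-test (reproducing printed table values
  from summaries); brain-behaviour association by Pearson r with exact
  two-tailed p. Type-I error of the correlation test is verified at ~5 %
  by simulation.

## Calibration and validation highlights

- The Monte Carlo minimum extent on the default mask is stable across
  simulation seeds at 22 +/- 2 voxels (500-iteration runs reproduce the
  5000-iteration value within +/- 2).
- Familywise error of the full cluster-threshold procedure, measured on
  500 independent null cohorts (smoothed standardised Gaussian fields,
  16 + 19 subjects), stays at or below alpha plus two binomial standard
  errors.
- On default cohorts, group ICA plus template matching identifies exactly
  the four planted networks (DMN, FPN, SN, VN) and reports the three
  unplanted templates absent, deterministically.
- Planted group differences at the five affected nodes are recovered with
  correct signs in the corrected cluster tables for the large majority of
  seeded cohorts.
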