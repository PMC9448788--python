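# Methods

This note documents the models, defaults, and design choices behind the
toolkit, in the order a maintainer is likely to ask about them.

## The metadata schema

The field registry (`aslbids.registry`) encodes, for each sidecar field,
its value kind, units, per-role requirement level, and an applicability
predicate evaluated on the ASL sidecar values. The ladder is ranked by
necessity for quantification: REQUIRED fields are exactly those the
single-delay CBF computation consumes (labeling scheme and timing, M0
declaration, field strength for constant selection, readout
dimensionality, echo time, flip angle, preparation repetition time, pair
count); RECOMMENDED fields improve or contextualize quantification
(acquisition voxel size, background-suppression details); everything else
in the BIDS 1.6.0 ASL set is OPTIONAL.

Conditional requirements are modelled as applicability, not as a second
severity axis: `SliceTiming` exists (and is REQUIRED) only for 2D
readouts, `LabelingDuration` only for (P)CASL, the bolus-cutoff fields
only for PASL with `BolusCutOffFlag` true, `M0Estimate` only for
`M0Type == "Estimate"`. A handful of fields carry different levels per
file role (`PhaseEncodingDirection` is REQUIRED on a PEPolar fieldmap and
OPTIONAL elsewhere), so a registry entry stores a role → level map rather
than a single level. Exactly `PostLabelingDelay`, `LabelingDuration`,
`FlipAngle` (and the vascular-crushing VENC) accept scalar-or-array
values; that is the minimal set needed for multi-delay and Look-Locker
style series.

All time-valued fields are seconds. Values above 10 s in a seconds-typed
field trigger a plausibility WARNING (`ASL404`) because the most common
real-world defect is milliseconds left over from DICOM.

## The validator

Severity maps the ladder directly: missing REQUIRED → ERROR, missing
RECOMMENDED → WARNING, missing OPTIONAL → silent; `--strict` promotes the
RECOMMENDED warnings. Structural rules cover: context row count vs volume
count, control/label balance, observed pairs vs `TotalAcquiredPairs`
(WARNING only, because averaged exports legitimately collapse
repetitions), the ban on mixing `deltam`/`cbf` volumes with raw
control/label pairs in one series, M0 declaration vs dataset contents,
the scale-factor deny-list (`RescaleSlope` and relatives may never appear
in a sidecar — scaling belongs in the voxels), and PEPolar linkage
(`IntendedFor` must resolve to an existing file; the two
`PhaseEncodingDirection` values must share an axis and differ in
polarity). Rule ids are stable strings (see the module docstring of
`aslbids.validation`); reports are deterministic (sorted by rule id,
path, field) and side-effect free, so validation is idempotent.

A `deltam`-only series must still carry `TotalAcquiredPairs`; the
pair-count cross-check then compares against the number of difference
volumes.

## Conversion transforms

Two conversion-time mandates are exposed as pure functions: DICOM-style
linear intensity scaling (`v·slope + intercept`, per series, since ASL
and M0 exports commonly carry different slopes) and restoring acquisition
order from export order via an explicit permutation that moves context
rows jointly with volumes. Vendor dialects that divide rather than
multiply are the caller's responsibility when constructing
`ScaleFactors`; the core stays single-convention.

## Quantification

Single-compartment single-delay forms, as given in the README. Numerical
choices:

- Constants live in one table keyed by `MagneticFieldStrength`:
  T1 blood 1.650 s (3 T) / 1.350 s (1.5 T); T1 tissue 1.330 s (3 T) /
  1.200 s (1.5 T), used only for the M0 saturation-recovery correction;
  λ = 0.9 mL/g; α = 0.85 (P)CASL, 0.98 PASL. Unknown field strengths
  raise rather than interpolate.
- The brain mask is `M0 > 0.1 ×` the 99th percentile of the M0 map
  (fraction configurable); voxels outside are zeroed, never NaN.
- `M0Estimate` scalars are used uncorrected: whether they are
  pre-corrected for relaxation is unspecified upstream, and applying the
  saturation factor to an already-corrected blood value would be wrong
  more often than not.
- For PASL the inversion time TI is taken to be `PostLabelingDelay`
  (effective, per slice for 2D); the alternative reading TI − TI₁ is not
  used. Flagged for upstream clarification.
- Multi-delay series produce one CBF map per distinct delay (pairs are
  grouped by their per-volume delay); no kinetic-model fitting.
- PASL without a bolus cutoff and Look-Locker series are refused
  (`UnsupportedSchemeError`) instead of silently producing mis-scaled
  maps. `M0Type == "Absent"` is refused unless the caller opts into the
  mean-control fallback, which is logged as approximate.

## The synthesizer

The generator inverts the quantifier's equations voxelwise: given a true
CBF map, the per-pair difference signal at each delay is computed through
the same constants and the same per-slice effective delays, control
volumes are a background-suppressed static baseline, labels are control
minus difference, and m0scans are the true M0 map attenuated by the
saturation factor for the declared `RepetitionTimePreparation` (4 s).
Because forward and inverse share one code path for the effective delay
and one constants table, a noise-free dataset quantifies back to the
ground truth at floating-point precision — this is the round-trip
property the test suite and acceptance script measure.

The phantom is a 16×16×5 grid: gray-matter block (CBF 60 mL/100 g/min,
M0 1000) inside a white-matter shell (CBF 20, M0 800), zero background —
conventional physiology used purely as a fixture. Background suppression
multiplies the static baseline by a single factor 0.1 (the m0scan is
never suppressed, reproducing the large ASL/M0 signal-level gap that
makes per-series scale factors dangerous in real data). Noise is
additive i.i.d. Gaussian per volume, seeded per plan; the default
σ = 1.0 puts the per-pair difference SNR in gray matter near 5, a
realistic single-average operating point. At that SNR with 40 pairs the
brain-masked mean CBF is recovered well within 5% in every seeded
replicate measured.

The five example plans mirror the published example configurations:
asl001 — GE-style single-PLD PCASL, 3D, four suppression pulses, time
series of `deltam` + in-series `m0scan`; asl002 — Philips-style
single-PLD PCASL, 2D-EPI, two pulses, separate m0scan (plus a
labeling-plane screenshot and location description); asl003 —
Siemens-style multi-TI PASL, 3D GRASE, two pulses, separate m0scan;
asl004 — custom multi-PLD PCASL, 2D-EPI, in-series m0scan, plus a
reversed phase-encoding m0scan under `fmap/`; asl005 — Siemens-style
single-PLD PCASL, 3D GRASE, four pulses, in-series m0scan. Sequence
parameters the published table does not print (delay values, durations,
pair counts, grid, noise level) are filled once with consensus-typical
values and are visible in `aslbids.synth.example_plan`; nothing
downstream depends on the specific choices except through round trips.
For asl001 the in-series placement of the m0scan is a reading of an
ambiguous source description and is fixed here as: m0scan rows first,
then difference volumes.

Defect injection (`mutate_dataset`) applies exactly one catalogued
defect per call; the published mapping to validator rules is:

| violation id       | must fire | may also fire |
|--------------------|-----------|---------------|
| `delete-field:<F>` | ASL101    | ASL601/ASL602 when `<F>` is a linkage field |
| `truncate-context` | ASL201    | ASL202 |
| `wrong-m0type`     | ASL301    | — |
| `scaling-key`      | ASL501    | — |
| `break-pepolar`    | ASL603    | — |
| `shuffle-context`  | ASL202    | ASL204 on `deltam` series |

`shuffle-context` deterministically relabels one row so the pair balance
breaks; a pure permutation of a balanced context would be semantically
legal and therefore undetectable by design.

## On-disk format choices

NIfTI images are written as float64 with scl slope/intercept pinned to
1/0, making "all scaling applied" bit-checkable and keeping the
control−label subtraction exact through a disk round trip (float32
storage would inject relative errors near the round-trip tolerance via
cancellation). Gzip members carry a zero mtime so identical datasets are
byte-identical — seeded generation is reproducible at the tree-hash
level. JSON sidecars are written UTF-8 with sorted keys; `_aslcontext.tsv`
is a single mandated column `volume_type` with LF endings and
case-sensitive tokens. One ASL run per subject is supported; the run
entity is parsed but multiple runs are rejected as ambiguous. `IntendedFor`
paths are forward-slash, relative to the subject directory. The PEPolar
fieldmap sidecar needs only `PhaseEncodingDirection` + `IntendedFor`;
when the main series' m0scan is in-series, the link targets the ASL
image itself.

## What passing tests do and do not show

The generator exercises format, validation, and quantification logic; it
emulates no MR physics beyond the forward perfusion model — no T2*
decay, motion, distortion, partial volume, or coil effects, and the
PEPolar fieldmap image is an undistorted copy. Recovery results
therefore demonstrate the *metadata sufficiency and internal consistency*
of the pipeline, not quantification accuracy on real scanner data.
Problem sizes (16×16×5 grids, tens of pairs, 25 noisy replicates) were
chosen so the whole suite runs in seconds while every property is still
measured on non-trivial data.

## Known limitations

- No DICOM reading; the conversion module exposes the mandated
  transforms for converter front-ends to use.
- No multi-delay kinetic fitting, partial-volume or motion correction,
  Look-Locker handling, or derivatives-tree modelling.
- Validation covers the `perf` datatype and its `fmap` linkage only;
  other datatypes in the tree are tolerated and listed, not validated.
- Constants are tabulated for 1.5 T and 3 T only.
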