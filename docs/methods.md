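# Methods

## Audiogram model

An audiogram is an ordered map from test frequency (kHz) to air-conduction
threshold (dB HL). The canonical grid is 0.125, 0.25, 0.5, 1, 2, 3, 4, 6,
8 kHz; it is the grid over which consecutive-frequency windows are built.
Off-grid frequencies (0.75, 1.5 kHz, ...) are accepted in input and flagged,
but excluded from window construction so the window set stays well defined.
Thresholds are stored as reals in [-10, 120] dB HL; a 5 dB measurement step
is deliberately not enforced, since nothing in the decision logic requires
it. Values outside the plausible range are validation errors that name the
offending frequency.

**Dummy coding.** Thresholds above 115 dB HL, and "no response" entries
(`NR` in input files), are replaced by 120 dB HL at ingestion so that
averages and differences remain computable at the audiometer's limit. The
rule is idempotent, and no stored value can lie in the open interval
(115, 120).

**Data check.** "Enough valid data" is concretized as: (a) every PTA
frequency named by the criteria is measured in the acute audiogram, and
(b) for each measured baseline, at least one full window of `window_size`
consecutive grid frequencies is measured in both acute and baseline. This is
the minimal condition making both criteria computable. Failures are reported
as a list of reasons, never raised, and make the affected recommendations
`not_computable`.

## Inclusion criteria

* **Severity**: acute 4PTA (mean of 0.5/1/2/4 kHz by default) must reach
  `min_severity_db`. The comparison is inclusive (>=): the difference
  criterion is explicitly inclusive, and the severity criterion follows it
  for symmetry. A value of 0 disables the criterion.
* **Difference**: the per-frequency series acute − baseline (positive =
  incident-related worsening), restricted to frequencies measured in both,
  is averaged over every run of `window_size` consecutive grid frequencies;
  the maximum complete-window mean must reach
  `min_window_mean_difference_db` (inclusive; 0 disables). Ties between
  windows are broken toward the lowest first frequency, so a single window
  is always reported as the maximum. An empty intersection or no complete
  window flags the comparison not computable.

A positive recommendation for a baseline requires both criteria; the
recommendation is made separately for every baseline variant. Windows
involving 6 and 8 kHz participate in the search like any others.

## Baseline variants

1. **Previous audiogram** of the affected ear (best reference when it
   exists).
2. **Contralateral ear** (assumes pre-incident symmetry; that assumption is
   the screener's to verify and is not modelled).
3. **ISO 7029 normative median**: shift(a, s, f) = alpha(s, f) · (a − 18)²
   for age a >= 18, with the per-sex, per-frequency coefficients alpha in
   dB/year² shipped as a versioned CSV resource (`iso7029_median.csv`,
   edition label "ISO 7029:2000 median"). Since the median threshold of
   otologically normal 18-year-olds is 0 dB HL by construction of the scale,
   the shift is the normative audiogram. Ages below 18 return 0 with a
   warning; ages above 70 (the standard's stated applicability limit)
   extrapolate the quadratic with a warning. Only the median is implemented;
   quantile spreads are out of scope. A missing coefficient is an explicit
   error, never a silent zero. Patients of unspecified sex get a
   `not_computable` normative comparison rather than an error.

## Grading

WHO and EU grades are looked up from an editable CSV resource on each
audiogram's own PTA. Shipped bands: WHO — no impairment <= 25, slight 26–40,
moderate 41–60, severe 61–80, profound >= 81; EU — normal < 20, mild 20–39,
moderate 40–69, severe 70–94, profound >= 95. Band edges are integers while
PTAs are real, so membership is decided by the largest lower edge not
exceeding the PTA (a PTA of 80.99 therefore grades severe, not profound).
Grading is advisory in every report: it formally applies to the better ear,
which the affected ear often is not.

## Recruitment rate

A patient counts as eligible iff the first baseline in the policy order
(default: previous, contralateral, normative) whose comparison is computable
recommends inclusion; later baselines are not consulted. The rate is
eligible/total, undefined (reported as null) for an empty cohort.

## Synthetic cohorts

The generator emulates a screening population: ages drawn uniformly on
18–80, a configurable female fraction (default 0.5), measured baselines
equal to the ISO 7029 median for the drawn age/sex plus independent Gaussian
noise per frequency (default SD 5 dB, clipped to [-10, 115] to stay out of
the dummy-coded gap), and an acute audiogram formed by adding an incident
loss of configurable magnitude over a contiguous frequency region (default
0.5–4 kHz, magnitudes 10–80 dB). The contralateral ear and, for a
configurable fraction of patients (default 0.3), a previous audiogram carry
the same pre-incident baseline — the symmetric-hearing idealization.

With `target_eligible_fraction` set, exactly `round(n * target)` records are
made eligible by construction: eligible records get an incident magnitude of
at least max(difference criterion, severity gap), with region baselines
capped so the ceiling never truncates the incident; ineligible records
undershoot the difference criterion (or, when only severity is active, keep
the acute PTA strictly below the minimum). Labels are therefore exact and
the decision engine must agree on every record. An infeasible target (e.g.
both criteria disabled with target < 1, or an incident region that cannot
cover the PTA frequencies or fit a window) raises an explicit error.

What the generator does **not** emulate: frequency-correlated measurement
error, 5 dB quantization, asymmetric pre-incident hearing, conductive
components, missing data patterns of real clinics. Passing tests on
synthetic cohorts therefore validate the decision logic, not the clinical
realism of any particular cohort.

## Numerical conventions

Means are computed at full floating-point precision and only rounded (to
2 decimals) for display. Determinism: all randomness flows through a single
`numpy` generator seeded from the spec, so identical spec + seed reproduces
a cohort bit for bit; report JSON is deterministic apart from a provenance
timestamp. Problem sizes in the tests (cohorts of 40–200, 1000 randomized
audiograms for the window-maximum oracle) keep the full suite under a few
seconds while exercising every code path.

## Known limitations

* The contralateral and normative baselines embody assumptions (symmetry,
  otological normality) that the tool reports but cannot verify; medical
  history checks remain with the investigator.
* The ISO 7029 model is extrapolated beyond age 70 with a warning rather
  than refused.
* Grading bands ship as 1997-era WHO and European Working Group tables;
  other classifications can be supplied via `--grading-table`.
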