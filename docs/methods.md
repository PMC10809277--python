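# Methods

## Calibration model

TWIM arrival times are converted to CCS by the corrected-time /
corrected-CCS power-law protocol. For a calibrant with arrival time
t_a (ms), m/z and charge z, and an instrument EDC delay coefficient:

    t'     = t_a − EDC · sqrt(m/z) / 1000          (flight-time correction)
    mu     = m_ion · m_gas / (m_ion + m_gas)       (m_ion = m/z · z, gas N2 = 28.0134 Da)
    omega' = CCS_ref · sqrt(mu) / z                (charge/reduced-mass normalization)
    omega' = A · t'^B                              (fitted per class / charge state)

and for unknowns the chain is inverted: CCS = A·t'^B · z / sqrt(mu).
The /1000 in the EDC term assumes arrival times in milliseconds; all
times in the package are milliseconds by contract. The ion mass is
taken as m/z·z (electron mass neglected, < 0.002%). Each correction is
an isolated function, so a platform with a differently scaled EDC term
is a one-line change.

Fitting runs in linear (omega') space by unweighted nonlinear least
squares, seeded from the log–log regression; a pure log–log fit is
selectable (`method="loglog"`) and its parameters are always reported
in the diagnostics. Log–log fitting effectively weights by relative
error and biases the curve toward small CCS, which is why it is the
seed rather than the default. Fewer than three calibrants is an error;
peptide charge states z = 1, 2, 3 are fitted separately.

Curve self-diagnostics: per-calibrant percent error
100·(calibrated − reference)/reference, their mean absolute value, and
RMSE in Å² computed on CCS.

## Arrival-time extraction

When calibrant arrival times are not supplied, they are extracted from
mobility-resolved mzML: intensities within ±`mz_tolerance` (default
0.05 Th, appropriate for a TOF at ~30k resolving power) of the target
m/z are summed per spectrum and binned by the spectrum's drift-time
value as stored in the file (no bin-index arithmetic of our own). A
single Gaussian is fitted to the most intense connected peak of the
resulting distribution — initialization: amplitude = max, mean =
argmax, sigma = FWHM/2.355 — and its fitted mean is the arrival time.
At least five nonzero points are required; an all-zero window is a
no-signal error; if the optimizer fails, the argmax grid point is
returned with an explicit fallback flag. No smoothing or multi-peak
deconvolution is attempted.

The mzML reader is a deliberately small lxml-based parser covering what
this task needs: 32/64-bit float arrays, zlib or no compression, and
the ion-mobility drift-time cvParam (MS:1002476); files without a
mobility dimension are rejected.

## Trendlines and assignment

Per-class trendlines regress reference drift-tube CCS on m/z. The
default form is a power law CCS = a·(m/z)^b — the canonical scaling of
biomolecular cross sections with mass — with linear and quadratic
forms available so externally published coefficients can be loaded
verbatim without refitting. At least five reference pairs are required;
evaluation outside the reference m/z range is allowed but flagged with
a warning. Trendlines exist only for the classes arbitrated at z = 1
(lipid, small molecule, peptide); multiply charged features bypass
trendline arbitration entirely and use the charge-matched peptide
curve.

For a z = 1 feature, every class with both a curve and a trendline is
attempted; classes are ranked by ΔCCS = |calibrated − trendline| and
the first m/z-eligible class wins. Eligibility uses strict
inequalities: small molecules require m/z < 550, lipids m/z > 300,
peptides are unconstrained. When the top-ranked class is ineligible the
assignment is flagged (`constraint_fallback`). Exact ΔCCS ties —
measure-zero on continuous data — break by the fixed priority
lipid > small molecule > peptide for determinism. A feature with no
eligible class raises an error carrying all per-class ΔCCS values; a
batch helper collects these instead of aborting.

### Calibration-effect score

d = 100·|CCS_assigned − CCS_next| / CCS_assigned, where "next" is the
class ranked second by ΔCCS (after excluding the assigned class — this
also covers the fallback case, where the excluded class is not rank 1).
Buckets: d ≥ 6 → 4, 3 ≤ d < 6 → 3, 1 ≤ d < 3 → 2, d < 1 → 1; the
boundary belongs to the higher score ("6% or greater", "between 3 and
6"). Multiply charged assignments score 0 by convention; with only one
attempted class the score is undefined and reported as missing, since
it measures disagreement between at least two calibrations. Two open
choices were settled as package conventions: the denominator is the
assigned-class CCS, and "next closest" means next by ΔCCS rank rather
than by CCS proximity, keeping the score consistent with the assignment
metric.

## Synthetic data

The generators emulate positive-mode conformational space rather than
any specific compendium. Defaults, chosen once:

- trendlines CCS = a·(m/z)^b with (a, b) = lipid (7.7, 0.55), small
  molecule (6.0, 0.54), peptide z=1 (9.5, 0.50): peptides lowest and
  lipids highest over m/z 300–1000, with lipid–peptide gaps of
  ~20–40 Å² and peptide–small-molecule gaps of ~25–40 Å², matching the
  ordering and spacing of published conformational-space maps;
- class m/z ranges: lipid 400–1000, small molecule 120–540, peptide
  300–1000 Th (each inside its eligibility window);
- calibration curves (A, B): lipid (420, 0.52), small molecule
  (430, 0.515), peptide z=1 (412, 0.524), z=2 (450, 0.49), z=3
  (465, 0.46). The z=1 curves agree to ~1–3% over the working
  drift-time range, which is the realistic regime — cross-class
  calibrations of a real feature differ by a few percent, not by tens;
- EDC 1.57, N₂ drift gas; trendline scatter 1.0 %CV (the residual
  scale of compendium-style reference sets); arrival times come out in
  the 1–16 ms range typical of TWIM separations.

Calibrant generation back-solves arrival times exactly through the
target curve and applies multiplicative Gaussian noise to the recorded
reference CCS only, so zero noise closes the loop exactly. Feature
generation draws m/z uniformly per class, sets the true CCS to the
trendline value times (1 + scatter), applies the signed calibration
error, and back-solves the arrival time through the class's own curve.
All randomness flows from a single integer seed through one
`numpy.random.Generator` in feature order.

### Robustness experiment

The perturbation experiment shifts one fixed base feature set by each
signed error level (a paired, common-random-numbers design: identical
m/z and scatter draws at every level, exactly as one would perturb a
fixed table of reference values), reruns the full assignment and
tabulates per-class accuracy. The paired design makes the directional
effects deterministic functions of the perturbation rather than
artifacts of resampling. Default problem size in the acceptance suite:
2,000 features per class across nine levels (−5…+5%), which runs in a
few seconds.

What passing shows — and does not. The synthetic features are ideal:
exactly on-trendline up to Gaussian scatter, no interfering isobars, no
detector saturation, no retention-time misalignment, and the same
curves generate and calibrate the data. Results therefore validate the
decision logic and its geometry (which class wins where, and how signed
errors move the boundary), not instrument-level accuracy on real
samples. Absolute accuracies depend on the chosen trendline spacing and
the 1% scatter; only the directional pattern (lipids degrade under
negative errors, peptides under positive, small molecules insensitive)
is a robust prediction.

## Numerical notes and limitations

- Corrected times must be positive; a non-positive t' raises a named
  error identifying the ion rather than propagating NaNs.
- Gaussian and power-law fits use `scipy.optimize.curve_fit` with
  analytic-free seeding as above; `maxfev` is raised so well-posed fits
  never die on iteration limits.
- Results CSV writes CCS with four decimals; round-trips preserve
  values to 0.01 Å². Parsing is locale-independent (decimal point).
- Charges z ≥ 4 are rejected outright rather than silently reusing the
  z=3 curve.
- Negative ionization mode, additional classes (e.g. native proteins),
  z ≥ 2 trendlines, vendor raw formats and feature identification are
  out of scope.
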