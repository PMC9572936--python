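# Methods

This note records the modelling choices behind `milkscreen`: what is
computed, what the synthetic data emulate, which parameters matter, and
where the design was genuinely open.

## Exact-mass arithmetic

Monoisotopic atomic masses (IUPAC/AME values to ≥ 6 decimals for C, H, N,
O, S, F, Cl, Na, plus ²H and ¹³C for the labelled internal standards) are
summed over the molecular formula, and the adduct ion m/z is

    m/z = (M + Σ added-atom masses − z·m_e) / z.

The electron mass is subtracted per unit charge — the physically correct
ion mass; at m/z 400 the electron amounts to ~1.4 ppm, which matters when
matching at 5 ppm. Four adduct species cover the panel: [M+H]⁺, [M+Na]⁺,
[M+2H]²⁺ and the ammonia-loss ion [M+H−NH₃]⁺ (sulfanilamide, whose
protonated molecule at 173 Th loses NH₃ in-source; only this reading
reproduces its tabulated 156.0114). The doubly charged assignment for
cefquinome, tilmicosin and spiramycin likewise follows from the tabulated
values, which only (M + 2 m_p)/2 reproduces.

Full double precision is carried everywhere; the 4-decimal rounding of the
published table is display-only.

### Panel database and transcription flags

The packaged 57-compound panel carries formula, adduct, expected RT, two
diagnostic product ions, normalised collision energy, MRL (absent for the
ten unauthorized substances), the screening target concentration (STC) and
the reported within-lab CV. STCs are shipped as configured data, not
computed MRL fractions: the class-wise fractions follow policy, not a
formula.

On load, every tabulated precursor m/z is recomputed; rows deviating by
more than 0.5 ppm are flagged as transcription discrepancies (penicillin G
+0.70 ppm, cefquinome −0.97 ppm, doxycycline +3.50 ppm, azithromycin
+1.73 ppm, sulfamonomethoxin +2.53 ppm). The recomputed value is
authoritative for matching — notably doxycycline, which shares
C₂₂H₂₄N₂O₈ with tetracycline yet prints a different precursor mass — but
flags are reported, never silently corrected, mirroring the audit
obligations of an official-control laboratory. All deviations sit well
inside the 5 ppm matching tolerance, so the flags never change a verdict.

## Identification

Matching tolerances are the instrumental specificity limits: |ppm| ≤ 5 for
the precursor, relative RT deviation ≤ 2.5%, both inclusive (the
regulatory phrasing is "≤"). Product ions are tabulated to one decimal, so
fragment matching uses an absolute ±0.05 Th window (configurable), each
observed ion consumed at most once.

Identification points: separation 1.0, HR precursor 1.5, each HR product
2.5; required total 4.0 with an MRL, 5.0 without. A fully detected analyte
scores 1.0 + 1.5 + 2×2.5 = 7.5; with one product ion, 5.0 — still enough
for either class. The separation point is only reachable alongside a
precursor match: candidates are pre-filtered by the m/z window, so a lone
RT coincidence identifies nothing.

**Candidate selection.** When several features fall in a compound's m/z
window, selection follows extracted-ion-chromatogram practice: features
inside the RT window take precedence, and within the window candidates
rank by number of matching diagnostic fragments, then intensity, then
smaller |ppm error|, then smaller RT deviation; outside the window, |ppm
error| alone. The fragment-then-intensity ordering is load-bearing for
this panel: four tetracyclines/epimers share one formula (and the
doxycycline pair even shares both product ions), and the two
281.07-sulfonamides share another, so a pure mass-error rule routinely
assigns an epimer's peak to the wrong analyte, while intensity alone lets
a drifting epimer peak outrank the true, fragment-confirmed one. Both
failure modes inflate the apparent dispersion of replicate readings far
beyond the generating value.

## Quantification and screening

Unweighted ordinary least squares on the five-level solvent line
(0.1, 0.5, 1, 5, 10 µg/L); weighting is exposed in configuration but the
acceptance criterion is only R² ≥ 0.999. Back-calculation clamps negative
vial concentrations to zero before applying the dilution factor

    sample µg/kg = vial µg/L × (4.1 mL / 1.0 g) × 10 = vial × 41,

where 4.1 mL is the extraction volume (4.0 mL acidified acetonitrile +
0.1 mL EDTA solution), ignoring the milk's own water contribution — a
self-consistent choice that maps every STC (4–75 µg/kg) to 0.098–1.83 µg/L,
inside the calibration range. Quantification reads the precursor+RT-matched
peak; fragments confirm identity but do not carry the response.

A sample screens *suspect* iff the analyte is identified **and** its
concentration strictly exceeds the cut-off Fm ("above which" ⇒ strict).
Batch QC requires the negative control compliant everywhere, the
screen-positive control (STC spike) suspect everywhere, and the four
labelled internal standards (10 µg/kg each) present within RT tolerance in
both controls. Internal standards are presence/RT checks only; no
isotope-dilution correction. Cefadroxil-d4's parent is not on the panel,
so its expected RT (8.5 min) is a synthetic modelling choice; the other
three inherit their parent's RT.

## Validation statistics

- Threshold value `T = B + 1.64·S_B` from 25 blank readings; cut-off
  factor `Fm = M − 1.64·SD` from 25 STC-spiked readings. Sample (n−1)
  standard deviations throughout (small-n sets; the divisor is otherwise
  unspecified), and 1.64 verbatim — not 1.645, not a t quantile.
- ccβ verdict: pass iff `Fm > T` strictly; ties fail. With Fm computed
  from the true normal parameters, the fraction of spiked samples below Fm
  is Φ(−1.64) ≈ 5.05% — the "less than 5%" reading of the same quantile;
  the simulation reproduces this at n = 10⁵ within ±0.5 points.
- Blank readings below the calibration range clamp to 0 before the blank
  statistics, so T ≥ B ≥ 0 regardless of whether an instrument would report
  noise or nothing.
- Precision: guide ceilings exactly as printed — 30% below 10 µg/kg, 25%
  from 10 to below 120 µg/kg — with the Horwitz function
  `CV = 2^(1 − 0.5·log₁₀C)` as a separate operation (it gives different
  numbers at those mass fractions; the printed guide values win inside
  their range). Boundaries: 10 µg/kg already takes 25% ("below 10"
  exclusive).
- Stability: reference intercept/slope ratio from the first curve meeting
  R² ≥ 0.999; each refit passes iff R² ≥ 0.999 and |Δ(y/x)|/|reference| ≤
  20% (inclusive).
- Ruggedness: two-sided Welch t-test (the unequal-variance form; a pooled
  option exists) at α = 0.05; a robust factor is *not* significant.
  Zero-variance equal groups define t = 0.

## The synthetic instrument

The generators are pure functions of (parameters, seed); per-run seeds
derive from the master seed through a splitting sequence, so studies and
batches reproduce bit-for-bit.

- **Response dispersion**: a spiked analyte's back-calculated
  concentration reading is normal with mean = nominal and SD = CV×nominal,
  truncated at 4 SD (keeps responses positive while staying symmetric, as
  the cut-off formulas presume). Per-analyte CVs default to the panel's
  reported within-lab values (2.7–18.5%).
- **Mass error**: zero-mean normal, SD 1.5 ppm, hard-truncated at ±5 ppm.
  **RT jitter**: zero-mean normal, SD 0.8% of expected RT, truncated at
  ±2.5%. Truncation at the tolerances means a true spike can never fail
  identification on tolerance grounds — deliberate, so identification
  failures in tests always indicate logic errors.
- **Blank interference**: Poisson count per analyte window (default 0.02
  per run), uniform RT inside the window, uniform mass error within
  ±5 ppm, exponential response (mean vial-equivalent 0.005 µg/L) — rare,
  low, unstructured, consistent with the observed absence of blank
  interference. No public blank-response distribution exists; these are
  modelling choices exposed in configuration, not claims about the
  instrument. Interference generated on top of a spike in the same window
  merges into the spike peak's response: co-eluting isobars are one
  chromatographic peak, not two.
- **Calibration**: per-compound ground-truth slopes (lognormal around
  5×10⁴ area·L/µg) and small positive intercepts, drawn once per
  instrument realisation and shared by every run in a study or batch;
  solvent standards carry 0.2% relative response noise, comfortably inside
  R² ≥ 0.999.
- **Species** labels (10 sheep + 10 cow + 5 goat per validation arm) are
  metadata only — the procedure treats the three milks identically — with
  an optional per-species response scale for ruggedness-style experiments.

What the generator does **not** model: chromatographic peak shapes,
matrix-effect suppression, carry-over, isotope patterns, or correlated
drift between runs. Passing tests therefore demonstrate the decision
logic, the statistics and their interplay under the stated dispersion
model — not robustness to structured matrix effects on real extracts.

## Problem sizes

Default study size is the validation plan itself (25 + 25 runs over the
full 57-compound panel). The CV-recovery analysis uses 200 seeded studies
of 25 spiked replicates; the false-negative quantile check uses 10⁵
replicate readings; the decision-statistic oracle check uses 1,000 random
vectors. These sizes give sampling error well below the tolerances they
are judged against (e.g. the mean of 200 study CVs has a relative standard
error of ~1%).

## Known limitations

- Screening semi-quantification has no measurement-uncertainty budget and
  no recovery correction; a suspect result is a trigger for confirmatory
  analysis, not a concentration claim.
- When `Fm ≤ T` the method reports failure and defers to new experiments;
  it does not re-estimate a numeric ccβ.
- Fragment matching uses a fixed ±0.05 Th window suited to one-decimal
  fragment tables; high-accuracy product-ion lists would warrant a ppm
  criterion.
- The dd-MS2 30 s acquisition window is not modelled as a gate on fragment
  availability.
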