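"""Screening-method validation statistics: detection capability, precision,
specificity, stability and ruggedness.

The screening decision level of each analyte is validated from 25 blank and
25 STC-fortified milk samples:

* threshold value  ``T  = B + 1.64 * S_B``  (blank mean + 1.64 SD),
* cut-off factor   ``Fm = M - 1.64 * SD``   (spiked mean - 1.64 SD).

``Fm > T`` is the acceptable outcome: at most ~5% of true STC-level samples
fall below the cut-off (the 1.64 quantile of a normal dispersion), so the
detection capability ccβ is at or below the screening target concentration.
``Fm <= T`` means the false-negative rate exceeds 5% and the analyte fails
at the STC.

Precision is judged against fixed guide ceilings — CV ≤ 30% for mass
fractions below 10 µg/kg, ≤ 25% from 10 up to 120 µg/kg — with the Horwitz
function CV = 2^(1 - 0.5 log10 C) available for higher mass fractions.
Stability of the standard solutions is monitored through the calibration
line (R² ≥ 0.999 and an intercept/slope ratio within ±20% of its reference),
and ruggedness through two-level factor experiments judged by a Welch
t-test at α = 0.05.

The sample (n-1) standard deviation is used throughout, and the 1.64
multiplier is applied verbatim (not 1.645, not a t quantile).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .compounds import Compound, CompoundDatabase, ConfigurationError
from .identify import match_rt, select_candidate
from .quantify import (
    CalibrationCurve,
    DilutionModel,
    fit_calibration,
    measure_concentration,
)

__all__ = [
    "Z_FACTOR",
    "BlankStats",
    "SpikeStats",
    "CcBetaVerdict",
    "StabilityRecord",
    "RuggednessResult",
    "ValidationReport",
    "threshold_value",
    "cutoff_factor",
    "assess_ccbeta",
    "cv_within_lab",
    "horwitz_cv",
    "max_allowed_cv",
    "specificity_check",
    "stability_assess",
    "ruggedness_ttest",
    "run_validation",
]

#: The 95th-percentile normal multiplier, as printed in the decision formulas.
Z_FACTOR = 1.64


def _mean_sd(readings: Sequence[float], what: str) -> tuple[float, float]:
    x = np.asarray(readings, dtype=float)
    if x.size < 2:
        raise ValueError(f"{what}: need at least 2 replicates, got {x.size}")
    return float(x.mean()), float(x.std(ddof=1))


@dataclass(frozen=True)
class BlankStats:
    """Blank-sample concentration readings for one analyte."""

    readings: tuple[float, ...]    # µg/kg
    mean: float
    sd: float

    @classmethod
    def from_readings(cls, readings: Sequence[float]) -> "BlankStats":
        mean, sd = _mean_sd(readings, "blank stats")
        return cls(tuple(float(x) for x in readings), mean, sd)


@dataclass(frozen=True)
class SpikeStats:
    """STC-fortified-sample concentration readings for one analyte."""

    readings: tuple[float, ...]    # µg/kg
    mean: float
    sd: float

    @classmethod
    def from_readings(cls, readings: Sequence[float]) -> "SpikeStats":
        mean, sd = _mean_sd(readings, "spike stats")
        return cls(tuple(float(x) for x in readings), mean, sd)

    @property
    def cv_pct(self) -> float:
        return cv_within_lab(self)


def threshold_value(blanks: BlankStats) -> float:
    """Threshold value T = B + 1.64 * S_B (µg/kg)."""
    return blanks.mean + Z_FACTOR * blanks.sd


def cutoff_factor(spikes: SpikeStats) -> float:
    """Cut-off factor Fm = M - 1.64 * SD (µg/kg).

    95% of samples truly at the STC read above Fm; a negative Fm (SD larger
    than M/1.64) is reported as-is with a warning.
    """
    fm = spikes.mean - Z_FACTOR * spikes.sd
    if fm < 0:
        warnings.warn(
            f"cut-off factor is negative ({fm:.3g}); spike dispersion exceeds "
            "the mean / 1.64", stacklevel=2,
        )
    return fm


def assess_ccbeta(t: float, fm: float, stc: float) -> tuple[bool, str]:
    """Judge detection capability at the STC from T and Fm.

    Returns ``(passed, message)``: pass (ccβ <= STC) iff Fm > T strictly;
    otherwise the false-negative rate exceeds 5% and new experiments are
    needed to establish the actual ccβ.
    """
    if not (math.isfinite(t) and math.isfinite(fm)):
        raise ValueError("T and Fm must be finite")
    if fm > t:
        return True, f"ccβ <= STC ({stc} µg/kg): Fm {fm:.3g} > T {t:.3g}"
    return False, (
        f"ccβ > STC ({stc} µg/kg): Fm {fm:.3g} <= T {t:.3g}; "
        "new experiments required to determine the actual ccβ"
    )


def cv_within_lab(spikes: SpikeStats) -> float:
    """Within-laboratory reproducibility CV (%) = 100 * SD / M."""
    if spikes.mean <= 0:
        raise ValueError("mean spiked concentration must be positive")
    return 100.0 * spikes.sd / spikes.mean


def horwitz_cv(mass_fraction: float) -> float:
    """Horwitz precision function CV(%) = 2^(1 - 0.5 * log10 C).

    ``mass_fraction`` is dimensionless (e.g. 100 µg/kg = 1e-7).
    """
    if mass_fraction <= 0:
        raise ValueError("mass fraction must be positive")
    return 2.0 ** (1.0 - 0.5 * math.log10(mass_fraction))


def max_allowed_cv(stc_ug_kg: float) -> float:
    """Maximum acceptable CV (%) at a given mass fraction.

    Fixed guide values: 30% below 10 µg/kg, 25% from 10 up to (excluding)
    120 µg/kg; the Horwitz function applies above that.
    """
    if stc_ug_kg <= 0:
        raise ValueError("STC must be positive")
    if stc_ug_kg < 10.0:
        return 30.0
    if stc_ug_kg < 120.0:
        return 25.0
    return horwitz_cv(stc_ug_kg * 1e-9)


@dataclass
class CcBetaVerdict:
    """Full per-analyte validation outcome."""

    analyte: str
    threshold: float           # T, µg/kg
    cutoff: float              # Fm, µg/kg
    stc: float                 # µg/kg
    passed: bool               # ccβ <= STC
    message: str
    cv_r_pct: float            # within-lab reproducibility CV (%)
    cv_limit_pct: float        # guide ceiling (%)
    precision_ok: bool


@dataclass
class ValidationReport:
    """Study-level validation report."""

    verdicts: list[CcBetaVerdict]
    n_blank: int
    n_spiked: int
    seed: int | None = None

    def __iter__(self):
        return iter(self.verdicts)

    def __getitem__(self, analyte: str) -> CcBetaVerdict:
        for v in self.verdicts:
            if v.analyte == analyte:
                return v
        raise KeyError(analyte)

    @property
    def all_pass(self) -> bool:
        return all(v.passed for v in self.verdicts)

    @property
    def all_precision_ok(self) -> bool:
        return all(v.precision_ok for v in self.verdicts)


def specificity_check(
    blank_runs: Iterable,
    db: CompoundDatabase,
    ppm_tol: float | None = None,
    rt_tol_frac: float | None = None,
) -> dict[str, int]:
    """Count blank runs with an interfering feature per analyte window.

    An interference is any feature inside the analyte's precursor m/z window
    that also elutes within the RT tolerance.  Specificity passes for an
    analyte when its count is 0 over all blanks.
    """
    runs = list(blank_runs)
    if not runs:
        raise ValueError("need at least 1 blank run")
    ppm_tol = db.ppm_tolerance if ppm_tol is None else ppm_tol
    rt_tol_frac = db.rt_tolerance_frac if rt_tol_frac is None else rt_tol_frac
    counts = {c.name: 0 for c in db}
    for run in runs:
        features = list(getattr(run, "features", run))
        for c in db:
            cand = select_candidate(features, c, ppm_tol)
            if cand is None:
                continue
            rt_ok, _ = match_rt(cand.rt_min, c.expected_rt, rt_tol_frac)
            if rt_ok:
                counts[c.name] += 1
    return counts


@dataclass
class StabilityRecord:
    """Stability of standard solutions tracked through calibration refits."""

    reference_yx: float
    yx_ratios: list[float]
    yx_rel_change: list[float]      # |Δ(y/x)| / |reference|
    r2: list[float]
    linearity_ok: list[bool]        # R² >= r2_min
    yx_ok: list[bool]               # relative change <= tolerance
    passed: list[bool]

    @property
    def all_pass(self) -> bool:
        return all(self.passed)


def stability_assess(
    curves: Sequence[CalibrationCurve],
    r2_min: float = 0.999,
    yx_tol: float = 0.20,
) -> StabilityRecord:
    """Assess a time-ordered series of calibration fits.

    The intercept/slope ratio of the first curve meeting the linearity
    criterion is the reference; each fit passes iff R² >= ``r2_min`` and its
    ratio stays within ``yx_tol`` (relative) of the reference.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("need at least 1 calibration curve")
    reference = next((c for c in curves if c.r2 >= r2_min), curves[0])
    ref_yx = reference.yx_ratio
    yx, rel, r2s, lin_ok, yx_ok, passed = [], [], [], [], [], []
    for c in curves:
        ratio = c.yx_ratio
        if ref_yx == 0.0:
            change = 0.0 if ratio == 0.0 else math.inf
        else:
            change = abs(ratio - ref_yx) / abs(ref_yx)
        ok_lin = c.r2 >= r2_min
        ok_yx = change <= yx_tol
        yx.append(ratio)
        rel.append(change)
        r2s.append(c.r2)
        lin_ok.append(ok_lin)
        yx_ok.append(ok_yx)
        passed.append(ok_lin and ok_yx)
    return StabilityRecord(ref_yx, yx, rel, r2s, lin_ok, yx_ok, passed)


@dataclass
class RuggednessResult:
    """Two-level factor experiment judged by a t-test."""

    factor: str
    t_stat: float
    p_value: float
    significant: bool
    alpha: float


def ruggedness_ttest(
    level_f: Sequence[float],
    level_F: Sequence[float],
    alpha: float = 0.05,
    factor: str = "",
    welch: bool = True,
) -> RuggednessResult:
    """Compare the two levels of a ruggedness factor with a two-sided t-test.

    Welch's unequal-variance form by default (``welch=False`` pools).  A
    robust factor is *not* significant: p >= alpha.  Two degenerate
    (zero-variance) groups yield t = 0 when their means agree.
    """
    a = np.asarray(level_f, dtype=float)
    b = np.asarray(level_F, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each factor level needs at least 2 readings")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if min(a.size, b.size) < 3:
            warnings.warn("degenerate zero-variance groups", stacklevel=2)
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math.inf if a.mean() > b.mean() else -math.inf
            p = 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    return RuggednessResult(factor, t, p, p < alpha, alpha)


def run_validation(
    study,
    db: CompoundDatabase,
    curves: Mapping[str, CalibrationCurve] | None = None,
    dilution: DilutionModel = DilutionModel(),
    ppm_tol: float | None = None,
    rt_tol_frac: float | None = None,
) -> ValidationReport:
    """Run the full detection-capability evaluation on a validation study.

    For each analyte, back-calculates the concentration reading of every
    blank and spiked run (0 when no feature matches the m/z x RT window),
    forms the blank/spike statistics, and issues the ccβ and precision
    verdicts.  ``curves`` defaults to fits of the study's own calibration
    series.
    """
    if len(study.blank_runs) < 2 or len(study.spiked_runs) < 2:
        raise ValueError("study needs >= 2 blank and >= 2 spiked runs")
    if curves is None:
        curves = {
            name: fit_calibration(levels, responses, compound=name, tag="study")
            for name, (levels, responses) in study.calibration.tables().items()
        }
    ppm_tol = db.ppm_tolerance if ppm_tol is None else ppm_tol
    rt_tol_frac = db.rt_tolerance_frac if rt_tol_frac is None else rt_tol_frac

    verdicts = []
    for c in db:
        curve = curves.get(c.name)
        if curve is None:
            raise ConfigurationError(f"no calibration curve for {c.name!r}")
        blank_readings = [
            measure_concentration(r.features, c, curve, dilution, ppm_tol,
                                  rt_tol_frac)
            for r in study.blank_runs
        ]
        spike_readings = [
            measure_concentration(r.features, c, curve, dilution, ppm_tol,
                                  rt_tol_frac)
            for r in study.spiked_runs
        ]
        blanks = BlankStats.from_readings(blank_readings)
        spikes = SpikeStats.from_readings(spike_readings)
        t = threshold_value(blanks)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fm = cutoff_factor(spikes)
        passed, message = assess_ccbeta(t, fm, c.stc)
        if spikes.mean > 0:
            cv = cv_within_lab(spikes)
        else:
            cv = float("nan")
        limit = max_allowed_cv(c.stc)
        precision_ok = bool(cv <= limit) if math.isfinite(cv) else False
        verdicts.append(
            CcBetaVerdict(
                analyte=c.name,
                threshold=t,
                cutoff=fm,
                stc=c.stc,
                passed=passed,
                message=message,
                cv_r_pct=cv,
                cv_limit_pct=limit,
                precision_ok=precision_ok,
            )
        )
    return ValidationReport(
        verdicts,
        n_blank=len(study.blank_runs),
        n_spiked=len(study.spiked_runs),
        seed=getattr(study, "seed", None),
    )
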