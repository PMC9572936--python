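"""Calibration fitting, back-calculation and cut-off screening decisions.

Semi-quantification runs a solvent calibration line (five standard levels,
0.1–10 µg/L) per compound, back-calculates the vial concentration of a
matched feature from its integrated response, and converts to the sample
concentration through the fixed dilution model of the extraction: 1.0 g of
milk extracted into 4.1 mL (4.0 mL acidified acetonitrile + 0.1 mL EDTA),
of which a 1:10-diluted aliquot is injected, i.e. sample µg/kg =
vial µg/L × 4.1 × 10.  That mapping deliberately lands the screening target
concentrations inside the calibration range (4 µg/kg -> 0.098 µg/L,
75 µg/kg -> 1.83 µg/L).

A sample screens *suspect* for an analyte when the analyte is identified and
its back-calculated sample concentration strictly exceeds the validated
cut-off Fm; otherwise it is *compliant*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .compounds import (
    Compound,
    CompoundDatabase,
    ConfigurationError,
    INTERNAL_STANDARDS,
)
from .identify import (
    FeatureObservation,
    IdentificationResult,
    identify,
    match_precursor,
    match_rt,
    select_candidate,
)
from .masses import ppm_error

__all__ = [
    "CalibrationCurve",
    "DilutionModel",
    "ScreeningDecision",
    "BatchQCReport",
    "fit_calibration",
    "back_calculate",
    "measure_concentration",
    "screen_sample",
    "qc_batch",
]

#: Linearity acceptance for a usable calibration curve.
R2_MIN_DEFAULT = 0.999


@dataclass(frozen=True)
class CalibrationCurve:
    """Unweighted least-squares line response = slope * level + intercept."""

    compound: str
    levels: tuple[float, ...]       # µg/L
    responses: tuple[float, ...]    # area units
    slope: float
    intercept: float
    r2: float
    tag: str = ""

    def __post_init__(self) -> None:
        if len(self.levels) < 2 or len(set(self.levels)) < 2:
            raise ValueError("calibration needs >= 2 distinct levels")
        if not np.isfinite(self.slope):
            raise ValueError("non-finite slope")

    @property
    def yx_ratio(self) -> float:
        """Intercept/slope ratio (µg/L), the stability monitoring statistic."""
        if self.slope == 0:
            raise ZeroDivisionError(f"{self.compound}: zero calibration slope")
        return self.intercept / self.slope

    @property
    def usable(self) -> bool:
        return self.r2 >= R2_MIN_DEFAULT


@dataclass(frozen=True)
class DilutionModel:
    """Fixed sample-preparation dilution: milk mass -> injected vial."""

    sample_mass_g: float = 1.0
    extract_volume_ml: float = 4.1
    aliquot_dilution: float = 10.0

    def __post_init__(self) -> None:
        if min(self.sample_mass_g, self.extract_volume_ml, self.aliquot_dilution) <= 0:
            raise ValueError("all dilution-model fields must be positive")

    @property
    def factor(self) -> float:
        """Multiply a vial µg/L by this to get the sample µg/kg."""
        return self.extract_volume_ml / self.sample_mass_g * self.aliquot_dilution

    def sample_to_vial(self, sample_ug_kg: float) -> float:
        return sample_ug_kg / self.factor

    def vial_to_sample(self, vial_ug_l: float) -> float:
        return vial_ug_l * self.factor


@dataclass
class ScreeningDecision:
    """Per-compound screening verdict for one sample run."""

    compound: str
    identification: IdentificationResult
    vial_ug_l: float
    sample_ug_kg: float
    cutoff_ug_kg: float | None
    verdict: str  # "compliant" | "suspect"


@dataclass
class InternalStandardCheck:
    name: str
    present: bool
    rt_rel_dev: float
    ppm: float


@dataclass
class BatchQCReport:
    """Batch quality-control outcome: controls and internal standards."""

    negative_control_ok: bool
    positive_control_ok: bool
    internal_standards: list[InternalStandardCheck]
    failures: list[str]

    @property
    def internal_standards_ok(self) -> bool:
        return all(c.present for c in self.internal_standards)

    @property
    def batch_pass(self) -> bool:
        return (
            self.negative_control_ok
            and self.positive_control_ok
            and self.internal_standards_ok
        )


def fit_calibration(
    levels: Sequence[float],
    responses: Sequence[float],
    compound: str = "",
    tag: str = "",
) -> CalibrationCurve:
    """Fit an unweighted ordinary-least-squares calibration line.

    Raises
    ------
    ValueError
        On unequal lengths, fewer than 2 points, or all-identical levels
        (degenerate design).
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("levels and responses must be equal-length, size >= 2")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all calibration levels identical")
    fit = stats.linregress(x, y)
    # rvalue**2 is ill-defined for exactly-constant y; treat as perfect fit
    r2 = 1.0 if np.allclose(y, fit.intercept + fit.slope * x) else fit.rvalue**2
    return CalibrationCurve(
        compound=compound,
        levels=tuple(x),
        responses=tuple(y),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(r2),
        tag=tag,
    )


def back_calculate(
    curve: CalibrationCurve,
    response: float,
    dilution: DilutionModel = DilutionModel(),
) -> float:
    """Back-calculate a sample concentration (µg/kg) from a response.

    Vial concentration (response - intercept)/slope is clamped at 0 before
    the dilution factor is applied, so sub-calibration noise never yields a
    negative concentration.
    """
    if curve.slope == 0:
        raise ZeroDivisionError(f"{curve.compound}: zero calibration slope")
    vial = (response - curve.intercept) / curve.slope
    return dilution.vial_to_sample(max(vial, 0.0))


def measure_concentration(
    features: Iterable[FeatureObservation],
    compound: Compound,
    curve: CalibrationCurve,
    dilution: DilutionModel = DilutionModel(),
    ppm_tol: float = 5.0,
    rt_tol_frac: float = 0.025,
) -> float:
    """Measured sample concentration (µg/kg) in the compound's m/z x RT window.

    Quantification only requires a precursor + RT match (fragments confirm
    identity, they do not carry the response); no matching feature reads 0.
    """
    candidate = select_candidate(features, compound, ppm_tol, rt_tol_frac)
    if candidate is None:
        return 0.0
    rt_ok, _ = match_rt(candidate.rt_min, compound.expected_rt, rt_tol_frac)
    if not rt_ok:
        return 0.0
    return back_calculate(curve, candidate.response, dilution)


def screen_sample(
    run,
    db: CompoundDatabase,
    curves: Mapping[str, CalibrationCurve],
    cutoffs: Mapping[str, float],
    dilution: DilutionModel = DilutionModel(),
    ppm_tol: float | None = None,
    rt_tol_frac: float | None = None,
) -> list[ScreeningDecision]:
    """Screen one sample run against the whole panel.

    Every *identified* compound must have a calibration curve and a cut-off;
    a missing one raises :class:`ConfigurationError` naming the compound.
    """
    ppm_tol = db.ppm_tolerance if ppm_tol is None else ppm_tol
    rt_tol_frac = db.rt_tolerance_frac if rt_tol_frac is None else rt_tol_frac
    results = identify(run, db, ppm_tol, rt_tol_frac)
    decisions = []
    for compound in db:
        ident = results[compound.name]
        vial = 0.0
        conc = 0.0
        cutoff = cutoffs.get(compound.name)
        if ident.identified:
            curve = curves.get(compound.name)
            if curve is None:
                raise ConfigurationError(
                    f"no calibration curve for identified compound {compound.name!r}"
                )
            if cutoff is None:
                raise ConfigurationError(
                    f"no cut-off configured for identified compound {compound.name!r}"
                )
            conc = back_calculate(curve, ident.feature.response, dilution)
            vial = dilution.sample_to_vial(conc)
        suspect = ident.identified and cutoff is not None and conc > cutoff
        decisions.append(
            ScreeningDecision(
                compound=compound.name,
                identification=ident,
                vial_ug_l=vial,
                sample_ug_kg=conc,
                cutoff_ug_kg=cutoff,
                verdict="suspect" if suspect else "compliant",
            )
        )
    return decisions


def check_internal_standards(
    features: Iterable[FeatureObservation],
    ppm_tol: float = 5.0,
    rt_tol_frac: float = 0.025,
) -> list[InternalStandardCheck]:
    """Verify the four labelled internal standards in a run's features."""
    feats = list(features)
    checks = []
    for std in INTERNAL_STANDARDS:
        best = None
        for f in feats:
            err = ppm_error(f.mz, std.mz)
            if abs(err) <= ppm_tol:
                dev = abs(f.rt_min - std.expected_rt) / std.expected_rt
                if best is None or dev < best[1]:
                    best = (err, dev)
        if best is None:
            checks.append(InternalStandardCheck(std.name, False, float("nan"),
                                                float("nan")))
        else:
            err, dev = best
            checks.append(
                InternalStandardCheck(std.name, dev <= rt_tol_frac, dev, err)
            )
    return checks


def qc_batch(
    batch,
    db: CompoundDatabase,
    curves: Mapping[str, CalibrationCurve] | None = None,
    cutoffs: Mapping[str, float] | None = None,
    dilution: DilutionModel = DilutionModel(),
) -> BatchQCReport:
    """Evaluate the quality controls of an analytical batch.

    The batch passes iff the negative control screens compliant for every
    analyte, the screen-positive control (spiked at STC) screens suspect for
    every analyte with a configured cut-off, and all four internal standards
    are present within the RT tolerance in both control runs.

    ``batch`` must expose ``calibration`` (used to fit curves when none are
    given) and ``control_run(role)`` for roles ``negative_control`` /
    ``positive_control``.
    """
    negative = batch.control_run("negative_control")
    positive = batch.control_run("positive_control")
    if negative is None or positive is None:
        raise ValueError("batch is missing a negative or positive control run")
    if curves is None:
        curves = {
            name: fit_calibration(levels, responses, compound=name, tag="batch")
            for name, (levels, responses) in batch.calibration.tables().items()
        }
    if cutoffs is None:
        # default screen against the STC itself scaled by nothing: the control
        # checks only need *some* cut-off below the spike; use half the STC.
        cutoffs = {c.name: 0.5 * c.stc for c in db}

    failures: list[str] = []
    neg = screen_sample(negative, db, curves, cutoffs, dilution)
    neg_ok = all(d.verdict == "compliant" for d in neg)
    if not neg_ok:
        bad = [d.compound for d in neg if d.verdict != "compliant"]
        failures.append(f"negative control not compliant for: {', '.join(bad)}")

    pos = screen_sample(positive, db, curves, cutoffs, dilution)
    pos_ok = all(
        d.verdict == "suspect" for d in pos if d.cutoff_ug_kg is not None
    )
    if not pos_ok:
        bad = [
            d.compound
            for d in pos
            if d.cutoff_ug_kg is not None and d.verdict != "suspect"
        ]
        failures.append(f"positive control not suspect for: {', '.join(bad)}")

    # check each control run separately; a standard must pass in both
    per_run = [
        check_internal_standards(r.features, db.ppm_tolerance, db.rt_tolerance_frac)
        for r in (negative, positive)
    ]
    is_checks = []
    for chk_neg, chk_pos in zip(*per_run):
        worst = max(chk_neg.rt_rel_dev, chk_pos.rt_rel_dev)
        is_checks.append(
            InternalStandardCheck(
                chk_neg.name,
                chk_neg.present and chk_pos.present,
                worst,
                chk_neg.ppm,
            )
        )
    for chk in is_checks:
        if not chk.present:
            failures.append(
                f"internal standard {chk.name} missing or RT-drifted "
                f"(rel. dev {chk.rt_rel_dev:.3f})"
            )
    return BatchQCReport(neg_ok, pos_ok, is_checks, failures)
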