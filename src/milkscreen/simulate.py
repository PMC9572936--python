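"""Synthetic instrument data with the statistical structure the method assumes.

No public raw data accompany the screening method, so every downstream stage
is exercised on generated feature tables that emulate what the full-scan
acquisition delivers after peak picking:

* *Blank milk*: no feature in any target m/z x RT window except rare,
  low-response false features (Poisson count per analyte window, uniform RT
  inside the window, exponential response), plus the four internal standards
  which are always present.
* *Spiked milk*: per spiked analyte one feature whose m/z carries a
  truncated-normal mass error (SD 1.5 ppm, hard-bounded at the 5 ppm
  tolerance), whose RT carries a truncated-normal jitter (SD 0.8%, bounded
  at 2.5%), and whose response is consistent with the calibration line at a
  back-calculated concentration dispersed with the analyte's within-lab CV
  (normal, truncated at 4 SD so responses stay positive).  Both diagnostic
  fragments are present.
* *Calibration series*: five solvent standards (0.1–10 µg/L) per analyte
  with a small relative response noise, from per-compound ground-truth
  slopes/intercepts drawn once per instrument realisation.
* *Validation studies* and *batches* compose the above in the layout the
  method prescribes (25 blanks + 25 STC spikes; calibration, solvent blanks,
  negative and screen-positive controls, unknowns).

Every generator is a pure function of (parameters, seed): the same seed
reproduces the same features bit-for-bit.  Species labels (bovine / ovine /
goat) are metadata only — the procedure is applied identically to all three
milks — unless a per-species response scale is set for ruggedness-style
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .compounds import Compound, CompoundDatabase, ConfigurationError, INTERNAL_STANDARDS
from .identify import FeatureObservation
from .quantify import DilutionModel

__all__ = [
    "NoiseModel",
    "InstrumentModel",
    "SyntheticRun",
    "CalibrationSeries",
    "ValidationStudy",
    "Batch",
    "BatchEntry",
    "gen_blank_run",
    "gen_spiked_run",
    "gen_validation_study",
    "gen_calibration_series",
    "gen_batch",
    "draw_concentration_readings",
]

_SPECIES = ("bovine", "ovine", "goat")


@dataclass(frozen=True)
class NoiseModel:
    """Dispersion parameters of the synthetic instrument.

    Defaults encode the study conditions: mass errors and RT jitter are
    truncated at the instrumental tolerances (5 ppm, 2.5%) so a true spike
    can never fail identification on tolerance grounds, and per-analyte
    response CVs default to the panel's reported within-lab values (the
    ``default_cv`` applies only to compounds without one).
    """

    mass_error_sd_ppm: float = 1.5
    mass_error_max_ppm: float = 5.0
    rt_jitter_sd_frac: float = 0.008
    rt_jitter_max_frac: float = 0.025
    default_cv: float = 0.05
    blank_false_rate: float = 0.02     # expected false features/run/analyte window
    blank_vial_scale_ug_l: float = 0.005   # mean vial-equivalent of a false feature
    calibration_cv: float = 0.002      # relative response noise of solvent standards
    trunc_sd: float = 4.0              # response-noise truncation, in SDs
    species_response_scale: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "mass_error_sd_ppm", "mass_error_max_ppm", "rt_jitter_sd_frac",
            "rt_jitter_max_frac", "default_cv", "blank_false_rate",
            "blank_vial_scale_ug_l", "calibration_cv", "trunc_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def cv_for(self, compound: Compound) -> float:
        return compound.cv_r if compound.cv_r is not None else self.default_cv

    def scale_for(self, species: str) -> float:
        return float(self.species_response_scale.get(species, 1.0))


@dataclass(frozen=True)
class InstrumentModel:
    """Per-compound ground-truth response lines of one instrument realisation."""

    slopes: Mapping[str, float]        # area units per µg/L
    intercepts: Mapping[str, float]    # area units
    is_response: float = 5.0e4         # internal-standard area

    @classmethod
    def from_seed(cls, db: CompoundDatabase, seed) -> "InstrumentModel":
        """Draw one instrument: slopes lognormal around 5e4 area/(µg/L),
        intercepts a small positive offset (< ~0.2% of the top level)."""
        rng = np.random.default_rng(seed)
        slopes, intercepts = {}, {}
        for c in db:
            slope = 5.0e4 * math.exp(rng.normal(0.0, 0.3))
            slopes[c.name] = slope
            intercepts[c.name] = rng.uniform(0.0, 0.002) * slope
        return cls(slopes=slopes, intercepts=intercepts)

    def response(self, name: str, vial_ug_l: float) -> float:
        return self.slopes[name] * vial_ug_l + self.intercepts[name]


@dataclass
class SyntheticRun:
    """One generated injection: features plus the ground truth behind them."""

    run_id: str
    species: str
    true_conc: dict[str, float]        # µg/kg in-sample, per spiked compound
    features: list[FeatureObservation]
    seed: int
    role: str = "sample"               # sample | solvent_blank | *_control | unknown


@dataclass
class CalibrationSeries:
    """Generated solvent calibration responses with their ground truth."""

    levels: tuple[float, ...]                      # µg/L
    responses: dict[str, tuple[float, ...]]        # per compound
    true_slopes: dict[str, float]
    true_intercepts: dict[str, float]
    seed: int

    def tables(self) -> dict[str, tuple[tuple[float, ...], tuple[float, ...]]]:
        return {name: (self.levels, resp) for name, resp in self.responses.items()}


@dataclass
class ValidationStudy:
    """Paired blank / STC-spiked replicate sets plus a calibration series."""

    blank_runs: list[SyntheticRun]
    spiked_runs: list[SyntheticRun]
    spike_levels: dict[str, float]     # µg/kg
    calibration: CalibrationSeries
    instrument: InstrumentModel
    seed: int


@dataclass
class BatchEntry:
    role: str
    run: SyntheticRun


@dataclass
class Batch:
    """Ordered analytical batch: calibration, controls and unknowns with
    solvent blanks interleaved before/after the curve, between the controls
    and the unknowns, and at the end of the sequence."""

    calibration: CalibrationSeries
    entries: list[BatchEntry]
    instrument: InstrumentModel
    seed: int

    def control_run(self, role: str) -> SyntheticRun | None:
        for e in self.entries:
            if e.role == role:
                return e.run
        return None

    def unknowns(self) -> list[SyntheticRun]:
        return [e.run for e in self.entries if e.role == "unknown"]


def _child_seeds(seed, n: int) -> list[int]:
    """Deterministic per-run integer seeds derived from a master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def _trunc_normal(rng: np.random.Generator, sd: float, bound: float,
                  size: int | None = None):
    """Zero-mean normal draw truncated at +/- bound (hard instrument limits)."""
    if sd == 0:
        return 0.0 if size is None else np.zeros(size)
    a, b = -bound / sd, bound / sd
    return stats.truncnorm.rvs(a, b, scale=sd, size=size, random_state=rng)


def draw_concentration_readings(
    rng: np.random.Generator,
    nominal: float,
    cv: float,
    n: int,
    trunc_sd: float = 4.0,
) -> np.ndarray:
    """Back-calculated concentration readings for replicate STC spikes.

    Normal with mean = nominal and SD = cv * nominal, truncated at
    ``trunc_sd`` standard deviations (keeps responses positive while staying
    symmetric, as the cut-off statistics presume).
    """
    if nominal < 0:
        raise ValueError("nominal concentration must be >= 0")
    if nominal == 0 or cv == 0:
        return np.full(n, float(nominal))
    eps = _trunc_normal(rng, cv, trunc_sd * cv, size=n)
    return nominal * (1.0 + np.asarray(eps))


def _is_features(rng: np.random.Generator, noise: NoiseModel,
                 instrument: InstrumentModel, run_id: str) -> list[FeatureObservation]:
    feats = []
    for std in INTERNAL_STANDARDS:
        dppm = float(_trunc_normal(rng, noise.mass_error_sd_ppm,
                                   noise.mass_error_max_ppm))
        drt = float(_trunc_normal(rng, noise.rt_jitter_sd_frac,
                                  noise.rt_jitter_max_frac))
        feats.append(
            FeatureObservation(
                mz=std.mz * (1.0 + dppm * 1e-6),
                rt_min=std.expected_rt * (1.0 + drt),
                response=instrument.is_response,
                run_id=run_id,
            )
        )
    return feats


def _false_features(rng: np.random.Generator, db: CompoundDatabase,
                    noise: NoiseModel, instrument: InstrumentModel,
                    run_id: str) -> list[tuple[str, FeatureObservation]]:
    """Rare unstructured interference, tagged with the analyte window it hit."""
    feats = []
    for c in db:
        for _ in range(rng.poisson(noise.blank_false_rate)):
            mz = c.precursor_mz * (
                1.0 + rng.uniform(-noise.mass_error_max_ppm,
                                  noise.mass_error_max_ppm) * 1e-6
            )
            rt = c.expected_rt * (
                1.0 + rng.uniform(-noise.rt_jitter_max_frac,
                                  noise.rt_jitter_max_frac)
            )
            vial = rng.exponential(noise.blank_vial_scale_ug_l)
            feats.append(
                (
                    c.name,
                    FeatureObservation(
                        mz=mz,
                        rt_min=rt,
                        response=instrument.response(c.name, vial),
                        run_id=run_id,
                    ),
                )
            )
    return feats


def gen_blank_run(
    db: CompoundDatabase,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    species: str = "bovine",
    run_id: str | None = None,
    instrument: InstrumentModel | None = None,
) -> SyntheticRun:
    """Generate one blank-milk injection (internal standards + rare noise)."""
    if instrument is None:
        instrument = InstrumentModel.from_seed(db, _child_seeds(seed, 2)[1])
    rng = np.random.default_rng(seed)
    run_id = run_id or f"blank-{seed}"
    features = _is_features(rng, noise, instrument, run_id)
    features += [f for _, f in _false_features(rng, db, noise, instrument, run_id)]
    return SyntheticRun(run_id, species, {}, features, int(seed), role="sample")


def gen_spiked_run(
    db: CompoundDatabase,
    level: Mapping[str, float],
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    species: str = "bovine",
    run_id: str | None = None,
    instrument: InstrumentModel | None = None,
    dilution: DilutionModel = DilutionModel(),
) -> SyntheticRun:
    """Generate one fortified-milk injection at the given per-analyte levels.

    For every compound with a positive level, one feature is emitted whose
    response corresponds (through the dilution model and the instrument's
    response line) to a concentration reading dispersed with that analyte's
    within-lab CV; both diagnostic fragments are attached.
    """
    for name, conc in level.items():
        if name not in db:
            raise ConfigurationError(f"spiked compound {name!r} not in database")
        if conc < 0:
            raise ValueError(f"{name}: spike level must be >= 0")
    if instrument is None:
        instrument = InstrumentModel.from_seed(db, _child_seeds(seed, 2)[1])
    rng = np.random.default_rng(seed)
    run_id = run_id or f"spiked-{seed}"
    features = _is_features(rng, noise, instrument, run_id)
    false_feats = _false_features(rng, db, noise, instrument, run_id)
    true_conc: dict[str, float] = {}
    scale = noise.scale_for(species)
    merged: set[int] = set()
    for c in db:
        nominal = float(level.get(c.name, 0.0))
        if nominal <= 0:
            continue
        true_conc[c.name] = nominal
        reading = float(
            draw_concentration_readings(rng, nominal, noise.cv_for(c), 1,
                                        noise.trunc_sd)[0]
        )
        vial = dilution.sample_to_vial(reading) * scale
        dppm = float(_trunc_normal(rng, noise.mass_error_sd_ppm,
                                   noise.mass_error_max_ppm))
        drt = float(_trunc_normal(rng, noise.rt_jitter_sd_frac,
                                  noise.rt_jitter_max_frac))
        rt = c.expected_rt * (1.0 + drt)
        response = instrument.response(c.name, vial)
        # a co-eluting interference in the same m/z x RT window merges into
        # the analyte's chromatographic peak rather than appearing twice
        for i, (name, f) in enumerate(false_feats):
            if (
                i not in merged
                and name == c.name
                and abs(f.rt_min - rt) / c.expected_rt <= noise.rt_jitter_max_frac
            ):
                response += f.response - instrument.intercepts[c.name]
                merged.add(i)
        features.append(
            FeatureObservation(
                mz=c.precursor_mz * (1.0 + dppm * 1e-6),
                rt_min=rt,
                response=response,
                fragment_mzs=c.fragment_mzs,
                run_id=run_id,
            )
        )
    features += [f for i, (_, f) in enumerate(false_feats) if i not in merged]
    return SyntheticRun(run_id, species, true_conc, features, int(seed),
                        role="sample")


def gen_calibration_series(
    db: CompoundDatabase,
    levels: Sequence[float] = (0.1, 0.5, 1.0, 5.0, 10.0),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    instrument: InstrumentModel | None = None,
) -> CalibrationSeries:
    """Generate the five-level solvent calibration series for every compound."""
    if len(set(levels)) < 2:
        raise ValueError("need >= 2 distinct calibration levels")
    if instrument is None:
        instrument = InstrumentModel.from_seed(db, _child_seeds(seed, 2)[1])
    rng = np.random.default_rng(seed)
    lv = tuple(float(x) for x in levels)
    responses = {}
    for c in db:
        eps = _trunc_normal(rng, noise.calibration_cv,
                            noise.trunc_sd * noise.calibration_cv
                            if noise.calibration_cv else 0.0,
                            size=len(lv))
        eps = np.atleast_1d(np.asarray(eps, dtype=float))
        resp = tuple(
            instrument.response(c.name, x) * (1.0 + e) for x, e in zip(lv, eps)
        )
        responses[c.name] = resp
    return CalibrationSeries(
        levels=lv,
        responses=responses,
        true_slopes=dict(instrument.slopes),
        true_intercepts=dict(instrument.intercepts),
        seed=int(seed),
    )


def gen_validation_study(
    db: CompoundDatabase,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    n_sheep: int = 10,
    n_cow: int = 10,
    n_goat: int = 5,
    spike_levels: Mapping[str, float] | None = None,
    dilution: DilutionModel = DilutionModel(),
) -> ValidationStudy:
    """Generate the paired blank + STC-spiked validation sample sets.

    Defaults follow the validation plan: 10 sheep + 10 cow + 5 goat samples,
    each analysed blank and fortified at the screening target concentration,
    all on one instrument realisation with one calibration series.
    """
    if n_sheep + n_cow + n_goat < 2:
        raise ValueError("need at least 2 validation samples")
    spike_levels = dict(spike_levels) if spike_levels is not None else db.stc_table()
    species = ["ovine"] * n_sheep + ["bovine"] * n_cow + ["goat"] * n_goat
    n = len(species)
    seeds = _child_seeds(seed, 2 * n + 2)
    instrument = InstrumentModel.from_seed(db, seeds[0])
    calibration = gen_calibration_series(db, noise=noise, seed=seeds[1],
                                         instrument=instrument)
    blanks = [
        gen_blank_run(db, noise, seeds[2 + i], sp, f"blank-{i:02d}", instrument)
        for i, sp in enumerate(species)
    ]
    spiked = [
        gen_spiked_run(db, spike_levels, noise, seeds[2 + n + i], sp,
                       f"spiked-{i:02d}", instrument, dilution)
        for i, sp in enumerate(species)
    ]
    return ValidationStudy(blanks, spiked, spike_levels, calibration,
                           instrument, int(seed))


def gen_batch(
    db: CompoundDatabase,
    n_unknowns: int = 0,
    contamination: Sequence[Mapping[str, float]] | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    dilution: DilutionModel = DilutionModel(),
) -> Batch:
    """Generate a full analytical batch in the prescribed injection order.

    Sequence: solvent blank, calibration series, solvent blank, negative
    control (blank milk), screen-positive control (STC-spiked milk), solvent
    blank, unknowns, solvent blank.  ``contamination[i]`` gives unknown i's
    true residue levels (µg/kg); missing entries mean a clean unknown.
    """
    if n_unknowns < 0:
        raise ValueError("n_unknowns must be >= 0")
    contamination = list(contamination or [])
    seeds = _child_seeds(seed, n_unknowns + 4)
    instrument = InstrumentModel.from_seed(db, seeds[0])
    calibration = gen_calibration_series(db, noise=noise, seed=seeds[1],
                                         instrument=instrument)
    stc = db.stc_table()

    def solvent(run_id: str) -> SyntheticRun:
        return SyntheticRun(run_id, "solvent", {}, [], int(seed),
                            role="solvent_blank")

    negative = gen_blank_run(db, noise, seeds[2], "bovine", "negative-control",
                             instrument)
    negative.role = "negative_control"
    positive = gen_spiked_run(db, stc, noise, seeds[3], "bovine",
                              "positive-control", instrument, dilution)
    positive.role = "positive_control"

    entries = [BatchEntry("solvent_blank", solvent("solvent-00"))]
    entries.append(BatchEntry("calibration", SyntheticRun(
        "calibration", "solvent", {}, [], int(seed), role="calibration")))
    entries.append(BatchEntry("solvent_blank", solvent("solvent-01")))
    entries.append(BatchEntry("negative_control", negative))
    entries.append(BatchEntry("positive_control", positive))
    entries.append(BatchEntry("solvent_blank", solvent("solvent-02")))
    for i in range(n_unknowns):
        levels = dict(contamination[i]) if i < len(contamination) else {}
        run = gen_spiked_run(db, levels, noise, seeds[4 + i], "bovine",
                             f"unknown-{i:02d}", instrument, dilution)
        run.role = "unknown"
        entries.append(BatchEntry("unknown", run))
    entries.append(BatchEntry("solvent_blank", solvent("solvent-03")))
    return Batch(calibration, entries, instrument, int(seed))
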