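"""Feature-to-compound matching and identification-point scoring.

A target compound is identified in a run when a detected chromatographic
feature matches its theoretical precursor m/z within the instrumental mass
accuracy (<=5 ppm), elutes within the retention-time tolerance (<=2.5%
relative), and carries enough diagnostic product ions.  Each piece of
evidence earns identification points — 1.0 for the chromatographic
separation, 1.5 for the high-resolution precursor, 2.5 per high-resolution
product ion — and identity is confirmed when the tally reaches 4 points for
authorized (MRL-bearing) substances or 5 points for unauthorized ones.

All tolerance comparisons are inclusive (<=), matching the regulatory
phrasing.  The separation point is only awarded alongside a precursor match:
a retention-time coincidence with no mass evidence identifies nothing, so
candidate features are pre-filtered by the precursor m/z window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .compounds import Compound, CompoundDatabase
from .masses import ppm_error

__all__ = [
    "FRAGMENT_TOL_DEFAULT",
    "IP_SEPARATION",
    "IP_PRECURSOR",
    "IP_PRODUCT",
    "FeatureObservation",
    "IdentificationResult",
    "match_precursor",
    "match_rt",
    "match_fragments",
    "identification_points",
    "select_candidate",
    "identify_compound",
    "identify",
]

#: Fragment m/z match tolerance (Th); product ions are tabulated to 1 decimal.
FRAGMENT_TOL_DEFAULT = 0.05

#: Identification points per evidence type.
IP_SEPARATION = 1.0   # chromatographic separation (UPLC retention time)
IP_PRECURSOR = 1.5    # high-resolution precursor ion
IP_PRODUCT = 2.5      # each high-resolution product ion

#: Required point totals.
IP_REQUIRED_AUTHORIZED = 4.0
IP_REQUIRED_UNAUTHORIZED = 5.0

#: Full-scan acquisition m/z range (Th).
ACQUISITION_MZ_RANGE = (150.0, 1000.0)


@dataclass(frozen=True)
class FeatureObservation:
    """One detected chromatographic peak with optional product ions."""

    mz: float
    rt_min: float
    response: float
    fragment_mzs: tuple[float, ...] = ()
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.response < 0:
            raise ValueError("feature response must be >= 0")
        lo, hi = ACQUISITION_MZ_RANGE
        if not lo <= self.mz <= hi:
            raise ValueError(
                f"feature m/z {self.mz} outside acquisition range [{lo}, {hi}]"
            )


@dataclass
class IdentificationResult:
    """Per-compound identification verdict for one run."""

    compound: str
    feature: FeatureObservation | None = None
    precursor_matched: bool = False
    ppm: float = float("nan")
    rt_matched: bool = False
    rt_rel_dev: float = float("nan")
    fragments_matched: int = 0
    points: float = 0.0
    required_points: float = IP_REQUIRED_AUTHORIZED
    identified: bool = False


def match_precursor(
    feature: FeatureObservation, compound: Compound, ppm_tol: float = 5.0
) -> tuple[bool, float]:
    """Match an observed m/z against a compound's theoretical precursor.

    Returns ``(flag, signed ppm error)``; the flag is true iff
    ``|ppm| <= ppm_tol`` (boundary inclusive).
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    err = ppm_error(feature.mz, compound.precursor_mz)
    return abs(err) <= ppm_tol, err


def match_rt(
    observed_rt: float, expected_rt: float, tol_frac: float = 0.025
) -> tuple[bool, float]:
    """Match a retention time within a relative tolerance window.

    Returns ``(flag, relative deviation)`` with the deviation as a fraction
    of the expected RT.
    """
    if expected_rt <= 0:
        raise ValueError("expected RT must be positive")
    if tol_frac <= 0:
        raise ValueError("tol_frac must be positive")
    dev = abs(observed_rt - expected_rt) / expected_rt
    return dev <= tol_frac, dev


def match_fragments(
    observed: Sequence[float],
    compound: Compound,
    frag_tol: float = FRAGMENT_TOL_DEFAULT,
) -> int:
    """Count tabulated product ions with a matching observation.

    Each observation is consumed at most once (nearest-first assignment), so
    a single observed ion cannot satisfy two tabulated fragments.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be positive")
    available = list(observed)
    matched = 0
    for frag in compound.fragment_mzs:
        best_i, best_d = -1, frag_tol
        for i, obs in enumerate(available):
            d = abs(obs - frag)
            if d <= best_d:
                best_i, best_d = i, d
        if best_i >= 0:
            matched += 1
            available.pop(best_i)
    return matched


def identification_points(
    rt_matched: bool, precursor_matched: bool, fragments_matched: int
) -> float:
    """Tally identification points for the matched evidence."""
    if fragments_matched < 0:
        raise ValueError("fragments_matched must be >= 0")
    return (
        IP_SEPARATION * bool(rt_matched)
        + IP_PRECURSOR * bool(precursor_matched)
        + IP_PRODUCT * fragments_matched
    )


def select_candidate(
    features: Iterable[FeatureObservation],
    compound: Compound,
    ppm_tol: float = 5.0,
    rt_tol_frac: float | None = None,
) -> FeatureObservation | None:
    """Pick the best candidate feature inside the compound's m/z window.

    Mirrors extracted-ion-chromatogram practice: the chromatogram is
    extracted at the theoretical m/z and the peak at the expected retention
    time whose product ions confirm the analyte is integrated.  Features
    inside the RT tolerance window therefore take precedence (isobaric panel
    members — the tetracycline epimers share a formula — would otherwise
    steal the assignment on mass error alone) and, within the window,
    candidates rank by number of matching diagnostic fragments, then
    intensity, with smaller |ppm error| then smaller RT deviation as
    deterministic tie-breaks.  Features outside the RT window rank by
    |ppm error| alone.  Returns None when no feature falls in the m/z window.
    """
    rt_tol = rt_tol_frac if rt_tol_frac is not None else 0.025
    best: FeatureObservation | None = None
    best_key: tuple | None = None
    for feat in features:
        ok, err = match_precursor(feat, compound, ppm_tol)
        if not ok:
            continue
        rt_dev = abs(feat.rt_min - compound.expected_rt) / compound.expected_rt
        in_window = rt_dev <= rt_tol
        n_frag = (
            match_fragments(feat.fragment_mzs, compound) if in_window else 0
        )
        key = (0 if in_window else 1,
               -n_frag,
               -feat.response if in_window else 0.0,
               abs(err), rt_dev)
        if best_key is None or key < best_key:
            best, best_key = feat, key
    return best


def identify_compound(
    features: Iterable[FeatureObservation],
    compound: Compound,
    ppm_tol: float = 5.0,
    rt_tol_frac: float = 0.025,
    frag_tol: float = FRAGMENT_TOL_DEFAULT,
) -> IdentificationResult:
    """Match, score and judge one compound against a run's feature list."""
    required = (
        IP_REQUIRED_AUTHORIZED if compound.authorized else IP_REQUIRED_UNAUTHORIZED
    )
    result = IdentificationResult(compound=compound.name, required_points=required)
    candidate = select_candidate(features, compound, ppm_tol, rt_tol_frac)
    if candidate is None:
        return result
    result.feature = candidate
    result.precursor_matched, result.ppm = match_precursor(
        candidate, compound, ppm_tol
    )
    result.rt_matched, result.rt_rel_dev = match_rt(
        candidate.rt_min, compound.expected_rt, rt_tol_frac
    )
    result.fragments_matched = match_fragments(
        candidate.fragment_mzs, compound, frag_tol
    )
    result.points = identification_points(
        result.rt_matched, result.precursor_matched, result.fragments_matched
    )
    result.identified = (
        result.precursor_matched
        and result.rt_matched
        and result.points >= required
    )
    return result


def identify(
    run,
    db: CompoundDatabase,
    ppm_tol: float | None = None,
    rt_tol_frac: float | None = None,
    frag_tol: float = FRAGMENT_TOL_DEFAULT,
) -> dict[str, IdentificationResult]:
    """Identify every panel compound in a run.

    ``run`` may be anything with a ``features`` attribute (a synthetic or
    loaded run) or a plain iterable of :class:`FeatureObservation`.  Absent
    features yield non-identified results, never errors.
    """
    features = list(getattr(run, "features", run))
    ppm_tol = db.ppm_tolerance if ppm_tol is None else ppm_tol
    rt_tol_frac = db.rt_tolerance_frac if rt_tol_frac is None else rt_tol_frac
    return {
        c.name: identify_compound(features, c, ppm_tol, rt_tol_frac, frag_tol)
        for c in db
    }
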