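"""Shared fixtures: the packaged panel, tiny synthetic compounds, and an
independent brute-force identification oracle."""

from __future__ import annotations

import pytest
from hypothesis import settings

from milkscreen.compounds import Compound, CompoundDatabase, load_default_db
from milkscreen.masses import ADDUCTS, adduct_mz, parse_formula

settings.register_profile("repro", derandomize=True, max_examples=50)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def db() -> CompoundDatabase:
    return load_default_db()


def make_compound(
    name: str = "Testamycin",
    formula: str = "C16H19N3O5S",
    adduct: str = "[M+H]+",
    rt: float = 10.0,
    fragments: tuple[float, ...] = (208.0, 349.1),
    mrl: float | None = 100.0,
    stc: float = 50.0,
    cv_r: float | None = 0.05,
) -> Compound:
    counts = parse_formula(formula)
    mz = adduct_mz(counts, adduct)
    return Compound(
        name=name,
        chemical_class="sulfonamide",
        formula=counts,
        adduct=ADDUCTS[adduct],
        expected_rt=rt,
        precursor_mz=mz,
        tabulated_mz=round(mz, 4),
        fragment_mzs=fragments,
        nce=30.0,
        mrl=mrl,
        stc=stc,
        cv_r=cv_r,
    )


def brute_force_identify(features, database, ppm_tol=5.0, rt_tol=0.025,
                         frag_tol=0.05):
    """All-pairs reference matcher, written independently of the library path.

    Enumerates every (feature, compound) pair, ranks candidates with the
    documented ordering via an explicit sort, and tallies points from first
    principles.
    """
    out = {}
    for comp in database:
        scored = []
        for f in features:
            ppm = 1e6 * (f.mz - comp.precursor_mz) / comp.precursor_mz
            if abs(ppm) > ppm_tol:
                continue
            rt_dev = abs(f.rt_min - comp.expected_rt) / comp.expected_rt
            in_window = rt_dev <= rt_tol
            # greedy nearest-first fragment assignment, observations consumed
            remaining = list(f.fragment_mzs)
            n_frag = 0
            for target in comp.fragment_mzs:
                cands = sorted(
                    (abs(o - target), i) for i, o in enumerate(remaining)
                )
                if cands and cands[0][0] <= frag_tol:
                    remaining.pop(cands[0][1])
                    n_frag += 1
            scored.append(
                (
                    (0 if in_window else 1,
                     -n_frag if in_window else 0,
                     -f.response if in_window else 0.0,
                     abs(ppm), rt_dev),
                    f, ppm, rt_dev, in_window, n_frag,
                )
            )
        if not scored:
            out[comp.name] = (None, 0.0, False)
            continue
        scored.sort(key=lambda item: item[0])
        _, f, ppm, rt_dev, in_window, n_frag = scored[0]
        points = 1.0 * in_window + 1.5 + 2.5 * n_frag
        required = 4.0 if comp.mrl is not None else 5.0
        identified = in_window and points >= required
        out[comp.name] = (f, points, identified)
    return out
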