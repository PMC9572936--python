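"""Target-panel data model: compounds, the packaged 57-analyte database,
screening target concentrations and the isotope-labelled internal standards.

The packaged database (``data/compound_db.csv``) carries, per analyte, the
molecular formula, adduct species, expected retention time, tabulated
precursor m/z, two diagnostic fragment m/z values, normalised collision
energy, the maximum residue limit (MRL, absent for unauthorized substances),
the screening target concentration (STC) at which the method is validated,
and the within-laboratory reproducibility CV used by the synthetic-data
generators.

On load, every tabulated precursor m/z is recomputed from formula + adduct;
rows deviating by more than :data:`MZ_FLAG_PPM` are loaded but flagged so a
transcription slip in the source table is reported rather than silently
adopted.  The recomputed value is authoritative for matching.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

from .masses import (
    ADDUCTS,
    MONOISOTOPIC_MASS,
    AdductSpec,
    FormulaError,
    adduct_mz,
    parse_formula,
    ppm_error,
)

__all__ = [
    "MZ_FLAG_PPM",
    "Compound",
    "CompoundDatabase",
    "CompoundDBError",
    "ConfigurationError",
    "InternalStandard",
    "INTERNAL_STANDARDS",
    "load_compound_db",
    "load_default_db",
    "assign_stc",
]

#: Rows whose tabulated precursor m/z deviates from recomputation by more
#: than this (ppm) are flagged as transcription discrepancies.
MZ_FLAG_PPM = 0.5

#: Hard instrumental matching tolerance (ppm); rows beyond it are still
#: loaded but would fail identification against their own tabulated value.
PPM_TOLERANCE_DEFAULT = 5.0

#: Retention-time matching tolerance as a fraction of the expected RT.
RT_TOLERANCE_FRAC_DEFAULT = 0.025

_REQUIRED_COLUMNS = [
    "name", "class", "formula", "adduct", "rt_min", "precursor_mz",
    "fragment1_mz", "fragment2_mz", "nce", "mrl_ug_kg", "stc_ug_kg",
]

_CLASSES = {
    "penicillin", "cephalosporin", "tetracycline", "pleuromutilin",
    "macrolide", "lincosamide", "quinolone", "sulfonamide",
}


class CompoundDBError(ValueError):
    """Raised for a malformed compound database file."""


class ConfigurationError(KeyError):
    """Raised when a required configured value (STC, cut-off, curve) is missing."""


@dataclass(frozen=True)
class Compound:
    """One target analyte of the screening panel."""

    name: str
    chemical_class: str
    formula: Mapping[str, int]
    adduct: AdductSpec
    expected_rt: float                 # min
    precursor_mz: float                # theoretical, recomputed (Th)
    tabulated_mz: float                # as printed in the source table (Th)
    fragment_mzs: tuple[float, ...]    # >= 2 diagnostic product ions (Th)
    nce: float                         # normalised collision energy
    mrl: float | None                  # µg/kg; None for unauthorized substances
    stc: float                         # µg/kg screening target concentration
    cv_r: float | None = None          # within-lab reproducibility CV, fraction
    mz_flag_ppm: float = 0.0           # recomputed-vs-tabulated deviation (ppm)

    def __post_init__(self) -> None:
        if self.stc <= 0:
            raise ValueError(f"{self.name}: STC must be positive")
        if self.mrl is not None and self.stc > self.mrl:
            raise ValueError(f"{self.name}: STC {self.stc} exceeds MRL {self.mrl}")
        if len(self.fragment_mzs) < 2:
            raise ValueError(f"{self.name}: at least 2 fragment m/z values required")
        if not 0 < self.expected_rt <= 30:
            raise ValueError(f"{self.name}: expected RT outside (0, 30] min")

    @property
    def authorized(self) -> bool:
        """True iff an MRL exists for this substance."""
        return self.mrl is not None

    @property
    def flagged(self) -> bool:
        """True iff the tabulated m/z disagrees with recomputation (> MZ_FLAG_PPM)."""
        return abs(self.mz_flag_ppm) > MZ_FLAG_PPM


@dataclass
class CompoundDatabase:
    """Ordered collection of target compounds with matching tolerance defaults."""

    compounds: list[Compound]
    version: str = "table-2+8"
    ppm_tolerance: float = PPM_TOLERANCE_DEFAULT
    rt_tolerance_frac: float = RT_TOLERANCE_FRAC_DEFAULT

    def __post_init__(self) -> None:
        names = [c.name for c in self.compounds]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CompoundDBError(f"duplicate compound names: {dupes}")
        self._by_name = {c.name: c for c in self.compounds}

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self.compounds)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Compound:
        try:
            return self._by_name[name]
        except KeyError:
            raise ConfigurationError(f"compound {name!r} not in database") from None

    def names(self) -> list[str]:
        return [c.name for c in self.compounds]

    def flagged(self) -> list[Compound]:
        """Compounds whose tabulated precursor m/z disagrees with recomputation."""
        return [c for c in self.compounds if c.flagged]

    def subset(self, names: list[str]) -> "CompoundDatabase":
        """New database restricted to the given compound names (order kept)."""
        return CompoundDatabase(
            [self[n] for n in names],
            version=self.version,
            ppm_tolerance=self.ppm_tolerance,
            rt_tolerance_frac=self.rt_tolerance_frac,
        )

    def stc_table(self) -> dict[str, float]:
        return {c.name: c.stc for c in self.compounds}


def _parse_row(row: Mapping[str, str], lineno: int) -> Compound:
    name = row["name"].strip()
    if not name:
        raise CompoundDBError(f"row {lineno}: empty compound name")
    try:
        formula = parse_formula(row["formula"].strip())
    except FormulaError as exc:
        raise CompoundDBError(f"row {lineno} ({name}): {exc}") from exc
    adduct_label = row["adduct"].strip()
    if adduct_label not in ADDUCTS:
        raise CompoundDBError(
            f"row {lineno} ({name}): unsupported adduct {adduct_label!r}"
        )
    adduct = ADDUCTS[adduct_label]
    chem_class = row["class"].strip()
    if chem_class not in _CLASSES:
        raise CompoundDBError(f"row {lineno} ({name}): unknown class {chem_class!r}")
    try:
        tabulated = float(row["precursor_mz"])
        rt = float(row["rt_min"])
        fragments = (float(row["fragment1_mz"]), float(row["fragment2_mz"]))
        nce = float(row["nce"])
        mrl_raw = row["mrl_ug_kg"].strip()
        mrl = float(mrl_raw) if mrl_raw else None
        stc = float(row["stc_ug_kg"])
        cv_raw = row.get("cv_r_pct", "").strip()
        cv_r = float(cv_raw) / 100.0 if cv_raw else None
    except ValueError as exc:
        raise CompoundDBError(f"row {lineno} ({name}): {exc}") from exc
    theoretical = adduct_mz(formula, adduct)
    return Compound(
        name=name,
        chemical_class=chem_class,
        formula=formula,
        adduct=adduct,
        expected_rt=rt,
        precursor_mz=theoretical,
        tabulated_mz=tabulated,
        fragment_mzs=fragments,
        nce=nce,
        mrl=mrl,
        stc=stc,
        cv_r=cv_r,
        mz_flag_ppm=ppm_error(tabulated, theoretical),
    )


def load_compound_db(path: str | Path) -> CompoundDatabase:
    """Load a compound database from a delimited-text file.

    Every row's precursor m/z is recomputed from formula + adduct; rows whose
    tabulated value disagrees are flagged (``Compound.flagged``), not dropped.

    Raises
    ------
    CompoundDBError
        On a missing column, duplicate name, unparsable formula, or empty file.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CompoundDBError(f"{path}: empty file")
        missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CompoundDBError(f"{path}: missing columns {missing}")
        compounds = [_parse_row(row, lineno) for lineno, row in enumerate(reader, 2)]
    if not compounds:
        raise CompoundDBError(f"{path}: no compound rows")
    return CompoundDatabase(compounds)


def load_default_db() -> CompoundDatabase:
    """Load the packaged 57-compound target panel."""
    with resources.as_file(
        resources.files("milkscreen.data").joinpath("compound_db.csv")
    ) as path:
        return load_compound_db(path)


def assign_stc(compound: Compound, stc_table: Mapping[str, float]) -> float:
    """Look up the configured screening target concentration for a compound.

    STCs are policy choices (the MRL or a class-wise fraction of it, or the
    lowest achievable level for unauthorized substances) and therefore ship
    as data rather than being computed from the MRL.
    """
    try:
        stc = stc_table[compound.name]
    except KeyError:
        raise ConfigurationError(
            f"no STC configured for {compound.name!r}"
        ) from None
    if compound.mrl is not None and stc > compound.mrl:
        raise ValueError(
            f"{compound.name}: configured STC {stc} exceeds MRL {compound.mrl}"
        )
    return stc


@dataclass(frozen=True)
class InternalStandard:
    """Isotope-labelled internal standard added to every sample (10 µg/kg).

    Modelled as a presence/retention-time check only; no isotope-dilution
    correction is applied.
    """

    name: str
    mz: float
    expected_rt: float
    spike_level: float = 10.0  # µg/kg


def _labelled_mz(formula: str, adduct: str, n_label: int, label: str) -> float:
    """m/z of an isotopically labelled ion: swap n atoms for their heavy label."""
    shift = {
        "13C": n_label * (MONOISOTOPIC_MASS["[13C]"] - MONOISOTOPIC_MASS["C"]),
        "D": n_label * (MONOISOTOPIC_MASS["D"] - MONOISOTOPIC_MASS["H"]),
    }[label]
    spec = ADDUCTS[adduct]
    return adduct_mz(formula, spec) + shift / spec.charge


#: The four labelled standards of the internal quality-control scheme.
#: Cefadroxil is not on the target panel; its expected RT is a synthetic
#: modelling choice (the other three inherit their parent's panel RT).
INTERNAL_STANDARDS: tuple[InternalStandard, ...] = (
    InternalStandard("Sulfanilamide-13C6",
                     _labelled_mz("C6H8N2O2S", "[M+H-NH3]+", 6, "13C"), 3.65),
    InternalStandard("Cefadroxil-d4",
                     _labelled_mz("C16H17N3O5S", "[M+H]+", 4, "D"), 8.50),
    InternalStandard("Enrofloxacin-d5",
                     _labelled_mz("C19H22FN3O3", "[M+H]+", 5, "D"), 10.66),
    InternalStandard("Penicillin G-d7",
                     _labelled_mz("C16H18N2O4S", "[M+Na]+", 7, "D"), 15.90),
)
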