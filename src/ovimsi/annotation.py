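"""Putative lipid annotation of discriminative masses.

Builds a formula-derived monoisotopic-mass table for the major
glycerophospholipid classes (PC, PE, PS, PI), sphingomyelin and their lyso
forms, and matches observed m/z values against species+adduct masses within a
tolerance.  Matching is mass-only: no fragmentation evidence is used, so every
assignment is putative and ambiguous matches are reported as a joined category
("PC/PE") listing all classes consistent with the mass.

Formula rules (n = total acyl carbons, d = total double bonds), diacyl:

    PC  C(n+8)  H(2n-2d+16) N O8  P
    PE  C(n+5)  H(2n-2d+10) N O8  P
    PS  C(n+6)  H(2n-2d+10) N O10 P
    PI  C(n+9)  H(2n-2d+15)   O13 P
    SM  C(n+5)  H(2n-2d+13) N2 O6 P      (d-sphingoid backbone, SM(d n:d))

Lyso forms replace one acyl chain with a hydroxyl: relative to the diacyl
formula at the same (n, d) this adds H2 and removes one O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

# CODATA/IUPAC monoisotopic atomic masses (Da)
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

ELECTRON_MASS = 0.00054857990

#: adduct name -> (mass shift in Da, polarity). Shifts include the electron.
ADDUCTS: dict[str, tuple[float, str]] = {
    "[M+H]+": (MONOISOTOPIC_MASS["H"] - ELECTRON_MASS, "positive"),
    "[M+Na]+": (MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, "positive"),
    "[M+K]+": (MONOISOTOPIC_MASS["K"] - ELECTRON_MASS, "positive"),
    "[M-H]-": (-(MONOISOTOPIC_MASS["H"] - ELECTRON_MASS), "negative"),
}

# class -> (C offset, H offset as (a, b) in H = 2n - 2d + b, N count, O count)
_DIACYL_RULES: dict[str, tuple[int, int, int, int]] = {
    "PC": (8, 16, 1, 8),
    "PE": (5, 10, 1, 8),
    "PS": (6, 10, 1, 10),
    "PI": (9, 15, 0, 13),
    "SM": (5, 13, 2, 6),
}
_LYSO_OF = {"LPC": "PC", "LPE": "PE", "LPS": "PS", "LPI": "PI"}

LIPID_CLASSES = tuple(_DIACYL_RULES) + tuple(_LYSO_OF)


def formula_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass of a formula given as element -> count."""
    return sum(MONOISOTOPIC_MASS[el] * k for el, k in formula.items())


def lipid_formula(lipid_class: str, carbons: int, double_bonds: int) -> dict[str, int]:
    """Element counts for a lipid species, from the class formula rules."""
    lyso = lipid_class in _LYSO_OF
    base = _LYSO_OF.get(lipid_class, lipid_class)
    if base not in _DIACYL_RULES:
        raise ValueError(f"unknown lipid class {lipid_class!r}")
    c_off, h_off, n_cnt, o_cnt = _DIACYL_RULES[base]
    formula = {
        "C": carbons + c_off,
        "H": 2 * carbons - 2 * double_bonds + h_off,
        "O": o_cnt,
        "P": 1,
    }
    if n_cnt:
        formula["N"] = n_cnt
    if lyso:
        formula["H"] += 2
        formula["O"] -= 1
    if formula["H"] <= 0:
        raise ValueError(f"{lipid_class}({carbons}:{double_bonds}) is not a valid species")
    return formula


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid species, e.g. PC(34:1)."""

    lipid_class: str
    carbons: int
    double_bonds: int
    formula: tuple[tuple[str, int], ...]
    monoisotopic_mass: float

    @property
    def name(self) -> str:
        return f"{self.lipid_class}({self.carbons}:{self.double_bonds})"

    def formula_string(self) -> str:
        order = ("C", "H", "N", "O", "P")
        return "".join(
            f"{el}{k}" if k > 1 else el for el, k in sorted(dict(self.formula).items(), key=lambda x: order.index(x[0])) if k > 0
        )


def make_species(lipid_class: str, carbons: int, double_bonds: int) -> LipidSpecies:
    f = lipid_formula(lipid_class, carbons, double_bonds)
    return LipidSpecies(
        lipid_class=lipid_class,
        carbons=carbons,
        double_bonds=double_bonds,
        formula=tuple(sorted(f.items())),
        monoisotopic_mass=formula_mass(f),
    )


def build_lipid_db(
    classes: Sequence[str] = LIPID_CLASSES,
    carbon_range: tuple[int, int] = (28, 44),
    db_range: tuple[int, int] = (0, 8),
    lyso_carbon_range: tuple[int, int] = (14, 22),
    lyso_db_range: tuple[int, int] = (0, 4),
) -> list[LipidSpecies]:
    """Enumerate species over carbon/double-bond grids for the given classes.

    Diacyl classes use ``carbon_range``/``db_range``; lyso classes (LPC...)
    use the lyso ranges (single acyl chains are shorter).  Double bonds are
    capped at carbons/2.
    """
    if not classes:
        raise ValueError("no lipid classes requested")
    species: list[LipidSpecies] = []
    for cls in classes:
        if cls not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {cls!r}")
        lo, hi = (lyso_carbon_range if cls in _LYSO_OF else carbon_range)
        dlo, dhi = (lyso_db_range if cls in _LYSO_OF else db_range)
        for n in range(lo, hi + 1):
            for d in range(dlo, min(dhi, n // 2) + 1):
                species.append(make_species(cls, n, d))
    return species


def adduct_mz(species: LipidSpecies, adduct: str) -> float:
    """Theoretical m/z of a singly charged species+adduct ion."""
    shift, _ = ADDUCTS[adduct]
    return species.monoisotopic_mass + shift


@dataclass
class AnnotationRecord:
    """Putative annotation of one discriminative mass.

    ``candidates`` holds every (species, adduct) whose theoretical m/z lies
    within tolerance; ``category`` joins the sorted unique candidate classes
    with "/" ("PC/PE"), or is "unassigned" when nothing matches.
    """

    observed_mz: float
    mode: str
    candidates: list[tuple[LipidSpecies, str, float, float]] = field(default_factory=list)

    @property
    def category(self) -> str:
        if not self.candidates:
            return "unassigned"
        return "/".join(sorted({sp.lipid_class for sp, _, _, _ in self.candidates}))

    @property
    def annotated(self) -> bool:
        return bool(self.candidates)


def annotate_mz(
    observed_mz: float,
    mode: str,
    db: Sequence[LipidSpecies],
    tolerance: float = 0.05,
    adducts: Mapping[str, tuple[float, str]] = ADDUCTS,
) -> AnnotationRecord:
    """Match one observed m/z against the DB with the mode's adduct set.

    Parameters
    ----------
    tolerance
        Maximum |observed - theoretical| in Da (default 0.05, TOF-scale).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    rec = AnnotationRecord(observed_mz=float(observed_mz), mode=mode)
    for adduct, (shift, polarity) in adducts.items():
        if polarity != mode:
            continue
        for sp in db:
            theo = sp.monoisotopic_mass + shift
            err = observed_mz - theo
            if abs(err) <= tolerance:
                rec.candidates.append((sp, adduct, theo, err))
    rec.candidates.sort(key=lambda c: abs(c[3]))
    return rec


def annotate_dm(dm, db: Sequence[LipidSpecies], tolerance: float = 0.05) -> AnnotationRecord:
    """Annotate a :class:`~ovimsi.diff.DiscriminativeMass` by its center m/z."""
    return annotate_mz(dm.center_mz, dm.mode, db, tolerance=tolerance)


def summarize_classes(
    records: Iterable[tuple[str, str, AnnotationRecord]],
) -> pd.DataFrame:
    """Category count table per (timepoint, direction), plus totals.

    Parameters
    ----------
    records
        Iterable of (timepoint, direction, AnnotationRecord).

    Returns
    -------
    DataFrame with columns timepoint, direction, category, count, and a
    ``fraction_annotated`` attribute in ``DataFrame.attrs``.
    """
    rows = [
        {"timepoint": tp, "direction": dr, "category": rec.category}
        for tp, dr, rec in records
    ]
    if not rows:
        out = pd.DataFrame(columns=["timepoint", "direction", "category", "count"])
        out.attrs["fraction_annotated"] = float("nan")
        return out
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["timepoint", "direction", "category"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    n_total = len(df)
    n_annot = int((df["category"] != "unassigned").sum())
    out.attrs["fraction_annotated"] = n_annot / n_total
    out.attrs["n_annotated"] = n_annot
    out.attrs["n_total"] = n_total
    return out


def db_to_frame(db: Sequence[LipidSpecies]) -> pd.DataFrame:
    """Lipid DB as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        {
            "class": [s.lipid_class for s in db],
            "carbons": [s.carbons for s in db],
            "double_bonds": [s.double_bonds for s in db],
            "formula": [s.formula_string() for s in db],
            "monoisotopic_mass": [s.monoisotopic_mass for s in db],
        }
    )
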