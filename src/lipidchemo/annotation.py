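"""Accurate-mass lipid annotation.

A measured m/z is matched against a species library by computing, for
every library formula and every adduct of the measurement's polarity, the
theoretical adduct m/z (multiplier x neutral monoisotopic mass + an
electron-corrected mass delta) and keeping matches within a ppm tolerance.
Lipid shorthand names (class, total acyl carbons:double bonds, optional
";On" extra oxygens, optional chromatographic-variant suffix) are parsed
and re-rendered for canonical comparison.

The bundled library (``data/lipid_library.csv``) transcribes the
differential-lipid tables of the emulated study verbatim, including their
printed inconsistencies, which are flagged with ``suspect=1`` rather than
silently corrected.  Multi-valued cells (ambiguous assignments) separate
options with ``|``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

# exact masses of the most abundant isotope (Da)
ELEMENT_MASSES = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

ELECTRON_MASS = 0.000549

#: adduct -> (multiplier, mass delta in Da incl. electron correction, polarity)
ADDUCTS = {
    "[M+H]+": (1, 1.007276, "positive"),
    "[M+NH4]+": (1, 18.033823, "positive"),
    "[M+Na]+": (1, 22.989218, "positive"),
    "[M+K]+": (1, 38.963158, "positive"),
    "[M-H]-": (1, -1.007276, "negative"),
    "[M+OAc]-": (1, 59.013851, "negative"),
    "[2M+Na]+": (2, 22.989218, "positive"),
}

LIPID_CLASSES = ("LPC", "PC O-", "PC", "PS", "PA", "Cer", "SM", "DG", "TG", "FA", "CE")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict:
    """'C24H50NO7P' -> element count dict; unknown elements are rejected."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        elem, num = match.groups()
        if elem not in ELEMENT_MASSES:
            raise ValueError(f"unsupported element {elem!r} in formula {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = match.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def monoisotopic_mass(formula) -> float:
    """Neutral monoisotopic mass (Da) of a formula string or count dict."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    unknown = set(counts) - set(ELEMENT_MASSES)
    if unknown:
        raise ValueError(f"unsupported element(s): {sorted(unknown)}")
    return sum(ELEMENT_MASSES[e] * n for e, n in counts.items())


def adduct_mz(mass: float, adduct: str) -> float:
    """m/z of an ionised form: multiplier * neutral mass + adduct delta."""
    if mass <= 0:
        raise ValueError(f"neutral mass must be > 0, got {mass}")
    if adduct not in ADDUCTS:
        raise ValueError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    mult, delta, _ = ADDUCTS[adduct]
    return mult * mass + delta


def ppm_error(measured: float, theoretical: float) -> float:
    return (measured - theoretical) / theoretical * 1e6


# --------------------------------------------------------------------------
# lipid shorthand
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LipidName:
    lipid_class: str
    carbons: int
    double_bonds: int
    extra_oxygens: int = 0
    variant: str | None = None

    def render(self, with_variant: bool = False) -> str:
        s = f"{self.lipid_class}{'' if self.lipid_class.endswith('-') else ' '}"
        s += f"{self.carbons}:{self.double_bonds}"
        if self.extra_oxygens == 1:
            s += ";O"
        elif self.extra_oxygens > 1:
            s += f";O{self.extra_oxygens}"
        if with_variant and self.variant:
            s += f" {self.variant}"
        return s


_SHORTHAND = re.compile(
    r"^(?P<cls>LPC|PC O-|PC|PS|PA|Cer|SM|DG|TG|FA|CE)\s*"
    r"(?P<c>\d+):(?P<db>\d+)"
    r"(?:;O(?P<ox>\d*))?"
    r"(?:\s+(?P<var>[A-Z]\d*))?$"
)


def parse_lipid_shorthand(name: str) -> LipidName:
    """Parse 'Cer 34:1;O2 B' -> (Cer, 34, 1, 2, 'B'); rejects with position."""
    text = name.strip()
    m = _SHORTHAND.match(text)
    if m is None:
        # locate the first offending position for the error message
        probe = re.match(r"(LPC|PC O-|PC|PS|PA|Cer|SM|DG|TG|FA|CE)\s*\d*:?", text)
        pos = probe.end() if probe else 0
        raise ValueError(f"cannot parse lipid shorthand {name!r} at position {pos}")
    ox = m.group("ox")
    extra_ox = 0 if ox is None else (1 if ox == "" else int(ox))
    return LipidName(
        lipid_class=m.group("cls"),
        carbons=int(m.group("c")),
        double_bonds=int(m.group("db")),
        extra_oxygens=extra_ox,
        variant=m.group("var"),
    )


# --------------------------------------------------------------------------
# library and matching
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationHit:
    species: str
    adduct: str
    formula: str
    theoretical_mz: float
    ppm: float


def load_lipid_library() -> pd.DataFrame:
    """The bundled species table (one row per printed m/z feature)."""
    with resources.files("lipidchemo.data").joinpath("lipid_library.csv").open() as fh:
        return pd.read_csv(fh)


def _species_formulas(library: pd.DataFrame):
    """Unique (species display name, formula) pairs, splitting '|' options."""
    pairs = set()
    for _, row in library.iterrows():
        for formula in str(row["formula"]).split("|"):
            name = str(row["lipid_assignment"])
            if name in ("N.D.", "nan"):
                name = formula
            pairs.add((name, formula))
    return sorted(pairs)


def annotate_feature(
    mz: float,
    polarity: str,
    tolerance_ppm: float = 10.0,
    library: pd.DataFrame | None = None,
) -> list[AnnotationHit]:
    """All (species, adduct) matches of the right polarity within tolerance.

    Hits are sorted by absolute ppm error, ties broken by species name.
    An empty list is a valid result.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be > 0")
    if polarity not in ("positive", "negative"):
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    if library is None:
        library = load_lipid_library()
    if not len(library):
        raise ValueError("species library is empty")
    hits = []
    for name, formula in _species_formulas(library):
        mass = monoisotopic_mass(formula)
        for adduct, (mult, delta, pol) in ADDUCTS.items():
            if pol != polarity:
                continue
            theo = mult * mass + delta
            err = ppm_error(mz, theo)
            if abs(err) <= tolerance_ppm:
                hits.append(AnnotationHit(name, adduct, formula, theo, err))
    return sorted(hits, key=lambda h: (abs(h.ppm), h.species, h.adduct))


def annotate_table(
    features: pd.DataFrame, tolerance_ppm: float = 10.0, library: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Annotate every feature descriptor row (columns mz, ion_mode)."""
    if library is None:
        library = load_lipid_library()
    rows = []
    for fid, row in features.iterrows():
        hits = annotate_feature(row["mz"], row["ion_mode"], tolerance_ppm, library)
        if not hits:
            rows.append(dict(feature_id=fid, measured_mz=row["mz"], adduct=None,
                             formula=None, lipid_assignment=None, ppm=None))
        for h in hits:
            rows.append(dict(feature_id=fid, measured_mz=row["mz"], adduct=h.adduct,
                             formula=h.formula, lipid_assignment=h.species,
                             ppm=round(h.ppm, 2)))
    return pd.DataFrame(rows)


def library_mass_check(library: pd.DataFrame | None = None, tolerance_ppm: float = 10.0) -> pd.DataFrame:
    """Per-row mass audit of the bundled table.

    ``ppm_printed`` is the deviation of the printed measured m/z from the
    theoretical m/z of the printed (formula, adduct) pair (best option for
    ambiguous rows).  ``species_recovered`` asks the annotation engine the
    operative question: queried at the printed m/z and polarity, does any
    hit within tolerance carry the row's printed formula?
    """
    if library is None:
        library = load_lipid_library()
    records = []
    for _, row in library.iterrows():
        formulas = str(row["formula"]).split("|")
        adducts = str(row["adduct"]).split("|")
        best = None
        for formula in formulas:
            for adduct in adducts:
                theo = adduct_mz(monoisotopic_mass(formula), adduct)
                err = ppm_error(row["measured_mz"], theo)
                if best is None or abs(err) < abs(best):
                    best = err
        polarity = "positive" if adducts[0].endswith("+") else "negative"
        hits = annotate_feature(row["measured_mz"], polarity, tolerance_ppm, library)
        recovered = any(h.formula in formulas for h in hits)
        records.append(
            dict(cohort=row["cohort"], entry=row["entry"],
                 feature_label=row["feature_label"], measured_mz=row["measured_mz"],
                 ppm_printed=round(best, 2), within_tolerance=abs(best) <= tolerance_ppm,
                 species_recovered=recovered, suspect=bool(row["suspect"]))
        )
    return pd.DataFrame(records)
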