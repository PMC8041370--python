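"""Molecular-formula arithmetic for HR-ESIMS assignments.

Monoisotopic masses, adduct m/z values, the hydrogen-deficiency index
(ring-and-double-bond equivalents, RDBE) and neutral-loss annotation of
fragment ions.  The conventions here follow standard positive-mode ESI
practice for small-molecule natural products: sodiated/protonated adduct
masses are reported as the plain monoisotopic sum of the neutral plus the
adduct atom, rounded half-up at four decimal places.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "MolecularFormula",
    "IsotopeTable",
    "AdductSpec",
    "LossCandidate",
    "LossMatch",
    "DEFAULT_ISOTOPES",
    "DEFAULT_LOSSES",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "rdbe",
    "annotate_loss",
    "round_mz",
    "KJ_PER_KCAL",
    "kj_to_kcal",
]

#: thermochemical calorie
KJ_PER_KCAL = 4.184

# Monoisotopic masses (Da) of the most abundant isotope, CODATA/NIST values.
# 12C is exactly 12 by definition of the unified atomic mass unit.
_NIST_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207117,
    "P": 30.97376200,
    "Na": 22.98976928,
    "F": 18.99840316,
    "Cl": 34.96885268,
    "Br": 78.91833760,
    "I": 126.90447300,
}

_HALOGENS = frozenset({"F", "Cl", "Br", "I"})

_SUPPORTED_ELEMENTS = frozenset(_NIST_MASSES)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element → count map; the unit of all mass/RDBE arithmetic."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {el: int(n) for el, n in self.counts.items() if n != 0}
        for el, n in cleaned.items():
            if el not in _SUPPORTED_ELEMENTS:
                raise ValueError(f"unsupported element symbol: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
        if not cleaned:
            raise ValueError("formula must contain at least one atom")
        object.__setattr__(self, "counts", cleaned)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged)

    def hill(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        counts = self.counts
        order: list[str] = []
        if "C" in counts:
            order.append("C")
            if "H" in counts:
                order.append("H")
            order.extend(sorted(el for el in counts if el not in ("C", "H")))
        else:
            order.extend(sorted(counts))
        return "".join(
            f"{el}{counts[el] if counts[el] != 1 else ''}" for el in order
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hill()


@dataclass(frozen=True)
class IsotopeTable:
    """Monoisotopic masses per element symbol (Da)."""

    masses: dict[str, float] = field(default_factory=lambda: dict(_NIST_MASSES))

    def __post_init__(self) -> None:
        if self.masses.get("C") != 12.0:
            raise ValueError("carbon-12 must weigh exactly 12 Da")
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("isotope masses must be positive")


DEFAULT_ISOTOPES = IsotopeTable()


@dataclass(frozen=True)
class AdductSpec:
    """An ESI adduct such as [M + Na]+: the atoms added and the charge."""

    name: str
    added: MolecularFormula
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")


#: The two adducts observed in the spectra this package reproduces.
ADDUCTS: dict[str, AdductSpec] = {
    "Na": AdductSpec("[M+Na]+", MolecularFormula({"Na": 1}), +1),
    "H": AdductSpec("[M+H]+", MolecularFormula({"H": 1}), +1),
}


@dataclass(frozen=True)
class LossCandidate:
    """A neutral-loss hypothesis (e.g. tiglic acid, -100 Da nominal)."""

    name: str
    formula: MolecularFormula
    nominal_mass: int

    def __post_init__(self) -> None:
        mono = monoisotopic_mass(self.formula)
        if abs(mono - self.nominal_mass) > 0.5:
            raise ValueError(
                f"{self.name}: monoisotopic mass {mono:.4f} is more than "
                f"0.5 Da from nominal {self.nominal_mass}"
            )


@dataclass(frozen=True)
class LossMatch:
    """A matched neutral loss: candidate, observed Δm, and error in ppm."""

    candidate: LossCandidate
    observed_delta: float
    error_ppm: float
    tied_with: tuple[LossCandidate, ...] = ()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string such as ``"C32H38O10"``.

    Implicit counts are 1; repeated element symbols accumulate.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        el, num = match.groups()
        if el not in _SUPPORTED_ELEMENTS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        n = int(num) if num else 1
        if n == 0:
            raise ValueError(f"zero count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return MolecularFormula(counts)


def monoisotopic_mass(
    f: MolecularFormula, table: IsotopeTable = DEFAULT_ISOTOPES
) -> float:
    """Monoisotopic mass in Da; additive over formula union."""
    mass = 0.0
    for el, n in f.counts.items():
        try:
            mass += n * table.masses[el]
        except KeyError:
            raise KeyError(f"element {el!r} missing from isotope table") from None
    return mass


def round_mz(mz: float, ndigits: int = 4) -> float:
    """Round half-up at `ndigits` decimals, the convention of printed m/z."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(mz)).quantize(q, rounding=ROUND_HALF_UP))


def adduct_mz(
    f: MolecularFormula,
    adduct: AdductSpec | str = "Na",
    table: IsotopeTable = DEFAULT_ISOTOPES,
) -> float:
    """m/z of a singly charged adduct ion.

    The value is the monoisotopic mass of neutral + adduct atoms with no
    electron-mass correction — the convention under which every printed
    "calcd for" value in the source spectra reproduces at 4 dp.
    """
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if abs(adduct.charge) != 1:
        raise ValueError("only singly charged adducts are supported")
    return monoisotopic_mass(f + adduct.added, table)


def rdbe(f: MolecularFormula) -> float:
    """Hydrogen-deficiency index (ring and double-bond equivalents).

    RDBE = (2·C + 2 + N − H − halogens) / 2.  Oxygen and sulfur do not
    contribute.  A half-integer result signals an odd-electron or invalid
    even-electron neutral and is returned as-is.
    """
    halogens = sum(f[x] for x in _HALOGENS)
    value = (2 * f["C"] + 2 + f["N"] - f["H"] - halogens) / 2
    return value


def kj_to_kcal(kj: float) -> float:
    """Convert kJ/mol to thermochemical kcal/mol."""
    return kj / KJ_PER_KCAL


def _loss(name: str, formula: str, nominal: int) -> LossCandidate:
    return LossCandidate(name, parse_formula(formula), nominal)


#: Neutral losses seen in limonoid ESI fragmentations: CO2 decarboxylation,
#: acetic acid from acetate esters, methacrylic/tiglic acids from the
#: corresponding C-3 esters, 2-hydroxyisovaleric acid, and sequential double
#: acetate loss.  User code may extend this list freely.
DEFAULT_LOSSES: tuple[LossCandidate, ...] = (
    _loss("carbon dioxide", "CO2", 44),
    _loss("acetic acid", "C2H4O2", 60),
    _loss("methacrylic acid", "C4H6O2", 86),
    _loss("tiglic acid", "C5H8O2", 100),
    _loss("2-hydroxyisovaleric acid", "C5H10O3", 118),
    _loss("2 x acetic acid", "C4H8O4", 120),
)


def annotate_loss(
    precursor_mz: float,
    fragment_mz: float,
    candidates: tuple[LossCandidate, ...] | list[LossCandidate] = DEFAULT_LOSSES,
    tol_ppm: float = 15.0,
    table: IsotopeTable = DEFAULT_ISOTOPES,
) -> LossMatch | None:
    """Match the precursor→fragment mass difference to a neutral loss.

    Returns the candidate minimising the absolute mass error, provided the
    error is within ``tol_ppm`` of the observed loss; exact ties are carried
    in ``tied_with`` rather than broken silently.  Returns None when no
    candidate matches (including the zero-loss case).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    delta = precursor_mz - fragment_mz
    if delta < 0:
        raise ValueError(
            f"fragment m/z {fragment_mz} exceeds precursor m/z {precursor_mz}"
        )
    scored: list[tuple[float, LossCandidate]] = []
    for cand in candidates:
        err = abs(delta - monoisotopic_mass(cand.formula, table))
        if delta > 0 and err / delta * 1e6 <= tol_ppm:
            scored.append((err, cand))
    if not scored:
        return None
    scored.sort(key=lambda pair: pair[0])
    best_err, best = scored[0]
    ties = tuple(c for e, c in scored[1:] if e == best_err)
    return LossMatch(
        candidate=best,
        observed_delta=delta,
        error_ppm=best_err / delta * 1e6,
        tied_with=ties,
    )
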