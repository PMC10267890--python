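"""Elemental-formula arithmetic for accurate-mass screening.

Covers the mass bookkeeping every other module leans on: Hill-notation
formula parsing/serialization, monoisotopic masses, the electrospray adduct
registry with its m/z transforms, isotope-pattern simulation by convolution,
and exhaustive molecular-formula enumeration from an accurate mass under
ring-plus-double-bond-equivalent (RDBE) plausibility constraints.

All masses are in daltons; m/z transforms include the electron mass so that
charged-species masses are physically correct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .masses import (
    ELECTRON_MASS,
    ISOTOPES,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    SUPPORTED_ELEMENTS,
    VALENCE,
)


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


@dataclass(frozen=True)
class ElementComposition:
    """An elemental composition (multiset of atoms).

    ``counts`` maps element symbols from the supported set to strictly
    positive integer counts. Instances are immutable and hashable so they can
    key dictionaries and sets.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {el: int(n) for el, n in self.counts.items() if n}
        for el, n in clean.items():
            if el not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el}")
        if not clean:
            raise FormulaError("composition must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self):
        return iter(self.counts.items())

    def __add__(self, other: "ElementComposition") -> "ElementComposition":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return ElementComposition(merged)

    def contains(self, other: "ElementComposition") -> bool:
        """True if ``other`` is a sub-composition (element-wise <=)."""
        return all(self[el] >= n for el, n in other.counts.items())

    def hill_formula(self) -> str:
        return serialize_formula(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_formula()


_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementComposition:
    """Parse a Hill-notation-like molecular formula.

    Accepts multi-digit counts and repeated element tokens (summed). Raises
    :class:`FormulaError` naming the offending token for unknown symbols, and
    for empty or non-formula input.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    s = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at {s[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementComposition(counts)


def serialize_formula(comp: ElementComposition) -> str:
    """Canonical Hill string: C, H, then remaining elements alphabetically."""
    order = [el for el in ("C", "H") if comp[el]]
    order += sorted(el for el in comp.counts if el not in ("C", "H"))
    parts = []
    for el in order:
        n = comp[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(comp: ElementComposition | str) -> float:
    """Sum of count x lightest-isotope exact mass over the composition."""
    if isinstance(comp, str):
        comp = parse_formula(comp)
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in comp)


def rdbe(comp: ElementComposition) -> float:
    """Ring-plus-double-bond equivalents, 1 + sum n_i (v_i - 2) / 2."""
    return 1.0 + sum(n * (VALENCE[el] - 2) for el, n in comp) / 2.0


# ---------------------------------------------------------------------------
# Adducts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Adduct:
    """An electrospray adduct defining the neutral-mass -> m/z transform.

    ``mass_delta`` is the signed mass added to ``n * M`` and already includes
    the electron correction, so m/z = (n * M + mass_delta) / |charge|.
    """

    name: str
    polarity: str  # "positive" | "negative"
    multimer: int = 1
    mass_delta: float = 0.0
    charge: int = 1

    def __post_init__(self) -> None:
        if self.multimer < 1:
            raise ValueError("multimer must be >= 1")
        if self.charge == 0:
            raise ValueError("charge must be nonzero")
        sign_ok = (self.charge > 0) == (self.polarity == "positive")
        if not sign_ok:
            raise ValueError(f"polarity/charge mismatch for {self.name}")

    def mz(self, neutral_mass: float) -> float:
        return (self.multimer * neutral_mass + self.mass_delta) / abs(self.charge)

    def neutral_mass(self, mz: float) -> float:
        return (mz * abs(self.charge) - self.mass_delta) / self.multimer


_FA = monoisotopic_mass(parse_formula("CH2O2"))   # formic acid
_HAC = monoisotopic_mass(parse_formula("C2H4O2"))  # acetic acid
_NH4 = monoisotopic_mass(parse_formula("NH4")) - ELECTRON_MASS
_H2O = monoisotopic_mass(parse_formula("H2O"))
_NA = MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS
_K = MONOISOTOPIC_MASS["K"] - ELECTRON_MASS


def _registry() -> dict[str, Adduct]:
    pos = {
        "[M+H]+": (1, PROTON_MASS),
        "[M+NH4]+": (1, _NH4),
        "[M+Na]+": (1, _NA),
        "[M+K]+": (1, _K),
        "[2M+H]+": (2, PROTON_MASS),
        "[2M+NH4]+": (2, _NH4),
        "[2M+Na]+": (2, _NA),
        "[2M+K]+": (2, _K),
        # in-source water loss of the protonated molecule
        "[M+H-H2O]+": (1, PROTON_MASS - _H2O),
    }
    neg = {
        "[M-H]-": (1, -PROTON_MASS),
        "[M+FA-H]-": (1, _FA - PROTON_MASS),
        "[M+Hac-H]-": (1, _HAC - PROTON_MASS),
        "[2M-H]-": (2, -PROTON_MASS),
        "[2M+FA-H]-": (2, _FA - PROTON_MASS),
        "[2M+Hac-H]-": (2, _HAC - PROTON_MASS),
    }
    reg: dict[str, Adduct] = {}
    for name, (n, d) in pos.items():
        reg[name] = Adduct(name, "positive", n, d, +1)
    for name, (n, d) in neg.items():
        reg[name] = Adduct(name, "negative", n, d, -1)
    return reg


#: The default adduct registry: the ESI forms observed on QTOF screening of
#: packaging migrants (6 negative incl. formate/acetate and 2M forms, 8
#: positive incl. 2M forms, plus in-source water loss). User-extensible:
#: callers may pass their own mapping wherever a registry is accepted.
ADDUCTS: dict[str, Adduct] = _registry()


def adducts_for_polarity(polarity: str,
                         registry: Mapping[str, Adduct] | None = None
                         ) -> list[Adduct]:
    reg = registry if registry is not None else ADDUCTS
    return [a for a in reg.values() if a.polarity == polarity]


_ADDUCT_CANON = {re.sub(r"[\s]", "", k).lower(): k for k in ADDUCTS}
# synonyms seen across MSP dialects / vendor exports
_ADDUCT_SYNONYMS = {
    "[m+h]": "[M+H]+", "m+h": "[M+H]+", "[m+h]1+": "[M+H]+",
    "[m-h]": "[M-H]-", "m-h": "[M-H]-", "[m-h]1-": "[M-H]-",
    "[m+na]": "[M+Na]+", "[m+k]": "[M+K]+", "[m+nh4]": "[M+NH4]+",
    "[m+hcoo]-": "[M+FA-H]-", "[m+hcooh-h]-": "[M+FA-H]-",
    "[m+ch3coo]-": "[M+Hac-H]-", "[m+ch3cooh-h]-": "[M+Hac-H]-",
    "[m-h2o+h]+": "[M+H-H2O]+",
}


def normalize_adduct(name: str, polarity: str | None = None) -> str | None:
    """Map an adduct label to its registry name, or None if unrecognized.

    Whitespace-insensitive and case-insensitive; a missing trailing charge
    sign is resolved from ``polarity`` when given, else by trying + then -.
    """
    if not name:
        return None
    key = re.sub(r"\s", "", name).lower()
    if key in _ADDUCT_CANON:
        return _ADDUCT_CANON[key]
    if key in _ADDUCT_SYNONYMS:
        return _ADDUCT_SYNONYMS[key]
    suffixes = {"positive": ["+"], "negative": ["-"]}.get(polarity, ["+", "-"])
    for suf in suffixes:
        if key + suf in _ADDUCT_CANON:
            return _ADDUCT_CANON[key + suf]
        if key + suf in _ADDUCT_SYNONYMS:
            return _ADDUCT_SYNONYMS[key + suf]
    return None


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """m/z of a neutral molecule observed as ``adduct``."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return adduct.mz(neutral_mass)


def neutral_mass_from_mz(mz: float, adduct: Adduct | str) -> float:
    """Inverse of :func:`adduct_mz` (exact to floating-point rounding)."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    return adduct.neutral_mass(mz)


# ---------------------------------------------------------------------------
# Isotope patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopePattern:
    """A centroided isotope pattern normalized to base peak 1."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("empty isotope pattern")
        base = max(ab for _, ab in self.peaks)
        if abs(base - 1.0) > 1e-9:
            raise ValueError("pattern must be base-peak normalized")

    @property
    def base_mz(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]

    def abundance_at(self, offset: int, window: float = 0.5) -> float:
        """Relative abundance of the peak nearest base m/z + offset Da."""
        target = self.base_mz + offset * 1.00336
        best = 0.0
        for mz, ab in self.peaks:
            if abs(mz - target) <= window and ab > best:
                best = ab
        return best


_GRID = 1000  # aggregation granularity: 1 mDa


def _convolve(a: dict[int, float], b: dict[int, float],
              floor: float) -> dict[int, float]:
    out: dict[int, float] = {}
    for ka, va in a.items():
        for kb, vb in b.items():
            p = va * vb
            if p < floor:
                continue
            k = ka + kb
            out[k] = out.get(k, 0.0) + p
    return out


def isotope_pattern(comp: ElementComposition | str,
                    prune_threshold: float = 1e-4) -> IsotopePattern:
    """Simulate the isotope pattern of a composition.

    Iteratively convolves per-element isotope distributions (binary
    exponentiation per element), aggregating probability mass on a 1 mDa
    grid, then prunes peaks below ``prune_threshold`` of the base peak and
    normalizes the base peak to 1.
    """
    if isinstance(comp, str):
        comp = parse_formula(comp)
    if not (0 < prune_threshold < 1):
        raise ValueError("prune_threshold must be in (0, 1)")
    floor = 1e-12
    dist: dict[int, float] = {0: 1.0}
    for el, n in comp:
        single = {int(round(m * _GRID)): p for m, p in ISOTOPES[el]}
        # binary exponentiation of the single-atom distribution
        power = single
        k = n
        while k:
            if k & 1:
                dist = _convolve(dist, power, floor)
            k >>= 1
            if k:
                power = _convolve(power, power, floor)
    base = max(dist.values())
    peaks = sorted(
        (key / _GRID, p / base)
        for key, p in dist.items()
        if p / base >= prune_threshold
    )
    return IsotopePattern(tuple(peaks))


def theoretical_pattern_for_adduct(comp: ElementComposition | str,
                                   adduct: Adduct | str,
                                   prune_threshold: float = 1e-4
                                   ) -> IsotopePattern:
    """Isotope pattern shifted onto the m/z axis of the given adduct."""
    if isinstance(comp, str):
        comp = parse_formula(comp)
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    pat = isotope_pattern(comp, prune_threshold)
    mono = monoisotopic_mass(comp)
    shift = adduct.mz(mono) - mono
    # multimer patterns are approximated by the monomer envelope shift
    return IsotopePattern(tuple((mz + shift, ab) for mz, ab in pat.peaks))


# ---------------------------------------------------------------------------
# Formula enumeration from accurate mass
# ---------------------------------------------------------------------------

@dataclass
class FormulaCandidate:
    composition: ElementComposition
    adduct: Adduct
    ppm_error: float
    mass_error: float


#: Default plausibility heuristics for formula enumeration.
DEFAULT_RDBE_RANGE = (0.0, 40.0)
DEFAULT_MAX_H_PER_C = 4.0


def enumerate_formulas(
    target_mz: float,
    adducts: Sequence[Adduct | str],
    tol: float = 0.005,
    elements: Iterable[str] = ("C", "H", "O", "N", "P", "S", "F", "Cl"),
    bounds: Mapping[str, int] | None = None,
    rdbe_range: tuple[float, float] = DEFAULT_RDBE_RANGE,
    max_h_per_c: float = DEFAULT_MAX_H_PER_C,
) -> list[FormulaCandidate]:
    """Enumerate elemental formulas consistent with an observed m/z.

    Exhaustive within per-element ``bounds`` (defaulting to the ceiling
    implied by the neutral target mass divided by the element mass). A
    candidate is kept iff |adduct_mz(M, a) - target_mz| <= tol, its RDBE is a
    non-negative integer inside ``rdbe_range``, and H/C <= ``max_h_per_c``
    when carbon is present. Sorted by absolute mass error.
    """
    elements = list(elements)
    if not elements:
        raise ValueError("element set must be non-empty")
    if tol <= 0:
        raise ValueError("tol must be positive")
    resolved = [ADDUCTS[a] if isinstance(a, str) else a for a in adducts]

    results: list[FormulaCandidate] = []
    seen: set[tuple[str, str]] = set()
    for adduct in resolved:
        neutral_target = adduct.neutral_mass(target_mz)
        if neutral_target <= 0:
            continue
        neutral_tol = tol * abs(adduct.charge) / adduct.multimer
        # search heavy elements first, hydrogen last, pruning on residual mass
        order = sorted(
            (el for el in elements if el != "H"),
            key=lambda el: -MONOISOTOPIC_MASS[el],
        )
        has_h = "H" in elements
        lim = {
            el: min(
                int((neutral_target + neutral_tol) // MONOISOTOPIC_MASS[el]),
                (bounds or {}).get(el, 10**9),
            )
            for el in elements
        }

        counts: dict[str, int] = {}

        def emit(mass: float) -> None:
            resid = neutral_target - mass
            if has_h:
                h_mass = MONOISOTOPIC_MASS["H"]
                lo = int(max(0, (resid - neutral_tol) // h_mass))
                hi = int((resid + neutral_tol) // h_mass) + 1
                h_range = [
                    h for h in range(lo, hi + 1)
                    if h <= lim["H"]
                    and abs(mass + h * h_mass - neutral_target) <= neutral_tol
                ]
            else:
                h_range = [0] if abs(resid) <= neutral_tol else []
            for h in h_range:
                full = dict(counts)
                if h:
                    full["H"] = h
                if not full:
                    continue
                comp = ElementComposition(full)
                r = rdbe(comp)
                if r < rdbe_range[0] - 1e-9 or r > rdbe_range[1] + 1e-9:
                    continue
                if abs(r - round(r)) > 1e-6:
                    continue
                c = comp["C"]
                if c and comp["H"] / c > max_h_per_c:
                    continue
                key = (serialize_formula(comp), adduct.name)
                if key in seen:
                    continue
                seen.add(key)
                err = adduct.mz(monoisotopic_mass(comp)) - target_mz
                results.append(
                    FormulaCandidate(comp, adduct, 1e6 * err / target_mz, err)
                )

        def walk(idx: int, mass: float) -> None:
            if idx == len(order):
                emit(mass)
                return
            el = order[idx]
            el_mass = MONOISOTOPIC_MASS[el]
            max_n = min(lim[el], int((neutral_target + neutral_tol - mass) // el_mass))
            for n in range(0, max_n + 1):
                if n:
                    counts[el] = n
                walk(idx + 1, mass + n * el_mass)
            counts.pop(el, None)

        walk(0, 0.0)

    results.sort(key=lambda c: (abs(c.mass_error), c.composition.hill_formula()))
    return results
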