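"""Compound annotation by spectral-library match and weighted database search.

Two evidence routes are combined. (1) Spectral matching against a curated
MS/MS library: a composite identification score in [0, 100] built from the
cosine similarity, the reverse cosine (reference-peak restricted), and the
fraction of reference peaks matched, with an 80% default cutoff. (2)
Precursor-oriented structure-database search for features without a library
hit: candidate entries whose theoretical adduct m/z falls inside the MS1
tolerance are scored on mass error, isotope-pattern agreement, and the
fraction of MS2 intensity explainable as sub-formulas of the candidate, then
weighted by database priority (e.g. 2 / 1.5 / 1 for a sample-specific GC-MS
list, a packaging-chemicals list, and a generic database). ``merge_annotations``
resolves every feature to library_match, db_annotated, or unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import chemcore
from .chemcore import (
    ADDUCTS,
    Adduct,
    ElementComposition,
    IsotopePattern,
    PROTON_MASS,
    adducts_for_polarity,
    monoisotopic_mass,
    parse_formula,
    rdbe,
)
from .masses import MONOISOTOPIC_MASS
from .speclib import SpectralLibrary

Peak = tuple[float, float]


# ---------------------------------------------------------------------------
# Structure databases
# ---------------------------------------------------------------------------

@dataclass
class DbEntry:
    name: str
    formula: str
    exact_mass: float
    inchikey: str = ""
    smiles: str = ""
    cas: str = ""


@dataclass
class StructureDatabase:
    """A weighted candidate-structure collection (e.g. volDB / cppDB / genDB).

    ``weight`` multiplies the base score of every hit from this database, so
    sample-relevant lists outrank generic ones at equal spectral evidence.
    """

    label: str
    weight: float
    entries: list[DbEntry]

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("database weight must be positive")
        for e in self.entries:
            if e.formula and e.exact_mass:
                theo = monoisotopic_mass(parse_formula(e.formula))
                if abs(theo - e.exact_mass) > 0.001:
                    raise ValueError(
                        f"{self.label}/{e.name}: exact_mass {e.exact_mass} "
                        f"disagrees with formula {e.formula} ({theo:.4f})")
            elif e.formula:
                e.exact_mass = monoisotopic_mass(parse_formula(e.formula))

    @classmethod
    def from_tsv(cls, path: str | Path, label: str, weight: float
                 ) -> "StructureDatabase":
        """Read the tab-separated layout (name, formula, exact mass,
        InChIKey, SMILES, CAS); a header line is detected and skipped."""
        entries = []
        for i, line in enumerate(Path(path).read_text().splitlines()):
            if not line.strip():
                continue
            cells = (line.split("\t") + [""] * 6)[:6]
            if i == 0 and cells[0].strip().lower() == "name":
                continue
            entries.append(DbEntry(
                name=cells[0].strip(), formula=cells[1].strip(),
                exact_mass=float(cells[2]) if cells[2].strip() else 0.0,
                inchikey=cells[3].strip(), smiles=cells[4].strip(),
                cas=cells[5].strip()))
        return cls(label=label, weight=weight, entries=entries)

    def to_tsv(self, path: str | Path) -> None:
        lines = ["name\tformula\texact_mass\tinchikey\tsmiles\tcas"]
        for e in self.entries:
            lines.append(f"{e.name}\t{e.formula}\t{e.exact_mass:.5f}\t"
                         f"{e.inchikey}\t{e.smiles}\t{e.cas}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class CandidateAnnotation:
    feature_id: str
    name: str
    source: str  # "library_match" | "db_search"
    final_score: float
    rank: int = 0
    db_label: str = ""
    db_weight: float = 1.0
    adduct: str = ""
    formula: str = ""
    scores: dict[str, float] = field(default_factory=dict)
    entry: object = None


# ---------------------------------------------------------------------------
# Spectral matching
# ---------------------------------------------------------------------------

def _pair_peaks(query: Sequence[Peak], ref: Sequence[Peak],
                tol: float) -> list[tuple[int, int]]:
    """Greedy nearest-m/z pairing within ``tol``; each peak used once.

    Candidate pairs are taken in order of increasing m/z gap, which is
    deterministic and reproducible by a brute-force oracle.
    """
    cands = []
    for qi, (qmz, _) in enumerate(query):
        for ri, (rmz, _) in enumerate(ref):
            gap = abs(qmz - rmz)
            if gap <= tol:
                cands.append((gap, qi, ri))
    cands.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _, qi, ri in cands:
        if qi in used_q or ri in used_r:
            continue
        pairs.append((qi, ri))
        used_q.add(qi)
        used_r.add(ri)
    return pairs


def _cosine(qv: np.ndarray, rv: np.ndarray) -> float:
    nq = np.linalg.norm(qv)
    nr = np.linalg.norm(rv)
    if nq == 0 or nr == 0:
        return 0.0
    return float(np.dot(qv, rv) / (nq * nr))


def composite_spectral_score(query: Sequence[Peak], ref: Sequence[Peak],
                             ms2_tol: float = 0.025,
                             weights: tuple[float, float, float] = (0.5, 0.25, 0.25)
                             ) -> tuple[float, dict[str, float]]:
    """Identification score in [0, 100].

    ``weights`` combine (cosine, reverse cosine, matched-reference-peak
    fraction). The cosine aligns both spectra (unmatched peaks are zeros on
    the other side); the reverse cosine is restricted to reference peaks, so
    extra query peaks (chimeric noise) do not punish it.
    """
    pairs = _pair_peaks(query, ref, ms2_tol)
    matched_q = {qi: ri for qi, ri in pairs}
    matched_r = {ri for _, ri in pairs}

    # full alignment vectors: one row per matched pair + unmatched singletons
    qv, rv = [], []
    for qi, ri in pairs:
        qv.append(query[qi][1])
        rv.append(ref[ri][1])
    for qi, (_, qint) in enumerate(query):
        if qi not in matched_q:
            qv.append(qint)
            rv.append(0.0)
    for ri, (_, rint) in enumerate(ref):
        if ri not in matched_r:
            qv.append(0.0)
            rv.append(rint)
    cos = _cosine(np.asarray(qv), np.asarray(rv))

    # reverse: reference peaks only
    qv_rev = np.zeros(len(ref))
    rv_rev = np.array([i for _, i in ref], dtype=float)
    for qi, ri in pairs:
        qv_rev[ri] = query[qi][1]
    rev = _cosine(qv_rev, rv_rev)

    frac = len(matched_r) / len(ref) if ref else 0.0
    w_cos, w_rev, w_frac = weights
    score = 100.0 * (w_cos * cos + w_rev * rev + w_frac * frac)
    return score, {"cosine": cos, "reverse": rev, "matched_fraction": frac}


def spectral_match(feature_id: str, precursor_mz: float, ms2: Sequence[Peak],
                   lib: SpectralLibrary, ms1_tol: float = 0.01,
                   ms2_tol: float = 0.025, cutoff: float = 80.0
                   ) -> list[CandidateAnnotation]:
    """Match a feature's MS2 spectrum against a spectral library.

    Library records within ``ms1_tol`` of the precursor are scored with
    :func:`composite_spectral_score`; only scores >= ``cutoff`` are
    returned, best first.
    """
    if not ms2:
        raise ValueError("query feature has no MS2 spectrum")
    hits = []
    for rec in lib:
        if rec.precursor_mz is None:
            continue
        if abs(rec.precursor_mz - precursor_mz) > ms1_tol:
            continue
        score, parts = composite_spectral_score(ms2, rec.peaks, ms2_tol)
        if score >= cutoff:
            hits.append(CandidateAnnotation(
                feature_id=feature_id, name=rec.name, source="library_match",
                final_score=score, adduct=rec.precursor_type or "",
                formula=rec.formula or "", scores=parts, entry=rec))
    hits.sort(key=lambda h: (-h.final_score, h.name.lower()))
    for i, h in enumerate(hits, start=1):
        h.rank = i
    return hits


# ---------------------------------------------------------------------------
# Sub-scores for database search
# ---------------------------------------------------------------------------

def isotope_score(measured: IsotopePattern, theoretical: IsotopePattern) -> float:
    """1 - mean |difference| of the A+1 and A+2 relative abundances,
    clamped to [0, 1]. A pattern missing a peak contributes abundance 0."""
    diffs = [
        abs(measured.abundance_at(k) - theoretical.abundance_at(k))
        for k in (1, 2)
    ]
    return float(np.clip(1.0 - np.mean(diffs), 0.0, 1.0))


def _subformula_exists(target: float, comp: ElementComposition,
                       tol: float) -> bool:
    """DFS: does a sub-composition of ``comp`` (RDBE >= -0.5) have
    monoisotopic mass within ``tol`` of ``target``?"""
    elements = sorted(comp.counts, key=lambda el: -MONOISOTOPIC_MASS[el])

    def walk(idx: int, mass: float, counts: dict[str, int]) -> bool:
        if mass > target + tol:
            return False
        if idx == len(elements):
            if abs(mass - target) <= tol and counts:
                sub = ElementComposition(dict(counts))
                return rdbe(sub) >= -0.5
            return False
        el = elements[idx]
        el_mass = MONOISOTOPIC_MASS[el]
        # residual upper bound: all remaining elements at full count
        remaining = sum(
            comp[e] * MONOISOTOPIC_MASS[e] for e in elements[idx + 1:]
        )
        for n in range(comp[el], -1, -1):
            m = mass + n * el_mass
            if m > target + tol:
                continue
            if m + remaining < target - tol:
                break
            if n:
                counts[el] = n
            else:
                counts.pop(el, None)
            if walk(idx + 1, m, counts):
                counts.pop(el, None)
                return True
        counts.pop(el, None)
        return False

    return walk(0, 0.0, {})


def subformula_fragment_score(candidate: ElementComposition | str,
                              adduct: Adduct | str, ms2: Sequence[Peak],
                              ms2_tol: float = 0.025) -> float:
    """Fraction of MS2 intensity explainable by candidate sub-formulas.

    Each product ion is tested as (sub-formula mass + charge carrier), the
    carrier being a proton for positive adducts and a proton loss for
    negative ones. This is a formula-level stand-in for structure-based
    fragmentation: it asks whether fragments are *elementally* consistent
    with the candidate. Invariant to intensity rescaling.
    """
    if not ms2:
        raise ValueError("empty MS2 spectrum")
    if isinstance(candidate, str):
        candidate = parse_formula(candidate)
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    carrier = PROTON_MASS if adduct.polarity == "positive" else -PROTON_MASS
    total = sum(i for _, i in ms2)
    if total == 0:
        return 0.0
    explained = 0.0
    for mz, inten in ms2:
        target = mz - carrier
        if target <= 0:
            continue
        if _subformula_exists(target, candidate, ms2_tol):
            explained += inten
    return explained / total


# ---------------------------------------------------------------------------
# Precursor-oriented database search
# ---------------------------------------------------------------------------

def db_search(feature_id: str, precursor_mz: float, polarity: str,
              dbs: Sequence[StructureDatabase],
              adduct_hypotheses: Sequence[Adduct | str] | None = None,
              ms2: Sequence[Peak] | None = None,
              measured_pattern: IsotopePattern | None = None,
              ms1_tol: float = 0.005, ms2_tol: float = 0.025,
              base_scale: float = 10.0) -> list[CandidateAnnotation]:
    """Precursor-oriented candidate search over weighted structure databases.

    For each adduct hypothesis (default: every registry adduct of the
    feature's polarity), entries whose theoretical adduct m/z lies within
    ``ms1_tol`` are scored. The base score is the mean of the available
    sub-scores (mass error, isotope agreement, fragment explanation) scaled
    to ``base_scale``; the final score multiplies in the database weight.
    Missing evidence (no isotope pattern / no MS2) is excluded from the mean
    rather than zeroed. Ties resolve to the higher-weight database, then
    name.
    """
    if not dbs:
        raise ValueError("no structure databases configured")
    if adduct_hypotheses is None:
        hypotheses: list[Adduct] = adducts_for_polarity(polarity)
    else:
        hypotheses = [ADDUCTS[a] if isinstance(a, str) else a
                      for a in adduct_hypotheses]

    out: list[CandidateAnnotation] = []
    for db in dbs:
        for entry in db.entries:
            if not entry.exact_mass:
                continue
            best = None  # (final, adduct, subscores)
            for adduct in hypotheses:
                theo = adduct.mz(entry.exact_mass)
                err = theo - precursor_mz
                if abs(err) > ms1_tol:
                    continue
                subs = {"formula": max(0.0, 1.0 - abs(err) / ms1_tol)}
                if measured_pattern is not None and entry.formula:
                    theo_pat = chemcore.theoretical_pattern_for_adduct(
                        entry.formula, adduct)
                    subs["isotope"] = isotope_score(measured_pattern, theo_pat)
                if ms2 and entry.formula:
                    subs["fragment"] = subformula_fragment_score(
                        entry.formula, adduct, ms2, ms2_tol)
                base = base_scale * float(np.mean(list(subs.values())))
                final = base * db.weight
                if best is None or final > best[0]:
                    best = (final, adduct, subs)
            if best is not None:
                final, adduct, subs = best
                out.append(CandidateAnnotation(
                    feature_id=feature_id, name=entry.name, source="db_search",
                    final_score=final, db_label=db.label, db_weight=db.weight,
                    adduct=adduct.name, formula=entry.formula,
                    scores=subs, entry=entry))
    out.sort(key=lambda c: (-c.final_score, -c.db_weight, c.name.lower()))
    for i, c in enumerate(out, start=1):
        c.rank = i
    return out


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

@dataclass
class FeatureAnnotation:
    feature_id: str
    status: str  # "library_match" | "db_annotated" | "unknown"
    best: CandidateAnnotation | None


def merge_annotations(feature_id: str,
                      library_hits: Sequence[CandidateAnnotation],
                      db_hits: Sequence[CandidateAnnotation]
                      ) -> FeatureAnnotation:
    """Resolve one feature: a library match above the cutoff always beats a
    database annotation; otherwise the best weighted database candidate; else
    unknown."""
    if library_hits:
        return FeatureAnnotation(feature_id, "library_match", library_hits[0])
    if db_hits:
        return FeatureAnnotation(feature_id, "db_annotated", db_hits[0])
    return FeatureAnnotation(feature_id, "unknown", None)


def annotations_to_frame(annotations: Iterable[FeatureAnnotation]) -> pd.DataFrame:
    """Result table mirroring suspect-screening report layout."""
    rows = []
    for ann in annotations:
        best = ann.best
        rows.append({
            "feature_id": ann.feature_id,
            "status": ann.status,
            "name": best.name if best else "",
            "formula": best.formula if best else "",
            "adduct": best.adduct if best else "",
            "score": round(best.final_score, 2) if best else np.nan,
            "source": (best.db_label or best.source) if best else "",
        })
    return pd.DataFrame(rows)
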