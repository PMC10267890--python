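"""MS/MS spectral-library compilation (MSP dialects in, one clean library out).

Workflow: ``read_msp`` one or more source libraries (NIST- or MS-DIAL-style
MSP; dialect differences are absorbed by a key-synonym table), harmonize each
record (adduct labels, canonical formulas, base-peak-100 intensities,
precursor/formula consistency flags), then ``compile_libraries`` to merge and
deduplicate by (InChIKey, adduct, collision energy) with a source-priority
rule. ``export_transitions`` turns the compiled library into a pseudo-MRM
transition list (top-N product ions per compound).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from . import chemcore
from .chemcore import FormulaError, normalize_adduct


class MspParseError(ValueError):
    """Malformed MSP input; message carries block index and offending line."""


Peak = tuple[float, float]


@dataclass
class SpectrumRecord:
    """One annotated MS/MS spectrum with compound metadata."""

    name: str
    peaks: list[Peak]
    precursor_mz: float | None = None
    precursor_type: str | None = None
    ion_mode: str | None = None  # "positive" | "negative"
    formula: str | None = None
    inchikey: str | None = None
    smiles: str | None = None
    cas: str | None = None
    retention_time: float | None = None
    collision_energy: str | None = None
    provenance: str = ""
    extra: dict[str, str] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"record {self.name!r} has an empty peak list")
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"record {self.name!r} has negative intensity")

    @property
    def base_intensity(self) -> float:
        return max(i for _, i in self.peaks)

    def identity_key(self) -> tuple[str, str, str]:
        """Deduplication key: InChIKey (first block if that is all we have,
        else full key), adduct label, collision-energy string."""
        if self.inchikey:
            ident = self.inchikey.strip()
            if len(ident) < 27:  # first block only
                ident = ident.split("-")[0]
        else:
            ident = self.name.strip().lower()
        return (ident, self.precursor_type or "", self.collision_energy or "")


@dataclass
class SpectralLibrary:
    records: list[SpectrumRecord]
    dialect: str = "canonical"

    @property
    def polarity(self) -> str:
        modes = {r.ion_mode for r in self.records if r.ion_mode}
        if len(modes) == 1:
            return next(iter(modes))
        return "mixed" if modes else "unknown"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def split_by_polarity(self) -> dict[str, "SpectralLibrary"]:
        out: dict[str, list[SpectrumRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.ion_mode or "unknown", []).append(rec)
        return {
            mode: SpectralLibrary(recs, self.dialect)
            for mode, recs in out.items()
        }


# --- MSP dialect handling --------------------------------------------------

_KEY_SYNONYMS = {
    "name": "name",
    "synon": "synon",
    "precursormz": "precursor_mz",
    "precursor m/z": "precursor_mz",
    "precursor_mz": "precursor_mz",
    "precursortype": "precursor_type",
    "precursor_type": "precursor_type",
    "adduct": "precursor_type",
    "adductionname": "precursor_type",
    "ionmode": "ion_mode",
    "ion_mode": "ion_mode",
    "ionization mode": "ion_mode",
    "formula": "formula",
    "molecular formula": "formula",
    "inchikey": "inchikey",
    "smiles": "smiles",
    "cas": "cas",
    "cas#": "cas",
    "casno": "cas",
    "cas number": "cas",
    "retentiontime": "retention_time",
    "retention_time": "retention_time",
    "rt": "retention_time",
    "collisionenergy": "collision_energy",
    "collision_energy": "collision_energy",
    "ce": "collision_energy",
    "num peaks": "num_peaks",
    "numpeaks": "num_peaks",
    "num_peaks": "num_peaks",
}

_ION_MODE_ALIASES = {
    "positive": "positive", "pos": "positive", "p": "positive", "+": "positive",
    "negative": "negative", "neg": "negative", "n": "negative", "-": "negative",
}

_PEAK_LINE = re.compile(r"^\s*([0-9.eE+-]+)[\s,;\t]+([0-9.eE+-]+)")


def _parse_block(lines: list[str], block_index: int, source: str,
                 peak_policy: str) -> SpectrumRecord:
    fields: dict[str, str] = {}
    extra: dict[str, str] = {}
    peaks: list[Peak] = []
    declared: int | None = None
    in_peaks = False
    for line in lines:
        if in_peaks:
            m = _PEAK_LINE.match(line)
            if not m:
                raise MspParseError(
                    f"block {block_index}: bad peak line {line.strip()!r}")
            peaks.append((float(m.group(1)), float(m.group(2))))
            continue
        if ":" not in line:
            raise MspParseError(
                f"block {block_index}: expected 'Key: value', got {line.strip()!r}")
        raw_key, value = line.split(":", 1)
        key = _KEY_SYNONYMS.get(raw_key.strip().lower())
        value = value.strip()
        if key is None:
            extra[raw_key.strip()] = value
        elif key == "num_peaks":
            declared = int(value)
            in_peaks = True
        else:
            fields[key] = value
    if declared is None:
        raise MspParseError(f"block {block_index}: missing 'Num Peaks' line")
    flags: set[str] = set()
    if len(peaks) != declared:
        if peak_policy == "error":
            raise MspParseError(
                f"block {block_index}: declared {declared} peaks, found {len(peaks)}")
        flags.add("peak_count_mismatch")
        peaks = peaks[:declared] if len(peaks) > declared else peaks
    if not peaks:
        raise MspParseError(f"block {block_index}: no peaks")
    if "name" not in fields:
        raise MspParseError(f"block {block_index}: missing Name")

    def _float(key: str) -> float | None:
        v = fields.get(key)
        if v is None:
            return None
        try:
            return float(v)
        except ValueError:
            return None

    ion_mode = fields.get("ion_mode")
    if ion_mode:
        ion_mode = _ION_MODE_ALIASES.get(ion_mode.strip().lower(), ion_mode)
    return SpectrumRecord(
        name=fields["name"],
        peaks=peaks,
        precursor_mz=_float("precursor_mz"),
        precursor_type=fields.get("precursor_type"),
        ion_mode=ion_mode,
        formula=fields.get("formula"),
        inchikey=fields.get("inchikey"),
        smiles=fields.get("smiles"),
        cas=fields.get("cas"),
        retention_time=_float("retention_time"),
        collision_energy=fields.get("collision_energy"),
        provenance=source,
        extra=extra,
        flags=flags,
    )


def read_msp(path: str | Path | io.TextIOBase, dialect: str = "auto",
             source: str | None = None,
             peak_count_policy: str = "truncate") -> SpectralLibrary:
    """Parse an MSP file into a :class:`SpectralLibrary`.

    ``dialect`` is advisory ("nist", "msdial", "auto"): header keys are
    resolved case-insensitively through one synonym table either way, and
    unrecognized keys are preserved in each record's ``extra`` map.
    ``peak_count_policy`` governs declared-vs-found peak-count mismatches:
    "truncate" (flag and truncate/keep) or "error".
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
        label = source or "stream"
    else:
        p = Path(path)
        text = p.read_text()
        label = source or p.stem
    records: list[SpectrumRecord] = []
    block: list[str] = []
    index = 0
    for line in text.splitlines() + [""]:
        if line.strip():
            block.append(line)
        elif block:
            records.append(_parse_block(block, index, label, peak_count_policy))
            block = []
            index += 1
    return SpectralLibrary(records, dialect=dialect)


_CANONICAL_ORDER = [
    ("NAME", "name"),
    ("PRECURSORMZ", "precursor_mz"),
    ("PRECURSORTYPE", "precursor_type"),
    ("IONMODE", "ion_mode"),
    ("FORMULA", "formula"),
    ("INCHIKEY", "inchikey"),
    ("SMILES", "smiles"),
    ("CASNO", "cas"),
    ("RETENTIONTIME", "retention_time"),
    ("COLLISIONENERGY", "collision_energy"),
    ("COMMENT", "provenance"),
]


def write_msp(lib: SpectralLibrary, path: str | Path | io.TextIOBase,
              dialect: str = "canonical",
              split_polarity: bool = False) -> list[Path]:
    """Write a library to MSP. Canonical dialect round-trips losslessly.

    With ``split_polarity`` (file paths only), one file per ion mode is
    written with ``.pos`` / ``.neg`` inserted before the suffix; the list of
    written paths is returned.
    """
    if split_polarity:
        if isinstance(path, io.TextIOBase):
            raise ValueError("split_polarity requires a file path")
        out = []
        for mode, sub in lib.split_by_polarity().items():
            tag = {"positive": "pos", "negative": "neg"}.get(mode, mode)
            p = Path(path)
            target = p.with_name(f"{p.stem}.{tag}{p.suffix}")
            write_msp(sub, target, dialect=dialect)
            out.append(target)
        return out

    buf = io.StringIO()
    for rec in lib.records:
        for key, attr in _CANONICAL_ORDER:
            value = getattr(rec, attr)
            if value is None or value == "":
                continue
            if attr in ("precursor_mz", "retention_time"):
                value = repr(float(value))  # shortest exact round-trip form
            buf.write(f"{key}: {value}\n")
        for key, value in rec.extra.items():
            buf.write(f"{key}: {value}\n")
        buf.write(f"Num Peaks: {len(rec.peaks)}\n")
        for mz, inten in rec.peaks:
            buf.write(f"{float(mz)!r}\t{float(inten)!r}\n")
        buf.write("\n")
    text = buf.getvalue()
    if isinstance(path, io.TextIOBase):
        path.write(text)
        return []
    Path(path).write_text(text)
    return [Path(path)]


# --- harmonization and compilation ----------------------------------------

def harmonize_record(rec: SpectrumRecord,
                     consistency_tol: float = 0.01) -> SpectrumRecord:
    """Normalize a parsed record in place of vendor idiosyncrasies.

    Adduct labels are mapped to registry names, formulas re-serialized to
    canonical Hill order, intensities rescaled to base peak 100, and a
    ``precursor_inconsistent`` flag is set when formula + adduct + precursor
    m/z disagree by more than ``consistency_tol`` Da. Problems are flagged,
    never fatal.
    """
    flags = set(rec.flags)
    adduct = rec.precursor_type
    if adduct:
        norm = normalize_adduct(adduct, rec.ion_mode)
        if norm is None:
            flags.add("unknown_adduct")
        else:
            adduct = norm
    formula = rec.formula
    comp = None
    if formula:
        try:
            comp = chemcore.parse_formula(formula)
            formula = comp.hill_formula()
        except FormulaError:
            flags.add("unparseable_formula")
    ion_mode = rec.ion_mode
    if adduct and adduct in chemcore.ADDUCTS:
        pol = chemcore.ADDUCTS[adduct].polarity
        if ion_mode and ion_mode != pol:
            flags.add("ion_mode_conflict")
        ion_mode = ion_mode or pol
    if (comp is not None and rec.precursor_mz
            and adduct in chemcore.ADDUCTS):
        theo = chemcore.adduct_mz(chemcore.monoisotopic_mass(comp), adduct)
        if abs(theo - rec.precursor_mz) > consistency_tol:
            flags.add("precursor_inconsistent")
    if rec.precursor_mz and any(
            mz > rec.precursor_mz + 0.5 for mz, _ in rec.peaks):
        flags.add("peaks_above_precursor")
    base = rec.base_intensity
    peaks = [(mz, 100.0 * i / base) for mz, i in rec.peaks] if base else rec.peaks
    return replace(rec, peaks=peaks, precursor_type=adduct, formula=formula,
                   ion_mode=ion_mode, flags=flags)


def harmonize(lib: SpectralLibrary, **kwargs) -> SpectralLibrary:
    return SpectralLibrary(
        [harmonize_record(r, **kwargs) for r in lib.records], lib.dialect)


def deduplicate(lib: SpectralLibrary,
                priority: Sequence[str] = ()) -> SpectralLibrary:
    """One record per (identity, adduct, collision energy) key.

    The survivor is chosen by source priority (earlier in ``priority`` wins;
    unlisted sources rank last), then highest peak count, then lower
    precursor m/z, then name. Idempotent.
    """
    rank = {label: i for i, label in enumerate(priority)}

    def quality(rec: SpectrumRecord):
        return (
            rank.get(rec.provenance, len(rank)),
            -len(rec.peaks),
            rec.precursor_mz if rec.precursor_mz is not None else float("inf"),
            rec.name.lower(),
        )

    best: dict[tuple, SpectrumRecord] = {}
    order: list[tuple] = []
    for rec in lib.records:
        key = rec.identity_key()
        if key not in best:
            best[key] = rec
            order.append(key)
        elif quality(rec) < quality(best[key]):
            best[key] = rec
    return SpectralLibrary([best[k] for k in order], lib.dialect)


def compile_libraries(libs: Iterable[SpectralLibrary],
                      priority: Sequence[str] = (),
                      allow_mixed_polarity: bool = False) -> SpectralLibrary:
    """Concatenate, deduplicate, and polarity-check source libraries.

    The merge result is stable under permutation of the input order for a
    fixed ``priority``. Mixed polarities are an error unless
    ``allow_mixed_polarity`` (callers then typically ``split_by_polarity``).
    """
    records: list[SpectrumRecord] = []
    for lib in libs:
        records.extend(lib.records)
    records.sort(key=lambda r: (r.name.lower(),
                                r.precursor_mz or 0.0, r.provenance))
    merged = deduplicate(SpectralLibrary(records), priority)
    if merged.polarity == "mixed" and not allow_mixed_polarity:
        raise ValueError(
            "mixed-polarity compilation; pass allow_mixed_polarity=True "
            "and split_by_polarity() before export")
    return merged


# --- transition export -----------------------------------------------------

@dataclass
class TransitionEntry:
    name: str
    precursor_mz: float
    reference_rt: float | None
    ion_mode: str | None
    transitions: list[tuple[float, float]]  # (product m/z, rel intensity)
    flags: set[str] = field(default_factory=set)


@dataclass
class TransitionLibrary:
    """Per-compound precursor + top product ions for pseudo-MRM screening."""

    entries: list[TransitionEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def export_transitions(lib: SpectralLibrary, top_n: int = 5,
                       rt_source: str = "retention_time") -> TransitionLibrary:
    """Select each compound's ``top_n`` most intense product ions.

    Intensities are normalized so the strongest transition is 100; ties at
    the cut rank resolve to the lower m/z. Records without a reference RT are
    exported with RT absent and flagged.
    """
    entries = []
    for rec in lib.records:
        if rec.precursor_mz is None:
            continue
        ranked = sorted(rec.peaks, key=lambda p: (-p[1], p[0]))[:top_n]
        top = ranked[0][1]
        transitions = [(mz, 100.0 * i / top) for mz, i in ranked]
        rt = getattr(rec, rt_source, None)
        flags = {"missing_rt"} if rt is None else set()
        entries.append(TransitionEntry(
            name=rec.name, precursor_mz=rec.precursor_mz, reference_rt=rt,
            ion_mode=rec.ion_mode, transitions=transitions, flags=flags))
    return TransitionLibrary(entries)


def write_transitions(tlib: TransitionLibrary, path: str | Path) -> Path:
    """Tab-separated transition list: compound, precursor, product, relative
    intensity, reference RT (empty when absent)."""
    lines = ["compound\tprecursor_mz\tproduct_mz\trel_intensity\trt"]
    for e in tlib.entries:
        rt = "" if e.reference_rt is None else f"{e.reference_rt:.4f}"
        for mz, rel in e.transitions:
            lines.append(
                f"{e.name}\t{e.precursor_mz:.5f}\t{mz:.5f}\t{rel:.4f}\t{rt}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_transitions(path: str | Path) -> TransitionLibrary:
    entries: dict[tuple[str, float], TransitionEntry] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        name, prec, prod, rel, rt = line.split("\t")
        key = (name, float(prec))
        if key not in entries:
            entries[key] = TransitionEntry(
                name=name, precursor_mz=float(prec),
                reference_rt=float(rt) if rt else None,
                ion_mode=None, transitions=[],
                flags=set() if rt else {"missing_rt"})
        entries[key].transitions.append((float(prod), float(rel)))
    return TransitionLibrary(list(entries.values()))
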