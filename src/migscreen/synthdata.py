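"""Seeded generators for every input the screening pipeline consumes.

The generators emulate the statistical structure the cleaning and screening
stages assume: log-normal compound abundances with multiplicative noise (so
adduct features of one compound correlate across samples, and ratio / RSD
filters see realistic dispersion), pooled-QC columns that are near-means of
the samples, procedural blanks at a configured background level, co-eluting
in-source fragments sharing the parent's abundance, and DIA runs with
Gaussian transition peaks at library ion ratios over a white-noise baseline.

Everything is a pure function of (parameters, seed): fixed inputs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemcore import ElementComposition, adduct_mz, monoisotopic_mass, rdbe
from .features import META_COLUMNS, FeatureTable
from .masses import PROTON_MASS
from .pseudomrm import DIARun, Trace
from .speclib import (
    SpectralLibrary,
    SpectrumRecord,
    TransitionLibrary,
)


@dataclass
class SyntheticCompound:
    """Ground truth for one simulated compound."""

    name: str
    formula: str
    ion_mode: str
    precursor_adduct: str
    reference_rt: float
    base_abundance: float
    fragments: list[tuple[float, float]]  # (m/z, relative intensity)
    adducts: list[tuple[str, float]] = field(default_factory=list)  # (name, response)
    has_insource_fragment: bool = False

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def precursor_mz(self) -> float:
        return adduct_mz(self.neutral_mass, self.precursor_adduct)


# ---------------------------------------------------------------------------
# Compounds and spectral libraries
# ---------------------------------------------------------------------------

def _random_composition(rng: np.random.Generator) -> ElementComposition:
    """A CHNO(+S/Cl) composition with an integer RDBE in [1, 12]."""
    while True:
        c = int(rng.integers(6, 26))
        n = int(rng.choice([0, 0, 0, 1, 1, 2]))
        o = int(rng.integers(0, 6))
        cl = int(rng.random() < 0.1)
        s = int(rng.random() < 0.08)
        max_r = (2 + 2 * c + n - cl - 1) // 2
        r = int(rng.integers(1, min(12, max_r) + 1))
        h = 2 + 2 * c + n - cl - 2 * r
        if h < 1 or h > 2 * c + 2:
            continue
        counts = {"C": c, "H": h}
        for el, k in (("N", n), ("O", o), ("S", s), ("Cl", cl)):
            if k:
                counts[el] = k
        comp = ElementComposition(counts)
        if rdbe(comp) >= 0 and abs(rdbe(comp) - round(rdbe(comp))) < 1e-9:
            return comp


def _random_subformula(rng: np.random.Generator,
                       comp: ElementComposition) -> ElementComposition | None:
    counts = {}
    for el, k in comp:
        n = int(rng.integers(0, k + 1))
        if n:
            counts[el] = n
    if not counts or counts == dict(comp.counts):
        return None
    sub = ElementComposition(counts)
    if rdbe(sub) < -0.5:
        return None
    return sub


def _fake_inchikey(rng: np.random.Generator) -> str:
    letters = np.array(list(string.ascii_uppercase))
    a = "".join(rng.choice(letters, 14))
    b = "".join(rng.choice(letters, 10))
    return f"{a}-{b}-N"


def make_compounds(n_compounds: int, seed: int, ion_mode: str = "positive",
                   insource_fraction: float = 0.0) -> list[SyntheticCompound]:
    """Generate ``n_compounds`` ground-truth compounds (deterministic per seed)."""
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    rng = np.random.default_rng(seed)
    carrier = PROTON_MASS if ion_mode == "positive" else -PROTON_MASS
    precursor_adduct = "[M+H]+" if ion_mode == "positive" else "[M-H]-"
    secondary = "[M+Na]+" if ion_mode == "positive" else "[M+FA-H]-"
    compounds = []
    for i in range(n_compounds):
        comp = _random_composition(rng)
        n_frag = int(rng.integers(5, 9))
        frags: list[tuple[float, float]] = []
        guard = 0
        while len(frags) < n_frag and guard < 200:
            guard += 1
            sub = _random_subformula(rng, comp)
            if sub is None:
                continue
            mz = monoisotopic_mass(sub) + carrier
            if mz < 50:
                continue
            frags.append((round(mz, 4), float(rng.uniform(10, 100))))
        frags.sort()
        top = max(i for _, i in frags)
        frags = [(m, 100.0 * v / top) for m, v in frags]
        compounds.append(SyntheticCompound(
            name=f"SYN-{i + 1:04d}",
            formula=comp.hill_formula(),
            ion_mode=ion_mode,
            precursor_adduct=precursor_adduct,
            reference_rt=float(np.round(rng.uniform(1.0, 12.0), 3)),
            base_abundance=float(np.round(rng.lognormal(np.log(2e5), 0.6), 1)),
            fragments=frags,
            adducts=[(precursor_adduct, 1.0),
                     (secondary, float(np.round(rng.uniform(0.1, 0.5), 3)))],
            has_insource_fragment=bool(rng.random() < insource_fraction),
        ))
    return compounds


def make_library(n_compounds: int, seed: int,
                 ion_mode: str = "positive",
                 source: str = "synthetic") -> SpectralLibrary:
    """A synthetic MS/MS spectral library (one record per compound)."""
    rng = np.random.default_rng(seed + 7)
    records = []
    for c in make_compounds(n_compounds, seed, ion_mode):
        records.append(SpectrumRecord(
            name=c.name,
            peaks=list(c.fragments),
            precursor_mz=round(c.precursor_mz, 5),
            precursor_type=c.precursor_adduct,
            ion_mode=ion_mode,
            formula=c.formula,
            inchikey=_fake_inchikey(rng),
            retention_time=c.reference_rt,
            collision_energy="20 eV",
            provenance=source,
        ))
    return SpectralLibrary(records, dialect="canonical")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def make_feature_table(
    compounds: list[SyntheticCompound],
    roles: dict[str, str],
    noise_cv: float = 0.1,
    blank_level: float = 0.05,
    qc_cv: float = 0.02,
    seed: int = 0,
) -> tuple[FeatureTable, dict[str, list[str]]]:
    """Simulate an aligned feature table with known redundancy structure.

    Each compound emits one feature per registered adduct; all of them share
    the compound's latent per-sample abundance multiplied by log-normal noise
    of coefficient of variation ``noise_cv``, so intra-compound features
    correlate strongly across samples. Blank columns sit at ``blank_level``
    of the mean abundance, QC columns are the sample mean with ``qc_cv``
    noise. Compounds flagged ``has_insource_fragment`` also emit a co-eluting
    feature at their strongest fragment m/z sharing the same latent
    abundance. Returns the table and the ground-truth feature grouping
    (compound name -> feature ids).
    """
    rng = np.random.default_rng(seed)
    sample_cols = [s for s, r in roles.items() if r == "sample"]
    blank_cols = [s for s, r in roles.items() if r == "blank"]
    qc_cols = [s for s, r in roles.items() if r == "qc"]
    if not sample_cols or not blank_cols or not qc_cols:
        raise ValueError("roles must include sample, blank and qc entries")

    sigma = np.sqrt(np.log(1 + noise_cv ** 2))
    rows = []
    ms2: dict[str, list[tuple[float, float]]] = {}
    truth: dict[str, list[str]] = {}
    fid = 0
    for c in compounds:
        latent = c.base_abundance * rng.lognormal(0.0, 0.8, size=len(sample_cols))
        members = []

        def emit(mz: float, response: float, adduct: str, attach_ms2: bool):
            nonlocal fid
            fid += 1
            feature_id = f"F{fid:05d}"
            noise = rng.lognormal(-sigma ** 2 / 2, sigma, size=len(sample_cols))
            intens = latent * response * noise
            blank = (blank_level * c.base_abundance * response
                     * rng.lognormal(-sigma ** 2 / 2, sigma, size=len(blank_cols))
                     if blank_level > 0 else np.zeros(len(blank_cols)))
            qsig = np.sqrt(np.log(1 + qc_cv ** 2))
            qc = intens.mean() * rng.lognormal(-qsig ** 2 / 2, qsig, size=len(qc_cols))
            row = {
                "feature_id": feature_id,
                "mz": round(mz, 5),
                "rt": c.reference_rt,
                "polarity": c.ion_mode,
                "adduct": adduct,
            }
            row.update({s: float(v) for s, v in zip(sample_cols, intens)})
            row.update({s: float(v) for s, v in zip(blank_cols, blank)})
            row.update({s: float(v) for s, v in zip(qc_cols, qc)})
            rows.append(row)
            members.append(feature_id)
            if attach_ms2:
                ms2[feature_id] = list(c.fragments)

        for k, (adduct, response) in enumerate(c.adducts):
            emit(adduct_mz(c.neutral_mass, adduct), response, adduct, k == 0)
        if c.has_insource_fragment and c.fragments:
            frag_mz = max(c.fragments, key=lambda p: p[1])[0]
            emit(frag_mz, 0.6, "", False)
        truth[c.name] = members

    data = pd.DataFrame(rows, columns=META_COLUMNS + list(roles))
    table = FeatureTable(data=data, roles=roles, ms2=ms2)
    return table, truth


def default_roles(n_samples: int = 6, n_blanks: int = 3, n_qc: int = 3
                  ) -> dict[str, str]:
    """A typical screening batch layout: triplicate procedural blanks and a
    pooled QC injected repeatedly alongside the samples."""
    roles = {f"S{i + 1}": "sample" for i in range(n_samples)}
    roles.update({f"B{i + 1}": "blank" for i in range(n_blanks)})
    roles.update({f"QC{i + 1}": "qc" for i in range(n_qc)})
    return roles


# ---------------------------------------------------------------------------
# DIA batches
# ---------------------------------------------------------------------------

def make_dia_batch(
    lib: TransitionLibrary,
    roles: dict[str, str],
    present_map: dict[str, set[str]],
    snr: float = 20.0,
    seed: int = 0,
    rt_jitter: float = 0.02,
    blank_contamination: float = 0.1,
    base_height: float = 50000.0,
    peak_sigma_min: float = 0.03,
    rt_step: float = 0.005,
    rt_span: tuple[float, float] = (0.0, 13.0),
) -> list[DIARun]:
    """Simulate DIA runs for a transition library.

    A compound present in a run contributes one Gaussian peak per transition
    at its reference RT (jittered by up to ``rt_jitter`` minutes per run),
    with heights proportional to the library's relative intensities and a
    white-noise baseline sized so the *weakest* transition has the requested
    signal-to-noise ratio. Blank-role runs carry every compound at
    ``blank_contamination`` of the nominal height. All runs share a single
    wide isolation window (all-ion fragmentation).
    """
    rng = np.random.default_rng(seed)
    grid = np.arange(rt_span[0], rt_span[1] + rt_step / 2, rt_step)
    # a compound's response factor is a property of the compound, shared by
    # sample and blank runs; run-to-run variation is much smaller
    response = {e.name: float(rng.lognormal(0.0, 0.3)) for e in lib}
    runs = []
    for sample_id, role in roles.items():
        # physically faithful: one chromatogram per distinct product m/z,
        # summing every compound's contribution at that m/z
        signals: dict[float, np.ndarray] = {}
        min_rel_at: dict[float, float] = {}
        for entry in lib:
            jitter = float(rng.uniform(-rt_jitter, rt_jitter))
            rt0 = (entry.reference_rt if entry.reference_rt is not None
                   else 6.0) + jitter
            run_scale = float(rng.lognormal(0.0, 0.05))
            nominal = base_height * response[entry.name]
            if role == "blank":
                amp = blank_contamination * nominal * run_scale
            elif sample_id in present_map.get(entry.name, set()):
                amp = nominal * run_scale
            else:
                amp = 0.0
            for prod_mz, rel in entry.transitions:
                key = round(prod_mz, 4)
                scaled_rel = response[entry.name] * rel / 100.0
                if key not in signals:
                    signals[key] = np.zeros_like(grid)
                    min_rel_at[key] = scaled_rel
                min_rel_at[key] = min(min_rel_at[key], scaled_rel)
                if amp > 0:
                    h = amp * rel / 100.0
                    signals[key] += h * np.exp(
                        -0.5 * ((grid - rt0) / peak_sigma_min) ** 2)
        traces = []
        for key in signals:
            noise_sd = base_height * min_rel_at[key] / snr if snr > 0 else 0.0
            noise = np.abs(rng.normal(0.0, noise_sd, size=grid.size))
            traces.append(Trace(window=0, product_mz=key,
                                rt=grid, intensity=signals[key] + noise))
        runs.append(DIARun(sample_id=sample_id, role=role,
                           windows=[(50.0, 1200.0)], traces=traces))
    return runs
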