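"""Pseudo-MRM screening of data-independent-acquisition (DIA) runs.

DIA / all-ion-fragmentation data contain product-ion signal for every
precursor at all times, so precursor-product transition chromatograms can be
extracted after the fact and treated like multiple-reaction-monitoring
traces — no re-acquisition needed. This module extracts transition
chromatograms for a :class:`~migscreen.speclib.TransitionLibrary`, detects
chromatographic peaks (moving-average smoothing, half-height width and apex
gates), scores each compound with a composite of retention-time agreement,
ion-ratio fidelity, peak-shape correlation, and coelution, and calls
presence per compound per sample with a blank-area ratio requirement.

The composite score is a transparent stand-in for trained posterior models
used by targeted-metabolomics software: the same four evidence components
are combined as an equally weighted mean on a 0-100 scale, with the
conventional screening thresholds (0.1 min RT tolerance, 15% amplitude
tolerance, 60% minimum score, 3x blank area) as defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .speclib import TransitionEntry, TransitionLibrary


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """One product-ion chromatogram inside a precursor isolation window."""

    window: int
    product_mz: float
    rt: np.ndarray         # minutes, strictly increasing
    intensity: np.ndarray  # >= 0

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.ndim != 1 or self.rt.shape != self.intensity.shape:
            raise ValueError("rt/intensity must be 1-D arrays of equal length")
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("trace rt must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity in trace")


@dataclass
class DIARun:
    """One acquisition: precursor windows plus product-ion traces."""

    sample_id: str
    role: str = "sample"
    windows: list[tuple[float, float]] = field(default_factory=lambda: [(50.0, 1200.0)])
    traces: list[Trace] = field(default_factory=list)

    def window_for(self, precursor_mz: float) -> int | None:
        for i, (lo, hi) in enumerate(self.windows):
            if lo <= precursor_mz <= hi:
                return i
        return None

    # -- canonical JSON fixture format ------------------------------------

    def to_json(self, path: str | Path) -> Path:
        doc = {
            "sample_id": self.sample_id,
            "role": self.role,
            "windows": [{"mz_low": lo, "mz_high": hi} for lo, hi in self.windows],
            "traces": [
                {
                    "window": t.window,
                    "product_mz": t.product_mz,
                    "rt": [round(float(x), 6) for x in t.rt],
                    "intensity": [round(float(x), 4) for x in t.intensity],
                }
                for t in self.traces
            ],
        }
        Path(path).write_text(json.dumps(doc))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "DIARun":
        doc = json.loads(Path(path).read_text())
        return cls(
            sample_id=doc["sample_id"],
            role=doc.get("role", "sample"),
            windows=[(w["mz_low"], w["mz_high"]) for w in doc["windows"]],
            traces=[
                Trace(t["window"], t["product_mz"],
                      np.asarray(t["rt"]), np.asarray(t["intensity"]))
                for t in doc["traces"]
            ],
        )


@dataclass
class DetectedPeak:
    rt_apex: float
    height: float
    area: float
    width_points: int
    left: int
    right: int
    trace: Trace | None = None


@dataclass
class MrmResult:
    compound: str
    sample_id: str
    rt_observed: float | None
    total_area: float
    subscores: dict[str, float]
    posterior_score: float
    present: bool = False
    blank_ratio: float = float("inf")


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_eics(run: DIARun, lib: TransitionLibrary,
                 mz_tol: float = 0.025) -> dict[str, list[Trace | None]]:
    """One trace per (compound, transition).

    Product ions are looked up within ``mz_tol`` in the isolation window
    containing the compound's precursor (nearest trace wins on ambiguity);
    missing signal yields ``None`` in that slot. Compounds whose precursor
    falls outside every window are skipped (empty list).
    """
    out: dict[str, list[Trace | None]] = {}
    for entry in lib:
        widx = run.window_for(entry.precursor_mz)
        if widx is None:
            out[entry.name] = []
            continue
        slots: list[Trace | None] = []
        for prod_mz, _rel in entry.transitions:
            best = None
            best_gap = mz_tol
            for tr in run.traces:
                if tr.window != widx:
                    continue
                gap = abs(tr.product_mz - prod_mz)
                if gap <= best_gap:
                    best, best_gap = tr, gap
            slots.append(best)
        out[entry.name] = slots
    return out


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def _smooth(y: np.ndarray, level: int) -> np.ndarray:
    if level <= 0:
        return y.astype(float)
    w = 2 * level + 1
    kernel = np.ones(w) / w
    pad = np.pad(y.astype(float), level, mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def detect_peaks(trace: Trace, smoothing_level: int = 1, min_width: int = 5,
                 min_height: float = 100.0,
                 area_floor_frac: float = 0.01) -> list[DetectedPeak]:
    """Detect chromatographic peaks in one transition trace.

    The trace is moving-average smoothed (window ``2 * level + 1`` points).
    Local maxima qualify when the contiguous run of points above half the
    apex spans at least ``min_width`` points and the apex is at least
    ``min_height``. Peak bounds extend outward until intensity falls below
    ``area_floor_frac`` of the apex or starts rising again (a neighboring
    peak); the area is the trapezoid integral over those bounds in
    intensity x minutes. Traces shorter than ``min_width`` yield no peaks.
    """
    y_raw = trace.intensity
    n = len(y_raw)
    if n < max(min_width, 2 * smoothing_level + 1):
        return []
    y = _smooth(y_raw, smoothing_level)
    peaks: list[DetectedPeak] = []
    for i in range(1, n - 1):
        if not (y[i] >= y[i - 1] and y[i] > y[i + 1]):
            continue
        apex = y[i]
        if apex < min_height:
            continue
        half = apex / 2.0
        lo = i
        while lo > 0 and y[lo - 1] >= half:
            lo -= 1
        hi = i
        while hi < n - 1 and y[hi + 1] >= half:
            hi += 1
        if hi - lo + 1 < min_width:
            continue
        if apex < np.max(y[lo:hi + 1]):
            continue  # shoulder: a higher apex owns this half-height run
        floor = apex * area_floor_frac
        left = lo
        while left > 0 and y[left - 1] <= y[left] and y[left - 1] > floor:
            left -= 1
        right = hi
        while right < n - 1 and y[right + 1] <= y[right] and y[right + 1] > floor:
            right += 1
        area = float(np.trapezoid(y_raw[left:right + 1],
                                  trace.rt[left:right + 1]))
        peaks.append(DetectedPeak(
            rt_apex=float(trace.rt[i]), height=float(apex), area=area,
            width_points=hi - lo + 1, left=left, right=right, trace=trace))
    peaks.sort(key=lambda p: -p.height)
    return peaks


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _pick_peak(peaks: Sequence[DetectedPeak],
               ref_rt: float | None, rt_tol: float) -> DetectedPeak | None:
    if not peaks:
        return None
    if ref_rt is None:
        return peaks[0]
    near = [p for p in peaks if abs(p.rt_apex - ref_rt) <= 3 * rt_tol]
    if not near:
        return None
    return max(near, key=lambda p: p.height)


def score_compound(entry: TransitionEntry,
                   peaks_per_transition: Sequence[Sequence[DetectedPeak]],
                   sample_id: str, rt_tol: float = 0.1, amp_tol: float = 0.15,
                   score_threshold: float = 60.0) -> MrmResult:
    """Composite pseudo-MRM score for one compound in one run.

    Sub-scores, each in [0, 1]:

    * ``rt``        — 1 - min(|rt_obs - rt_ref| / rt_tol, 1); 1 with no reference.
    * ``ratio``     — 1 - min(mean relative deviation of observed vs library
      ion ratios / amp_tol, 1).
    * ``shape``     — mean pairwise Pearson correlation of the transition
      traces over the union peak span.
    * ``coelution`` — fraction of library transitions whose apex lies within
      rt_tol of the group-median apex.

    ``posterior_score`` is 100 x the mean of available sub-scores; the
    presence flag is only set later by :func:`call_presence`.
    """
    chosen: list[DetectedPeak | None] = [
        _pick_peak(peaks, entry.reference_rt, rt_tol)
        for peaks in peaks_per_transition
    ]
    detected = [(i, p) for i, p in enumerate(chosen) if p is not None]
    if not detected:
        return MrmResult(entry.name, sample_id, None, 0.0, {}, 0.0)

    apexes = [p.rt_apex for _, p in detected]
    median_rt = float(np.median(apexes))
    heights = {i: p.height for i, p in detected}
    total_area = float(sum(p.area for _, p in detected))

    # the observed RT is the apex of the strongest detected transition
    strongest = max(detected, key=lambda ip: ip[1].height)[1]
    rt_obs = strongest.rt_apex

    subs: dict[str, float] = {}
    if entry.reference_rt is not None:
        subs["rt"] = 1.0 - min(abs(rt_obs - entry.reference_rt) / rt_tol, 1.0)
    else:
        subs["rt"] = 1.0

    # ion-ratio fidelity: both sides normalized to their strongest transition
    ref_rel = {i: rel for i, (_, rel) in enumerate(entry.transitions)}
    obs_max = max(heights.values())
    devs = []
    for i, p in detected:
        obs_rel = 100.0 * p.height / obs_max
        ref = ref_rel[i]
        if ref > 0:
            devs.append(abs(obs_rel - ref) / ref)
    if devs:
        subs["ratio"] = 1.0 - min(float(np.mean(devs)) / amp_tol, 1.0)

    # shape: pairwise correlation over the union span
    if len(detected) >= 2:
        left = min(p.left for _, p in detected)
        right = max(p.right for _, p in detected)
        segs = []
        for _, p in detected:
            seg = p.trace.intensity[left:right + 1]
            if np.std(seg) > 0:
                segs.append(seg)
        cors = []
        for a in range(len(segs)):
            for b in range(a + 1, len(segs)):
                cors.append(float(np.corrcoef(segs[a], segs[b])[0, 1]))
        if cors:
            subs["shape"] = float(np.clip(np.mean(cors), 0.0, 1.0))
    else:
        subs["shape"] = 1.0

    n_lib = len(entry.transitions)
    n_coeluting = sum(1 for rt in apexes if abs(rt - median_rt) <= rt_tol)
    subs["coelution"] = n_coeluting / n_lib if n_lib else 0.0

    posterior = 100.0 * float(np.mean(list(subs.values())))
    return MrmResult(entry.name, sample_id, rt_obs, total_area, subs, posterior)


def call_presence(result: MrmResult, blank_results: Sequence[MrmResult],
                  min_blank_ratio: float = 3.0, score_threshold: float = 60.0,
                  blank_floor: float = 1.0) -> MrmResult:
    """Final presence call: score >= threshold AND area >= ratio x blank max.

    The blank reference is the largest blank-run area for the compound; an
    all-zero blank is replaced by ``blank_floor`` so any real signal passes
    the ratio. Returns an updated copy of ``result``.
    """
    blank_max = max((b.total_area for b in blank_results), default=0.0)
    denom = blank_max if blank_max > 0 else blank_floor
    ratio = result.total_area / denom
    present = (result.posterior_score >= score_threshold
               and result.total_area >= min_blank_ratio * denom)
    return MrmResult(
        compound=result.compound, sample_id=result.sample_id,
        rt_observed=result.rt_observed, total_area=result.total_area,
        subscores=result.subscores, posterior_score=result.posterior_score,
        present=present, blank_ratio=ratio)


# ---------------------------------------------------------------------------
# Batch screening
# ---------------------------------------------------------------------------

def screen_batch(runs: Sequence[DIARun], lib: TransitionLibrary,
                 mz_tol: float = 0.025, smoothing_level: int = 1,
                 min_width: int = 5, min_height: float = 100.0,
                 rt_tol: float = 0.1, amp_tol: float = 0.15,
                 score_threshold: float = 60.0,
                 min_blank_ratio: float = 3.0) -> list[MrmResult]:
    """Score every compound in every run and call presence against the
    batch's blank runs. Returns one MrmResult per (compound, non-blank run)."""
    scored: dict[str, dict[str, MrmResult]] = {}
    for run in runs:
        eics = extract_eics(run, lib, mz_tol)
        for entry in lib:
            slots = eics.get(entry.name, [])
            peaks = [
                detect_peaks(tr, smoothing_level, min_width, min_height)
                if tr is not None else []
                for tr in slots
            ]
            res = score_compound(entry, peaks, run.sample_id,
                                 rt_tol, amp_tol, score_threshold)
            scored.setdefault(entry.name, {})[run.sample_id] = res

    blank_ids = [r.sample_id for r in runs if r.role == "blank"]
    results: list[MrmResult] = []
    for run in runs:
        if run.role == "blank":
            continue
        for entry in lib:
            res = scored[entry.name][run.sample_id]
            blanks = [scored[entry.name][b] for b in blank_ids]
            results.append(call_presence(
                res, blanks, min_blank_ratio, score_threshold))
    return results


def results_to_frame(results: Sequence[MrmResult]):
    """Presence matrix + score components as a DataFrame (one row per
    compound x sample)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "compound": r.compound,
            "sample_id": r.sample_id,
            "rt_observed": r.rt_observed,
            "total_area": r.total_area,
            "posterior_score": round(r.posterior_score, 2),
            "blank_ratio": (round(r.blank_ratio, 3)
                            if np.isfinite(r.blank_ratio) else np.inf),
            "present": r.present,
            **{f"score_{k}": round(v, 4) for k, v in r.subscores.items()},
        }
        for r in results
    ])
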