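"""Feature-table cleaning and redundancy clustering.

A *feature* is a mass-retention-time pair with per-sample intensities from
peak alignment. Cleaning removes noise and background before structural
elucidation: a minimum-height gate, a sample-max/blank-max presence ratio, a
blank/QC background ratio, and a QC relative-standard-deviation (RSD)
repeatability gate. The survivors are grouped into clusters of co-eluting,
intensity-correlated features (the same compound seen as several adducts,
dimers, isotopologues, or in-source fragments), each cluster keeping its most
intense and most connected member for downstream identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .chemcore import ADDUCTS

META_COLUMNS = ["feature_id", "mz", "rt", "polarity", "adduct"]

ROLES = ("sample", "blank", "qc")


class RoleError(ValueError):
    """Sample-role configuration does not support the requested filter."""


@dataclass
class FeatureTable:
    """Aligned feature x sample intensity matrix with sample roles.

    ``data`` holds one row per feature: the metadata columns in
    :data:`META_COLUMNS` followed by one intensity column per sample.
    ``roles`` maps each sample column to "sample", "blank", or "qc".
    ``ms2`` and ``isotopes`` carry optional per-feature MS2 peak lists and
    measured isotope patterns, keyed by feature_id.
    """

    data: pd.DataFrame
    roles: Mapping[str, str]
    ms2: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    isotopes: dict[str, object] = field(default_factory=dict)
    history: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        unknown = set(self.roles.values()) - set(ROLES)
        if unknown:
            raise RoleError(f"unknown sample roles: {sorted(unknown)}")
        for s in self.roles:
            if s not in self.data.columns:
                raise ValueError(f"role map names absent sample column {s!r}")
        self.data = self.data.reset_index(drop=True)
        cols = list(self.roles)
        self.data[cols] = self.data[cols].astype(float)

    # -- accessors ---------------------------------------------------------

    def columns_for(self, role: str) -> list[str]:
        return [s for s, r in self.roles.items() if r == role]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data["feature_id"])

    def intensities(self, role: str) -> pd.DataFrame:
        return self.data[self.columns_for(role)]

    def __len__(self) -> int:
        return len(self.data)

    def _keep(self, mask: np.ndarray, step: str) -> "FeatureTable":
        kept = self.data.loc[mask].reset_index(drop=True)
        ids = set(kept["feature_id"])
        return FeatureTable(
            data=kept,
            roles=self.roles,
            ms2={k: v for k, v in self.ms2.items() if k in ids},
            isotopes={k: v for k, v in self.isotopes.items() if k in ids},
            history=self.history + [(step, int((~mask).sum()))],
        )

    # -- I/O -----------------------------------------------------------------

    def to_csv(self, path: str | Path, roles_path: str | Path | None = None) -> None:
        self.data.to_csv(path, index=False)
        if roles_path is not None:
            pd.DataFrame(
                {"sample_id": list(self.roles), "role": list(self.roles.values())}
            ).to_csv(roles_path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, roles_path: str | Path) -> "FeatureTable":
        data = pd.read_csv(path)
        roles_df = pd.read_csv(roles_path)
        roles = dict(zip(roles_df["sample_id"], roles_df["role"]))
        return cls(data=data, roles=roles)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_min_height(table: FeatureTable, min_height: float = 3000) -> FeatureTable:
    """Drop features whose maximum height over sample-role columns is below
    ``min_height`` (default 3000 counts)."""
    cols = table.columns_for("sample")
    if not cols:
        raise RoleError("no sample-role columns")
    mask = table.data[cols].max(axis=1).to_numpy() >= min_height
    return table._keep(mask, "min_height")


def filter_sample_blank_ratio(table: FeatureTable, min_ratio: float = 5,
                              blank_floor: float = 1.0) -> FeatureTable:
    """Keep features whose sample max / blank max exceeds ``min_ratio``.

    An all-zero blank is replaced by ``blank_floor`` counts so the ratio is
    defined; with the default floor of 1 count any visible sample signal
    passes.
    """
    blanks = table.columns_for("blank")
    if not blanks:
        raise RoleError("sample/blank ratio filter requires >=1 blank column")
    sample_max = table.data[table.columns_for("sample")].max(axis=1).to_numpy()
    blank_max = table.data[blanks].max(axis=1).to_numpy()
    blank_max = np.where(blank_max <= 0, blank_floor, blank_max)
    mask = sample_max / blank_max > min_ratio
    return table._keep(mask, "sample_blank_ratio")


def filter_blank_qc_ratio(table: FeatureTable, max_ratio: float = 0.5) -> FeatureTable:
    """Remove background features: mean(blank) / mean(QC) > ``max_ratio``.

    A zero QC mean with nonzero blank signal is treated as background and
    removed (the ratio is unbounded there).
    """
    blanks = table.columns_for("blank")
    qcs = table.columns_for("qc")
    if not blanks or not qcs:
        raise RoleError("blank/QC filter requires blank and qc columns")
    blank_mean = table.data[blanks].mean(axis=1).to_numpy()
    qc_mean = table.data[qcs].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(qc_mean > 0, blank_mean / np.where(qc_mean > 0, qc_mean, 1.0),
                         np.where(blank_mean > 0, np.inf, 0.0))
    mask = ~(ratio > max_ratio)
    return table._keep(mask, "blank_qc_ratio")


def filter_qc_rsd(table: FeatureTable, max_rsd_percent: float = 30) -> FeatureTable:
    """Remove features whose QC relative standard deviation (percent,
    sample standard deviation / mean x 100) exceeds ``max_rsd_percent``."""
    qcs = table.columns_for("qc")
    if len(qcs) < 2:
        raise RoleError("QC RSD filter requires >=2 qc columns")
    qc = table.data[qcs].to_numpy(dtype=float)
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, 100.0 * sd / np.where(mean > 0, mean, 1.0), np.inf)
    mask = ~(rsd > max_rsd_percent)
    return table._keep(mask, "qc_rsd")


def clean(table: FeatureTable, min_height: float = 3000, min_sample_blank: float = 5,
          max_blank_qc: float = 0.5, max_qc_rsd: float = 30) -> FeatureTable:
    """The standard cleaning cascade: height, sample/blank, blank/QC, QC RSD."""
    out = filter_min_height(table, min_height)
    out = filter_sample_blank_ratio(out, min_sample_blank)
    out = filter_blank_qc_ratio(out, max_blank_qc)
    out = filter_qc_rsd(out, max_qc_rsd)
    return out


# ---------------------------------------------------------------------------
# Spectral-quality gate
# ---------------------------------------------------------------------------

def filter_spectral_quality(table: FeatureTable, min_fragments: int = 3,
                            min_rel_intensity: float = 0.05) -> FeatureTable:
    """Keep only features with a representative MS2 spectrum.

    A spectrum counts as representative when at least ``min_fragments`` peaks
    rise above ``min_rel_intensity`` of its base peak; featureless "grass"
    and spectrum-absent features are dropped, as they carry no structural
    information.
    """
    keep = []
    for fid in table.data["feature_id"]:
        peaks = table.ms2.get(fid)
        if not peaks:
            keep.append(False)
            continue
        base = max(i for _, i in peaks)
        good = sum(1 for _, i in peaks if base and i >= min_rel_intensity * base)
        keep.append(good >= min_fragments)
    return table._keep(np.asarray(keep, dtype=bool), "spectral_quality")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterEdge:
    a: str
    b: str
    pearson_r: float
    p_value: float
    link_type: str  # correlation | adduct | in_source_fragment | dimer | isotopologue


@dataclass
class FeatureCluster:
    member_ids: list[str]
    edges: list[ClusterEdge]
    most_intense: str | None = None
    most_connected: str | None = None


def _pairwise_adduct_deltas(polarity: str) -> dict[float, str]:
    """Mass differences between singly charged monomer adducts of one
    polarity (e.g. Na-vs-H gives 21.9819)."""
    adducts = [a for a in ADDUCTS.values()
               if a.polarity == polarity and a.multimer == 1]
    deltas = {}
    for i, a in enumerate(adducts):
        for b in adducts[i + 1:]:
            d = abs(a.mass_delta - b.mass_delta)
            if d > 1e-6:
                deltas[d] = f"{a.name}/{b.name}"
    return deltas


_C13_SPACING = 1.0033548378


def _classify_link(fa: pd.Series, fb: pd.Series,
                   ms2: Mapping[str, list], mz_link_tol: float,
                   include_isotopologues: bool) -> str:
    lo, hi = (fa, fb) if fa["mz"] <= fb["mz"] else (fb, fa)
    dmz = hi["mz"] - lo["mz"]
    polarity = fa.get("polarity") or "positive"
    for delta, _label in _pairwise_adduct_deltas(polarity).items():
        if abs(dmz - delta) <= mz_link_tol:
            return "adduct"
    # dimer: the heavier member is a 2M form of the lighter member's neutral
    monomers = [a for a in ADDUCTS.values()
                if a.polarity == polarity and a.multimer == 1]
    dimers = [a for a in ADDUCTS.values()
              if a.polarity == polarity and a.multimer == 2]
    for am in monomers:
        m = am.neutral_mass(lo["mz"])
        if m <= 0:
            continue
        for ad in dimers:
            if abs(ad.mz(m) - hi["mz"]) <= mz_link_tol:
                return "dimer"
    if include_isotopologues:
        for k in (1, 2):
            if abs(dmz - k * _C13_SPACING) <= mz_link_tol:
                return "isotopologue"
    # in-source fragment: the lighter feature's m/z appears in the heavier
    # feature's MS2 spectrum
    parent_ms2 = ms2.get(hi["feature_id"]) or []
    if any(abs(mz - lo["mz"]) <= max(mz_link_tol, 0.025) for mz, _ in parent_ms2):
        return "in_source_fragment"
    return "correlation"


def cluster_features(table: FeatureTable, min_r: float = 0.8,
                     max_p: float = 0.05, mz_link_tol: float = 0.005,
                     rt_window: float = 0.025,
                     include_isotopologues: bool = False) -> list[FeatureCluster]:
    """Group redundant features into clusters.

    Edges connect co-eluting features (|delta RT| <= ``rt_window`` minutes)
    whose cross-sample intensity profiles correlate with Pearson r >=
    ``min_r`` at p <= ``max_p`` (two-sided t test with n-2 degrees of
    freedom). Connected components are returned with every edge annotated as
    an adduct pair, dimer, in-source fragment, isotopologue (optional), or
    plain correlation, judged at ``mz_link_tol`` Da. Features with constant
    intensity vectors contribute no edges (correlation undefined).
    """
    cols = table.columns_for("sample")
    if len(cols) < 3:
        raise RoleError("clustering needs >=3 sample columns for p-values")
    df = table.data
    inten = df[cols].to_numpy(dtype=float)
    rt = df["rt"].to_numpy(dtype=float)
    order = np.argsort(rt)

    g = nx.Graph()
    g.add_nodes_from(df["feature_id"])
    edges: list[ClusterEdge] = []
    for ii, i in enumerate(order):
        for j in order[ii + 1:]:
            if rt[j] - rt[i] > rt_window:
                break
            xi, xj = inten[i], inten[j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            r, p = stats.pearsonr(xi, xj)
            if r >= min_r and p <= max_p:
                fa, fb = df.iloc[i], df.iloc[j]
                link = _classify_link(fa, fb, table.ms2, mz_link_tol,
                                      include_isotopologues)
                edge = ClusterEdge(fa["feature_id"], fb["feature_id"],
                                   float(r), float(p), link)
                edges.append(edge)
                g.add_edge(edge.a, edge.b, data=edge)

    meta = df.set_index("feature_id")
    sample_max = df[cols].max(axis=1)
    sample_max.index = df["feature_id"]

    clusters = []
    for component in nx.connected_components(g):
        members = sorted(component)
        sub = [e for e in edges if e.a in component and e.b in component]
        cluster = FeatureCluster(member_ids=members, edges=sub)
        _assign_representatives(cluster, g, sample_max, meta)
        clusters.append(cluster)
    clusters.sort(key=lambda c: meta.loc[c.member_ids[0], "rt"])
    return clusters


def _assign_representatives(cluster: FeatureCluster, g: nx.Graph,
                            sample_max: pd.Series, meta: pd.DataFrame) -> None:
    def intense_key(fid: str):
        return (-sample_max.loc[fid], meta.loc[fid, "mz"], fid)

    def connected_key(fid: str):
        return (-g.degree(fid), meta.loc[fid, "mz"], fid)

    cluster.most_intense = min(cluster.member_ids, key=intense_key)
    cluster.most_connected = min(cluster.member_ids, key=connected_key)


def select_representatives(cluster: FeatureCluster) -> dict[str, str]:
    """Representatives of a cluster: highest sample intensity and highest
    degree, ties resolved to the lower m/z (assigned during clustering)."""
    if not cluster.member_ids:
        raise ValueError("empty cluster")
    return {"most_intense": cluster.most_intense,
            "most_connected": cluster.most_connected}


def keep_representatives(table: FeatureTable,
                         clusters: Sequence[FeatureCluster]) -> FeatureTable:
    """Reduce the table to cluster representatives (plus unclustered features)."""
    clustered: set[str] = set()
    keep: set[str] = set()
    for c in clusters:
        clustered.update(c.member_ids)
        keep.update({c.most_intense, c.most_connected} - {None})
    mask = np.array([
        fid in keep or fid not in clustered for fid in table.data["feature_id"]
    ], dtype=bool)
    return table._keep(mask, "representatives")


# ---------------------------------------------------------------------------
# Polarity merge
# ---------------------------------------------------------------------------

def _neutral_mass(row: pd.Series) -> float | None:
    adduct = row.get("adduct")
    if not isinstance(adduct, str) or adduct not in ADDUCTS:
        adduct = "[M+H]+" if row.get("polarity") == "positive" else "[M-H]-"
    return ADDUCTS[adduct].neutral_mass(row["mz"])


def merge_polarities(pos_table: FeatureTable, neg_table: FeatureTable,
                     mz_tol: float = 0.005, rt_tol: float = 0.025) -> FeatureTable:
    """Merge positive- and negative-mode tables into one neutral-mass table.

    Features whose adduct-inferred neutral masses agree within ``mz_tol`` Da
    and retention times within ``rt_tol`` minutes are merged into one entry
    carrying both polarities' evidence (the positive row survives with a
    ``neg_counterpart`` column). Ambiguous many-to-many matches resolve to
    the closest neutral-mass pairing; the rest pass through unmerged.
    """
    pos = pos_table.data.copy()
    neg = neg_table.data.copy()
    pos["_neutral"] = [_neutral_mass(r) for _, r in pos.iterrows()]
    neg["_neutral"] = [_neutral_mass(r) for _, r in neg.iterrows()]

    pairs = []  # (gap, pos_idx, neg_idx)
    for i, prow in pos.iterrows():
        for j, nrow in neg.iterrows():
            if abs(prow["rt"] - nrow["rt"]) > rt_tol:
                continue
            gap = abs(prow["_neutral"] - nrow["_neutral"])
            if gap <= mz_tol:
                pairs.append((gap, i, j))
    pairs.sort()
    used_pos: set = set()
    used_neg: set = set()
    match: dict = {}
    for gap, i, j in pairs:
        if i in used_pos or j in used_neg:
            continue
        match[i] = j
        used_pos.add(i)
        used_neg.add(j)

    pos["neg_counterpart"] = [
        neg.loc[match[i], "feature_id"] if i in match else None for i in pos.index
    ]
    unmatched_neg = neg.loc[~neg.index.isin(used_neg)].copy()
    unmatched_neg["neg_counterpart"] = None
    merged = pd.concat([pos, unmatched_neg], ignore_index=True)
    merged = merged.drop(columns=["_neutral"])

    roles = dict(pos_table.roles)
    roles.update(neg_table.roles)
    # fill intensity columns missing from one polarity with zeros
    for col in roles:
        if col not in merged.columns:
            merged[col] = 0.0
    merged[list(roles)] = merged[list(roles)].fillna(0.0)
    ms2 = {**neg_table.ms2, **pos_table.ms2}
    iso = {**neg_table.isotopes, **pos_table.isotopes}
    return FeatureTable(data=merged, roles=roles, ms2=ms2, isotopes=iso,
                        history=pos_table.history + [("merge_polarities", 0)])
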