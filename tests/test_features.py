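"""Feature-table filters, redundancy clustering, and polarity merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migscreen import features as ft
from migscreen import synthdata as sd
from migscreen.features import (
    FeatureTable,
    META_COLUMNS,
    RoleError,
    cluster_features,
    filter_blank_qc_ratio,
    filter_min_height,
    filter_qc_rsd,
    filter_sample_blank_ratio,
    filter_spectral_quality,
    keep_representatives,
    merge_polarities,
    select_representatives,
)

ROLES = {"S1": "sample", "S2": "sample", "S3": "sample",
         "B1": "blank", "B2": "blank", "QC1": "qc", "QC2": "qc", "QC3": "qc"}


def make_table(rows, ms2=None):
    """rows: list of dicts with mz, rt and per-sample intensities."""
    data = []
    for i, row in enumerate(rows):
        rec = {"feature_id": f"F{i + 1:03d}", "mz": row.get("mz", 100.0 + i),
               "rt": row.get("rt", 5.0), "polarity": row.get("polarity", "positive"),
               "adduct": row.get("adduct", "")}
        for s in ROLES:
            rec[s] = float(row.get(s, 0.0))
        data.append(rec)
    return FeatureTable(data=pd.DataFrame(data, columns=META_COLUMNS + list(ROLES)),
                        roles=ROLES, ms2=ms2 or {})


class TestMinHeight:
    def test_boundary(self):
        tab = make_table([
            {"S1": 2999},          # below -> removed
            {"S1": 3000},          # at threshold -> kept
            {"S1": 100, "B1": 99999},  # blank height does not rescue
        ])
        out = filter_min_height(tab)
        assert out.feature_ids == ["F002"]

    def test_empty_table(self):
        out = filter_min_height(make_table([]))
        assert len(out) == 0


class TestSampleBlankRatio:
    @pytest.mark.parametrize("sample,blank,kept", [
        (100, 10, True),    # ratio 10 > 5
        (40, 10, False),    # ratio 4
        (50, 10, False),    # ratio exactly 5, not >
    ])
    def test_arithmetic(self, sample, blank, kept):
        tab = make_table([{"S1": sample, "B1": blank}])
        assert (len(filter_sample_blank_ratio(tab)) == 1) is kept

    def test_zero_blank_uses_floor(self):
        tab = make_table([{"S1": 6.0}])  # blank 0 -> floor 1 -> ratio 6
        assert len(filter_sample_blank_ratio(tab)) == 1
        assert len(filter_sample_blank_ratio(make_table([{"S1": 4.0}]))) == 0

    def test_requires_blank_columns(self):
        roles = {k: v for k, v in ROLES.items() if v != "blank"}
        tab = make_table([{"S1": 10}])
        tab2 = FeatureTable(tab.data.drop(columns=["B1", "B2"]), roles)
        with pytest.raises(RoleError):
            filter_sample_blank_ratio(tab2)


class TestBlankQcRatio:
    @pytest.mark.parametrize("blank,qc,kept", [
        (60, 100, False),   # 0.6 > 0.5 -> removed
        (0, 100, True),     # zero blank kept
        (50, 100, True),    # exactly 0.5, not > -> kept
    ])
    def test_arithmetic(self, blank, qc, kept):
        tab = make_table([{
            "B1": blank, "B2": blank, "QC1": qc, "QC2": qc, "QC3": qc,
        }])
        assert (len(filter_blank_qc_ratio(tab)) == 1) is kept

    def test_zero_qc_with_blank_signal_removed(self):
        tab = make_table([{"B1": 10, "B2": 10}])
        assert len(filter_blank_qc_ratio(tab)) == 0


class TestQcRsd:
    @pytest.mark.parametrize("qc,kept", [
        ((100, 100, 100), True),   # RSD 0
        ((50, 150, 100), False),   # RSD 50
        ((90, 100, 110), True),    # RSD 10
    ])
    def test_arithmetic(self, qc, kept):
        tab = make_table([{"QC1": qc[0], "QC2": qc[1], "QC3": qc[2]}])
        assert (len(filter_qc_rsd(tab)) == 1) is kept

    def test_two_qc_oracle(self):
        # sd(50, 150)/mean = 70.71/100
        tab = make_table([{"QC1": 50, "QC2": 150}])
        tab = FeatureTable(tab.data.drop(columns=["QC3"]),
                           {k: v for k, v in ROLES.items() if k != "QC3"})
        assert len(filter_qc_rsd(tab, max_rsd_percent=70)) == 0
        assert len(filter_qc_rsd(tab, max_rsd_percent=71)) == 1


intensity_rows = st.lists(
    st.fixed_dictionaries({
        s: st.floats(0, 1e6, allow_nan=False) for s in ROLES
    }),
    min_size=0, max_size=12)


class TestFilterProperties:
    @given(intensity_rows)
    @settings(derandomize=True, max_examples=40)
    def test_subset_and_idempotent(self, rows):
        tab = make_table(rows)
        for filt in (filter_min_height, filter_sample_blank_ratio,
                     filter_blank_qc_ratio, filter_qc_rsd):
            out = filt(tab)
            assert set(out.feature_ids) <= set(tab.feature_ids)
            again = filt(out)
            assert again.feature_ids == out.feature_ids

    @given(intensity_rows)
    @settings(derandomize=True, max_examples=30)
    def test_order_invariance(self, rows):
        tab = make_table(rows)
        filters = [filter_min_height, filter_sample_blank_ratio,
                   filter_blank_qc_ratio, filter_qc_rsd]
        forward = tab
        for f in filters:
            forward = f(forward)
        backward = tab
        for f in reversed(filters):
            backward = f(backward)
        assert forward.feature_ids == backward.feature_ids


class TestSpectralQuality:
    def test_grass_spectrum_removed(self):
        ms2 = {"F001": [(60.0, 100.0)] + [(70.0 + i, 1.0) for i in range(20)]}
        tab = make_table([{"S1": 10}], ms2=ms2)
        assert len(filter_spectral_quality(tab)) == 0

    def test_structured_spectrum_kept(self):
        ms2 = {"F001": [(60.0 + i * 10, 50.0 + i) for i in range(6)]}
        tab = make_table([{"S1": 10}], ms2=ms2)
        assert len(filter_spectral_quality(tab)) == 1

    def test_spectrum_absent_removed(self):
        tab = make_table([{"S1": 10}])
        assert len(filter_spectral_quality(tab)) == 0


def correlated_rows(rng, mz_pair, rt, base=1e5, cv=0.03):
    latent = base * rng.lognormal(0, 0.8, size=3)
    rows = []
    for mz, resp in mz_pair:
        noise = rng.lognormal(0, cv, size=3)
        vals = latent * resp * noise
        rows.append({"mz": mz, "rt": rt,
                     "S1": vals[0], "S2": vals[1], "S3": vals[2],
                     "QC1": latent.mean(), "QC2": latent.mean(),
                     "QC3": latent.mean()})
    return rows


class TestClustering:
    def test_planted_pair_clusters(self):
        rng = np.random.default_rng(3)
        rows = correlated_rows(rng, [(200.0, 1.0), (222.0, 0.4)], rt=5.0)
        rows += correlated_rows(rng, [(400.0, 1.0)], rt=9.0)
        tab = make_table(rows)
        clusters = cluster_features(tab)
        grouped = [set(c.member_ids) for c in clusters]
        assert {"F001", "F002"} in grouped

    def test_sodium_proton_delta_annotated_as_adduct(self):
        rng = np.random.default_rng(4)
        # [M+H]+ 114.0913 and [M+Na]+ 136.0733: delta 21.9819
        rows = correlated_rows(rng, [(114.0913, 1.0), (136.0733, 0.3)], rt=3.1)
        clusters = cluster_features(make_table(rows))
        links = {e.link_type for c in clusters for e in c.edges}
        assert links == {"adduct"}

    def test_insource_fragment_link(self):
        rng = np.random.default_rng(5)
        # diethanolamine-like fragment 106.0866 under parent 288.2544, both
        # at 7.20 min; the parent's MS2 contains the fragment m/z
        rows = correlated_rows(rng, [(288.2544, 1.0), (106.0866, 0.5)], rt=7.20)
        ms2 = {"F001": [(106.0866, 100.0), (88.0757, 40.0)]}
        tab = make_table(rows, ms2=ms2)
        clusters = cluster_features(tab)
        assert len(clusters) == 1
        assert clusters[0].edges[0].link_type == "in_source_fragment"
        # the parent (more intense) is the retained representative
        assert clusters[0].most_intense == "F001"

    def test_rt_window_separates(self):
        rng = np.random.default_rng(6)
        rows = correlated_rows(rng, [(200.0, 1.0)], rt=5.0)
        rows += correlated_rows(rng, [(222.0, 1.0)], rt=5.1)  # > 0.025 min
        clusters = cluster_features(make_table(rows))
        assert all(len(c.member_ids) == 1 for c in clusters)

    def test_constant_vector_contributes_no_edge(self):
        rows = [
            {"mz": 200.0, "rt": 5.0, "S1": 10, "S2": 10, "S3": 10},
            {"mz": 222.0, "rt": 5.0, "S1": 10, "S2": 20, "S3": 30},
        ]
        clusters = cluster_features(make_table(rows))
        assert all(not c.edges for c in clusters)

    def test_requires_three_samples(self):
        roles = dict(ROLES)
        roles.pop("S3")
        tab = make_table([{"S1": 1}])
        small = FeatureTable(tab.data.drop(columns=["S3"]), roles)
        with pytest.raises(RoleError):
            cluster_features(small)

    def test_recovers_planted_groups(self):
        """On tables with shared latent abundance per compound and CV <= 10%
        multiplicative noise, >= 95% of planted adduct groups are recovered
        exactly."""
        compounds = sd.make_compounds(20, seed=21, insource_fraction=0.3)
        roles = sd.default_roles(n_samples=8)
        tab, truth = sd.make_feature_table(compounds, roles,
                                           noise_cv=0.05, seed=22)
        clusters = cluster_features(tab)
        found = [set(c.member_ids) for c in clusters]
        exact = sum(1 for members in truth.values()
                    if len(members) > 1 and set(members) in found)
        multi = sum(1 for m in truth.values() if len(m) > 1)
        assert exact / multi >= 0.95


class TestRepresentatives:
    def test_singleton(self):
        rng = np.random.default_rng(7)
        tab = make_table(correlated_rows(rng, [(200.0, 1.0)], rt=5.0))
        clusters = cluster_features(tab)
        reps = select_representatives(clusters[0])
        assert reps == {"most_intense": "F001", "most_connected": "F001"}

    def test_chain_middle_most_connected(self):
        # three co-eluting features a-b-c where only consecutive pairs share
        # a latent: b has degree 2
        rng = np.random.default_rng(8)
        lat1 = 1e5 * rng.lognormal(0, 0.8, size=3)
        lat2 = 1e5 * rng.lognormal(0, 0.8, size=3)
        rows = []
        for mz, vals in [(200.0, lat1), (210.0, lat1 + lat2), (220.0, lat2)]:
            rows.append({"mz": mz, "rt": 5.0,
                         "S1": vals[0], "S2": vals[1], "S3": vals[2]})
        tab = make_table(rows)
        clusters = cluster_features(tab, min_r=0.5, max_p=0.5)
        cluster = max(clusters, key=lambda c: len(c.member_ids))
        if len(cluster.member_ids) == 3 and len(cluster.edges) == 2:
            assert cluster.most_connected == "F002"

    def test_equal_degree_tie_lower_mz(self):
        rng = np.random.default_rng(9)
        rows = correlated_rows(rng, [(300.0, 1.0), (278.0, 1.0)], rt=5.0)
        clusters = cluster_features(make_table(rows))
        assert clusters[0].most_connected == "F002"  # 278 < 300

    def test_representatives_are_members(self):
        compounds = sd.make_compounds(10, seed=31)
        tab, _ = sd.make_feature_table(compounds, sd.default_roles(),
                                       noise_cv=0.05, seed=32)
        for c in cluster_features(tab):
            assert c.most_intense in c.member_ids
            assert c.most_connected in c.member_ids

    def test_keep_representatives_subset(self):
        compounds = sd.make_compounds(10, seed=33)
        tab, _ = sd.make_feature_table(compounds, sd.default_roles(),
                                       noise_cv=0.05, seed=34)
        clusters = cluster_features(tab)
        out = keep_representatives(tab, clusters)
        assert set(out.feature_ids) <= set(tab.feature_ids)
        assert len(out) <= len(tab)


class TestMergePolarities:
    def _tables(self, pos_mz, neg_mz, pos_rt=5.0, neg_rt=5.0):
        pos = make_table([{"mz": pos_mz, "rt": pos_rt,
                           "polarity": "positive", "adduct": "[M+H]+",
                           "S1": 10, "S2": 20, "S3": 30}])
        neg = make_table([{"mz": neg_mz, "rt": neg_rt,
                           "polarity": "negative", "adduct": "[M-H]-",
                           "S1": 5, "S2": 10, "S3": 15}])
        return pos, neg

    def test_same_neutral_mass_merged(self):
        # caprolactam: 113.0841 neutral seen both ways
        pos, neg = self._tables(114.0913, 112.0768)
        merged = merge_polarities(pos, neg)
        assert len(merged) == 1
        assert merged.data.loc[0, "neg_counterpart"] == "F001"

    def test_rt_apart_not_merged(self):
        pos, neg = self._tables(114.0913, 112.0768, neg_rt=5.1)
        merged = merge_polarities(pos, neg)
        assert len(merged) == 2

    def test_no_counterpart_passthrough(self):
        pos, neg = self._tables(114.0913, 300.0)
        merged = merge_polarities(pos, neg)
        assert len(merged) == 2
        assert merged.data["neg_counterpart"].isna().all()


def test_csv_roundtrip(tmp_path):
    compounds = sd.make_compounds(5, seed=41)
    tab, _ = sd.make_feature_table(compounds, sd.default_roles(), seed=42)
    tab.to_csv(tmp_path / "t.csv", tmp_path / "r.csv")
    back = FeatureTable.from_csv(tmp_path / "t.csv", tmp_path / "r.csv")
    assert back.feature_ids == tab.feature_ids
    assert back.roles == dict(tab.roles)
    pd.testing.assert_frame_equal(back.data, tab.data)
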