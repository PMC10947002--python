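"""Period rates, severity grading, parcellation and group statistics."""

import numpy as np
import pandas as pd
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from scipy import stats

from fetalmorpho import cohort as ch
from fetalmorpho import surface_io as sio
from fetalmorpho import synthetic as syn


class TestPeriodRates:
    def test_flat_trajectory_all_zero(self):
        pr = ch.period_rates(10, 10, 10, (20.0, 24.0, 30.0))
        assert pr.immediate == pr.longterm == pr.global_ == 0.0

    def test_linear_trajectory_equal_rates(self):
        pr = ch.period_rates(100, 110, 140, (23.0, 25.0, 31.0))
        assert pr.immediate == pytest.approx(5.0)
        assert pr.longterm == pytest.approx(5.0)
        assert pr.global_ == pytest.approx(5.0)

    def test_piecewise_trajectory(self):
        pr = ch.period_rates(0, 12, 12, (20.0, 24.0, 30.0))
        assert pr.immediate == pytest.approx(3.0)
        assert pr.longterm == pytest.approx(0.0)
        assert pr.global_ == pytest.approx(1.2)

    def test_difference_variant(self):
        pr = ch.period_rates(0, 12, 12, (20.0, 24.0, 30.0),
                             global_definition="difference")
        assert pr.global_ == pytest.approx(-3.0)

    def test_nonincreasing_ga_rejected(self):
        with pytest.raises(ValueError):
            ch.period_rates(1, 2, 3, (24.0, 24.0, 30.0))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        xs=st.tuples(*[st.floats(-1e4, 1e4) for _ in range(3)]),
        ga1=st.floats(18, 30),
        d1=st.floats(0.5, 6),
        d2=st.floats(0.5, 10),
    )
    def test_rate_identities_property(self, xs, ga1, d1, d2):
        x1, x2, x3 = xs
        ga = (ga1, ga1 + d1, ga1 + d1 + d2)
        pr = ch.period_rates(x1, x2, x3, ga)
        assert pr.immediate == pytest.approx((x2 - x1) / d1, rel=1e-9, abs=1e-9)
        assert pr.longterm == pytest.approx((x3 - x2) / d2, rel=1e-9, abs=1e-9)
        assert pr.global_ == pytest.approx((x3 - x1) / (d1 + d2), rel=1e-9, abs=1e-9)

    def test_decimal_weeks_conversion(self):
        assert ch.decimal_weeks(23, 3) == pytest.approx(23.428571, rel=1e-6)
        with pytest.raises(ValueError):
            ch.decimal_weeks(23, 7)


class TestVentriculomegaly:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (9, "none"), (10, "mild"), (11, "mild"), (12, "mild"),
            (13, "moderate"), (14, "moderate"), (15, "moderate"),
            (16, "severe"), (17, "severe"), (20, "severe"),
        ],
    )
    def test_integer_bands(self, d, expected):
        assert ch.classify_ventriculomegaly(d) == expected

    def test_fractional_rounds_half_up(self):
        assert ch.classify_ventriculomegaly(12.5) == "moderate"
        assert ch.classify_ventriculomegaly(12.4) == "mild"
        assert ch.classify_ventriculomegaly(15.5) == "severe"
        assert ch.classify_ventriculomegaly(9.4) == "none"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ch.classify_ventriculomegaly(-1.0)


class TestParcellation:
    def test_atlas_self_labels_exact(self):
        atlas = syn.make_atlas_surface(26.0)
        parc = ch.parcellate_lobes(atlas, atlas)
        assert np.array_equal(parc.labels, atlas.lobe_labels)

    def test_rotated_scaled_atlas_recovered(self):
        atlas = syn.make_atlas_surface(26.0)
        R = trimesh.transformations.rotation_matrix(np.deg2rad(30), [0, 0, 1])[:3, :3]
        moved = sio.SurfaceMesh(
            vertices=atlas.vertices @ R.T * 1.1, faces=atlas.faces
        )
        parc = ch.parcellate_lobes(moved, atlas)
        assert (parc.labels == atlas.lobe_labels).mean() >= 0.98

    def test_generator_subject_agreement(self):
        phases = syn.sample_fold_phases(np.random.default_rng(8))
        subject = syn.generate_surface(27.0, 28.0, 0.15, phases)
        atlas = syn.make_atlas_surface(27.0)
        parc = ch.parcellate_lobes(subject, atlas)
        assert (parc.labels == subject.lobe_labels).mean() >= 0.90

    def test_partition_property(self):
        atlas = syn.make_atlas_surface(24.0)
        parc = ch.parcellate_lobes(atlas, atlas)
        counts = parc.region_counts()
        assert sum(counts.values()) == atlas.n_vertices
        assert len(counts) == 8

    def test_atlas_without_labels_rejected(self):
        atlas = syn.make_atlas_surface(24.0)
        bare = sio.SurfaceMesh(vertices=atlas.vertices, faces=atlas.faces)
        with pytest.raises(ValueError, match="lobe labels"):
            ch.parcellate_lobes(atlas, bare)


class TestCurvatureSummary:
    def test_constant_field(self):
        atlas = syn.make_atlas_surface(24.0)
        parc = ch.LobeParcellation(labels=atlas.lobe_labels)
        summ = ch.subject_curvature_summary(np.full(atlas.n_vertices, 0.3), parc)
        for region, info in summ.items():
            assert info["value"] == pytest.approx(0.3)

    def test_hemisphere_split_field(self):
        atlas = syn.make_atlas_surface(24.0)
        parc = ch.LobeParcellation(labels=atlas.lobe_labels)
        left = np.isin(atlas.lobe_labels, [0, 2, 4, 6])
        field = np.where(left, 1.0, -1.0)
        summ = ch.subject_curvature_summary(field, parc)
        for i, name in enumerate(syn.LOBE_NAMES):
            assert summ[name]["value"] == pytest.approx(1.0 if i % 2 == 0 else -1.0)
        assert abs(summ["whole"]["value"]) <= 1.0

    def test_programmed_lobe_offsets_recovered(self, rng):
        atlas = syn.make_atlas_surface(24.0)
        parc = ch.LobeParcellation(labels=atlas.lobe_labels)
        offsets = {i: 0.1 * (i + 1) for i in range(8)}
        field = np.array([offsets[l] for l in atlas.lobe_labels])
        field = field + rng.normal(0, 0.005, size=len(field))
        summ = ch.subject_curvature_summary(field, parc)
        for i, name in enumerate(syn.LOBE_NAMES):
            assert summ[name]["value"] == pytest.approx(offsets[i], rel=0.10)

    def test_length_mismatch_rejected(self):
        parc = ch.LobeParcellation(labels=np.zeros(5, dtype=int))
        with pytest.raises(ValueError):
            ch.subject_curvature_summary(np.zeros(4), parc)


class TestAndersonDarling:
    def test_size_under_null(self):
        keep = 0
        for rep in range(100):
            x = np.random.default_rng(rep).normal(size=200)
            if not ch.anderson_darling_normal(x).reject_normality:
                keep += 1
        assert keep >= 90

    def test_power_heavy_tails(self):
        reject = 0
        for rep in range(100):
            x = np.random.default_rng(rep).standard_t(df=2, size=200)
            if ch.anderson_darling_normal(x).reject_normality:
                reject += 1
        assert reject >= 90

    def test_constant_sample_degenerate(self):
        res = ch.anderson_darling_normal(np.full(20, 3.0))
        assert res.degenerate and res.reject_normality

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ch.anderson_darling_normal(np.arange(5.0))


def brute_force_kruskal(groups):
    """Independent H computation from first principles (rank sums)."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    # average ranks for ties, built by explicit enumeration
    sorted_vals = pooled[order]
    i = 0
    while i < len(sorted_vals):
        j = i
        while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = np.mean(np.arange(i, j) + 1)
        i = j
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = ch.kruskal_wallis([1.0, 1.0, 1.0], [1.0, 1.0])
        assert h == 0.0 and p == 1.0

    def test_matches_brute_force_oracle(self):
        cases = [
            ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]),
            ([1.0, 1.0, 2.0], [2.0, 3.0], [4.0, 4.0, 5.0]),
            ([10.0, 20.0], [15.0, 25.0, 30.0], [5.0]),
        ]
        for groups in cases:
            h, _ = ch.kruskal_wallis(*groups)
            assert h == pytest.approx(brute_force_kruskal(groups), rel=1e-12)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            ch.kruskal_wallis([1.0, 2.0])

    def test_type_one_error_calibrated(self):
        reject = 0
        n_sims = 300
        for rep in range(n_sims):
            g = np.random.default_rng(rep)
            samples = [g.normal(size=10) for _ in range(3)]
            _, p = ch.kruskal_wallis(*samples)
            reject += p < 0.05
        assert 0.03 <= reject / n_sims <= 0.07


class TestDunnPosthoc:
    def test_adjusted_not_below_raw(self, rng):
        samples = {k: rng.normal(loc=i, size=12) for i, k in enumerate("abc")}
        df = ch.dunn_posthoc(samples)
        assert (df["p_adjusted"] >= df["p_raw"] - 1e-15).all()
        assert len(df) == 3

    def test_detects_separated_group(self, rng):
        samples = {
            "a": rng.normal(0, 1, 15),
            "b": rng.normal(0, 1, 15),
            "c": rng.normal(8, 1, 15),
        }
        df = ch.dunn_posthoc(samples)
        ac = df[(df.group_a == "a") & (df.group_b == "c")].iloc[0]
        ab = df[(df.group_a == "a") & (df.group_b == "b")].iloc[0]
        assert ac.p_adjusted < 0.05 < ab.p_adjusted


class TestCompareGroups:
    @staticmethod
    def _table(rng, effect=3.0):
        rows = []
        for i in range(15):
            rows.append({"subject_id": f"o{i}", "group": "osb",
                         "parameter": "v", "period": "global",
                         "rate": float(rng.lognormal(np.log(effect), 0.5))})
        for i in range(10):
            rows.append({"subject_id": f"c{i}", "group": "control",
                         "parameter": "v", "period": "global",
                         "rate": float(rng.lognormal(0.0, 0.5))})
        return pd.DataFrame(rows)

    def test_medians_match_brute_force_sort(self, rng):
        tab = self._table(rng)
        res = ch.compare_groups(tab)[0]
        for gname in ("osb", "control"):
            vals = np.sort(tab[tab.group == gname]["rate"].to_numpy())
            assert res.medians[gname] == pytest.approx(np.percentile(vals, 50))
            lo, hi = res.iqrs[gname]
            assert lo <= res.medians[gname] <= hi

    def test_detects_programmed_difference(self, rng):
        res = ch.compare_groups(self._table(rng, effect=4.0))[0]
        assert res.significant and res.p_adjusted < 0.05

    def test_single_subject_group_skipped(self):
        tab = pd.DataFrame([
            {"subject_id": "a", "group": "osb", "parameter": "v",
             "period": "global", "rate": 1.0},
            {"subject_id": "b", "group": "control", "parameter": "v",
             "period": "global", "rate": 2.0},
        ])
        res = ch.compare_groups(tab)[0]
        assert res.skipped_reason is not None
        assert res.h_statistic is None
        assert res.medians["osb"] == 1.0

    def test_rates_table_excludes_incomplete(self):
        rows = []
        for t, ga in ((1, 23.0), (2, 25.0), (3, 31.0)):
            rows.append({"subject_id": "full", "group": "osb", "timepoint": t,
                         "ga_weeks": ga, "parameter": "v", "value": 10.0 * t})
        rows.append({"subject_id": "partial", "group": "osb", "timepoint": 1,
                     "ga_weeks": 23.0, "parameter": "v", "value": 5.0})
        rates = ch.rates_table(pd.DataFrame(rows))
        assert set(rates.subject_id) == {"full"}
        assert len(rates) == 3
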