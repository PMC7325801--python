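"""FC construction, Fisher-z statistics, crosstab, and classical MDS."""

import numpy as np
import pytest

from mdcore import (
    FCMatrix,
    ParcelTimeSeries,
    ValidationError,
    classical_mds,
    connection_group_stats,
    fisher_z,
    fisher_z_inv,
    group_average_fc,
    network_crosstab,
    parcel_fc,
)
from mdcore.fcnet import GROUP_NAMES, connection_pair_counts


def make_fc(r, parcels=None, hemis=None):
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    parcels = parcels or tuple(f"L_p{i}" for i in range(n))
    hemis = hemis or tuple(p[0] for p in parcels)
    return FCMatrix(r=r, parcel_ids=parcels, hemispheres=hemis)


def uniform_fc(n, off, parcels=None, hemis=None):
    r = np.full((n, n), off)
    np.fill_diagonal(r, 1.0)
    return make_fc(r, parcels, hemis)


class TestParcelFC:
    def test_self_and_anticorrelation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(60)
        ts = ParcelTimeSeries(
            data=np.column_stack([x, -x]),
            parcel_ids=("L_a", "L_b"),
            hemispheres=("L", "L"),
        )
        fc = parcel_fc(ts)
        assert fc.r[0, 0] == 1.0
        assert fc.r[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((50, 5))
        ts = ParcelTimeSeries(
            data=data,
            parcel_ids=tuple(f"L_p{i}" for i in range(5)),
            hemispheres=("L",) * 5,
        )
        fc = parcel_fc(ts)
        centered = data - data.mean(axis=0)
        for i in range(5):
            for j in range(5):
                num = (centered[:, i] * centered[:, j]).sum()
                den = np.sqrt((centered[:, i] ** 2).sum() * (centered[:, j] ** 2).sum())
                assert fc.r[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_constant_series_named(self):
        ts = ParcelTimeSeries(
            data=np.column_stack([np.ones(10), np.arange(10.0)]),
            parcel_ids=("L_flat", "L_ok"),
            hemispheres=("L", "L"),
        )
        with pytest.raises(ValidationError, match="L_flat"):
            parcel_fc(ts)


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_round_trip_identity(self):
        r = np.linspace(-0.999, 0.999, 101)
        np.testing.assert_allclose(fisher_z_inv(fisher_z(r)), r, atol=1e-12)

    def test_out_of_domain_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            z = fisher_z(1.0)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))
        with pytest.raises(ValidationError):
            fisher_z(1.0, clamp=False)


class TestConnectionGroups:
    PARCELS = ("L_c1", "L_c2", "L_p1", "L_n1", "R_c1", "R_c2", "R_p1", "R_n1")
    PARTITION = {
        "L_c1": "core", "L_c2": "core", "L_p1": "penumbra", "L_n1": "nonMD",
        "R_c1": "core", "R_c2": "core", "R_p1": "penumbra", "R_n1": "nonMD",
    }

    def test_toy_pair_counts(self):
        """2 core, 1 penumbra, 1 nonMD per hemisphere: CC=1, CP=2, PP=0,
        CN=2, PN=1, NN=0 within-hemisphere pairs."""
        fc = uniform_fc(8, 0.1, self.PARCELS)
        counts = connection_pair_counts(fc, self.PARTITION)
        expected = {
            ("core", "core"): 1, ("core", "penumbra"): 2,
            ("penumbra", "penumbra"): 0, ("core", "nonMD"): 2,
            ("penumbra", "nonMD"): 1, ("nonMD", "nonMD"): 0,
        }
        for hemi in ("L", "R"):
            for group, n in expected.items():
                assert counts[(hemi, group)] == n

    def test_empty_group_raises_unless_allowed(self):
        fcs = [uniform_fc(8, 0.1, self.PARCELS) for _ in range(3)]
        with pytest.raises(ValidationError, match="no pairs"):
            connection_group_stats(fcs, self.PARTITION)
        stats = connection_group_stats(fcs, self.PARTITION, allow_empty=True)
        assert len(stats.comparisons) < 30  # empty groups skipped

    def test_all_equal_fc_gives_equal_means_and_zero_t(self):
        fcs = [uniform_fc(8, 0.2, self.PARCELS) for _ in range(4)]
        stats = connection_group_stats(fcs, self.PARTITION, allow_empty=True)
        for hemi in ("L", "R"):
            defined = stats.mean_z[hemi][:, ~np.isnan(stats.mean_z[hemi][0])]
            np.testing.assert_allclose(defined, np.arctanh(0.2), atol=1e-12)
        assert all(c["t"] == 0.0 for c in stats.comparisons)

    def test_group_count_and_comparison_count(self, default_config):
        from mdcore import iter_rest_timeseries

        fcs = [parcel_fc(ts) for ts in iter_rest_timeseries(default_config, 4)]
        part = default_config.atlas.parcel_partition()
        stats = connection_group_stats(fcs, part)
        assert len(GROUP_NAMES) == 6
        assert stats.m == 30
        assert len(stats.comparisons) == 30

    def test_core_core_exceeds_core_penumbra_both_hemispheres(self, default_config):
        from mdcore import iter_rest_timeseries

        fcs = [parcel_fc(ts) for ts in iter_rest_timeseries(default_config, 8)]
        part = default_config.atlas.parcel_partition()
        stats = connection_group_stats(fcs, part)
        for hemi in ("L", "R"):
            assert stats.group_mean(hemi, ("core", "core")) > stats.group_mean(
                hemi, ("core", "penumbra")
            )
            comp = next(
                c for c in stats.comparisons
                if c["hemisphere"] == hemi
                and {c["group_a"], c["group_b"]}
                == {("core", "core"), ("core", "penumbra")}
            )
            assert comp["significant"] and comp["t"] > 0

    def test_invariant_to_relabeling_within_class(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(-0.4, 0.6, size=(8, 8))
        r = 0.5 * (base + base.T)
        np.fill_diagonal(r, 1.0)
        fc = make_fc(r, self.PARCELS)
        stats = connection_group_stats([fc, fc], self.PARTITION, allow_empty=True)
        # swap the two left core parcels: same class, same group means
        perm = [1, 0, 2, 3, 4, 5, 6, 7]
        fc2 = make_fc(r[np.ix_(perm, perm)], self.PARCELS)
        stats2 = connection_group_stats([fc2, fc2], self.PARTITION, allow_empty=True)
        np.testing.assert_allclose(
            stats.mean_z["L"], stats2.mean_z["L"], atol=1e-12, equal_nan=True
        )


class TestNetworkCrosstab:
    def test_counts_sum_to_parcel_totals(self, default_config):
        atlas = default_config.atlas
        part = atlas.parcel_partition()
        networks = {
            p: atlas.networks[a]
            for p, a in zip(atlas.parcel_ids, atlas.parcel_area_names)
        }
        tab = network_crosstab(part, networks)
        total = sum(sum(v.values()) for v in tab.values())
        assert total == 360

    def test_all_core_areas_in_fpn(self, default_config):
        atlas = default_config.atlas
        part = atlas.parcel_partition()
        networks = {
            p: atlas.networks[a]
            for p, a in zip(atlas.parcel_ids, atlas.parcel_area_names)
        }
        tab = network_crosstab(part, networks)
        n_core_total = sum(v["core"] for v in tab.values())
        assert tab["FPN"]["core"] == n_core_total == 20  # 10 areas x 2 hemispheres

    def test_missing_labels_rejected(self):
        with pytest.raises(ValidationError, match="network"):
            network_crosstab({"L_a": "core"}, {})


class TestGroupAverageFC:
    def test_single_subject_identity(self):
        fc = uniform_fc(4, 0.3)
        out = group_average_fc([fc])
        np.testing.assert_allclose(out.r, fc.r, atol=1e-9)

    def test_opposite_subjects_cancel(self):
        fc1 = uniform_fc(4, 0.5)
        fc2 = uniform_fc(4, -0.5)
        out = group_average_fc([fc1, fc2])
        off = out.r[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_matches_tanh_mean_arctanh_oracle(self):
        rng = np.random.default_rng(4)
        fcs = []
        for _ in range(3):
            base = rng.uniform(-0.8, 0.8, size=(5, 5))
            r = 0.5 * (base + base.T)
            np.fill_diagonal(r, 1.0)
            fcs.append(make_fc(r))
        out = group_average_fc(fcs)
        stack = np.stack([fc.r for fc in fcs])
        mask = ~np.eye(5, dtype=bool)
        oracle = np.tanh(np.arctanh(stack[:, mask]).mean(axis=0))
        np.testing.assert_allclose(out.r[mask], oracle, atol=1e-12)


class TestClassicalMDS:
    def test_two_points(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        res = classical_mds(d, k=1)
        np.testing.assert_allclose(np.sort(res.coordinates[:, 0]), [-1.0, 1.0], atol=1e-9)

    def test_equilateral_triangle_distances_reproduced(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = classical_mds(d, k=2)
        np.testing.assert_allclose(res.distances(), d, atol=1e-9)

    def test_planar_configuration_round_trip(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((7, 2))
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        res = classical_mds(d, k=2)
        np.testing.assert_allclose(res.distances(), d, atol=1e-8)
        assert res.n_negative == 0

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            classical_mds(d)

    def test_core_areas_cluster_in_embedding(self, default_config):
        """The MD core occupies a tighter region of the 1-r embedding than
        its separation from the penumbra."""
        from mdcore import iter_rest_timeseries

        fcs = [parcel_fc(ts) for ts in iter_rest_timeseries(default_config, 6)]
        gavg = group_average_fc(fcs)
        part = default_config.atlas.parcel_partition()
        md = [i for i, p in enumerate(gavg.parcel_ids) if part[p] != "nonMD"]
        classes = np.array([part[gavg.parcel_ids[i]] for i in md])
        d = 1.0 - gavg.r[np.ix_(md, md)]
        np.fill_diagonal(d, 0.0)
        res = classical_mds(np.clip(d, 0.0, None), k=2)
        emb = res.distances()
        core = classes == "core"
        cc = emb[np.ix_(core, core)]
        cc_mean = cc[np.triu_indices_from(cc, k=1)].mean()
        cp_mean = emb[np.ix_(core, ~core)].mean()
        assert cc_mean < cp_mean
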