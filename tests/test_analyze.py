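import numpy as np
import pandas as pd
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from cycif.analyze import (
    WANDERLUST_DEFAULTS,
    GateConfig,
    export_for_embedding,
    gate_cell_cycle,
    hcluster,
    load_supplementary_table,
    normalize_for_export,
    pairwise_r2,
)

from .oracles import brute_force_upgma, pearson_textbook


class TestPairwiseR2:
    def test_affine_relation_r2_one(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        t["y"] = 2 * t.x + 1
        r, r2, n = pairwise_r2(t, "x", "y")
        assert r2 == pytest.approx(1.0)
        assert n == 4

    def test_five_point_hand_vectors_match_textbook(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        t = pd.DataFrame({"x": x, "y": y})
        r, r2, _ = pairwise_r2(t, "x", "y")
        r_oracle = pearson_textbook(x, y)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert r2 == pytest.approx(r_oracle**2, abs=1e-12)

    def test_log_transform(self, rng):
        x = rng.lognormal(0, 1, 100)
        noise = rng.lognormal(0, 0.1, 100)
        t = pd.DataFrame({"x": x, "y": x**1.5 * noise})
        r_log, _, _ = pairwise_r2(t, "x", "y", transform="log")
        assert r_log == pytest.approx(
            pearson_textbook(np.log(x), np.log(t.y)), abs=1e-12
        )

    def test_zero_variance_undefined(self):
        t = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        r, r2, n = pairwise_r2(t, "x", "y")
        assert np.isnan(r) and np.isnan(r2)

    def test_missing_skipped(self):
        t = pd.DataFrame({"x": [1, 2, np.nan, 4, 5.0], "y": [1, 2, 3, 4, 5.0]})
        _, _, n = pairwise_r2(t, "x", "y")
        assert n == 4

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.floats(min_value=0.1, max_value=10),
        b=st.floats(min_value=-5, max_value=5),
        seed=st.integers(0, 2**31),
    )
    def test_r2_invariant_under_affine(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(30)
        y = x + 0.3 * rng.random(30)
        t = pd.DataFrame({"x": x, "y": y, "ys": a * y + b})
        _, r2_raw, _ = pairwise_r2(t, "x", "y")
        _, r2_aff, _ = pairwise_r2(t, "x", "ys")
        assert r2_aff == pytest.approx(r2_raw, abs=1e-9)


class TestHCluster:
    def test_two_points_single_merge(self):
        t = pd.DataFrame({"a": [0.0, 3.0], "b": [0.0, 4.0]})
        res = hcluster(t, ["a", "b"], n_clusters=1)
        assert res.merge_heights.tolist() == [5.0]

    def test_four_points_match_hand_upgma(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [10.5, 0.0]])
        t = pd.DataFrame(pts, columns=["a", "b"])
        res = hcluster(t, ["a", "b"], n_clusters=1)
        oracle = brute_force_upgma(pts)
        np.testing.assert_allclose(sorted(res.merge_heights), oracle, atol=1e-9)

    def test_oracle_equivalence_random_small_sets(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            pts = rng.random((n, 3)) * 10
            t = pd.DataFrame(pts, columns=["a", "b", "c"])
            res = hcluster(t, ["a", "b", "c"], n_clusters=1)
            oracle = brute_force_upgma(pts)
            np.testing.assert_allclose(sorted(res.merge_heights), oracle, atol=1e-9)

    def test_merge_heights_monotone(self, rng):
        pts = rng.random((40, 4))
        t = pd.DataFrame(pts, columns=list("abcd"))
        res = hcluster(t, list("abcd"), n_clusters=3)
        assert (np.diff(res.merge_heights) >= -1e-12).all()

    def test_separated_gaussians_recovered(self, rng):
        a = rng.normal(0, 1, (100, 2))
        b = rng.normal(10, 1, (100, 2))  # 10 sigma separation
        t = pd.DataFrame(np.vstack([a, b]), columns=["x", "y"])
        res = hcluster(t, ["x", "y"], n_clusters=2)
        labels = res.labels
        assert len(set(labels[:100])) == 1
        assert len(set(labels[100:])) == 1
        assert labels[0] != labels[100]

    def test_missing_rows_dropped_and_counted(self):
        t = pd.DataFrame({"a": [1.0, np.nan, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]})
        res = hcluster(t, ["a", "b"], n_clusters=2)
        assert res.n_dropped == 1
        assert len(res.labels) == 3

    def test_too_many_clusters_rejected(self):
        t = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="n_clusters"):
            hcluster(t, ["a"], n_clusters=3)


class TestGateCellCycle:
    def cfg(self):
        return GateConfig(
            prb_column="prb", dna_column="dna", ki67_column="ki67",
            prb_threshold=10.0, dna_threshold=100.0, ki67_threshold=5.0,
        )

    def test_all_below_thresholds_all_g0(self):
        t = pd.DataFrame({"prb": [1.0] * 5, "dna": [50.0] * 5, "ki67": [1.0] * 5})
        labels, fractions = gate_cell_cycle(t, self.cfg())
        assert (labels == "G0").all()
        assert fractions["G0"] == 1.0

    def test_three_cluster_mixture_recovered_exactly(self, rng):
        n = 300
        # G0: low prb, low ki67; G1/S: high prb, low dna; G2: high prb, high dna
        g0 = pd.DataFrame(
            {"prb": rng.normal(2, 1, n), "dna": rng.normal(50, 5, n),
             "ki67": rng.normal(1, 0.5, n)}
        )
        g1s = pd.DataFrame(
            {"prb": rng.normal(50, 5, n // 2), "dna": rng.normal(60, 5, n // 2),
             "ki67": rng.normal(20, 2, n // 2)}
        )
        g2 = pd.DataFrame(
            {"prb": rng.normal(50, 5, n // 3), "dna": rng.normal(150, 10, n // 3),
             "ki67": rng.normal(20, 2, n // 3)}
        )
        t = pd.concat([g0, g1s, g2], ignore_index=True)
        labels, fractions = gate_cell_cycle(t, self.cfg())
        total = n + n // 2 + n // 3
        assert fractions["G0"] == pytest.approx(n / total)
        assert fractions["G1/S"] == pytest.approx((n // 2) / total)
        assert fractions["G2"] == pytest.approx((n // 3) / total)

    def test_fractions_sum_to_one(self, rng):
        t = pd.DataFrame(
            {"prb": rng.random(100) * 20, "dna": rng.random(100) * 200,
             "ki67": rng.random(100) * 10}
        )
        _, fractions = gate_cell_cycle(t, self.cfg())
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_table_undefined_fractions(self):
        t = pd.DataFrame({"prb": [], "dna": [], "ki67": []})
        labels, fractions = gate_cell_cycle(t, self.cfg())
        assert len(labels) == 0
        assert all(np.isnan(v) for v in fractions.values())

    def test_missing_markers_unlabelled(self):
        t = pd.DataFrame(
            {"prb": [1.0, np.nan], "dna": [50.0, 50.0], "ki67": [1.0, 1.0]}
        )
        labels, _ = gate_cell_cycle(t, self.cfg())
        assert labels.iloc[1] == "unlabelled"

    def test_missing_column_raises(self):
        t = pd.DataFrame({"prb": [1.0]})
        with pytest.raises(KeyError, match="gate marker"):
            gate_cell_cycle(t, self.cfg())


class TestNormalizeForExport:
    def test_all_zeros_percentile_stays_zero(self):
        t = pd.DataFrame({"a": [0.0, 0.0, 0.0]})
        out = normalize_for_export(t, method="percentile")
        assert (out["a"] == 0.0).all()

    def test_arcsinh_inverse_identity(self):
        c = 150.0
        t = pd.DataFrame({"a": [c * np.sinh(1.0)]})
        out = normalize_for_export(t, method="arcsinh", cofactor=c)
        assert out["a"].iloc[0] == pytest.approx(1.0, rel=1e-12)

    def test_percentile_matches_minmax_formula(self, rng):
        vals = rng.random(50) * 100
        t = pd.DataFrame({"a": vals})
        out = normalize_for_export(t, method="percentile")
        expected = (vals - vals.min()) / (vals.max() - vals.min())
        np.testing.assert_allclose(out["a"], expected, atol=1e-12)

    def test_method_recorded_in_metadata(self):
        t = pd.DataFrame({"a": [1.0, 2.0]})
        out = normalize_for_export(t, method="arcsinh", cofactor=5.0)
        assert out.attrs["normalization"]["method"] == "arcsinh"
        assert out.attrs["normalization"]["cofactor"] == 5.0

    def test_non_finite_rejected_with_location(self):
        t = pd.DataFrame({"a": [1.0, np.inf, 3.0]})
        with pytest.raises(ValueError, match="a"):
            normalize_for_export(t)


class TestExportForEmbedding:
    def _table(self):
        return pd.DataFrame(
            {
                "condition": ["DMSO"] * 3 + ["vem_0.1uM"] * 2,
                "m1": [1.0, 2.0, 3.0, 4.0, 5.0],
                "m2": [5.0, 4.0, 3.0, 2.0, 1.0],
            }
        )

    def test_one_file_per_condition_plus_manifest(self, tmp_path):
        files = export_for_embedding(self._table(), tmp_path, "condition")
        csvs = [f for f in files if f.suffix == ".csv"]
        assert len(csvs) == 2
        assert (tmp_path / "manifest.yaml").exists()

    def test_manifest_records_tool_defaults(self, tmp_path):
        export_for_embedding(self._table(), tmp_path, "condition")
        with open(tmp_path / "manifest.yaml") as fh:
            doc = yaml.safe_load(fh)
        assert doc["wanderlust_defaults"] == {
            "L": 30, "K": 5, "n_landmarks": 20, "n_graphs": 25, "metric": "cosine",
        }
        assert WANDERLUST_DEFAULTS["metric"] == "cosine"

    def test_reimport_bit_exact(self, tmp_path, rng):
        t = pd.DataFrame(
            {"condition": ["a"] * 4, "m": rng.random(4) * 1e6}
        )
        files = export_for_embedding(t, tmp_path, "condition")
        back = pd.read_csv(files[0])
        np.testing.assert_array_equal(back["m"].to_numpy(), t["m"].to_numpy())

    def test_incomplete_rejected(self, tmp_path):
        t = self._table()
        t.loc[0, "m1"] = np.nan
        with pytest.raises(ValueError, match="complete"):
            export_for_embedding(t, tmp_path, "condition")


class TestLoadSupplementaryTable:
    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_supplementary_table(tmp_path / "nope.csv")

    def test_csv_with_condition_column(self, tmp_path):
        t = pd.DataFrame({"Condition": ["DMSO", "x"], "pS6_235": [1.0, 2.0]})
        p = tmp_path / "supp.csv"
        t.to_csv(p, index=False)
        out = load_supplementary_table(p)
        assert "condition" in out.columns

    def test_explicit_condition_column(self, tmp_path):
        t = pd.DataFrame({"well": ["DMSO", "x"], "pS6_235": [1.0, 2.0]})
        p = tmp_path / "supp.csv"
        t.to_csv(p, index=False)
        out = load_supplementary_table(p, condition_column="well")
        assert list(out["condition"]) == ["DMSO", "x"]

    def test_ps6_correlation_on_synthetic_layout(self, tmp_path, rng):
        # emulate the deposited 8-channel table's layout: condition rows with
        # two S6-phosphosite columns at a known correlation
        from cycif.analyze import ps6_correlation
        from cycif.synth import sample_correlated_intensities

        corr = np.array([[1.0, 0.9], [0.9, 1.0]])
        x = sample_correlated_intensities(2000, corr, 0.0, 0.5, rng)
        t = pd.DataFrame(
            {
                "condition": ["DMSO"] * 1000 + ["0.1uM vemurafenib"] * 1000,
                "p-S6(S235/236)": np.log(x[:, 0]),
                "p-S6(S240/244)": np.log(x[:, 1]),
                "Ki-67": rng.random(2000),
            }
        )
        p = tmp_path / "supp.csv"
        t.to_csv(p, index=False)
        table = load_supplementary_table(p)
        r2, n = ps6_correlation(table, "dmso")
        assert n == 1000
        assert r2 == pytest.approx(0.81, abs=0.05)

    def test_unidentifiable_layout_refused(self, tmp_path):
        t = pd.DataFrame({"a": [1.0], "b": [2.0]})
        p = tmp_path / "supp.csv"
        t.to_csv(p, index=False)
        with pytest.raises(ValueError, match="condition column"):
            load_supplementary_table(p)
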