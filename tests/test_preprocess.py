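"""Ct normalization, stability ranking, imputation, averaging, scaling."""

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st
import pandas as pd
import pytest

from hmfnet import preprocess
from hmfnet.containers import Profile, ProfileSet


def _ct(rows):
    return pd.DataFrame(
        rows, columns=["animal", "strain", "organ", "age_weeks", "gene", "Ct"]
    )


class TestNormalizeCt:
    def test_single_sample_median_centering(self):
        ct = _ct(
            [
                ("a1", "d", "o", 4.0, "g1", 10.0),
                ("a1", "d", "o", 4.0, "g2", 12.0),
                ("a1", "d", "o", 4.0, "g3", 14.0),
            ]
        )
        out = preprocess.normalize_ct(ct)
        # dCt = (-2, 0, 2); with one sample the ddCt centering removes it all
        assert out["value"].tolist() == [0.0, 0.0, 0.0]

    def test_identical_samples_center_to_zero(self):
        rows = []
        for a in ("a1", "a2", "a3"):
            rows += [(a, "d", "o", 4.0, g, ct) for g, ct in [("g1", 8.0), ("g2", 9.0)]]
        out = preprocess.normalize_ct(_ct(rows))
        assert np.allclose(out["value"], 0.0)

    def test_hand_computed_two_sample_table(self):
        # sample a1: Ct (10, 12, 14) -> dCt (-2, 0, 2)
        # sample a2: Ct (20, 21, 25) -> dCt (-1, 0, 4)
        # per-gene medians over samples: (-1.5, 0, 3)
        # -ddCt: a1 (0.5, 0, 1), a2 (-0.5, 0, -1)
        rows = [
            ("a1", "d", "o", 4.0, "g1", 10.0),
            ("a1", "d", "o", 4.0, "g2", 12.0),
            ("a1", "d", "o", 4.0, "g3", 14.0),
            ("a2", "d", "o", 6.0, "g1", 20.0),
            ("a2", "d", "o", 6.0, "g2", 21.0),
            ("a2", "d", "o", 6.0, "g3", 25.0),
        ]
        out = preprocess.normalize_ct(_ct(rows)).set_index(["animal", "gene"])["value"]
        expected = {
            ("a1", "g1"): 0.5,
            ("a1", "g2"): 0.0,
            ("a1", "g3"): 1.0,
            ("a2", "g1"): -0.5,
            ("a2", "g2"): 0.0,
            ("a2", "g3"): -1.0,
        }
        for key, val in expected.items():
            assert out[key] == pytest.approx(val)

    def test_median_zero_invariants_hold_exactly(self):
        rng = np.random.default_rng(0)
        rows = []
        for a in range(6):
            age = [4.0, 6.0, 8.0][a % 3]
            for g in range(5):
                rows.append((f"a{a}", "d", "o", age, f"g{g}", rng.normal(25, 3)))
        out = preprocess.normalize_ct(_ct(rows))
        # recompute dCt and ddCt from the inverse relation value = -ddCt
        ddct = -out["value"]
        per_gene = ddct.groupby(out["gene"]).median()
        assert np.allclose(per_gene, 0.0)

    def test_all_missing_sample_dropped_with_warning(self, caplog):
        rows = [
            ("a1", "d", "o", 4.0, "g1", 10.0),
            ("a1", "d", "o", 4.0, "g2", 11.0),
            ("a2", "d", "o", 4.0, "g1", np.nan),
            ("a2", "d", "o", 4.0, "g2", np.nan),
        ]
        with caplog.at_level("WARNING"):
            out = preprocess.normalize_ct(_ct(rows))
        assert "a2" not in set(out["animal"])
        assert any("all genes missing" in r.message for r in caplog.records)

    def test_missing_entries_propagate(self):
        rows = [
            ("a1", "d", "o", 4.0, "g1", 10.0),
            ("a1", "d", "o", 4.0, "g2", np.nan),
            ("a1", "d", "o", 4.0, "g3", 14.0),
        ]
        out = preprocess.normalize_ct(_ct(rows)).set_index("gene")["value"]
        assert np.isnan(out["g2"])
        assert np.isfinite(out["g1"])


class TestRankPseudoReference:
    def test_constant_genes_tie_at_rank_one(self):
        rows = []
        for a in ("a1", "a2", "a3"):
            rows += [(a, "d", "o", 4.0, g, v) for g, v in [("g1", 5.0), ("g2", 9.0)]]
        out = preprocess.rank_pseudo_reference(_ct(rows))
        assert (out["rank"] == 1).all()

    def test_noisy_gene_ranked_last(self):
        rows = []
        for i, a in enumerate(("a1", "a2", "a3", "a4")):
            rows += [
                (a, "d", "o", 4.0, "g1", 5.0),
                (a, "d", "o", 4.0, "g2", 9.0),
                (a, "d", "o", 4.0, "g3", 20.0 + 10.0 * i),
            ]
        out = preprocess.rank_pseudo_reference(_ct(rows)).set_index("candidate")
        assert out.loc["g3", "rank"] == 4  # 3 genes + the median candidate

    def test_ranks_match_brute_force_sort(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(3)]
        rows = []
        data = {}
        for a in ("a1", "a2", "a3", "a4"):
            vals = rng.normal(20, 2, size=3)
            data[a] = vals
            rows += [(a, "d", "o", 4.0, g, v) for g, v in zip(genes, vals)]
        out = preprocess.rank_pseudo_reference(_ct(rows)).set_index("candidate")
        mat = np.stack([data[a] for a in ("a1", "a2", "a3", "a4")])
        scores = {g: mat[:, i].std(ddof=1) for i, g in enumerate(genes)}
        scores["<median>"] = np.median(mat, axis=1).std(ddof=1)
        order = sorted(scores, key=scores.get)
        for rank, cand in enumerate(order, start=1):
            assert out.loc[cand, "rank"] == rank
            assert out.loc[cand, "score"] == pytest.approx(scores[cand])


def _expr(rows):
    return pd.DataFrame(
        rows, columns=["animal", "strain", "organ", "age_weeks", "gene", "value"]
    )


class TestImputeMissing:
    def test_no_missing_is_identity(self):
        df = _expr([("a1", "d", "o", 4.0, "g1", 1.0), ("a1", "d", "o", 4.0, "g2", 2.0)])
        out = preprocess.impute_missing(df)
        pd.testing.assert_frame_equal(out, df)

    def test_constant_neighbors_impute_their_value(self):
        rows = [("a0", "d", "o", 4.0, "g1", 0.0), ("a0", "d", "o", 4.0, "g2", np.nan)]
        for i in range(1, 4):
            rows += [
                (f"a{i}", "d", "o", 4.0, "g1", 0.0),
                (f"a{i}", "d", "o", 4.0, "g2", 7.0),
            ]
        out = preprocess.impute_missing(_expr(rows), k=3)
        val = out[(out.animal == "a0") & (out.gene == "g2")]["value"].iloc[0]
        assert val == pytest.approx(7.0)

    def test_two_nearest_neighbor_mean_matches_exhaustive_oracle(self):
        # s1 is missing g3; distances on shared genes (g1, g2):
        # d(s1,s2)=0.1, d(s1,s3)=0.1, d(s1,s4)~14.1, d(s1,s5)~15.6
        # -> k=2 neighbors are s2, s3 with g3 values (5, 7) -> imputed 6
        g = {"s1": (0.0, 0.0, np.nan), "s2": (0.1, 0.0, 5.0), "s3": (0.0, 0.1, 7.0),
             "s4": (10.0, 10.0, 100.0), "s5": (11.0, 11.0, 200.0)}
        rows = []
        for a, (v1, v2, v3) in g.items():
            rows += [
                (a, "d", "o", 4.0, "g1", v1),
                (a, "d", "o", 4.0, "g2", v2),
                (a, "d", "o", 4.0, "g3", v3),
            ]
        out = preprocess.impute_missing(_expr(rows), k=2)
        val = out[(out.animal == "s1") & (out.gene == "g3")]["value"].iloc[0]
        assert val == pytest.approx(6.0)

    def test_never_alters_observed_entries(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(6):
            for g in range(4):
                v = np.nan if (i, g) == (0, 0) else rng.normal()
                rows.append((f"a{i}", "d", "o", 4.0, f"g{g}", v))
        df = _expr(rows)
        out = preprocess.impute_missing(df, k=3)
        merged = df.merge(
            out, on=["animal", "strain", "organ", "age_weeks", "gene"], suffixes=("", "_i")
        )
        observed = merged["value"].notna()
        assert np.allclose(merged.loc[observed, "value"], merged.loc[observed, "value_i"])

    def test_fewer_neighbors_than_k_warns_and_uses_all(self, caplog):
        rows = [
            ("a1", "d", "o", 4.0, "g1", 1.0),
            ("a1", "d", "o", 4.0, "g2", np.nan),
            ("a2", "d", "o", 4.0, "g1", 1.5),
            ("a2", "d", "o", 4.0, "g2", 3.0),
        ]
        with caplog.at_level("WARNING"):
            out = preprocess.impute_missing(_expr(rows), k=10)
        val = out[(out.animal == "a1") & (out.gene == "g2")]["value"].iloc[0]
        assert val == pytest.approx(3.0)
        assert any("neighbor" in r.message for r in caplog.records)


class TestMeanProfilesAndScaling:
    def test_replicate_mean_and_single_replicate(self):
        rows = [
            ("a1", "d", "o", 4.0, "g1", 1.0),
            ("a2", "d", "o", 4.0, "g1", 3.0),
            ("a1", "d", "o", 6.0, "g1", 5.0),
        ]
        ps = preprocess.mean_profiles(_expr(rows))
        p = ps[("d", "o", "g1")]
        assert p.mean == pytest.approx([2.0, 5.0])
        assert list(p.n_reps) == [2, 1]

    def test_dropped_cell_shortens_one_profile(self):
        rows = []
        for age in (4.0, 6.0, 8.0):
            rows.append(("a1", "d", "o1", age, "g1", 1.0 * age))
            if age != 6.0:
                rows.append(("a1", "d", "o2", age, "g1", 2.0 * age))
        ps = preprocess.mean_profiles(_expr(rows))
        assert len(ps[("d", "o1", "g1")].times) == 3
        assert len(ps[("d", "o2", "g1")].times) == 2

    def test_affine_scaling_example(self):
        ps = ProfileSet([Profile("d", "o", "g", [4.0, 6.0, 8.0], [2.0, 4.0, 6.0])])
        out = preprocess.scale_profiles(ps)
        assert out[("d", "o", "g")].scaled == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_profile_scales_to_zeros(self):
        ps = ProfileSet([Profile("d", "o", "g", [4.0, 6.0], [3.0, 3.0])])
        out = preprocess.scale_profiles(ps)
        assert np.all(out[("d", "o", "g")].scaled == 0.0)

    def test_scaling_invertible_with_stored_extrema(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=5)
        ps = preprocess.scale_profiles(
            ProfileSet([Profile("d", "o", "g", np.arange(5.0), vals)])
        )
        p = ps[("d", "o", "g")]
        back = p.scaled * (p.smax - p.smin) + p.smin
        assert back == pytest.approx(vals, abs=1e-12)

    def test_scaling_idempotent_on_scaled_profiles(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=6)
        once = preprocess.scale_profiles(
            ProfileSet([Profile("d", "o", "g", np.arange(6.0), vals)])
        )
        rescaled_input = ProfileSet(
            [Profile("d", "o", "g", np.arange(6.0), once[("d", "o", "g")].scaled)]
        )
        twice = preprocess.scale_profiles(rescaled_input)
        assert twice[("d", "o", "g")].scaled == pytest.approx(
            once[("d", "o", "g")].scaled
        )


class TestScalingProperties:
    """Property: scaled values always land in [0, 1] with both ends attained."""

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=8))
    def test_bounds_and_extrema(self, vals):
        ps = preprocess.scale_profiles(
            ProfileSet([Profile("d", "o", "g", np.arange(len(vals), dtype=float), vals)])
        )
        s = ps[("d", "o", "g")].scaled
        assert np.all((s >= 0.0) & (s <= 1.0))
        if len(set(vals)) > 1:
            assert s.min() == 0.0 and s.max() == 1.0
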