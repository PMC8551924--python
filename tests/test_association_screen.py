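"""Correlation screen: statistics, BH step-up, venn classes, ranking."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nbscreen.association_screen import (
    ScreenConfig,
    ScreenInputError,
    bh_fdr,
    classify_against_expected,
    fisher_z,
    pair_pvalue,
    pearson_r,
    rank_by_effect,
    run_screen,
    verify_against_annotation_sets,
)
from nbscreen.drug_screen import build_cytotoxicity_matrix
from nbscreen.genomic_profiling import segment_probes_to_genes
from nbscreen.synthetic_cohort import (
    ArmEvent,
    CohortConfig,
    PlantedPair,
    generate_cohort,
)


def brute_force_bh(p, q):
    """Literal step-up definition, independent of the screen's implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestPearson:
    def test_perfect_linear(self):
        assert pearson_r([1, 2, 3], [3, 5, 7]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # sums: Sdxdy = 3.0, Sdx2 = Sdy2 = 5.0 -> r = 3/5
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_is_undefined_not_zero(self):
        with pytest.raises(ScreenInputError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFisherZ:
    def test_closed_form_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.9) == pytest.approx(0.5 * np.log(1.9 / 0.1), abs=1e-12)
        assert fisher_z(0.9) == pytest.approx(1.4722, abs=1e-4)

    def test_odd_symmetry_on_grid(self):
        for r in np.linspace(-0.99, 0.99, 41):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-14)

    def test_unit_correlation_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            z = fisher_z(1.0)
        assert np.isfinite(z) and z == pytest.approx(np.arctanh(1 - 1e-7))


class TestPairPvalue:
    def test_null_statistic_gives_p_one(self):
        z_std, p = pair_pvalue(0.0, 13)
        assert z_std == 0.0 and p == pytest.approx(1.0)

    def test_standardization_example(self):
        z = np.arctanh(0.745)
        z_std, _ = pair_pvalue(z, 13)
        assert z_std == pytest.approx(z * np.sqrt(10), abs=1e-12)
        assert z_std == pytest.approx(3.04, abs=0.01)

    def test_monotone_decreasing_in_abs_z(self):
        ps = [pair_pvalue(z, 13)[1] for z in np.linspace(0, 3, 31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_small_n_undefined(self):
        with pytest.raises(ScreenInputError):
            pair_pvalue(0.5, 3)


class TestBenjaminiHochberg:
    def test_worked_example_three_discoveries(self):
        q, reject = bh_fdr([0.001, 0.02, 0.03, 0.5], 0.1)
        assert reject.sum() == 3 and not reject[3]

    def test_all_ones_no_discoveries(self):
        _, reject = bh_fdr([1.0, 1.0, 1.0], 0.1)
        assert not reject.any()

    def test_single_p_below_q_is_discovered(self):
        _, reject = bh_fdr([0.05], 0.1)
        assert reject.all()

    def test_adjusted_q_dominates_p(self, rng):
        p = rng.uniform(size=200)
        q, _ = bh_fdr(p, 0.1)
        assert (q >= p - 1e-12).all()

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(2000):
            m = int(rng.integers(1, 51))
            p = rng.uniform(size=m)
            if rng.random() < 0.3:  # inject ties and extremes
                p[: m // 2] = np.round(p[: m // 2], 2)
            _, reject = bh_fdr(p, 0.1)
            assert (reject == brute_force_bh(p, 0.1)).all()


def small_screen_frames(n_genes=6, n_drugs=8, n_samples=13, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"S{i:02d}" for i in range(n_samples)]
    G = pd.DataFrame(rng.normal(size=(n_genes, n_samples)),
                     index=[f"g{i}" for i in range(n_genes)], columns=samples)
    D = pd.DataFrame(rng.normal(size=(n_drugs, n_samples)),
                     index=[f"d{i}" for i in range(n_drugs)], columns=samples)
    return G, D


class TestRunScreen:
    def test_enumerates_every_pair(self):
        G, D = small_screen_frames()
        table = run_screen(G, D)
        assert len(table) == 48
        assert table["testable"].all()

    def test_no_shared_samples_is_an_error(self):
        G, D = small_screen_frames()
        D.columns = [f"T{i}" for i in range(D.shape[1])]
        with pytest.raises(ScreenInputError, match="shared samples"):
            run_screen(G, D)

    def test_constant_gene_is_undefined_and_excluded_from_m(self):
        G, D = small_screen_frames()
        G.iloc[0] = 1.5
        table = run_screen(G, D)
        und = table[~table["testable"]]
        assert set(und["gene_id"]) == {"g0"}
        assert (und["reason"] == "constant").all()
        assert und["p"].isna().all()
        assert table["testable"].sum() + len(und) == len(table)

    def test_missing_samples_trigger_min_samples_guard(self):
        G, D = small_screen_frames()
        D.iloc[0, :10] = np.nan  # 3 paired values < min_samples=5
        table = run_screen(G, D)
        d0 = table[table["drug_id"] == "d0"]
        assert (~d0["testable"]).all()
        assert (d0["reason"] == "too_few_samples").all()

    def test_sample_permutation_invariance(self):
        G, D = small_screen_frames()
        perm = np.random.default_rng(3).permutation(G.shape[1])
        table1 = run_screen(G, D).sort_values(["gene_id", "drug_id"])
        table2 = run_screen(G.iloc[:, perm], D.iloc[:, perm]).sort_values(
            ["gene_id", "drug_id"]
        )
        for col in ("r", "z", "q"):
            assert np.allclose(table1[col].to_numpy(), table2[col].to_numpy(),
                               atol=1e-12)

    def test_planted_sign_matches_slope_sign(self):
        cfg = CohortConfig(
            n_drugs=20,
            arm_event_rates=(ArmEvent("17q", "gain", 0.5), ArmEvent("11q", "loss", 0.5)),
            planted_pairs=(
                PlantedPair("GNA13", "D001", 30.0),
                PlantedPair("CBL", "D002", -30.0),
            ),
            response_noise_sd=2.0,
        )
        cohort = generate_cohort(cfg, seed=21)
        profile = segment_probes_to_genes(cohort.probe_table, list(cfg.panel))
        cyto = build_cytotoxicity_matrix(cohort.plates)
        table = run_screen(profile, cyto).set_index(["gene_id", "drug_id"])
        assert table.loc[("GNA13", "D001"), "z"] > 0
        assert table.loc[("CBL", "D002"), "z"] < 0
        # sign(z) == sign(r) throughout
        t = table.dropna(subset=["r"])
        assert (np.sign(t["z"]) == np.sign(t["r"])).all()

    def test_normal_convention_available(self):
        G, D = small_screen_frames()
        t_exact = run_screen(G, D)
        t_norm = run_screen(G, D, ScreenConfig(test="normal"))
        z = t_norm["z_std"].to_numpy()
        from scipy import stats as ss

        assert np.allclose(t_norm["p"], np.minimum(2 * ss.norm.sf(np.abs(z)), 1.0))
        assert not np.allclose(t_exact["p"], t_norm["p"])


class TestVennClassification:
    def make_table(self, n=20, n_sig=5):
        table = pd.DataFrame(
            {
                "gene_id": [f"g{i % 4}" for i in range(n)],
                "drug_id": [f"d{i // 4}" for i in range(n)],
                "significant": [i < n_sig for i in range(n)],
            }
        )
        return table

    def test_counts_partition_universe(self):
        table = self.make_table()
        expected = {("g0", "d0"), ("g1", "d0"), ("g3", "d4")}
        out, counts = classify_against_expected(table, expected)
        assert counts["TP"] + counts["FP"] + counts["FN"] + counts["TN"] == len(table)
        assert (out["venn_class"].isin(["TP", "FP", "FN", "TN"])).all()
        assert counts["TP"] == 2 and counts["FN"] == 1

    def test_empty_expected_set(self):
        _, counts = classify_against_expected(self.make_table(), set())
        assert counts["TP"] == 0 and counts["FN"] == 0

    def test_expected_equals_universe(self):
        table = self.make_table()
        universe = set(zip(table["gene_id"], table["drug_id"]))
        _, counts = classify_against_expected(table, universe)
        assert counts["FP"] == 0 and counts["TN"] == 0

    def test_outside_universe_expected_warned_and_reported(self):
        with pytest.warns(UserWarning, match="not in the enumerated universe"):
            _, counts = classify_against_expected(
                self.make_table(), {("gX", "dX")}
            )
        assert counts["expected_outside_universe"] == 1


class TestRanking:
    def test_rank_score_is_product_of_cytotoxicity_and_z(self):
        table = pd.DataFrame(
            {"gene_id": ["GNA13"], "drug_id": ["PIK-75"], "z": [1.4],
             "significant": [True]}
        )
        out = rank_by_effect(table, {"PIK-75": 78.9})
        assert out.loc[0, "rank_score"] == pytest.approx(110.46)

    def test_zero_z_zero_score_and_oddness(self):
        table = pd.DataFrame(
            {"gene_id": ["a", "b"], "drug_id": ["d", "d"], "z": [0.0, 0.8],
             "significant": [True, True]}
        )
        out = rank_by_effect(table, {"d": 55.0})
        assert out.set_index("gene_id").loc["a", "rank_score"] == 0.0
        flipped = rank_by_effect(table.assign(z=-table["z"]), {"d": 55.0})
        assert np.allclose(
            sorted(flipped["rank_score"]), sorted(-out["rank_score"])
        )

    def test_descending_order_with_deterministic_ties(self):
        table = pd.DataFrame(
            {"gene_id": ["b", "a", "c"], "drug_id": ["d", "d", "d"],
             "z": [1.0, 1.0, 2.0], "significant": True}
        )
        out = rank_by_effect(table, {"d": 10.0})
        assert list(out["gene_id"]) == ["c", "a", "b"]


class TestAnnotationVerification:
    def test_empty_sets_verify_nothing(self):
        table = pd.DataFrame({"gene_id": ["a"], "drug_id": ["d"]})
        out, counts = verify_against_annotation_sets(table, {})
        assert not out["verified"].any()

    def test_union_of_overlapping_sets(self):
        table = pd.DataFrame(
            {"gene_id": list("abcde"), "drug_id": ["d"] * 5}
        )
        sets = {
            "s1": {("a", "d"), ("b", "d"), ("c", "d")},
            "s2": {("b", "d"), ("c", "d"), ("d", "d"), ("e", "d")},
        }
        out, counts = verify_against_annotation_sets(table, sets)
        union_row = counts.set_index("set").loc["__union__"]
        assert union_row["n_pairs"] == 5
        assert out["verified"].sum() == 5

    def test_all_significant_pairs_in_set_gives_fraction_one(self):
        table = pd.DataFrame(
            {"gene_id": list("ab"), "drug_id": ["d", "d"], "significant": [True, False]}
        )
        out, _ = verify_against_annotation_sets(table, {"s": {("a", "d")}})
        sig = out[out["significant"]]
        assert sig["verified"].all()


@given(
    n=st.integers(min_value=5, max_value=15),
    scale=st.floats(min_value=0.1, max_value=10, allow_nan=False),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_correlation_invariant_to_affine_rescaling(n, scale, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    r1 = pearson_r(x, y)
    r2 = pearson_r(scale * x + 3.0, y)
    assert r1 == pytest.approx(r2, abs=1e-9)
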