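import math

import numpy as np
import pandas as pd
import pytest

from hdscreen.compare import (
    RankedDataset,
    compile_dataset,
    hypergeom_p,
    overlap_significance,
    pairwise_overlap_matrix,
    running_overlap_curve,
    screen_ranked_dataset,
)


def enumeration_hypergeom(overlap, n_a, n_b, universe):
    """P(X >= overlap) by counting all C(universe, n_b) draws."""
    total = math.comb(universe, n_b)
    favorable = sum(
        math.comb(n_a, k) * math.comb(universe - n_a, n_b - k)
        for k in range(overlap, min(n_a, n_b) + 1)
    )
    return favorable / total


class TestCompileDataset:
    def test_deletion_sums_source_calls(self):
        rec = pd.DataFrame(
            {
                "gene_id": ["g1"] * 4,
                "value": [1, 1, -1, 0],
                "source_id": ["a", "b", "c", "d"],
            }
        )
        ds = compile_dataset(rec, "deletion_fitness")
        assert ds.scores["g1"] == 1

    def test_deletion_rejects_non_ternary_values(self):
        rec = pd.DataFrame({"gene_id": ["g1"], "value": [0.5], "source_id": ["a"]})
        with pytest.raises(ValueError):
            compile_dataset(rec, "deletion_fitness")

    def test_flux_absolute_sum_and_absent_zero(self):
        rec = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g1"],
                "value": [2.0, -1.5, 3.0],
                "source_id": ["s"] * 3,
                "compartment": ["c1", "c2", "c3"],
                "timepoint": [1, 1, 1],
            }
        )
        ds = compile_dataset(rec, "flux", flux_universe=["g1", "g2"])
        assert ds.scores["g1"] == pytest.approx(6.5)
        assert ds.scores["g2"] == 0.0

    def test_abundance_sd_normalize_then_add(self):
        # source A values {2, 6} (sd 2*sqrt2), source B {4, 12} (sd 4*sqrt2)
        rec = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g1", "g2"],
                "value": [2.0, 6.0, 4.0, 12.0],
                "source_id": ["A", "A", "B", "B"],
            }
        )
        ds = compile_dataset(rec, "protein_abundance")
        sd_a, sd_b = 2.0 * math.sqrt(2), 4.0 * math.sqrt(2)
        assert ds.scores["g1"] == pytest.approx(2.0 / sd_a + 4.0 / sd_b)

    def test_mrna_mean_skips_absent_sources(self):
        rec = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g2"],
                "value": [1.0, 3.0, 10.0],
                "source_id": ["A", "B", "A"],
            }
        )
        ds = compile_dataset(rec, "mrna")
        assert ds.scores["g1"] == pytest.approx(2.0)
        assert ds.scores["g2"] == pytest.approx(10.0)  # only source A has it

    def test_phospho_mixes_qualitative_and_quantitative(self):
        rec = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g1", "g2"],
                "value": [1, -1, 2.0, 4.0],
                "source_id": ["q", "q", "m", "m"],
                "qualitative": [True, True, False, False],
            }
        )
        ds = compile_dataset(rec, "phospho")
        sd = math.sqrt(2.0)
        assert ds.scores["g1"] == pytest.approx(1 + 2.0 / sd)

    def test_flux_source_order_invariance(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame(
            {
                "gene_id": rng.choice([f"g{i}" for i in range(50)], 200),
                "value": rng.normal(size=200),
                "source_id": rng.choice(["a", "b"], 200),
                "compartment": rng.choice(["c1", "c2"], 200),
                "timepoint": rng.choice([1, 2], 200),
            }
        )
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        d1 = compile_dataset(rec, "flux", flux_top=5)
        d2 = compile_dataset(shuffled, "flux", flux_top=5)
        pd.testing.assert_series_equal(d1.scores, d2.scores)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            compile_dataset(pd.DataFrame({"gene_id": [], "value": []}), "foo")


class TestOverlapSignificance:
    @staticmethod
    def ranked(values, category="mrna"):
        return RankedDataset(
            scores=pd.Series(values, index=[f"g{i}" for i in range(len(values))]),
            category=category,
        )

    def test_identical_rankings_maximal_overlap(self):
        ds = self.ranked(np.linspace(5, 1, 40))
        res = overlap_significance(ds, ds)
        for f, k in zip(res.fractions, res.overlap_counts):
            assert k == max(1, int(np.floor(f * 40)))
        assert res.min_p == min(res.p_values)

    def test_exact_small_universe_value(self):
        # universe 10, top sets of 5 and 4, overlap 4 -> 5/210
        p = hypergeom_p(4, 5, 4, 10)
        assert p == pytest.approx(5 / 210, abs=1e-12)

    def test_matches_enumeration_for_small_universes(self):
        for universe in range(3, 13):
            for n_a in range(1, universe + 1):
                for n_b in range(1, universe + 1):
                    for k in range(0, min(n_a, n_b) + 1):
                        expect = enumeration_hypergeom(k, n_a, n_b, universe)
                        assert hypergeom_p(k, n_a, n_b, universe) == pytest.approx(
                            expect, abs=1e-12
                        )

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        a = self.ranked(rng.normal(size=60))
        b = self.ranked(rng.normal(size=60))
        ra = overlap_significance(a, b)
        rb = overlap_significance(b, a)
        assert ra.p_values == rb.p_values

    def test_small_universe_rejected(self):
        a = self.ranked(np.arange(5.0))
        with pytest.raises(ValueError):
            overlap_significance(a, a)

    def test_correlated_bias_detected_over_seeds(self, small_screen):
        from hdscreen.simulate import simulate_external_datasets

        _, truth, _ = small_screen
        eff = truth.table.set_index("strain_id")["effect_log2"]
        screen = RankedDataset(scores=eff, category="screen")
        wins = 0
        n_trials = 20
        for seed in range(n_trials):
            good = simulate_external_datasets(truth, "mrna", corr=0.7, seed=seed)
            null = simulate_external_datasets(truth, "mrna", corr=0.0, seed=seed + 1000)
            pg = overlap_significance(screen, good).neg_log10_min_p
            pn = overlap_significance(screen, null).neg_log10_min_p
            wins += pg > pn
        assert wins >= 0.8 * n_trials

    def test_pairwise_matrix_symmetric(self):
        rng = np.random.default_rng(4)
        ds = {
            "a": self.ranked(rng.normal(size=50)),
            "b": self.ranked(rng.normal(size=50)),
            "c": self.ranked(rng.normal(size=50)),
        }
        mat = pairwise_overlap_matrix(ds)
        assert (mat.to_numpy().T == mat.to_numpy())[~np.isnan(mat)].all()


class TestRunningOverlapCurve:
    def test_own_top_set_peaks_then_falls(self):
        ranking = pd.Index([f"g{i}" for i in range(200)])
        top = set(ranking[:40])
        curve = running_overlap_curve(ranking, top)
        # the start window (half-width 50) holds the 40 members: ~0.78
        assert curve["smoothed"].iloc[0] > 0.75
        assert curve["smoothed"].iloc[-1] < 0.1
        assert curve["smoothed"].is_monotonic_decreasing

    def test_random_set_stays_at_base_rate(self):
        rng = np.random.default_rng(5)
        ranking = pd.Index([f"g{i}" for i in range(1000)])
        top = set(rng.choice(ranking, 200, replace=False))
        curve = running_overlap_curve(ranking, top)
        assert (curve["smoothed"] - 0.2).abs().max() < 0.05

    def test_empty_top_set_rejected(self):
        with pytest.raises(ValueError):
            running_overlap_curve(pd.Index(["a", "b"]), set())

    def test_unknown_genes_rejected(self):
        with pytest.raises(ValueError):
            running_overlap_curve(pd.Index(["a", "b"]), {"zzz"})


class TestScreenRanking:
    def test_ranking_orders_by_best_p(self, small_screen):
        from hdscreen.difftest import test_all_days
        from hdscreen.normalize import normalize_table
        from hdscreen.compare import rank_screen_results

        _, truth, table = small_screen
        res = test_all_days(normalize_table(table))
        ranking = rank_screen_results(res, mode="pvalue")
        assert len(ranking) == 500
        # spiked strains should concentrate at the front of the ranking
        front = set(ranking[:50])
        assert len(front & set(truth.spiked)) >= 20

        ds = screen_ranked_dataset(res)
        assert list(ds.ranking()[:10]) == list(ranking[:10])

    def test_signed_ranking_puts_directions_at_opposite_ends(self, small_screen):
        from hdscreen.difftest import test_all_days
        from hdscreen.normalize import normalize_table
        from hdscreen.compare import rank_screen_results

        _, truth, table = small_screen
        res = test_all_days(normalize_table(table))
        ranking = rank_screen_results(res, mode="signed")
        tt = truth.table.set_index("strain_id")
        front = [tt.loc[s, "direction"] for s in ranking[:20]]
        back = [tt.loc[s, "direction"] for s in ranking[-20:]]
        # decreased-signal strains lead, increased-signal strains trail,
        # and neither direction leaks to the wrong end
        assert front.count("-") >= 5 and front.count("+") == 0
        assert back.count("+") >= 5 and back.count("-") == 0
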