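"""Selection scoring, standardization/smoothing, locus flags, background comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rholandscape import tnseq
from rholandscape.synthetic import (
    make_background_fitness,
    simulate_transposon_selection,
)


class TestSelectionScores:
    def test_equal_channels_zero(self):
        x = np.random.default_rng(0).lognormal(8, 1, 500)
        assert np.allclose(tnseq.selection_scores(x, x), 0.0)

    def test_depleted_insertion_positive_score(self):
        rng = np.random.default_rng(1)
        ref = rng.lognormal(8, 0.5, 1000)
        sel = ref.copy()
        sel[0] = ref[0] / 4.0  # depleted 4x under selection
        sc = tnseq.selection_scores(ref, sel)
        assert sc[0] == pytest.approx(2.0, abs=0.02)

    def test_antisymmetry_under_channel_swap(self):
        rng = np.random.default_rng(2)
        ref = rng.lognormal(8, 1, 400)
        sel = rng.lognormal(8, 1, 400)
        np.testing.assert_allclose(
            tnseq.selection_scores(ref, sel), -tnseq.selection_scores(sel, ref), atol=1e-12
        )

    def test_nonpositive_intensities_floored(self):
        ref = np.array([0.0, 10.0, 20.0])
        sel = np.array([10.0, 10.0, 10.0])
        sc = tnseq.selection_scores(ref, sel)
        assert np.all(np.isfinite(sc))


class TestZscoreSmooth:
    def test_standard_normal_scores_unchanged(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(5000)
        z, _ = tnseq.zscore_and_smooth(s, np.arange(5000) * 50.0)
        np.testing.assert_allclose(z, (s - s.mean()) / s.std(ddof=1), atol=1e-12)
        assert abs(z.mean()) < 1e-10 and abs(z.std(ddof=1) - 1) < 1e-10

    def test_running_median_matches_brute_force(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.uniform(0, 25_000, 500))
        s = rng.standard_normal(500)
        _, zsm = tnseq.zscore_and_smooth(s, pos, window_bp=500)
        z = (s - s.mean()) / s.std(ddof=1)
        brute = np.array([np.median(z[(pos >= p - 250) & (pos <= p + 250)]) for p in pos])
        np.testing.assert_array_equal(zsm, brute)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            tnseq.zscore_and_smooth(np.ones(10), np.arange(10.0))

    def test_robust_variant(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(2000)
        s[:20] += 50  # outliers barely move median/MAD
        z_rob, _ = tnseq.zscore_and_smooth(s, np.arange(2000) * 50.0, robust=True)
        assert abs(np.median(z_rob)) < 0.05


class TestGeneMedians:
    def test_median_of_probe_scores(self, small_annotation):
        g = small_annotation.genes.iloc[0]
        table = pd.DataFrame(
            {
                "position": [g.start + 10, g.start + 60, g.start + 110, 10_000_000 % small_annotation.genome_length],
                "strand": ["+", "-", "+", "+"],
                "score": [1.0, 2.0, 9.0, 5.0],
            }
        )
        med = tnseq.gene_median_scores(table, small_annotation)
        assert med[g.gene_id] == 2.0

    def test_empty_gene_missing(self, small_annotation):
        table = pd.DataFrame({"position": [0], "strand": ["+"], "score": [1.0]})
        med = tnseq.gene_median_scores(table, small_annotation)
        assert med.isna().sum() >= len(small_annotation.genes) - 1

    def test_planted_effects_rank_recovered(self, annotation):
        rng = np.random.default_rng(6)
        genes = list(annotation.genes["gene_id"])
        chosen = [genes[i] for i in rng.permutation(len(genes))[:20]]
        fitness = {g: float(s) for g, s in zip(chosen, np.linspace(-0.2, 0.2, 20))}
        raw, truth = simulate_transposon_selection(annotation, fitness, seed=7)
        scored = tnseq.score_table(raw)
        med = tnseq.gene_median_scores(scored, annotation)
        observed = med[chosen].to_numpy()
        expected = -np.array([fitness[g] for g in chosen]) * truth.generations
        rho = stats.spearmanr(observed, expected).statistic
        assert rho >= 0.9


class TestFlags:
    def test_threshold_nesting(self, annotation):
        wt, _ = make_background_fitness(annotation, seed=8)
        raw, _ = simulate_transposon_selection(annotation, wt, seed=9)
        scored = tnseq.assign_loci(tnseq.score_table(raw), annotation)
        flags = tnseq.flag_loci(scored, strict_z=2.0, relaxed_z=1.0)
        assert (flags["strict"] <= flags["relaxed"]).all()
        tighter = tnseq.flag_loci(scored, strict_z=3.0, relaxed_z=1.0)
        assert tighter["strict"].sum() <= flags["strict"].sum()

    def test_negative_extreme_is_advantage(self, small_annotation):
        rng = np.random.default_rng(10)
        n = 600
        table = pd.DataFrame(
            {
                "position": np.arange(n) * 50 % small_annotation.genome_length,
                "strand": "+",
                "score": rng.normal(0, 1, n),
            }
        )
        table = table.sort_values("position").reset_index(drop=True)
        g = small_annotation.genes.iloc[3]
        inside = (table.position >= g.start) & (table.position < g.end)
        table.loc[inside, "score"] = -8.0
        z, zsm = tnseq.zscore_and_smooth(table["score"].to_numpy(), table["position"].to_numpy())
        table["z"], table["z_smoothed"] = z, zsm
        table = tnseq.assign_loci(table, small_annotation)
        flags = tnseq.flag_loci(table).set_index("locus_id")
        assert flags.loc[g.gene_id, "strict"]
        assert flags.loc[g.gene_id, "direction"] == "advantage"

    def test_null_strict_flag_rate_consistent_with_gaussian_tail(self, annotation):
        raw, _ = simulate_transposon_selection(annotation, {}, depth_noise_sd=0.2, seed=11)
        scored = tnseq.assign_loci(tnseq.score_table(raw), annotation)
        flags = tnseq.flag_loci(scored, strict_z=2.0)
        # smoothing (median of ~10 z values) shrinks the null SD well below 1,
        # so per-locus max |smoothed z| rarely reaches 2
        assert flags["strict"].mean() <= 0.05


class TestCompare:
    def test_identical_tables_no_unique(self, annotation):
        wt, _ = make_background_fitness(annotation, seed=12)
        raw, _ = simulate_transposon_selection(annotation, wt, seed=13)
        scored = tnseq.assign_loci(tnseq.score_table(raw), annotation)
        flags = tnseq.flag_loci(scored)
        med = tnseq.gene_median_scores(scored, annotation)
        comp = tnseq.compare_backgrounds(flags, flags, med, med)
        assert comp.unique_a == comp.unique_b == 0
        assert comp.shared_anticorrelated == 0
        assert comp.pearson_between_backgrounds == pytest.approx(1.0)

    def test_locus_universe_mismatch_rejected(self, annotation):
        wt, _ = make_background_fitness(annotation, seed=14)
        raw, _ = simulate_transposon_selection(annotation, wt, seed=15)
        scored = tnseq.assign_loci(tnseq.score_table(raw), annotation)
        flags = tnseq.flag_loci(scored)
        med = tnseq.gene_median_scores(scored, annotation)
        with pytest.raises(ValueError):
            tnseq.compare_backgrounds(flags, flags.iloc[:-5], med, med)

    def test_majority_unique_landscape_recovered(self, annotation):
        wt, mut = make_background_fitness(
            annotation, n_effect_loci=40, shared_fraction=0.3, seed=16
        )
        data = {}
        for name, fit, seed in [("WT", wt, 17), ("rho*", mut, 18)]:
            raw, _ = simulate_transposon_selection(annotation, fit, seed=seed)
            scored = tnseq.assign_loci(tnseq.score_table(raw, background=name), annotation)
            reps = pd.DataFrame(
                {
                    c: tnseq.gene_median_scores(scored, annotation, c)
                    for c in scored.columns
                    if c.startswith("score_rep")
                }
            )
            data[name] = (
                tnseq.flag_loci(scored),
                tnseq.gene_median_scores(scored, annotation),
                reps,
            )
        comp = tnseq.compare_backgrounds(
            data["WT"][0], data["rho*"][0], data["WT"][1], data["rho*"][1],
            data["WT"][2], data["rho*"][2],
        )
        assert abs(comp.unique_fraction - 0.7) <= 0.1
        assert comp.pearson_between_replicates > comp.pearson_between_backgrounds
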