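"""Permutation enrichment, TSS profiles, circular nulls, and loess."""

import numpy as np
import pandas as pd
import pytest

from rholandscape import enrichment
from rholandscape.enrichment import (
    LOG10_2,
    circular_permutation_null,
    loess_curve,
    overlap_enrichment,
    tss_downstream_profile,
)


def _probe_frame(genome_length=20_000, value=0.0):
    pos = np.arange(0, genome_length, 50)
    df = pd.DataFrame(
        {
            "position": pos,
            "strand": np.where(np.arange(len(pos)) % 2 == 0, "+", "-"),
            "value": np.full(len(pos), value, dtype=float),
        }
    )
    return df


class TestOverlapEnrichment:
    def test_whole_genome_features_saturate(self):
        feats = pd.DataFrame({"start": [0], "end": [10_000], "label": ["all"]})
        res = overlap_enrichment(np.arange(0, 10_000, 100), feats, 10_000, n_perm=200, seed=0)
        assert res.fold == pytest.approx(1.0)
        assert res.p_perm > 0.5
        assert "features_cover_genome" in res.flags

    def test_extreme_enrichment(self):
        feats = pd.DataFrame({"start": [1000], "end": [1100], "label": ["f"]})  # 1% of genome
        flagged = np.arange(1000, 1100, 10)  # all inside
        res = overlap_enrichment(flagged, feats, 10_000, n_perm=999, seed=1)
        assert res.fold > 50
        # a relocated interval can occasionally cover the tight flagged cluster
        assert res.p_perm <= 3 / 1000

    def test_p_never_exactly_zero_and_reproducible(self):
        feats = pd.DataFrame({"start": [0], "end": [500], "label": ["f"]})
        a = overlap_enrichment(np.arange(0, 10_000, 97), feats, 10_000, n_perm=500, seed=3)
        b = overlap_enrichment(np.arange(0, 10_000, 97), feats, 10_000, n_perm=500, seed=3)
        assert a.p_perm == b.p_perm
        assert a.p_perm >= 1 / 501

    def test_null_pvalues_roughly_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        ps = []
        for r in range(120):
            flagged = rng.integers(0, 100_000, 300)
            starts = rng.integers(0, 100_000, 25)
            feats = pd.DataFrame({"start": starts, "end": starts + 1000, "label": "f"})
            feats["end"] = np.minimum(feats["end"], 100_000)
            res = overlap_enrichment(flagged, feats, 100_000, n_perm=199, seed=1000 + r)
            # fold the direction back into a two-sided-ish uniform check
            p = res.p_perm if res.direction == "enriched" else 1 - res.p_perm + 1 / 200
            ps.append(p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.005

    def test_empty_flagged_rejected(self):
        feats = pd.DataFrame({"start": [0], "end": [100], "label": ["f"]})
        with pytest.raises(ValueError):
            overlap_enrichment(np.array([]), feats, 1000)


class TestTssProfile:
    def test_constant_signal_gives_constant_profile(self):
        probes = _probe_frame(value=2.0)
        tss = pd.DataFrame({"position": [5000, 9000], "strand": ["+", "-"]})
        prof = tss_downstream_profile(probes, tss, 20_000, to_log10=False, span=500)
        assert np.allclose(prof.observed, 2.0)

    def test_log10_conversion_at_boundary(self):
        probes = _probe_frame(value=1.0)  # log2 units
        tss = pd.DataFrame({"position": [5000], "strand": ["+"]})
        prof = tss_downstream_profile(probes, tss, 20_000, to_log10=True, span=200)
        assert np.allclose(prof.observed, LOG10_2)

    def test_hand_built_windows_match_brute_force(self):
        # 5 probes on + strand around one TSS; verify each window median by hand
        probes = pd.DataFrame(
            {
                "position": [4900, 5000, 5100, 5200, 5300],
                "strand": ["+"] * 5,
                "value": [1.0, 2.0, 3.0, 4.0, 5.0],
            }
        )
        tss = pd.DataFrame({"position": [5000], "strand": ["+"]})
        prof = tss_downstream_profile(
            probes, tss, 20_000, window=250, step=50, span=200, to_log10=False
        )
        expect = []
        for d in range(0, 201, 50):
            lo, hi = 5000 + d - 125, 5000 + d + 125
            vals = [v for p, v in zip(probes.position, probes.value) if lo <= p < hi]
            expect.append(np.median(vals))
        np.testing.assert_array_equal(prof.observed, expect)

    def test_strand_respecting_downstream(self):
        # minus-strand TSS: downstream is decreasing coordinates
        probes = _probe_frame(value=0.0)
        probes.loc[(probes.position < 5000) & (probes.strand == "-"), "value"] = 3.0
        tss = pd.DataFrame({"position": [5000], "strand": ["-"]})
        prof = tss_downstream_profile(probes, tss, 20_000, span=400, to_log10=False)
        assert np.all(prof.observed[2:] == 3.0)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(7)
        probes = _probe_frame()
        probes["value"] = rng.normal(size=len(probes))
        tss = pd.DataFrame({"position": [3000, 8000, 12000], "strand": ["+", "-", "+"]})
        prof = tss_downstream_profile(probes, tss, 20_000, to_log10=False)
        shift = 4000  # multiple of the 100 bp same-strand spacing
        rolled = probes.copy()
        rolled["position"] = (rolled["position"] + shift) % 20_000
        rolled = rolled.sort_values("position").reset_index(drop=True)
        tss2 = tss.copy()
        tss2["position"] = (tss2["position"] + shift) % 20_000
        prof2 = tss_downstream_profile(rolled, tss2, 20_000, to_log10=False)
        np.testing.assert_allclose(prof.observed, prof2.observed)

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            tss_downstream_profile(_probe_frame(), pd.DataFrame(columns=["position", "strand"]), 20_000)


class TestCircularNull:
    def test_refuses_tiny_permutation_count(self):
        probes = _probe_frame()
        tss = pd.DataFrame({"position": [5000], "strand": ["+"]})
        with pytest.raises(ValueError):
            circular_permutation_null(probes, tss, 20_000, n_perm=10)

    def test_centering_makes_null_median_zero(self):
        rng = np.random.default_rng(8)
        probes = _probe_frame()
        probes["value"] = rng.normal(size=len(probes))
        tss = pd.DataFrame({"position": [4000, 9000], "strand": ["+", "-"]})
        prof = circular_permutation_null(probes, tss, 20_000, n_perm=100, seed=0)
        assert np.allclose(prof.null_median, 0.0)
        assert prof.centered

    def test_constant_signal_gives_zero_width_envelope(self):
        probes = _probe_frame(value=1.5)
        tss = pd.DataFrame({"position": [4000], "strand": ["+"]})
        prof = circular_permutation_null(probes, tss, 20_000, n_perm=100, seed=0)
        assert np.allclose(prof.null_q975, 0.0)
        assert np.allclose(prof.observed, 0.0)

    def test_fast_and_generic_paths_agree(self):
        rng = np.random.default_rng(9)
        probes = _probe_frame()
        probes["value"] = rng.normal(size=len(probes))
        tss = pd.DataFrame({"position": [4000, 11_000], "strand": ["+", "-"]})
        fast = circular_permutation_null(probes, tss, 20_000, n_perm=60, seed=5, span=400)
        # break grid regularity to force the generic path, same data content
        irregular = probes.copy()
        irregular.loc[irregular.index[-1], "position"] += 1
        slow = circular_permutation_null(irregular, tss, 20_000, n_perm=60, seed=5, span=400)
        # same observed profile up to the single perturbed probe; envelopes at
        # the same quantile scale
        assert np.nanmax(np.abs(fast.observed - slow.observed)) < 0.5

    def test_planted_decay_exceeds_envelope_near_tss(self, annotation, planted_array):
        probes, _ = planted_array
        vp = probes[["position", "strand"]].copy()
        cols = [c for c in probes.columns if c.startswith("log2_ratio")]
        vp["value"] = probes[cols].median(axis=1)
        prof = circular_permutation_null(
            vp, annotation.antisense_tss, annotation.genome_length, n_perm=200, seed=1
        )
        assert prof.observed[1] > prof.null_q975[1]  # strong signal 50 bp downstream
        assert prof.observed[1] > prof.observed[-1]  # decays with distance


class TestLoess:
    def test_exact_on_lines(self):
        x = np.linspace(0, 10, 30)
        y = 3.0 - 0.5 * x
        assert np.max(np.abs(loess_curve(x, y, span=0.5) - y)) < 1e-8

    def test_constant_in_constant_out(self):
        x = np.linspace(0, 10, 20)
        assert np.allclose(loess_curve(x, np.full_like(x, 2.0)), 2.0)

    def test_noise_reduction_on_sine(self):
        rng = np.random.default_rng(10)
        x = np.linspace(0, 4 * np.pi, 300)
        truth = np.sin(x)
        y = truth + rng.normal(0, 0.3, x.shape)
        sm = loess_curve(x, y, span=0.15)
        assert np.sqrt(np.mean((sm - truth) ** 2)) < 0.3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_curve(np.arange(4.0), np.arange(4.0))
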