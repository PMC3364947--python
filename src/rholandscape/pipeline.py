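"""End-to-end orchestration: synthesize -> analyze -> report.

One top-level seed expands deterministically into per-stage seeds (stable
spawn keys of a numpy SeedSequence), so any stage can be re-run independently
and the whole run is byte-reproducible. Every output embeds the resolved
configuration and package version.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import enrichment, epistasis, pathway_mi, synthetic, tiling, tnseq
from .growth import fit_condition_table, growth_rate_ratio, sample_posterior
from .synthetic import GrowthParams

log = logging.getLogger("rholandscape.pipeline")

_STAGES = ("annotation", "growth", "tiling", "enrichment", "pathways", "tnseq", "epistasis")


@dataclass
class RunConfig:
    seed: int = 0
    n_genes: int = 120
    genome_length: int = 300_000
    feature_fraction: float = 0.10
    alpha_probe: float = 0.01
    fold_probe: float = 2.0
    fold_gene: float = 1.5
    n_perm_enrichment: int = 2_000
    n_perm_mi: int = 10_000
    alpha_mi: float = 1e-3
    n_posterior: int = 4_000
    strict_z: float = 2.0
    relaxed_z: float = 1.0
    readthrough_log2: float = 2.0
    antisense_bias: float = 0.8
    noise_sd_array: float = 0.1
    n_replicates_array: int = 4
    growth_noise_sd: float = 0.005
    n_growth_replicates: int = 6
    ratio_orientation: str = "rho*/WT"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable across runs and platforms)."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic dataset; write tables and a JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": asdict(config),
        "package_version": __version__,
        "stages": {},
    }
    t_all = time.time()

    def _stage(name):
        log.info("stage %s starting", name)
        return time.time()

    try:
        t = _stage("annotation")
        ann = synthetic.make_annotation(
            n_genes=config.n_genes,
            genome_length=config.genome_length,
            feature_fraction=config.feature_fraction,
            seed=stage_seed(config.seed, "annotation"),
        )
        ann.write_gff3(out / "genes.gff3")
        ann.write_feature_bed(out / "features.bed")
        ann.write_tss_bed(out / "antisense_tss.bed")
        log.info("stage annotation done in %.1fs", time.time() - t)

        # growth: WT vs rho*-like strain in two conditions
        t = _stage("growth")
        gseed = stage_seed(config.seed, "growth")
        truth_rates = {
            ("WT", "glucose"): 1.0,
            ("rho*", "glucose"): 1.06,
            ("WT", "acetate"): 0.27,
            ("rho*", "acetate"): 0.32,
        }
        curves = {
            key: synthetic.simulate_growth_curves(
                GrowthParams(gamma=g, lag=2.0, amplitude=6.0, baseline=-6.6),
                n_replicates=config.n_growth_replicates,
                noise_sd=config.growth_noise_sd,
                seed=gseed + i,
            )
            for i, (key, g) in enumerate(sorted(truth_rates.items()))
        }
        growth_table = fit_condition_table(curves, n_posterior=config.n_posterior, seed=gseed)
        growth_table.to_csv(out / "growth_rates.tsv", sep="\t", index=False)
        report["stages"]["growth"] = {
            "n_groups": len(growth_table),
            "rates": {
                f"{s}/{c}": round(r, 4)
                for (s, c), r in growth_table.set_index(["strain", "condition"])["rate"].items()
            },
        }
        log.info("stage growth done in %.1fs", time.time() - t)

        # tiling calls
        t = _stage("tiling")
        probes, truth = synthetic.simulate_tiling_array(
            ann,
            readthrough_log2=config.readthrough_log2,
            antisense_bias=config.antisense_bias,
            n_replicates=config.n_replicates_array,
            noise_sd=config.noise_sd_array,
            seed=stage_seed(config.seed, "tiling"),
        )
        called = tiling.call_significant_probes(
            probes, alpha=config.alpha_probe, fold=config.fold_probe
        )
        called = tiling.assign_orientation(called, ann)
        gene_calls = tiling.gene_level_calls(called, ann, fold=config.fold_gene)
        called.to_csv(out / "probe_calls.tsv", sep="\t", index=False)
        gene_calls.to_csv(out / "gene_calls.tsv", sep="\t", index=False)
        frac_anti = tiling.antisense_fraction(called)
        report["stages"]["tiling"] = {
            "n_significant_probes": int(called["significant"].sum()),
            "n_genes_over": int((gene_calls["call"] == "over_in_rho*").sum()),
            "n_genes_under": int((gene_calls["call"] == "under_in_rho*").sum()),
            "antisense_fraction_up": round(float(frac_anti), 4),
            "ratio_orientation": config.ratio_orientation,
        }
        log.info("stage tiling done in %.1fs", time.time() - t)

        # enrichment + TSS profile
        t = _stage("enrichment")
        eseed = stage_seed(config.seed, "enrichment")
        up = called[called["significant"] & (called["direction"] == "up_in_rho*")]
        enr = enrichment.overlap_enrichment(
            up["position"].to_numpy(),
            ann.features,
            ann.genome_length,
            n_perm=config.n_perm_enrichment,
            seed=eseed,
        )
        value_probes = called[["position", "strand"]].copy()
        value_probes["value"] = called["median_log2"].to_numpy()
        profile = enrichment.circular_permutation_null(
            value_probes,
            ann.antisense_tss,
            ann.genome_length,
            n_perm=max(config.n_perm_enrichment, 200),
            seed=eseed + 1,
        )
        smoothed = enrichment.loess_curve(profile.offsets.astype(float), profile.observed)
        pd.DataFrame(
            {
                "offset": profile.offsets,
                "observed_centered": profile.observed,
                "null_median": profile.null_median,
                "null_q975": profile.null_q975,
                "loess": smoothed,
            }
        ).to_csv(out / "tss_profile.tsv", sep="\t", index=False)
        report["stages"]["enrichment"] = {
            "feature_overlap_fold": round(enr.fold, 3),
            "feature_overlap_p": enr.p_perm,
            "profile_max_offset": int(profile.offsets[int(np.nanargmax(profile.observed))]),
        }
        log.info("stage enrichment done in %.1fs", time.time() - t)

        # pathways
        t = _stage("pathways")
        pseed = stage_seed(config.seed, "pathways")
        gene_ratio = gene_calls.set_index("gene_id")["median_sense_log2"].fillna(0.0)
        rng = np.random.default_rng(pseed)
        membership: dict[str, set[str]] = {}
        up_genes = list(gene_calls[gene_calls["call"] == "over_in_rho*"]["gene_id"])
        all_genes = list(gene_calls["gene_id"])
        if up_genes:
            membership["planted_up_module"] = set(up_genes)
        for j in range(10):
            membership[f"random_set_{j}"] = set(
                rng.choice(all_genes, size=min(15, len(all_genes)), replace=False)
            )
        page = pathway_mi.run_page(
            gene_ratio.to_numpy(),
            list(gene_ratio.index),
            membership,
            alpha=config.alpha_mi,
            n_perm=config.n_perm_mi,
            seed=pseed,
        )
        page.to_csv(out / "pathways.tsv", sep="\t", index=False)
        report["stages"]["pathways"] = {
            "n_significant": int(page["significant"].sum()),
            "n_non_redundant": int(page["non_redundant"].sum()),
        }
        log.info("stage pathways done in %.1fs", time.time() - t)

        # transposon landscapes
        t = _stage("tnseq")
        tseed = stage_seed(config.seed, "tnseq")
        wt_fit, mut_fit = synthetic.make_background_fitness(ann, seed=tseed)
        comps = {}
        flags = {}
        gmed = {}
        repmed = {}
        for name, fit, s in [("WT", wt_fit, tseed + 1), ("rho*", mut_fit, tseed + 2)]:
            raw, _ = synthetic.simulate_transposon_selection(ann, fit, seed=s)
            scored = tnseq.score_table(raw, background=name)
            scored = tnseq.assign_loci(scored, ann)
            scored.to_csv(out / f"selection_scores_{name.replace('*', 'star')}.tsv", sep="\t", index=False)
            flags[name] = tnseq.flag_loci(scored, config.strict_z, config.relaxed_z)
            gmed[name] = tnseq.gene_median_scores(scored, ann)
            repmed[name] = pd.DataFrame(
                {
                    c: tnseq.gene_median_scores(scored, ann, column=c)
                    for c in scored.columns
                    if c.startswith("score_rep")
                }
            )
        comp = tnseq.compare_backgrounds(
            flags["WT"], flags["rho*"], gmed["WT"], gmed["rho*"], repmed["WT"], repmed["rho*"]
        )
        report["stages"]["tnseq"] = {
            "unique_fraction": round(comp.unique_fraction, 4),
            "shared_correlated": comp.shared_correlated,
            "shared_anticorrelated": comp.shared_anticorrelated,
            "unique_WT": comp.unique_a,
            "unique_rho*": comp.unique_b,
            "pearson_between_backgrounds": round(comp.pearson_between_backgrounds, 4),
            "pearson_between_replicates": round(comp.pearson_between_replicates, 4),
        }
        log.info("stage tnseq done in %.1fs", time.time() - t)

        # epistasis
        t = _stage("epistasis")
        eps_seed = stage_seed(config.seed, "epistasis")
        rows = []
        for i, (label, eps_true) in enumerate([("null_pair", 0.0), ("positive_pair", 0.2), ("negative_pair", -0.2)]):
            q = synthetic.make_fitness_quartet(epsilon=eps_true, seed=eps_seed + i)
            res = epistasis.multiplicative_epistasis(q)
            rows.append(
                {
                    "pair": label,
                    "true_epsilon": eps_true,
                    "epsilon": res.epsilon,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "sign_call": res.sign_call,
                    "predicted_gamma_ab": res.predicted_gamma_ab,
                }
            )
        eps_table = pd.DataFrame(rows)
        eps_table.to_csv(out / "epistasis.tsv", sep="\t", index=False)
        report["stages"]["epistasis"] = {
            r["pair"]: r["sign_call"] for r in rows
        }
        log.info("stage epistasis done in %.1fs", time.time() - t)
    except Exception as exc:
        report["failed_stage"] = getattr(exc, "stage", "unknown")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise

    report["elapsed_s"] = None  # timings go to logs, not the reproducible report
    del report["elapsed_s"]
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    log.info("pipeline done in %.1fs", time.time() - t_all)
    return report
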