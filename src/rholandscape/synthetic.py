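"""Synthetic data with the statistical structure the analyses assume.

Generates, with recorded ground truth: a circular-genome annotation; plate-reader
OD600 growth curves; two-channel tiling-array probe tables with planted
terminator-readthrough, antisense, and feature-biased effects; and
transposon-selection probe tables with background-specific fitness effects.

Everything is seeded; identical seeds give identical output. The truth object
returned alongside each dataset is what recovery tests compare estimates to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Annotation

PROBE_SPACING = 50  # bp between adjacent probes, alternating strands


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class GrowthParams:
    """True growth-model parameters for one strain/condition.

    gamma is the maximum growth rate in doublings/hour, lag in hours,
    amplitude and baseline in log2-OD units (the generator and the fitter share
    the logistic-in-log2-OD parameterization; see the growth module).
    """

    gamma: float
    lag: float
    amplitude: float
    baseline: float

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass
class TilingTruth:
    """Planted per-probe effects for a simulated tiling array."""

    probe_effects: np.ndarray  # true log2(rho*/WT) per probe
    de_genes_up: list[str]
    de_genes_down: list[str]
    planted_gene_overlap_antisense: int
    planted_gene_overlap_sense: int
    planted_in_features: int


@dataclass
class SelectionTruth:
    """Planted locus fitness effects for a transposon selection."""

    locus_fitness: dict[str, float]  # selection coefficient s per gene
    generations: float


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def make_annotation(
    n_genes: int,
    genome_length: int = 300_000,
    feature_fraction: float = 0.10,
    seed: int = 0,
    tss_fraction: float = 0.5,
) -> Annotation:
    """Random circular-genome annotation with non-overlapping genes.

    Genes (800-1400 bp) alternate strands with 600-1200 bp intergenic gaps; a
    terminator sits at each gene 3' end; antisense TSS are placed inside a
    `tss_fraction` subset of genes on the opposite strand, far enough from the
    antisense-downstream gene edge that a few-hundred-bp readthrough tail stays
    inside the gene. Feature intervals (emulating a horizontally-acquired-DNA
    set) are 2.5 kb blocks chosen uniformly to cover ~`feature_fraction` of
    the genome.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0 <= feature_fraction < 1):
        raise ValueError("feature_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    lengths = rng.integers(800, 1401, size=n_genes)
    gaps = rng.integers(600, 1201, size=n_genes)
    if lengths.sum() + gaps.sum() > genome_length:
        raise ValueError(
            f"genome_length={genome_length} too short for {n_genes} genes "
            f"(need >= {int(lengths.sum() + gaps.sum())})"
        )
    genes = []
    pos = int(gaps[0] // 2)
    for i in range(n_genes):
        start, end = pos, pos + int(lengths[i])
        strand = "+" if i % 2 == 0 else "-"
        genes.append({"gene_id": f"g{i:04d}", "start": start, "end": end, "strand": strand})
        pos = end + int(gaps[i])
    genes = pd.DataFrame(genes)

    term = pd.DataFrame(
        {
            "position": np.where(genes["strand"] == "+", genes["end"], genes["start"]),
            "strand": genes["strand"],
        }
    )

    n_tss = int(round(tss_fraction * n_genes))
    tss_rows = []
    for _, g in genes.iloc[rng.permutation(n_genes)[:n_tss]].iterrows():
        anti = "-" if g.strand == "+" else "+"
        # downstream of an antisense TSS runs toward the gene 5' end
        if anti == "-":
            p = int(rng.integers(g.start + 500, g.end - 50))
        else:
            p = int(rng.integers(g.start + 50, g.end - 500))
        tss_rows.append({"position": p, "strand": anti})
    tss = pd.DataFrame(tss_rows, columns=["position", "strand"]).sort_values("position").reset_index(drop=True)

    block = 2500
    n_blocks = genome_length // block
    k = int(round(feature_fraction * n_blocks))
    chosen = np.sort(rng.permutation(n_blocks)[:k])
    feats = pd.DataFrame(
        {
            "start": chosen * block,
            "end": (chosen + 1) * block,
            "label": [f"feat_{j}" for j in range(k)],
        }
    )

    return Annotation(genome_length, genes, term, feats, tss)


def probe_positions(genome_length: int) -> pd.DataFrame:
    """Array layout: one probe every 50 bp, alternating between strands."""
    pos = np.arange(0, genome_length, PROBE_SPACING)
    strand = np.where(np.arange(len(pos)) % 2 == 0, "+", "-")
    return pd.DataFrame({"position": pos, "strand": strand})


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------


def logistic_log2_od(t: np.ndarray, params: GrowthParams) -> np.ndarray:
    """log2(OD - blank) trajectory implied by the logistic growth model."""
    k = 4.0 * params.gamma / params.amplitude
    tm = params.lag + 2.0 / k
    return params.baseline + params.amplitude / (1.0 + np.exp(-k * (t - tm)))


def simulate_growth_curves(
    params: GrowthParams,
    n_replicates: int = 8,
    dt_min: float = 10.0,
    t_max_h: float = 16.0,
    noise_sd: float = 0.005,
    blank: float = 0.04,
    seed: int = 0,
) -> list["GrowthCurve"]:
    """OD600 time series sampled every `dt_min` minutes with iid OD noise.

    The noiseless trajectory is ``blank + 2**y(t)`` with y the logistic curve in
    log2-OD space whose maximum slope is ``params.gamma`` doublings/hour.
    """
    from .growth import GrowthCurve

    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max_h + 1e-9, dt_min / 60.0)
    clean = blank + 2.0 ** logistic_log2_od(t, params)
    curves = []
    for i in range(n_replicates):
        od = clean + rng.normal(0.0, noise_sd, size=t.shape)
        curves.append(GrowthCurve(well_id=f"w{i:02d}", times=t.copy(), od=od, blank=blank))
    return curves


def make_fitness_quartet(
    gamma_00: float = 1.0,
    w_a: float = 0.90,
    w_b: float = 0.85,
    epsilon: float = 0.0,
    rel_noise: float = 0.02,
    n_samples: int = 2000,
    seed: int = 0,
) -> "FitnessQuartet":
    """Four strains' growth-rate estimates and posterior draws for epistasis tests.

    True rates are gamma_00, gamma_00*w_a, gamma_00*w_b and
    gamma_00*(w_a*w_b + epsilon). Each strain's estimate carries a relative
    measurement error `rel_noise` (default 2%, the scale of typical plate-reader
    rate CIs), and its posterior draws scatter around the estimate with the same
    relative SD.
    """
    from .epistasis import FitnessQuartet

    rng = np.random.default_rng(seed)
    truths = {
        "00": gamma_00,
        "A": gamma_00 * w_a,
        "B": gamma_00 * w_b,
        "AB": gamma_00 * (w_a * w_b + epsilon),
    }
    est, samples = {}, {}
    for key, g in truths.items():
        ghat = g * (1.0 + rel_noise * rng.standard_normal())
        est[key] = ghat
        samples[key] = ghat * (1.0 + rel_noise * rng.standard_normal(n_samples))
    return FitnessQuartet(
        gamma_00=est["00"],
        gamma_a=est["A"],
        gamma_b=est["B"],
        gamma_ab=est["AB"],
        samples_00=samples["00"],
        samples_a=samples["A"],
        samples_b=samples["B"],
        samples_ab=samples["AB"],
        labels=("rho*", "A"),
    )


# ---------------------------------------------------------------------------
# tiling array
# ---------------------------------------------------------------------------


def _decay_effects(
    probes: pd.DataFrame,
    origin: int,
    strand: str,
    amplitude: float,
    decay_bp: float,
    span: int,
    genome_length: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and effect sizes for same-strand probes downstream of `origin`."""
    pos = probes["position"].to_numpy()
    on_strand = (probes["strand"] == strand).to_numpy()
    if strand == "+":
        d = (pos - origin) % genome_length
    else:
        d = (origin - pos) % genome_length
    sel = on_strand & (d < span)
    idx = np.nonzero(sel)[0]
    eff = amplitude * np.exp(-d[idx] / decay_bp)
    return idx, eff


def simulate_tiling_array(
    ann: Annotation,
    readthrough_log2: float = 2.0,
    antisense_bias: float = 0.8,
    n_replicates: int = 4,
    noise_sd: float = 0.1,
    seed: int = 0,
    decay_bp: float = 500.0,
    span: int = 500,
    readthrough_fraction: float = 0.25,
    feature_planted_fraction: float = 0.25,
    de_down_fraction: float = 0.2,
) -> tuple[pd.DataFrame, TilingTruth]:
    """Probe table of per-replicate log2(rho*/WT) ratios with planted effects.

    Planted structure (all recorded in the returned truth):

    * readthrough tails: exponentially decaying positive effects downstream of a
      `readthrough_fraction` subset of terminators, on the terminated strand;
    * antisense tails: the same decaying effects downstream of every antisense
      TSS (these land on gene-antisense probes);
    * differentially expressed genes: flat sense-strand effects on enough genes
      that among planted gene-overlapping up-effects the antisense fraction is
      ~`antisense_bias`; a `de_down_fraction` of DE genes get negative effects;
    * feature-biased effects: extra positive effects at intergenic probes inside
      feature intervals, sized so ~`feature_planted_fraction` of planted
      up-effect probes fall in features (creates genuine overlap enrichment).

    Observed replicate columns are truth + iid Gaussian log2 noise.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    probes = probe_positions(ann.genome_length)
    n = len(probes)
    effects = np.zeros(n)

    # 1. terminator readthrough (mostly intergenic: gaps exceed the strong tail)
    n_rt = int(round(readthrough_fraction * len(ann.terminators)))
    rt_rows = ann.terminators.iloc[rng.permutation(len(ann.terminators))[:n_rt]]
    for _, r in rt_rows.iterrows():
        idx, eff = _decay_effects(
            probes, int(r.position), r.strand, readthrough_log2, decay_bp, span, ann.genome_length
        )
        effects[idx] = np.maximum(effects[idx], eff)

    # 2. antisense readthrough downstream of antisense TSS
    for _, r in ann.antisense_tss.iterrows():
        idx, eff = _decay_effects(
            probes, int(r.position), r.strand, readthrough_log2, decay_bp, span, ann.genome_length
        )
        effects[idx] = np.maximum(effects[idx], eff)

    gene_plus = ann.gene_at(probes["position"].to_numpy(), "+")
    gene_minus = ann.gene_at(probes["position"].to_numpy(), "-")
    in_gene = (gene_plus >= 0) | (gene_minus >= 0)
    probe_strand = probes["strand"].to_numpy()
    sense_gene = np.where(probe_strand == "+", gene_plus, gene_minus)
    anti_gene = np.where(probe_strand == "+", gene_minus, gene_plus)

    # count strong antisense planted probes (those that can pass a 2-fold filter)
    strong = effects >= 1.0
    n_anti = int(np.sum(strong & (anti_gene >= 0) & (sense_gene < 0)))

    # 3. DE genes: sense effects sized to hit the antisense bias among planted
    #    gene-overlapping up-effects
    tssed = set()
    for _, r in ann.antisense_tss.iterrows():
        gp = ann.gene_at(np.array([int(r.position)]), "+" if r.strand == "-" else "-")[0]
        if gp >= 0:
            tssed.add(gp)
    candidates = [i for i in range(len(ann.genes)) if i not in tssed]
    probes_per_gene = max(1, int(np.median(ann.genes.eval("end-start")) / (2 * PROBE_SPACING)))
    target_sense = n_anti * (1.0 - antisense_bias) / max(antisense_bias, 1e-9)
    n_de_up = int(round(target_sense / probes_per_gene)) if antisense_bias < 1 else 0
    n_de_down = int(round(de_down_fraction * max(n_de_up, 1))) if n_de_up else 0
    order = rng.permutation(len(candidates))
    de_up = [candidates[j] for j in order[:n_de_up]]
    de_down = [candidates[j] for j in order[n_de_up : n_de_up + n_de_down]]
    n_sense_planted = 0
    for gi, sign in [(g, +1) for g in de_up] + [(g, -1) for g in de_down]:
        g = ann.genes.iloc[gi]
        sel = (sense_gene == gi) & (anti_gene < 0)
        effects[sel] = sign * readthrough_log2
        if sign > 0:
            n_sense_planted += int(sel.sum())

    # 4. feature-biased intergenic effects
    n_strong_now = int(np.sum(effects >= 1.0))
    n_feat_target = int(
        round(feature_planted_fraction / max(1 - feature_planted_fraction, 1e-9) * n_strong_now)
    )
    in_feature = np.zeros(n, dtype=bool)
    pos = probes["position"].to_numpy()
    for _, f in ann.features.iterrows():
        in_feature |= (pos >= f.start) & (pos < f.end)
    feat_candidates = np.nonzero(in_feature & ~in_gene & (effects == 0))[0]
    chosen = rng.permutation(feat_candidates)[:n_feat_target]
    effects[chosen] = readthrough_log2

    obs = effects[:, None] + rng.normal(0.0, noise_sd, size=(n, n_replicates))
    table = probes.copy()
    for j in range(n_replicates):
        table[f"log2_ratio_rep{j + 1}"] = obs[:, j]
    truth = TilingTruth(
        probe_effects=effects,
        de_genes_up=[ann.genes.iloc[g].gene_id for g in de_up],
        de_genes_down=[ann.genes.iloc[g].gene_id for g in de_down],
        planted_gene_overlap_antisense=n_anti,
        planted_gene_overlap_sense=n_sense_planted,
        planted_in_features=int(np.sum((effects >= 1.0) & in_feature)),
    )
    return table, truth


# ---------------------------------------------------------------------------
# transposon selections
# ---------------------------------------------------------------------------


def make_background_fitness(
    ann: Annotation,
    n_effect_loci: int = 40,
    shared_fraction: float = 0.3,
    effect_size: float = 0.15,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Two background-specific fitness maps (WT, rho*) over the gene set.

    A `shared_fraction` of effect loci carry the same selection coefficient in
    both backgrounds; the remainder are split evenly between background-unique
    sets, mirroring a landscape where the majority of fitness-relevant loci are
    background-specific. Signs are random; |s| = effect_size per generation.
    """
    rng = np.random.default_rng(seed)
    gene_ids = list(ann.genes["gene_id"])
    if n_effect_loci > len(gene_ids):
        raise ValueError("more effect loci requested than genes available")
    chosen = [gene_ids[i] for i in rng.permutation(len(gene_ids))[:n_effect_loci]]
    n_shared = int(round(shared_fraction * n_effect_loci))
    n_unique = n_effect_loci - n_shared
    n_wt_only = n_unique // 2
    signs = rng.choice([-1.0, 1.0], size=n_effect_loci)
    wt: dict[str, float] = {}
    mut: dict[str, float] = {}
    for j, g in enumerate(chosen):
        s = float(signs[j] * effect_size)
        if j < n_shared:
            wt[g] = s
            mut[g] = s
        elif j < n_shared + n_wt_only:
            wt[g] = s
        else:
            mut[g] = s
    return wt, mut


def simulate_transposon_selection(
    ann: Annotation,
    locus_fitness: Mapping[str, float],
    generations: float = 10.0,
    depth_noise_sd: float = 0.2,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, SelectionTruth]:
    """Reference/selected intensity pairs per probe for one genetic background.

    Selected abundance = reference x 2**(s * generations) x noise, where s is
    the selection coefficient of the gene containing the probe (0 elsewhere).
    Negative s (deleterious insertion under selection) therefore gives positive
    log2(reference:selected) scores downstream.
    """
    if generations <= 0:
        raise ValueError("generations must be positive")
    known = set(ann.genes["gene_id"])
    unknown = set(locus_fitness) - known
    if unknown:
        raise ValueError(f"unknown locus ids in locus_fitness: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    probes = probe_positions(ann.genome_length)
    pos = probes["position"].to_numpy()
    gene_plus = ann.gene_at(pos, "+")
    gene_minus = ann.gene_at(pos, "-")
    gene_row = np.where(gene_plus >= 0, gene_plus, gene_minus)
    s = np.zeros(len(probes))
    gid_by_row = ann.genes["gene_id"].to_dict()
    for i in range(len(probes)):
        if gene_row[i] >= 0:
            s[i] = locus_fitness.get(gid_by_row[gene_row[i]], 0.0)
    table = probes.copy()
    for j in range(n_replicates):
        ref = 2.0 ** rng.normal(10.0, 0.5, size=len(probes))  # library abundance
        sel = ref * 2.0 ** (s * generations) * 2.0 ** rng.normal(0.0, depth_noise_sd, size=len(probes))
        # independent measurement noise on the reference channel as well
        ref_obs = ref * 2.0 ** rng.normal(0.0, depth_noise_sd / 2, size=len(probes))
        table[f"reference_rep{j + 1}"] = ref_obs
        table[f"selected_rep{j + 1}"] = sel
    truth = SelectionTruth(locus_fitness=dict(locus_fitness), generations=float(generations))
    return table, truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_fixture_set(out_dir: str | Path, seed: int = 0, n_genes: int = 120) -> dict[str, Path]:
    """Write a complete plain-text fixture set (annotation + all data tables)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = make_annotation(n_genes=n_genes, seed=seed)
    paths = {}
    ann.write_gff3(out / "genes.gff3")
    ann.write_feature_bed(out / "features.bed")
    ann.write_tss_bed(out / "antisense_tss.bed")
    paths["genes"] = out / "genes.gff3"
    paths["features"] = out / "features.bed"
    paths["tss"] = out / "antisense_tss.bed"

    tab, _ = simulate_tiling_array(ann, seed=seed + 1)
    tab.to_csv(out / "tiling_probes.tsv", sep="\t", index=False)
    paths["tiling"] = out / "tiling_probes.tsv"

    wt_fit, mut_fit = make_background_fitness(
        ann, n_effect_loci=min(40, max(2, n_genes // 3)), seed=seed + 2
    )
    for name, fit, s in [("WT", wt_fit, seed + 3), ("rhostar", mut_fit, seed + 4)]:
        sel, _ = simulate_transposon_selection(ann, fit, seed=s)
        sel.to_csv(out / f"selection_{name}.tsv", sep="\t", index=False)
        paths[f"selection_{name}"] = out / f"selection_{name}.tsv"

    rows = []
    for cond, g in [("glucose", 1.0), ("acetate", 0.3)]:
        for strain, mult in [("WT", 1.0), ("rhostar", 1.06)]:
            curves = simulate_growth_curves(
                GrowthParams(gamma=g * mult, lag=2.0, amplitude=6.0, baseline=-6.6),
                seed=seed + 5,
            )
            for c in curves:
                for t, od in zip(c.times, c.od):
                    rows.append(
                        {
                            "well": f"{strain}_{cond}_{c.well_id}",
                            "strain": strain,
                            "condition": cond,
                            "time_min": round(t * 60, 3),
                            "od": od,
                        }
                    )
    pd.DataFrame(rows).to_csv(out / "growth_curves.tsv", sep="\t", index=False)
    paths["growth"] = out / "growth_curves.tsv"
    return paths
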