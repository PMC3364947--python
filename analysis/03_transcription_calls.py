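#!/usr/bin/env python
"""Call differentially transcribed probes and genes between the two backgrounds.

Applies the moderated probe test (Bonferroni p < 0.01 and > 2-fold change),
assigns sense/antisense orientation against the gene annotation, summarizes
the antisense fraction among up-regulated probes, and makes 1.5-fold
gene-level calls. Writes results/probe_calls.tsv and results/gene_calls.tsv.
"""

from pathlib import Path

import pandas as pd

from rholandscape import tiling
from rholandscape.annotation import Annotation, read_bed_intervals, read_gff3_genes

ROOT = Path(__file__).resolve().parent.parent / "results"
GENOME_LENGTH = 300_000


def load_annotation() -> Annotation:
    genes = read_gff3_genes(ROOT / "data" / "genes.gff3")
    feats = read_bed_intervals(ROOT / "data" / "features.bed")
    tss = read_bed_intervals(ROOT / "data" / "antisense_tss.bed")
    tss = tss.rename(columns={"start": "position"})[["position", "strand"]]
    return Annotation(GENOME_LENGTH, genes, features=feats, antisense_tss=tss)


def main() -> None:
    ann = load_annotation()
    probes = pd.read_csv(ROOT / "data" / "tiling_probes.tsv", sep="\t")
    called = tiling.call_significant_probes(probes, alpha=0.01, fold=2.0)
    called = tiling.assign_orientation(called, ann)
    called.to_csv(ROOT / "probe_calls.tsv", sep="\t", index=False)

    n_sig = int(called["significant"].sum())
    n_up = int((called["significant"] & (called["direction"] == "up_in_rho*")).sum())
    print(f"significant probes: {n_sig} of {len(called)} ({n_up} up in rho*)")
    print(f"antisense fraction among up gene-overlapping probes: "
          f"{tiling.antisense_fraction(called):.1%}")
    print(f"antisense fraction among down probes: "
          f"{tiling.antisense_fraction(called, direction='up_in_WT'):.1%}")

    gene_calls = tiling.gene_level_calls(called, ann, fold=1.5)
    gene_calls.to_csv(ROOT / "gene_calls.tsv", sep="\t", index=False)
    n_over = int((gene_calls["call"] == "over_in_rho*").sum())
    n_under = int((gene_calls["call"] == "under_in_rho*").sum())
    print(f"gene calls at 1.5-fold: {n_over} overexpressed, {n_under} underexpressed")

    # smoothed display track, one file per strand
    for strand in "+-":
        sub = called[called["strand"] == strand].sort_values("position")
        sm = tiling.smooth_track(
            sub["position"].to_numpy(float), sub["median_log2"].to_numpy(), "gaussian", 100
        )
        name = "plus" if strand == "+" else "minus"
        tiling.write_bedgraph(ROOT / f"log2_ratio_smoothed_{name}.bedgraph", sub["position"], sm)
    print("wrote smoothed bedGraph tracks (Gaussian kernel, 100 bp width)")


if __name__ == "__main__":
    main()
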