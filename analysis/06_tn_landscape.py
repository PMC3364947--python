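#!/usr/bin/env python
"""Score transposon selections in both backgrounds and compare the landscapes.

Computes per-probe selection scores (log2 reference:selected), Z-scores and
500-bp running-median smoothing, flags loci under strict (|Z| >= 2) and
relaxed (|Z| >= 1) criteria, and partitions flagged loci into
background-unique and shared(correlated/anticorrelated) sets with replicate
and cross-background correlations.
Writes results/tn_flags_<bg>.tsv and results/tn_landscape_comparison.tsv.
"""

import importlib.util
from pathlib import Path

import pandas as pd

from rholandscape import tnseq

ROOT = Path(__file__).resolve().parent.parent / "results"
_spec = importlib.util.spec_from_file_location(
    "transcription_calls", Path(__file__).parent / "03_transcription_calls.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)


def main() -> None:
    ann = _mod.load_annotation()
    data = {}
    for name, fname in (("WT", "selection_WT.tsv"), ("rho*", "selection_rhostar.tsv")):
        raw = pd.read_csv(ROOT / "data" / fname, sep="\t")
        scored = tnseq.assign_loci(tnseq.score_table(raw, background=name), ann)
        flags = tnseq.flag_loci(scored, strict_z=2.0, relaxed_z=1.0)
        flags.to_csv(ROOT / f"tn_flags_{name.replace('*', 'star')}.tsv", sep="\t", index=False)
        reps = pd.DataFrame(
            {
                c: tnseq.gene_median_scores(scored, ann, c)
                for c in scored.columns
                if c.startswith("score_rep")
            }
        )
        data[name] = (flags, tnseq.gene_median_scores(scored, ann), reps)
        print(f"{name}: {int(flags['strict'].sum())} strict / "
              f"{int(flags['relaxed'].sum())} relaxed flagged loci")

    comp = tnseq.compare_backgrounds(
        data["WT"][0], data["rho*"][0], data["WT"][1], data["rho*"][1],
        data["WT"][2], data["rho*"][2],
    )
    summary = pd.DataFrame(
        [
            {
                "unique_WT": comp.unique_a,
                "unique_rho*": comp.unique_b,
                "shared_correlated": comp.shared_correlated,
                "shared_anticorrelated": comp.shared_anticorrelated,
                "unique_fraction": round(comp.unique_fraction, 4),
                "pearson_between_backgrounds": round(comp.pearson_between_backgrounds, 4),
                "pearson_between_replicates": round(comp.pearson_between_replicates, 4),
            }
        ]
    )
    summary.to_csv(ROOT / "tn_landscape_comparison.tsv", sep="\t", index=False)
    print(f"\n{comp.unique_fraction:.0%} of flagged loci are unique to one background "
          f"(replicate r = {comp.pearson_between_replicates:.2f}, "
          f"cross-background r = {comp.pearson_between_backgrounds:.2f})")


if __name__ == "__main__":
    main()
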