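#!/usr/bin/env python
"""Generate the synthetic study dataset used by all downstream analysis scripts.

Writes a circular-genome annotation (genes, terminators, feature intervals,
antisense TSS), tiling-array probe tables with planted readthrough/antisense
effects, transposon-selection tables for two genetic backgrounds, and
plate-reader growth curves, all under results/data/.
"""

from pathlib import Path

from rholandscape.synthetic import write_fixture_set

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    paths = write_fixture_set(OUT, seed=1, n_genes=120)
    print(f"wrote {len(paths)} files under {OUT}:")
    for name, p in sorted(paths.items()):
        print(f"  {name:16s} {p.name}  ({p.stat().st_size // 1024} KB)")


if __name__ == "__main__":
    main()
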