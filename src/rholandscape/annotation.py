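"""Genome annotation model shared by the simulation and analysis modules.

The genome is circular. Genes are non-overlapping within each strand
(guaranteed by the synthetic generator and validated on input), which lets
probe->gene assignment be an exact sorted-interval lookup per strand.
Coordinates are 0-based half-open internally; GFF3 output is 1-based closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STRANDS = ("+", "-")


@dataclass
class Annotation:
    """Circular-genome annotation: genes, terminators, feature intervals, antisense TSS.

    Attributes
    ----------
    genome_length : int
        Length of the circular genome in bp.
    genes : pd.DataFrame
        Columns ``gene_id, start, end, strand`` with 0-based half-open intervals,
        non-overlapping within each strand.
    terminators : pd.DataFrame
        Columns ``position, strand`` — candidate termination sites at gene 3' ends.
    features : pd.DataFrame
        Columns ``start, end, label`` — genomic feature intervals (e.g. a set of
        horizontally acquired elements such as prophages / insertion sequences).
    antisense_tss : pd.DataFrame
        Columns ``position, strand`` — antisense transcription start sites.
    """

    genome_length: int
    genes: pd.DataFrame
    terminators: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["position", "strand"]))
    features: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["start", "end", "label"]))
    antisense_tss: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["position", "strand"]))

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        g = self.genes
        if len(g):
            if not ((g["end"] > g["start"]).all()):
                raise ValueError("degenerate gene interval (end <= start)")
            if (g["start"] < 0).any() or (g["end"] > self.genome_length).any():
                raise ValueError("gene interval outside [0, genome_length)")
            if not g["strand"].isin(STRANDS).all():
                raise ValueError("gene strand must be '+' or '-'")
            for s in STRANDS:
                sub = g[g["strand"] == s].sort_values("start")
                if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                    raise ValueError(f"overlapping genes on strand {s}")
        f = self.features
        if len(f):
            if (f["start"] < 0).any() or (f["end"] > self.genome_length).any():
                raise ValueError("feature interval outside genome")
        self._index = {
            s: _SortedGenes(self.genes[self.genes["strand"] == s]) for s in STRANDS
        }

    # ---- interval lookups -------------------------------------------------

    def gene_at(self, positions: np.ndarray, strand: str) -> np.ndarray:
        """Gene index (into ``self.genes``) covering each position on `strand`, or -1."""
        return self._index[strand].lookup(np.asarray(positions))

    def overlapping_gene_ids(self, positions: np.ndarray) -> dict[str, np.ndarray]:
        """Per-strand gene row indices covering each position (-1 where none)."""
        positions = np.asarray(positions)
        return {s: self.gene_at(positions, s) for s in STRANDS}

    # ---- I/O --------------------------------------------------------------

    def write_gff3(self, path: str | Path, seqid: str = "synthetic_genome") -> None:
        rows = []
        for _, r in self.genes.iterrows():
            rows.append(
                f"{seqid}\trholandscape\tgene\t{int(r.start) + 1}\t{int(r.end)}\t.\t"
                f"{r.strand}\t.\tID={r.gene_id}"
            )
        Path(path).write_text(
            "##gff-version 3\n"
            f"##sequence-region {seqid} 1 {self.genome_length}\n" + "\n".join(rows) + "\n"
        )

    def write_feature_bed(self, path: str | Path, seqid: str = "synthetic_genome") -> None:
        with open(path, "w") as fh:
            for _, r in self.features.iterrows():
                fh.write(f"{seqid}\t{int(r.start)}\t{int(r.end)}\t{r.label}\n")

    def write_tss_bed(self, path: str | Path, seqid: str = "synthetic_genome") -> None:
        with open(path, "w") as fh:
            for i, r in self.antisense_tss.iterrows():
                fh.write(
                    f"{seqid}\t{int(r.position)}\t{int(r.position) + 1}\ttss_{i}\t0\t{r.strand}\n"
                )


class _SortedGenes:
    """Sorted non-overlapping interval lookup for one strand."""

    def __init__(self, genes: pd.DataFrame):
        genes = genes.sort_values("start")
        self.starts = genes["start"].to_numpy(dtype=np.int64)
        self.ends = genes["end"].to_numpy(dtype=np.int64)
        self.rows = genes.index.to_numpy()

    def lookup(self, positions: np.ndarray) -> np.ndarray:
        if len(self.starts) == 0:
            return np.full(len(positions), -1, dtype=np.int64)
        i = np.searchsorted(self.starts, positions, side="right") - 1
        ok = (i >= 0) & (positions < self.ends[np.clip(i, 0, None)])
        out = np.where(ok, self.rows[np.clip(i, 0, None)], -1)
        return out.astype(np.int64)


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Read gene records from a GFF3 file into the internal 0-based frame."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9 or parts[2] != "gene":
            continue
        attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
        rows.append(
            {
                "gene_id": attrs.get("ID", f"gene_{len(rows)}"),
                "start": int(parts[3]) - 1,
                "end": int(parts[4]),
                "strand": parts[6],
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand"])


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED file; returns start/end/label (+ strand when present)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        p = line.split("\t")
        row = {"start": int(p[1]), "end": int(p[2]), "label": p[3] if len(p) > 3 else "."}
        if len(p) > 5:
            row["strand"] = p[5]
        rows.append(row)
    return pd.DataFrame(rows)


def locus_intervals(ann: Annotation) -> pd.DataFrame:
    """Genes plus intergenic complement as a single strand-agnostic locus table.

    Intergenic regions (complement of the union of gene intervals on both
    strands, circular) are labelled by their flanking genes. Used by the
    transposon-selection module, where an insertion disrupts a locus
    regardless of strand.
    """
    g = ann.genes.sort_values("start").reset_index(drop=True)
    rows = []
    merged: list[list] = []
    for _, r in g.iterrows():
        if merged and r.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(r.end))
            merged[-1][2].append(r.gene_id)
        else:
            merged.append([int(r.start), int(r.end), [r.gene_id]])
    for _, r in g.iterrows():
        rows.append({"locus_id": r.gene_id, "start": int(r.start), "end": int(r.end), "kind": "gene"})
    n = len(merged)
    for i in range(n):
        end_i = merged[i][1]
        start_next = merged[(i + 1) % n][0] + (ann.genome_length if i == n - 1 else 0)
        if start_next > end_i:
            left = merged[i][2][-1]
            right = merged[(i + 1) % n][2][0]
            rows.append(
                {
                    "locus_id": f"ig_{left}|{right}",
                    "start": end_i % ann.genome_length,
                    "end": start_next % ann.genome_length if start_next > ann.genome_length else start_next,
                    "kind": "intergenic",
                }
            )
    return pd.DataFrame(rows)
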