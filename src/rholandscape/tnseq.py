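"""Transposon-library selection scoring and fitness-landscape comparison.

Per probe, the selection score is log2(reference/selected) intensity after
per-array median centering: positive scores mean the insertion was depleted
under selection (disadvantageous), negative that it was enriched
(advantageous). Scores are standardized to Z over the table, smoothed with a
running median over a 500 bp window, and a locus (gene or intergenic region)
is flagged when at least one of its probes has |smoothed Z| above threshold.
Each background is flagged under a strict and a relaxed threshold; a locus is
"unique (strict)" to a background when it passes the strict criterion there
and not even the relaxed criterion in the other background. Probe->locus
assignment ignores probe strand (an insertion disrupts a locus regardless of
which strand the array reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, locus_intervals
from .tiling import smooth_track


@dataclass
class LandscapeComparison:
    shared_correlated: int
    shared_anticorrelated: int
    unique_a: int
    unique_b: int
    pearson_between_backgrounds: float
    pearson_between_replicates: float
    labels: tuple[str, str] = ("WT", "rho*")

    @property
    def n_flagged(self) -> int:
        return self.shared_correlated + self.shared_anticorrelated + self.unique_a + self.unique_b

    @property
    def unique_fraction(self) -> float:
        return (self.unique_a + self.unique_b) / self.n_flagged if self.n_flagged else float("nan")


def selection_scores(
    reference: np.ndarray, selected: np.ndarray, floor: float | None = None
) -> np.ndarray:
    """log2(reference/selected) per probe, each array median-centered.

    reference/selected are (n_probes,) or (n_probes, n_replicates) intensity
    arrays; non-positive intensities are floored to the smallest positive value
    of the array (counted via the returned array's mask handling upstream).
    """
    ref = np.atleast_2d(np.asarray(reference, dtype=float).T).T
    sel = np.atleast_2d(np.asarray(selected, dtype=float).T).T
    if ref.shape != sel.shape:
        raise ValueError("reference and selected must have the same shape")
    out = np.empty_like(ref)
    for j in range(ref.shape[1]):
        r, s = ref[:, j].copy(), sel[:, j].copy()
        for arr in (r, s):
            pos = arr[arr > 0]
            if len(pos) == 0:
                raise ValueError("an array channel has no positive intensities")
            f = floor if floor is not None else pos.min()
            np.clip(arr, f, None, out=arr)
        sc = np.log2(r / s)
        out[:, j] = sc - np.median(sc)
    return out if np.asarray(reference).ndim == 2 else out[:, 0]


def zscore_and_smooth(
    scores: np.ndarray,
    positions: np.ndarray,
    window_bp: float = 500.0,
    robust: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize scores over the table and running-median smooth along the genome.

    robust=True standardizes with median/MAD (scaled to SD units) instead of
    mean/SD. Probes from both strands are smoothed together (insertions are
    strand-agnostic).
    """
    scores = np.asarray(scores, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(scores) < 2:
        raise ValueError("need >= 2 probes")
    if robust:
        center = np.median(scores)
        scale = 1.4826 * np.median(np.abs(scores - center))
    else:
        center = scores.mean()
        scale = scores.std(ddof=1)
    if scale == 0:
        raise ValueError("zero score dispersion; cannot standardize")
    z = (scores - center) / scale
    order = np.argsort(positions, kind="stable")
    z_sorted = z[order]
    sm_sorted = smooth_track(positions[order], z_sorted, method="running_median", width=window_bp)
    z_smoothed = np.empty_like(z)
    z_smoothed[order] = sm_sorted
    return z, z_smoothed


def score_table(
    raw: pd.DataFrame, background: str = "WT", condition: str = "selection"
) -> pd.DataFrame:
    """Score a raw reference/selected intensity table (replicate columns paired).

    Expects columns ``reference_rep<i>`` / ``selected_rep<i>``; emits per-replicate
    ``score_rep<i>`` plus pooled ``score`` (mean over replicates), ``z`` and
    ``z_smoothed``.
    """
    ref_cols = sorted(c for c in raw.columns if c.startswith("reference_rep"))
    sel_cols = sorted(c for c in raw.columns if c.startswith("selected_rep"))
    if not ref_cols or len(ref_cols) != len(sel_cols):
        raise ValueError("paired reference_rep*/selected_rep* columns required")
    out = raw[["position", "strand"]].copy()
    scores = selection_scores(raw[ref_cols].to_numpy(), raw[sel_cols].to_numpy())
    for j, _ in enumerate(ref_cols):
        out[f"score_rep{j + 1}"] = scores[:, j]
    out["score"] = scores.mean(axis=1)
    z, z_sm = zscore_and_smooth(out["score"].to_numpy(), out["position"].to_numpy())
    out["z"] = z
    out["z_smoothed"] = z_sm
    out.attrs["background"] = background
    out.attrs["condition"] = condition
    return out


def assign_loci(table: pd.DataFrame, ann: Annotation) -> pd.DataFrame:
    """Attach a strand-agnostic locus_id (gene, else flanking-gene-labelled intergenic)."""
    pos = table["position"].to_numpy()
    gp = ann.gene_at(pos, "+")
    gm = ann.gene_at(pos, "-")
    gid = ann.genes["gene_id"].to_dict()
    loci = locus_intervals(ann)
    inter = loci[loci["kind"] == "intergenic"].sort_values("start")
    istarts = inter["start"].to_numpy()
    iids = inter["locus_id"].to_numpy()
    locus = np.empty(len(table), dtype=object)
    for i in range(len(table)):
        if gp[i] >= 0:
            locus[i] = gid[gp[i]]
        elif gm[i] >= 0:
            locus[i] = gid[gm[i]]
        elif len(istarts):
            j = np.searchsorted(istarts, pos[i], side="right") - 1
            locus[i] = iids[j] if j >= 0 else iids[-1]  # wrap-around interval
        else:
            locus[i] = "ig_none"
    out = table.copy()
    out["locus_id"] = locus
    out.attrs.update(table.attrs)
    return out


def gene_median_scores(table: pd.DataFrame, ann: Annotation, column: str = "score") -> pd.Series:
    """Per-gene median of probe scores whose centers fall inside the gene."""
    pos = table["position"].to_numpy()
    gp = ann.gene_at(pos, "+")
    gm = ann.gene_at(pos, "-")
    row = np.where(gp >= 0, gp, gm)
    gid = ann.genes["gene_id"].to_dict()
    vals: dict[str, list[float]] = {}
    col = table[column].to_numpy()
    for i in range(len(table)):
        if row[i] >= 0:
            vals.setdefault(gid[row[i]], []).append(col[i])
    out = pd.Series(
        {g: float(np.median(v)) for g, v in vals.items()}, name=column, dtype=float
    )
    return out.reindex(ann.genes["gene_id"])  # missing genes -> NaN


def flag_loci(
    table: pd.DataFrame, strict_z: float = 2.0, relaxed_z: float = 1.0
) -> pd.DataFrame:
    """Per-locus strict/relaxed significance flags with effect direction.

    A locus is flagged when >= 1 of its probes has |z_smoothed| >= threshold;
    the direction of its most extreme probe is recorded (negative smoothed Z =
    insertion enriched under selection = advantage).
    """
    if "locus_id" not in table.columns:
        raise ValueError("assign loci first (assign_loci)")
    if strict_z < relaxed_z:
        raise ValueError("strict threshold must be >= relaxed threshold")
    rows = []
    for locus, sub in table.groupby("locus_id", sort=True):
        zs = sub["z_smoothed"].to_numpy()
        i = int(np.argmax(np.abs(zs)))
        extreme = float(zs[i])
        rows.append(
            {
                "locus_id": locus,
                "max_abs_z": abs(extreme),
                "strict": abs(extreme) >= strict_z,
                "relaxed": abs(extreme) >= relaxed_z,
                "direction": "advantage" if extreme < 0 else "disadvantage",
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["strict_z"] = strict_z
    out.attrs["relaxed_z"] = relaxed_z
    return out


def compare_backgrounds(
    flags_a: pd.DataFrame,
    flags_b: pd.DataFrame,
    scores_a: pd.Series,
    scores_b: pd.Series,
    replicate_scores_a: pd.DataFrame | None = None,
    replicate_scores_b: pd.DataFrame | None = None,
    labels: tuple[str, str] = ("WT", "rho*"),
) -> LandscapeComparison:
    """Partition flagged loci into unique/shared(correlated|anticorrelated).

    scores_a/scores_b are gene-median score series on a shared locus universe
    (used for the shared-loci sign split and the Pearson correlation);
    replicate_scores_* are optional per-replicate gene-median frames for the
    replicate-correlation reference.
    """
    fa = flags_a.set_index("locus_id")
    fb = flags_b.set_index("locus_id")
    if set(fa.index) != set(fb.index):
        raise ValueError("locus universes differ between backgrounds")
    strict_a = set(fa.index[fa["strict"]])
    strict_b = set(fb.index[fb["strict"]])
    relaxed_a = set(fa.index[fa["relaxed"]])
    relaxed_b = set(fb.index[fb["relaxed"]])
    unique_a = strict_a - relaxed_b
    unique_b = strict_b - relaxed_a
    shared = (strict_a | strict_b) - unique_a - unique_b
    corr = anti = 0
    for locus in shared:
        sa = scores_a.get(locus, np.nan)
        sb = scores_b.get(locus, np.nan)
        if np.isfinite(sa) and np.isfinite(sb) and sa * sb < 0:
            anti += 1
        else:
            corr += 1
    both = pd.concat([scores_a.rename("a"), scores_b.rename("b")], axis=1).dropna()
    r_ab = float(both["a"].corr(both["b"])) if len(both) > 2 else float("nan")
    r_rep = float("nan")
    reps = []
    for frame in (replicate_scores_a, replicate_scores_b):
        if frame is not None and frame.shape[1] >= 2:
            cols = list(frame.columns)
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    sub = frame[[cols[i], cols[j]]].dropna()
                    if len(sub) > 2:
                        reps.append(float(sub[cols[i]].corr(sub[cols[j]])))
    if reps:
        r_rep = float(np.mean(reps))
    return LandscapeComparison(
        shared_correlated=corr,
        shared_anticorrelated=anti,
        unique_a=len(unique_a),
        unique_b=len(unique_b),
        pearson_between_backgrounds=r_ab,
        pearson_between_replicates=r_rep,
        labels=labels,
    )
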