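"""Differential-transcription calling on tiling-array log-ratios.

Probe-level calls use a moderated one-sample statistic: the replicate mean over
a standard error built from the per-probe SD shrunk half-way toward the global
median SD. Its p-value is computed from the statistic's exact null distribution
under iid Gaussian replicate noise (a one-dimensional integral over the
sample-SD density), so family-wise error control by Bonferroni is calibrated
even with few replicates. A probe is significant when the Bonferroni-corrected
p is below alpha AND the |median log2 ratio| exceeds the fold threshold
(defaults: alpha 0.01, 2-fold). Gene-level calls use the median of
sense-oriented probes against a softer 1.5-fold threshold.

Internal ratio convention: log2(rho*/WT); readers/writers carry an explicit
orientation field because published tables mix both orientations.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .annotation import Annotation

REPL_PREFIX = "log2_ratio_rep"


def replicate_columns(probes: pd.DataFrame) -> list[str]:
    return [c for c in probes.columns if c.startswith(REPL_PREFIX)]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_arrays(
    channel1: np.ndarray, channel2: np.ndarray, floor: float = 1.0
) -> np.ndarray:
    """Per-array log2 ratio, median-centered at 0.

    channel1/channel2 are (n_probes, n_replicates) intensity matrices (one
    column per array). Intensities are floored before the log.
    """
    c1 = np.asarray(channel1, dtype=float)
    c2 = np.asarray(channel2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("channel matrices must have the same shape")
    if (c1.max(axis=0) <= 0).any() or (c2.max(axis=0) <= 0).any():
        raise ValueError("an array channel is all zero")
    ratio = np.log2(np.maximum(c1, floor) / np.maximum(c2, floor))
    return ratio - np.median(ratio, axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# moderated one-sample test
# ---------------------------------------------------------------------------


@lru_cache(maxsize=16)
def _null_grid(n_rep: int, n_nodes: int = 400):
    """Quadrature nodes/weights over the null sample-SD distribution (sigma units)."""
    nu = n_rep - 1
    # s/sigma where s^2 ~ chi2_nu / nu
    u, w = np.polynomial.legendre.leggauss(n_nodes)
    lo, hi = 1e-4, 6.0
    u = 0.5 * (u + 1) * (hi - lo) + lo
    w = w * 0.5 * (hi - lo)
    log_pdf = (
        np.log(2.0)
        + (nu / 2.0) * np.log(nu / 2.0)
        - gammaln(nu / 2.0)
        + (nu - 1) * np.log(u)
        - nu * u**2 / 2.0
    )
    dens = np.exp(log_pdf)
    m = float(np.sqrt(stats.chi2.ppf(0.5, nu) / nu))  # median of s/sigma
    return u, w * dens, m


def moderated_z_pvalues(t_abs: np.ndarray, n_rep: int) -> np.ndarray:
    """Two-sided p-values for T = mean / (((s + s_med)/2) / sqrt(n)) under the null.

    Under iid Gaussian noise T = sqrt(n) * Z * 2 / (u + m) with Z standard
    normal, u the per-probe SD in sigma units and m the (effectively exact over
    many probes) median SD in sigma units; the tail is integrated numerically
    over the density of u.
    """
    u, wdens, m = _null_grid(n_rep)
    t_abs = np.atleast_1d(np.asarray(t_abs, dtype=float))
    # P(|T| > t) = E_u[ 2 * Phi_bar( t * (u + m) / 2 ) ]
    arg = t_abs[:, None] * (u[None, :] + m) / 2.0
    p = 2.0 * (stats.norm.sf(arg) @ wdens)
    return np.clip(p, 0.0, 1.0)


def call_significant_probes(
    probes: pd.DataFrame,
    alpha: float = 0.01,
    fold: float = 2.0,
    test: str = "moderated_z",
) -> pd.DataFrame:
    """Per-probe one-sample test of replicate log2 ratios against 0 + fold filter.

    Adds columns ``mean_log2, median_log2, stat, p_raw, p_bonferroni,
    significant, direction`` and drops (counting them in ``.attrs['n_excluded']``)
    probes with fewer than 2 finite replicates.
    """
    cols = replicate_columns(probes)
    if len(cols) < 2:
        raise ValueError("need >= 2 replicate columns")
    X = probes[cols].to_numpy(dtype=float)
    n_finite = np.isfinite(X).sum(axis=1)
    keep = n_finite >= 2
    out = probes.loc[keep].copy()
    out.attrs["n_excluded"] = int((~keep).sum())
    X = X[keep]
    n = X.shape[1]
    mean = np.nanmean(X, axis=1)
    med = np.nanmedian(X, axis=1)
    sd = np.nanstd(X, axis=1, ddof=1)
    if test == "moderated_z":
        s_mod = (sd + np.median(sd)) / 2.0
        t = mean / (s_mod / np.sqrt(n))
        p = moderated_z_pvalues(np.abs(t), n)
    elif test == "t":
        t, p = stats.ttest_1samp(X, 0.0, axis=1)
        t = np.asarray(t)
        p = np.asarray(p)
    else:
        raise ValueError(f"unknown test {test!r}")
    n_probes = len(out)
    p_bonf = np.minimum(1.0, p * n_probes)
    out["mean_log2"] = mean
    out["median_log2"] = med
    out["stat"] = t
    out["p_raw"] = p
    out["p_bonferroni"] = p_bonf
    fold_thr = np.log2(fold) if fold > 0 else -np.inf
    out["significant"] = (p_bonf < alpha) & (np.abs(med) > fold_thr)
    out["direction"] = np.where(med > 0, "up_in_rho*", "up_in_WT")
    out.attrs["alpha"] = alpha
    out.attrs["fold"] = fold
    return out


# ---------------------------------------------------------------------------
# orientation and gene-level calls
# ---------------------------------------------------------------------------


def assign_orientation(probes: pd.DataFrame, ann: Annotation) -> pd.DataFrame:
    """Sense/antisense/both/intergenic assignment of each probe to genes.

    A probe covered by genes on both strands is 'both' and is excluded from
    sense/antisense fraction denominators downstream.
    """
    pos = probes["position"].to_numpy()
    strand = probes["strand"].to_numpy()
    gp = ann.gene_at(pos, "+")
    gm = ann.gene_at(pos, "-")
    same = np.where(strand == "+", gp, gm)
    opp = np.where(strand == "+", gm, gp)
    orientation = np.full(len(probes), "intergenic", dtype=object)
    orientation[(same >= 0) & (opp < 0)] = "sense"
    orientation[(same < 0) & (opp >= 0)] = "antisense"
    orientation[(same >= 0) & (opp >= 0)] = "both"
    gid = ann.genes["gene_id"].to_dict()
    gene_id = np.full(len(probes), "", dtype=object)
    for i in range(len(probes)):
        ids = []
        if same[i] >= 0:
            ids.append(gid[same[i]])
        if opp[i] >= 0 and opp[i] != same[i]:
            ids.append(gid[opp[i]])
        gene_id[i] = ";".join(ids)
    out = probes.copy()
    out["orientation"] = orientation
    out["gene_id"] = gene_id
    out.attrs.update(probes.attrs)
    return out


def antisense_fraction(probes: pd.DataFrame, direction: str = "up_in_rho*") -> float:
    """Fraction of significant gene-overlapping probes (given direction) that are antisense.

    'both'-oriented probes are excluded from the denominator.
    """
    sub = probes[
        probes["significant"]
        & (probes["direction"] == direction)
        & probes["orientation"].isin(["sense", "antisense"])
    ]
    if len(sub) == 0:
        return float("nan")
    return float((sub["orientation"] == "antisense").mean())


def gene_level_calls(probes: pd.DataFrame, ann: Annotation, fold: float = 1.5) -> pd.DataFrame:
    """Per-gene median of sense-probe log2 ratios with a |ratio| > fold call."""
    if "orientation" not in probes.columns:
        raise ValueError("assign orientation first (assign_orientation)")
    med_col = "median_log2" if "median_log2" in probes.columns else None
    if med_col is None:
        probes = probes.copy()
        probes["median_log2"] = probes[replicate_columns(probes)].median(axis=1)
    sense = probes[probes["orientation"] == "sense"]
    rows = []
    thr = np.log2(fold)
    grouped = sense.groupby("gene_id")["median_log2"].median()
    for _, g in ann.genes.iterrows():
        v = grouped.get(g.gene_id, np.nan)
        if np.isnan(v):
            call, flag = "none", "no_sense_probes"
        elif v > thr:
            call, flag = "over_in_rho*", ""
        elif v < -thr:
            call, flag = "under_in_rho*", ""
        else:
            call, flag = "none", ""
        rows.append(
            {"gene_id": g.gene_id, "median_sense_log2": v, "call": call, "flag": flag}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# track smoothing
# ---------------------------------------------------------------------------


def smooth_track(
    positions: np.ndarray, values: np.ndarray, method: str = "gaussian", width: float = 100.0
) -> np.ndarray:
    """Positional smoothing of a genome track.

    gaussian: kernel-weighted mean with SD = width (bp), truncated at 4 SD.
    running_median: median over the window of total length `width` centered on
    each position; edge windows are truncated.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(positions) == 0:
        return values.copy()
    if width <= 0:
        raise ValueError("width must be positive")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    out = np.empty_like(values)
    if method == "gaussian":
        half = 4.0 * width
    elif method == "running_median":
        half = width / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    lo = np.searchsorted(positions, positions - half, side="left")
    hi = np.searchsorted(positions, positions + half, side="right")
    for i in range(len(positions)):
        w = values[lo[i] : hi[i]]
        if method == "gaussian":
            d = positions[lo[i] : hi[i]] - positions[i]
            k = np.exp(-0.5 * (d / width) ** 2)
            out[i] = np.sum(k * w) / np.sum(k)
        else:
            out[i] = np.median(w)
    return out


def write_bedgraph(path, positions, values, seqid: str = "synthetic_genome", span: int = 50) -> None:
    with open(path, "w") as fh:
        for p, v in zip(positions, values):
            fh.write(f"{seqid}\t{int(p)}\t{int(p) + span}\t{v:.5f}\n")
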