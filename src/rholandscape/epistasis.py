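"""Multiplicative epistasis between two mutations from growth-rate data.

For alleles A and B with relative fitnesses w_X = gamma_X / gamma_00 (wild type
reference), the multiplicative epistasis is

    epsilon = w_AB - w_A * w_B        (linear scale, default)
    epsilon = log2(w_AB / (w_A w_B))  (log scale, optional)

Positive epsilon means the double mutant is fitter than the product of the
single-mutant effects predicts. Confidence intervals come from recomputing
epsilon over paired posterior draws of all four rates (strains measured
independently, so draws are paired only by index). A competition-experiment
cross-check estimates the selection coefficient from the slope of the log2
count ratio over passages and reports the posterior probability that the
epistasis sign matches a stated reference sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class UndefinedFitnessError(ValueError):
    """Raised when the reference strain shows no growth (w undefined)."""


@dataclass
class FitnessQuartet:
    """Growth rates (with posterior draws) for 00, A, B and AB strains."""

    gamma_00: float
    gamma_a: float
    gamma_b: float
    gamma_ab: float
    samples_00: np.ndarray
    samples_a: np.ndarray
    samples_b: np.ndarray
    samples_ab: np.ndarray
    labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        n = {len(self.samples_00), len(self.samples_a), len(self.samples_b), len(self.samples_ab)}
        if len(n) != 1:
            raise ValueError("all four posterior sample sets must have equal length")


@dataclass
class EpistasisResult:
    epsilon: float
    ci_low: float
    ci_high: float
    sign_call: str  # positive / negative / none
    predicted_gamma_ab: float  # no-epistasis multiplicative prediction
    scale: str = "linear"
    flags: list[str] = field(default_factory=list)


def relative_fitness(gamma_mut: float, gamma_ref: float) -> float:
    """w = gamma_mut / gamma_ref; undefined when the reference does not grow."""
    if gamma_ref <= 0:
        raise UndefinedFitnessError(
            "reference growth rate is zero; relative fitness undefined "
            "(e.g. complete absence of wild-type growth in a condition)"
        )
    return gamma_mut / gamma_ref


def _epsilon(g00, ga, gb, gab, scale: str):
    wa, wb, wab = ga / g00, gb / g00, gab / g00
    if scale == "linear":
        return wab - wa * wb
    if scale == "log":
        return np.log2(wab / (wa * wb))
    raise ValueError(f"unknown scale {scale!r}")


def multiplicative_epistasis(quartet: FitnessQuartet, scale: str = "linear") -> EpistasisResult:
    """Point estimate, paired-draw 95% CI and sign call for epsilon."""
    if quartet.gamma_00 <= 0:
        raise UndefinedFitnessError("gamma_00 = 0: epsilon undefined in this condition")
    eps = float(_epsilon(quartet.gamma_00, quartet.gamma_a, quartet.gamma_b, quartet.gamma_ab, scale))
    flags = []
    g00 = quartet.samples_00
    mask = g00 > 0
    if scale == "log":
        mask &= (quartet.samples_a > 0) & (quartet.samples_b > 0) & (quartet.samples_ab > 0)
    if not mask.all():
        flags.append("nonpositive_draws_dropped")
    draws = _epsilon(
        g00[mask], quartet.samples_a[mask], quartet.samples_b[mask], quartet.samples_ab[mask], scale
    )
    lo, hi = np.percentile(draws, [2.5, 97.5])
    if lo > 0:
        sign = "positive"
    elif hi < 0:
        sign = "negative"
    else:
        sign = "none"
    wa = quartet.gamma_a / quartet.gamma_00
    wb = quartet.gamma_b / quartet.gamma_00
    return EpistasisResult(
        epsilon=eps,
        ci_low=float(lo),
        ci_high=float(hi),
        sign_call=sign,
        predicted_gamma_ab=float(quartet.gamma_00 * wa * wb),
        scale=scale,
        flags=flags,
    )


def competition_epistasis_sign(
    counts: np.ndarray, reference_sign: int = 1
) -> tuple[float, float, list[str]]:
    """Posterior probability that the competition-derived epistasis sign matches.

    Parameters
    ----------
    counts : array (n_passages, 2)
        Paired counts of (focal, competitor) over serial passages. Zero counts
        receive a 0.5 pseudo-count (flagged).
    reference_sign : {+1, -1}
        Sign identified from growth-curve data.

    Returns
    -------
    (selection_coefficient, p_sign_match, flags)
        The per-passage selection coefficient is the OLS slope of the log2
        count ratio versus passage number; the sign posterior is a normal
        approximation around that slope. With < 3 passages the slope SE is
        undefined and p = 0.5 is returned (no information).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] < 2:
        raise ValueError("counts must be (n_passages >= 2, 2)")
    flags = []
    if (counts == 0).any():
        counts = counts + np.where(counts == 0, 0.5, 0.0)
        flags.append("pseudocount_applied")
    ratio = np.log2(counts[:, 0] / counts[:, 1])
    x = np.arange(len(ratio), dtype=float)
    if len(ratio) == 2:
        s = float(ratio[1] - ratio[0])
        return s, 0.5, flags + ["two_points_no_se"]
    res = stats.linregress(x, ratio)
    s = float(res.slope)
    if not np.isfinite(res.stderr) or res.stderr == 0:
        p = 1.0 if np.sign(s) == reference_sign else (0.5 if s == 0 else 0.0)
        return s, float(p), flags + ["zero_residual_slope"]
    z = s / res.stderr
    p_pos = float(stats.norm.cdf(z))  # P(true slope > 0)
    p = p_pos if reference_sign > 0 else 1.0 - p_pos
    return s, p, flags
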