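"""Bin-count selection and the subsampling permutation test.

GI and LI values are comparable only when computed with the same number of
histogram bins K. ``select_k_freedman_diaconis`` automates the choice from
the data; ``permutation_test`` assesses whether an LI (or GI) difference
between two experimental conditions survives subsampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import PairedSample, alignment_values, compute_debias

__all__ = ["BinSelection", "PermutationTestResult", "select_k_freedman_diaconis", "permutation_test"]

K_MIN = 3
K_MAX = 100


@dataclass(frozen=True)
class BinSelection:
    """Outcome of automatic bin-count selection."""

    k: int
    bin_width: float
    q1: float
    q3: float
    n: int


@dataclass(frozen=True)
class PermutationTestResult:
    """Subsampling permutation test for a GI or LI contrast.

    ``fraction_contradicting`` is the fraction of iterations in which the
    subsampled statistics reversed the full-data ordering; the reported
    p-value is floored at 1/n_iter (a fraction of zero means p < 1/n_iter,
    not p = 0).
    """

    p_value: float
    fraction_contradicting: float
    n_iter: int
    subsample_fraction: float
    direction: Literal["a_less", "b_less"]
    statistic: Literal["LI", "GI"]
    seed: int
    statistic_a: float = float("nan")
    statistic_b: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "p_value": self.p_value,
            "fraction_contradicting": self.fraction_contradicting,
            "n_iter": self.n_iter,
            "subsample_fraction": self.subsample_fraction,
            "direction": self.direction,
            "statistic": self.statistic,
            "seed": self.seed,
            "statistic_a": self.statistic_a,
            "statistic_b": self.statistic_b,
        }


def select_k_freedman_diaconis(
    values, domain_low: float, domain_high: float
) -> BinSelection:
    """Freedman–Diaconis bin count for an alignment/difference distribution.

    bin_width = (Q3 - Q1) / n^(1/3); k = ceil(domain span / bin_width),
    clamped to [3, 100]. Applied to the alignment (or normalized-difference)
    values, i.e. the distribution actually being binned.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for bin selection")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError(
            "interquartile range is zero; automatic bin selection is "
            "undefined — supply K manually"
        )
    bin_width = iqr / v.size ** (1.0 / 3.0)
    k = math.ceil((domain_high - domain_low) / bin_width)
    k = min(max(k, K_MIN), K_MAX)
    return BinSelection(k=k, bin_width=float(bin_width), q1=float(q1), q3=float(q3), n=int(v.size))


def select_k_for_sample(sample: PairedSample, normalize: bool = True) -> BinSelection:
    """Convenience: FD selection on a sample's own alignment values."""
    from .core import _alignment_domain

    low, high = _alignment_domain(sample.mode)
    return select_k_freedman_diaconis(
        alignment_values(sample, normalize=normalize), low, high
    )


def permutation_test(
    sample_a: PairedSample,
    sample_b: PairedSample,
    k: int,
    statistic: Literal["LI", "GI"] = "LI",
    n_iter: int = 100,
    subsample_fraction: float = 0.5,
    seed: int = 0,
    normalize: bool = True,
) -> PermutationTestResult:
    """Subsampling permutation test for a GI/LI difference between conditions.

    The full-data statistics fix the ordering (say condition a below b).
    Each iteration independently subsamples ``floor(fraction * N)``
    observations without replacement from each condition, recomputes the
    statistic, and counts iterations in which the subsampled ordering is
    strictly reversed. Ties count as non-contradicting (conservative).
    """
    if sample_a.mode != sample_b.mode:
        raise ValueError("samples must share a mode")
    if statistic not in ("LI", "GI"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not 0 < subsample_fraction < 1:
        raise ValueError("subsample_fraction must lie in (0, 1)")
    n_sub_a = int(subsample_fraction * sample_a.n)
    n_sub_b = int(subsample_fraction * sample_b.n)
    if n_sub_a < 2 or n_sub_b < 2:
        raise ValueError("subsample size below 2; increase N or the fraction")

    rng = np.random.default_rng(seed)

    def stat(sample: PairedSample, run_seed: int) -> float:
        res = compute_debias(sample, k=k, seed=run_seed, normalize=normalize)
        return res.li if statistic == "LI" else res.gi

    max_seed = 2**31 - 1
    full_a = stat(sample_a, int(rng.integers(max_seed)))
    full_b = stat(sample_b, int(rng.integers(max_seed)))
    a_less = full_a <= full_b
    direction = "a_less" if a_less else "b_less"

    contradicting = 0
    for _ in range(n_iter):
        sub_a = sample_a.subsample(n_sub_a, rng)
        sub_b = sample_b.subsample(n_sub_b, rng)
        sa = stat(sub_a, int(rng.integers(max_seed)))
        sb = stat(sub_b, int(rng.integers(max_seed)))
        if (sa > sb) if a_less else (sb > sa):
            contradicting += 1

    fraction = contradicting / n_iter
    return PermutationTestResult(
        p_value=max(fraction, 1.0 / n_iter),
        fraction_contradicting=fraction,
        n_iter=int(n_iter),
        subsample_fraction=float(subsample_fraction),
        direction=direction,
        statistic=statistic,
        seed=int(seed),
        statistic_a=full_a,
        statistic_b=full_b,
    )
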