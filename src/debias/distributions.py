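"""Quantized distributions on fixed domains and the Earth Mover's Distance.

The decomposition of observed coupling into global and local components
compares three K-bin histograms on a common domain: the *observed* alignment
distribution, a *resampled* (marginals-only) alignment distribution, and the
flat *uniform* reference. This module provides the histogram container, the
analytic uniform reference, and the 1-D Earth Mover's Distance between
histograms sharing a domain and bin count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CouplingHistogram",
    "quantize",
    "uniform_reference",
    "emd",
    "mean_alignment",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class CouplingHistogram:
    """K-bin histogram of alignment angles or normalized intensity differences.

    Parameters
    ----------
    domain_low, domain_high
        Bounds of the fixed quantization domain (degrees for orientation
        data, dimensionless on [-1, 1] for co-localization differences).
    k
        Number of equal-width bins, at least 2.
    frequencies
        Fraction of observations per bin; non-negative, summing to 1.
    n_source
        Number of observations that were quantized (0 for analytic
        references such as the uniform baseline).
    """

    domain_low: float
    domain_high: float
    k: int
    frequencies: np.ndarray = field(repr=False)
    n_source: int = 0

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freq)
        if self.k < 2:
            raise ValueError(f"need at least 2 bins, got k={self.k}")
        if not self.domain_low < self.domain_high:
            raise ValueError(
                f"empty domain [{self.domain_low}, {self.domain_high}]"
            )
        if freq.shape != (self.k,):
            raise ValueError(
                f"expected {self.k} frequencies, got shape {freq.shape}"
            )
        if np.any(freq < 0):
            raise ValueError("negative bin frequency")
        if abs(freq.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {freq.sum()}, not 1")

    @property
    def bin_width(self) -> float:
        return (self.domain_high - self.domain_low) / self.k

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.domain_low, self.domain_high, self.k + 1)

    def same_support(self, other: "CouplingHistogram") -> bool:
        return (
            self.k == other.k
            and self.domain_low == other.domain_low
            and self.domain_high == other.domain_high
        )


def quantize(
    values,
    domain_low: float,
    domain_high: float,
    k: int,
) -> CouplingHistogram:
    """Bin values into K equal-width bins and return normalized frequencies.

    Bins are half-open ``[edge_i, edge_{i+1})`` except the last, which is
    closed so that ``domain_high`` itself is counted in bin K.

    Raises
    ------
    ValueError
        If ``k < 2``, the input is empty, or any value falls outside
        ``[domain_low, domain_high]``.
    """
    if k < 2:
        raise ValueError(f"need at least 2 bins, got k={k}")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot quantize an empty sequence")
    below = v < domain_low
    above = v > domain_high
    if below.any() or above.any():
        bad = v[below | above][0]
        raise ValueError(
            f"value {bad} outside domain [{domain_low}, {domain_high}]"
        )
    width = (domain_high - domain_low) / k
    idx = np.floor((v - domain_low) / width).astype(int)
    # the domain maximum floors to k; fold it into the closed last bin
    idx = np.minimum(idx, k - 1)
    counts = np.bincount(idx, minlength=k).astype(float)
    return CouplingHistogram(
        domain_low=float(domain_low),
        domain_high=float(domain_high),
        k=int(k),
        frequencies=counts / v.size,
        n_source=int(v.size),
    )


def uniform_reference(
    k: int, domain_low: float = 0.0, domain_high: float = 90.0
) -> CouplingHistogram:
    """Analytic flat reference: every bin holds exactly 1/K.

    This is the alignment distribution expected with neither global bias
    nor local interaction; it is constructed exactly rather than sampled.
    """
    if k < 2:
        raise ValueError(f"need at least 2 bins, got k={k}")
    return CouplingHistogram(
        domain_low=float(domain_low),
        domain_high=float(domain_high),
        k=int(k),
        frequencies=np.full(k, 1.0 / k),
        n_source=0,
    )


def emd(a: CouplingHistogram, b: CouplingHistogram) -> float:
    """Earth Mover's Distance between two same-support histograms.

    For 1-D histograms with unit bin spacing this is the L1 distance
    between cumulative sums::

        EMD(A, B) = sum_i | sum_{j<=i} a_j - sum_{j<=i} b_j |

    Histograms with different K or domains are not comparable and are
    rejected.
    """
    if not a.same_support(b):
        raise ValueError(
            "histograms are not comparable: "
            f"k={a.k} on [{a.domain_low}, {a.domain_high}] vs "
            f"k={b.k} on [{b.domain_low}, {b.domain_high}]"
        )
    return float(np.abs(np.cumsum(a.frequencies - b.frequencies)).sum())


def mean_alignment(values) -> float:
    """Arithmetic mean of alignment values (degrees in orientation mode)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mean_alignment of an empty sequence")
    return float(v.mean())
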