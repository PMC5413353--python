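"""Readers, writers and dataset grouping for the command-line workflow.

The canonical interchange format is a two-column numeric table (CSV or TSV),
one row per matched pair: two angles in degrees (orientation mode) or two
raw intensities (co-localization mode). Matched pixel pairs can also be
pulled directly from a pair of single-channel TIFF images with an optional
mask. Results round-trip through JSON; CSV output is one flat row.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DeBiasResult, PairedSample
from .stats import PermutationTestResult

__all__ = [
    "ConditionSet",
    "read_paired_table",
    "read_image_pair",
    "write_result",
    "read_result_json",
]

logger = logging.getLogger("debias")


@dataclass(frozen=True)
class ConditionSet:
    """Named group of samples analysed together under one shared K."""

    name: str
    samples: tuple[PairedSample, ...]
    mode: str
    k: int

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError(f"condition {self.name!r} has no samples")
        modes = {s.mode for s in self.samples}
        if modes != {self.mode}:
            raise ValueError(
                f"condition {self.name!r} mixes modes {sorted(modes)}; all "
                f"samples must be {self.mode!r}"
            )
        if self.k < 2:
            raise ValueError("k must be >= 2")

    def pooled(self) -> PairedSample:
        """All member samples concatenated into one sample."""
        x = np.concatenate([s.x for s in self.samples])
        y = np.concatenate([s.y for s in self.samples])
        return PairedSample(self.mode, x, y, label=self.name)


def _separator(path: Path, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_paired_table(
    path: str | Path,
    mode: str,
    dialect: str | None = None,
) -> PairedSample:
    """Read a two-column paired table into a validated sample.

    A single header row is auto-detected and skipped. Rows with missing or
    non-numeric entries are dropped with a logged count. Orientation values
    are wrapped to [-90, 90] on construction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _separator(path, dialect)
    df = pd.read_csv(path, sep=sep, header=None, skipinitialspace=True, comment="#")
    if df.shape[1] != 2:
        raise ValueError(
            f"{path}: expected exactly 2 columns, found {df.shape[1]}"
        )
    df = df.apply(pd.to_numeric, errors="coerce")
    # a non-numeric first row is a header
    if df.iloc[0].isna().all() and len(df) > 1:
        df = df.iloc[1:]
    n_raw = len(df)
    df = df.dropna()
    dropped = n_raw - len(df)
    if dropped:
        logger.info("%s: dropped %d rows with missing/non-numeric entries", path, dropped)
    if df.empty:
        raise ValueError(f"{path}: no valid data rows")
    return PairedSample(mode, df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), label=path.stem)


def read_image_pair(
    path_x: str | Path,
    path_y: str | Path,
    mask: str | Path | None = None,
    subsample_n: int | None = None,
    seed: int = 0,
    mode: str = "colocalization",
) -> PairedSample:
    """Extract matched pixel intensities from two single-channel TIFF images.

    Pixels where the (optional) mask is nonzero form the pairs; a seeded
    random subset of ``subsample_n`` pixels is taken when requested.
    """
    import tifffile

    img_x = np.asarray(tifffile.imread(str(path_x)), dtype=float)
    img_y = np.asarray(tifffile.imread(str(path_y)), dtype=float)
    if img_x.shape != img_y.shape:
        raise ValueError(
            f"image shape mismatch: {img_x.shape} vs {img_y.shape}"
        )
    if img_x.ndim != 2:
        raise ValueError(f"expected single-channel 2-D images, got shape {img_x.shape}")
    if mask is not None:
        m = np.asarray(tifffile.imread(str(mask)))
        if m.shape != img_x.shape:
            raise ValueError(f"mask shape {m.shape} does not match images {img_x.shape}")
        keep = m != 0
        if not keep.any():
            raise ValueError("mask selects no pixels")
    else:
        keep = np.ones(img_x.shape, dtype=bool)
    x = img_x[keep]
    y = img_y[keep]
    if subsample_n is not None and subsample_n < x.size:
        rng = np.random.default_rng(seed)
        idx = rng.choice(x.size, size=subsample_n, replace=False)
        x, y = x[idx], y[idx]
    label = f"{Path(path_x).stem}+{Path(path_y).stem}"
    return PairedSample(mode, x, y, label=label)


def _result_dict(result: DeBiasResult | PermutationTestResult) -> dict:
    d = result.to_dict()
    d["result_type"] = type(result).__name__
    return d


def write_result(
    result: DeBiasResult | PermutationTestResult,
    path: str | Path,
    format: str = "json",
) -> None:
    """Write a result as round-trippable JSON or a one-row CSV."""
    path = Path(path)
    d = _result_dict(result)
    if format == "json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(d))
            writer.writeheader()
            writer.writerow(d)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_result_json(path: str | Path) -> DeBiasResult | PermutationTestResult:
    """Load a JSON result written by :func:`write_result`."""
    d = json.loads(Path(path).read_text())
    kind = d.pop("result_type")
    if kind == "DeBiasResult":
        return DeBiasResult(**d)
    if kind == "PermutationTestResult":
        return PermutationTestResult(**d)
    raise ValueError(f"unknown result type {kind!r}")
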