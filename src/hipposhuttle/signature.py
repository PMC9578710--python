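"""Temporal gene-signature activity index.

Given a genes × samples expression matrix (log2 scale by default) with a
sample sheet assigning each sample to a time point (control samples form
their own group), the pathway activity of a gene signature at a time point is

    index(t) = sum over signature genes g with z_g(t) > 0.5 of z_g(t),
               divided by the number of signature genes,

where z is the per-gene z-score across all samples and replicate z values are
averaged per (gene, time) before thresholding.  Large signatures may first be
restricted to genes responding to the perturbation by more than a two-fold
change versus the control mean.  Comparing the peak times of several
signatures (ROS, AKT, YAP) orders the underlying processes in time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SignatureIndexSeries",
    "NoPeakError",
    "zscore",
    "fc_filter",
    "expression_index",
    "peak_time",
    "load_signature",
]


def load_signature(path: str | Path) -> list[str]:
    """Read a one-gene-per-line signature file (``#`` lines are comments).

    Synthetic placeholder lists of the published signature sizes ship under
    ``hipposhuttle/data/signatures/``; real lists are user-supplied.
    """
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    if not genes:
        raise ValueError(f"signature file {path} contains no genes")
    return genes


class NoPeakError(ValueError):
    """A constant index series has no peak time."""


@dataclass
class ExpressionMatrix:
    """Expression values (genes × samples) with per-sample time labels.

    ``sample_times``: time point (hours) per sample, indexed like the matrix
    columns; ``control_samples`` designate the untreated group used for
    fold-change filtering.  Values are log2 unless ``log_scale`` is False.
    """

    values: pd.DataFrame
    sample_times: pd.Series
    control_samples: tuple[str, ...] = ()
    log_scale: bool = True

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        missing = set(self.values.columns) - set(self.sample_times.index)
        if missing:
            raise ValueError(f"samples without a time assignment: {sorted(missing)}")
        unknown = set(self.control_samples) - set(self.values.columns)
        if unknown:
            raise ValueError(f"unknown control samples: {sorted(unknown)}")

    @property
    def time_points(self) -> np.ndarray:
        return np.unique(self.sample_times[list(self.values.columns)])

    @classmethod
    def from_files(
        cls, matrix_path: str | Path, sample_sheet_path: str | Path,
        log_scale: bool = True,
    ) -> "ExpressionMatrix":
        """Read a TSV/CSV matrix (rows = genes) and a sample sheet with
        columns sample, time, group (group 'control' marks controls)."""
        matrix_path = Path(matrix_path)
        sep = "\t" if matrix_path.suffix in (".tsv", ".txt") else ","
        values = pd.read_csv(matrix_path, sep=sep, index_col=0)
        sheet = pd.read_csv(sample_sheet_path)
        sample_times = pd.Series(
            sheet["time"].to_numpy(float), index=sheet["sample"]
        )
        controls = tuple(sheet.loc[sheet["group"] == "control", "sample"])
        return cls(values, sample_times, controls, log_scale)


@dataclass
class SignatureIndexSeries:
    """Per-time-point activity index of one signature."""

    name: str
    times: np.ndarray
    index: np.ndarray
    n_signature_genes: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.index).all():
            raise ValueError("index values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "index": self.index, "signature": self.name}
        )


def zscore(matrix: ExpressionMatrix | pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-score across all samples (sd with n-1 denominator).

    Zero-variance genes get all-zero rows and are returned in the flagged
    list rather than producing NaNs.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    flagged = list(df.index[(sd == 0) | sd.isna()])
    sd_safe = sd.replace(0, np.nan)
    z = df.sub(mean, axis=0).div(sd_safe, axis=0)
    z.loc[flagged] = 0.0
    return z, flagged


def fc_filter(
    matrix: ExpressionMatrix,
    signature_genes: Sequence[str],
    fc_threshold: float = 2.0,
) -> list[str]:
    """Keep signature genes whose strongest response versus the control mean
    exceeds ``fc_threshold`` (absolute fold change, either direction).

    Signature genes absent from the matrix are dropped with a warning.
    """
    if not matrix.control_samples:
        raise ValueError("fold-change filtering requires control samples")
    present = [g for g in signature_genes if g in matrix.values.index]
    missing = sorted(set(signature_genes) - set(present))
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}", stacklevel=2)
    treated = [c for c in matrix.values.columns if c not in matrix.control_samples]
    sub = matrix.values.loc[present]
    ctrl_mean = sub[list(matrix.control_samples)].mean(axis=1)
    if matrix.log_scale:
        log_fc = sub[treated].sub(ctrl_mean, axis=0).abs()
        max_fc = np.power(2.0, log_fc.max(axis=1))
    else:
        ratio = sub[treated].div(ctrl_mean, axis=0)
        max_fc = np.maximum(ratio, 1.0 / ratio).max(axis=1)
    return list(max_fc.index[max_fc > fc_threshold])


def expression_index(
    z_matrix: pd.DataFrame,
    signature_genes: Sequence[str],
    sample_times: pd.Series,
    z_threshold: float = 0.5,
    name: str = "signature",
    replicate_policy: str = "average",
) -> SignatureIndexSeries:
    """Signature activity index over time.

    Replicate z values at a time point are averaged per gene before
    thresholding (``replicate_policy='average'``, the default) or thresholded
    per replicate and then averaged (``'threshold_first'``).  The sum of
    above-threshold z values is normalized to the number of signature genes
    present in the matrix.  The threshold is strict (> 0.5, not >=).
    """
    genes = [g for g in signature_genes if g in z_matrix.index]
    missing = sorted(set(signature_genes) - set(genes))
    if not genes:
        raise ValueError(
            f"no signature genes found in the matrix; missing: {missing}"
        )
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}", stacklevel=2)
    times = np.unique(sample_times[list(z_matrix.columns)])
    values = np.empty(len(times))
    z_sub = z_matrix.loc[genes]
    for i, t in enumerate(times):
        samples = [c for c in z_matrix.columns if sample_times[c] == t]
        if replicate_policy == "average":
            z_t = z_sub[samples].mean(axis=1)
            values[i] = z_t[z_t > z_threshold].sum() / len(genes)
        elif replicate_policy == "threshold_first":
            per_rep = z_sub[samples].where(z_sub[samples] > z_threshold, 0.0)
            values[i] = per_rep.sum(axis=0).mean() / len(genes)
        else:
            raise ValueError(f"unknown replicate_policy {replicate_policy!r}")
    return SignatureIndexSeries(name, times, values, len(genes))


def peak_time(series: SignatureIndexSeries) -> tuple[float, bool]:
    """Time point of the index maximum; ties break to the earliest time.

    Returns (time, tie_flag); raises ``NoPeakError`` for a constant series.
    """
    idx = series.index
    if np.ptp(idx) == 0:
        raise NoPeakError(f"index series {series.name!r} is constant: no peak")
    best = float(idx.max())
    at_max = series.times[idx == best]
    return float(at_max.min()), len(at_max) > 1
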