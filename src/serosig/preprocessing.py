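"""Replicate aggregation and Z-normalization with training-derived parameters.

The classifier is fit on Z-transformed concentrations.  To keep the
cross-validation contract leakage-free, normalization parameters (per-marker
mean and sample sd) are fit on the training rows of each fold and applied
unchanged to the held-out rows; a global mode reproducing a single whole-cohort
transform is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class NormalizationParams:
    """Per-marker location/scale fitted on a stated subject subset.

    ``sd`` uses the n-1 denominator.  Markers with zero sd are degenerate:
    they carry no single-marker signal, are mapped to z = 0, and are excluded
    from ranking.
    """

    mean: np.ndarray
    sd: np.ndarray
    degenerate: np.ndarray  # boolean mask, True where sd == 0

    def __post_init__(self) -> None:
        if not (len(self.mean) == len(self.sd) == len(self.degenerate)):
            raise ValueError("parameter vectors must share one entry per marker")
        if np.any(self.sd < 0):
            raise ValueError("sd must be nonnegative")


def aggregate_replicates(replicates: np.ndarray, *, method: str = "mean") -> np.ndarray:
    """Collapse a subjects x markers x R replicate tensor to a matrix.

    The arithmetic mean is the conventional reduction for quadruplicate
    sandwich-ELISA readings; ``method='median'`` is available for robustness.
    """
    rep = np.asarray(replicates, dtype=float)
    if rep.ndim != 3 or rep.shape[2] < 1:
        raise ValueError("expected a subjects x markers x R tensor with R >= 1")
    if not np.all(np.isfinite(rep)):
        raise ValueError("replicate tensor contains non-finite values")
    if method == "mean":
        return rep.mean(axis=2)
    if method == "median":
        return np.median(rep, axis=2)
    raise ValueError(f"unknown aggregation method {method!r}")


def zscore_fit(matrix: np.ndarray, rows: np.ndarray | None = None) -> NormalizationParams:
    """Fit per-marker mean and sample sd on the given subject rows only."""
    x = np.asarray(matrix, dtype=float)
    if rows is not None:
        x = x[np.asarray(rows)]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 subjects to fit normalization")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return NormalizationParams(mean=mean, sd=sd, degenerate=sd == 0)


def zscore_apply(matrix: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Apply a fitted transform: z = (x - mean)/sd; degenerate markers -> 0."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[1] != len(params.mean):
        raise ValueError(
            f"matrix has {x.shape[1]} markers but params describe {len(params.mean)}"
        )
    safe_sd = np.where(params.degenerate, 1.0, params.sd)
    z = (x - params.mean) / safe_sd
    z[:, params.degenerate] = 0.0
    return z
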