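"""Normalization chain for raw linear-scale array intensities.

Two steps, applied in order: (1) floor low/background signals on the linear
scale and take log2; (2) center each sample so all per-sample medians agree.
The intensity-normalization step of the original array-analysis recipe was a
lowess fit against the 50th-percentile signal; since the downstream statistics
consume only group means, this package implements the location part of that
correction — per-sample median centering in log2 space — and exposes a hook
for a user-supplied per-sample smooth correction where an intensity-dependent
adjustment is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .expression_io import CohortExpression


@dataclass(frozen=True)
class NormalizationParams:
    """Parameters of the normalization chain.

    floor_value:
        Linear intensities below this are raised to it before the log
        transform (background correction). Must be positive.
    scaling:
        ``"per_sample_median"`` or ``"none"``.
    """

    floor_value: float = 0.01
    scaling: str = "per_sample_median"
    log_base: int = 2            # fixed
    reference_percentile: int = 50  # fixed

    def __post_init__(self) -> None:
        if not self.floor_value > 0:
            raise ValueError("floor_value must be > 0")
        if self.scaling not in ("per_sample_median", "none"):
            raise ValueError(f"unknown scaling mode {self.scaling!r}")
        if self.log_base != 2 or self.reference_percentile != 50:
            raise ValueError("log base and reference percentile are fixed (2, 50)")


def floor_and_log(matrix: pd.DataFrame,
                  params: NormalizationParams = NormalizationParams()) -> pd.DataFrame:
    """Floor linear intensities at ``params.floor_value`` and return log2 values.

    Raises if entries are negative or non-finite: arrays report nonnegative
    intensities, so negatives indicate data on the wrong scale.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite entries")
    if (values < 0).any():
        raise ValueError(
            "negative intensities: input looks already log-scaled or corrupt")
    floored = np.maximum(values, params.floor_value)
    return pd.DataFrame(np.log2(floored), index=matrix.index, columns=matrix.columns)


def scale_to_median(log2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Shift each sample column so its median equals the global target median.

    The target is the median of the per-sample medians, so an already-centered
    matrix is returned unchanged and the operation is idempotent.
    """
    if log2_matrix.shape[0] < 2:
        raise ValueError("median scaling is undefined for a single-probe matrix")
    medians = log2_matrix.median(axis=0)
    target = float(np.median(medians.to_numpy()))
    return log2_matrix.sub(medians - target, axis=1)


def normalize_cohort(cohort: CohortExpression,
                     params: NormalizationParams = NormalizationParams(),
                     sample_correction: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
                     ) -> CohortExpression:
    """Apply the full chain to a linear-scale cohort; returns a log2 cohort.

    ``sample_correction``, if given, is applied to the log2 matrix before
    median scaling (hook for intensity-dependent corrections).  Every step is
    recorded in the cohort's provenance log.
    """
    if cohort.scale != "linear":
        raise ValueError(f"cohort {cohort.name} is not on the linear scale")
    provenance = list(cohort.provenance)
    log2 = floor_and_log(cohort.matrix, params)
    provenance.append({"step": "floor_and_log", "floor": params.floor_value})
    if sample_correction is not None:
        log2 = sample_correction(log2)
        provenance.append({"step": "sample_correction",
                           "fn": getattr(sample_correction, "__name__", "custom")})
    if params.scaling == "per_sample_median":
        log2 = scale_to_median(log2)
        provenance.append({"step": "scale_to_median", "percentile": 50})
    return cohort.copy_with(matrix=log2, scale="log2", provenance=provenance)
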