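"""Outcome prediction from the map distribution inside a lesion.

The point prediction is the unweighted mean of the map's per-voxel
values over the covered voxels of the (normalized) contour under
prediction.  Predictions are left on the continuous scale (no rounding
to the ordinal grid); the error is the absolute difference between the
prediction and the actual outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .core import CaseRecord, ContourFile, GridMismatchError, StrokeMap

__all__ = ["PredictionResult", "UncoveredError", "extract_distribution", "predict_case"]


class UncoveredError(ValueError):
    """The contour has no voxel with defined map value - never silently 0."""


@dataclass
class PredictionResult:
    """Distribution characteristics of one map inside one contour.

    ``covered`` is False when no contour voxel carried a defined map
    value (after frequency thresholding); all statistics are then None.
    """

    parameter: str
    predicted_mean: Optional[float]
    sd: Optional[float]
    min: Optional[float]
    max: Optional[float]
    median: Optional[float]
    n_voxels_covered: int
    coverage_fraction: float
    covered: bool = True
    actual: Optional[float] = None
    abs_error: Optional[float] = None

    @classmethod
    def uncovered(cls, parameter: str, actual: Optional[float] = None) -> "PredictionResult":
        return cls(
            parameter=parameter,
            predicted_mean=None, sd=None, min=None, max=None, median=None,
            n_voxels_covered=0, coverage_fraction=0.0, covered=False,
            actual=actual, abs_error=None,
        )


def extract_distribution(
    psm: StrokeMap, contour: ContourFile, min_count: int = 0
) -> PredictionResult:
    """Statistics of the map values inside a contour.

    Voxels count as covered when the accumulated weight is positive and
    the contributor count is at least ``min_count`` (0 disables the
    frequency threshold).  Raises UncoveredError when nothing is
    covered.
    """
    if contour.space != psm.space:
        raise GridMismatchError("contour and map live on different grids")
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    idx = contour.flat_indices()
    w = psm.weight_map.reshape(-1)[idx]
    c = psm.count_map.reshape(-1)[idx]
    ok = (w > 0) & (c >= min_count)
    n = int(ok.sum())
    if n == 0:
        raise UncoveredError(
            f"contour {contour.case_id} is not covered by the {psm.parameter} map"
        )
    vals = psm.sum_map.reshape(-1)[idx][ok] / w[ok]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return PredictionResult(
        parameter=psm.parameter,
        predicted_mean=float(vals.sum() / n),
        sd=sd,
        min=float(vals.min()),
        max=float(vals.max()),
        median=float(np.median(vals)),
        n_voxels_covered=n,
        coverage_fraction=n / contour.volume_voxels,
    )


def predict_case(
    maps: Mapping[str, StrokeMap],
    contour: ContourFile,
    actuals: Optional[CaseRecord] = None,
    min_count: int = 0,
) -> list[PredictionResult]:
    """Predict every parameter with a map, filling errors where possible.

    Uncovered parameters yield an uncovered result without aborting the
    rest.
    """
    results = []
    for parameter, psm in maps.items():
        actual = actuals.value(parameter) if actuals is not None else None
        try:
            res = extract_distribution(psm, contour, min_count=min_count)
        except UncoveredError:
            results.append(PredictionResult.uncovered(parameter, actual=actual))
            continue
        res.actual = actual
        if actual is not None:
            res.abs_error = abs(res.predicted_mean - actual)
        results.append(res)
    return results
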