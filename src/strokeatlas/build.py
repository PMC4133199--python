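"""Case selection and voxel-wise weighted aggregation into stroke maps.

A map for parameter p under weight variant k accumulates, over each
contributing case i with value p_i and weight w_i, the quantities
w_i * p_i and w_i on every voxel of the case's atlas-space contour, plus
a contributor count.  The map value at a voxel is the accumulated
weighted sum divided by the accumulated weight; for variant 1 this is
exactly the mean over contributing cases.  Accumulators are kept so maps
over disjoint cohorts (variants 1-2 only) merge exactly.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    AtlasSpace,
    CaseRecord,
    ContourFile,
    GridMismatchError,
    SelectionSpec,
    StrokeMap,
    WeightContext,
    centroid_distance,
    overlap_volume,
)
from .weighting import compute_weight, weight_spec

__all__ = [
    "NoContributingCasesError",
    "select_cases",
    "weight_context",
    "build_psm",
    "build_frequency_map",
    "merge_psm",
]


class NoContributingCasesError(ValueError):
    """Selection and missing-value removal left no case to aggregate."""


def select_cases(
    cases: Sequence[CaseRecord], spec: SelectionSpec
) -> list[CaseRecord]:
    """Cases admitted by the selection spec, order preserved.

    A case missing a value for a *constrained* variable is excluded;
    unconstrained variables never exclude anyone.
    """
    return [c for c in cases if spec.admits(c)]


def weight_context(
    contour: ContourFile, predicted: Optional[ContourFile] = None
) -> WeightContext:
    """Build the weight inputs for one atlas-side contour.

    Overlap and centroid distance are computed in atlas space; both
    contours must live on the same grid.
    """
    if predicted is None:
        return WeightContext(v_psa=contour.volume_cm3)
    if predicted.space != contour.space:
        raise GridMismatchError("predicted contour is on a different grid")
    return WeightContext(
        v_psa=contour.volume_cm3,
        v_p=predicted.volume_cm3,
        v_o=overlap_volume(contour.mask, predicted.mask, contour.space),
        d=centroid_distance(contour.mask, predicted.mask, contour.space),
    )


def build_psm(
    cases: Sequence[CaseRecord],
    contours: Mapping[str, ContourFile],
    parameter: str,
    weight_id: int,
    selection: Optional[SelectionSpec] = None,
    predicted_contour: Optional[ContourFile] = None,
    space: Optional[AtlasSpace] = None,
) -> StrokeMap:
    """Aggregate a cohort into one stroke map.

    Cases are filtered by ``selection``; cases with a missing value of
    ``parameter`` are silently skipped and ``n_cases`` reflects actual
    contributors.  ``predicted_contour`` is required for the variants
    that depend on the case under prediction (ids >= 3).
    """
    selection = selection or SelectionSpec.all_cases()
    spec = weight_spec(weight_id)
    if spec.needs_predicted_case and predicted_contour is None:
        raise ValueError(
            f"weight {weight_id} requires the predicted case's contour"
        )

    selected = select_cases(cases, selection)
    contributors: list[tuple[CaseRecord, ContourFile, float]] = []
    for case in selected:
        value = case.value(parameter)
        if value is None:
            continue
        try:
            contour = contours[case.case_id]
        except KeyError:
            raise KeyError(f"no contour for case {case.case_id!r}") from None
        contributors.append((case, contour, value))
    if not contributors:
        raise NoContributingCasesError(
            f"no contributing cases for parameter {parameter!r} under {selection}"
        )

    space = space or contributors[0][1].space
    for _, contour, _ in contributors:
        if contour.space != space:
            raise GridMismatchError(
                f"contour {contour.case_id} is on a different grid"
            )

    shape = tuple(space.dims)
    sum_flat = np.zeros(space.n_voxels)
    weight_flat = np.zeros(space.n_voxels)
    count_flat = np.zeros(space.n_voxels, dtype=np.int32)
    for case, contour, value in contributors:
        ctx = weight_context(
            contour, predicted_contour if spec.needs_predicted_case else None
        )
        w = compute_weight(weight_id, ctx)
        idx = contour.flat_indices()
        sum_flat[idx] += w * value
        weight_flat[idx] += w
        count_flat[idx] += 1

    return StrokeMap(
        parameter=parameter,
        weight_id=weight_id,
        sum_map=sum_flat.reshape(shape),
        weight_map=weight_flat.reshape(shape),
        count_map=count_flat.reshape(shape),
        n_cases=len(contributors),
        selection=selection,
        space=space,
        case_ids=tuple(case.case_id for case, _, _ in contributors),
    )


def build_frequency_map(
    contours: Sequence[ContourFile] | Mapping[str, ContourFile],
    space: Optional[AtlasSpace] = None,
) -> np.ndarray:
    """Per-voxel count of contour files covering each voxel."""
    if isinstance(contours, Mapping):
        contours = list(contours.values())
    if not contours:
        if space is None:
            raise ValueError("space is required for an empty contour set")
        return np.zeros(space.dims, dtype=np.int32)
    space = space or contours[0].space
    freq = np.zeros(space.n_voxels, dtype=np.int32)
    for contour in contours:
        if contour.space != space:
            raise GridMismatchError(
                f"contour {contour.case_id} is on a different grid"
            )
        freq[contour.flat_indices()] += 1
    return freq.reshape(space.dims)


def merge_psm(a: StrokeMap, b: StrokeMap) -> StrokeMap:
    """Merge two maps built over disjoint cohorts by summing accumulators.

    Only the pre-computable variants (weight ids 1-2) merge; the others
    depend on the predicted case and cannot be combined after the fact.
    """
    if a.weight_id not in (1, 2) or b.weight_id not in (1, 2):
        raise ValueError(
            "only maps with weight ids 1-2 are pre-computable and mergeable"
        )
    if a.weight_id != b.weight_id:
        raise ValueError("weight ids differ")
    if a.parameter != b.parameter:
        raise ValueError("parameters differ")
    if a.selection != b.selection:
        raise ValueError("selection specs differ")
    if a.space != b.space:
        raise GridMismatchError("maps live on different grids")
    dup = set(a.case_ids) & set(b.case_ids)
    if dup:
        raise ValueError(f"contributing case sets are not disjoint: {sorted(dup)}")
    return StrokeMap(
        parameter=a.parameter,
        weight_id=a.weight_id,
        sum_map=a.sum_map + b.sum_map,
        weight_map=a.weight_map + b.weight_map,
        count_map=a.count_map + b.count_map,
        n_cases=a.n_cases + b.n_cases,
        selection=a.selection,
        space=a.space,
        case_ids=a.case_ids + b.case_ids,
    )
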