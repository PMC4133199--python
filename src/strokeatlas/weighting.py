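"""The eight map-building weight variants, as a pluggable registry.

Variant 1 is plain averaging (weight 1).  Variant 2 favours smaller
atlas-side contours.  Variants 3, 4 and 8 favour contours with a higher
overlap with the contour under prediction, variant 5 favours contours
whose centroid is closer, and variants 6-7 penalise the non-overlapping
remainder of the atlas-side / predicted contour respectively.  Variants
1-2 do not depend on the predicted case, so maps built with them can be
pre-computed and merged; variants 3-8 cannot.

Weights carry units (cm^-3 for the 1/v_psa family) before normalization;
the map's division by the summed weights cancels them, so no reference-
volume rescaling is applied.  User-defined variants may be registered
under ids >= 9.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

from .core import WeightContext

__all__ = ["WeightSpec", "compute_weight", "register_weight", "weight_spec", "BUILTIN_WEIGHT_IDS"]

BUILTIN_WEIGHT_IDS = tuple(range(1, 9))


@dataclass(frozen=True)
class WeightSpec:
    """A single weight variant: id, dependence flag, and formula."""

    weight_id: int
    needs_predicted_case: bool
    formula: Callable[[WeightContext], float]
    description: str = ""


def _w1(ctx: WeightContext) -> float:
    return 1.0


def _w2(ctx: WeightContext) -> float:
    return 1.0 / ctx.v_psa


def _w3(ctx: WeightContext) -> float:
    return ctx.v_o / ctx.v_psa + ctx.v_o / ctx.v_p


def _w4(ctx: WeightContext) -> float:
    return ctx.v_o / ctx.v_p


def _w5(ctx: WeightContext) -> float:
    return 1.0 / (1.0 + ctx.d)


def _w6(ctx: WeightContext) -> float:
    return (1.0 / ctx.v_psa) * (1.0 - (ctx.v_psa - ctx.v_o) / ctx.v_psa)


def _w7(ctx: WeightContext) -> float:
    return (1.0 / ctx.v_psa) * (1.0 - (ctx.v_p - ctx.v_o) / ctx.v_p)


def _w8(ctx: WeightContext) -> float:
    return (1.0 / ctx.v_psa) * (ctx.v_o / ctx.v_p)


_REGISTRY: Dict[int, WeightSpec] = {}


def register_weight(spec: WeightSpec) -> None:
    """Register a weight variant. Built-in ids 1-8 cannot be replaced."""
    if spec.weight_id in BUILTIN_WEIGHT_IDS and spec.weight_id in _REGISTRY:
        raise ValueError(f"built-in weight id {spec.weight_id} cannot be replaced")
    _REGISTRY[spec.weight_id] = spec


for _k, _fn, _needs, _desc in [
    (1, _w1, False, "plain averaging (no weighting)"),
    (2, _w2, False, "favour smaller atlas contours (1/v_psa)"),
    (3, _w3, True, "overlap fraction of both contours (v_o/v_psa + v_o/v_p)"),
    (4, _w4, True, "overlap fraction of the predicted contour (v_o/v_p)"),
    (5, _w5, True, "favour closer centroids (1/(1+d))"),
    (6, _w6, True, "size-weighted penalty on the non-overlapped atlas part"),
    (7, _w7, True, "size-weighted penalty on the non-overlapped predicted part"),
    (8, _w8, True, "size-weighted overlap fraction ((1/v_psa)(v_o/v_p))"),
]:
    register_weight(WeightSpec(_k, _needs, _fn, _desc))
del _k, _fn, _needs, _desc


def weight_spec(weight_id: int) -> WeightSpec:
    try:
        return _REGISTRY[weight_id]
    except KeyError:
        raise KeyError(f"unknown weight id {weight_id}") from None


def compute_weight(weight_id: int, ctx: WeightContext) -> float:
    """Evaluate weight variant ``weight_id`` on ``ctx``.

    Raises ValueError when the variant needs the predicted case but
    v_p / v_o / d are absent from the context.
    """
    spec = weight_spec(weight_id)
    if spec.needs_predicted_case:
        if ctx.v_p is None or ctx.v_o is None or ctx.d is None:
            raise ValueError(
                f"weight {weight_id} requires v_p, v_o and d in the context"
            )
    w = float(spec.formula(ctx))
    if w < 0:
        raise ValueError(f"weight {weight_id} evaluated to a negative value {w}")
    return w
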