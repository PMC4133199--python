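"""Leave-one-out experiment grid and summary statistics.

Each case is predicted from maps built over all remaining cases, for
every combination of weight variant and selection spec in the grid.  The
default grid crosses 8 weight variants with 4 infarct-volume ranges
(whole, <=8.0, <=25.9, <=70 cm^3) and 4 ranges each for NIHSS at
admission and at day 7 ([0-42], [0-5], [6-13], [14-42]), i.e. 512 cells.

``run_loo`` produces a long-format table (one row per case x parameter x
grid cell); the summary operations pool it by variant and selection
mode, compute error-reduction ratios, best selection variables,
pairwise variant t-tests and dichotomized ROC analyses.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .core import (
    AtlasSpace,
    CaseRecord,
    ContourFile,
    SelectionSpec,
    StrokeMap,
    OUTCOME_PARAMETERS,
)
from .weighting import BUILTIN_WEIGHT_IDS, compute_weight, weight_spec
from .core import WeightContext

__all__ = [
    "TABLE_COLUMNS",
    "SELECTION_MODES",
    "DICHOTOMIZATION_SCHEMES",
    "LOOWorkload",
    "AUCResult",
    "reference_volume_ranges",
    "reference_nihss_ranges",
    "reference_grid",
    "enumerate_grid",
    "plan_loo",
    "run_loo",
    "summarize_by_variant",
    "error_reduction_ratio",
    "best_selection_variables",
    "compare_variants",
    "dichotomized_auc",
    "selection_of_row",
]

TABLE_COLUMNS = [
    "case_id", "parameter", "weight_id",
    "vol_lo", "vol_hi", "nihssa_lo", "nihssa_hi", "nihss7_lo", "nihss7_hi",
    "predicted", "actual", "abs_error", "covered",
]

#: NIHSS thresholds 5 and 13 give four ranges (discharge home / rehab / nursing)
_NIHSS_RANGES = ((0, 42), (0, 5), (6, 13), (14, 42))
_VOLUME_THRESHOLDS = (8.0, 25.9, 70.0)


def reference_volume_ranges() -> list[tuple[float, float]]:
    """Whole range plus the three upper-threshold ranges (cm^3)."""
    return [(0.0, math.inf)] + [(0.0, t) for t in _VOLUME_THRESHOLDS]


def reference_nihss_ranges() -> list[tuple[int, int]]:
    return [tuple(r) for r in _NIHSS_RANGES]


def enumerate_grid(
    weights: Iterable[int],
    volume_ranges: Sequence[tuple[float, float]],
    nihssa_ranges: Sequence[tuple[int, int]],
    nihss7_ranges: Sequence[tuple[int, int]],
) -> list[tuple[int, SelectionSpec]]:
    """Cartesian product of the grid factors, deterministic order."""
    weights = list(weights)
    if not (weights and volume_ranges and nihssa_ranges and nihss7_ranges):
        raise ValueError("all factor lists must be nonempty")
    return [
        (k, SelectionSpec(volume_range=v, nihssa_range=na, nihss7_range=n7))
        for k, v, na, n7 in itertools.product(
            weights, volume_ranges, nihssa_ranges, nihss7_ranges
        )
    ]


def reference_grid() -> list[tuple[int, SelectionSpec]]:
    """The full 8 x 4 x 4 x 4 = 512-cell grid."""
    return enumerate_grid(
        BUILTIN_WEIGHT_IDS,
        reference_volume_ranges(),
        reference_nihss_ranges(),
        reference_nihss_ranges(),
    )


@dataclass(frozen=True)
class LOOWorkload:
    """Bookkeeping of a leave-one-out design: scheduled builds and the
    case-processing events they imply (each build processes all cases
    except the predicted one)."""

    n_cases: int
    n_parameters: int
    n_grid_cells: int
    n_psm_builds: int
    n_case_processings: int


def plan_loo(
    n_cases: int,
    parameters: Sequence[str],
    grid: Sequence[tuple[int, SelectionSpec]],
) -> LOOWorkload:
    """Count the work a leave-one-out run would schedule, by enumeration."""
    builds = 0
    processings = 0
    for _case in range(n_cases):
        for _param in parameters:
            for _cell in grid:
                builds += 1
                processings += n_cases - 1
    return LOOWorkload(
        n_cases=n_cases,
        n_parameters=len(parameters),
        n_grid_cells=len(grid),
        n_psm_builds=builds,
        n_case_processings=processings,
    )


def _membership(sorted_idx: np.ndarray, query: np.ndarray) -> np.ndarray:
    """query[i] in sorted_idx, vectorized."""
    pos = np.searchsorted(sorted_idx, query)
    pos_c = np.minimum(pos, len(sorted_idx) - 1)
    return (len(sorted_idx) > 0) & (sorted_idx[pos_c] == query) & (
        pos < len(sorted_idx)
    )


def run_loo(
    cases: Sequence[CaseRecord],
    contours: Mapping[str, ContourFile],
    parameters: Optional[Sequence[str]] = None,
    grid: Optional[Sequence[tuple[int, SelectionSpec]]] = None,
    min_count: int = 0,
    space: Optional[AtlasSpace] = None,
) -> pd.DataFrame:
    """Leave-one-out evaluation over the full grid.

    For each case c, parameter p and grid cell (k, sel): a map is built
    from every other case admitted by sel (with c's contour driving the
    weights for variants >= 3) and c is predicted from it.  Cells where
    no voxel of c's contour is covered - or where no case contributes -
    are recorded with ``covered=False``.

    The implementation aggregates with vectorized accumulator algebra
    but is numerically equivalent to composing ``build_psm`` and
    ``extract_distribution`` per cell.
    """
    if len(cases) < 2:
        raise ValueError("leave-one-out needs at least 2 cases")
    parameters = list(parameters) if parameters is not None else list(OUTCOME_PARAMETERS)
    grid = list(grid) if grid is not None else reference_grid()
    n = len(cases)
    space = space or contours[cases[0].case_id].space
    vsz_cm3 = space.voxel_volume_cm3

    idx_list = [contours[c.case_id].flat_indices() for c in cases]
    vols = np.array([contours[c.case_id].volume_cm3 for c in cases])
    cents = np.array([contours[c.case_id].centroid_mm() for c in cases])

    weight_ids = sorted({k for k, _ in grid})
    sel_list: list[SelectionSpec] = []
    sel_index: dict[SelectionSpec, int] = {}
    for _, sel in grid:
        if sel not in sel_index:
            sel_index[sel] = len(sel_list)
            sel_list.append(sel)
    admits = np.array(
        [[sel.admits(c) for c in cases] for sel in sel_list], dtype=bool
    )
    pvals = np.array(
        [[np.nan if c.value(p) is None else c.value(p) for c in cases]
         for p in parameters]
    )

    cell_weight = np.array([k for k, _ in grid])
    cell_sel = np.array([sel_index[sel] for _, sel in grid])

    rows: list[tuple] = []
    for j, case in enumerate(cases):
        idx_j = idx_list[j]
        vj = len(idx_j)
        cover = np.zeros((n, vj))
        overlap_vox = np.zeros(n)
        for i in range(n):
            if i == j:
                continue
            m = _membership(idx_list[i], idx_j)
            cover[i] = m
            overlap_vox[i] = m.sum()
        dist = np.linalg.norm(cents - cents[j], axis=1)

        w_table = np.zeros((len(weight_ids), n))
        for ki, k in enumerate(weight_ids):
            needs = weight_spec(k).needs_predicted_case
            for i in range(n):
                if i == j:
                    continue
                ctx = WeightContext(
                    v_psa=vols[i],
                    v_p=vols[j] if needs else None,
                    v_o=overlap_vox[i] * vsz_cm3 if needs else None,
                    d=dist[i] if needs else None,
                )
                w_table[ki, i] = compute_weight(k, ctx)
        w_of = {k: w_table[ki] for ki, k in enumerate(weight_ids)}

        for pi, parameter in enumerate(parameters):
            avail = ~np.isnan(pvals[pi])
            avail_j = avail.copy()
            avail_j[j] = False
            p_filled = np.where(avail_j, pvals[pi], 0.0)
            contrib = admits & avail_j  # (n_sel, n)
            cnt = contrib.astype(float) @ cover  # (n_sel, vj)

            coef_w = np.stack(
                [w_of[k] * contrib[s] for k, s in zip(cell_weight, cell_sel)]
            )
            coef_s = coef_w * p_filled
            wm = coef_w @ cover
            sm = coef_s @ cover

            actual = case.value(parameter)
            cnt_cells = cnt[cell_sel]
            ok = (wm > 0) & (cnt_cells >= min_count)
            n_ok = ok.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                vals = np.where(ok, sm / np.where(wm > 0, wm, 1.0), 0.0)
            means = np.divide(
                vals.sum(axis=1), n_ok,
                out=np.full(len(grid), np.nan), where=n_ok > 0,
            )
            for g, (k, sel) in enumerate(grid):
                covered = n_ok[g] > 0
                pred = float(means[g]) if covered else None
                err = (
                    abs(pred - actual)
                    if covered and actual is not None
                    else None
                )
                rows.append(
                    (
                        case.case_id, parameter, k,
                        sel.volume_range[0], sel.volume_range[1],
                        sel.nihssa_range[0], sel.nihssa_range[1],
                        sel.nihss7_range[0], sel.nihss7_range[1],
                        pred, actual, err, covered,
                    )
                )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def selection_of_row(row) -> SelectionSpec:
    """Rebuild the SelectionSpec encoded in a table row."""
    return SelectionSpec(
        volume_range=(row["vol_lo"], row["vol_hi"]),
        nihssa_range=(int(row["nihssa_lo"]), int(row["nihssa_hi"])),
        nihss7_range=(int(row["nihss7_lo"]), int(row["nihss7_hi"])),
    )


def _vol_full(t: pd.DataFrame) -> pd.Series:
    return (t["vol_lo"] <= 0) & np.isinf(t["vol_hi"])


def _nihssa_full(t: pd.DataFrame) -> pd.Series:
    return (t["nihssa_lo"] == 0) & (t["nihssa_hi"] == 42)


def _nihss7_full(t: pd.DataFrame) -> pd.Series:
    return (t["nihss7_lo"] == 0) & (t["nihss7_hi"] == 42)


#: selection modes -> predicate choosing which grid cells are pooled
SELECTION_MODES = {
    "all": lambda t: _vol_full(t) & _nihssa_full(t) & _nihss7_full(t),
    "volume": lambda t: _nihssa_full(t) & _nihss7_full(t),
    "nihssa": lambda t: _vol_full(t) & _nihss7_full(t),
    "volume_nihssa": lambda t: _nihss7_full(t),
    "volume_nihssa_nihss7": lambda t: pd.Series(True, index=t.index),
}


def _mode_pool(table: pd.DataFrame, selection_mode: str) -> pd.DataFrame:
    try:
        predicate = SELECTION_MODES[selection_mode]
    except KeyError:
        raise KeyError(
            f"unknown selection mode {selection_mode!r}; "
            f"choose from {sorted(SELECTION_MODES)}"
        ) from None
    pool = table[predicate(table) & table["covered"] & table["abs_error"].notna()]
    return pool


def summarize_by_variant(
    table: pd.DataFrame, selection_mode: str = "all"
) -> pd.DataFrame:
    """Mean +/- sample SD of the absolute error per weight variant.

    Errors are pooled across cases, parameters and the selection cells
    admitted by ``selection_mode``; uncovered rows are excluded.  A
    single-row pool reports SD 0 with n = 1.
    """
    pool = _mode_pool(table, selection_mode)
    if pool.empty:
        raise ValueError(f"no errors to pool for mode {selection_mode!r}")
    out = []
    for k, grp in pool.groupby("weight_id", sort=True):
        errs = grp["abs_error"].to_numpy(dtype=float)
        sd = float(np.std(errs, ddof=1)) if len(errs) > 1 else 0.0
        out.append({"weight_id": int(k), "mean": float(errs.mean()),
                    "sd": sd, "n": len(errs)})
    return pd.DataFrame(out).set_index("weight_id")


class UndefinedRatioError(ZeroDivisionError):
    """Baseline pool has zero mean error."""


def error_reduction_ratio(
    table: pd.DataFrame,
    constrained_mode: str,
    baseline_mode: str = "all",
    weight_id: Optional[int] = None,
) -> float:
    """Mean error under a constrained mode divided by the baseline mean."""
    cpool = _mode_pool(table, constrained_mode)
    bpool = _mode_pool(table, baseline_mode)
    if weight_id is not None:
        cpool = cpool[cpool["weight_id"] == weight_id]
        bpool = bpool[bpool["weight_id"] == weight_id]
    if cpool.empty or bpool.empty:
        raise ValueError("both pools must be nonempty")
    baseline = bpool["abs_error"].mean()
    if baseline == 0:
        raise UndefinedRatioError("baseline mean error is zero")
    return float(cpool["abs_error"].mean() / baseline)


def _range_widths(spec: SelectionSpec) -> tuple[float, float, float]:
    return (
        spec.volume_range[1] - spec.volume_range[0],
        spec.nihssa_range[1] - spec.nihssa_range[0],
        spec.nihss7_range[1] - spec.nihss7_range[0],
    )


def best_selection_variables(
    table: pd.DataFrame, actual_value: float
) -> tuple[SelectionSpec, float, float]:
    """Most frequent selection spec in the first-quartile error range.

    Among rows whose actual outcome equals ``actual_value``, rows with
    error <= the 25th percentile (linear interpolation, boundary ties
    included) are kept and the modal selection spec returned, together
    with that spec's mean +/- SD error over all rows with this actual
    value.  Frequency ties break toward the wider (more inclusive)
    ranges, then enumeration order.
    """
    pool = table[
        table["covered"]
        & table["abs_error"].notna()
        & (table["actual"] == actual_value)
    ]
    if len(pool) < 4:
        raise ValueError(
            f"need at least 4 scored rows with actual={actual_value}, "
            f"got {len(pool)}"
        )
    errs = pool["abs_error"].to_numpy(dtype=float)
    q25 = float(np.percentile(errs, 25))
    best_rows = pool[pool["abs_error"] <= q25]

    counts: dict[SelectionSpec, int] = {}
    first_seen: dict[SelectionSpec, int] = {}
    for order, (_, row) in enumerate(best_rows.iterrows()):
        spec = selection_of_row(row)
        counts[spec] = counts.get(spec, 0) + 1
        first_seen.setdefault(spec, order)
    winner = max(
        counts,
        key=lambda s: (counts[s], _range_widths(s), -first_seen[s]),
    )
    spec_rows = pool[
        (pool["vol_lo"] == winner.volume_range[0])
        & (pool["vol_hi"] == winner.volume_range[1])
        & (pool["nihssa_lo"] == winner.nihssa_range[0])
        & (pool["nihssa_hi"] == winner.nihssa_range[1])
        & (pool["nihss7_lo"] == winner.nihss7_range[0])
        & (pool["nihss7_hi"] == winner.nihss7_range[1])
    ]
    spec_errs = spec_rows["abs_error"].to_numpy(dtype=float)
    sd = float(np.std(spec_errs, ddof=1)) if len(spec_errs) > 1 else 0.0
    return winner, float(spec_errs.mean()), sd


def compare_variants(
    table: pd.DataFrame,
    selection_mode: str = "volume_nihssa_nihss7",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Pairwise two-sample t-test p-values between weight variants.

    Welch's unequal-variance test by default; ``equal_var=True`` gives
    the classic pooled test.  Degenerate pairs (both groups constant
    with equal means) report p = 1.
    """
    pool = _mode_pool(table, selection_mode)
    groups = {
        int(k): g["abs_error"].to_numpy(dtype=float)
        for k, g in pool.groupby("weight_id", sort=True)
    }
    ids = sorted(groups)
    for k in ids:
        if len(groups[k]) < 2:
            raise ValueError(f"variant {k} has fewer than 2 errors")
    p = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    for a, b in itertools.combinations(ids, 2):
        xa, xb = groups[a], groups[b]
        if xa.std() == 0 and xb.std() == 0:
            pv = 1.0 if xa.mean() == xb.mean() else 0.0
        else:
            pv = float(stats.ttest_ind(xa, xb, equal_var=equal_var).pvalue)
            if math.isnan(pv):
                pv = 1.0
        p.loc[a, b] = p.loc[b, a] = pv
    return p


#: scheme -> (positive = unfavourable predicate on actuals, score sign)
DICHOTOMIZATION_SCHEMES = {
    "mrs_0_2": (lambda a: a >= 3, +1.0),   # favourable 0-2 vs unfavourable 3-6
    "mrs_0_1": (lambda a: a >= 2, +1.0),   # excellent 0-1 vs 2-6
    "bi_0_45": (lambda a: a <= 45, -1.0),  # unfavourable BI 0-45 vs 46-100
}


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    scheme: str
    method: str


def _delong_ci(scores, labels, auc, alpha=0.05):
    # DeLong covariance via midrank placements
    pos = scores[labels]
    neg = scores[~labels]
    m, nn = len(pos), len(neg)
    all_s = np.concatenate([pos, neg])
    rk_all = stats.rankdata(all_s)
    rk_pos = stats.rankdata(pos)
    rk_neg = stats.rankdata(neg)
    v10 = (rk_all[:m] - rk_pos) / nn
    v01 = 1.0 - (rk_all[m:] - rk_neg) / m
    var_pos = np.var(v10, ddof=1) / m if m > 1 else 0.0
    var_neg = np.var(v01, ddof=1) / nn if nn > 1 else 0.0
    var = var_pos + var_neg
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    return max(auc - z * se, 0.0), min(auc + z * se, 1.0)


def dichotomized_auc(
    predicted: Sequence[float],
    actual: Sequence[float],
    scheme: str,
    n_boot: int = 2000,
    seed: int = 0,
    method: str = "bootstrap",
) -> AUCResult:
    """Area under the ROC of the continuous prediction as a score for
    the unfavourable class, with a 95% CI.

    ``method='bootstrap'`` (default) uses a seeded percentile bootstrap;
    ``method='delong'`` uses the DeLong asymptotic CI.
    """
    if scheme not in DICHOTOMIZATION_SCHEMES:
        raise KeyError(
            f"unknown scheme {scheme!r}; choose from {sorted(DICHOTOMIZATION_SCHEMES)}"
        )
    label_fn, sign = DICHOTOMIZATION_SCHEMES[scheme]
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be 1-D and the same length")
    labels = label_fn(actual)
    scores = sign * predicted
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present after dichotomizing")
    auc = float(roc_auc_score(labels, scores))

    if method == "delong":
        lo, hi = _delong_ci(scores, labels, auc)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            take = rng.integers(0, len(labels), size=len(labels))
            lb = labels[take]
            if lb.all() or not lb.any():
                continue
            boots.append(roc_auc_score(lb, scores[take]))
        if len(boots) < 10:
            raise ValueError("too few valid bootstrap resamples")
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return AUCResult(
        auc=auc, ci_low=float(lo), ci_high=float(hi),
        n_pos=n_pos, n_neg=n_neg, scheme=scheme, method=method,
    )
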