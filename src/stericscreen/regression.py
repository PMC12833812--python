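"""Selectivity-to-free-energy conversion and the univariate regression screen.

Observed enantioselectivity maps to the free-energy difference between the
two diastereomeric transition states,

    ddG = R T ln((1 + ee) / (1 - ee)),   R = 1.98720e-3 kcal/(mol K),

so all model errors are in kcal/mol. Each (dataset, descriptor family)
pair is screened by fitting ordinary least squares for every variant of
the family (radius / atom / ensemble-aggregation choices) and keeping the
single most robust model — the one with the largest leave-one-out Q² —
mirroring how a practitioner would absorb the arbitrariness of, e.g., the
probe-radius choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import (
    GAS_CONSTANT_KCAL,
    DescriptorTable,
    ReactionDataset,
    ReactionRecord,
    ValidationError,
    logger,
)


class DegeneratePredictorError(ValueError):
    """Constant descriptor column: no univariate slope is identifiable."""


def ee_to_ddg(ee: float, temperature: float) -> float:
    """Signed ee fraction -> ddG in kcal/mol at ``temperature`` (K).

    Strictly monotone in ee, odd in sign, and divergent as |ee| -> 1
    (which is why upstream ingestion clamps |ee| = 1 entries).
    """
    if not -1.0 < ee < 1.0:
        raise ValidationError(f"|ee| must be < 1, got {ee}")
    if temperature <= 0:
        raise ValidationError("temperature must be > 0 K")
    return GAS_CONSTANT_KCAL * temperature * math.log((1.0 + ee) / (1.0 - ee))


def ddg_to_ee(ddg: float, temperature: float) -> float:
    """Inverse of :func:`ee_to_ddg`: ee = tanh(ddG / (2 R T))."""
    if temperature <= 0:
        raise ValidationError("temperature must be > 0 K")
    return math.tanh(ddg / (2.0 * GAS_CONSTANT_KCAL * temperature))


def aggregate_catalyst_ddg(records: Sequence[ReactionRecord]) -> float:
    """Mean ddG over a catalyst's records (each converted at its own
    temperature) — the catalyst's average performance across the reported
    substrate combinations."""
    if not records:
        raise ValidationError("no records for catalyst")
    return float(np.mean([ee_to_ddg(r.ee, r.temperature) for r in records]))


def dataset_ddg(dataset: ReactionDataset) -> dict[str, float]:
    """catalyst_id -> average ddG (kcal/mol) for one dataset."""
    by_cat: dict[str, list[ReactionRecord]] = {}
    for rec in dataset.records:
        by_cat.setdefault(rec.catalyst_id, []).append(rec)
    return {cid: aggregate_catalyst_ddg(recs) for cid, recs in sorted(by_cat.items())}


# --------------------------------------------------------------------------
# univariate OLS with LOO Q²
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    """One univariate OLS fit of ddG on a descriptor variant.

    ``q2_loo`` = 1 - PRESS/TSS, with PRESS the sum of squared leave-one-out
    prediction errors; always <= R² for a non-degenerate fit and may be
    negative (worse than predicting the mean). ``p_slope`` is the two-sided
    t-test p-value for slope != 0 on n-2 degrees of freedom. ``degenerate``
    marks a constant-response fit where R²/p/Q² are undefined (NaN) and
    only the MAE is meaningful.
    """

    n: int
    slope: float
    intercept: float
    r_squared: float
    mae: float
    p_slope: float
    q2_loo: float
    descriptor_variant_id: str = ""
    degenerate: bool = False


def fit_univariate(
    x_values: Sequence[float],
    y_values: Sequence[float],
    descriptor_variant_id: str = "",
) -> RegressionResult:
    """OLS fit of y (ddG, kcal/mol) on one descriptor variant x.

    Leave-one-out predictions use the leverage identity
    e_(i) = e_i / (1 - h_ii), which reproduces explicit n-refit LOO exactly
    for OLS. Requires n >= 4 (two degrees of freedom for the slope t-test)
    and a non-constant predictor.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and equally long")
    n = x.size
    if n < 4:
        raise ValidationError(f"need n >= 4 catalysts for a screened fit, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in regression input")
    sxx = float(np.sum((x - x.mean()) ** 2))
    # treat float-noise-level variation as constant too: a predictor whose
    # spread is ~1e-10 of its magnitude yields a meaningless, ill-conditioned
    # slope rather than information
    x_scale = max(float(np.abs(x).max()), 1.0e-300)
    if sxx <= n * (1.0e-10 * x_scale) ** 2:
        raise DegeneratePredictorError(
            f"descriptor {descriptor_variant_id!r} is (numerically) constant "
            "across catalysts"
        )
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    mae = float(np.mean(np.abs(resid)))

    if tss == 0.0:
        return RegressionResult(
            n=n, slope=slope, intercept=intercept,
            r_squared=math.nan, mae=mae, p_slope=math.nan, q2_loo=math.nan,
            descriptor_variant_id=descriptor_variant_id, degenerate=True,
        )

    r_squared = 1.0 - sse / tss
    # two-sided t-test for slope; p bottoms out at tiny for exact fits
    df = n - 2
    se_slope = math.sqrt(max(sse, 0.0) / df / sxx)
    if se_slope == 0.0:
        p_slope = math.nextafter(0.0, 1.0)
    else:
        t_stat = slope / se_slope
        p_slope = float(2.0 * stats.t.sf(abs(t_stat), df))
        p_slope = max(p_slope, math.nextafter(0.0, 1.0))
    leverage = 1.0 / n + (x - x.mean()) ** 2 / sxx
    press = float(np.sum((resid / (1.0 - leverage)) ** 2))
    q2_loo = 1.0 - press / tss
    return RegressionResult(
        n=n, slope=slope, intercept=intercept,
        r_squared=r_squared, mae=mae, p_slope=p_slope, q2_loo=q2_loo,
        descriptor_variant_id=descriptor_variant_id,
    )


# --------------------------------------------------------------------------
# per-dataset screen
# --------------------------------------------------------------------------


@dataclass
class ScreenCell:
    """Screen outcome for one (dataset, descriptor family): the most robust
    variant (largest Q², ties broken by smaller MAE then lexicographic
    variant id) plus every variant fit for audit. ``missing`` marks a family
    with zero usable variants on this dataset."""

    dataset_id: str
    descriptor_family: str
    best: RegressionResult | None
    all_variants: list[RegressionResult] = field(default_factory=list)

    @property
    def missing(self) -> bool:
        return self.best is None


def _best_variant(fits: list[RegressionResult]) -> RegressionResult | None:
    usable = [f for f in fits if not f.degenerate and math.isfinite(f.q2_loo)]
    if not usable:
        return None
    return min(usable, key=lambda f: (-f.q2_loo, f.mae, f.descriptor_variant_id))


def screen_dataset(
    dataset: ReactionDataset,
    descriptor_table: DescriptorTable,
    families: Sequence[str] | None = None,
    min_n: int = 4,
) -> list[ScreenCell]:
    """Fit every descriptor variant against one dataset's ddG values and
    select the most robust model per family.

    Catalysts missing a value for a particular variant are dropped from
    that variant's fit only (pairwise deletion, per-variant n recorded); a
    family whose every variant is unusable yields a cell with
    ``missing=True`` rather than being silently dropped.
    """
    ddg = dataset_ddg(dataset)
    if families is None:
        families = descriptor_table.family_names
    cells: list[ScreenCell] = []
    for family in families:
        fits: list[RegressionResult] = []
        for variant in descriptor_table.variants_for_family(family):
            col = descriptor_table.values[variant]
            xs, ys = [], []
            for cid, y in ddg.items():
                if cid in col.index and math.isfinite(col[cid]):
                    xs.append(float(col[cid]))
                    ys.append(y)
            n_dropped = len(ddg) - len(xs)
            if n_dropped:
                logger.info(
                    "%s/%s: dropped %d catalysts lacking a value",
                    dataset.dataset_id, variant, n_dropped,
                )
            if len(xs) < min_n:
                continue
            try:
                fits.append(fit_univariate(xs, ys, descriptor_variant_id=variant))
            except DegeneratePredictorError:
                logger.info("%s/%s: constant predictor, skipped",
                            dataset.dataset_id, variant)
        cells.append(
            ScreenCell(
                dataset_id=dataset.dataset_id,
                descriptor_family=family,
                best=_best_variant(fits),
                all_variants=fits,
            )
        )
    return cells


def screen_collection(
    datasets: Sequence[ReactionDataset],
    descriptor_table: DescriptorTable,
    families: Sequence[str] | None = None,
    min_n: int = 4,
) -> list[ScreenCell]:
    """Screen every dataset; datasets below the usable-catalyst threshold
    are reported unscreenable (warning) and skipped."""
    cells: list[ScreenCell] = []
    for ds in datasets:
        if len(ds.catalyst_ids) < min_n:
            logger.warning("dataset %s has < %d catalysts; unscreenable",
                           ds.dataset_id, min_n)
            continue
        cells.extend(screen_dataset(ds, descriptor_table, families, min_n))
    return cells


def scores_frame(cells: Sequence[ScreenCell]):
    """Tidy table of every fit in the screen (the audit trail: one row per
    dataset x family x variant, with a ``selected`` flag)."""
    import pandas as pd

    rows = []
    for cell in cells:
        for fit in cell.all_variants:
            rows.append(
                {
                    "dataset_id": cell.dataset_id,
                    "family": cell.descriptor_family,
                    "variant": fit.descriptor_variant_id,
                    "n": fit.n,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "mae": fit.mae,
                    "p_slope": fit.p_slope,
                    "q2_loo": fit.q2_loo,
                    "selected": cell.best is not None
                    and fit.descriptor_variant_id == cell.best.descriptor_variant_id,
                }
            )
        if cell.missing:
            rows.append(
                {
                    "dataset_id": cell.dataset_id,
                    "family": cell.descriptor_family,
                    "variant": "<missing>",
                    "n": 0, "slope": math.nan, "intercept": math.nan,
                    "r_squared": math.nan, "mae": math.nan, "p_slope": math.nan,
                    "q2_loo": math.nan, "selected": False,
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["dataset_id", "family", "variant"], ignore_index=True
    )
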