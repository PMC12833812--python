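"""Cross-dataset meta-analysis of the univariate screen.

Aggregates selected (per-family best) models across many reaction
datasets: the proportion of datasets where a family gives a statistically
meaningful model at each confidence level, average R²/MAE, breakdowns by
structural-diversity class and by reaction class, a dummy mean-predictor
baseline, and a deterministic family ranking. "Meaningful with >95%
confidence" is operationalized as two-sided slope p < 0.05 on the selected
variant (p < 0.01 for 99%); for univariate OLS the slope t-test and the
model F-test coincide, so no distinction arises. No multiple-testing
correction is applied: confidence is reported per dataset, nominally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CatalystStructure, ReactionDataset, ValidationError, logger
from .regression import ScreenCell, dataset_ddg, scores_frame

#: Confidence grid: 90 / 95 / 99 % as slope-test alpha levels.
DEFAULT_ALPHAS = (0.10, 0.05, 0.01)


# --------------------------------------------------------------------------
# diversity classification
# --------------------------------------------------------------------------


def classify_diversity(
    dataset: ReactionDataset,
    catalysts: Mapping[str, CatalystStructure],
    threshold: int = 1,
    overrides: Mapping[str, str] | None = None,
) -> str:
    """Classify a dataset's structural diversity as ``limited`` or
    ``significant``.

    A catalyst "differs beyond the modular substituent" when its backbone
    or active-site class differs from the dataset's modal values. Datasets
    with ``threshold`` (default 1) or fewer such catalysts are ``limited``;
    more are ``significant``. The printed criterion is applied with judgment
    in practice, so a per-dataset override table is honored first.
    """
    if overrides and dataset.dataset_id in overrides:
        label = overrides[dataset.dataset_id]
        if label not in ("limited", "significant"):
            raise ValidationError(f"override label {label!r} invalid")
        return label
    scaffolds = []
    for cid in dataset.catalyst_ids:
        cat = catalysts.get(cid)
        if cat is None or cat.scaffold is None:
            raise ValidationError(
                f"dataset {dataset.dataset_id!r}: catalyst {cid!r} lacks scaffold "
                "labels; dataset unclassifiable"
            )
        scaffolds.append(cat.scaffold)
    backbones = [s.backbone_id for s in scaffolds]
    sites = [s.active_site_class for s in scaffolds]
    modal_backbone = max(sorted(set(backbones)), key=backbones.count)
    modal_site = max(sorted(set(sites)), key=sites.count)
    n_differing = sum(
        1
        for s in scaffolds
        if s.backbone_id != modal_backbone or s.active_site_class != modal_site
    )
    return "limited" if n_differing <= threshold else "significant"


# --------------------------------------------------------------------------
# aggregation over datasets
# --------------------------------------------------------------------------


def proportion_meaningful(cells: Sequence[ScreenCell], alpha: float) -> float:
    """Fraction of datasets whose selected model has slope p < alpha."""
    if not cells:
        raise ValidationError("no screen cells")
    hits = sum(
        1 for c in cells if c.best is not None and c.best.p_slope < alpha
    )
    return hits / len(cells)


@dataclass
class FamilySummary:
    family: str
    n_datasets: int
    proportion_significant: dict[float, float]
    avg_r_squared: float
    avg_mae: float
    by_group: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)


@dataclass
class MetaSummary:
    families: dict[str, FamilySummary]
    alphas: tuple[float, ...]
    dummy_baseline_mae: float | None = None


def category_averages(
    cells: Sequence[ScreenCell],
    grouping: Mapping[str, str],
) -> dict[str, dict[str, float]]:
    """Unweighted group means of selected-model R² and MAE.

    ``grouping`` maps dataset_id -> label (e.g., diversity or reaction
    class); every dataset must carry a label. Empty groups are omitted with
    a warning. Datasets whose cell is missing are skipped.
    """
    groups: dict[str, list[ScreenCell]] = {}
    for cell in cells:
        if cell.dataset_id not in grouping:
            raise ValidationError(f"dataset {cell.dataset_id!r} lacks a group label")
        groups.setdefault(grouping[cell.dataset_id], []).append(cell)
    out: dict[str, dict[str, float]] = {}
    for label in sorted(groups):
        usable = [c.best for c in groups[label] if c.best is not None]
        if not usable:
            logger.warning("group %r has no usable fits; omitted", label)
            continue
        out[label] = {
            "n_datasets": float(len(usable)),
            "avg_r_squared": float(np.mean([f.r_squared for f in usable])),
            "avg_mae": float(np.mean([f.mae for f in usable])),
        }
    return out


def dummy_baseline(datasets: Sequence[ReactionDataset]) -> float:
    """Average (across datasets) MAE of predicting every catalyst's ddG by
    the dataset mean — the floor any useful univariate model must beat."""
    if not datasets:
        raise ValidationError("no datasets")
    maes = []
    for ds in datasets:
        vals = np.array(list(dataset_ddg(ds).values()))
        maes.append(float(np.mean(np.abs(vals - vals.mean()))))
    return float(np.mean(maes))


def summarize(
    cells: Sequence[ScreenCell],
    datasets: Sequence[ReactionDataset] = (),
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    groupings: Mapping[str, Mapping[str, str]] | None = None,
) -> MetaSummary:
    """Build the full per-family meta-summary.

    ``groupings`` maps a grouping name (e.g., ``"diversity"``,
    ``"reaction_class"``) to a dataset_id -> label mapping; each produces a
    per-family breakdown of average R²/MAE.
    """
    by_family: dict[str, list[ScreenCell]] = {}
    for cell in cells:
        by_family.setdefault(cell.descriptor_family, []).append(cell)
    families: dict[str, FamilySummary] = {}
    for family in sorted(by_family):
        fam_cells = by_family[family]
        usable = [c.best for c in fam_cells if c.best is not None]
        props = {a: proportion_meaningful(fam_cells, a) for a in alphas}
        summary = FamilySummary(
            family=family,
            n_datasets=len(fam_cells),
            proportion_significant=props,
            avg_r_squared=float(np.mean([f.r_squared for f in usable]))
            if usable else math.nan,
            avg_mae=float(np.mean([f.mae for f in usable])) if usable else math.nan,
        )
        if groupings:
            for name, mapping in groupings.items():
                summary.by_group[name] = category_averages(fam_cells, mapping)
        families[family] = summary
    return MetaSummary(
        families=families,
        alphas=tuple(alphas),
        dummy_baseline_mae=dummy_baseline(datasets) if datasets else None,
    )


def rank_families(summary: MetaSummary, alpha: float | None = None) -> list[str]:
    """Family ranking: proportion significant at the strictest alpha
    (descending), then average R² (descending), then average MAE
    (ascending), then family name — fully deterministic."""
    if alpha is None:
        alpha = min(summary.alphas)

    def key(fam: str):
        s = summary.families[fam]
        r2 = s.avg_r_squared if math.isfinite(s.avg_r_squared) else -math.inf
        mae = s.avg_mae if math.isfinite(s.avg_mae) else math.inf
        return (-s.proportion_significant[alpha], -r2, mae, fam)

    return sorted(summary.families, key=key)


# --------------------------------------------------------------------------
# report generation
# --------------------------------------------------------------------------


def summary_frame(summary: MetaSummary) -> pd.DataFrame:
    rows = []
    for fam in sorted(summary.families):
        s = summary.families[fam]
        row = {
            "family": fam,
            "n_datasets": s.n_datasets,
            "avg_r_squared": s.avg_r_squared,
            "avg_mae": s.avg_mae,
        }
        for a in summary.alphas:
            row[f"prop_significant_alpha_{a:g}"] = s.proportion_significant[a]
        for gname, groups in s.by_group.items():
            for label, vals in groups.items():
                row[f"{gname}:{label}:avg_r_squared"] = vals["avg_r_squared"]
                row[f"{gname}:{label}:avg_mae"] = vals["avg_mae"]
        rows.append(row)
    return pd.DataFrame(rows)


def generate_report(
    summary: MetaSummary,
    cells: Sequence[ScreenCell],
    out_dir: str | Path,
    datasets: Sequence[ReactionDataset] = (),
    descriptor_table=None,
    descriptor_metadata: Mapping | None = None,
    run_params: Mapping | None = None,
) -> dict[str, list[str]]:
    """Write the screen outputs: the tidy scores CSV, the meta-summary CSV,
    per-dataset scatter plots for the top-ranked family (fitted line
    overlaid), and a run-metadata JSON recording every parameter.

    Returns the written file names keyed by kind. Re-running with identical
    inputs reproduces byte-identical CSVs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {"csv": [], "plots": [], "metadata": []}

    scores = scores_frame(cells)
    scores_path = out / "screen_scores.csv"
    scores.to_csv(scores_path, index=False, float_format="%.10g")
    written["csv"].append(scores_path.name)

    meta_path = out / "meta_summary.csv"
    summary_frame(summary).to_csv(meta_path, index=False, float_format="%.10g")
    written["csv"].append(meta_path.name)

    # plots: top-ranked family only, one per dataset, to bound output volume
    top = rank_families(summary)[0] if summary.families else None
    ds_lookup = {ds.dataset_id: ds for ds in datasets}
    if top is not None:
        from .regression import dataset_ddg as _ddg

        for cell in cells:
            if cell.descriptor_family != top or cell.best is None:
                continue
            ds = ds_lookup.get(cell.dataset_id)
            if ds is None:
                continue
            fig, ax = plt.subplots(figsize=(4, 3))
            ddg = _ddg(ds)
            fit = cell.best
            if descriptor_table is not None and (
                fit.descriptor_variant_id in descriptor_table.values.columns
            ):
                col = descriptor_table.values[fit.descriptor_variant_id]
                pairs = [
                    (float(col[cid]), y)
                    for cid, y in ddg.items()
                    if cid in col.index and math.isfinite(col[cid])
                ]
                xs = np.array([p[0] for p in pairs])
                ys = np.array([p[1] for p in pairs])
                ax.scatter(xs, ys, s=18)
                grid = np.linspace(xs.min(), xs.max(), 50)
                ax.plot(grid, fit.intercept + fit.slope * grid, lw=1)
                ax.set_xlabel(fit.descriptor_variant_id)
            else:
                ax.scatter(range(len(ddg)), list(ddg.values()), s=18)
                ax.set_xlabel("catalyst (sorted)")
            ax.set_title(
                f"{cell.dataset_id} | {fit.descriptor_variant_id}\n"
                f"R2={fit.r_squared:.2f} MAE={fit.mae:.2f} Q2={fit.q2_loo:.2f}"
            , fontsize=8)
            ax.set_ylabel("ddG (kcal/mol)")
            fig.tight_layout()
            name = f"fit_{cell.dataset_id}_{top}.png"
            fig.savefig(out / name, dpi=100)
            plt.close(fig)
            written["plots"].append(name)

    metadata = {
        "descriptor_metadata": dict(descriptor_metadata or {}),
        "run_params": dict(run_params or {}),
        "alphas": list(summary.alphas),
        "dummy_baseline_mae_kcal_mol": summary.dummy_baseline_mae,
        "family_ranking": rank_families(summary) if summary.families else [],
    }
    meta_json = out / "run_metadata.json"
    meta_json.write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    written["metadata"].append(meta_json.name)
    return written
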