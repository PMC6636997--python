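"""Cohort-level analysis: cortical layers, heterogeneity, correlations, tests.

Depths bin into cortical layers I (0-100 um), II/III (100-320 um),
IV (320-450 um) and V (450-600 um).  Aggregation is two-stage, mirroring
a per-animal design: capillary metrics are averaged within each
animal-layer cell (with spatial STD and CV across capillaries computed
per animal), then cell means are averaged across animals with SEM over
animals.

Temporal fluctuations come from 15-point series (0.6-s bins over a 9-s
acquisition) per capillary; Pearson correlations between metric series
are compared on the Fisher-z scale.  Group contrasts use one-way ANOVA
with Tukey HSD (Tukey-Kramer for unequal n) or two-sample t-tests, at
the 0.05 significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "LAYER_EDGES",
    "assign_layer",
    "assign_layers",
    "LayerSummary",
    "layer_aggregate",
    "fluctuation_series",
    "temporal_fluctuation",
    "pairwise_correlations",
    "GroupComparison",
    "compare_groups",
    "BranchGroupSummary",
    "branch_group_summary",
]

LAYER_EDGES = [(0.0, 100.0, "I"), (100.0, 320.0, "II/III"),
               (320.0, 450.0, "IV"), (450.0, 600.0, "V")]

FLUCTUATION_METRICS = ("flux_rbc_per_s", "speed_mm_per_s", "line_density", "mean_po2_mmhg")
CORRELATION_PAIRS = (
    ("flux_rbc_per_s", "mean_po2_mmhg"),
    ("speed_mm_per_s", "mean_po2_mmhg"),
    ("line_density", "mean_po2_mmhg"),
    ("flux_rbc_per_s", "speed_mm_per_s"),
    ("flux_rbc_per_s", "line_density"),
    ("speed_mm_per_s", "line_density"),
)


def assign_layer(depth_um: float) -> str:
    """Cortical layer for a depth [um]: [0,100) I, [100,320) II/III,
    [320,450) IV, [450,600] V.  Out-of-range depths raise."""
    if not 0 <= depth_um <= 600:
        raise ValueError(f"depth {depth_um} um outside the 0-600 um range")
    for lo, hi, label in LAYER_EDGES:
        if lo <= depth_um < hi:
            return label
    return "V"  # depth == 600: upper bin closed


def assign_layers(depths_um) -> pd.Series:
    return pd.Series([assign_layer(d) for d in np.asarray(depths_um, float)])


@dataclass
class LayerSummary:
    """Two-stage layer aggregates.

    animal_layer : one row per (animal, layer, metric) with the
        within-animal mean, spatial STD and CV across capillaries, and n.
    layer : one row per (layer, metric) with the cross-animal mean, SEM
        (NaN for a single animal), mean spatial STD/CV, and animal count.
    """

    animal_layer: pd.DataFrame
    layer: pd.DataFrame
    dropped_cells: list = field(default_factory=list)


def layer_aggregate(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    vessel_class: str | None = "capillary",
    layer_col: str = "layer",
) -> LayerSummary:
    """Aggregate per-segment metrics per animal-layer, then across animals.

    NaN metric values (rejected segmentations, unconverged fits) are
    excluded listwise per metric; animal-layer cells with no finite value
    for a metric are dropped from that metric's cross-animal mean and
    recorded in ``dropped_cells``.
    """
    df = table.copy()
    if vessel_class is not None:
        df = df[df["vessel_class"] == vessel_class]
    if layer_col not in df.columns:
        df[layer_col] = assign_layers(df["depth_um"]).values
    if metrics is None:
        metrics = [c for c in FLUCTUATION_METRICS if c in df.columns]

    rows, dropped = [], []
    for (animal, layer), cell in df.groupby(["animal_id", layer_col], sort=True):
        for m in metrics:
            vals = cell[m].dropna().to_numpy()
            if len(vals) == 0:
                dropped.append((animal, layer, m))
                continue
            mean = float(np.mean(vals))
            std = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
            rows.append({
                "animal_id": animal, "layer": layer, "metric": m,
                "mean": mean, "std": std,
                "cv": std / mean if mean != 0 else np.nan,
                "n_segments": len(vals),
            })
    animal_layer = pd.DataFrame(
        rows, columns=["animal_id", "layer", "metric", "mean", "std", "cv", "n_segments"]
    )

    out = []
    for (layer, m), cell in animal_layer.groupby(["layer", "metric"], sort=True):
        means = cell["mean"].to_numpy()
        n = len(means)
        out.append({
            "layer": layer, "metric": m,
            "mean": float(np.mean(means)),
            "sem": float(np.std(means, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "spatial_std": float(cell["std"].mean(skipna=True)),
            "spatial_cv": float(cell["cv"].mean(skipna=True)),
            "n_animals": n,
        })
    layer_df = pd.DataFrame(
        out, columns=["layer", "metric", "mean", "sem", "spatial_std", "spatial_cv", "n_animals"]
    )
    return LayerSummary(animal_layer, layer_df, dropped)


def fluctuation_series(
    trace,
    calib,
    n_bins: int = 15,
    smoothing_window: int = 3,
) -> pd.DataFrame:
    """Split a long acquisition into equal time bins and re-derive metrics.

    A 30000-cycle (9-s) trace yields 15 bins of 2000 cycles (0.6 s); each
    bin is independently segmented and fit, giving per-bin RBC flux,
    speed, line-density and Mean-PO2.  Bins whose segmentation is
    rejected carry NaN flow metrics.
    """
    from .segmentation import build_intensity_trace, compute_flow_metrics, segment_trace
    from .trace import PhotonTrace
    from .transients import pooled_po2

    per_bin = trace.n_cycles // n_bins
    if per_bin < 100:
        raise ValueError("trace too short for the requested number of bins")
    rows = []
    for b in range(n_bins):
        sub = PhotonTrace(
            trace.counts[b * per_bin : (b + 1) * per_bin],
            trace.bin_edges_us,
            trace.cycle_period_us,
            f"{trace.segment_id}#b{b}",
        )
        seg = segment_trace(build_intensity_trace(sub), smoothing_window=smoothing_window)
        flow = compute_flow_metrics(seg, build_intensity_trace(sub))
        mean = pooled_po2(sub, np.arange(sub.n_cycles), calib)
        rows.append({
            "bin": b,
            "flux_rbc_per_s": flow.flux_rbc_per_s if flow.valid else np.nan,
            "speed_mm_per_s": flow.speed_mm_per_s if flow.valid else np.nan,
            "line_density": flow.line_density if flow.valid else np.nan,
            "mean_po2_mmhg": mean.po2_mmhg if mean.valid else np.nan,
        })
    return pd.DataFrame(rows).set_index("bin")


def temporal_fluctuation(series: pd.DataFrame) -> pd.DataFrame:
    """STD and CV of each metric over the 15-point fluctuation series.

    Metrics with any missing bin are excluded (NaN row), matching the
    all-bins-present requirement of the 15-point design.
    """
    rows = []
    for m in series.columns:
        vals = series[m].to_numpy(dtype=float)
        if np.all(np.isfinite(vals)):
            std = float(np.std(vals, ddof=1))
            mean = float(np.mean(vals))
            rows.append({"metric": m, "mean": mean, "std": std,
                         "cv": std / mean if mean != 0 else np.nan})
        else:
            rows.append({"metric": m, "mean": np.nan, "std": np.nan, "cv": np.nan})
    return pd.DataFrame(rows).set_index("metric")


def pairwise_correlations(series: pd.DataFrame, pairs=CORRELATION_PAIRS) -> pd.DataFrame:
    """Pearson r and Fisher z = atanh(r) between metric fluctuation series.

    Pairs with missing bins or zero variance get NaN; |r| = 1 gives
    infinite z, flagged and excluded from downstream group tests.
    """
    rows = []
    for a, b in pairs:
        row = {"metric_a": a, "metric_b": b, "r": np.nan, "fisher_z": np.nan,
               "usable": False}
        if a in series.columns and b in series.columns:
            x = series[a].to_numpy(dtype=float)
            y = series[b].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.all() and np.std(x) > 0 and np.std(y) > 0:
                r = float(stats.pearsonr(x, y).statistic)
                with np.errstate(divide="ignore"):
                    z = float(np.arctanh(np.clip(r, -1.0, 1.0)))
                row.update(r=r, fisher_z=z, usable=bool(np.isfinite(z)))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """One-way ANOVA (+ Tukey HSD) or two-sample t-test across groups."""

    design: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, p_adj, significant
    alpha: float = 0.05

    @property
    def any_significant(self) -> bool:
        return bool(self.pairwise["significant"].any())


def compare_groups(values_by_group: dict, design: str = "anova_tukey",
                   alpha: float = 0.05) -> GroupComparison:
    """Compare metric distributions across named groups.

    ``anova_tukey``: one-way ANOVA F test plus Tukey HSD adjusted
    pairwise comparisons (Tukey-Kramer for unequal group sizes).
    ``t_test``: two-sample (Welch) t-test, exactly two groups.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    groups = {k: v[np.isfinite(v)] for k, v in groups.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")

    if design == "t_test":
        if len(groups) != 2:
            raise ValueError("t_test design requires exactly two groups")
        (ka, va), (kb, vb) = groups.items()
        res = stats.ttest_ind(va, vb, equal_var=False)
        pairwise = pd.DataFrame([{
            "group_a": ka, "group_b": kb, "p_adj": float(res.pvalue),
            "significant": bool(res.pvalue < alpha),
        }])
        return GroupComparison(design, float(res.statistic), float(res.pvalue),
                               pairwise, alpha)

    if design != "anova_tukey":
        raise ValueError(f"unknown design {design!r}")
    f_stat, p = stats.f_oneway(*groups.values())
    data = np.concatenate(list(groups.values()))
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    tuk = pairwise_tukeyhsd(data, labels, alpha=alpha)
    summary = tuk.summary().data
    pairwise = pd.DataFrame(
        [{"group_a": row[0], "group_b": row[1], "p_adj": float(row[3]),
          "significant": bool(row[6])} for row in summary[1:]]
    )
    return GroupComparison(design, float(f_stat), float(p), pairwise, alpha)


@dataclass
class BranchGroupSummary:
    """Upstream (A1-A3) vs downstream (V1-V3) capillary contrast."""

    group_stats: pd.DataFrame   # group x metric: mean, sem, n
    tests: pd.DataFrame         # metric, t, p, significant
    slopes: pd.DataFrame        # group, response, slope, intercept, r_squared
    warning: str | None = None


def branch_group_summary(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    max_depth_um: float = 300.0,
    alpha: float = 0.05,
) -> BranchGroupSummary:
    """Contrast branch-ordered capillaries above ``max_depth_um``.

    Capillaries with assigned branch orders are pooled into upstream
    (A1-A3) and downstream (V1-V3) groups; per-metric means +- SEM and
    Welch t-tests are reported, along with OLS regressions of Mean-PO2
    and SO2 on RBC flux within each group (the slope measures how
    strongly local oxygenation tracks local flux).
    """
    if metrics is None:
        metrics = [c for c in ("mean_po2_mmhg", "rbc_po2_mmhg", "so2", "eat_mmhg",
                               "flux_rbc_per_s", "speed_mm_per_s", "line_density")
                   if c in table.columns]
    df = table[(table.get("vessel_class", "capillary") == "capillary")
               & (table["depth_um"] <= max_depth_um)].copy()
    order = df.get("branch_order", pd.Series("unassigned", index=df.index)).astype(str)
    df["branch_group"] = np.where(
        order.str.startswith("A"), "A1-A3",
        np.where(order.str.startswith("V"), "V1-V3", "unassigned"),
    )
    grouped = df[df["branch_group"] != "unassigned"]
    if grouped.empty:
        empty = pd.DataFrame()
        return BranchGroupSummary(empty, empty, empty,
                                  warning="no branch orders assigned")

    stat_rows, test_rows, slope_rows = [], [], []
    for m in metrics:
        for g, cell in grouped.groupby("branch_group"):
            vals = cell[m].dropna().to_numpy()
            stat_rows.append({
                "group": g, "metric": m,
                "mean": float(np.mean(vals)) if len(vals) else np.nan,
                "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                "n": len(vals),
            })
        a = grouped.loc[grouped["branch_group"] == "A1-A3", m].dropna()
        v = grouped.loc[grouped["branch_group"] == "V1-V3", m].dropna()
        if len(a) > 1 and len(v) > 1:
            res = stats.ttest_ind(a, v, equal_var=False)
            test_rows.append({"metric": m, "t": float(res.statistic),
                              "p": float(res.pvalue),
                              "significant": bool(res.pvalue < alpha)})
    for g, cell in grouped.groupby("branch_group"):
        for response in ("mean_po2_mmhg", "so2"):
            if response not in cell.columns or "flux_rbc_per_s" not in cell.columns:
                continue
            sub = cell[["flux_rbc_per_s", response]].dropna()
            if len(sub) < 3 or sub["flux_rbc_per_s"].std() == 0:
                continue
            res = stats.linregress(sub["flux_rbc_per_s"], sub[response])
            slope_rows.append({
                "group": g, "response": response,
                "slope": float(res.slope), "intercept": float(res.intercept),
                "r_squared": float(res.rvalue**2),
            })
    return BranchGroupSummary(
        pd.DataFrame(stat_rows), pd.DataFrame(test_rows), pd.DataFrame(slope_rows)
    )
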