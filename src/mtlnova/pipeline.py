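"""Full study orchestration.

Runs, in order: classifiability filtering, traffic-light profiling,
hyper-palatability classification, per-group nutrient summaries
(median/IQR with Kruskal-Wallis + Dunn/Bonferroni), per-nutrient light
distributions with chi-square tests, binary any-red / any-green logistic
models, ordinal (proportional-odds) models of red counts, green counts
and the 8-level MTL score with PCI+PF pooling, the sensitivity battery
(median-split binary models, linear score models), the no-red and
no-red-plus-two-green subgroup analyses, and hyper-palatable food
proportions among foods. Everything is deterministic given the inputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .databank import Databank, FilterResult, filter_classifiable, read_databank
from .fopl import ThresholdConfig, default_thresholds, profile_databank, NUTRIENTS
from .hpf import DEFAULT_FACTORS, EnergyFactors, classify_databank

__all__ = [
    "AnalysisConfig",
    "StudyReport",
    "run_study",
    "subgroup_no_red",
    "subgroup_no_red_two_green",
    "hpf_proportions",
]

#: nutrient summary columns: (label, databank column)
_SUMMARY_NUTRIENTS = (
    ("fat", "fat_g"),
    ("satfat", "satfat_g"),
    ("sugar", "sugar_g"),
    ("salt", "salt_g"),
    ("energy_kcal", "energy_kcal"),
    ("energy_density_kcal_per_g", "energy_density"),
    ("protein", "protein_g"),
    ("fibre", "fibre_g"),
    ("carb", "carb_g"),
    ("water", "water_g"),
)

_GROUP_ORDER = ("MPF", "PCI", "PF", "UPF")


@dataclass(frozen=True)
class AnalysisConfig:
    """Study configuration.

    ``pooled_groups`` are merged (as ``pool_label``) for the ordinal
    analyses and the binary any-green model, where sparse categories make
    separate estimates unstable.
    """

    thresholds: ThresholdConfig | None = None
    reference: str = "MPF"
    pooled_groups: tuple[str, ...] = ("PCI", "PF")
    pool_label: str = "PCI+PF"
    energy_factors: EnergyFactors = DEFAULT_FACTORS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference not in _GROUP_ORDER:
            raise ValueError(f"reference must be one of {_GROUP_ORDER}")
        unknown = set(self.pooled_groups) - set(_GROUP_ORDER)
        if unknown:
            raise ValueError(f"pooled groups not NOVA groups: {unknown}")

    def resolved_thresholds(self) -> ThresholdConfig:
        return self.thresholds or default_thresholds()


@dataclass
class StudyReport:
    """All study tables as tidy DataFrames plus a provenance block."""

    group_counts: pd.DataFrame
    removal_report: dict[str, int]
    nutrient_summary: pd.DataFrame
    nutrient_tests: pd.DataFrame
    light_distribution: pd.DataFrame
    light_tests: pd.DataFrame
    red_green_counts: pd.DataFrame
    binary_or: pd.DataFrame
    ordinal_or: pd.DataFrame
    sensitivity_median_split: pd.DataFrame
    sensitivity_linear: pd.DataFrame
    subgroup_no_red: pd.DataFrame
    subgroup_no_red_tests: pd.DataFrame
    subgroup_no_red_two_green: pd.DataFrame
    subgroup_no_red_two_green_tests: pd.DataFrame
    hpf_proportions: pd.DataFrame
    hpf_tests: pd.DataFrame
    provenance: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            name: value
            for name, value in vars(self).items()
            if isinstance(value, pd.DataFrame)
        }

    def write(self, outdir) -> None:
        """Write every table as CSV; reruns are byte-identical."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables().items():
            table.to_csv(outdir / f"{name}.csv", index=False,
                         float_format="%.6f")
        meta = {"removal_report": self.removal_report,
                "provenance": self.provenance}
        (outdir / "provenance.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )


def _merged_frame(databank: Databank, cfg: AnalysisConfig) -> pd.DataFrame:
    """Items + traffic-light profile + HPF flags, one row per item."""
    items = databank.to_frame()
    profiles = profile_databank(databank, cfg.resolved_thresholds())
    hpf = classify_databank(databank, cfg.energy_factors).drop(
        columns=["nova_group"]
    )
    merged = items.merge(
        profiles.drop(columns=["nova_group", "is_drink"]), on="item_id"
    ).merge(hpf, on="item_id")
    merged["is_drink"] = merged["is_drink"].astype(bool)
    merged["energy_density"] = merged["energy_kcal"] / 100.0
    return merged


def _pooled(series: pd.Series, cfg: AnalysisConfig) -> pd.Series:
    return series.replace({g: cfg.pool_label for g in cfg.pooled_groups})


def _group_values(frame: pd.DataFrame, column: str):
    """Non-null values per NOVA group, in fixed group order."""
    groups, labels = [], []
    for g in _GROUP_ORDER:
        vals = frame.loc[frame["nova_group"] == g, column].dropna()
        if len(vals):
            groups.append(vals.to_numpy(dtype=float))
            labels.append(g)
    return groups, labels


def _nutrient_summary(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    summary_rows, test_rows = [], []
    for label, column in _SUMMARY_NUTRIENTS:
        if frame[column].notna().sum() == 0:
            continue
        all_vals = frame[column].dropna().to_numpy(dtype=float)
        med, q1, q3 = stats.median_iqr(all_vals)
        summary_rows.append(
            {"nutrient": label, "nova_group": "ALL", "n": len(all_vals),
             "median": med, "q1": q1, "q3": q3}
        )
        groups, labels = _group_values(frame, column)
        for g_label, vals in zip(labels, groups):
            med, q1, q3 = stats.median_iqr(vals)
            summary_rows.append(
                {"nutrient": label, "nova_group": g_label, "n": len(vals),
                 "median": med, "q1": q1, "q3": q3}
            )
        if len(groups) >= 2:
            kw = stats.kruskal_wallis(groups, labels)
            test_rows.append(
                {"nutrient": label, "statistic": kw.statistic, "df": kw.df,
                 "p_value": kw.p_value}
            )
            for a, b, p_adj in kw.pairwise:
                test_rows.append(
                    {"nutrient": label, "statistic": np.nan, "df": np.nan,
                     "p_value": p_adj, "contrast": f"{a} vs {b}"}
                )
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


def _light_tables(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    dist_rows, test_rows = [], []
    for nutrient in NUTRIENTS:
        col = f"light_{nutrient}"
        counts = (
            frame.groupby(["nova_group", col], observed=True)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=["green", "amber", "red"], fill_value=0)
            .reindex(_GROUP_ORDER, fill_value=0)
        )
        total = counts.to_numpy().sum()
        for g in counts.index:
            for light in counts.columns:
                n = int(counts.loc[g, light])
                dist_rows.append(
                    {"nutrient": nutrient, "nova_group": g, "light": light,
                     "n": n}
                )
        table = counts.loc[counts.sum(axis=1) > 0]
        table = table.loc[:, table.sum(axis=0) > 0]
        if table.shape[0] >= 2 and table.shape[1] >= 2:
            res = stats.chi_square_independence(table.to_numpy())
            test_rows.append(
                {"nutrient": nutrient, "statistic": res.statistic,
                 "df": res.df, "p_value": res.p_value}
            )
    dist = pd.DataFrame(dist_rows)
    per_nutrient_totals = dist.groupby("nutrient")["n"].transform("sum")
    dist["pct"] = (100 * dist["n"] / per_nutrient_totals).round(1)
    return dist, pd.DataFrame(test_rows)


def _or_rows(results, analysis: str) -> list[dict]:
    return [
        {"analysis": analysis, "contrast": r.contrast, "or": r.estimate,
         "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value,
         "method": r.method, "corrected": r.corrected}
        for r in results
    ]


def run_study(source, cfg: AnalysisConfig | None = None) -> StudyReport:
    """Execute the full study on a databank (object or CSV path)."""
    cfg = cfg or AnalysisConfig()
    databank = source if isinstance(source, Databank) else read_databank(source)
    if len(databank) == 0:
        raise ValueError("databank is empty; nothing to analyse")
    filtered: FilterResult = filter_classifiable(databank)
    if len(filtered.databank) == 0:
        raise ValueError("no classifiable items after filtering")
    frame = _merged_frame(filtered.databank, cfg)
    ref = cfg.reference

    group_counts = (
        frame.groupby("nova_group", observed=True)
        .agg(n=("item_id", "size"), n_drinks=("is_drink", "sum"))
        .reindex(_GROUP_ORDER, fill_value=0)
        .reset_index()
    )
    group_counts["pct"] = (100 * group_counts["n"] / len(frame)).round(1)

    nutrient_summary, nutrient_tests = _nutrient_summary(frame)
    light_distribution, light_tests = _light_tables(frame)

    # red / green count distributions per group
    rg_rows = []
    for measure in ("n_red", "n_green"):
        counts = (
            frame.groupby(["nova_group", measure], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
        for _, row in counts.iterrows():
            rg_rows.append(
                {"measure": measure, "nova_group": row["nova_group"],
                 "count": int(row[measure]), "n": int(row["n"])}
            )
    red_green_counts = pd.DataFrame(rg_rows)

    # binary models: any-red unpooled, any-green pooled
    group = frame["nova_group"]
    or_rows = _or_rows(
        stats.binary_logistic(group, frame["any_red"], ref), "any_red"
    )
    pooled = _pooled(group, cfg)
    or_rows += _or_rows(
        stats.binary_logistic(pooled, frame["any_green"], ref), "any_green"
    )
    binary_or = pd.DataFrame(or_rows)

    # ordinal models, PCI+PF pooled
    ord_rows = []
    for analysis, outcome in (
        ("n_red_ordinal", frame["n_red"]),
        ("n_green_ordinal", frame["n_green"]),
        ("mtl_ordinal8", frame["mtl_ordinal8"]),
    ):
        ord_rows += _or_rows(
            stats.proportional_odds(pooled, outcome, ref), analysis
        )
    ordinal_or = pd.DataFrame(ord_rows)

    # sensitivity battery
    ms_rows = []
    for label, column in _SUMMARY_NUTRIENTS[:5]:
        values = frame[column]
        if values.notna().all():
            ms_rows += _or_rows(
                stats.median_split_logistic(group, values, ref),
                f"above_median_{label}",
            )
    ms_rows += _or_rows(
        stats.median_split_logistic(pooled, frame["mtl_continuous"], ref),
        "above_median_mtl_score",
    )
    sensitivity_median_split = pd.DataFrame(ms_rows)

    lin_rows = []
    for analysis, outcome in (
        ("n_red_linear", frame["n_red"]),
        ("n_green_linear", frame["n_green"]),
        ("mtl_continuous_linear", frame["mtl_continuous"]),
    ):
        for r in stats.linear_score_model(pooled, outcome, ref):
            lin_rows.append(
                {"analysis": analysis, "contrast": r.contrast,
                 "mean_diff": r.estimate, "ci_low": r.ci_low,
                 "ci_high": r.ci_high, "p_value": r.p_value}
            )
    sensitivity_linear = pd.DataFrame(lin_rows)

    # subgroup analyses
    sub_nr, sub_nr_tests = _subgroup_tables(frame, frame["n_red"] == 0, ref)
    sub_nr2g, sub_nr2g_tests = _subgroup_tables(
        frame, (frame["n_red"] == 0) & (frame["n_green"] >= 2), ref
    )

    hpf_prop, hpf_tests = _hpf_tables(frame, ref)

    provenance = {
        "n_input": len(databank),
        "n_classifiable": len(frame),
        "thresholds": cfg.resolved_thresholds().name,
        "reference": ref,
        "pooled_groups": list(cfg.pooled_groups),
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            repr((cfg.reference, cfg.pooled_groups, cfg.seed)).encode()
        ).hexdigest()[:16],
    }
    return StudyReport(
        group_counts=group_counts,
        removal_report=filtered.removed,
        nutrient_summary=nutrient_summary,
        nutrient_tests=nutrient_tests,
        light_distribution=light_distribution,
        light_tests=light_tests,
        red_green_counts=red_green_counts,
        binary_or=binary_or,
        ordinal_or=ordinal_or,
        sensitivity_median_split=sensitivity_median_split,
        sensitivity_linear=sensitivity_linear,
        subgroup_no_red=sub_nr,
        subgroup_no_red_tests=sub_nr_tests,
        subgroup_no_red_two_green=sub_nr2g,
        subgroup_no_red_two_green_tests=sub_nr2g_tests,
        hpf_proportions=hpf_prop,
        hpf_tests=hpf_tests,
        provenance=provenance,
    )


def subgroup_no_red(frame: pd.DataFrame) -> pd.DataFrame:
    """Items with no red light ('healthy' under red-avoidance behaviour)."""
    return frame.loc[frame["n_red"] == 0]


def subgroup_no_red_two_green(frame: pd.DataFrame) -> pd.DataFrame:
    """Items with no red and at least two green lights."""
    return frame.loc[(frame["n_red"] == 0) & (frame["n_green"] >= 2)]


def _subgroup_tables(
    frame: pd.DataFrame, mask: pd.Series, ref: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Composition and nutrient comparisons for a 'healthy' subset.

    Within-UPF comparisons (in vs out of the subset) use Mann-Whitney;
    across-group comparisons among subset items use Kruskal-Wallis.
    """
    subset = frame.loc[mask]
    comp_rows = []
    n_sub = len(subset)
    for g in _GROUP_ORDER:
        n_g = int((subset["nova_group"] == g).sum())
        comp_rows.append(
            {"nova_group": g, "n": n_g,
             "pct_of_subgroup": round(100 * n_g / n_sub, 1) if n_sub else 0.0}
        )
    comp_rows.append(
        {"nova_group": "ALL", "n": n_sub,
         "pct_of_subgroup": round(100 * n_sub / len(frame), 1)}
    )
    composition = pd.DataFrame(comp_rows)

    test_rows = []
    if n_sub == 0:
        warnings.warn("empty subgroup; analyses skipped", stacklevel=2)
        return composition, pd.DataFrame(test_rows)
    upf_in = subset.loc[subset["nova_group"] == "UPF"]
    upf_out = frame.loc[(frame["nova_group"] == "UPF") & ~mask]
    for label, column in _SUMMARY_NUTRIENTS:
        x = upf_in[column].dropna().to_numpy(dtype=float)
        y = upf_out[column].dropna().to_numpy(dtype=float)
        if len(x) and len(y):
            u, p = stats.mann_whitney(x, y)
            med_in, q1_in, q3_in = stats.median_iqr(x)
            med_out, _, _ = stats.median_iqr(y)
            test_rows.append(
                {"analysis": "upf_in_vs_out", "nutrient": label,
                 "statistic": u, "p_value": p,
                 "median_in": med_in, "median_out": med_out}
            )
        groups, labels = _group_values(subset, column)
        if len(groups) >= 2:
            kw = stats.kruskal_wallis(groups, labels)
            med_ref = med_upf = np.nan
            for g_label, vals in zip(labels, groups):
                med = stats.median_iqr(vals)[0]
                if g_label == ref:
                    med_ref = med
                if g_label == "UPF":
                    med_upf = med
            test_rows.append(
                {"analysis": "across_groups_within_subgroup",
                 "nutrient": label, "statistic": kw.statistic,
                 "p_value": kw.p_value, "median_in": med_upf,
                 "median_out": med_ref}
            )
    return composition, pd.DataFrame(test_rows)


def _hpf_tables(
    frame: pd.DataFrame, ref: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hyper-palatable proportions among foods, overall and 'healthy'."""
    foods = frame.loc[~frame["is_drink"]]
    if len(foods) == 0:
        raise ValueError("no food items; HPF analysis undefined")
    subsets = {
        "all_foods": foods,
        "healthy_foods": foods.loc[foods["n_red"] == 0],
    }
    flags = ("cluster_fat_na", "cluster_fat_sugar", "cluster_carb_na",
             "any_hpf")
    prop_rows, test_rows = [], []
    for subset_name, sub in subsets.items():
        for flag in flags:
            total_flag = int(sub[flag].sum())
            for g in (*_GROUP_ORDER, "ALL"):
                sel = sub if g == "ALL" else sub.loc[sub["nova_group"] == g]
                n = len(sel)
                k = int(sel[flag].sum())
                prop_rows.append(
                    {"subset": subset_name, "cluster": flag, "nova_group": g,
                     "n_foods": n, "n_hpf": k,
                     "pct_hpf": round(100 * k / n, 1) if n else 0.0,
                     "pct_of_all_hpf": round(100 * k / total_flag, 1)
                     if total_flag else 0.0}
                )
            # chi-square UPF vs reference group
            upf = sub.loc[sub["nova_group"] == "UPF", flag]
            mpf = sub.loc[sub["nova_group"] == ref, flag]
            table = np.array(
                [[upf.sum(), len(upf) - upf.sum()],
                 [mpf.sum(), len(mpf) - mpf.sum()]],
                dtype=float,
            )
            if table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
                res = stats.chi_square_independence(table)
                test_rows.append(
                    {"subset": subset_name, "cluster": flag,
                     "contrast": f"UPF vs {ref}", "statistic": res.statistic,
                     "df": res.df, "p_value": res.p_value}
                )
    return pd.DataFrame(prop_rows), pd.DataFrame(test_rows)


def hpf_proportions(
    frame: pd.DataFrame, subset: str = "all_foods", reference: str = "MPF"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standalone HPF proportion table + chi-square tests for one subset."""
    if subset not in ("all_foods", "healthy_foods"):
        raise ValueError(f"unknown subset {subset!r}")
    prop, tests = _hpf_tables(frame, reference)
    return (
        prop.loc[prop["subset"] == subset].reset_index(drop=True),
        tests.loc[tests["subset"] == subset].reset_index(drop=True),
    )
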