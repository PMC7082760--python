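"""Replicated cross-validation protocol and group comparisons.

The evaluation protocol runs, per genomic aberration and per racial group,
R replications of k-fold cross-validation (default 10 x 3-fold).  In each
fold the non-test portion is split ~70/30 into training and validation sets,
giving ~47/20/33% of the group overall; pooling the k test folds of one
replication covers every patient exactly once, so each replication yields
one AICE/RMSE value per (race, grade) cell.  Replicate vectors from two
racial groups are compared with a two-sided paired t-test (paired by
replication index) at alpha = 0.05, with a 95% CI of the mean difference.

Estimated Gleason Scores under the intervention arm are additionally mapped
to genomic risk scores (GRS) in [0, 1] by a configurable monotone mapping;
the default is a logistic stand-in centered at GS 7.5, NOT the published
Mahal/Spratt risk model (whose coefficients users may supply instead).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data import CohortTable, GRADE_LABELS, schema_for_aberration
from .metrics import (
    CounterfactualEstimates,
    GroupMetrics,
    aice,
    mean_ice,
    rmse,
)
from .model import DLVMConfig, fit_dlvm, infer_counterfactual

__all__ = [
    "CVPlan",
    "ComparisonResult",
    "make_cv_plan",
    "run_aberration_experiment",
    "paired_t_test",
    "map_gs_to_grs",
    "compare_races",
    "summarize_experiment",
]


@dataclass
class CVPlan:
    """Replicated stratified cross-validation design."""

    n_replications: int = 10
    n_folds: int = 3
    train_fraction: float = 0.47
    valid_fraction: float = 0.20
    test_fraction: float = 0.33
    stratify_by: str = "grade"   # "grade" | "outcome" | "none"
    master_seed: int = 0

    def __post_init__(self):
        total = self.train_fraction + self.valid_fraction + self.test_fraction
        if abs(total - 1.0) > 0.01:
            raise ValueError(f"split fractions must sum to 1 (got {total:.3f})")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")

    @property
    def valid_share_of_rest(self) -> float:
        """Validation share of the non-test portion (~0.30 by default)."""
        return self.valid_fraction / (self.train_fraction + self.valid_fraction)


def _strat_labels(cohort: CohortTable, plan: CVPlan) -> np.ndarray:
    if plan.stratify_by == "grade":
        return cohort.grade()
    if plan.stratify_by == "outcome":
        return cohort.outcome.astype(str)
    return np.zeros(cohort.n, dtype=int)


def make_cv_plan(cohort: CohortTable, plan: CVPlan) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Index triples (train, valid, test) for every (replication, fold).

    Within each replication the test folds partition the cohort; the
    remaining samples are split into train/validation at the plan's ratio,
    stratified where feasible.  Deterministic given ``plan.master_seed``.
    """
    min_n = 3 * plan.n_folds
    if cohort.n < min_n:
        raise ValueError(
            f"cohort of size {cohort.n} is too small for a {plan.n_folds}-fold "
            f"plan; need at least {min_n}"
        )
    labels = _strat_labels(cohort, plan)
    # strata thinner than the fold count cannot be stratified over
    _, counts = np.unique(labels, return_counts=True)
    stratifiable = counts.min() >= plan.n_folds
    rep_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(plan.master_seed).spawn(plan.n_replications)
    ]

    triples = []
    for rep in range(plan.n_replications):
        if stratifiable:
            kf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True,
                                 random_state=rep_seeds[rep])
            folds = kf.split(np.zeros(cohort.n), labels)
        else:
            rng = np.random.default_rng(rep_seeds[rep])
            perm = rng.permutation(cohort.n)
            chunks = np.array_split(perm, plan.n_folds)
            folds = (
                (np.setdiff1d(np.arange(cohort.n), test), test) for test in chunks
            )
        for fold_i, (rest, test) in enumerate(folds):
            strat = labels[rest]
            try:
                tr, va = train_test_split(
                    rest, test_size=plan.valid_share_of_rest,
                    random_state=rep_seeds[rep] + 7919 * fold_i, stratify=strat,
                )
            except ValueError:  # a stratum with a single member
                tr, va = train_test_split(
                    rest, test_size=plan.valid_share_of_rest,
                    random_state=rep_seeds[rep] + 7919 * fold_i,
                )
            triples.append((np.sort(tr), np.sort(va), np.sort(test)))
    return triples


def _seed_from(*parts) -> int:
    """Stable small seed from mixed ints/strings."""
    text = "|".join(str(p) for p in parts)
    return zlib.crc32(text.encode()) % (2**31)


def run_aberration_experiment(
    cohort: CohortTable,
    aberration: str,
    plan: CVPlan,
    config: DLVMConfig,
    races: tuple[str, ...] | None = None,
    convention: str = "root",
    grs_mapping=None,
    collect_estimates: list | None = None,
) -> dict[tuple[str, str], GroupMetrics]:
    """The full protocol for one aberration: per race, replicated CV.

    Each racial group is modeled separately.  Per replication the k test
    folds are pooled (every patient contributes exactly one test-set
    estimate), then AICE/RMSE/mean-ICE/GRS are computed per grade cell plus
    an ``"all"`` cell.  A cell empty in some replication is recorded as NaN
    for that replicate, never fabricated.

    Returns a dict keyed by (race, grade label).  ``collect_estimates``, if
    given, receives per-patient estimate rows for the report.
    """
    schema_ab = schema_for_aberration(cohort.schema, aberration)
    cohort = CohortTable(schema_ab, cohort.frame)
    present = sorted(set(cohort.race) - {"unknown"})
    races = tuple(races) if races else tuple(present)

    results: dict[tuple[str, str], GroupMetrics] = {}
    for race in races:
        idx = np.flatnonzero(cohort.race == race)
        sub = cohort.subset(idx)
        race_plan = CVPlan(**{**plan.__dict__,
                              "master_seed": _seed_from(plan.master_seed, aberration, race)})
        triples = make_cv_plan(sub, race_plan)
        per_cell: dict[str, dict[str, list[float]]] = {
            g: {"aice": [], "rmse": [], "mean_ice": [], "grs": []}
            for g in (*GRADE_LABELS, "all")
        }
        cell_n: dict[str, int] = {}
        for rep in range(race_plan.n_replications):
            pool_parts = []
            test_rows = []
            for fold in range(race_plan.n_folds):
                tr, va, te = triples[rep * race_plan.n_folds + fold]
                fit_seed = _seed_from(race_plan.master_seed, rep, fold)
                cfg = DLVMConfig(**{**config.__dict__, "seed": fit_seed})
                model = fit_dlvm(sub.subset(tr), sub.subset(va), cfg)
                est = infer_counterfactual(model, sub.subset(te))
                pool_parts.append(est)
                test_rows.append(te)
            order = np.concatenate(test_rows)
            pooled = CounterfactualEstimates(
                np.concatenate([e.y_hat_0 for e in pool_parts]),
                np.concatenate([e.y_hat_1 for e in pool_parts]),
                np.concatenate([e.t_factual for e in pool_parts]),
                np.concatenate([e.y_factual for e in pool_parts]),
            )
            grades = sub.grade()[order]
            if collect_estimates is not None:
                for j in range(pooled.n):
                    collect_estimates.append({
                        "aberration": aberration, "race": race,
                        "replication": rep, "row": int(idx[order[j]]),
                        "t": int(pooled.t_factual[j]),
                        "y": float(pooled.y_factual[j]),
                        "y_hat_0": float(pooled.y_hat_0[j]),
                        "y_hat_1": float(pooled.y_hat_1[j]),
                        "ice": float(pooled.ice[j]),
                        "grade": grades[j],
                    })
            for g in (*GRADE_LABELS, "all"):
                mask = np.ones(pooled.n, bool) if g == "all" else grades == g
                cell = per_cell[g]
                if not mask.any():
                    for key in cell:
                        cell[key].append(float("nan"))
                    continue
                part = pooled.subset(mask)
                cell_n[g] = int(mask.sum())
                cell["aice"].append(aice(part, convention=convention))
                cell["rmse"].append(rmse(part))
                cell["mean_ice"].append(mean_ice(part))
                cell["grs"].append(float(np.mean(map_gs_to_grs(part.y_hat_1, grs_mapping))))
        for g, cell in per_cell.items():
            a = np.asarray(cell["aice"])
            if np.isnan(a).all():
                continue  # cell empty in every replication: flagged missing
            results[(race, g)] = GroupMetrics(
                race=race, grade=g, aberration=aberration,
                aice=float(np.nanmean(a)),
                rmse=float(np.nanmean(cell["rmse"])),
                n=cell_n.get(g, 0) or 1,
                convention=convention,
                replicate_values=list(zip(cell["aice"], cell["rmse"])),
                replicate_mean_ice=cell["mean_ice"],
                replicate_grs=cell["grs"],
            )
    return results


@dataclass
class ComparisonResult:
    """Paired two-sided t-test between two groups' replicate metric values."""

    group_a: str
    group_b: str
    metric: str
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    reject: bool
    alpha: float = 0.05
    degenerate: bool = False
    aberration: str = ""
    grade: str = ""


def paired_t_test(values_a, values_b, alpha: float = 0.05,
                  group_a: str = "A", group_b: str = "B",
                  metric: str = "aice", **labels) -> ComparisonResult:
    """Two-sided paired Student's t-test with a 95% CI of the mean difference.

    Pairing is by position (replication index).  Zero-variance differences
    are degenerate: p is reported as the limiting value (1 if the mean
    difference is zero, else 0) with ``degenerate=True``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least 2 paired values")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = len(d) - 1
    if sd == 0.0:
        t_stat = 0.0 if md == 0 else float(np.sign(md)) * float("inf")
        p = 1.0 if md == 0 else 0.0
        ci = (md, md)
        degenerate = True
    else:
        res = stats.ttest_rel(a, b)
        t_stat, p = float(res.statistic), float(res.pvalue)
        half = stats.t.ppf(0.975, df) * sd / np.sqrt(len(d))
        ci = (md - half, md + half)
        degenerate = False
    return ComparisonResult(
        group_a=group_a, group_b=group_b, metric=metric,
        t_statistic=t_stat, p_value=p, ci_low=ci[0], ci_high=ci[1],
        reject=bool(p < alpha), alpha=alpha, degenerate=degenerate,
        **labels,
    )


class GRSMappingError(ValueError):
    """The supplied risk mapping is not monotone non-decreasing."""


def map_gs_to_grs(estimated_gs, mapping=None, center: float = 7.5,
                  scale: float = 1.0):
    """Map estimated Gleason Scores to genomic risk scores in [0, 1].

    The default is a logistic curve ``1 / (1 + exp(-(gs - center)/scale))``
    — a declared stand-in, not the published risk model.  A user-supplied
    ``mapping`` callable is probed for monotonicity on a GS grid and its
    output clipped to [0, 1].
    """
    gs = np.asarray(estimated_gs, dtype=float)
    if mapping is None:
        return expit((gs - center) / scale)
    grid = np.linspace(2.0, 12.0, 101)
    probe = np.asarray([mapping(g) for g in grid], dtype=float)
    if np.any(np.diff(probe) < -1e-9):
        raise GRSMappingError("risk mapping must be monotone non-decreasing")
    out = np.asarray([mapping(g) for g in np.atleast_1d(gs)], dtype=float)
    out = np.clip(out, 0.0, 1.0)
    return out if gs.ndim else float(out[0])


def compare_races(results: dict, metric: str = "aice", alpha: float = 0.05,
                  race_a: str = "AA", race_b: str = "EA") -> list[ComparisonResult]:
    """Paired comparisons between two races across all shared grade cells."""
    out = []
    grades = sorted({g for (_, g) in results})
    for g in grades:
        ka, kb = (race_a, g), (race_b, g)
        if ka not in results or kb not in results:
            continue
        ma, mb = results[ka], results[kb]
        if metric == "aice":
            va = [v[0] for v in ma.replicate_values]
            vb = [v[0] for v in mb.replicate_values]
        elif metric == "rmse":
            va = [v[1] for v in ma.replicate_values]
            vb = [v[1] for v in mb.replicate_values]
        elif metric == "grs":
            va, vb = ma.replicate_grs, mb.replicate_grs
        elif metric == "mean_ice":
            va, vb = ma.replicate_mean_ice, mb.replicate_mean_ice
        else:
            raise ValueError(f"unknown metric {metric!r}")
        pairs = (~np.isnan(np.asarray(va))) & (~np.isnan(np.asarray(vb)))
        if pairs.sum() < 2:  # too few replications to pair; skip the cell
            continue
        out.append(paired_t_test(va, vb, alpha=alpha, group_a=race_a,
                                 group_b=race_b, metric=metric,
                                 aberration=ma.aberration, grade=g))
    return out


def summarize_experiment(results_by_aberration: dict[str, dict],
                         comparisons: list[ComparisonResult]):
    """Tidy report tables: replicate-level metrics and test outcomes.

    Returns ``(metrics_df, comparisons_df)``; one metrics row per
    (aberration, race, grade, replication, metric) and one comparisons row
    per test.  Adds Benjamini-Hochberg adjusted p-values alongside the raw
    per-comparison values (clearly separated; the protocol itself applies no
    correction).
    """
    rows = []
    for aberration, results in results_by_aberration.items():
        for (race, grade), gm in results.items():
            for rep, (a_val, r_val) in enumerate(gm.replicate_values):
                for metric, value in (
                    ("aice", a_val),
                    ("rmse", r_val),
                    ("mean_ice", gm.replicate_mean_ice[rep]),
                    ("grs", gm.replicate_grs[rep]),
                ):
                    rows.append({
                        "aberration": aberration, "race": race, "grade": grade,
                        "replication": rep, "metric": metric, "value": value,
                        "convention": gm.convention, "n": gm.n,
                    })
    metrics_df = pd.DataFrame(rows)

    crows = [{
        "aberration": c.aberration, "grade": c.grade, "metric": c.metric,
        "group_a": c.group_a, "group_b": c.group_b,
        "t_statistic": c.t_statistic, "p_value": c.p_value,
        "ci_low": c.ci_low, "ci_high": c.ci_high,
        "reject": c.reject, "alpha": c.alpha, "degenerate": c.degenerate,
    } for c in comparisons]
    comparisons_df = pd.DataFrame(crows)
    if len(comparisons_df):
        finite = comparisons_df["p_value"].to_numpy()
        comparisons_df["p_value_bh"] = stats.false_discovery_control(
            np.clip(finite, 0.0, 1.0)
        )
    return metrics_df, comparisons_df


def write_report(metrics_df: pd.DataFrame, comparisons_df: pd.DataFrame,
                 out_dir) -> dict[str, str]:
    """Write the tidy tables as TSV (12 significant digits; round-trippable)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("metrics", metrics_df), ("comparisons", comparisons_df)):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.12g")
        paths[name] = str(p)
    return paths


def plot_metric_boxplots(metrics_df: pd.DataFrame, path, metric: str = "aice") -> None:
    """Box plots of per-replication metric values by (grade, race)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = metrics_df[metrics_df["metric"] == metric]
    grades = [g for g in (*GRADE_LABELS, "all") if g in set(sub["grade"])]
    fig, axes = plt.subplots(1, max(len(grades), 1), figsize=(4 * max(len(grades), 1), 4),
                             squeeze=False)
    for ax, grade in zip(axes[0], grades):
        cell = sub[sub["grade"] == grade]
        races = sorted(set(cell["race"]))
        data = [cell[cell["race"] == r]["value"].to_numpy() for r in races]
        ax.boxplot(data, tick_labels=races)
        ax.set_title(f"{metric} — {grade} grade")
        ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
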