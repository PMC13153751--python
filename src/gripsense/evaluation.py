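"""Validation protocols, error metrics, and raw NASA-TLX scoring.

Three schemes mirror the study's evaluation design:

* ``random_kfold`` — rows shuffled and split into 5 near-equal folds;
* ``leave_one_user_out`` — one fold per participant, training never sees
  any row of the held-out person (cross-person generalization);
* ``few_day_calibration`` — training combines all other participants'
  rows with the target user's first ``d`` days (an onboarding scenario);
  evaluation uses the target's remaining days.  ``d = 0`` reduces to the
  leave-one-user-out fold for that participant.

Metrics are MAE (kg), MAPE (%) and R^2, computed per fold and aggregated
as mean (SD) across folds or participants.  A mean-predictor baseline is
always evaluated alongside, since relative improvement over it is the
meaningful desk-scale yardstick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from gripsense.errors import DataError, UsageError
from gripsense.features import KEY_COLUMNS, TARGET_COLUMN
from gripsense.models import FittedModel, ModelConfig, fit, predict

METRIC_NAMES = ("mae", "mape", "r2")


def metrics(true, pred) -> tuple[float, float, float]:
    """(MAE kg, MAPE %, R^2) for one fold.

    MAPE uses the true grip as denominator, so every true value must be
    positive.  With zero variance in the true values R^2 is undefined and
    returned as NaN with a warning.
    """
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape or t.ndim != 1 or t.size == 0:
        raise UsageError("true and pred must be equal-length nonempty vectors")
    if np.any(t <= 0):
        raise DataError("MAPE undefined: true grip values must be > 0")
    err = np.abs(t - p)
    mae = float(err.mean())
    mape = float(100.0 * (err / t).mean())
    ss_tot = float(((t - t.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("zero variance in true values; R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(((t - p) ** 2).sum()) / ss_tot
    return mae, mape, r2


@dataclass(frozen=True)
class SplitPlan:
    """Declarative description of one validation scheme."""

    scheme: str  # random_kfold | leave_one_user_out | few_day_calibration
    folds: int = 5
    target: str | None = None
    calibration_days: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("random_kfold", "leave_one_user_out",
                               "few_day_calibration"):
            raise UsageError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "few_day_calibration":
            if self.target is None:
                raise UsageError("few_day_calibration needs a target participant")
            if not 0 <= self.calibration_days <= 4:
                raise UsageError("calibration_days must be in 0..4")


def iter_splits(plan: SplitPlan, keys: pd.DataFrame
                ) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
    """Yield (fold_name, train_positions, test_positions) for a plan.

    ``keys`` only needs the participant_id / day / set_index columns;
    positions are integer row positions into that frame.  Test rows never
    intersect training rows in any scheme.
    """
    n = len(keys)
    idx = np.arange(n)
    if plan.scheme == "random_kfold":
        if plan.folds > n:
            raise UsageError(f"cannot make {plan.folds} folds from {n} rows")
        rng = np.random.default_rng(plan.rng_seed)
        perm = rng.permutation(n)
        for f, test in enumerate(np.array_split(perm, plan.folds)):
            mask = np.ones(n, dtype=bool)
            mask[test] = False
            yield f"fold_{f + 1}", idx[mask], np.sort(test)
    elif plan.scheme == "leave_one_user_out":
        pids = keys["participant_id"].to_numpy()
        unique = sorted(pd.unique(pids))
        if len(unique) < 2:
            raise UsageError("leave-one-user-out needs at least 2 participants")
        for pid in unique:
            test = pids == pid
            yield str(pid), idx[~test], idx[test]
    else:  # few_day_calibration
        pids = keys["participant_id"].to_numpy()
        days = keys["day"].to_numpy()
        target_mask = pids == plan.target
        if not target_mask.any():
            raise UsageError(f"no rows for target participant {plan.target!r}")
        target_days = np.sort(pd.unique(days[target_mask]))
        d = plan.calibration_days
        if d >= len(target_days):
            raise UsageError(
                f"calibration_days={d} but target has only "
                f"{len(target_days)} distinct days")
        calib_days = set(target_days[:d].tolist())
        train = ~target_mask | np.isin(days, list(calib_days)) & target_mask
        test = target_mask & ~np.isin(days, list(calib_days))
        yield f"{plan.target}_d{d}", idx[train], idx[test]


@dataclass
class EvaluationReport:
    """Per-fold metrics plus aggregation for one scheme/config run."""

    scheme: str
    algorithm: str
    folds: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def aggregate(self) -> dict[str, float]:
        out: dict[str, float] = {"n_folds": len(self.folds)}
        for m in METRIC_NAMES:
            vals = np.array([f[m] for f in self.folds], dtype=float)
            base = np.array([f[f"baseline_{m}"] for f in self.folds], dtype=float)
            out[f"{m}_mean"] = float(np.mean(vals))
            out[f"{m}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            out[f"baseline_{m}_mean"] = float(np.mean(base))
        return out

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "algorithm": self.algorithm,
                "metadata": self.metadata, "folds": self.folds,
                "aggregate": self.aggregate()}


def _evaluate_plan(data: pd.DataFrame, plan: SplitPlan, config: ModelConfig
                   ) -> EvaluationReport:
    report = EvaluationReport(plan.scheme, config.algorithm,
                              metadata={"rng_seed": plan.rng_seed})
    keys = data[list(KEY_COLUMNS)]
    y_all = data[TARGET_COLUMN].to_numpy(dtype=float)
    for name, tr, te in iter_splits(plan, keys):
        model = fit(config, data.iloc[tr])
        pred = predict(model, data.iloc[te])
        mae, mape, r2 = metrics(y_all[te], pred)
        base_pred = np.full(te.size, y_all[tr].mean())
        bmae, bmape, br2 = metrics(y_all[te], base_pred)
        report.folds.append({
            "fold": name, "n_train": int(tr.size), "n_test": int(te.size),
            "mae": mae, "mape": mape, "r2": r2,
            "baseline_mae": bmae, "baseline_mape": bmape, "baseline_r2": br2,
        })
    return report


def random_kfold(data: pd.DataFrame, k: int = 5, seed: int = 0,
                 config: ModelConfig | None = None) -> EvaluationReport:
    """Shuffled k-fold cross-validation (5 folds by default)."""
    config = config or ModelConfig("svr_rbf")
    plan = SplitPlan("random_kfold", folds=k, rng_seed=seed)
    rep = _evaluate_plan(data, plan, config)
    rep.metadata["k"] = k
    return rep


def leave_one_user_out(data: pd.DataFrame,
                       config: ModelConfig | None = None) -> EvaluationReport:
    """One fold per participant; training excludes every row of that person."""
    config = config or ModelConfig("svr_rbf")
    plan = SplitPlan("leave_one_user_out")
    return _evaluate_plan(data, plan, config)


def few_day_calibration(data: pd.DataFrame, target: str, d: int,
                        config: ModelConfig | None = None,
                        day_selection: str = "first") -> EvaluationReport:
    """Calibrate on the target's first ``d`` days, test on the rest.

    ``day_selection="all_subsets"`` instead averages over every possible
    choice of ``d`` calibration days (a sensitivity analysis; the test
    rows are always the complementary days).
    """
    config = config or ModelConfig("svr_rbf")
    if day_selection == "first":
        plan = SplitPlan("few_day_calibration", target=target,
                         calibration_days=d)
        return _evaluate_plan(data, plan, config)
    if day_selection != "all_subsets":
        raise UsageError(f"unknown day_selection {day_selection!r}")

    keys = data[list(KEY_COLUMNS)]
    pids = keys["participant_id"].to_numpy()
    days = keys["day"].to_numpy()
    tmask = pids == target
    target_days = sorted(pd.unique(days[tmask]).tolist())
    if d >= len(target_days):
        raise UsageError(f"calibration_days={d} but target has only "
                         f"{len(target_days)} days")
    idx = np.arange(len(data))
    y_all = data[TARGET_COLUMN].to_numpy(dtype=float)
    report = EvaluationReport("few_day_calibration", config.algorithm,
                              metadata={"day_selection": "all_subsets"})
    for subset in combinations(target_days, d):
        calib = np.isin(days, subset) & tmask
        test = tmask & ~calib
        tr = idx[~tmask | calib]
        te = idx[test]
        model = fit(config, data.iloc[tr])
        pred = predict(model, data.iloc[te])
        mae, mape, r2 = metrics(y_all[te], pred)
        bp = np.full(te.size, y_all[tr].mean())
        bmae, bmape, br2 = metrics(y_all[te], bp)
        report.folds.append({
            "fold": f"{target}_days={list(subset)}", "n_train": int(tr.size),
            "n_test": int(te.size), "mae": mae, "mape": mape, "r2": r2,
            "baseline_mae": bmae, "baseline_mape": bmape, "baseline_r2": br2,
        })
    return report


def calibration_curve(data: pd.DataFrame, config: ModelConfig | None = None,
                      days: Sequence[int] = (0, 1, 2, 3, 4)) -> dict[int, EvaluationReport]:
    """MAPE-vs-calibration-days table across all participants.

    For every ``d`` each participant in turn is the calibration target;
    the per-participant fold metrics are collected into one report per d.
    """
    config = config or ModelConfig("svr_rbf")
    participants = sorted(data["participant_id"].unique().tolist())
    out: dict[int, EvaluationReport] = {}
    for d in days:
        rep = EvaluationReport("few_day_calibration", config.algorithm,
                               metadata={"calibration_days": d})
        for pid in participants:
            sub = few_day_calibration(data, pid, d, config)
            rep.folds.extend(sub.folds)
        out[d] = rep
    return out


def tlx_overall(subscale_means: Iterable[float]) -> float:
    """Raw NASA-TLX overall workload: the plain average of the 6 subscales.

    Each subscale is rated on the 11-point 0 (low) to 10 (high) scale;
    the overall score is reported to 2 decimals.
    """
    vals = np.asarray(list(subscale_means), dtype=float)
    if vals.shape != (6,):
        raise UsageError(f"expected exactly 6 subscale means, got {vals.size}")
    if np.any(vals < 0) or np.any(vals > 10) or not np.all(np.isfinite(vals)):
        raise DataError("subscale means must lie in [0, 10]")
    return round(float(vals.mean()), 2)


# -- report rendering ---------------------------------------------------------

def render_markdown(report_obj: dict) -> str:
    """Markdown tables in the published layout (rows = scope, cols = algorithm)."""
    lines: list[str] = [f"# Evaluation report — {report_obj.get('scheme', '?')}", ""]
    results = report_obj.get("results")
    if results:
        algs = sorted({a for scope in results.values() for a in scope})
        for metric, unit in (("mae", "kg"), ("mape", "%"), ("r2", "")):
            lines.append(f"## {metric.upper()}{f' ({unit})' if unit else ''}")
            lines.append("| Task | " + " | ".join(algs) + " |")
            lines.append("|---" * (len(algs) + 1) + "|")
            for scope, by_alg in results.items():
                cells = []
                for a in algs:
                    agg = by_alg.get(a)
                    if agg is None:
                        cells.append("—")
                    else:
                        cells.append(f"{agg[f'{metric}_mean']:.2f} "
                                     f"({agg[f'{metric}_sd']:.2f})")
                lines.append(f"| {scope} | " + " | ".join(cells) + " |")
            lines.append("")
    curve = report_obj.get("calibration")
    if curve:
        ds = sorted(curve, key=int)
        lines.append("## Calibration days")
        lines.append("| Metric | " + " | ".join(f"Day {d}" for d in ds) + " |")
        lines.append("|---" * (len(ds) + 1) + "|")
        for metric in ("mae", "mape"):
            cells = [f"{curve[d][f'{metric}_mean']:.2f} "
                     f"({curve[d][f'{metric}_sd']:.2f})" for d in ds]
            lines.append(f"| {metric.upper()} | " + " | ".join(cells) + " |")
        lines.append("")
    return "\n".join(lines)
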