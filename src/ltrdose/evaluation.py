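"""Scenario cross-validation, metrics, synergy scoring and feature importance.

Prediction scenarios
--------------------
The practical value of a combination-response model depends on what is
assumed known at prediction time, so folds are built at scenario-specific
grains:

* **S1** — fill gaps in partially measured dose–response matrices: each
  (pair, cell line) matrix contributes entries to every fold, monotherapies
  always stay in training.
* **S2** — entirely new drug combinations: every row of a held-out drug
  pair, in all cell lines, goes to test; monotherapies stay in training.
* **S3** — as S2, but all monotherapy rows are also removed from training
  (they are not test rows either); the hardest setting.
* **S4** — new (pair, cell line) triplets: the same pair measured in other
  cell lines may remain in training.

Every plan carries machine-checkable leakage guarantees (:meth:`CVPlan.verify`).

Synergy
-------
:func:`combo_score` implements the NCI ALMANAC combination score: growth
values are truncated at 100, the expected combination growth is
``ya * yb / 100`` when both monotherapy growths are positive and
``min(ya, yb)`` otherwise, and the score is the sum over the dose grid of
(expected - observed).  Larger scores mean stronger synergy (observed growth
below the independence expectation).  The same routine is applied to
measured and to predicted matrices, so score-level evaluation inherits no
convention mismatch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc, precision_recall_curve, roc_auc_score

from .core import LTRParameters
from .features import MONO, FeatureLayout, validate_records
from .trainer import predict

__all__ = [
    "CVPlan",
    "make_folds",
    "regression_metrics",
    "aggregate_fold_metrics",
    "combo_score",
    "score_panel",
    "synergy_discrimination",
    "permutation_importance",
    "weight_norms",
]

SCENARIOS = ("S1", "S2", "S3", "S4")


@dataclass
class CVPlan:
    """Fold assignments with scenario-specific leakage guarantees."""

    scenario: str
    k: int
    seed: int
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    notes: str = ""

    def verify(self, records: pd.DataFrame) -> None:
        """Assert the constructive guarantees on actual row content."""
        rec = records.reset_index(drop=True)
        mono = (rec["drug_b"] == MONO).to_numpy()
        pair = _pair_key(rec)
        test_union: list[np.ndarray] = []
        for train, test in self.folds:
            if np.intersect1d(train, test).size:
                raise AssertionError("train and test overlap within a fold")
            if mono[test].any():
                raise AssertionError("monotherapy rows may never be test rows")
            if self.scenario in ("S2", "S3"):
                train_pairs = set(pair[i] for i in train if not mono[i])
                test_pairs = set(pair[i] for i in test)
                if train_pairs & test_pairs:
                    raise AssertionError(
                        "held-out drug pair leaked into the training fold"
                    )
            if self.scenario == "S3" and mono[train].any():
                raise AssertionError("monotherapy rows present in an S3 training fold")
            if self.scenario == "S4":
                train_trip = set(zip(pair[train], rec.loc[train, "cell_line"]))
                test_trip = set(zip(pair[test], rec.loc[test, "cell_line"]))
                if train_trip & test_trip:
                    raise AssertionError("held-out (pair, cell) triplet leaked into training")
            test_union.append(test)
        all_test = np.concatenate(test_union) if test_union else np.array([], dtype=int)
        if len(np.unique(all_test)) != len(all_test):
            raise AssertionError("folds do not partition the test universe")


def _pair_key(rec: pd.DataFrame) -> np.ndarray:
    """Unordered drug-pair identity (monotherapy rows key on the single drug)."""
    a = rec["drug_a"].to_numpy(dtype=object)
    b = rec["drug_b"].to_numpy(dtype=object)
    return np.array([f"{x}|{y}" if x <= y else f"{y}|{x}" for x, y in zip(a, b)],
                    dtype=object)


def make_folds(records: pd.DataFrame, scenario: str, k: int = 5,
               seed: int = 0) -> CVPlan:
    """Build a k-fold plan under a named scenario (see module docstring)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rec = validate_records(records).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    mono_mask = (rec["drug_b"] == MONO).to_numpy()
    mono_idx = np.flatnonzero(mono_mask)
    combo_idx = np.flatnonzero(~mono_mask)
    pair = _pair_key(rec)

    test_folds: list[list[int]] = [[] for _ in range(k)]
    if scenario == "S1":
        groups = pd.DataFrame({
            "idx": combo_idx,
            "matrix": [f"{pair[i]}|{rec.at[i, 'cell_line']}" for i in combo_idx],
        }).groupby("matrix")["idx"]
        if groups.ngroups < 1 or len(combo_idx) < k:
            raise ValueError("fewer combination measurements than folds")
        # per-matrix stratified dealing so every matrix stays partially observed
        for _, idx in groups:
            shuffled = rng.permutation(idx.to_numpy())
            offset = int(rng.integers(k))
            for j, row in enumerate(shuffled):
                test_folds[(j + offset) % k].append(row)
    elif scenario in ("S2", "S3"):
        units = np.array(sorted(set(pair[combo_idx])), dtype=object)
        if len(units) < k:
            raise ValueError(f"only {len(units)} drug pairs for {k} folds")
        rng.shuffle(units)
        for f, chunk in enumerate(np.array_split(units, k)):
            members = set(chunk)
            test_folds[f] = [i for i in combo_idx if pair[i] in members]
    else:  # S4
        trip = np.array([f"{pair[i]}|{rec.at[i, 'cell_line']}" for i in combo_idx],
                        dtype=object)
        units = np.array(sorted(set(trip)), dtype=object)
        if len(units) < k:
            raise ValueError(f"only {len(units)} (pair, cell) triplets for {k} folds")
        rng.shuffle(units)
        for f, chunk in enumerate(np.array_split(units, k)):
            members = set(chunk)
            test_folds[f] = [i for i, t in zip(combo_idx, trip) if t in members]

    folds = []
    for f in range(k):
        test = np.array(sorted(test_folds[f]), dtype=int)
        train_combo = np.setdiff1d(combo_idx, test)
        if scenario == "S3":
            train = train_combo
        else:
            train = np.union1d(train_combo, mono_idx)
        folds.append((train, test))
    notes = {
        "S1": "per-matrix stratified holdout; monotherapies in training",
        "S2": "pair-level holdout across all cell lines; monotherapies in training",
        "S3": "pair-level holdout; all monotherapy rows dropped from training",
        "S4": "(pair, cell)-triplet holdout; monotherapies in training",
    }[scenario]
    plan = CVPlan(scenario=scenario, k=k, seed=seed, folds=folds, notes=notes)
    plan.verify(rec)
    return plan


# ---------------------------------------------------------------------------
# regression metrics
# ---------------------------------------------------------------------------

def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """RMSE plus Pearson and Spearman correlations for one fold."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 entries")
    out = {"rmse": float(np.sqrt(np.mean((y_true - y_pred) ** 2)))}
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        warnings.warn("constant input: correlations undefined", RuntimeWarning)
        out["pearson"] = float("nan")
        out["spearman"] = float("nan")
    else:
        out["pearson"] = float(stats.pearsonr(y_true, y_pred).statistic)
        out["spearman"] = float(stats.spearmanr(y_true, y_pred).statistic)
    return out


def aggregate_fold_metrics(per_fold: list[dict]) -> pd.DataFrame:
    """Mean +/- SD across folds (metrics are never pooled across folds)."""
    frame = pd.DataFrame(per_fold)
    return pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=1)})


# ---------------------------------------------------------------------------
# synergy scoring
# ---------------------------------------------------------------------------

def _truncate_growth(y: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(y, dtype=float), 100.0)


def _expected_growth(ya: float, yb: float) -> float:
    if ya > 0 and yb > 0:
        return ya * yb / 100.0
    return min(ya, yb)


def combo_score(matrix: np.ndarray, mono_a: np.ndarray, mono_b: np.ndarray) -> float:
    """NCI ALMANAC combination score of one dose–response matrix.

    ``matrix[i, j]`` is the combination %-growth at level ``i`` of drug A and
    level ``j`` of drug B; ``mono_a``/``mono_b`` are the monotherapy %-growth
    vectors at the same levels.  See the module docstring for the formula.
    """
    matrix = np.asarray(matrix, dtype=float)
    mono_a = np.asarray(mono_a, dtype=float).ravel()
    mono_b = np.asarray(mono_b, dtype=float).ravel()
    if matrix.ndim != 2 or matrix.shape != (mono_a.size, mono_b.size):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match monotherapy vectors "
            f"({mono_a.size}, {mono_b.size})"
        )
    if not (np.all(np.isfinite(matrix)) and np.all(np.isfinite(mono_a))
            and np.all(np.isfinite(mono_b))):
        raise ValueError("incomplete dose grid: non-finite growth values")
    obs = _truncate_growth(matrix)
    ya = _truncate_growth(mono_a)
    yb = _truncate_growth(mono_b)
    score = 0.0
    for i in range(ya.size):
        for j in range(yb.size):
            score += _expected_growth(ya[i], yb[j]) - obs[i, j]
    return float(score)


def score_panel(records: pd.DataFrame, predicted: np.ndarray) -> pd.DataFrame:
    """Compute measured and predicted combination scores per (pair, cell).

    ``predicted`` aligns with ``records`` rows; combination matrices are
    filled from it while the monotherapy anchors are taken from the measured
    table in both cases, so the two scores differ only through the predicted
    combination entries.  Matrices with incomplete grids or missing
    monotherapy vectors are skipped.
    """
    rec = validate_records(records).reset_index(drop=True)
    predicted = np.asarray(predicted, dtype=float)
    mono = rec["drug_b"] == MONO
    mono_tab = {}
    for (d, cell), grp in rec[mono].groupby(["drug_a", "cell_line"]):
        mono_tab[(d, cell)] = grp.set_index("conc_a")["response"]
    rows = []
    for (a, b, cell), grp in rec[~mono].groupby(["drug_a", "drug_b", "cell_line"]):
        la = np.array(sorted(grp["conc_a"].unique()))
        lb = np.array(sorted(grp["conc_b"].unique()))
        if len(grp) != la.size * lb.size:
            continue
        ma = mono_tab.get((a, cell))
        mb = mono_tab.get((b, cell))
        if ma is None or mb is None or not (set(la) <= set(ma.index) and set(lb) <= set(mb.index)):
            continue
        meas = np.full((la.size, lb.size), np.nan)
        pred = np.full((la.size, lb.size), np.nan)
        ia = {v: i for i, v in enumerate(la)}
        ib = {v: i for i, v in enumerate(lb)}
        for row_idx, row in grp.iterrows():
            meas[ia[row["conc_a"]], ib[row["conc_b"]]] = row["response"]
            pred[ia[row["conc_a"]], ib[row["conc_b"]]] = predicted[row_idx]
        va = ma.loc[la].to_numpy()
        vb = mb.loc[lb].to_numpy()
        rows.append({
            "drug_a": a, "drug_b": b, "cell_line": cell,
            "measured_score": combo_score(meas, va, vb),
            "predicted_score": combo_score(pred, va, vb),
        })
    return pd.DataFrame(rows)


def synergy_discrimination(scores: pd.DataFrame,
                           thresholds: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0)
                           ) -> pd.DataFrame:
    """Top-% synergy discrimination: label the top X% of measured scores as
    synergistic and rank by predicted scores; report AUROC and area under
    the PR curve per threshold.  Degenerate thresholds are skipped."""
    rows = []
    measured = scores["measured_score"].to_numpy()
    predicted = scores["predicted_score"].to_numpy()
    for pct in thresholds:
        cutoff = np.percentile(measured, 100.0 - pct)
        labels = (measured > cutoff).astype(int)
        if labels.min() == labels.max():
            warnings.warn(f"threshold {pct}% yields a single class; skipped",
                          RuntimeWarning)
            continue
        prec, recall, _ = precision_recall_curve(labels, predicted)
        rows.append({
            "threshold_pct": pct,
            "n_positive": int(labels.sum()),
            "auroc": float(roc_auc_score(labels, predicted)),
            "aupr": float(auc(recall, prec)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature importance
# ---------------------------------------------------------------------------

def permutation_importance(model: LTRParameters, X: np.ndarray, y: np.ndarray,
                           layout: FeatureLayout, n_perm: int = 20,
                           seed: int = 0) -> pd.DataFrame:
    """Per-column permutation importance.

    For every raw feature column the importance is the mean, over ``n_perm``
    seeded permutations, of the drop in Pearson correlation between
    measured responses and predictions when that column is shuffled.  The
    homogeneous constant is never permuted.  Constant columns have exactly
    zero importance (permutation leaves them unchanged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    base = stats.pearsonr(y, predict(model, X)[:, 0]).statistic
    rows = []
    names = layout.column_names
    for block in layout.blocks:
        if block.name == "constant":
            continue
        for col in range(block.start, block.stop):
            column = X[:, col]
            if np.all(column == column[0]):
                rows.append({"column": names[col], "block": block.name,
                             "importance": 0.0, "importance_sd": 0.0})
                continue
            drops = np.empty(n_perm)
            Xp = X.copy()
            for p in range(n_perm):
                Xp[:, col] = column[rng.permutation(len(column))]
                r = stats.pearsonr(y, predict(model, Xp)[:, 0]).statistic
                drops[p] = base - r
            Xp[:, col] = column
            rows.append({"column": names[col], "block": block.name,
                         "importance": float(drops.mean()),
                         "importance_sd": float(drops.std(ddof=1))})
    return pd.DataFrame(rows)


def weight_norms(model: LTRParameters, layout: FeatureLayout) -> tuple[pd.DataFrame, pd.DataFrame]:
    """L2 weight norms per raw feature and per feature block.

    Feature ``j`` gets ``|lambda_u[j]| * || concat_d U^(d)[j, :] ||``; block
    norms aggregate their features in quadrature.  Suitable for heatmaps of
    how much weight each feature set carries.
    """
    if layout.width != model.n:
        raise ValueError(
            f"layout width {layout.width} does not match model input dim {model.n}"
        )
    stacked = np.hstack(model.U)                       # n x (n_d * n_k)
    per_feature = np.abs(model.lambda_u) * np.linalg.norm(stacked, axis=1)
    names = layout.column_names
    feat = pd.DataFrame({
        "column": names,
        "block": [b.name for b in layout.blocks for _ in b.feature_names],
        "l2_norm": per_feature,
    })
    block = (feat.assign(sq=feat["l2_norm"] ** 2)
             .groupby("block", sort=False)["sq"].sum()
             .pow(0.5).rename("l2_norm").reset_index())
    return feat, block
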