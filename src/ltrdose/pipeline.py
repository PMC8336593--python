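"""High-level experiment plumbing shared by the CLI and the test harness.

Glue only: encode a response table under a named feature configuration,
run scenario cross-validation (train per fold, predict the held-out rows),
and collect per-fold metrics.  The four feature configurations mirror the
standard ablation: tensor indices alone, plus fingerprints, plus omics, or
everything.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .evaluation import CVPlan, aggregate_fold_metrics, make_folds, regression_metrics
from .features import FeatureLayout, Vocabulary, assemble, filter_fingerprints, select_omics
from .trainer import HyperParams, fit, predict

__all__ = ["FEATURE_SETS", "encode_for_config", "cross_validate", "CVResult"]

FEATURE_SETS = ("tensor", "tensor+fp", "tensor+omics", "all")


def encode_for_config(records: pd.DataFrame,
                      feature_set: str = "tensor",
                      vocab: Vocabulary | None = None,
                      fingerprints: pd.DataFrame | None = None,
                      omics: dict[str, pd.DataFrame] | None = None,
                      omics_fraction: float = 1.0,
                      zscore_auxiliary: bool = False,
                      scale_aux_blocks: bool = True,
                      ) -> tuple[np.ndarray, FeatureLayout]:
    """Assemble the design matrix for one named feature configuration.

    Fingerprints pass through constant-bit filtering and omics blocks
    through top-variance selection before they enter the matrix.  With
    ``scale_aux_blocks`` each auxiliary block is divided by the square root
    of its width so that wide blocks do not dominate the row energy — under
    a degree-``n_d`` product model, unscaled wide blocks inflate the factor
    inner products by ``(row energy)^{n_d/2}`` and destabilize training.
    Column scaling leaves the representable function class unchanged (it is
    absorbed by the input-scaling vector and the projection factors).
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set!r}; choose from {FEATURE_SETS}")
    fp = None
    om = None
    if feature_set in ("tensor+fp", "all"):
        if fingerprints is None:
            raise ValueError(f"feature set {feature_set!r} needs a fingerprint table")
        fp, _ = filter_fingerprints(fingerprints)
    if feature_set in ("tensor+omics", "all"):
        if not omics:
            raise ValueError(f"feature set {feature_set!r} needs omics tables")
        om = {}
        for name, table in omics.items():
            if omics_fraction < 1.0:
                table, _ = select_omics(table, omics_fraction)
            om[name] = table
    X, layout = assemble(records, vocab=vocab, fingerprints=fp, omics=om,
                         zscore_auxiliary=zscore_auxiliary)
    if scale_aux_blocks:
        for b in layout.blocks:
            if b.name.startswith(("fp_", "omics_")):
                X[:, b.slice] /= np.sqrt(b.width)
    return X, layout


@dataclass
class CVResult:
    plan: CVPlan
    per_fold: list[dict]
    predictions: pd.DataFrame     # columns: row, fold, y_true, y_pred

    def summary(self) -> pd.DataFrame:
        return aggregate_fold_metrics(self.per_fold)


def cross_validate(records: pd.DataFrame, scenario: str, hyper: HyperParams,
                   k: int = 5, seed: int = 0,
                   feature_set: str = "tensor",
                   vocab: Vocabulary | None = None,
                   fingerprints: pd.DataFrame | None = None,
                   omics: dict[str, pd.DataFrame] | None = None,
                   omics_fraction: float = 1.0,
                   zscore_auxiliary: bool = True,
                   max_folds: int | None = None,
                   inner_validation: bool = True,
                   n_restarts: int = 1,
                   ) -> CVResult:
    """Scenario cross-validation: one model trained per fold.

    The design matrix is encoded once over the shared vocabularies (the
    encoding uses no response values, so this leaks nothing); fold training
    seeds are derived deterministically from the plan seed.  ``max_folds``
    caps how many of the k folds are actually run, for budgeted experiments.

    With ``inner_validation`` a slice of each training fold — held out at
    the *same scenario grain* as the outer split, so that e.g. validation
    pairs are unseen pairs — steers epoch selection: the model snapshot with
    the best validation RMSE is kept.  Validating at the deployment grain is
    what stops the high-capacity polynomial from memorizing its way past
    the generalization optimum.

    ``n_restarts`` averages the predictions of independently initialized
    fits (a light ensemble); factorized polynomial training is non-convex,
    and restart averaging damps the initialization-to-initialization
    variance of single fits.
    """
    rec = records.reset_index(drop=True)
    X, layout = encode_for_config(rec, feature_set, vocab=vocab,
                                  fingerprints=fingerprints, omics=omics,
                                  omics_fraction=omics_fraction,
                                  zscore_auxiliary=zscore_auxiliary)
    y = rec["response"].to_numpy(dtype=float)
    plan = make_folds(rec, scenario, k=k, seed=seed)
    plan.verify(rec)
    per_fold = []
    pred_rows = []
    for f, (train, test) in enumerate(plan.folds):
        if max_folds is not None and f >= max_folds:
            break
        if inner_validation:
            inner = make_folds(rec.iloc[train].reset_index(drop=True),
                               scenario, k=min(5, max(2, k)), seed=seed + 17)
            sub_train, sub_val = inner.folds[0]
            tr_idx, val_idx = train[sub_train], train[sub_val]
            val = (X[val_idx], y[val_idx])
        else:
            tr_idx, val = train, None
        preds, val_scores = [], []
        for r in range(n_restarts):
            fold_hyper = replace(hyper, seed=hyper.seed + 1000 * f + 7907 * r)
            params, tr_trace = fit(X[tr_idx], y[tr_idx], fold_hyper,
                                   validation=val, restore_best=val is not None)
            preds.append(predict(params, X[test])[:, 0])
            val_scores.append(min(tr_trace.validation) if tr_trace.validation else 0.0)
        if val is not None and n_restarts > 1:
            # average only restart members close to the best validation RMSE:
            # a diverged member would otherwise poison the ensemble mean
            best = min(val_scores)
            keep = [p for p, s in zip(preds, val_scores) if s <= 1.1 * best]
        else:
            keep = preds
        y_hat = np.mean(keep, axis=0)
        # responses are bounded assay readouts; never extrapolate outside the
        # training range
        y_hat = np.clip(y_hat, y[tr_idx].min(), y[tr_idx].max())
        per_fold.append(regression_metrics(y[test], y_hat))
        pred_rows.append(pd.DataFrame({
            "row": test, "fold": f, "y_true": y[test], "y_pred": y_hat,
        }))
    predictions = pd.concat(pred_rows, ignore_index=True) if pred_rows else pd.DataFrame(
        columns=["row", "fold", "y_true", "y_pred"])
    return CVResult(plan=plan, per_fold=per_fold, predictions=predictions)
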