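"""Predicting per-spot gene expression from ITF subsets.

One regressor per gene, leave-one-out cross-validation over spots: for
every spot s the learner is fit on all other spots and predicts gene g at
s; accuracy is the Pearson correlation between held-out predictions and
truth across spots.  Inputs (both ITFs and counts) are log1p-transformed,
consistent with the correlation analysis.

Learners are interchangeable plug-ins behind a fit/predict interface with
a seed; gradient-boosted trees (lightgbm, the default, and xgboost) plus
an AdaBoost variant are registered.  All run single-threaded so results
are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PredictionTask",
    "CVResult",
    "make_learner",
    "loocv_predict",
    "evaluate_pcc",
    "compare_learners",
    "LEARNERS",
]


def _make_lightgbm(seed: int, **kw):
    from lightgbm import LGBMRegressor

    params = dict(
        n_estimators=200, learning_rate=0.1, min_child_samples=5,
        random_state=seed, n_jobs=1, deterministic=True,
        force_row_wise=True, verbose=-1,
    )
    params.update(kw)
    return LGBMRegressor(**params)


def _make_xgboost(seed: int, **kw):
    from xgboost import XGBRegressor

    params = dict(
        n_estimators=200, learning_rate=0.1, max_depth=4,
        random_state=seed, n_jobs=1, verbosity=0,
    )
    params.update(kw)
    return XGBRegressor(**params)


def _make_adaboost(seed: int, **kw):
    from sklearn.ensemble import AdaBoostRegressor
    from sklearn.tree import DecisionTreeRegressor

    params = dict(
        estimator=DecisionTreeRegressor(max_depth=4, random_state=seed),
        n_estimators=100, random_state=seed,
    )
    params.update(kw)
    return AdaBoostRegressor(**params)


LEARNERS = {
    "lightgbm": _make_lightgbm,
    "xgboost": _make_xgboost,
    "adaboost": _make_adaboost,
}

DEFAULT_LEARNER = "lightgbm"


def make_learner(name: str, seed: int, **hyperparams):
    """Instantiate a registered learner with a seed; unknown names raise."""
    try:
        factory = LEARNERS[name]
    except KeyError:
        raise ValueError(
            f"unknown learner {name!r}; registered: {sorted(LEARNERS)}"
        ) from None
    return factory(seed, **hyperparams)


@dataclass(frozen=True)
class PredictionTask:
    """Which ITFs predict which genes, and with what learner."""

    itf_subset: tuple[str, ...]
    gene_subset: tuple[str, ...]
    learner: str = DEFAULT_LEARNER
    seed: int = 0
    hyperparams: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.itf_subset or not self.gene_subset:
            raise ValueError("ITF and gene subsets must be non-empty")


@dataclass
class CVResult:
    """Held-out predictions and per-gene accuracy of one LOOCV run.

    ``pcc`` holds NaN for genes whose correlation is undefined (zero
    variance on either side); those genes are listed in ``undefined``.
    """

    predictions: pd.DataFrame  # spots x genes, held-out predictions
    truth: pd.DataFrame        # spots x genes, log1p counts
    pcc: pd.Series             # gene -> Pearson(pred, truth), NaN if undefined
    undefined: list[str]
    learner: str
    seed: int


def evaluate_pcc(pred, truth) -> float | None:
    """Sample Pearson correlation; None when either side has zero variance."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if pred.size < 3:
        raise ValueError("need at least 3 values")
    if np.std(pred) == 0.0 or np.std(truth) == 0.0:
        return None
    return float(np.corrcoef(pred, truth)[0, 1])


def loocv_predict(
    itf_table: pd.DataFrame,
    expression: pd.DataFrame,
    task: PredictionTask,
) -> CVResult:
    """Leave-one-out CV over spots, one regressor per gene.

    ``itf_table`` and ``expression`` are spots x variables on the same spot
    index; both are log1p-transformed here.  Genes that are constant
    across spots get an undefined (NaN) PCC, flagged rather than zeroed.
    """
    if not (itf_table.index == expression.index).all():
        raise ValueError("ITF table and expression must share the spot index")
    n_spots = len(itf_table)
    if n_spots < 10:
        raise ValueError("LOOCV needs at least 10 spots")
    missing_itfs = set(task.itf_subset) - set(itf_table.columns)
    missing_genes = set(task.gene_subset) - set(expression.columns)
    if missing_itfs or missing_genes:
        raise KeyError(
            f"missing from data: ITFs {sorted(missing_itfs)}, genes {sorted(missing_genes)}"
        )
    X = np.log1p(itf_table[list(task.itf_subset)]).to_numpy()
    Y = np.log1p(expression[list(task.gene_subset)]).to_numpy()

    preds = np.empty_like(Y)
    mask = np.ones(n_spots, dtype=bool)
    with warnings.catch_warnings():
        # lightgbm's sklearn wrapper warns about feature names even for
        # all-numpy fit/predict; harmless here
        warnings.filterwarnings(
            "ignore", message=".*does not have valid feature names.*"
        )
        for g, gene in enumerate(task.gene_subset):
            y = Y[:, g]
            for s in range(n_spots):
                mask[s] = False
                model = make_learner(task.learner, task.seed, **task.hyperparams)
                model.fit(X[mask], y[mask])
                preds[s, g] = model.predict(X[s:s + 1])[0]
                mask[s] = True

    pred_df = pd.DataFrame(preds, index=itf_table.index, columns=list(task.gene_subset))
    truth_df = pd.DataFrame(Y, index=itf_table.index, columns=list(task.gene_subset))
    pcc = {}
    undefined = []
    for gene in task.gene_subset:
        val = evaluate_pcc(pred_df[gene], truth_df[gene])
        if val is None:
            undefined.append(gene)
            pcc[gene] = np.nan
        else:
            pcc[gene] = val
    return CVResult(
        predictions=pred_df,
        truth=truth_df,
        pcc=pd.Series(pcc, name="pcc"),
        undefined=undefined,
        learner=task.learner,
        seed=task.seed,
    )


def compare_learners(cv_a: CVResult, cv_b: CVResult) -> tuple[float, float]:
    """Mean per-gene PCC difference (a - b) and a paired two-sided t-test p.

    Both runs must cover the same genes and spots.  When the paired
    differences have zero variance (e.g. identical runs) the t statistic is
    undefined and the p-value is NaN.
    """
    if list(cv_a.pcc.index) != list(cv_b.pcc.index):
        raise ValueError("CV results cover different gene lists")
    if not (cv_a.predictions.index == cv_b.predictions.index).all():
        raise ValueError("CV results cover different spots")
    a = cv_a.pcc.to_numpy()
    b = cv_b.pcc.to_numpy()
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with defined PCC")
    mean_diff = float(np.mean(a[ok] - b[ok]))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.ttest_rel(a[ok], b[ok])
    return mean_diff, float(t.pvalue)
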