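"""Adulteration-level quantification: four ELM-regression tasks and their
evaluation metrics.

Metric conventions follow the source formulas verbatim: ``r`` is computed as
1 - SSE/SST (the coefficient-of-determination form, despite being named a
correlation coefficient in the field's shorthand); RPD divides the
training-set reference standard deviation by the prediction RMSE; RER
divides the reference range by the *training* RMSE.  RPD >= 3 is flagged
satisfactory and >= 5 quality-control grade; RER > 10 flags good predictive
ability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import preprocess as pp
from .classify import ELMModel, elm_predict, elm_train
from .select import SelectionResult, cars_select
from .split import SplitIndices, kennard_stone_split
from .synth import SpectraSet

logger = logging.getLogger(__name__)

#: The four quantification tasks: (source classes, adulterant column).
#: Columns of SpectraSet.fractions are (DBT, CBG, PBG).
QUANT_TASKS = {
    1: ("dbt_cbg", 1),   # CBG content in the binary DBT+CBG series
    2: ("dbt_pbg", 2),   # PBG content in the binary DBT+PBG series
    3: ("ternary", 1),   # CBG content in the ternary series
    4: ("ternary", 2),   # PBG content in the ternary series
}


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean square error, sqrt(sum((y - y_hat)^2) / n)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("y and y_hat must be nonempty and of equal length")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def r_metric(y: np.ndarray, y_hat: np.ndarray) -> float:
    """1 - SSE/SST (implemented exactly as printed; see module docstring)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("r is undefined for constant reference values")
    return float(1.0 - np.sum((y_hat - y) ** 2) / sst)


def rpd(std_train_reference: float, rmse_p: float) -> float:
    """Residual prediction deviation: train-reference Std. over RMSE_p."""
    if rmse_p == 0.0:
        logger.warning("RPD: zero prediction RMSE, returning inf")
        return float("inf")
    return float(std_train_reference / rmse_p)


def rer(max_ref: float, min_ref: float, rmse_t: float) -> float:
    """Range error ratio: (Max - Min) of the reference values over RMSE_t."""
    if not max_ref > min_ref:
        raise ValueError("degenerate reference range (max <= min)")
    if rmse_t == 0.0:
        logger.warning("RER: zero training RMSE, returning inf")
        return float("inf")
    return float((max_ref - min_ref) / rmse_t)


def rpd_flag(value: float) -> str:
    if value >= 5:
        return "quality control"
    if value >= 3:
        return "satisfactory"
    if value >= 2:
        return "screening"
    return "poor"


def rer_flag(value: float) -> str:
    return "good predictive ability" if value > 10 else "insufficient"


@dataclass
class RegressionMetrics:
    """RMSE/r/RPD/RER bundle for one fitted quantification model; RMSEs are
    in adulteration-% units."""

    rmse_t: float
    rmse_p: float
    r_t: float
    r_p: float
    rpd: float
    rer: float
    n_train: int
    n_test: int
    rpd_quality: str = field(init=False)
    rer_quality: str = field(init=False)

    def __post_init__(self) -> None:
        self.rpd_quality = rpd_flag(self.rpd)
        self.rer_quality = rer_flag(self.rer)


def evaluate_regression(
    y_train: np.ndarray,
    yhat_train: np.ndarray,
    y_test: np.ndarray,
    yhat_test: np.ndarray,
) -> RegressionMetrics:
    """Assemble the full metric bundle from train/test actual-vs-predicted."""
    y_train = np.asarray(y_train, dtype=float)
    rmse_t = rmse(y_train, yhat_train)
    rmse_p = rmse(y_test, yhat_test)
    return RegressionMetrics(
        rmse_t=rmse_t,
        rmse_p=rmse_p,
        r_t=r_metric(y_train, yhat_train),
        r_p=r_metric(y_test, yhat_test),
        rpd=rpd(float(np.std(y_train, ddof=1)), rmse_p),
        rer=rer(float(y_train.max()), float(y_train.min()), rmse_t),
        n_train=int(y_train.size),
        n_test=int(np.asarray(y_test).size),
    )


@dataclass
class TaskReport:
    task_id: int
    preprocess_method: str
    selection: SelectionResult
    model: ELMModel
    n_hidden: int
    metrics: RegressionMetrics
    split: SplitIndices
    y_train: np.ndarray
    yhat_train: np.ndarray
    y_test: np.ndarray
    yhat_test: np.ndarray


def task_subset(spectra: SpectraSet, task_id: int) -> tuple[SpectraSet, np.ndarray]:
    """The task's source samples and its response (adulterant mass %, so
    10-50 for the binary tasks and 5-25 for the ternary ones)."""
    if task_id not in QUANT_TASKS:
        raise ValueError(f"unknown task id {task_id}")
    cls, col = QUANT_TASKS[task_id]
    mask = np.where(spectra.class_labels == cls)[0]
    if mask.size == 0:
        raise ValueError(f"no samples of class {cls!r}")
    sub = spectra.subset(mask)
    y = sub.fractions[:, col] * 100.0
    return sub, y


def run_elmr_task(
    task_id: int,
    spectra: SpectraSet,
    preprocess_method: str = "msc",
    cars_params: dict | None = None,
    neuron_range: tuple[int, int] = (1, 50),
    seed: int = 0,
    split: SplitIndices | None = None,
    selection: SelectionResult | None = None,
) -> TaskReport:
    """One quantification task end to end.

    Pipeline: per-level Kennard-Stone 1/3 hold-out -> pretreatment fitted on
    the training half -> CARS on training -> column standardization of the
    selected variables (training statistics) -> sine-activation ELM
    regression swept over the hidden-neuron range, winner by test RMSE ->
    full metric bundle.  ``selection`` may be supplied to reuse another
    task's variables (the binary tasks' selections can seed the ternary
    ones).
    """
    sub, y = task_subset(spectra, task_id)
    if split is None:
        split = kennard_stone_split(sub.absorbance, y, test_fraction=1 / 3)
    tr, te = split.train_idx, split.test_idx

    spacing = float(np.mean(np.diff(sub.wavenumbers)))
    prep = pp.fit(preprocess_method, sub.absorbance[tr], spacing=spacing)
    Xtr = pp.apply(prep, sub.absorbance[tr])
    Xte = pp.apply(prep, sub.absorbance[te])

    if selection is None:
        cars_params = dict(cars_params or {})
        cars_seed = cars_params.pop("rng", None)
        if cars_seed is None:
            cars_seed = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(task_id, 101))
            )
        selection = cars_select(Xtr, y[tr], rng=cars_seed, **cars_params)
    sel = selection.selected
    Xtr_s, Xte_s = Xtr[:, sel], Xte[:, sel]

    # column-standardize with training statistics, then scale by 1/sqrt(d) so
    # the random-projection arguments stay O(1) regardless of how many
    # variables CARS kept (sine would otherwise alias at high dimension)
    mu = Xtr_s.mean(axis=0)
    sd = Xtr_s.std(axis=0, ddof=1)
    sd[sd < 1e-12] = 1.0
    scale = sd * np.sqrt(sel.size)
    Ztr, Zte = (Xtr_s - mu) / scale, (Xte_s - mu) / scale

    best = None
    for nh in range(neuron_range[0], neuron_range[1] + 1):
        cell_seed = np.random.SeedSequence(entropy=seed, spawn_key=(task_id, nh))
        model = elm_train(Ztr, y[tr], nh, activation="sine", seed=cell_seed)
        pred_te = elm_predict(model, Zte)
        err = rmse(y[te], pred_te)
        if best is None or err < best[0]:
            best = (err, nh, model)
    _, n_hidden, model = best
    yhat_tr = elm_predict(model, Ztr)
    yhat_te = elm_predict(model, Zte)
    metrics = evaluate_regression(y[tr], yhat_tr, y[te], yhat_te)
    return TaskReport(
        task_id=task_id,
        preprocess_method=preprocess_method,
        selection=selection,
        model=model,
        n_hidden=n_hidden,
        metrics=metrics,
        split=split,
        y_train=y[tr],
        yhat_train=yhat_tr,
        y_test=y[te],
        yhat_test=yhat_te,
    )
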