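"""The two headline experiments.

``run_identification`` compares the six pretreatments (each paired with
SWDA variable screening, PCA to three components, and Fisher LDA), then
sweeps an ELM over the best pretreatment's representation.

``run_quantification`` runs the four adulteration-level regression tasks
over a pretreatment x CARS grid and keeps the best model per task.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import preprocess as pp
from .classify import (
    DiscriminantModel,
    ELMModel,
    SweepEntry,
    accuracy,
    fisher_lda_fit,
    fisher_lda_predict,
    pca_fit,
    pca_transform,
    sweep_elm,
)
from .regress import TaskReport, run_elmr_task
from .select import SelectionResult, swda_select
from .split import SplitIndices, stratified_ks_split
from .synth import CLASS_LABELS, SpectraSet

logger = logging.getLogger(__name__)

QUANT_METHODS = ("centralization", "first_derivative", "second_derivative", "msc", "snv")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31) from a stage name."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class GridRow:
    method: str
    n_selected: int
    train_accuracy: float
    test_accuracy: float


@dataclass
class IdentificationReport:
    grid: list[GridRow]
    best_method: str
    split: SplitIndices
    selections: dict[str, SelectionResult]
    lda_model: DiscriminantModel
    df_coefficients: np.ndarray
    confusion_train: np.ndarray
    confusion_test: np.ndarray
    elm_curve: list[SweepEntry]
    elm_best: SweepEntry
    elm_model: ELMModel
    elm_confusion_test: np.ndarray
    classes: np.ndarray


def _lda_for_method(
    spectra: SpectraSet,
    split: SplitIndices,
    method: str,
    swda_params: dict,
):
    """Preprocess -> SWDA -> PCA(3) -> Fisher LDA for one pretreatment."""
    tr, te = split.train_idx, split.test_idx
    spacing = float(np.mean(np.diff(spectra.wavenumbers)))
    prep = pp.fit(method, spectra.absorbance[tr], spacing=spacing)
    Xtr = pp.apply(prep, spectra.absorbance[tr])
    Xte = pp.apply(prep, spectra.absorbance[te])
    sel = swda_select(Xtr, spectra.class_labels[tr], **swda_params)
    pca = pca_fit(Xtr[:, sel.selected], n_components=3)
    Str = pca_transform(pca, Xtr[:, sel.selected])
    Ste = pca_transform(pca, Xte[:, sel.selected])
    lda = fisher_lda_fit(Str, spectra.class_labels[tr])
    rep_tr = accuracy(spectra.class_labels[tr], fisher_lda_predict(lda, Str),
                      np.array(CLASS_LABELS))
    rep_te = accuracy(spectra.class_labels[te], fisher_lda_predict(lda, Ste),
                      np.array(CLASS_LABELS))
    return sel, pca, Str, Ste, lda, rep_tr, rep_te


def run_identification(
    spectra: SpectraSet,
    seed: int = 0,
    methods: tuple[str, ...] = pp.METHOD_ORDER,
    swda_params: dict | None = None,
    neuron_range: tuple[int, int] = (1, 50),
) -> IdentificationReport:
    swda_params = swda_params or {}
    split = stratified_ks_split(spectra)
    grid: list[GridRow] = []
    selections: dict[str, SelectionResult] = {}
    per_method = {}
    for method in methods:
        t0 = time.perf_counter()
        try:
            out = _lda_for_method(spectra, split, method, swda_params)
        except Exception as exc:
            raise RuntimeError(f"identification stage failed at method {method!r}") from exc
        sel, pca, Str, Ste, lda, rep_tr, rep_te = out
        selections[method] = sel
        per_method[method] = out
        grid.append(
            GridRow(
                method=method,
                n_selected=int(sel.selected.size),
                train_accuracy=rep_tr.accuracy_pct,
                test_accuracy=rep_te.accuracy_pct,
            )
        )
        logger.info(
            "identify/%s: %d vars, train %.2f%%, test %.2f%% (%.1fs)",
            method, sel.selected.size, rep_tr.accuracy_pct, rep_te.accuracy_pct,
            time.perf_counter() - t0,
        )

    best_method = max(grid, key=lambda r: r.test_accuracy).method
    sel, pca, Str, Ste, lda, rep_tr, rep_te = per_method[best_method]
    curve, best_entry, best_model = sweep_elm(
        Str, spectra.class_labels[split.train_idx],
        Ste, spectra.class_labels[split.test_idx],
        np.array(CLASS_LABELS),
        neuron_range=neuron_range,
        seed=stage_seed(seed, "elm_sweep"),
    )
    from .classify import elm_decode  # local to avoid cycle at import time

    classes = np.array(CLASS_LABELS)
    pred_te = classes[(elm_decode(best_model, Ste) - 1).astype(int)]
    elm_conf = accuracy(spectra.class_labels[split.test_idx], pred_te, classes).confusion
    return IdentificationReport(
        grid=grid,
        best_method=best_method,
        split=split,
        selections=selections,
        lda_model=lda,
        df_coefficients=lda.coef,
        confusion_train=rep_tr.confusion,
        confusion_test=rep_te.confusion,
        elm_curve=curve,
        elm_best=best_entry,
        elm_model=best_model,
        elm_confusion_test=elm_conf,
        classes=classes,
    )


def run_quantification(
    spectra: SpectraSet,
    seed: int = 0,
    methods: tuple[str, ...] = QUANT_METHODS,
    tasks: tuple[int, ...] = (1, 2, 3, 4),
    cars_params: dict | None = None,
    neuron_range: tuple[int, int] = (1, 50),
) -> dict[int, TaskReport]:
    """Run each quantification task over the pretreatment grid and keep the
    best report per task (lowest prediction RMSE).  Tasks 3 and 4 also try
    the binary tasks' selected variables, keeping whichever wins."""
    reports: dict[int, TaskReport] = {}
    for task_id in tasks:
        best: TaskReport | None = None
        for method in methods:
            rep = run_elmr_task(
                task_id, spectra, preprocess_method=method,
                cars_params=cars_params, neuron_range=neuron_range,
                seed=stage_seed(seed, f"quant_t{task_id}_{method}"),
            )
            if best is None or rep.metrics.rmse_p < best.metrics.rmse_p:
                best = rep
        # inherit the paired binary task's selection for the ternary tasks
        paired = {3: 1, 4: 2}.get(task_id)
        if paired is not None and paired in reports:
            rep = run_elmr_task(
                task_id, spectra,
                preprocess_method=reports[paired].preprocess_method,
                selection=reports[paired].selection,
                neuron_range=neuron_range,
                seed=stage_seed(seed, f"quant_t{task_id}_inherit"),
            )
            if rep.metrics.rmse_p < best.metrics.rmse_p:
                best = rep
        logger.info(
            "quantify/task %d: %s, %d vars, RMSE_p %.3f, r_p %.4f",
            task_id, best.preprocess_method, best.selection.selected.size,
            best.metrics.rmse_p, best.metrics.r_p,
        )
        reports[task_id] = best
    return reports
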