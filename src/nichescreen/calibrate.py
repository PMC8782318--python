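"""Model calibration and the final model run.

The retained predictors are swept over a grid of feature-class settings
(L, LQ, H, LQH, LQHP) × regularization multipliers (0.5–4.0 in steps of
0.5).  Each cell is a single full-data fit; its AICc is computed from the
presence likelihood under the model's raw distribution normalized over the
background sample, with k = the number of nonzero coefficients and n = the
number of presences.  The cell with the lowest AICc wins (ties: fewer
parameters, then lower RM, then feature-class order); the winning settings
give the final model, suitability map and evaluation metrics.

Calibration fits use no cross-validation replicates so that k and lnL are
well-defined for a single model; replicate CV remains the screening
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import maxent, metrics
from .rasters_io import GridSpec, Layer, OccurrenceSet, PredictorCollection, extract

logger = logging.getLogger(__name__)

DEFAULT_FEATURE_CLASSES = ("L", "LQ", "H", "LQH", "LQHP")
DEFAULT_RMS = tuple(np.arange(0.5, 4.01, 0.5))


class CalibrationError(RuntimeError):
    """All candidate cells inadmissible (too few presences for any model)."""


def aicc(ln_likelihood: float, k: int, n: int) -> float:
    """AICc = 2k − 2lnL + 2k(k+1)/(n−k−1); +inf when n ≤ k+1."""
    if n <= k + 1:
        return float("inf")
    return 2 * k - 2 * ln_likelihood + 2 * k * (k + 1) / (n - k - 1)


def model_likelihood(
    model: maxent.NicheModel,
    presence_cov: np.ndarray,
    background_cov: np.ndarray,
) -> float:
    """Presence log-likelihood under raw output normalized over background.

    lnL = Σ_presences [η(x) − log Σ_background e^η]; presences with missing
    covariates are excluded and logged.
    """
    presence_cov = np.atleast_2d(np.asarray(presence_cov, dtype=float))
    ok = ~np.isnan(presence_cov).any(axis=1)
    if (~ok).any():
        logger.info("model_likelihood: excluded %d presences on nodata", int((~ok).sum()))
    background_cov = np.asarray(background_cov, dtype=float)
    bg_ok = ~np.isnan(background_cov).any(axis=1)
    log_z = float(logsumexp(model.eta(background_cov[bg_ok])))
    eta_p = model.eta(presence_cov[ok])
    return float((eta_p - log_z).sum())


@dataclass
class CalibrationCell:
    fc: str
    rm: float
    aicc: float
    k_params: int
    ln_likelihood: float
    train_auc: float
    model: maxent.NicheModel | None = None


@dataclass
class CalibrationResult:
    grid: list[CalibrationCell]
    best: CalibrationCell
    final_model: maxent.NicheModel
    final_map: Layer | None = None
    final_metrics: metrics.EvalMetrics | None = None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fc\trm\tk\tlnL\taicc\tauc\n")
            for cell in self.grid:
                fh.write(
                    f"{cell.fc}\t{cell.rm:g}\t{cell.k_params}\t"
                    f"{cell.ln_likelihood:.6f}\t{cell.aicc:.6f}\t{cell.train_auc:.6f}\n"
                )


def select_best(
    grid: list[CalibrationCell],
    feature_classes: Sequence[str] = DEFAULT_FEATURE_CLASSES,
) -> CalibrationCell:
    """Minimum-AICc cell; ties -> fewer parameters, lower RM, FC order."""
    fc_order = {fc: i for i, fc in enumerate(feature_classes)}
    admissible = [c for c in grid if np.isfinite(c.aicc)]
    if not admissible:
        raise CalibrationError(
            "every candidate model is inadmissible (n ≤ k+1); "
            "use more presences or simpler feature classes"
        )
    return min(
        admissible,
        key=lambda c: (c.aicc, c.k_params, c.rm, fc_order.get(c.fc, len(fc_order))),
    )


def predict_map(
    model: maxent.NicheModel,
    collection: PredictorCollection,
    output: str = "logistic",
    name: str = "suitability",
) -> Layer:
    """Suitability surface over the collection grid.

    Cells that are nodata in any of the model's input variables are nodata
    in the output.
    """
    grid = collection.grid
    n_cells = grid.n_rows * grid.n_cols
    raw = np.empty((n_cells, len(model.variables)))
    for j, v in enumerate(model.variables):
        raw[:, j] = collection.layer(v).values.filled(np.nan).ravel()
    suit = maxent.predict_logistic(model, raw, output=output)
    values = np.ma.masked_invalid(suit.reshape(grid.n_rows, grid.n_cols))
    out_grid = GridSpec(
        n_rows=grid.n_rows, n_cols=grid.n_cols,
        x_origin=grid.x_origin, y_origin=grid.y_origin,
        cell_size=grid.cell_size, nodata_value=grid.nodata_value,
        crs_tag=grid.crs_tag,
    )
    return Layer(name=name, grid=out_grid, values=values)


def calibrate(
    occurrences: OccurrenceSet,
    retained_variables: list[str],
    collection: PredictorCollection,
    engine_config: maxent.EngineConfig | None = None,
    background: np.ndarray | None = None,
    feature_classes: Sequence[str] = DEFAULT_FEATURE_CLASSES,
    rms: Sequence[float] = DEFAULT_RMS,
    make_map: bool = True,
) -> CalibrationResult:
    """Sweep FC × RM, pick minimum AICc, fit and evaluate the final model.

    One background sample (seeded from the engine config) is shared by
    every cell so that AICc values are comparable across the grid.
    """
    from .rasters_io import sample_background

    engine_config = engine_config or maxent.EngineConfig()
    if background is None:
        background = sample_background(
            collection, engine_config.n_background, engine_config.seed
        )
    pres_cov, pres_ok = extract(collection, retained_variables, occurrences.points)
    bg_cov, _ = extract(collection, retained_variables, background)
    pres_cov = pres_cov[pres_ok]
    n_pres = pres_cov.shape[0]

    cells: list[CalibrationCell] = []
    for fc in feature_classes:
        for rm in rms:
            cfg = replace(engine_config.with_fc(fc), rm=float(rm), n_replicates=1)
            try:
                model = maxent.fit(pres_cov, bg_cov, cfg, variables=retained_variables)
            except (maxent.ConvergenceError, maxent.DegenerateDataError) as exc:
                logger.warning("calibration cell (%s, %.1f) failed: %s", fc, rm, exc)
                cells.append(
                    CalibrationCell(fc, float(rm), float("inf"), 0, float("-inf"), float("nan"))
                )
                continue
            lnl = model_likelihood(model, pres_cov, bg_cov)
            cells.append(
                CalibrationCell(
                    fc=fc, rm=float(rm),
                    aicc=aicc(lnl, model.k_params, n_pres),
                    k_params=model.k_params,
                    ln_likelihood=lnl,
                    train_auc=model.training_auc,
                    model=model,
                )
            )
    best = select_best(cells, feature_classes)
    final_model = best.model
    assert final_model is not None
    final_model.permutation_importance = maxent.permutation_importance(
        final_model, pres_cov, bg_cov, seed=engine_config.seed
    )

    pres_scores = maxent.predict_logistic(final_model, pres_cov)
    bg_scores = maxent.predict_logistic(final_model, bg_cov)
    final_metrics = metrics.confusion_metrics(pres_scores, bg_scores)
    final_map = predict_map(final_model, collection) if make_map else None
    logger.info(
        "calibration best: FC=%s RM=%.1f (k=%d, AICc=%.2f, AUC=%.3f)",
        best.fc, best.rm, best.k_params, best.aicc, final_metrics.auc,
    )
    return CalibrationResult(
        grid=cells, best=best, final_model=final_model,
        final_map=final_map, final_metrics=final_metrics,
    )
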