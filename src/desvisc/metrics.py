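"""Fit statistics and leave-one-system-out cross-validation.

All metrics are computed on log10 viscosity, the scale the model is
trained and reported on:

* R^2 = 1 - SS_res / SS_tot about the mean experimental log eta,
* RMSE = sqrt(mean squared residual) in log10 units,
* AARD = (100/n) * sum |residual / log eta_exp| in percent.

AARD divides by the experimental log viscosity, which vanishes at
eta = 1 mPa*s; points with |log eta_exp| below a small epsilon are
excluded from the AARD sum and counted loudly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import AnnModel, TrainingConfig, train

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "CvReport",
    "compute_metrics",
    "residual_summary",
    "evaluate_model",
    "loso_cv",
]


@dataclass
class MetricsReport:
    """R^2 / RMSE / AARD plus the per-record residuals (calc - exp)."""

    r_squared: float
    rmse: float
    aard_percent: float
    n: int
    residuals: np.ndarray
    n_aard_excluded: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["residuals"] = np.asarray(self.residuals).tolist()
        return d


def compute_metrics(
    log_pred: np.ndarray, log_exp: np.ndarray, aard_eps: float = 1e-9
) -> MetricsReport:
    """Compare predicted against experimental log10 viscosities.

    ``r_squared`` is NaN when the experimental vector is constant
    (SS_tot = 0 leaves the coefficient undefined).
    """
    log_pred = np.asarray(log_pred, dtype=float).ravel()
    log_exp = np.asarray(log_exp, dtype=float).ravel()
    if log_pred.shape != log_exp.shape:
        raise ValidationError("prediction and experiment lengths differ")
    n = log_exp.size
    if n < 2:
        raise ValidationError("at least two points required")
    residuals = log_pred - log_exp
    ss_res = float(residuals @ residuals)
    centered = log_exp - log_exp.mean()
    ss_tot = float(centered @ centered)
    if ss_tot < 1e-30:
        logger.warning("constant experimental vector: R^2 undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / n))
    usable = np.abs(log_exp) > aard_eps
    n_excluded = int(n - usable.sum())
    if n_excluded:
        logger.warning(
            "AARD: excluded %d point(s) with |log eta_exp| <= %g "
            "(division by ~0 at eta ~ 1 mPa*s)",
            n_excluded,
            aard_eps,
        )
    if usable.any():
        aard = float(
            100.0 * np.mean(np.abs(residuals[usable] / log_exp[usable]))
        )
    else:
        aard = float("nan")
    return MetricsReport(
        r_squared=r2,
        rmse=rmse,
        aard_percent=aard,
        n=n,
        residuals=residuals,
        n_aard_excluded=n_excluded,
    )


def residual_summary(report: MetricsReport, band: float = 0.05) -> float:
    """Fraction of residuals inside the closed band |r| <= band."""
    r = np.asarray(report.residuals)
    return float(np.count_nonzero(np.abs(r) <= band) / r.size)


def evaluate_model(model: AnnModel, dataset, split: str | None = None) -> MetricsReport:
    """Metrics of a trained model on one split (or the whole dataset)."""
    X, y = dataset.design(split)
    pred = model.forward(X, warn_extrapolation=False)
    return compute_metrics(pred, y)


@dataclass
class CvReport:
    """Leave-one-system-out summary: per-system held-out R^2 and their
    unweighted mean Q^2."""

    systems: list[str]
    per_system_r2: dict[str, float]
    q_squared: float
    excluded: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "system_id": self.systems,
                "r_squared": [self.per_system_r2[s] for s in self.systems],
            }
        )


def loso_cv(
    dataset, layer_sizes, config: TrainingConfig | None = None
) -> CvReport:
    """Hold out one system at a time, retrain on the rest, score R^2 on
    the held-out system; Q^2 is the unweighted mean over systems.

    Cross-validating whole systems rather than random points probes the
    descriptors: the held-out composition is genuinely unseen.  Systems
    with fewer than two records or a constant response cannot carry an
    R^2 and are excluded with a warning.
    """
    if config is None:
        config = TrainingConfig()
    if dataset.features is None:
        raise ValidationError("dataset needs an attached feature matrix")
    ids = dataset.system_ids
    y_all = dataset.log_viscosity
    unique = list(dict.fromkeys(ids))  # first-appearance order
    per_system: dict[str, float] = {}
    excluded: list[str] = []
    for system in unique:
        held = ids == system
        y_held = y_all[held]
        if held.sum() < 2 or np.ptp(y_held) < 1e-12:
            warnings.warn(
                f"system {system}: fewer than 2 records or constant "
                "response; R^2 undefined, excluded from Q^2",
                stacklevel=2,
            )
            excluded.append(system)
            continue
        X_tr = dataset.features[~held]
        y_tr = y_all[~held]
        model = train((X_tr, y_tr), layer_sizes, config)
        pred = model.forward(dataset.features[held], warn_extrapolation=False)
        per_system[system] = compute_metrics(pred, y_held).r_squared
    if not per_system:
        raise ValidationError("no system with enough records for LOSO CV")
    systems = list(per_system)
    q2 = float(np.mean([per_system[s] for s in systems]))
    return CvReport(
        systems=systems, per_system_r2=per_system, q_squared=q2,
        excluded=excluded,
    )
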