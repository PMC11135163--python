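"""Williams-plot applicability domain.

The reliability region of the model is bounded by the leverage of a
query relative to the training design and by the standardized residual:

* leverage ``h_i = v_i (V^T V)^-1 v_i^T`` with ``V`` the p x d* matrix of
  scaled training features (d* = 9 inputs, no intercept column),
* critical leverage ``h* = 3 (d* + 1) / p``,
* standardized residual ``SDR_i = r_i / s`` with ``s`` the standard
  deviation of the training residuals,
* a point is inside the domain when ``0 < h_i < h*`` and ``|SDR_i| < 3``;
  coverage is the percentage of all points inside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import AnnModel

__all__ = [
    "AdReport",
    "leverages",
    "critical_leverage",
    "standardized_residuals",
    "williams_report",
    "plot_williams",
]

FLAGS = ("inside", "leverage_outlier", "response_outlier", "both")


def leverages(V: np.ndarray, queries: np.ndarray | None = None) -> np.ndarray:
    """Hat-matrix diagonal entries of ``queries`` with respect to the
    training design ``V`` (rows = points, columns = the d* model inputs,
    already scaled like the model's).

    With ``queries=None`` the training self-leverages are returned; their
    sum equals the column rank of ``V``.  Query points outside the
    training cloud may exceed the [0, 1] range of training leverages.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    Q = V if queries is None else np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != V.shape[1]:
        raise ValidationError("query feature width differs from training design")
    G = V.T @ V
    rank = np.linalg.matrix_rank(V)
    if rank < V.shape[1]:
        warnings.warn(
            f"rank-deficient training design (rank {rank} < {V.shape[1]}); "
            "using pseudo-inverse",
            stacklevel=2,
        )
        Ginv = np.linalg.pinv(G)
    else:
        Ginv = np.linalg.inv(G)
    return np.einsum("ij,jk,ik->i", Q, Ginv, Q)


def critical_leverage(d_star: int, p: int, factor: float = 3.0) -> float:
    """Williams-plot cutoff ``h* = factor * (d* + 1) / p`` (factor 3 is
    the conventional rule)."""
    if p <= d_star:
        raise ValidationError(
            f"need more training points ({p}) than inputs ({d_star})"
        )
    return factor * (d_star + 1) / p


def standardized_residuals(
    residuals: np.ndarray, reference_residuals: np.ndarray
) -> np.ndarray:
    """Residuals divided by the sample standard deviation of the
    reference (training) residuals."""
    reference = np.asarray(reference_residuals, dtype=float)
    if reference.size < 2:
        raise ValidationError("reference residual set too small")
    s = float(np.std(reference, ddof=1))
    if s < 1e-15:
        raise ValidationError(
            "zero spread in reference residuals (degenerate perfect fit)"
        )
    return np.asarray(residuals, dtype=float) / s


@dataclass
class AdReport:
    """Per-point leverage, SDR and domain flag, plus the coverage."""

    h: np.ndarray
    h_star: float
    sdr: np.ndarray
    flags: np.ndarray  # one of FLAGS per point
    coverage_percent: float
    split: np.ndarray | None = None

    @property
    def n_inside(self) -> int:
        return int(np.count_nonzero(self.flags == "inside"))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"h": self.h, "sdr": self.sdr, "flag": self.flags}
        )
        if self.split is not None:
            df["split"] = self.split
        df.attrs["h_star"] = self.h_star
        return df


def williams_report(
    model: AnnModel,
    dataset,
    sdr_bound: float = 3.0,
    leverage_factor: float = 3.0,
) -> AdReport:
    """Flag every record of the dataset by the two domain boundaries.

    The training split defines the leverage design and the residual
    scale; coverage is computed over *all* records (training, testing and
    external alike).
    """
    if dataset.features is None:
        raise ValidationError("dataset needs an attached feature matrix")
    X = dataset.features
    y = dataset.log_viscosity
    U = model.scale_inputs(X, warn=False)
    train_mask = dataset.mask("train")
    if not np.any(train_mask):
        train_mask = np.ones(len(dataset), dtype=bool)
    V = U[train_mask]
    h = leverages(V, U)
    h_star = critical_leverage(V.shape[1], V.shape[0], factor=leverage_factor)
    pred = model.forward(X, warn_extrapolation=False)
    residuals = pred - y
    sdr = standardized_residuals(residuals, residuals[train_mask])
    lev_out = h >= h_star
    resp_out = np.abs(sdr) >= sdr_bound
    flags = np.where(
        lev_out & resp_out,
        "both",
        np.where(lev_out, "leverage_outlier",
                 np.where(resp_out, "response_outlier", "inside")),
    )
    coverage = 100.0 * np.count_nonzero(flags == "inside") / len(flags)
    return AdReport(
        h=h,
        h_star=h_star,
        sdr=sdr,
        flags=flags,
        coverage_percent=float(coverage),
        split=dataset.splits,
    )


def plot_williams(report: AdReport, path: str, sdr_bound: float = 3.0):
    """Render the Williams plot (leverage vs standardized residual)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    groups = (
        report.split if report.split is not None
        else np.full(len(report.h), "")
    )
    for label in np.unique(groups):
        m = groups == label
        ax.scatter(report.h[m], report.sdr[m], s=12, alpha=0.6,
                   label=label or "all")
    ax.axvline(report.h_star, ls="--", c="k", lw=1)
    ax.axhline(sdr_bound, ls="--", c="k", lw=1)
    ax.axhline(-sdr_bound, ls="--", c="k", lw=1)
    ax.set_xlabel("leverage $h_i$")
    ax.set_ylabel("standardized residual")
    ax.set_title(f"Williams plot (coverage {report.coverage_percent:.2f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
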