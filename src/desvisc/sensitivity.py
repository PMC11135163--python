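"""Partial-derivatives (PaD) input-contribution analysis.

The influence of each input on the predicted log viscosity is measured
by the exact gradient of the network output with respect to that input,
obtained by the chain rule through the affine scalers and the tanh
layers (tanh' = 1 - tanh^2).  Relative contributions aggregate the
squared *scaled* gradients over a dataset:

    C_j = 100 * sum_i g_ij^2 / sum_{k in subset} sum_i g_ik^2

Working on the scaled gradients makes the ranking independent of the
physical units of each input; by default the subset is S1..S8 so the
molecular descriptors are compared among themselves, with the
temperature input available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .network import FEATURE_NAMES, AnnModel, input_gradients_scaled

__all__ = ["ContributionReport", "gradients", "relative_contributions"]


def gradients(
    model: AnnModel, X: np.ndarray, scaled: bool = False
) -> np.ndarray:
    """Per-point gradients d(log eta)/dx_j for every model input.

    With ``scaled=False`` (default) the derivatives are expressed on the
    unscaled, physical input scale; with ``scaled=True`` they are
    d(y_scaled)/d(u_scaled), the quantity the contribution analysis uses.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    U = model.scale_inputs(X, warn=False)
    g = input_gradients_scaled(model, U)
    if scaled:
        return g
    in_span = model.input_max - model.input_min
    out_span = model.output_max - model.output_min
    # du/dx = 2/in_span, dy/dy_scaled = out_span/2
    return g * (out_span / in_span)


@dataclass
class ContributionReport:
    """Relative contributions (%) over the reported input subset."""

    inputs: list[str]
    contributions_percent: np.ndarray
    gradients: np.ndarray  # per-point derivatives on the unscaled scale,
    # all 9 inputs, for export/inspection

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "input": self.inputs,
                "contribution_percent": self.contributions_percent,
            }
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.inputs, self.contributions_percent.tolist()))

    def gradient_frame(self) -> pd.DataFrame:
        """Per-point derivative table, one column per model input."""
        return pd.DataFrame(
            self.gradients,
            columns=[f"d_logeta_d{n}" for n in FEATURE_NAMES],
        )


def relative_contributions(
    model: AnnModel,
    data,
    subset: list[int] | None = None,
    include_temperature: bool = False,
) -> ContributionReport:
    """Squared-gradient contribution of each input over a dataset.

    ``data`` may be a feature array or a dataset object; for a dataset
    with split labels the training records are used.  The default subset
    is the eight molecular descriptors; ``include_temperature=True``
    normalizes over all nine inputs instead.
    """
    if hasattr(data, "design"):
        if np.any(data.mask("train")):
            X, _ = data.design("train")
        else:
            X, _ = data.design()
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[0] == 0:
        raise ValidationError("empty dataset for contribution analysis")
    if subset is None:
        subset = list(range(9)) if include_temperature else list(range(8))
    g_scaled = gradients(model, X, scaled=True)
    sq = np.sum(g_scaled**2, axis=0)
    total = float(sq[subset].sum())
    if total <= 0.0:
        raise ValidationError(
            "all gradients vanish over the subset; contributions undefined"
        )
    contrib = 100.0 * sq[subset] / total
    names = [FEATURE_NAMES[j] for j in subset]
    return ContributionReport(
        inputs=names,
        contributions_percent=contrib,
        gradients=gradients(model, X, scaled=False),
    )
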