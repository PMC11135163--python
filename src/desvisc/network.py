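"""Feed-forward network for log10 viscosity, with Bayesian-regularized
Levenberg-Marquardt training.

Architecture
------------
Inputs are the nine descriptors ``(S1..S8, T)``, min-max scaled to
[-1, +1].  Hidden neurons compute ``tanh(W u + b)`` (so hidden activations
are always inside (-1, +1)); the output neuron is affine.  The scaled
output is mapped back to log10(eta / mPa*s) by the inverse of the target
scaler.  The reference architecture for the viscosity problem is
9-19-16-1.

Training
--------
The regularized objective is ``F = beta * E_D + alpha * E_W`` with
``E_D`` the sum of squared residuals and ``E_W`` the sum of squared
weights.  An inner Levenberg-Marquardt loop minimizes F; after each
accepted step the hyperparameters are re-estimated by the evidence
framework with the Gauss-Newton Hessian approximation
``H = 2 beta J^T J + 2 alpha I``:

    gamma = n_w - 2 alpha tr(H^-1)        (effective number of parameters)
    alpha = gamma / (2 E_W)
    beta  = (N - gamma) / (2 E_D)

A fixed-penalty variant (``algorithm="l2"``) keeps alpha and beta
constant, which is convenient for closed-form cross-checks.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    ConvergenceWarning,
    ExtrapolationWarning,
    SchemaError,
    ValidationError,
)

__all__ = [
    "AnnModel",
    "TrainingConfig",
    "GridSearchResult",
    "train",
    "grid_search",
    "save_model",
    "load_model",
    "export_weight_table",
    "import_weight_table",
    "random_model",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "T")

_SCHEMA_VERSION = 1


@dataclass
class TrainingConfig:
    """Knobs of the Levenberg-Marquardt trainer.

    algorithm : "bayesian_regularization" re-estimates (alpha, beta) by the
        evidence framework each accepted step; "l2" (alias "l2_gradient")
        keeps ``alpha`` fixed and beta = 1.
    tolerance : relative change of the data error E_D below which, after
        ``patience`` consecutive accepted steps, training stops.
    """

    algorithm: str = "bayesian_regularization"
    max_iterations: int = 300
    tolerance: float = 1e-9
    patience: int = 5
    seed: int = 0
    alpha: float = 0.0  # fixed weight penalty for algorithm="l2"
    mu_initial: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 0.1
    mu_max: float = 1e10

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValidationError("iteration budget must be positive")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.algorithm not in (
            "bayesian_regularization",
            "l2",
            "l2_gradient",
        ):
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")

    @property
    def bayesian(self) -> bool:
        return self.algorithm == "bayesian_regularization"


@dataclass
class AnnModel:
    """Trained predictor: layer sizes, weights/biases and the two scalers."""

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]  # weights[l] has shape (n_out_l, n_in_l)
    biases: list[np.ndarray]  # biases[l] has shape (n_out_l,)
    input_min: np.ndarray
    input_max: np.ndarray
    output_min: float
    output_max: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        self.layer_sizes = sizes
        if len(sizes) < 2 or sizes[-1] != 1:
            raise ValidationError(
                "layer_sizes must run from the input width to a single output"
            )
        if len(self.weights) != len(sizes) - 1 or len(self.biases) != len(sizes) - 1:
            raise ValidationError("one weight/bias pair required per layer")
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            W = np.asarray(W, dtype=float)
            b = np.asarray(b, dtype=float)
            self.weights[l] = W
            self.biases[l] = b
            if W.shape != (sizes[l + 1], sizes[l]) or b.shape != (sizes[l + 1],):
                raise ValidationError(
                    f"layer {l}: weight shape {W.shape} inconsistent with "
                    f"layer sizes {sizes}"
                )
        self.input_min = np.asarray(self.input_min, dtype=float)
        self.input_max = np.asarray(self.input_max, dtype=float)
        if self.input_min.shape != (sizes[0],) or self.input_max.shape != (sizes[0],):
            raise ValidationError("input scaler length must match input width")
        if np.any(self.input_max <= self.input_min):
            raise ValidationError("input scaler requires max > min per feature")
        if not self.output_max > self.output_min:
            raise ValidationError("output scaler requires max > min")

    # -- sizes -------------------------------------------------------------

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_parameters(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.weights, self.biases))

    # -- scaling -----------------------------------------------------------

    def scale_inputs(self, X: np.ndarray, warn: bool = True) -> np.ndarray:
        """Min-max map features onto [-1, +1] (values outside the training
        range map outside the interval and trigger an extrapolation
        warning)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValidationError(
                f"expected {self.n_inputs} features, got {X.shape[1]}"
            )
        if warn:
            outside = (X < self.input_min) | (X > self.input_max)
            if np.any(outside):
                n_rows = int(np.any(outside, axis=1).sum())
                warnings.warn(
                    f"{n_rows} query point(s) outside the training feature "
                    "range; predictions are extrapolations",
                    ExtrapolationWarning,
                    stacklevel=2,
                )
        span = self.input_max - self.input_min
        return 2.0 * (X - self.input_min) / span - 1.0

    def unscale_output(self, u: np.ndarray) -> np.ndarray:
        return (np.asarray(u) + 1.0) / 2.0 * (self.output_max - self.output_min) + self.output_min

    def scale_output(self, y: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(y) - self.output_min) / (self.output_max - self.output_min) - 1.0

    # -- evaluation --------------------------------------------------------

    def forward(self, X: np.ndarray, warn_extrapolation: bool = True) -> np.ndarray:
        """Predict log10 viscosity for unscaled feature rows."""
        U = self.scale_inputs(X, warn=warn_extrapolation)
        y_scaled = _forward_scaled(self.weights, self.biases, U)
        return self.unscale_output(y_scaled)

    def predict_viscosity(self, X: np.ndarray, warn_extrapolation: bool = True) -> np.ndarray:
        """Predict viscosity in mPa*s (10 ** log-prediction)."""
        return 10.0 ** self.forward(X, warn_extrapolation=warn_extrapolation)

    def hidden_activations(self, X: np.ndarray) -> list[np.ndarray]:
        U = self.scale_inputs(X, warn=False)
        acts = _activations(self.weights, self.biases, U)
        return acts[1:-1]


# ---------------------------------------------------------------------------
# forward / jacobian kernels (operate on scaled inputs and scaled targets)


def _activations(
    weights: Sequence[np.ndarray], biases: Sequence[np.ndarray], U: np.ndarray
) -> list[np.ndarray]:
    """Per-layer activations: [U, a_1, ..., a_{L-1}, y_scaled(n,)]."""
    acts = [U]
    a = U
    n_layers = len(weights)
    for l in range(n_layers - 1):
        a = np.tanh(a @ weights[l].T + biases[l])
        acts.append(a)
    y = a @ weights[-1].T + biases[-1]
    acts.append(y[:, 0])
    return acts


def _forward_scaled(
    weights: Sequence[np.ndarray], biases: Sequence[np.ndarray], U: np.ndarray
) -> np.ndarray:
    return _activations(weights, biases, U)[-1]


def _pack(weights: Sequence[np.ndarray], biases: Sequence[np.ndarray]) -> np.ndarray:
    return np.concatenate(
        [np.concatenate([W.ravel(), b]) for W, b in zip(weights, biases)]
    )


def _unpack(
    w: np.ndarray, layer_sizes: Sequence[int]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases, pos = [], [], 0
    for l in range(len(layer_sizes) - 1):
        n_out, n_in = layer_sizes[l + 1], layer_sizes[l]
        W = w[pos : pos + n_out * n_in].reshape(n_out, n_in)
        pos += n_out * n_in
        b = w[pos : pos + n_out]
        pos += n_out
        weights.append(W)
        biases.append(b)
    return weights, biases


def _jacobian(
    weights: Sequence[np.ndarray], biases: Sequence[np.ndarray], U: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Jacobian d y_scaled / d params (packed order) and y_scaled.

    Backpropagates the per-sample sensitivity delta_l = dy/dz_l through
    the tanh layers (tanh' = 1 - tanh^2); the parameter blocks are outer
    products delta x activation.
    """
    acts = _activations(weights, biases, U)
    n = U.shape[0]
    n_layers = len(weights)
    blocks: list[np.ndarray] = []
    delta = np.ones((n, 1))  # dy/dz at the linear output layer
    for l in range(n_layers - 1, -1, -1):
        a_in = acts[l]
        JW = (delta[:, :, None] * a_in[:, None, :]).reshape(n, -1)
        blocks.append(np.hstack([JW, delta]))
        if l > 0:
            delta = (delta @ weights[l]) * (1.0 - acts[l] ** 2)
    J = np.hstack(blocks[::-1])
    return J, acts[-1]


def input_gradients_scaled(model: AnnModel, U: np.ndarray) -> np.ndarray:
    """d y_scaled / d u (scaled inputs), one row per sample."""
    acts = _activations(model.weights, model.biases, np.atleast_2d(U))
    n = acts[0].shape[0]
    delta = np.ones((n, 1))
    for l in range(len(model.weights) - 1, 0, -1):
        delta = (delta @ model.weights[l]) * (1.0 - acts[l] ** 2)
    return delta @ model.weights[0]


# ---------------------------------------------------------------------------
# training


def _init_parameters(
    layer_sizes: Sequence[int], seed: int
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Symmetric uniform weights scaled by fan-in; zero biases."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for l in range(len(layer_sizes) - 1):
        n_out, n_in = layer_sizes[l + 1], layer_sizes[l]
        limit = 1.0 / np.sqrt(n_in)
        weights.append(rng.uniform(-limit, limit, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    return weights, biases


def _feature_scalers(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = X.min(axis=0).astype(float)
    hi = X.max(axis=0).astype(float)
    flat = hi - lo < 1e-12
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} constant feature(s); widening their scaler "
            "range by +/-0.5",
            stacklevel=2,
        )
        lo = lo.copy()
        hi = hi.copy()
        lo[flat] -= 0.5
        hi[flat] += 0.5
    return lo, hi


def _solve_spd(A: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        c = np.linalg.cholesky(A)
        z = np.linalg.solve(c, rhs)
        return np.linalg.solve(c.T, z)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, rhs, rcond=None)[0]


def _trace_inverse(H: np.ndarray) -> float:
    try:
        return float(np.trace(np.linalg.inv(H)))
    except np.linalg.LinAlgError:
        # near-singular Gauss-Newton Hessian: ridge-stabilize
        warnings.warn(
            "singular Hessian approximation; using ridge-stabilized inverse",
            stacklevel=2,
        )
        jitter = 1e-10 * max(np.trace(H) / H.shape[0], 1.0)
        return float(np.trace(np.linalg.inv(H + jitter * np.eye(H.shape[0]))))


def train(
    data: Union["object", tuple[np.ndarray, np.ndarray]],
    layer_sizes: Sequence[int],
    config: TrainingConfig | None = None,
) -> AnnModel:
    """Fit the network on the training records of a dataset (or an
    explicit ``(X, y)`` pair).

    Returns the model with the converged weights; the final alpha, beta
    and effective-parameter count gamma, the iteration count and a data
    fingerprint are stored in ``model.metadata``.  If the iteration budget
    is exhausted before the tolerance is met the model carries
    ``metadata["converged"] = False`` and a :class:`ConvergenceWarning`
    is emitted.
    """
    if config is None:
        config = TrainingConfig()
    if isinstance(data, tuple):
        X, y = data
    else:
        # a Dataset: use its train split if labelled, otherwise everything
        if np.any(data.mask("train")):
            X, y = data.design("train")
        else:
            X, y = data.design()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be 2-D with one target per row")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("features and targets must be finite")
    sizes = tuple(int(s) for s in layer_sizes)
    if sizes[0] != X.shape[1]:
        raise ValidationError(
            f"layer_sizes[0] = {sizes[0]} but data has {X.shape[1]} features"
        )

    in_lo, in_hi = _feature_scalers(X)
    out_lo, out_hi = float(y.min()), float(y.max())
    if out_hi - out_lo < 1e-12:
        out_lo -= 0.5
        out_hi += 0.5
    U = 2.0 * (X - in_lo) / (in_hi - in_lo) - 1.0
    t = 2.0 * (y - out_lo) / (out_hi - out_lo) - 1.0

    weights0, biases0 = _init_parameters(sizes, config.seed)
    w = _pack(weights0, biases0)
    w, info = _levenberg_marquardt(w, U, t, sizes, config)
    weights, biases = _unpack(w, sizes)

    fingerprint = hashlib.sha1(
        X.tobytes() + y.tobytes()
    ).hexdigest()[:12]
    metadata = {
        "seed": config.seed,
        "algorithm": config.algorithm,
        "config": asdict(config),
        "data_fingerprint": fingerprint,
        "n_train": int(X.shape[0]),
        **info,
    }
    model = AnnModel(
        layer_sizes=sizes,
        weights=[W.copy() for W in weights],
        biases=[b.copy() for b in biases],
        input_min=in_lo,
        input_max=in_hi,
        output_min=out_lo,
        output_max=out_hi,
        metadata=metadata,
    )
    if not info["converged"]:
        warnings.warn(
            "training stopped on the iteration budget before reaching "
            "tolerance",
            ConvergenceWarning,
            stacklevel=2,
        )
    return model


def _levenberg_marquardt(
    w: np.ndarray,
    U: np.ndarray,
    t: np.ndarray,
    layer_sizes: tuple[int, ...],
    cfg: TrainingConfig,
) -> tuple[np.ndarray, dict]:
    n_w = w.size
    N = t.size
    eye = np.eye(n_w)
    alpha = 0.0 if cfg.bayesian else float(cfg.alpha)
    beta = 1.0
    gamma = float(n_w)

    def data_error(wvec: np.ndarray) -> float:
        Ws, bs = _unpack(wvec, layer_sizes)
        e = _forward_scaled(Ws, bs, U) - t
        return float(e @ e)

    E_D = data_error(w)
    E_W = float(w @ w)
    F = beta * E_D + alpha * E_W
    mu = cfg.mu_initial
    n_iter = 0
    converged = False
    stagnant = 0

    for n_iter in range(1, cfg.max_iterations + 1):
        Ws, bs = _unpack(w, layer_sizes)
        J, y_scaled = _jacobian(Ws, bs, U)
        e = y_scaled - t
        g = 2.0 * (beta * (J.T @ e) + alpha * w)
        if np.max(np.abs(g)) < 1e-12:
            converged = True
            break
        JtJ = J.T @ J
        A0 = 2.0 * (beta * JtJ + alpha * eye)

        accepted = False
        E_D_new = E_D
        while mu <= cfg.mu_max:
            step = _solve_spd(A0 + mu * eye, -g)
            w_new = w + step
            E_D_new = data_error(w_new)
            E_W_new = float(w_new @ w_new)
            F_new = beta * E_D_new + alpha * E_W_new
            if np.isfinite(F_new) and F_new < F:
                accepted = True
                break
            mu *= cfg.mu_increase
        if not accepted:
            converged = True  # no descent direction left at mu_max
            break

        rel_drop = abs(E_D - E_D_new) / max(E_D, 1e-300)
        w = w_new
        E_D, E_W = E_D_new, E_W_new
        mu = max(mu * cfg.mu_decrease, 1e-20)

        if cfg.bayesian:
            H = A0  # Gauss-Newton Hessian at the accepted neighborhood
            gamma = n_w - 2.0 * alpha * _trace_inverse(H)
            gamma = float(np.clip(gamma, 1e-6, min(n_w, N - 1e-6) if N > 1 else n_w))
            alpha = gamma / max(2.0 * E_W, 1e-300)
            beta = max((N - gamma), 1e-6) / max(2.0 * E_D, 1e-300)
        F = beta * E_D + alpha * E_W

        if rel_drop < cfg.tolerance:
            stagnant += 1
            if stagnant >= cfg.patience:
                converged = True
                break
        else:
            stagnant = 0

    info = {
        "alpha": float(alpha),
        "beta": float(beta),
        "gamma": float(gamma),
        "n_iterations": int(n_iter),
        "converged": bool(converged),
        "final_sse_scaled": float(E_D),
    }
    return w, info


# ---------------------------------------------------------------------------
# architecture grid search


@dataclass
class GridSearchResult:
    """Ranked architectures plus the selected compromise."""

    table: pd.DataFrame  # columns: architecture, rmse, n_parameters
    selected: tuple[int, ...]
    best_model: AnnModel


def _arch_n_parameters(sizes: Sequence[int]) -> int:
    return sum(
        sizes[l + 1] * sizes[l] + sizes[l + 1] for l in range(len(sizes) - 1)
    )


def default_layer_grid(
    n_inputs: int = 9, max_neurons: int = 25
) -> list[tuple[int, ...]]:
    """1..25 single-hidden-layer plus the 25 x 25 two-layer grid
    (625 two-layer configurations)."""
    grid: list[tuple[int, ...]] = [
        (n_inputs, h, 1) for h in range(1, max_neurons + 1)
    ]
    grid += [
        (n_inputs, h1, h2, 1)
        for h1 in range(1, max_neurons + 1)
        for h2 in range(1, max_neurons + 1)
    ]
    return grid


def grid_search(
    dataset,
    layer_grid: Sequence[Sequence[int]] | None = None,
    config: TrainingConfig | None = None,
    seeds: Sequence[int] = (0,),
    selection_rtol: float = 0.01,
) -> GridSearchResult:
    """Train every candidate architecture and rank by pooled RMSE.

    RMSE is evaluated on the combined train + test records (the external
    set stays untouched).  The selected architecture is the one with the
    fewest parameters among all candidates whose RMSE is within
    ``selection_rtol`` of the minimum — the simplest model that achieves
    one of the lowest errors.
    """
    if config is None:
        config = TrainingConfig()
    if layer_grid is None:
        n_in = dataset.features.shape[1]
        layer_grid = default_layer_grid(n_inputs=n_in)
    layer_grid = [tuple(int(s) for s in arch) for arch in layer_grid]
    if not layer_grid:
        raise ValidationError("empty architecture grid")

    pool_mask = dataset.mask("train") | dataset.mask("test")
    if not np.any(pool_mask):
        pool_mask = np.ones(len(dataset), dtype=bool)
    X_pool = dataset.features[pool_mask]
    y_pool = dataset.log_viscosity[pool_mask]

    rows = []
    models: dict[tuple[int, ...], AnnModel] = {}
    for arch in layer_grid:
        rmses = []
        best_for_arch: tuple[float, AnnModel] | None = None
        for seed in seeds:
            cfg = TrainingConfig(**{**asdict(config), "seed": int(seed)})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model = train(dataset, arch, cfg)
                pred = model.forward(X_pool, warn_extrapolation=False)
            rmse = float(np.sqrt(np.mean((pred - y_pool) ** 2)))
            rmses.append(rmse)
            if best_for_arch is None or rmse < best_for_arch[0]:
                best_for_arch = (rmse, model)
        models[arch] = best_for_arch[1]
        rows.append(
            {
                "architecture": arch,
                "rmse": float(np.mean(rmses)),
                "n_parameters": _arch_n_parameters(arch),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["rmse", "n_parameters"], kind="stable"
    ).reset_index(drop=True)
    best_rmse = table["rmse"].iloc[0]
    within = table[table["rmse"] <= best_rmse * (1.0 + selection_rtol)]
    selected = within.sort_values(
        ["n_parameters", "rmse"], kind="stable"
    )["architecture"].iloc[0]
    return GridSearchResult(
        table=table, selected=tuple(selected), best_model=models[tuple(selected)]
    )


# ---------------------------------------------------------------------------
# serialization


def save_model(model: AnnModel, target: Union[str, IO[str]]) -> None:
    """Write the model to a self-describing JSON document."""
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "input_min": model.input_min.tolist(),
        "input_max": model.input_max.tolist(),
        "output_min": model.output_min,
        "output_max": model.output_max,
        "metadata": _json_safe(model.metadata),
    }
    if hasattr(target, "write"):
        json.dump(doc, target)  # type: ignore[arg-type]
    else:
        with open(target, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_model(source: Union[str, IO[str]]) -> AnnModel:
    try:
        if hasattr(source, "read"):
            doc = json.load(source)  # type: ignore[arg-type]
        else:
            with open(source, "r", encoding="utf-8") as fh:
                doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not a valid model JSON document: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema_version") != _SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported model schema version "
            f"{doc.get('schema_version') if isinstance(doc, dict) else '?'}"
        )
    try:
        return AnnModel(
            layer_sizes=tuple(doc["layer_sizes"]),
            weights=[np.asarray(W, dtype=float) for W in doc["weights"]],
            biases=[np.asarray(b, dtype=float) for b in doc["biases"]],
            input_min=np.asarray(doc["input_min"], dtype=float),
            input_max=np.asarray(doc["input_max"], dtype=float),
            output_min=float(doc["output_min"]),
            output_max=float(doc["output_max"]),
            metadata=doc.get("metadata", {}),
        )
    except KeyError as exc:
        raise SchemaError(f"model JSON missing field {exc}") from exc


def export_weight_table(model: AnnModel, target: Union[str, IO[str]]) -> None:
    """Flat CSV mirroring a per-neuron weight table.

    One ``weight`` row per neuron (layer, neuron, bias, incoming weights
    w0..w_{m-1}); scaler rows carry the min/max pairs so the table alone
    reconstructs the predictor.
    """
    max_in = max(model.layer_sizes[:-1] + (2,))
    cols = ["kind", "layer", "neuron", "bias"] + [f"w{i}" for i in range(max_in)]
    rows = []
    for l, (W, b) in enumerate(zip(model.weights, model.biases)):
        for n in range(W.shape[0]):
            row = dict.fromkeys(cols, "")
            row.update(kind="weight", layer=l, neuron=n, bias=repr(float(b[n])))
            for m, wv in enumerate(W[n]):
                row[f"w{m}"] = repr(float(wv))
            rows.append(row)
    for j in range(model.n_inputs):
        row = dict.fromkeys(cols, "")
        row.update(
            kind="input_scaler", layer="", neuron=j,
            bias="", w0=repr(float(model.input_min[j])),
            w1=repr(float(model.input_max[j])),
        )
        rows.append(row)
    row = dict.fromkeys(cols, "")
    row.update(
        kind="output_scaler", layer="", neuron=0, bias="",
        w0=repr(float(model.output_min)), w1=repr(float(model.output_max)),
    )
    rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(target, index=False)


def import_weight_table(source: Union[str, IO[str]]) -> AnnModel:
    """Rebuild a model from the per-neuron CSV written by
    :func:`export_weight_table`."""
    df = pd.read_csv(source, keep_default_na=False, dtype=str)
    required = {"kind", "layer", "neuron", "bias"}
    if not required.issubset(df.columns):
        raise SchemaError("weight-table CSV missing required columns")
    wrows = df[df["kind"] == "weight"]
    if wrows.empty:
        raise SchemaError("weight-table CSV has no weight rows")
    wcols = [c for c in df.columns if c.startswith("w")]
    layers = sorted(wrows["layer"].astype(int).unique())
    weights, biases = [], []
    for l in layers:
        sub = wrows[wrows["layer"].astype(int) == l].copy()
        sub = sub.sort_values("neuron", key=lambda s: s.astype(int))
        bias = sub["bias"].astype(float).to_numpy()
        mat = []
        for _, r in sub.iterrows():
            vals = [float(r[c]) for c in wcols if r[c] != ""]
            mat.append(vals)
        widths = {len(m) for m in mat}
        if len(widths) != 1:
            raise SchemaError(f"layer {l}: inconsistent weight-row widths")
        weights.append(np.asarray(mat))
        biases.append(bias)
    in_rows = df[df["kind"] == "input_scaler"].sort_values(
        "neuron", key=lambda s: s.astype(int)
    )
    out_rows = df[df["kind"] == "output_scaler"]
    if in_rows.empty or out_rows.empty:
        raise SchemaError("weight-table CSV missing scaler rows")
    layer_sizes = tuple([weights[0].shape[1]] + [W.shape[0] for W in weights])
    return AnnModel(
        layer_sizes=layer_sizes,
        weights=weights,
        biases=biases,
        input_min=in_rows["w0"].astype(float).to_numpy(),
        input_max=in_rows["w1"].astype(float).to_numpy(),
        output_min=float(out_rows["w0"].iloc[0]),
        output_max=float(out_rows["w1"].iloc[0]),
        metadata={"source": "weight_table"},
    )


# ---------------------------------------------------------------------------
# test / example helper


def random_model(
    layer_sizes: Sequence[int],
    seed: int = 0,
    input_min: np.ndarray | None = None,
    input_max: np.ndarray | None = None,
    output_range: tuple[float, float] = (-1.0, 4.0),
    weight_scale: float = 1.0,
) -> AnnModel:
    """A randomly weighted network, handy as a teacher function in
    simulation studies."""
    sizes = tuple(int(s) for s in layer_sizes)
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for l in range(len(sizes) - 1):
        limit = weight_scale / np.sqrt(sizes[l])
        weights.append(rng.uniform(-limit, limit, size=(sizes[l + 1], sizes[l])))
        biases.append(rng.uniform(-0.2, 0.2, size=sizes[l + 1]))
    if input_min is None:
        input_min = np.full(sizes[0], -1.0)
    if input_max is None:
        input_max = np.full(sizes[0], 1.0)
    return AnnModel(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        input_min=np.asarray(input_min, dtype=float),
        input_max=np.asarray(input_max, dtype=float),
        output_min=float(output_range[0]),
        output_max=float(output_range[1]),
        metadata={"seed": seed, "random": True},
    )
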