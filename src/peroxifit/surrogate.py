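"""ANN-surrogate parametrization of the H2O2 model.

Small feed-forward regressors map the 7 physical parameters (normalized to
the unit cube) to 22 property values evaluated at fixed conditions (pure
H2O2 and a 70 wt% water-peroxide mixture at several temperatures).  A
weighted target function F measures the squared relative deviation of the
predicted properties from experimental references; the optimizer minimizes
F over the surrogate by a large uniform random search followed by a local
stochastic refinement p_try = p_start + xi .* dp with xi uniform in
[-0.5, 0.5]^7 and out-of-range proposals rejected.

Architectures span 1-3 hidden layers x {2, 4, 8, 16} neurons x
{ReLu, Sigmoid}, written "ReLu/1/8" (activation/layers/neurons).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .forcefield import PARAMETER_ORDER, ParameterRanges

__all__ = [
    "TrainingTable",
    "SurrogateModel",
    "TargetWeights",
    "PROPERTY_LAYOUT",
    "normalize",
    "denormalize",
    "train_surrogate",
    "evaluate_architectures",
    "target_function",
    "random_search",
    "local_refine",
    "ARCHITECTURE_GRID",
]

#: The 22 property/condition slots: (property, composition, temperature K).
#: Properties: rho (kg/m^3), epsilon (-), mu (cP), P_v (bar), lambda (mN/m),
#: wt_v (weight % peroxide in the vapor).  Compositions: pure H2O2 ("pure")
#: and the 70 wt% peroxide-water mixture ("mix70").
PROPERTY_LAYOUT = (
    ("rho", "pure", 273), ("rho", "pure", 293), ("rho", "pure", 313),
    ("epsilon", "pure", 273), ("epsilon", "pure", 293), ("epsilon", "pure", 313),
    ("mu", "pure", 293), ("mu", "pure", 313),
    ("P_v", "pure", 393), ("P_v", "pure", 423),
    ("lambda", "pure", 293), ("lambda", "pure", 313),
    ("rho", "mix70", 273), ("rho", "mix70", 293), ("rho", "mix70", 313),
    ("epsilon", "mix70", 293),
    ("mu", "mix70", 293),
    ("P_v", "mix70", 393), ("P_v", "mix70", 423),
    ("lambda", "mix70", 293), ("lambda", "mix70", 313),
    ("wt_v", "mix70", 393),
)

#: Experimental reference values per slot (handbook-typical defaults).
DEFAULT_REFERENCES = (
    1471.0, 1450.0, 1426.0,
    84.2, 73.0, 64.0,
    1.245, 0.94,
    0.35, 1.013,
    80.4, 76.2,
    1288.0, 1270.0, 1250.0,
    77.0,
    1.17,
    0.55, 1.70,
    77.0, 73.5,
    40.0,
)


def _slot_name(slot) -> str:
    prop, comp, T = slot
    return f"{prop}_{comp}_{T}K"


PROPERTY_NAMES = tuple(_slot_name(s) for s in PROPERTY_LAYOUT)

#: Architecture grid: activation x layers x neurons-per-layer.
ARCHITECTURE_GRID = tuple(
    f"{act}/{layers}/{n}"
    for act in ("ReLu", "Sigm")
    for layers in (1, 2, 3)
    for n in (2, 4, 8, 16)
)


def _parse_arch(arch: str):
    try:
        act, layers, n = arch.split("/")
        layers, n = int(layers), int(n)
    except ValueError as exc:
        raise ValueError(f"malformed architecture string {arch!r}") from exc
    if arch not in ARCHITECTURE_GRID:
        raise ValueError(f"architecture {arch!r} outside the supported grid")
    activation = {"ReLu": "relu", "Sigm": "logistic"}[act]
    return activation, (n,) * layers


@dataclass
class TrainingTable:
    """Rows of (7-parameter vector, 22-property vector)."""

    P: np.ndarray
    Y: np.ndarray
    ranges: ParameterRanges = field(default_factory=ParameterRanges)

    def __post_init__(self) -> None:
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.P.shape[1] != 7 or self.Y.shape[1] != len(PROPERTY_LAYOUT):
            raise ValueError("table must have 7 parameter and 22 property columns")
        if len(self.P) != len(self.Y):
            raise ValueError("parameter and property row counts differ")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("property values must be finite")
        lo, hi = self.ranges.lower(), self.ranges.upper()
        if np.any(self.P < lo - 1e-9) or np.any(self.P > hi + 1e-9):
            raise ValueError("parameters outside ParameterRanges")

    def __len__(self) -> int:
        return len(self.P)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.hstack([self.P, self.Y]), columns=list(PARAMETER_ORDER) + list(PROPERTY_NAMES)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ranges: ParameterRanges | None = None):
        cols = list(PARAMETER_ORDER) + list(PROPERTY_NAMES)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"table missing columns: {missing}")
        return cls(
            P=df[list(PARAMETER_ORDER)].to_numpy(),
            Y=df[list(PROPERTY_NAMES)].to_numpy(),
            ranges=ranges or ParameterRanges(),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, ranges: ParameterRanges | None = None):
        return cls.from_frame(pd.read_csv(path), ranges=ranges)


@dataclass(frozen=True)
class TargetWeights:
    """Eq-style weights and references: composition weight wc (1 pure, 0.25
    mixture), property weight wp (1 for rho/epsilon/P_v/lambda/wt_v, 0.5 for
    viscosity), and experimental reference x_e per slot."""

    wc: np.ndarray = field(
        default_factory=lambda: np.array(
            [1.0 if s[1] == "pure" else 0.25 for s in PROPERTY_LAYOUT]
        )
    )
    wp: np.ndarray = field(
        default_factory=lambda: np.array(
            [0.5 if s[0] == "mu" else 1.0 for s in PROPERTY_LAYOUT]
        )
    )
    x_e: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_REFERENCES))

    def __post_init__(self) -> None:
        for name in ("wc", "wp", "x_e"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.shape != (len(PROPERTY_LAYOUT),):
                raise ValueError(f"{name} must have {len(PROPERTY_LAYOUT)} entries")
        if np.any(self.wc <= 0) or np.any(self.wp <= 0):
            raise ValueError("weights must be strictly positive")
        if np.any(self.x_e == 0):
            raise ValueError("experimental references must be nonzero")


def normalize(p, ranges: ParameterRanges) -> np.ndarray:
    """Affine map of a 7-parameter vector onto the unit cube."""
    p = np.asarray(p, dtype=float)
    lo, hi = ranges.lower(), ranges.upper()
    if np.any(p < lo - 1e-12) or np.any(p > hi + 1e-12):
        bad = PARAMETER_ORDER[int(np.argmax((p < lo - 1e-12) | (p > hi + 1e-12)))]
        raise ValueError(f"parameter {bad} outside its range")
    return (p - lo) / (hi - lo)


def denormalize(u, ranges: ParameterRanges) -> np.ndarray:
    """Inverse of :func:`normalize`."""
    u = np.asarray(u, dtype=float)
    lo, hi = ranges.lower(), ranges.upper()
    return lo + u * (hi - lo)


@dataclass
class SurrogateModel:
    """A trained parameter->property regressor bound to its normalizations.

    ``predict_normalized`` maps points of the unit cube to 22 property values
    on the physical scale; output normalization is an affine map fixed by the
    training-table extrema.
    """

    arch: str
    net: MLPRegressor
    ranges: ParameterRanges
    y_min: np.ndarray
    y_max: np.ndarray
    loss_history: np.ndarray

    def predict_normalized(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        single = u.ndim == 1
        yn = self.net.predict(np.atleast_2d(u))
        y = self.y_min + yn * (self.y_max - self.y_min)
        return y[0] if single else y

    def predict(self, p) -> np.ndarray:
        """Predict properties for physical parameter vectors."""
        p = np.asarray(p, dtype=float)
        single = p.ndim == 1
        u = np.array([normalize(row, self.ranges) for row in np.atleast_2d(p)])
        out = self.predict_normalized(u)
        return out[0] if single else out

    def to_json(self, path) -> None:
        payload = {
            "arch": self.arch,
            "ranges": {n: list(getattr(self.ranges, n)) for n in PARAMETER_ORDER},
            "y_min": self.y_min.tolist(),
            "y_max": self.y_max.tolist(),
            "coefs": [w.tolist() for w in self.net.coefs_],
            "intercepts": [b.tolist() for b in self.net.intercepts_],
            "loss_history": self.loss_history.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SurrogateModel":
        with open(path) as fh:
            payload = json.load(fh)
        activation, hidden = _parse_arch(payload["arch"])
        net = MLPRegressor(hidden_layer_sizes=hidden, activation=activation)
        coefs = [np.array(w) for w in payload["coefs"]]
        intercepts = [np.array(b) for b in payload["intercepts"]]
        net.coefs_ = coefs
        net.intercepts_ = intercepts
        net.n_layers_ = len(coefs) + 1
        net.n_outputs_ = coefs[-1].shape[1]
        net.out_activation_ = "identity"
        net.n_features_in_ = coefs[0].shape[0]
        ranges = ParameterRanges(**{k: tuple(v) for k, v in payload["ranges"].items()})
        return cls(
            arch=payload["arch"],
            net=net,
            ranges=ranges,
            y_min=np.array(payload["y_min"]),
            y_max=np.array(payload["y_max"]),
            loss_history=np.array(payload["loss_history"]),
        )


def train_surrogate(
    table: TrainingTable,
    arch: str = "ReLu/1/8",
    seed: int = 0,
    max_iter: int = 1500,
    batch_size: int = 64,
    n_restarts: int = 3,
) -> SurrogateModel:
    """Train one surrogate by backpropagation on normalized inputs/outputs.

    Mini-batch adaptive-moment gradient descent with MSE loss and a plateau
    stopping rule; ``n_restarts`` seeded weight initializations are tried and
    the run with the lowest final training loss kept, so the result is
    deterministic given ``seed``.  Inputs are normalized to the unit cube by
    the parameter ranges, outputs by the training-table extrema.
    """
    if len(table) < 50:
        raise ValueError("need at least 50 training rows")
    activation, hidden = _parse_arch(arch)
    u = np.array([normalize(p, table.ranges) for p in table.P])
    y_min = table.Y.min(axis=0)
    y_max = table.Y.max(axis=0)
    span = np.where(y_max > y_min, y_max - y_min, 1.0)
    yn = (table.Y - y_min) / span
    import warnings as _w

    net = None
    for k in range(max(n_restarts, 1)):
        trial = MLPRegressor(
            hidden_layer_sizes=hidden,
            activation=activation,
            solver="adam",
            batch_size=min(batch_size, len(table)),
            learning_rate_init=0.003,
            max_iter=max_iter,
            tol=1e-9,
            n_iter_no_change=200,
            random_state=seed + 7919 * k,
            shuffle=True,
        )
        with _w.catch_warnings():
            _w.simplefilter("ignore")  # convergence warnings at max_iter are fine
            trial.fit(u, yn)
        if net is None or trial.best_loss_ < net.best_loss_:
            net = trial
    # degenerate (constant) columns keep span 0: predictions equal the constant
    return SurrogateModel(
        arch=arch,
        net=net,
        ranges=table.ranges,
        y_min=y_min,
        y_max=y_max,
        loss_history=np.array(net.loss_curve_),
    )


def evaluate_architectures(
    train: TrainingTable,
    validation: TrainingTable,
    seed: int = 0,
    archs=ARCHITECTURE_GRID,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Validation deviation of every architecture on a held-out table.

    Returns one row per architecture with the mean absolute relative
    deviation per property and overall, sorted best-first.  Warns when the
    two tables share rows.
    """
    import warnings as _w

    if len(train) and len(validation):
        joint = np.vstack([train.P, validation.P])
        if len(np.unique(joint.round(12), axis=0)) < len(joint):
            _w.warn("training and validation tables share rows")
    rows = []
    for arch in archs:
        model = train_surrogate(train, arch=arch, seed=seed, max_iter=max_iter)
        pred = model.predict(validation.P)
        rel = np.abs(pred - validation.Y) / np.abs(validation.Y)
        row = {"arch": arch, "deviation": float(rel.mean())}
        row.update({name: float(rel[:, j].mean()) for j, name in enumerate(PROPERTY_NAMES)})
        rows.append(row)
    return pd.DataFrame(rows).sort_values("deviation", ignore_index=True)


def target_function(x, weights: TargetWeights = TargetWeights()) -> float:
    """Weighted sum of squared relative deviations from experiment.

    F = sum_i wc_i wp_i ((x_i - x_ei)/x_ei)^2; zero iff every property
    matches its reference.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != weights.x_e.shape or not np.all(np.isfinite(x)):
        raise ValueError("x must be a finite 22-vector")
    rel = (x - weights.x_e) / weights.x_e
    return float(np.sum(weights.wc * weights.wp * rel**2))


def _target_batch(Y, weights: TargetWeights) -> np.ndarray:
    rel = (Y - weights.x_e) / weights.x_e
    return np.sum(weights.wc * weights.wp * rel**2, axis=1)


def random_search(
    models,
    weights: TargetWeights = TargetWeights(),
    n: int = 100_000,
    seed: int = 0,
    candidate_band: float = 0.10,
    batch: int = 20_000,
) -> dict:
    """Global random search of F over the unit cube for one or more surrogates.

    Draws ``n`` uniform points, evaluates F through each model and reports
    the per-model minimizer plus all samples whose F lies within
    ``candidate_band`` (relative) of the minimum — the local-minimum
    candidate pool.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(models, (list, tuple)):
        models = [models]
    rng = np.random.default_rng(seed)
    best = [{"F": np.inf, "u": None} for _ in models]
    candidates = [[] for _ in models]
    remaining = n
    while remaining > 0:
        m = min(batch, remaining)
        u = rng.random((m, 7))
        for i, model in enumerate(models):
            f = _target_batch(model.predict_normalized(u), weights)
            j = int(np.argmin(f))
            if f[j] < best[i]["F"]:
                best[i] = {"F": float(f[j]), "u": u[j].copy()}
            thr = best[i]["F"] * (1.0 + candidate_band) + 1e-300
            candidates[i].append(u[f <= thr])
        remaining -= m
    out = []
    for i, model in enumerate(models):
        thr = best[i]["F"] * (1.0 + candidate_band) + 1e-300
        cand = np.vstack(candidates[i]) if candidates[i] else np.empty((0, 7))
        cand = cand[_target_batch(model.predict_normalized(cand), weights) <= thr]
        out.append(
            {
                "u_best": best[i]["u"],
                "p_best": denormalize(best[i]["u"], model.ranges),
                "F_best": best[i]["F"],
                "candidates": cand,
            }
        )
    return out[0] if len(out) == 1 else out


def local_refine(
    p_start,
    delta_p,
    evaluator,
    n_iter: int = 200,
    seed: int = 0,
    ranges: ParameterRanges | None = None,
) -> dict:
    """Stochastic local refinement p_try = p_start + xi .* dp.

    ``xi`` is uniform in [-0.5, 0.5]^7; ``evaluator`` maps a physical
    parameter vector to F.  Proposals outside the parameter ranges are
    rejected (not clamped); the best point found so far is kept, so F never
    increases across accepted iterations.
    """
    ranges = ranges or ParameterRanges()
    p_start = np.asarray(p_start, dtype=float)
    delta_p = np.asarray(delta_p, dtype=float) * np.ones(7)
    if not ranges.contains(p_start):
        raise ValueError("p_start outside ParameterRanges")
    rng = np.random.default_rng(seed)
    p_best = p_start.copy()
    f_best = float(evaluator(p_best))
    n_rejected = 0
    for _ in range(n_iter):
        xi = rng.uniform(-0.5, 0.5, size=7)
        p_try = p_best + xi * delta_p
        if not ranges.contains(p_try):
            n_rejected += 1
            continue
        f_try = float(evaluator(p_try))
        if f_try < f_best:
            p_best, f_best = p_try, f_try
    return {
        "p_best": p_best,
        "F_best": f_best,
        "n_rejected": n_rejected,
        "all_rejected": n_rejected == n_iter,
    }
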