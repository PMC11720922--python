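"""Offset-adjusted hazard models fitted on case-base sampled person-moments.

Both model families estimate the log-hazard ``f(X, t)`` from the binary
case/base labels: during fitting the constant sampling offset ``log(B/b)`` is
added to the linear predictor before the sigmoid, and at prediction time the
offset is replaced by zero so that ``h(t|X) = exp(f(X, t))``.

* :class:`CBLR` — logistic regression on user-specified design terms over the
  covariates and time (optionally a natural-spline basis of log-time),
  maximum likelihood via IRLS; deterministic.
* :class:`CBNN` — a feed-forward network taking the covariates and time as
  inputs, trained by Adam on binary cross-entropy with the fixed offset.

The risk function ``F(t|X) = 1 - exp(-int_0^t h(u|X) du)`` is recovered by a
left-endpoint Riemann sum on a user grid.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._nn import DenseNet
from .sampling import PersonMomentTable
from .simulate import spline_basis

__all__ = [
    "Scaling",
    "RiskCurve",
    "HazardModel",
    "CBLRSpec",
    "CBLR",
    "CBNNSpec",
    "CBNN",
    "fit_cblr",
    "build_cbnn",
    "fit_cbnn",
    "predict_hazard",
    "predict_risk",
]


@dataclass(frozen=True)
class Scaling:
    """Feature scaling frozen from training data.

    Covariates are standardized by the training mean and standard deviation;
    time is divided by the training maximum.  ``identity`` produces a no-op
    scaling for models that consume raw features (the regression model's fit
    is affine-invariant, so its design uses unscaled covariates).
    """

    center: np.ndarray
    scale: np.ndarray
    time_max: float
    names: tuple[str, ...]

    @classmethod
    def fit(cls, covariates: pd.DataFrame, times: np.ndarray) -> "Scaling":
        sd = covariates.std(ddof=0).to_numpy(float)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(
            center=covariates.mean().to_numpy(float),
            scale=sd,
            time_max=float(np.max(times)),
            names=tuple(covariates.columns),
        )

    @classmethod
    def identity(cls, names: tuple[str, ...]) -> "Scaling":
        p = len(names)
        return cls(np.zeros(p), np.ones(p), 1.0, names)

    def transform(self, covariates: pd.DataFrame, t: np.ndarray) -> np.ndarray:
        X = covariates[list(self.names)].to_numpy(float)
        Xs = (X - self.center) / self.scale
        return np.column_stack([Xs, np.asarray(t, dtype=float) / self.time_max])


@dataclass
class RiskCurve:
    """Cumulative event probability ``F(t|X)`` on an ascending time grid.

    ``values`` has one row per covariate profile and one column per grid
    time; rows are nondecreasing and lie in [0, 1] by construction.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("grid times must be strictly ascending")
        if self.values.shape[1] != self.times.size:
            raise ValueError("values must have one column per grid time")

    def at_time(self, t: float) -> np.ndarray:
        """Risk at the last grid point <= t (stepwise-previous)."""
        j = int(np.searchsorted(self.times, t, side="right")) - 1
        if j < 0:
            return np.zeros(self.values.shape[0])
        return self.values[:, j]


class HazardModel(ABC):
    """Anything that maps (covariates, time) to a log-hazard."""

    @abstractmethod
    def log_hazard(self, X: pd.DataFrame, t: np.ndarray | float) -> np.ndarray:
        """Per-row log-hazard; scalar ``t`` broadcasts over rows of ``X``."""

    def predict_hazard(self, X: pd.DataFrame, t: np.ndarray | float) -> np.ndarray:
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("t must be nonnegative")
        return np.exp(self.log_hazard(X, t))

    def predict_risk(self, X: pd.DataFrame, grid: np.ndarray) -> RiskCurve:
        """Left-endpoint Riemann sum of the hazard on ``grid``.

        The grid must be ascending and start at 0 or the first positive
        point; an implicit interval [0, grid[0]] uses the hazard at the
        midpoint of that interval (models with log-time features are
        undefined at exactly 0).
        """
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("grid must be a non-empty 1-d array")
        if np.any(np.diff(grid) <= 0) or grid[0] < 0:
            raise ValueError("grid must be ascending and nonnegative")
        if grid[0] == 0:
            # F(0) = 0; the first interval's left endpoint (t = 0) is replaced
            # by its midpoint since log-time models are undefined at 0
            if grid.size == 1:
                return RiskCurve(grid, np.zeros((len(X), 1)))
            lefts = grid[:-1].copy()
            lefts[0] = grid[1] / 2
            dt = np.diff(grid)
            hz = np.stack(
                [self.predict_hazard(X, np.full(len(X), te)) for te in lefts], axis=1
            )
            H = np.concatenate(
                [np.zeros((len(X), 1)), np.cumsum(hz * dt, axis=1)], axis=1
            )
        else:
            lefts = np.concatenate([[grid[0] / 2], grid[:-1]])
            dt = np.diff(grid, prepend=0.0)
            hz = np.stack(
                [self.predict_hazard(X, np.full(len(X), te)) for te in lefts], axis=1
            )
            H = np.cumsum(hz * dt, axis=1)
        return RiskCurve(grid, -np.expm1(-H))


# --------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class CBLRSpec:
    """Design specification for the logistic hazard model.

    ``terms`` is a list of strings over the covariate names and the special
    name ``time``; a term may be a single name or a product ``"a*b"``.  When
    ``terms`` is None, the default design (each covariate plus time,
    linearly) is derived from the fitted moments.  ``spline_knots`` adds a
    natural cubic spline basis of ``log(time / time_scale)`` (excluding its
    constant column; an intercept is always present).
    """

    terms: tuple[str, ...] | None = None
    spline_knots: tuple[float, ...] | None = None
    time_scale: float = 1.0

    def resolved_terms(self, covariate_names: list[str]) -> tuple[str, ...]:
        if self.terms is not None:
            return tuple(self.terms)
        return tuple(covariate_names) + ("time",)

    def column_names(self, covariate_names: list[str]) -> list[str]:
        cols = ["const"]
        if self.spline_knots is not None:
            cols += [f"logt_s{i}" for i in range(len(self.spline_knots) - 1)]
        cols += list(self.resolved_terms(covariate_names))
        return cols

    def design(
        self, covariates: pd.DataFrame, t: np.ndarray | float
    ) -> np.ndarray:
        t = np.broadcast_to(np.asarray(t, dtype=float), (len(covariates),))

        def col(name: str) -> np.ndarray:
            if name == "time":
                return t
            return covariates[name].to_numpy(float)

        blocks = [np.ones((len(covariates), 1))]
        if self.spline_knots is not None:
            if np.any(t <= 0):
                raise ValueError("t must be positive for log-time spline terms")
            basis = spline_basis(np.log(t / self.time_scale), self.spline_knots)
            blocks.append(basis[:, 1:])  # drop the basis intercept
        cols = []
        for term in self.resolved_terms(list(covariates.columns)):
            parts = [p.strip() for p in term.split("*")]
            v = col(parts[0])
            for p in parts[1:]:
                v = v * col(p)
            cols.append(v)
        if cols:
            blocks.append(np.column_stack(cols))
        return np.hstack(blocks)


class CBLR(HazardModel):
    """Case-base logistic regression: linear log-hazard in design terms."""

    def __init__(self, spec: CBLRSpec | None = None) -> None:
        self.spec = spec or CBLRSpec()
        self.coef_: np.ndarray | None = None
        self.column_names_: list[str] | None = None
        self.covariate_names_: list[str] | None = None

    def fit(self, moments: PersonMomentTable) -> "CBLR":
        y = moments.label
        if y.min() == y.max():
            raise ValueError("moments must contain both case and base rows")
        X = self.spec.design(moments.covariates, moments.moment_time)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                "design matrix is rank deficient; drop collinear terms"
            )
        offset = np.full(len(y), moments.offset)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset).fit(
                maxiter=200
            )
        except sm.tools.sm_exceptions.PerfectSeparationError as err:  # pragma: no cover
            raise ValueError(f"separable design: {err}") from err
        self.coef_ = np.asarray(res.params)
        self.covariate_names_ = moments.covariate_names
        self.column_names_ = self.spec.column_names(moments.covariate_names)
        self._result = res
        return self

    def log_hazard(self, X: pd.DataFrame, t: np.ndarray | float) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        return self.spec.design(X, t) @ self.coef_

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": "cblr",
            "terms": list(self.spec.resolved_terms(self.covariate_names_ or [])),
            "spline_knots": list(self.spec.spline_knots or []) or None,
            "time_scale": self.spec.time_scale,
            "coef": list(map(float, self.coef_)),
            "columns": self.column_names_,
            "covariates": self.covariate_names_,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CBLR":
        payload = json.loads(Path(path).read_text())
        spec = CBLRSpec(
            terms=tuple(payload["terms"]),
            spline_knots=tuple(payload["spline_knots"]) if payload["spline_knots"] else None,
            time_scale=payload["time_scale"],
        )
        model = cls(spec)
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.column_names_ = payload["columns"]
        model.covariate_names_ = payload["covariates"]
        return model


# --------------------------------------------------------------------------
# neural network


@dataclass(frozen=True)
class CBNNSpec:
    """Architecture and optimizer settings for the network hazard model."""

    layer1_nodes: int = 75
    layer2_nodes: int = 50
    dropout: float = 0.01
    activation: str = "relu"
    learning_rate: float = 0.001
    n_batches: int = 100
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.layer1_nodes < 1 or self.layer2_nodes < 1:
            raise ValueError("layer widths must be positive integers")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in ("relu", "linear"):
            raise ValueError("activation must be 'relu' or 'linear'")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class CBNN(HazardModel):
    """Feed-forward network log-hazard with the covariates and time as inputs.

    The network output ``f(X, t)`` is a single linear unit; during training
    the sampling offset is added before the sigmoid (not trainable), and at
    prediction the hazard is ``exp(f)`` with the offset fixed at zero.
    """

    def __init__(
        self,
        spec: CBNNSpec,
        p: int,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        if p < 1:
            raise ValueError("need at least one covariate")
        self.spec = spec
        self.p = p
        self.net = DenseNet(
            n_inputs=p + 1,
            hidden=(spec.layer1_nodes, spec.layer2_nodes),
            activation=spec.activation,
            dropout=spec.dropout,
            rng=rng,
        )
        self.scaling: Scaling | None = None
        self.history_: dict | None = None

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def fit(
        self,
        moments: PersonMomentTable,
        rng: np.random.Generator | int | None = None,
        val_moments: PersonMomentTable | None = None,
    ) -> "CBNN":
        """Train on ``moments``; early-stop on ``val_moments`` when given.

        Validation moments are scaled with the training scaling and scored
        with the training offset; without them a random 20% of the training
        moments is held out for early stopping.
        """
        self.scaling = Scaling.fit(moments.covariates, moments.moment_time)
        X = self.scaling.transform(moments.covariates, moments.moment_time)
        X_val = y_val = None
        if val_moments is not None:
            X_val = self.scaling.transform(
                val_moments.covariates, val_moments.moment_time
            )
            y_val = val_moments.label
        self.history_ = self.net.fit(
            X,
            moments.label,
            offset=moments.offset,
            X_val=X_val,
            y_val=y_val,
            learning_rate=self.spec.learning_rate,
            n_batches=self.spec.n_batches,
            max_epochs=self.spec.max_epochs,
            patience=self.spec.patience,
            val_fraction=self.spec.val_fraction,
            rng=rng,
        )
        return self

    def log_hazard(self, X: pd.DataFrame, t: np.ndarray | float) -> np.ndarray:
        if self.scaling is None:
            raise RuntimeError("model is not fitted")
        t = np.broadcast_to(np.asarray(t, dtype=float), (len(X),))
        return self.net.predict(self.scaling.transform(X, t))

    def save(self, path: str | Path) -> None:
        """Serialize weights and scaling to JSON (small nets only)."""
        payload = {
            "model": "cbnn",
            "spec": self.spec.__dict__,
            "p": self.p,
            "W": [w.tolist() for w in self.net.W],
            "b": [b.tolist() for b in self.net.b],
            "scaling": None
            if self.scaling is None
            else {
                "center": self.scaling.center.tolist(),
                "scale": self.scaling.scale.tolist(),
                "time_max": self.scaling.time_max,
                "names": list(self.scaling.names),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CBNN":
        payload = json.loads(Path(path).read_text())
        model = cls(CBNNSpec(**payload["spec"]), payload["p"], rng=0)
        model.net.W = [np.asarray(w) for w in payload["W"]]
        model.net.b = [np.asarray(b) for b in payload["b"]]
        if payload["scaling"]:
            s = payload["scaling"]
            model.scaling = Scaling(
                np.asarray(s["center"]),
                np.asarray(s["scale"]),
                s["time_max"],
                tuple(s["names"]),
            )
        return model


# --------------------------------------------------------------------------
# functional surface


def fit_cblr(moments: PersonMomentTable, spec: CBLRSpec | None = None) -> CBLR:
    """Fit the logistic hazard model on sampled person-moments."""
    return CBLR(spec).fit(moments)


def build_cbnn(
    spec: CBNNSpec, p: int, rng: np.random.Generator | int | None = None
) -> CBNN:
    """Construct an untrained network hazard model for ``p`` covariates."""
    return CBNN(spec, p, rng=rng)


def fit_cbnn(
    model: CBNN,
    moments: PersonMomentTable,
    rng: np.random.Generator | int | None = None,
    val_moments: PersonMomentTable | None = None,
) -> CBNN:
    """Train the network on sampled person-moments (seeded, in place)."""
    return model.fit(moments, rng=rng, val_moments=val_moments)


def predict_hazard(
    model: HazardModel, X: pd.DataFrame, t: np.ndarray | float
) -> np.ndarray:
    """Hazard ``exp(f(X, t))`` with the sampling offset fixed at zero."""
    return model.predict_hazard(X, t)


def predict_risk(model: HazardModel, X: pd.DataFrame, grid: np.ndarray) -> RiskCurve:
    """Risk curve ``F(t|X)`` on ``grid`` via the left-endpoint Riemann sum."""
    return model.predict_risk(X, grid)
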