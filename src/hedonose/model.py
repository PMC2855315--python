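"""Ensemble feedforward-network model of odor pleasantness.

The predictor is an ensemble of 20 small three-layer networks (120 inputs,
5 tanh hidden units, linear output) trained by plain full-batch gradient
descent for 20 epochs from independent random initializations; the ensemble
prediction is the average of the members.  Targets are median VAS
pleasantness centered at the scale midpoint (15), so the sign of a
prediction carries the pleasant/unpleasant classification.

Usage follows the Model/Results convention::

    model = PleasantnessModel(features, targets)   # raw FeatureMatrix
    res = model.fit(seed=0)
    per_sample, per_odorant = res.predict(new_features)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data import PleasantnessTable, RatingTable, VAS_MID, as_pleasantness_table
from .features import (
    FULLY_NORMALIZED,
    FeatureMatrix,
    N_FEATURES,
    Normalizer,
    RAW,
)

#: internal target scale: centered VAS divided by this, so targets lie in [-1, 1]
TARGET_SCALE = 15.0


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture and trainer of one ensemble member.

    120 inputs -> ``hidden_units`` tanh units -> linear output, trained with
    full-batch gradient descent on squared error for ``epochs`` sweeps.
    ``learning_rate`` and ``init_scale`` (uniform weight init in
    [-init_scale, init_scale]) are implementation choices; the defaults were
    picked so the ensemble reliably converges within the 20-epoch budget on
    unit-norm signature rows.
    """

    hidden_units: int = 5
    epochs: int = 20
    learning_rate: float = 1.0
    init_scale: float = 0.2
    n_runs: int = 20
    input_dim: int = N_FEATURES

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.epochs < 1:
            raise ValueError("hidden_units and epochs must be >= 1")
        if self.learning_rate <= 0 or self.init_scale <= 0:
            raise ValueError("learning_rate and init_scale must be positive")


@dataclass
class _Network:
    """Weights of one member network (tanh hidden layer, linear output)."""

    W1: np.ndarray  # (input_dim, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float

    def forward(self, X: np.ndarray) -> np.ndarray:
        H = np.tanh(X @ self.W1 + self.b1)
        return H @ self.w2 + self.b2


def _init_network(spec: NetworkSpec, rng: np.random.Generator) -> _Network:
    s = spec.init_scale
    return _Network(
        W1=rng.uniform(-s, s, size=(spec.input_dim, spec.hidden_units)),
        b1=rng.uniform(-s, s, size=spec.hidden_units),
        w2=rng.uniform(-s, s, size=spec.hidden_units),
        b2=float(rng.uniform(-s, s)),
    )


def _train_network(
    net: _Network, X: np.ndarray, y: np.ndarray, spec: NetworkSpec
) -> _Network:
    n = X.shape[0]
    lr = spec.learning_rate
    for _ in range(spec.epochs):
        H = np.tanh(X @ net.W1 + net.b1)
        pred = H @ net.w2 + net.b2
        r = (pred - y) / n  # gradient of 0.5 * mean squared error
        g_w2 = H.T @ r
        g_b2 = r.sum()
        dH = np.outer(r, net.w2) * (1.0 - H * H)
        g_W1 = X.T @ dH
        g_b1 = dH.sum(axis=0)
        net.W1 -= lr * g_W1
        net.b1 -= lr * g_b1
        net.w2 -= lr * g_w2
        net.b2 -= lr * g_b2
    return net


class PleasantnessModel:
    """Ensemble network model mapping 120-feature signatures to pleasantness.

    Parameters
    ----------
    features
        FeatureMatrix of the training measurements.  A raw matrix is
        normalized internally (column z-score then unit-norm rows) and the
        column statistics are frozen for prediction on novel odorants; an
        already fully normalized matrix is used as-is (pass the normalizer
        used, if any, via ``normalizer`` so prediction can transform raw
        novel data).
    targets
        Per-odorant pleasantness: a PleasantnessTable, RatingTable (medians
        taken), mapping or Series on the 0-30 VAS scale.  Every training
        odorant must have a target; each measurement (repetition) becomes a
        training row carrying its odorant's centered target.
    spec
        NetworkSpec; defaults to the standard 5-hidden-unit, 20-epoch,
        20-member configuration.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        targets: "PleasantnessTable | RatingTable | Mapping[str, float] | pd.Series",
        spec: NetworkSpec | None = None,
        normalizer: Normalizer | None = None,
    ):
        self.spec = spec or NetworkSpec()
        table = as_pleasantness_table(targets)
        missing = sorted(set(features.odorant_ids) - set(table.odorants))
        if missing:
            raise ValueError(f"odorants without a pleasantness target: {missing[:5]}")
        if features.state == RAW:
            self.normalizer = Normalizer().fit(features)
            self._X_matrix = self.normalizer.transform(features)
        elif features.state == FULLY_NORMALIZED:
            self.normalizer = normalizer
            self._X_matrix = features
        else:
            raise ValueError(f"unsupported matrix state {features.state}")
        self.features = features
        self.targets = table
        n_odorants = len(set(features.odorant_ids))
        if n_odorants < 10:
            import warnings

            warnings.warn(
                f"only {n_odorants} training odorants; predictions are "
                "unreliable below ~30 samples",
                stacklevel=2,
            )
        self._y_centered = np.array(
            [table[o] - VAS_MID for o in features.odorant_ids]
        )

    @classmethod
    def from_tables(
        cls,
        features: FeatureMatrix,
        ratings: RatingTable,
        spec: NetworkSpec | None = None,
    ) -> "PleasantnessModel":
        """Build from a feature matrix and a raw rating table (medians taken)."""
        return cls(features, ratings, spec=spec)

    def fit(self, seed: int = 0) -> "PleasantnessResults":
        """Train the ensemble from ``spec.n_runs`` seeded initializations."""
        X = self._X_matrix.values
        y = self._y_centered / TARGET_SCALE
        rng = np.random.default_rng(seed)
        networks = [
            _train_network(_init_network(self.spec, rng), X, y, self.spec)
            for _ in range(self.spec.n_runs)
        ]
        return PleasantnessResults(self, networks, seed)


def _ensemble_predict(networks: list[_Network], X: np.ndarray) -> np.ndarray:
    preds = np.mean([net.forward(X) for net in networks], axis=0)
    return preds * TARGET_SCALE


def classify(predictions: "pd.Series | np.ndarray") -> "pd.Series | np.ndarray":
    """Sign rule on centered predictions: pleasant iff > 0 (ties unpleasant)."""
    values = predictions.values if isinstance(predictions, pd.Series) else np.asarray(predictions)
    labels = np.where(values > 0, "pleasant", "unpleasant")
    if isinstance(predictions, pd.Series):
        return pd.Series(labels, index=predictions.index)
    return labels


class PleasantnessResults:
    """Fitted ensemble: predictions, diagnostics and serialization."""

    def __init__(
        self, model: PleasantnessModel, networks: list[_Network], seed: int
    ):
        self.model = model
        self.networks = networks
        self.seed = seed
        self.spec = model.spec
        self.normalizer = model.normalizer

    # -- prediction -------------------------------------------------------

    def _transform(self, features: FeatureMatrix) -> FeatureMatrix:
        if features.state == FULLY_NORMALIZED:
            return features
        if features.state != RAW:
            raise ValueError(f"unsupported matrix state {features.state}")
        if self.normalizer is None:
            raise ValueError(
                "model has no frozen normalizer; pass a fully normalized matrix"
            )
        return self.normalizer.transform(features)

    def predict(self, features: FeatureMatrix) -> tuple[pd.Series, pd.Series]:
        """Predict centered pleasantness per sample and per odorant.

        Per-sample predictions average the ensemble members; per-odorant
        predictions average a given odorant's retained repetitions.
        """
        if features.values.shape[1] != N_FEATURES:
            raise ValueError(f"feature dimension must be {N_FEATURES}")
        X = self._transform(features)
        per_sample = pd.Series(
            _ensemble_predict(self.networks, X.values),
            index=X.sample_ids, name="predicted_centered",
        )
        by_odorant = per_sample.groupby(
            pd.Index(X.odorant_ids, name="odorant")
        ).mean()
        # preserve first-appearance odorant order
        order = list(dict.fromkeys(X.odorant_ids))
        return per_sample, by_odorant.loc[order].rename("predicted_centered")

    def classify(self, features: FeatureMatrix | None = None) -> pd.Series:
        """Pleasant/unpleasant labels per odorant (positive prediction = pleasant)."""
        _, per_odorant = self.predict(features if features is not None else self.model.features)
        return classify(per_odorant)

    # -- diagnostics ------------------------------------------------------

    @property
    def fittedvalues(self) -> pd.Series:
        """Centered predictions on the training samples."""
        per_sample, _ = self.predict(self.model._X_matrix)
        return per_sample

    @property
    def fitted_odorants(self) -> pd.Series:
        _, per_odorant = self.predict(self.model._X_matrix)
        return per_odorant

    def training_correlation(self) -> tuple[float, float]:
        """Pearson r (and two-tailed p) between fitted and target odorant medians."""
        per_odorant = self.fitted_odorants
        truth = np.array([self.model.targets[o] - VAS_MID for o in per_odorant.index])
        r, p = stats.pearsonr(per_odorant.values, truth)
        return float(r), float(p)

    def summary(self) -> str:
        r, p = self.training_correlation()
        s = self.spec
        lines = [
            "Odor pleasantness ensemble network",
            "=" * 44,
            f"{'Training samples:':<28}{self.model.features.n_samples}",
            f"{'Training odorants:':<28}{len(set(self.model.features.odorant_ids))}",
            f"{'Ensemble members:':<28}{s.n_runs}",
            f"{'Hidden units / epochs:':<28}{s.hidden_units} / {s.epochs}",
            f"{'Learning rate / init:':<28}{s.learning_rate} / {s.init_scale}",
            f"{'Seed:':<28}{self.seed}",
            f"{'Training Pearson r:':<28}{r:.3f} (p = {p:.2g})",
            "=" * 44,
            "Targets are median VAS - 15; positive predictions classify as pleasant.",
        ]
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize spec, ensemble weights and frozen preprocessing to JSON."""
        payload = {
            "spec": {
                "hidden_units": self.spec.hidden_units,
                "epochs": self.spec.epochs,
                "learning_rate": self.spec.learning_rate,
                "init_scale": self.spec.init_scale,
                "n_runs": self.spec.n_runs,
                "input_dim": self.spec.input_dim,
            },
            "seed": self.seed,
            "networks": [
                {
                    "W1": net.W1.tolist(),
                    "b1": net.b1.tolist(),
                    "w2": net.w2.tolist(),
                    "b2": net.b2,
                }
                for net in self.networks
            ],
            "normalizer": None
            if self.normalizer is None
            else {
                "row_norm": self.normalizer.row_norm,
                "means": self.normalizer.means_.tolist(),
                "sds": self.normalizer.sds_.tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "FrozenEnsemble":
        payload = json.loads(Path(path).read_text())
        spec = NetworkSpec(**payload["spec"])
        networks = [
            _Network(
                W1=np.asarray(d["W1"]), b1=np.asarray(d["b1"]),
                w2=np.asarray(d["w2"]), b2=float(d["b2"]),
            )
            for d in payload["networks"]
        ]
        normalizer = None
        if payload["normalizer"] is not None:
            normalizer = Normalizer(row_norm=payload["normalizer"]["row_norm"])
            normalizer.means_ = np.asarray(payload["normalizer"]["means"])
            normalizer.sds_ = np.asarray(payload["normalizer"]["sds"])
        return FrozenEnsemble(spec, networks, normalizer, payload.get("seed", 0))


class FrozenEnsemble:
    """A deserialized ensemble: prediction only, no training data attached."""

    def __init__(
        self,
        spec: NetworkSpec,
        networks: list[_Network],
        normalizer: Normalizer | None,
        seed: int = 0,
    ):
        self.spec = spec
        self.networks = networks
        self.normalizer = normalizer
        self.seed = seed

    predict = PleasantnessResults.predict
    _transform = PleasantnessResults._transform
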