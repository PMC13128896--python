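"""Feed-forward age regressor on selected CpGs plus a sex indicator.

The network is implemented directly on NumPy (fully-connected ReLU layers,
inverted dropout, L2 weight decay, Adam, squared-error loss) so that training
is bit-reproducible from a seed on one platform and input gradients are
available in closed form for attribution. Ensembling follows a
leave-one-cohort-out (LOCO) scheme: one submodel per held-out cohort, trained
on an 80:20 split of the remaining cohorts, combined by an unweighted mean.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleMeta
from .selection import FeatureSet

__all__ = [
    "ModelConfig",
    "AgeModel",
    "LocoEnsemble",
    "make_design",
    "train_mlp",
    "loco_train",
    "predict_age",
    "tune_hyperparameters",
]

SEX_COLUMN = "sex"

#: search-space bounds used for validation and random search
SEARCH_SPACE = {
    "n_hidden_layers": (2, 8),
    "width": (128, 256, 512, 1024),
    "dropout": (0.15, 0.5),
    "l2": (1e-6, 0.1),
    "learning_rate": (1e-5, 1e-3),
    "epochs": (10, 5000),
}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the age regressor.

    ``production_default`` mirrors the published configuration (2 x 1024
    units, dropout 0.25, L2 1.71e-5, lr 3.06e-5, 5000 epochs);
    ``test_default`` is a desk-scale configuration for fast tests.
    """

    n_hidden_layers: int = 2
    width: int = 1024
    dropout: float = 0.25
    l2: float = 1.71e-5
    learning_rate: float = 3.06e-5
    epochs: int = 5000
    seed: int = 0
    loss: str = "mse"
    standardize: bool = False
    batch_size: int | None = None  # None = full batch

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 1 or self.width < 1 or self.epochs < 1:
            raise ValueError("layers, width and epochs must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.l2 < 0 or self.learning_rate <= 0:
            raise ValueError("l2 must be >= 0 and learning_rate > 0")
        if self.loss != "mse":
            raise ValueError("only squared-error loss is supported")

    @classmethod
    def production_default(cls) -> "ModelConfig":
        return cls()

    @classmethod
    def test_default(cls, seed: int = 0) -> "ModelConfig":
        return cls(
            n_hidden_layers=2, width=64, dropout=0.0, l2=1e-6,
            learning_rate=1e-2, epochs=300, seed=seed,
        )


def make_design(
    m: BetaMatrix,
    meta: SampleMeta,
    features: FeatureSet | Sequence[str],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Build the model design matrix: feature columns in order, then sex.

    Rows follow ``meta`` order. Returns ``(X, ages)`` where ``X`` is indexed
    by sample ID.
    """
    feature_ids = list(features.cpgs if isinstance(features, FeatureSet) else features)
    probe_idx = {p: i for i, p in enumerate(m.probe_ids)}
    missing = [f for f in feature_ids if f not in probe_idx]
    if missing:
        raise KeyError(f"features absent from beta matrix: {missing[:5]}")
    sample_idx = {s: j for j, s in enumerate(m.sample_ids)}
    absent = [s for s in meta.sample_id if s not in sample_idx]
    if absent:
        raise KeyError(f"samples absent from beta matrix: {absent[:5]}")
    if np.any(meta.sex < 0):
        bad = [sid for sid, s in zip(meta.sample_id, meta.sex) if s < 0]
        raise ValueError(f"samples with unknown sex cannot enter the design: {bad[:5]}")
    rows = [probe_idx[f] for f in feature_ids]
    cols = [sample_idx[s] for s in meta.sample_id]
    block = m.values[np.ix_(rows, cols)].T
    if np.isnan(block).any():
        raise ValueError("design contains missing betas; impute first")
    X = pd.DataFrame(block, index=list(meta.sample_id), columns=feature_ids)
    X[SEX_COLUMN] = meta.sex.astype(float)
    return X, meta.age.copy()


def _init_params(sizes: Sequence[int], rng: np.random.Generator):
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        scale = math.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class AgeModel:
    """A trained feed-forward regressor with its feature contract."""

    config: ModelConfig
    feature_names: list[str]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None

    # -- numeric core -----------------------------------------------------
    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.x_mean is not None:
            return (X - self.x_mean) / self.x_sd
        return X

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Eval-mode forward pass. Returns predictions and pre-activations."""
        pre = []
        h = X
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            pre.append(z)
            h = np.maximum(z, 0.0) if l < len(self.weights) - 1 else z
        return h[:, 0], pre

    def predict_array(self, X: np.ndarray) -> np.ndarray:
        return self._forward(self._transform(np.asarray(X, dtype=float)))[0]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self.check_contract(X)
        return self.predict_array(X.to_numpy(dtype=float))

    def check_contract(self, X: pd.DataFrame) -> None:
        if list(X.columns) != self.feature_names:
            raise ValueError(
                "design columns do not match the model's feature contract "
                f"(expected {len(self.feature_names)} columns starting "
                f"{self.feature_names[:3]}, got {list(X.columns)[:3]})"
            )

    def input_gradients(self, X: np.ndarray) -> np.ndarray:
        """d prediction / d input for each row of ``X`` (eval mode)."""
        X = np.asarray(X, dtype=float)
        Xt = self._transform(X)
        _, pre = self._forward(Xt)
        grad = np.ones((X.shape[0], 1))
        for l in range(len(self.weights) - 1, -1, -1):
            grad = grad @ self.weights[l].T
            if l > 0:
                grad = grad * (pre[l - 1] > 0)
        if self.x_mean is not None:
            grad = grad / self.x_sd
        return grad

    # -- persistence ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(json.dumps(asdict(self.config)))
        (directory / "features.txt").write_text("\n".join(self.feature_names) + "\n")
        arrays = {f"W{l}": W for l, W in enumerate(self.weights)}
        arrays.update({f"b{l}": b for l, b in enumerate(self.biases)})
        if self.x_mean is not None:
            arrays["x_mean"] = self.x_mean
            arrays["x_sd"] = self.x_sd
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "AgeModel":
        directory = Path(directory)
        config = ModelConfig(**json.loads((directory / "config.json").read_text()))
        features = [
            line.strip()
            for line in (directory / "features.txt").read_text().splitlines()
            if line.strip()
        ]
        data = np.load(directory / "weights.npz")
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        return cls(
            config=config,
            feature_names=features,
            weights=[data[f"W{l}"] for l in range(n_layers)],
            biases=[data[f"b{l}"] for l in range(n_layers)],
            x_mean=data["x_mean"] if "x_mean" in data.files else None,
            x_sd=data["x_sd"] if "x_sd" in data.files else None,
        )


def train_mlp(
    X: pd.DataFrame | np.ndarray,
    ages: np.ndarray,
    config: ModelConfig,
    feature_names: Sequence[str] | None = None,
) -> AgeModel:
    """Train the regressor from scratch; fixed seed gives identical weights."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        feature_names = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(Xa.shape[1])
        ]
    y = np.asarray(ages, dtype=float)
    if Xa.shape[0] < 2:
        raise ValueError("training requires at least 2 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite ages in training targets")

    rng = np.random.default_rng(config.seed)
    x_mean = x_sd = None
    if config.standardize:
        x_mean = Xa.mean(axis=0)
        x_sd = Xa.std(axis=0)
        x_sd = np.where(x_sd == 0, 1.0, x_sd)
        Xa = (Xa - x_mean) / x_sd

    sizes = [Xa.shape[1]] + [config.width] * config.n_hidden_layers + [1]
    weights, biases = _init_params(sizes, rng)
    params = weights + biases
    opt = _Adam(params, config.learning_rate)
    n = Xa.shape[0]
    batch = n if config.batch_size is None else min(config.batch_size, n)

    for epoch in range(config.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb, yb = Xa[idx], y[idx]
            # forward with dropout on hidden activations
            activations = [xb]
            pre, masks = [], []
            h = xb
            for l in range(len(weights)):
                z = h @ weights[l] + biases[l]
                pre.append(z)
                if l < len(weights) - 1:
                    h = np.maximum(z, 0.0)
                    if config.dropout > 0:
                        mask = (rng.random(h.shape) >= config.dropout) / (1 - config.dropout)
                        h = h * mask
                        masks.append(mask)
                    else:
                        masks.append(None)
                    activations.append(h)
                else:
                    h = z
            pred = h[:, 0]
            err = pred - yb
            if not np.all(np.isfinite(err)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; try a lower learning rate "
                    f"(lr={config.learning_rate}, width={config.width})"
                )
            delta = (2.0 / len(idx)) * err[:, None]
            w_grads = [np.empty(0)] * len(weights)
            b_grads = [np.empty(0)] * len(biases)
            for l in range(len(weights) - 1, -1, -1):
                w_grads[l] = activations[l].T @ delta + 2 * config.l2 * weights[l]
                b_grads[l] = delta.sum(axis=0)
                if l > 0:
                    delta = delta @ weights[l].T
                    if masks[l - 1] is not None:
                        delta = delta * masks[l - 1]
                    delta = delta * (pre[l - 1] > 0)
            opt.step(params, w_grads + b_grads)

    return AgeModel(config, feature_names, weights, biases, x_mean, x_sd)


@dataclass
class LocoEnsemble:
    """One submodel per held-out cohort; prediction = unweighted mean."""

    submodels: dict[str, AgeModel]
    feature_names: list[str]
    held_out_mae: dict[str, float]
    internal_test_mae: dict[str, float]
    config: ModelConfig
    train_cohorts: dict[str, list[str]] = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        preds = [m.predict(X) for m in self.submodels.values()]
        return np.mean(preds, axis=0)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "held_out_cohorts": list(self.submodels),
            "held_out_mae": self.held_out_mae,
            "internal_test_mae": self.internal_test_mae,
            "train_cohorts": self.train_cohorts,
            "config": asdict(self.config),
        }
        (directory / "ensemble.json").write_text(json.dumps(manifest, indent=2))
        for cohort, model in self.submodels.items():
            model.save(directory / f"exclude_{cohort}")

    @classmethod
    def load(cls, directory: str | Path) -> "LocoEnsemble":
        directory = Path(directory)
        manifest = json.loads((directory / "ensemble.json").read_text())
        submodels = {
            c: AgeModel.load(directory / f"exclude_{c}") for c in manifest["held_out_cohorts"]
        }
        any_model = next(iter(submodels.values()))
        return cls(
            submodels=submodels,
            feature_names=any_model.feature_names,
            held_out_mae=manifest["held_out_mae"],
            internal_test_mae=manifest["internal_test_mae"],
            config=ModelConfig(**manifest["config"]),
            train_cohorts=manifest.get("train_cohorts", {}),
        )


def _fold_seed(base_seed: int, cohort: str) -> int:
    import zlib

    return (base_seed * 1000003 + zlib.crc32(cohort.encode())) % (2**31)


def loco_train(
    X: pd.DataFrame,
    ages: np.ndarray,
    cohorts: Sequence[str],
    config: ModelConfig,
    always_train: str | None = None,
    train_fraction: float = 0.8,
) -> LocoEnsemble:
    """Train one submodel per held-out cohort.

    The held-out cohort contributes no training rows; the remaining cohorts
    are pooled and split ``train_fraction`` : rest with a per-fold seed, with
    the held-in part used for fitting and the rest for an internal test MAE.
    ``always_train`` names a cohort that is never held out.
    """
    cohorts = np.asarray([str(c) for c in cohorts])
    ages = np.asarray(ages, dtype=float)
    unique = list(dict.fromkeys(cohorts))
    if len(unique) < 2:
        raise ValueError("LOCO requires at least 2 cohorts")
    eligible = [c for c in unique if c != always_train]
    if not eligible:
        raise ValueError("no cohort eligible for holding out")

    submodels: dict[str, AgeModel] = {}
    held_out_mae: dict[str, float] = {}
    internal_mae: dict[str, float] = {}
    train_cohorts: dict[str, list[str]] = {}
    for held in eligible:
        pool = np.flatnonzero(cohorts != held)
        held_idx = np.flatnonzero(cohorts == held)
        rng = np.random.default_rng(_fold_seed(config.seed, held))
        order = rng.permutation(pool.size)
        n_train = max(1, int(round(train_fraction * pool.size)))
        tr = pool[order[:n_train]]
        te = pool[order[n_train:]]
        fold_config = replace(config, seed=_fold_seed(config.seed, held) + 1)
        model = train_mlp(X.iloc[tr], ages[tr], fold_config)
        submodels[held] = model
        held_out_mae[held] = float(np.mean(np.abs(model.predict(X.iloc[held_idx]) - ages[held_idx])))
        if te.size:
            internal_mae[held] = float(np.mean(np.abs(model.predict(X.iloc[te]) - ages[te])))
        train_cohorts[held] = sorted(set(cohorts[tr]))
    return LocoEnsemble(
        submodels=submodels,
        feature_names=list(X.columns),
        held_out_mae=held_out_mae,
        internal_test_mae=internal_mae,
        config=config,
        train_cohorts=train_cohorts,
    )


def predict_age(model: AgeModel | LocoEnsemble, X: pd.DataFrame) -> np.ndarray:
    """Predict ages; LOCO ensembles average their submodels."""
    return model.predict(X)


def _sample_config(rng: np.random.Generator, base: ModelConfig,
                   space: Mapping[str, tuple] = SEARCH_SPACE) -> ModelConfig:
    lo, hi = space["n_hidden_layers"]
    layers = int(rng.integers(lo, hi + 1))
    width = int(rng.choice(space["width"]))
    dropout = float(rng.uniform(*space["dropout"]))
    l2 = float(np.exp(rng.uniform(np.log(space["l2"][0]), np.log(space["l2"][1]))))
    lr = float(np.exp(rng.uniform(np.log(space["learning_rate"][0]),
                                  np.log(space["learning_rate"][1]))))
    epochs = int(rng.integers(space["epochs"][0], space["epochs"][1] + 1))
    return replace(base, n_hidden_layers=layers, width=width, dropout=dropout,
                   l2=l2, learning_rate=lr, epochs=epochs)


def tune_hyperparameters(
    X: pd.DataFrame,
    ages: np.ndarray,
    cohorts: Sequence[str],
    n_trials: int,
    seed: int = 0,
    base_config: ModelConfig | None = None,
    space: Mapping[str, tuple] = SEARCH_SPACE,
    always_train: str | None = None,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Seeded random search minimizing mean LOCO held-out MAE.

    Returns the best configuration and the full trial log (one row per
    trial with its sampled hyperparameters and per-fold MAEs).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    base = base_config or ModelConfig.test_default()
    rng = np.random.default_rng(seed)
    rows, configs = [], []
    failures = []
    for trial in range(n_trials):
        cfg = _sample_config(rng, base, space)
        cfg = replace(cfg, seed=seed + trial)
        try:
            ens = loco_train(X, ages, cohorts, cfg, always_train=always_train)
        except (FloatingPointError, ValueError) as exc:  # pragma: no cover - rare
            failures.append(f"trial {trial}: {exc}")
            continue
        mean_mae = float(np.mean(list(ens.held_out_mae.values())))
        rows.append(
            {
                "trial": trial, "mean_loco_mae": mean_mae,
                "n_hidden_layers": cfg.n_hidden_layers, "width": cfg.width,
                "dropout": cfg.dropout, "l2": cfg.l2,
                "learning_rate": cfg.learning_rate, "epochs": cfg.epochs,
                **{f"mae_{c}": v for c, v in ens.held_out_mae.items()},
            }
        )
        configs.append(cfg)
    if not rows:
        raise RuntimeError("all tuning trials failed: " + "; ".join(failures))
    log = pd.DataFrame(rows)
    best = int(log["mean_loco_mae"].idxmin())
    return configs[best], log
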