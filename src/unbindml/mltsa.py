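"""Machine-learning transition-state analysis (MLTSA).

An ensemble of independently seeded classifiers (multilayer perceptrons or
gradient-boosted decision trees) is trained to predict the IN/OUT outcome
of downhill trajectories from their early-time features (default window
0.05-0.1 ns).  Each replica draws its own 70/30 train/validation split *by
simulation* — frames of one trajectory never appear on both sides — and is
scored by the fraction of correctly predicted validation frames.

Two importance metrics rank the features afterwards:

* RAD (relative accuracy drop): a feature's variance is removed by
  replacing its column with the feature's global mean; the replica's
  validation accuracy is re-measured and the relative drop
  ``(A0 - A_f) / A0`` is averaged over replicas.  A permutation variant is
  available via ``method="permute"``.
* RFI (relative feature importance): the Gini impurity-reduction importance
  of the tree ensembles, averaged over replicas (each replica's importances
  sum to 1).

Per-residue aggregation averages the feature values of all columns that
carry a residue id, so pair-distance profiles can be read residue-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError, StructuralError, TrainingError
from .featurize import FeatureDescriptor, FeatureMatrix

MODEL_KINDS = ("mlp", "gbdt")


@dataclass(frozen=True)
class EnsembleConfig:
    """Declarative training configuration (thin wrapper interface)."""

    model_kind: str = "mlp"
    n_models: int = 100
    train_fraction: float = 0.7
    window: tuple[float, float] = (0.05, 0.1)
    base_seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model_kind.lower() not in MODEL_KINDS:
            raise ConfigurationError(f"unknown model_kind {self.model_kind!r}")
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.n_models < 1:
            raise ConfigurationError("n_models must be >= 1")
        if not self.window[0] < self.window[1]:
            raise ConfigurationError("window must satisfy t_start < t_end")


@dataclass
class ImportanceProfile:
    """Per-feature (or per-residue) importance across replicas."""

    metric: str                      # "RAD" or "RFI"
    per_replica: np.ndarray          # (n_models, D)
    names: tuple[str, ...]
    descriptors: tuple | None = None
    level: str = "feature"

    def __post_init__(self):
        self.per_replica = np.asarray(self.per_replica, float)
        if self.per_replica.shape[1] != len(self.names):
            raise StructuralError("one name per importance column required")

    @property
    def mean(self) -> np.ndarray:
        return self.per_replica.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.per_replica.std(axis=0, ddof=0)

    def top(self, k: int) -> list[str]:
        order = np.argsort(-self.mean, kind="stable")
        return [self.names[i] for i in order[:k]]

    def top_indices(self, k: int) -> np.ndarray:
        return np.argsort(-self.mean, kind="stable")[:k]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"name": self.names, "mean": self.mean, "sd": self.sd}
        )
        df["rank"] = (-df["mean"]).rank(method="first").astype(int)
        return df.sort_values("rank").reset_index(drop=True)


def _resolve_xy(X, y):
    if isinstance(X, FeatureMatrix):
        if y is None:
            y = X.labels
        descriptors = X.descriptors
        X = X.values
    else:
        descriptors = None
        X = np.asarray(X, float)
    if X.ndim != 3:
        raise StructuralError(
            "X must be (n_simulations, n_frames, n_features); got "
            f"ndim={X.ndim}"
        )
    if y is None:
        raise TrainingError("labels are required for training")
    y = np.asarray(y)
    if len(y) != X.shape[0]:
        raise StructuralError("one label per simulation required")
    return X, y, descriptors


class MLTSAEnsemble(BaseEstimator, ClassifierMixin):
    """Replica ensemble of outcome classifiers on early-time frames.

    Parameters
    ----------
    model_kind : {"mlp", "gbdt"}
    n_models : int
        Number of independently split and seeded replicas.
    train_fraction : float
        Fraction of *simulations* per replica used for training.
    base_seed : int
        Replica r uses ``base_seed + r`` for both its split and its model
        initialization.
    hidden_layer_sizes, max_iter : MLP hyperparameters.
    n_estimators, max_depth, learning_rate : GBDT hyperparameters.

    Fitted attributes
    -----------------
    models_, scalers_ : per-replica fitted estimators (+ MLP scalers)
    splits_ : list of (train_sim_indices, val_sim_indices)
    accuracies_ : per-replica validation-frame accuracy
    classes_ : label classes
    """

    def __init__(
        self,
        model_kind: str = "mlp",
        n_models: int = 100,
        train_fraction: float = 0.7,
        base_seed: int = 0,
        hidden_layer_sizes: tuple = (100,),
        max_iter: int = 200,
        n_estimators: int = 100,
        max_depth: int = 3,
        learning_rate: float = 0.1,
    ):
        self.model_kind = model_kind
        self.n_models = n_models
        self.train_fraction = train_fraction
        self.base_seed = base_seed
        self.hidden_layer_sizes = hidden_layer_sizes
        self.max_iter = max_iter
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate

    # -- internals ---------------------------------------------------------
    def _make_model(self, seed: int):
        kind = self.model_kind.lower()
        if kind == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=self.hidden_layer_sizes,
                activation="relu",
                solver="adam",
                max_iter=self.max_iter,
                random_state=seed,
            )
        if kind == "gbdt":
            return GradientBoostingClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                learning_rate=self.learning_rate,
                random_state=seed,
            )
        raise ConfigurationError(f"unknown model_kind {self.model_kind!r}")

    @staticmethod
    def _flatten(X, y, sims):
        n_frames = X.shape[1]
        xs = X[sims].reshape(len(sims) * n_frames, X.shape[2])
        ys = np.repeat(y[sims], n_frames)
        return xs, ys

    def _replica_accuracy(self, r: int, X, y) -> float:
        _, val = self.splits_[r]
        xv, yv = self._flatten(X, y, val)
        if self.scalers_[r] is not None:
            xv = self.scalers_[r].transform(xv)
        return float((self.models_[r].predict(xv) == yv).mean())

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y=None):
        """Fit all replicas.  X is (S, T, D) or a FeatureMatrix (whose
        labels are used when y is omitted)."""
        X, y, descriptors = _resolve_xy(X, y)
        S = X.shape[0]
        if S < 10:
            raise TrainingError(f"need >= 10 simulations, got {S}")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise TrainingError("training requires at least two classes")
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        n_train = int(round(self.train_fraction * S))
        n_train = min(max(n_train, 1), S - 1)
        self.models_, self.scalers_, self.splits_ = [], [], []
        accuracies = []
        use_scaler = self.model_kind.lower() == "mlp"
        for r in range(self.n_models):
            seed = self.base_seed + r
            rng = np.random.default_rng(seed)
            perm = rng.permutation(S)
            train, val = perm[:n_train], perm[n_train:]
            xt, yt = self._flatten(X, y, train)
            scaler = None
            if use_scaler:
                scaler = StandardScaler().fit(xt)
                xt = scaler.transform(xt)
            model = self._make_model(seed)
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # MLP convergence chatter
                model.fit(xt, yt)
            self.models_.append(model)
            self.scalers_.append(scaler)
            self.splits_.append((train, val))
            accuracies.append(None)  # placeholder, filled below
        self.n_features_in_ = X.shape[2]
        self._X = X
        self._y = y
        self.descriptors_ = descriptors
        self.accuracies_ = np.array(
            [self._replica_accuracy(r, X, y) for r in range(self.n_models)]
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Majority vote over replicas for 2-D frame data (n_frames, D)."""
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise StructuralError("predict expects (n_frames, n_features)")
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=int)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        for model, scaler in zip(self.models_, self.scalers_):
            xp = scaler.transform(X) if scaler is not None else X
            pred = model.predict(xp)
            for i, c in enumerate(pred):
                votes[i, class_index[c]] += 1
        return self.classes_[votes.argmax(axis=1)]

    # -- accuracy and importances ------------------------------------------
    def ensemble_accuracy(self) -> tuple[float, float]:
        """Mean and sd of per-replica validation-frame accuracy."""
        return float(self.accuracies_.mean()), float(
            self.accuracies_.std(ddof=0)
        )

    def rad_importance(
        self, X=None, y=None, method: str = "mean", seed: int = 0
    ) -> ImportanceProfile:
        """Relative accuracy drop per feature.

        For each replica r and feature f, feature f's column is corrupted
        over the whole data set (replaced by its global mean, or permuted
        across all frames when ``method="permute"``), replica r's
        validation accuracy ``A_f`` is re-measured, and
        ``RAD = (A0 - A_f) / A0``.
        """
        if method not in ("mean", "permute"):
            raise ConfigurationError(f"unknown RAD method {method!r}")
        if X is None:
            X, y = self._X, self._y
        else:
            X, y, _ = _resolve_xy(X, y)
        if X.shape[2] != self.n_features_in_:
            raise StructuralError(
                f"{X.shape[2]} features but ensemble was trained on "
                f"{self.n_features_in_}"
            )
        rng = np.random.default_rng(seed)
        D = X.shape[2]
        rad = np.zeros((self.n_models, D))
        for f in range(D):
            corrupted = X.copy()
            if method == "mean":
                corrupted[:, :, f] = X[:, :, f].mean()
            else:
                flat = X[:, :, f].ravel()
                corrupted[:, :, f] = flat[rng.permutation(flat.size)].reshape(
                    X.shape[:2]
                )
            for r in range(self.n_models):
                a0 = self.accuracies_[r]
                af = self._replica_accuracy(r, corrupted, y)
                rad[r, f] = (a0 - af) / a0
        names = self._feature_names(D)
        return ImportanceProfile(
            metric="RAD",
            per_replica=rad,
            names=names,
            descriptors=self.descriptors_,
        )

    def rfi_importance(self) -> ImportanceProfile:
        """Per-replica normalized Gini importances, GBDT ensembles only."""
        if self.model_kind.lower() != "gbdt":
            raise TypeError(
                "Gini feature importance requires a GBDT ensemble; "
                f"this ensemble is {self.model_kind!r}"
            )
        rfi = np.stack(
            [m.feature_importances_ for m in self.models_], axis=0
        )
        totals = rfi.sum(axis=1, keepdims=True)
        rfi = rfi / np.where(totals == 0, 1.0, totals)
        names = self._feature_names(rfi.shape[1])
        return ImportanceProfile(
            metric="RFI",
            per_replica=rfi,
            names=names,
            descriptors=self.descriptors_,
        )

    def _feature_names(self, D: int) -> tuple[str, ...]:
        if self.descriptors_ is not None:
            return tuple(d.label() for d in self.descriptors_)
        return tuple(f"f{i}" for i in range(D))


# ---------------------------------------------------------------------------
# residue-level aggregation
# ---------------------------------------------------------------------------

def aggregate_by_residue(
    profile: ImportanceProfile,
    descriptors: tuple[FeatureDescriptor, ...] | None = None,
) -> ImportanceProfile:
    """Average feature importances per residue.

    Features whose descriptor carries a residue id (pair distances,
    per-residue minima) are grouped by that id and averaged; features
    without one (PCA components, waters) pass through ungrouped.
    """
    descriptors = descriptors or profile.descriptors
    if descriptors is None:
        raise ConfigurationError(
            "residue aggregation needs feature descriptors"
        )
    if len(descriptors) != profile.per_replica.shape[1]:
        raise StructuralError("descriptor count does not match profile width")
    groups: dict[str, list[int]] = {}
    for i, d in enumerate(descriptors):
        if d.residue_id is not None:
            key = f"res{d.residue_id}"
        else:
            key = d.label()
        groups.setdefault(key, []).append(i)
    names = tuple(groups)
    agg = np.stack(
        [profile.per_replica[:, idx].mean(axis=1) for idx in groups.values()],
        axis=1,
    )
    return ImportanceProfile(
        metric=profile.metric, per_replica=agg, names=names, level="residue"
    )


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def train_ensemble(
    features: FeatureMatrix, config: EnsembleConfig = EnsembleConfig()
) -> MLTSAEnsemble:
    """Window the features and fit a replica ensemble per the config."""
    windowed = features.window(*config.window)
    hp = dict(config.hyperparameters)
    ensemble = MLTSAEnsemble(
        model_kind=config.model_kind.lower(),
        n_models=config.n_models,
        train_fraction=config.train_fraction,
        base_seed=config.base_seed,
        **hp,
    )
    return ensemble.fit(windowed)


def ensemble_accuracy(ensemble: MLTSAEnsemble) -> tuple[float, float]:
    return ensemble.ensemble_accuracy()


def rad_importance(
    ensemble: MLTSAEnsemble, features: FeatureMatrix | None = None, **kw
) -> ImportanceProfile:
    if features is None:
        return ensemble.rad_importance(**kw)
    return ensemble.rad_importance(features.values, features.labels, **kw)


def rfi_importance(ensemble: MLTSAEnsemble) -> ImportanceProfile:
    return ensemble.rfi_importance()


def scan_time_windows(
    features: FeatureMatrix,
    config: EnsembleConfig,
    windows: list[tuple[float, float]],
) -> pd.DataFrame:
    """Train one ensemble per time window; report mean/sd accuracy each.

    Used to pick the earliest window from which outcomes are predictable.
    """
    rows = []
    for t0, t1 in windows:
        if not t0 < t1:
            raise ConfigurationError(f"empty window ({t0}, {t1})")
        cfg = EnsembleConfig(
            model_kind=config.model_kind,
            n_models=config.n_models,
            train_fraction=config.train_fraction,
            window=(t0, t1),
            base_seed=config.base_seed,
            hyperparameters=config.hyperparameters,
        )
        ens = train_ensemble(features, cfg)
        mean, sd = ens.ensemble_accuracy()
        rows.append(
            {"t_start": t0, "t_end": t1, "mean_accuracy": mean, "sd": sd}
        )
    return pd.DataFrame(rows)


def plot_importance(profile: ImportanceProfile, path=None, top: int | None = None):
    """Bar plot of mean importance (+/- sd) per feature or residue."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = profile.top_indices(top or len(profile.names))
    fig, ax = plt.subplots(figsize=(max(6, len(order) * 0.25), 4))
    ax.bar(
        range(len(order)),
        profile.mean[order],
        yerr=profile.sd[order],
        color="steelblue",
    )
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels([profile.names[i] for i in order], rotation=90, fontsize=7)
    ax.set_ylabel(f"mean {profile.metric}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
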