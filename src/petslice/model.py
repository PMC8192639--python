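"""The 2.5-D slice-submodule classifier.

A 3-D volume of shape ``(nx, ny, nz)`` is decomposed into its
``nx + ny + nz`` orthogonal 2-D planes.  Each plane feeds its own CNN
submodule — four blocks of [3x3 conv (stride 1, same padding), batch norm,
ReLU, 2x2 max pool (stride 2)] followed by a dense layer and sigmoid —
producing one per-slice probability.  No weights are shared between
submodules.  The per-slice probabilities are concatenated and passed
through a single fully connected unit with sigmoid for the final
probability; a subject is called positive when it is strictly greater than
the decision threshold.

Training follows the reference recipe: binary cross-entropy on the final
output only, Adam at learning rate 1e-4, mini-batches of 4, at most 30
epochs, monitoring validation loss after every epoch and keeping the
weights from the epoch with the lowest validation loss.  Convolution
weights use He initialization, dense layers Xavier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from ._nn import DTYPE, Adam, SubmoduleStack, _sigmoid

__all__ = [
    "ModelConfig",
    "PredictionRecord",
    "SubmoduleSpec",
    "submodule_spec",
    "n_submodules",
    "SliceSubmoduleClassifier",
]

DEFAULT_FILTERS = (32, 64, 128, 128)


@dataclass
class ModelConfig:
    """Serializable hyperparameter bundle (defaults follow the reference recipe)."""

    conv_filters: tuple[int, int, int, int] = DEFAULT_FILTERS
    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 30
    decision_threshold: float = 0.5
    validation_fraction: float = 0.2
    seed: int | None = 0

    def estimator(self) -> "SliceSubmoduleClassifier":
        return SliceSubmoduleClassifier(
            conv_filters=self.conv_filters,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            decision_threshold=self.decision_threshold,
            validation_fraction=self.validation_fraction,
            random_state=self.seed,
        )


@dataclass
class PredictionRecord:
    """Final probability plus the per-submodule probability vector for one subject.

    ``submodule_probabilities`` is ordered sagittal (ascending slice index),
    then coronal, then axial — the same ordering as
    :func:`petslice.preprocessing.extract_slices`.
    """

    subject_id: str
    final_probability: float
    submodule_probabilities: np.ndarray
    predicted_class: int


@dataclass
class SubmoduleSpec:
    """Static description of one submodule for a given slice shape."""

    slice_shape: tuple[int, int]
    layers: list[dict] = field(default_factory=list)
    feature_map_shapes: list[tuple[int, int, int]] = field(default_factory=list)
    flattened_size: int = 0
    parameter_count: int = 0


def submodule_spec(
    slice_shape: tuple[int, int],
    conv_filters: tuple[int, int, int, int] = DEFAULT_FILTERS,
) -> SubmoduleSpec:
    """Trace the submodule architecture for one slice shape.

    Raises
    ------
    ValueError
        If either in-plane dimension is too small to survive the four
        2x2 poolings (each must be >= 16); the offending dimension is named.
    """
    h, w = slice_shape
    for dim_name, v in (("height", h), ("width", w)):
        if v < 16:
            raise ValueError(
                f"slice {dim_name} {v} is too small: each in-plane dimension "
                "must be >= 16 to survive four 2x2 poolings"
            )
    spec = SubmoduleSpec(slice_shape=(h, w))
    c_in = 1
    n_params = 0
    for c_out in conv_filters:
        spec.layers.append(
            {"type": "conv3x3", "stride": 1, "padding": "same",
             "in_channels": c_in, "out_channels": c_out, "init": "he"}
        )
        n_params += 9 * c_in * c_out
        spec.layers.append({"type": "batch_norm", "channels": c_out})
        n_params += 2 * c_out
        spec.layers.append({"type": "relu"})
        spec.layers.append({"type": "max_pool2x2", "stride": 2})
        h, w = h // 2, w // 2
        spec.feature_map_shapes.append((h, w, c_out))
        c_in = c_out
    spec.flattened_size = h * w * conv_filters[-1]
    spec.layers.append({"type": "flatten"})
    spec.layers.append(
        {"type": "dense", "in_features": spec.flattened_size, "out_features": 1,
         "init": "xavier"}
    )
    n_params += spec.flattened_size * 1 + 1
    spec.layers.append({"type": "sigmoid"})
    spec.parameter_count = n_params
    return spec


def n_submodules(slice_counts: tuple[int, int, int]) -> int:
    """Total submodules for a volume: one per slice, summed over the three axes."""
    return int(sum(slice_counts))


class _Network:
    """Three axis stacks plus the fully connected fusion head."""

    def __init__(self, dims: tuple[int, int, int],
                 conv_filters: tuple[int, int, int, int],
                 rng: np.random.Generator):
        nx, ny, nz = dims
        for shape in ((ny, nz), (nx, nz), (nx, ny)):
            submodule_spec(shape, conv_filters)  # validates, names bad dims
        self.dims = dims
        self.stacks = [
            SubmoduleStack(nx, (ny, nz), conv_filters, rng),
            SubmoduleStack(ny, (nx, nz), conv_filters, rng),
            SubmoduleStack(nz, (nx, ny), conv_filters, rng),
        ]
        s_total = nx + ny + nz
        limit = np.sqrt(6.0 / (s_total + 1))
        from ._nn import Param

        self.head_w = Param(rng.uniform(-limit, limit, size=(s_total, 1)))
        self.head_b = Param(np.zeros((1,)))
        self._cache: tuple | None = None

    def params(self):
        out = []
        for st in self.stacks:
            out.extend(st.params())
        out.extend([self.head_w, self.head_b])
        return out

    @staticmethod
    def _axis_inputs(X: np.ndarray) -> list[np.ndarray]:
        # (B, nx, ny, nz) -> per-axis (S, B, H, W, 1)
        return [
            X.transpose(1, 0, 2, 3)[..., None],
            X.transpose(2, 0, 1, 3)[..., None],
            X.transpose(3, 0, 1, 2)[..., None],
        ]

    def forward(self, X: np.ndarray, training: bool) -> tuple[np.ndarray, np.ndarray]:
        """Returns (final probabilities (B,), submodule probabilities (B, S_total))."""
        ps = [
            st.forward(xi, training)
            for st, xi in zip(self.stacks, self._axis_inputs(X.astype(DTYPE)))
        ]
        P = np.concatenate([p.T for p in ps], axis=1)  # (B, S_total)
        z = P @ self.head_w.value + self.head_b.value  # (B, 1)
        p_final = _sigmoid(z[:, 0])
        if training:
            self._cache = (P,)
        return p_final, P

    def backward(self, dz: np.ndarray) -> None:
        """Backprop from d(loss)/d(head pre-sigmoid), shape (B,)."""
        (P,) = self._cache
        self._cache = None
        dz2 = dz[:, None].astype(DTYPE)
        self.head_w.grad += P.T @ dz2
        self.head_b.grad += dz2.sum(axis=0)
        dP = dz2 @ self.head_w.value.T  # (B, S_total)
        nx, ny, nz = self.dims
        offsets = np.cumsum([0, nx, ny, nz])
        for st, lo, hi in zip(self.stacks, offsets[:-1], offsets[1:]):
            st.backward(np.ascontiguousarray(dP[:, lo:hi].T))

    def state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        for st in self.stacks:
            for layer in st.layers:
                if hasattr(layer, "running_mean"):
                    arrays.append(layer.running_mean.copy())
                    arrays.append(layer.running_var.copy())
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.params():
            p.value[...] = next(it)
        for st in self.stacks:
            for layer in st.layers:
                if hasattr(layer, "running_mean"):
                    layer.running_mean[...] = next(it)
                    layer.running_var[...] = next(it)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    pc = np.clip(p, 1e-7, 1.0 - 1e-7)
    return float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


class SliceSubmoduleClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style 2.5-D CNN for binary classification of 3-D volumes.

    Parameters
    ----------
    conv_filters : tuple of 4 ints, default (32, 64, 128, 128)
        Channels of the four convolutional layers of every submodule.
    learning_rate : float, default 1e-4
        Adam step size.
    batch_size : int, default 4
    max_epochs : int, default 30
    decision_threshold : float, default 0.5
        Positive iff final probability strictly exceeds this.
    validation_fraction : float, default 0.2
        Held-out fraction for the internal stratified validation split when
        no explicit validation set is passed to :meth:`fit`.
    random_state : int or None
        Seed for weight initialization, splitting and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    slice_counts_ : (nx, ny, nz)
    n_submodules_ : int
    history_ : DataFrame with per-epoch ``train_loss`` and ``val_loss``
    checkpoint_epoch_ : int, epoch (0-based) with the lowest validation loss
    """

    def __init__(self, conv_filters=DEFAULT_FILTERS, learning_rate=1e-4,
                 batch_size=4, max_epochs=30, decision_threshold=0.5,
                 validation_fraction=0.2, random_state=None, verbose=False):
        self.conv_filters = conv_filters
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.decision_threshold = decision_threshold
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 4:
            raise ValueError("X must be stacked volumes of shape (n, nx, ny, nz)")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"training set must contain both classes, got classes {self.classes_}"
            )
        y01 = (y == self.classes_[1]).astype(np.float64)

        if X_val is None:
            X_tr, X_va, y_tr, y_va = train_test_split(
                X, y01, test_size=self.validation_fraction, stratify=y01,
                random_state=(self.random_state if self.random_state is not None else None),
            )
        else:
            X_tr, y_tr = X, y01
            X_va = np.asarray(X_val, dtype=np.float64)
            y_va = (np.asarray(y_val) == self.classes_[1]).astype(np.float64)
        if len(np.unique(y_tr)) != 2:
            raise ValueError("training split ended up single-class; enlarge the set")

        rng = np.random.default_rng(self.random_state)
        dims = X.shape[1:]
        net = _Network(dims, tuple(self.conv_filters), rng)
        opt = Adam(net.params(), lr=self.learning_rate)

        history = []
        best_val = np.inf
        best_state = None
        best_epoch = -1
        n_tr = len(X_tr)
        bs = self.batch_size
        for epoch in range(self.max_epochs):
            perm = rng.permutation(n_tr)
            tot_loss = 0.0
            for start in range(0, n_tr, bs):
                idx = perm[start:start + bs]
                xb, yb = X_tr[idx], y_tr[idx]
                opt.zero_grad()
                p, _ = net.forward(xb, training=True)
                loss = _bce(p, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch "
                        f"starting {start}: {loss}"
                    )
                net.backward((p - yb) / len(idx))
                opt.step()
                tot_loss += loss * len(idx)
            train_loss = tot_loss / n_tr
            val_loss = self._eval_loss(net, X_va, y_va)
            if not np.isfinite(val_loss):
                raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
            history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
            if self.verbose:
                print(f"epoch {epoch}: train {train_loss:.4f}  val {val_loss:.4f}")
            if val_loss < best_val:
                best_val = val_loss
                best_state = net.state()
                best_epoch = epoch

        net.load_state(best_state)
        self.network_ = net
        self.history_ = pd.DataFrame(history)
        self.checkpoint_epoch_ = best_epoch
        self.slice_counts_ = tuple(int(d) for d in dims)
        self.n_submodules_ = n_submodules(self.slice_counts_)
        return self

    @staticmethod
    def _eval_loss(net: _Network, X: np.ndarray, y: np.ndarray, bs: int = 16) -> float:
        tot = 0.0
        for start in range(0, len(X), bs):
            p, _ = net.forward(X[start:start + bs], training=False)
            tot += _bce(p, y[start:start + bs]) * len(p)
        return tot / len(X)

    # ------------------------------------------------------------ inference
    def _check_input(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise ValueError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4 or tuple(X.shape[1:]) != self.slice_counts_:
            raise ValueError(
                f"expected volumes of dims {self.slice_counts_}, got array of "
                f"shape {X.shape}"
            )
        return X

    def _forward_eval(self, X: np.ndarray, bs: int = 16) -> tuple[np.ndarray, np.ndarray]:
        ps, subs = [], []
        for start in range(0, len(X), bs):
            p, P = self.network_.forward(X[start:start + bs], training=False)
            ps.append(p)
            subs.append(P)
        return np.concatenate(ps), np.concatenate(subs)

    def predict_proba(self, X) -> np.ndarray:
        X = self._check_input(X)
        p, _ = self._forward_eval(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)[:, 1]
        return self.classes_[(proba > self.decision_threshold).astype(int)]

    # -------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Serialize the fitted model to a single ``.npz`` checkpoint."""
        if not hasattr(self, "network_"):
            raise ValueError("classifier is not fitted")
        import json

        meta = {
            "conv_filters": list(self.conv_filters),
            "decision_threshold": self.decision_threshold,
            "slice_counts": list(self.slice_counts_),
            "classes": [int(c) for c in self.classes_],
            "checkpoint_epoch": int(self.checkpoint_epoch_),
        }
        state = self.network_.state()
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **{f"arr_{i}": a for i, a in enumerate(state)},
        )

    @classmethod
    def load(cls, path) -> "SliceSubmoduleClassifier":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            state = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
        clf = cls(
            conv_filters=tuple(meta["conv_filters"]),
            decision_threshold=meta["decision_threshold"],
        )
        dims = tuple(meta["slice_counts"])
        net = _Network(dims, tuple(meta["conv_filters"]), np.random.default_rng(0))
        net.load_state(state)
        clf.network_ = net
        clf.classes_ = np.array(meta["classes"])
        clf.slice_counts_ = dims
        clf.n_submodules_ = n_submodules(dims)
        clf.checkpoint_epoch_ = meta["checkpoint_epoch"]
        clf.history_ = pd.DataFrame()
        return clf

    def predict_record(self, X, subject_ids=None) -> list[PredictionRecord]:
        """Final and per-submodule probabilities for each subject."""
        X = self._check_input(X)
        p, P = self._forward_eval(X)
        if subject_ids is None:
            subject_ids = [f"sub-{i:04d}" for i in range(len(X))]
        return [
            PredictionRecord(
                subject_id=str(sid),
                final_probability=float(pi),
                submodule_probabilities=np.asarray(Pi, dtype=np.float64),
                predicted_class=int(pi > self.decision_threshold),
            )
            for sid, pi, Pi in zip(subject_ids, p, P)
        ]
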