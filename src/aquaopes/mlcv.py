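"""Machine-learned collective variables: LDA, Deep-LDA, TICA, Deep-TICA.

Two families of CVs:

* discriminant CVs separate labelled bound/unbound descriptor data by
  maximizing Fisher's ratio w^T S_b w / w^T S_w w, either directly on the
  descriptors (LDA) or on the last hidden layer h of a small network
  (Deep-LDA, s = w^T h, optionally sharpness-tamed by s -> s + s^3);

* slow-mode CVs extract the most slowly decorrelating directions from a
  trajectory via the time-lagged covariance generalized eigenproblem
  C(tau) v = lambda C(0) v (TICA), or from network features (Deep-TICA).
  Frames from biased runs enter with weights exp(beta*V), approximating
  the rescaled physical time.

Deep models are trained by alternating a closed-form solve for the
projection (LDA direction / leading TICA eigenvector of the features)
with Adam gradient steps on the network under that fixed projection.
All estimators follow the scikit-learn fit/transform protocol and are
seed-deterministic on one thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from ._mlp import MLP

__all__ = [
    "ScatterPair", "TicaSolution", "CVModel",
    "scatter_matrices", "lda_direction", "cubic_transform", "tica",
    "train_deep_lda", "train_deep_tica",
    "LDACV", "DeepLDACV", "TICACV", "DeepTICACV",
]


# --------------------------------------------------------------------------
# linear building blocks
# --------------------------------------------------------------------------

@dataclass
class ScatterPair:
    """Between/within scatter of two labelled descriptor clouds."""

    S_b: np.ndarray
    S_w: np.ndarray
    mu_B: np.ndarray
    mu_U: np.ndarray


def scatter_matrices(X_B, X_U) -> ScatterPair:
    X_B = np.asarray(X_B, dtype=float)
    X_U = np.asarray(X_U, dtype=float)
    if len(X_B) == 0 or len(X_U) == 0:
        raise ValueError("both classes must be non-empty")
    if X_B.shape[1] != X_U.shape[1]:
        raise ValueError("descriptor dimensions differ between classes")
    mu_B, mu_U = X_B.mean(axis=0), X_U.mean(axis=0)
    d = mu_B - mu_U
    S_b = np.outer(d, d)
    S_w = np.cov(X_B.T, ddof=0) + np.cov(X_U.T, ddof=0)
    S_w = np.atleast_2d(S_w)
    return ScatterPair(S_b=S_b, S_w=S_w, mu_B=mu_B, mu_U=mu_U)


def lda_direction(X_B, X_U, reg_lambda: float = 0.0) -> np.ndarray:
    """Unit Fisher-optimal direction w ~ (S_w + lambda I)^-1 (mu_B - mu_U)."""
    sp = scatter_matrices(X_B, X_U)
    delta = sp.mu_B - sp.mu_U
    if np.allclose(delta, 0.0):
        raise ValueError("degenerate classes: mu_B == mu_U gives no direction")
    A = sp.S_w + reg_lambda * np.eye(len(delta))
    try:
        w = np.linalg.solve(A, delta)
    except np.linalg.LinAlgError:
        raise ValueError("singular within-scatter; use reg_lambda > 0")
    return w / np.linalg.norm(w)


def fisher_ratio(X_B, X_U, w, reg_lambda: float = 0.0) -> float:
    sp = scatter_matrices(X_B, X_U)
    w = np.asarray(w, dtype=float)
    denom = w @ (sp.S_w + reg_lambda * np.eye(len(w))) @ w
    return float((w @ sp.S_b @ w) / denom)


def cubic_transform(s):
    """s -> s + s^3 (strictly monotone; widens sharp CV distributions)."""
    s = np.asarray(s, dtype=float)
    return s + s**3


# --------------------------------------------------------------------------
# TICA
# --------------------------------------------------------------------------

@dataclass
class TicaSolution:
    """Generalized-eigenproblem solution C(tau) v = lambda C(0) v."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray           # columns, C(0)-orthonormal
    lag_time: float
    mean: np.ndarray

    @property
    def implied_timescales(self) -> np.ndarray:
        lam = np.clip(self.eigenvalues, 1e-12, 1.0 - 1e-12)
        return -self.lag_time / np.log(lam)


def _tica_covariances(X, lag_frames, weights):
    n = len(X)
    idx0 = np.arange(n - lag_frames)
    idx1 = idx0 + lag_frames
    w = weights
    mean = (w[:, None] * X).sum(axis=0) / w.sum()
    Y = X - mean
    p = np.sqrt(w[idx0] * w[idx1])    # pair weights (geometric mean)
    psum = p.sum()
    Y0, Y1 = Y[idx0], Y[idx1]
    C0 = (Y0.T @ (p[:, None] * Y0) + Y1.T @ (p[:, None] * Y1)) / (2 * psum)
    Ct = Y0.T @ (p[:, None] * Y1) / psum
    Ct = 0.5 * (Ct + Ct.T)
    return C0, Ct, mean


def tica(X, times=None, lag_time: float = 1.0, frame_weights=None,
         reg: float = 1e-8) -> TicaSolution:
    """Linear TICA on a (weighted) descriptor trajectory.

    ``times`` must be uniformly spaced; the lag in frames is
    round(lag_time / dt) (dt = 1 when times is None).  ``frame_weights``
    default to 1; pass exp(beta*V) for biased data.  C(tau) is
    symmetrized, C(0) regularized by ``reg * trace/dim * I``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < X.shape[1]:
        raise ValueError("expected (n_frames, n_features) with n_frames large")
    n = len(X)
    dt = 1.0 if times is None else float(np.diff(np.asarray(times)[:2])[0])
    lag_frames = int(round(lag_time / dt))
    if lag_frames < 1 or lag_frames >= n:
        raise ValueError(f"lag of {lag_frames} frames outside (0, {n})")
    w = (np.ones(n) if frame_weights is None
         else np.asarray(frame_weights, dtype=float))
    if np.any(w <= 0):
        raise ValueError("frame weights must be positive")
    C0, Ct, mean = _tica_covariances(X, lag_frames, w)
    C0r = C0 + reg * np.trace(C0) / len(C0) * np.eye(len(C0))
    try:
        lam, vec = scipy.linalg.eigh(Ct, C0r)
    except scipy.linalg.LinAlgError:
        raise ValueError("C(0) not positive definite; increase reg")
    order = np.argsort(lam)[::-1]
    return TicaSolution(eigenvalues=lam[order], eigenvectors=vec[:, order],
                        lag_time=lag_frames * dt, mean=mean)


# --------------------------------------------------------------------------
# serializable CV model
# --------------------------------------------------------------------------

@dataclass
class CVModel:
    """A descriptor -> scalar CV, linear or NN-backed.

    evaluate() standardizes the input, pushes it through the (optional)
    network to the last hidden layer h, projects s = w^T h, rescales by
    (offset, scale) and applies the output transform.  Round-trips
    through JSON reproduce outputs exactly (floats serialized at full
    precision).
    """

    kind: str
    input_mean: np.ndarray
    input_std: np.ndarray
    projection: np.ndarray
    offset: float = 0.0
    scale: float = 1.0
    output_transform: str = "identity"      # "identity" | "cubic"
    layers_W: list = field(default_factory=list)
    layers_b: list = field(default_factory=list)
    activation: str = "tanh"
    training_meta: dict = field(default_factory=dict)

    def _features(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.input_mean) / self.input_std
        if not self.layers_W:
            return Z
        net = MLP([w.shape[0] for w in self.layers_W] + [self.layers_W[-1].shape[1]],
                  activation=self.activation, linear_output=False)
        net.set_weights(self.layers_W, self.layers_b)
        return net.forward(Z)

    def evaluate(self, X) -> np.ndarray:
        h = self._features(X)
        s = (h @ self.projection - self.offset) / self.scale
        if self.output_transform == "cubic":
            s = cubic_transform(s)
        elif self.output_transform != "identity":
            raise ValueError(f"unknown output transform {self.output_transform!r}")
        return s

    __call__ = evaluate

    def to_json(self) -> str:
        def arr(a):
            return np.asarray(a, dtype=float).tolist()
        return json.dumps({
            "format_version": 1, "kind": self.kind,
            "input_mean": arr(self.input_mean), "input_std": arr(self.input_std),
            "projection": arr(self.projection), "offset": self.offset,
            "scale": self.scale, "output_transform": self.output_transform,
            "layers_W": [arr(w) for w in self.layers_W],
            "layers_b": [arr(b) for b in self.layers_b],
            "activation": self.activation, "training_meta": self.training_meta,
        })

    @classmethod
    def from_json(cls, text: str) -> "CVModel":
        d = json.loads(text)
        if d.get("format_version") != 1:
            raise ValueError("unsupported CV model format")
        return cls(kind=d["kind"],
                   input_mean=np.array(d["input_mean"]),
                   input_std=np.array(d["input_std"]),
                   projection=np.array(d["projection"]),
                   offset=d["offset"], scale=d["scale"],
                   output_transform=d["output_transform"],
                   layers_W=[np.array(w) for w in d["layers_W"]],
                   layers_b=[np.array(b) for b in d["layers_b"]],
                   activation=d["activation"],
                   training_meta=d["training_meta"])

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "CVModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------

def _standardize(X):
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    return (X - mean) / std, mean, std


def _split_classes(X, y):
    y = np.asarray(y)
    labels = np.unique(y)
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {len(labels)}")
    # the "bound" (positive-side) state: label "B" when present, else the
    # larger label (so 1 beats 0)
    bound = "B" if "B" in labels.astype(str) else labels[1]
    other = labels[labels.astype(str) != str(bound)][0]
    return X[y.astype(str) == str(bound)], X[y == other], labels


class LDACV(BaseEstimator, TransformerMixin):
    """Closed-form two-class linear discriminant CV s = w^T d."""

    def __init__(self, reg_lambda: float = 0.0, output_transform: str = "identity"):
        self.reg_lambda = reg_lambda
        self.output_transform = output_transform

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Z, mean, std = _standardize(X)
        X_B, X_U, labels = _split_classes(Z, y)
        w = lda_direction(X_B, X_U, self.reg_lambda)
        a_B, a_U = X_B @ w, X_U @ w
        if a_B.mean() < a_U.mean():
            w = -w
            a_B, a_U = -a_B, -a_U
        mid = 0.5 * (a_B.mean() + a_U.mean())
        half = 0.5 * abs(a_B.mean() - a_U.mean())
        self.w_ = w
        self.classes_ = labels
        self.fisher_ratio_ = fisher_ratio(X_B, X_U, w, self.reg_lambda)
        self.model_ = CVModel(kind="lda", input_mean=mean, input_std=std,
                              projection=w, offset=mid, scale=half,
                              output_transform=self.output_transform)
        return self

    def transform(self, X):
        return self.model_.evaluate(X)[:, None]


class DeepLDACV(BaseEstimator, TransformerMixin):
    """Deep-LDA CV: Fisher's criterion applied to the last hidden layer.

    The network d -> h is trained by alternating (i) the closed-form LDA
    projection w on the current h with (ii) Adam steps on the network
    under fixed w, maximizing (w . dmu_h)^2 / (w^T S_w,h w + lambda).
    A validation split (stratified tail) early-stops on the held-out
    Fisher ratio.  The exported CV is s = w^T h, rescaled so the class
    means sit at +-1, then passed through s + s^3 by default.
    """

    def __init__(self, hidden_sizes=(32, 16, 8), activation: str = "tanh",
                 lr: float = 1e-3, epochs: int = 300,
                 reg_lambda: float | None = None, seed: int = 0,
                 val_fraction: float = 0.2, patience: int = 20,
                 output_transform: str = "cubic"):
        self.hidden_sizes = hidden_sizes
        self.activation = activation
        self.lr = lr
        self.epochs = epochs
        self.reg_lambda = reg_lambda
        self.seed = seed
        self.val_fraction = val_fraction
        self.patience = patience
        self.output_transform = output_transform

    def _projection(self, h_B, h_U, lam):
        sp = scatter_matrices(h_B, h_U)
        delta = sp.mu_B - sp.mu_U
        A = sp.S_w + lam * np.eye(len(delta))
        w = np.linalg.solve(A, delta)
        nrm = np.linalg.norm(w)
        return w / nrm if nrm > 0 else w

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Z, mean, std = _standardize(X)
        X_B, X_U, labels = _split_classes(Z, y)
        rng = np.random.Generator(np.random.PCG64(self.seed))
        X_B = X_B[rng.permutation(len(X_B))]
        X_U = X_U[rng.permutation(len(X_U))]
        n_vB = max(1, int(self.val_fraction * len(X_B)))
        n_vU = max(1, int(self.val_fraction * len(X_U)))
        tB, vB = X_B[:-n_vB], X_B[-n_vB:]
        tU, vU = X_U[:-n_vU], X_U[-n_vU:]
        n_h = self.hidden_sizes[-1]
        net = MLP([Z.shape[1], *self.hidden_sizes], activation=self.activation,
                  seed=self.seed, linear_output=False)
        Xt = np.vstack([tB, tU])
        nB = len(tB)
        best = (-np.inf, None, None, 0)
        for epoch in range(self.epochs):
            H, cache = net.forward(Xt, cache=True)
            hB, hU = H[:nB], H[nB:]
            lam = (self.reg_lambda if self.reg_lambda is not None
                   else 0.05 * np.trace(scatter_matrices(hB, hU).S_w) / n_h)
            w = self._projection(hB, hU, lam)
            aB, aU = hB @ w, hU @ w
            delta = aB.mean() - aU.mean()
            D = aB.var() + aU.var() + lam
            loss = -(delta * delta) / D
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite Deep-LDA loss at epoch {epoch}")
            # d(loss)/da for fixed w
            dA = np.empty(len(H))
            dA[:nB] = -(2 * delta / len(aB) * D
                        - delta**2 * 2 * (aB - aB.mean()) / len(aB)) / D**2
            dA[nB:] = -(-2 * delta / len(aU) * D
                        - delta**2 * 2 * (aU - aU.mean()) / len(aU)) / D**2
            grads = net.backward(cache, dA[:, None] * w[None, :])
            net.adam_step(grads, self.lr)
            hvB, hvU = net.forward(vB), net.forward(vU)
            try:
                w_val = self._projection(hvB, hvU, lam)
                val_ratio = fisher_ratio(hvB, hvU, w_val, lam)
            except np.linalg.LinAlgError:
                val_ratio = -np.inf
            if val_ratio > best[0]:
                best = (val_ratio, *net.get_weights(), epoch)
            elif epoch - best[3] > self.patience:
                break
        if best[1] is not None:
            net.set_weights(best[1], best[2])
        H = net.forward(np.vstack([X_B, X_U]))
        hB, hU = H[:len(X_B)], H[len(X_B):]
        lam = (self.reg_lambda if self.reg_lambda is not None
               else 0.05 * np.trace(scatter_matrices(hB, hU).S_w) / n_h)
        w = self._projection(hB, hU, lam)
        aB, aU = hB @ w, hU @ w
        if aB.mean() < aU.mean():
            w, aB, aU = -w, -aB, -aU
        mid = 0.5 * (aB.mean() + aU.mean())
        half = max(0.5 * abs(aB.mean() - aU.mean()), 1e-12)
        self.classes_ = labels
        self.projection_ = w
        self.fisher_ratio_ = fisher_ratio(hB, hU, w, lam)
        self.model_ = CVModel(
            kind="deep_lda", input_mean=mean, input_std=std, projection=w,
            offset=mid, scale=half, output_transform=self.output_transform,
            layers_W=net.W, layers_b=net.b, activation=self.activation,
            training_meta={"seed": self.seed, "lr": self.lr,
                           "epochs": self.epochs,
                           "hidden_sizes": list(self.hidden_sizes)})
        return self

    def transform(self, X):
        return self.model_.evaluate(X)[:, None]


class TICACV(BaseEstimator, TransformerMixin):
    """Linear TICA estimator; transform() gives the leading components."""

    def __init__(self, lag_time: float = 1.0, n_components: int = 1,
                 reg: float = 1e-8):
        self.lag_time = lag_time
        self.n_components = n_components
        self.reg = reg

    def fit(self, X, y=None, times=None, frame_weights=None):
        self.solution_ = tica(X, times=times, lag_time=self.lag_time,
                              frame_weights=frame_weights, reg=self.reg)
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        V = self.solution_.eigenvectors[:, :self.n_components]
        return (X - self.solution_.mean) @ V

    @property
    def implied_timescales_(self):
        return self.solution_.implied_timescales


class DeepTICACV(BaseEstimator, TransformerMixin):
    """Deep-TICA: slow modes of network features on (biased) trajectories.

    The network d -> f (n_out features) is trained by alternating the
    generalized eigensolve on the current features with Adam steps that
    maximize the leading eigenvalue under the fixed eigenvector, i.e. the
    autocorrelation rho = C01/C00 of the projected series at the lag.
    Frames may carry weights exp(beta*V) from a biased run (pair weight:
    geometric mean of the endpoint weights); unit weights recover the
    unbiased objective exactly.  transform() returns the leading
    eigenfunction scaled to unit weighted variance.
    """

    def __init__(self, hidden_sizes=(32, 16), n_out: int = 2,
                 activation: str = "tanh", lr: float = 1e-3,
                 epochs: int = 300, lag_time: float = 1.0, seed: int = 0,
                 val_fraction: float = 0.2, patience: int = 20,
                 reg: float = 1e-6):
        self.hidden_sizes = hidden_sizes
        self.n_out = n_out
        self.activation = activation
        self.lr = lr
        self.epochs = epochs
        self.lag_time = lag_time
        self.seed = seed
        self.val_fraction = val_fraction
        self.patience = patience
        self.reg = reg

    def _solve(self, F, lag_frames, w):
        C0, Ct, mean = _tica_covariances(F, lag_frames, w)
        C0r = C0 + self.reg * np.trace(C0) / len(C0) * np.eye(len(C0))
        lam, vec = scipy.linalg.eigh(Ct, C0r)
        i = np.argmax(lam)
        return lam[i], vec[:, i], mean

    def fit(self, X, y=None, times=None, frame_weights=None):
        X = np.asarray(X, dtype=float)
        Z, mean, std = _standardize(X)
        n = len(Z)
        dt = 1.0 if times is None else float(np.diff(np.asarray(times)[:2])[0])
        lagf = int(round(self.lag_time / dt))
        if lagf < 1 or lagf >= n:
            raise ValueError(f"lag of {lagf} frames outside (0, {n})")
        w = (np.ones(n) if frame_weights is None
             else np.asarray(frame_weights, dtype=float) / np.mean(frame_weights))
        if np.any(w <= 0):
            raise ValueError("frame weights must be positive")
        n_val = max(lagf + 2, int(self.val_fraction * n))
        Zt, Zv = Z[:-n_val], Z[-n_val:]
        wt, wv = w[:-n_val], w[-n_val:]
        net = MLP([Z.shape[1], *self.hidden_sizes, self.n_out],
                  activation=self.activation, seed=self.seed,
                  linear_output=False)
        nt = len(Zt)
        idx0 = np.arange(nt - lagf)
        idx1 = idx0 + lagf
        p = np.sqrt(wt[idx0] * wt[idx1])
        psum = p.sum()
        wsum = wt.sum()
        best = (-np.inf, None, None, 0)
        for epoch in range(self.epochs):
            F, cache = net.forward(Zt, cache=True)
            lam, v, fmean = self._solve(F, lagf, wt)
            Y = (F - fmean) @ v
            y0, y1 = Y[idx0], Y[idx1]
            C00 = float((p * (y0**2 + y1**2)).sum() / (2 * psum))
            C01 = float((p * y0 * y1).sum() / psum)
            rho = C01 / C00
            loss = -rho
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite Deep-TICA loss at epoch {epoch}")
            dY = np.zeros(nt)
            dy0 = -(p * y1 / psum - rho * p * y0 / psum) / C00
            dy1 = -(p * y0 / psum - rho * p * y1 / psum) / C00
            np.add.at(dY, idx0, dy0)
            np.add.at(dY, idx1, dy1)
            dY -= wt / wsum * dY.sum()   # gradient through the weighted mean
            grads = net.backward(cache, dY[:, None] * v[None, :])
            net.adam_step(grads, self.lr)
            try:
                lam_v, _, _ = self._solve(net.forward(Zv), lagf, wv)
            except scipy.linalg.LinAlgError:
                lam_v = -np.inf
            if lam_v > best[0]:
                best = (lam_v, *net.get_weights(), epoch)
            elif epoch - best[3] > self.patience:
                break
        if best[1] is not None:
            net.set_weights(best[1], best[2])
        F = net.forward(Z)
        lam, v, fmean = self._solve(F, lagf, w)
        Y = (F - fmean) @ v
        var = float((w * (Y - (w * Y).sum() / w.sum())**2).sum() / w.sum())
        self.eigenvalue_ = float(lam)
        self.implied_timescale_ = float(-lagf * dt / np.log(np.clip(lam, 1e-12, 1 - 1e-12)))
        self.model_ = CVModel(
            kind="deep_tica", input_mean=mean, input_std=std, projection=v,
            offset=float(fmean @ v), scale=float(np.sqrt(var)),
            output_transform="identity", layers_W=net.W, layers_b=net.b,
            activation=self.activation,
            training_meta={"seed": self.seed, "lr": self.lr,
                           "lag_time": self.lag_time, "epochs": self.epochs,
                           "hidden_sizes": list(self.hidden_sizes),
                           "n_out": self.n_out})
        return self

    def transform(self, X):
        return self.model_.evaluate(X)[:, None]


# --------------------------------------------------------------------------
# spec-level convenience wrappers
# --------------------------------------------------------------------------

def train_deep_lda(X_B, X_U, hidden_sizes=(32, 16, 8), lr: float = 1e-3,
                   epochs: int = 300, reg_lambda: float | None = None,
                   seed: int = 0, activation: str = "tanh",
                   output_transform: str = "cubic") -> CVModel:
    X = np.vstack([np.asarray(X_U, dtype=float), np.asarray(X_B, dtype=float)])
    y = np.r_[np.zeros(len(X_U)), np.ones(len(X_B))]
    est = DeepLDACV(hidden_sizes=hidden_sizes, activation=activation, lr=lr,
                    epochs=epochs, reg_lambda=reg_lambda, seed=seed,
                    output_transform=output_transform).fit(X, y)
    return est.model_


def train_deep_tica(X, times=None, lag_time: float = 1.0,
                    frame_weights=None, hidden_sizes=(32, 16),
                    lr: float = 1e-3, epochs: int = 300,
                    seed: int = 0, activation: str = "tanh") -> CVModel:
    est = DeepTICACV(hidden_sizes=hidden_sizes, activation=activation, lr=lr,
                     epochs=epochs, lag_time=lag_time, seed=seed)
    est.fit(X, times=times, frame_weights=frame_weights)
    return est.model_
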