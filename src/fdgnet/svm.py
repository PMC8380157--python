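"""Polynomial-kernel support vector machine with a differentiable head.

The dual problem

    max Q(a) = sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t.  0 <= a_i <= C,   sum_i a_i y_i = 0,

with the inhomogeneous polynomial kernel K(x, z) = (x.z + 1)^q, is solved by
sequential minimal optimization (Platt's two-multiplier working-set scheme
with the second-choice |E1 - E2| heuristic).  The decision score is
s(x) = sum_i a_i y_i K(x, x_i) + b, classified by sign(s) (ties to +1).

For end-to-end training the sign is replaced by a two-way softmax over
(s, -s), so y0 = e^s / (e^s + e^-s) — equivalently the logistic 1/(1+e^-2s)
— which makes the cross-entropy loss differentiable in the embedding x
while the SVM parameters stay frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_CLIP = 1e-12


def poly_kernel(x: np.ndarray, z: np.ndarray, q: int) -> float:
    """Inhomogeneous polynomial kernel (x.z + 1)^q."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape[-1] != z.shape[-1]:
        raise ValueError(f"dimension mismatch {x.shape} vs {z.shape}")
    return (x @ z.T + 1.0) ** q if x.ndim > 1 or z.ndim > 1 else float((x @ z + 1.0) ** q)


@dataclass
class SVMTrainingConfig:
    C: float = 1.0
    q: int = 2
    tol: float = 1e-3
    max_passes: int = 200
    seed: int = 0
    standardize: bool = False  # z-score features before the kernel (off: raw embeddings)

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if int(self.q) != self.q or self.q < 1:
            raise ValueError("q must be an integer >= 1")
        self.q = int(self.q)
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class SVMModel:
    """Kernel expansion over the support set {i : a_i > 0}.

    When trained with ``standardize=True`` the model stores the feature
    mean/scale and applies them to every input before the kernel; the
    stored support vectors are then in standardized coordinates.
    """

    support_vectors: np.ndarray  # (n_sv, d)
    alphas: np.ndarray           # (n_sv,), in (0, C]
    labels: np.ndarray           # (n_sv,), +-1
    bias: float
    q: int
    C: float = 1.0
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_scale

    @property
    def weights(self) -> np.ndarray:
        """w_i = a_i y_i, the fixed output weights of the kernel expansion."""
        return self.alphas * self.labels

    @property
    def n_support(self) -> int:
        return len(self.alphas)


def dual_objective(alphas: np.ndarray, labels: np.ndarray, K: np.ndarray) -> float:
    """Q(a) for a full multiplier vector against a precomputed Gram matrix."""
    ay = alphas * labels
    return float(alphas.sum() - 0.5 * ay @ K @ ay)


class _SMOSolver:
    """Platt-style SMO on a precomputed Gram matrix."""

    EPS = 1e-8

    def __init__(self, K: np.ndarray, y: np.ndarray, C: float, tol: float,
                 rng: np.random.Generator) -> None:
        self.K, self.y, self.C, self.tol, self.rng = K, y, C, tol, rng
        n = len(y)
        self.a = np.zeros(n)
        self.b = 0.0
        self.E = -y.astype(float)  # f(x)=0 initially

    def _f(self, i: int) -> float:
        return float((self.a * self.y) @ self.K[i] + self.b)

    def _take_step(self, i1: int, i2: int) -> bool:
        if i1 == i2:
            return False
        a1, a2 = self.a[i1], self.a[i2]
        y1, y2 = self.y[i1], self.y[i2]
        E1, E2 = self.E[i1], self.E[i2]
        s = y1 * y2
        if s < 0:
            L, H = max(0.0, a2 - a1), min(self.C, self.C + a2 - a1)
        else:
            L, H = max(0.0, a1 + a2 - self.C), min(self.C, a1 + a2)
        if L >= H - self.EPS:
            return False
        k11, k12, k22 = self.K[i1, i1], self.K[i1, i2], self.K[i2, i2]
        eta = k11 + k22 - 2.0 * k12
        if eta > 0:
            a2n = a2 + y2 * (E1 - E2) / eta
            a2n = min(max(a2n, L), H)
        else:
            # objective at the two clip ends (degenerate curvature)
            f1 = y1 * (E1 + self.b) - a1 * k11 - s * a2 * k12
            f2 = y2 * (E2 + self.b) - s * a1 * k12 - a2 * k22
            L1, H1 = a1 + s * (a2 - L), a1 + s * (a2 - H)
            obj_l = (L1 * f1 + L * f2 + 0.5 * L1 * L1 * k11 + 0.5 * L * L * k22
                     + s * L * L1 * k12)
            obj_h = (H1 * f1 + H * f2 + 0.5 * H1 * H1 * k11 + 0.5 * H * H * k22
                     + s * H * H1 * k12)
            if obj_l < obj_h - self.EPS:
                a2n = L
            elif obj_l > obj_h + self.EPS:
                a2n = H
            else:
                return False
        if abs(a2n - a2) < self.EPS * (a2n + a2 + self.EPS):
            return False
        a1n = a1 + s * (a2 - a2n)
        b1 = self.b - E1 - y1 * (a1n - a1) * k11 - y2 * (a2n - a2) * k12
        b2 = self.b - E2 - y1 * (a1n - a1) * k12 - y2 * (a2n - a2) * k22
        if 0 < a1n < self.C:
            bn = b1
        elif 0 < a2n < self.C:
            bn = b2
        else:
            bn = 0.5 * (b1 + b2)
        da1, da2, db = a1n - a1, a2n - a2, bn - self.b
        self.a[i1], self.a[i2], self.b = a1n, a2n, bn
        self.E += y1 * da1 * self.K[i1] + y2 * da2 * self.K[i2] + db
        return True

    def _examine(self, i2: int) -> bool:
        y2, a2, E2 = self.y[i2], self.a[i2], self.E[i2]
        r2 = E2 * y2
        if (r2 < -self.tol and a2 < self.C) or (r2 > self.tol and a2 > 0):
            nb = np.flatnonzero((self.a > 0) & (self.a < self.C))
            if len(nb) > 1:
                i1 = int(nb[np.argmax(np.abs(self.E[nb] - E2))])
                if self._take_step(i1, i2):
                    return True
            if len(nb):
                start = self.rng.integers(len(nb))
                for k in range(len(nb)):
                    if self._take_step(int(nb[(start + k) % len(nb)]), i2):
                        return True
            n = len(self.y)
            start = self.rng.integers(n)
            for k in range(n):
                if self._take_step(int((start + k) % n), i2):
                    return True
        return False

    def solve(self, max_passes: int) -> bool:
        """Returns True on KKT convergence within ``max_passes`` sweeps."""
        examine_all = True
        for _sweep in range(max_passes):
            changed = 0
            idx = range(len(self.y)) if examine_all else \
                np.flatnonzero((self.a > 0) & (self.a < self.C))
            for i in idx:
                changed += self._examine(int(i))
            if examine_all:
                if changed == 0:
                    return True
                examine_all = False
            elif changed == 0:
                examine_all = True
        return False


def train_smo(features: np.ndarray, labels: np.ndarray,
              cfg: SVMTrainingConfig) -> SVMModel:
    """Solve the polynomial-kernel dual by SMO and return the support expansion.

    The bias is recomputed after convergence as the mean KKT value over
    non-bound support vectors (all support vectors if every one is at bound).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, d) matching labels")
    if len(X) < 2:
        raise ValueError("need at least 2 samples")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be +-1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    mean = scale = None
    if cfg.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale < 1e-12] = 1.0  # constant features pass through
        X = (X - mean) / scale
    K = (X @ X.T + 1.0) ** cfg.q
    solver = _SMOSolver(K, y, cfg.C, cfg.tol, np.random.default_rng(cfg.seed))
    if not solver.solve(cfg.max_passes):
        warnings.warn(f"SMO did not fully converge within {cfg.max_passes} sweeps; "
                      "returning best iterate")
    a, b = solver.a, solver.b
    ay = a * y
    # bias from KKT: for non-bound SVs, y_i = sum_j a_j y_j K_ij + b
    nb = np.flatnonzero((a > solver.EPS) & (a < cfg.C - solver.EPS))
    basis = nb if len(nb) else np.flatnonzero(a > solver.EPS)
    if len(basis):
        b = float(np.mean(y[basis] - K[basis] @ ay))
    sv = np.flatnonzero(a > solver.EPS)
    return SVMModel(support_vectors=X[sv].copy(), alphas=a[sv].copy(),
                    labels=y[sv].copy(), bias=float(b), q=cfg.q, C=cfg.C,
                    feature_mean=mean, feature_scale=scale)


def svm_score(m: SVMModel, x: np.ndarray) -> float | np.ndarray:
    """Pre-sign decision score s = sum_i a_i y_i K(x, x_i) + b.

    Accepts a single vector (returns a float) or an (n, d) batch.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None] if single else x
    if m.n_support == 0:
        s = np.full(len(X), m.bias)
    else:
        if X.shape[1] != m.support_vectors.shape[1]:
            raise ValueError(f"dimension mismatch: {X.shape[1]} vs "
                             f"{m.support_vectors.shape[1]}")
        Xt = m.transform(X)
        s = ((Xt @ m.support_vectors.T + 1.0) ** m.q) @ m.weights + m.bias
    return float(s[0]) if single else s


def svm_sign_predict(m: SVMModel, x: np.ndarray):
    """sign(s) with s = 0 mapped to +1."""
    s = svm_score(m, x)
    if np.isscalar(s):
        return 1 if s >= 0 else -1
    return np.where(np.asarray(s) >= 0, 1, -1)


def score_gradient(m: SVMModel, x: np.ndarray) -> np.ndarray:
    """ds/dx = sum_i a_i y_i q (x.x_i + 1)^(q-1) x_i, row-wise for batches."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None] if single else x
    if m.n_support == 0:
        g = np.zeros_like(X)
    else:
        Xt = m.transform(X)
        base = (Xt @ m.support_vectors.T + 1.0) ** (m.q - 1)
        g = (base * m.weights) @ m.support_vectors * m.q
        if m.feature_scale is not None:  # chain rule through the z-score
            g = g / m.feature_scale
    return g[0] if single else g


@dataclass
class SoftmaxOutput:
    y0: float  # probability of the positive class
    y1: float  # probability of the negative class
    s: float   # the underlying linear score

    def __post_init__(self) -> None:
        assert 0.0 < self.y0 < 1.0 and 0.0 < self.y1 < 1.0


def softmax_head(s: float) -> SoftmaxOutput:
    """Two-way softmax over (s, -s): y0 = e^s / (e^s + e^-s).

    Computed with max-subtraction so it is stable for |s| up to ~1e4;
    outputs are clipped away from exact 0/1 so downstream logs stay finite.
    """
    s = float(s)
    if not np.isfinite(s):
        raise ValueError("score must be finite")
    m = max(s, -s)
    e0, e1 = np.exp(s - m), np.exp(-s - m)
    y0 = e0 / (e0 + e1)
    y0 = min(max(y0, _CLIP), 1.0 - _CLIP)
    return SoftmaxOutput(y0=y0, y1=1.0 - y0, s=s)


def softmax_probs(s: np.ndarray) -> np.ndarray:
    """Vectorized y0 for a score array (same stable formulation)."""
    s = np.asarray(s, dtype=float)
    m = np.abs(s)
    e0, e1 = np.exp(s - m), np.exp(-s - m)
    return np.clip(e0 / (e0 + e1), _CLIP, 1.0 - _CLIP)


def binary_cross_entropy(targets: np.ndarray, y0s: np.ndarray) -> float:
    """H = -sum_i [p_i log y0_i + (1 - p_i) log(1 - y0_i)] (sum over samples)."""
    p = np.asarray(targets, dtype=float).ravel()
    y0 = np.asarray(y0s, dtype=float).ravel()
    if p.shape != y0.shape:
        raise ValueError("targets and probabilities must have equal length")
    if not set(np.unique(p)) <= {0.0, 1.0}:
        raise ValueError("targets must be 0/1")
    if np.any(y0 <= 0.0) or np.any(y0 >= 1.0):
        warnings.warn("probabilities at 0/1 clipped to (1e-12, 1 - 1e-12)")
        y0 = np.clip(y0, _CLIP, 1.0 - _CLIP)
    return float(-(p * np.log(y0) + (1.0 - p) * np.log(1.0 - y0)).sum())


def head_loss_and_grad(s: np.ndarray, p: np.ndarray) -> tuple[float, np.ndarray]:
    """Cross-entropy through the softmax head and its analytic dH/ds.

    Per-sample gradient is 2 (y0 - p); the returned loss is the sum over
    samples (divide by n for a mean-reduced objective).
    """
    y0 = softmax_probs(s)
    loss = binary_cross_entropy(p, y0)
    return loss, 2.0 * (y0 - np.asarray(p, dtype=float))


# -- serialization ---------------------------------------------------------

def save_svm(m: SVMModel, path) -> None:
    arrays = dict(support_vectors=m.support_vectors, alphas=m.alphas,
                  labels=m.labels, bias=np.array([m.bias]),
                  q=np.array([m.q]), C=np.array([m.C]))
    if m.feature_mean is not None:
        arrays["feature_mean"] = m.feature_mean
        arrays["feature_scale"] = m.feature_scale
    np.savez(path, **arrays)


def load_svm(path) -> SVMModel:
    with np.load(path) as z:
        return SVMModel(support_vectors=z["support_vectors"], alphas=z["alphas"],
                        labels=z["labels"], bias=float(z["bias"][0]),
                        q=int(z["q"][0]), C=float(z["C"][0]),
                        feature_mean=z.get("feature_mean"),
                        feature_scale=z.get("feature_scale"))


def export_svm_csv(m: SVMModel, path) -> None:
    """Inspection CSV: one row per support vector (index, alpha, y, weight)."""
    import pandas as pd

    pd.DataFrame({"index": np.arange(m.n_support), "alpha": m.alphas,
                  "y": m.labels.astype(int), "weight": m.weights}).to_csv(path, index=False)
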