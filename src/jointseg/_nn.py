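"""Minimal feed-forward neural network backend (numpy).

Implements exactly what the two type classifiers need and nothing more:
fully-connected layers with Xavier-uniform initialization, per-layer batch
normalization followed by tanh, a softmax output head, L1 or L2 weight
penalties, cross-entropy loss, and Adam with mini-batches. Batch-norm running
statistics are frozen at inference, so a trained network is a deterministic
function; all stochasticity (init, shuffling) comes from the seed.
"""

from __future__ import annotations

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9
_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLP:
    """Feed-forward classifier: [linear → batchnorm → tanh]*H → linear → softmax.

    Parameters
    ----------
    penalty : {"l1", "l2"}
        Weight penalty applied to every weight matrix including the output
        layer; coefficient ``lam``.
    """

    def __init__(
        self,
        n_in: int,
        hidden: tuple[int, ...],
        n_out: int,
        *,
        penalty: str = "l2",
        lam: float = 1e-3,
        seed: int = 0,
    ) -> None:
        if penalty not in ("l1", "l2"):
            raise ValueError("penalty must be 'l1' or 'l2'")
        self.n_in, self.hidden, self.n_out = n_in, tuple(hidden), n_out
        self.penalty, self.lam = penalty, float(lam)
        rng = np.random.default_rng(seed)
        dims = [n_in, *hidden, n_out]
        self.W = [_xavier(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 1)]
        self.b_out = np.zeros(n_out)
        nh = len(hidden)
        self.gamma = [np.ones(h) for h in hidden]
        self.beta = [np.zeros(h) for h in hidden]
        self.run_mean = [np.zeros(h) for h in hidden]
        self.run_var = [np.ones(h) for h in hidden]
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0

    # ---- parameter bookkeeping -------------------------------------------------
    def _params(self) -> list[np.ndarray]:
        return [*self.W, self.b_out, *self.gamma, *self.beta]

    def _init_adam(self) -> None:
        if self._adam_m is None:
            self._adam_m = [np.zeros_like(p) for p in self._params()]
            self._adam_v = [np.zeros_like(p) for p in self._params()]

    def copy(self) -> "MLP":
        other = MLP(
            self.n_in, self.hidden, self.n_out, penalty=self.penalty, lam=self.lam
        )
        other.W = [w.copy() for w in self.W]
        other.b_out = self.b_out.copy()
        other.gamma = [g.copy() for g in self.gamma]
        other.beta = [b.copy() for b in self.beta]
        other.run_mean = [r.copy() for r in self.run_mean]
        other.run_var = [r.copy() for r in self.run_var]
        return other

    # ---- forward / backward ----------------------------------------------------
    def _forward(self, X: np.ndarray, training: bool):
        caches = []
        h = X
        for i in range(len(self.hidden)):
            z = h @ self.W[i]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                self.run_mean[i] = _BN_MOMENTUM * self.run_mean[i] + (1 - _BN_MOMENTUM) * mu
                self.run_var[i] = _BN_MOMENTUM * self.run_var[i] + (1 - _BN_MOMENTUM) * var
            else:
                mu, var = self.run_mean[i], self.run_var[i]
            ivar = 1.0 / np.sqrt(var + _BN_EPS)
            zhat = (z - mu) * ivar
            a = np.tanh(self.gamma[i] * zhat + self.beta[i])
            caches.append((h, zhat, ivar, a))
            h = a
        logits = h @ self.W[-1] + self.b_out
        return logits, caches

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(np.asarray(X, np.float64), training=False)
        return softmax(logits)

    def _reg_loss(self) -> float:
        if self.penalty == "l1":
            return self.lam * sum(np.abs(w).sum() for w in self.W)
        return self.lam * sum((w**2).sum() for w in self.W)

    def _reg_grad(self, w: np.ndarray) -> np.ndarray:
        if self.penalty == "l1":
            return self.lam * np.sign(w)
        return 2.0 * self.lam * w

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(X)
        nll = -np.mean(np.log(p[np.arange(len(y)), y] + 1e-12))
        return float(nll + self._reg_loss())

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict_proba(X).argmax(axis=1) == y))

    def _backward(self, X, y, logits, caches):
        B = X.shape[0]
        p = softmax(logits)
        dz = p.copy()
        dz[np.arange(B), y] -= 1.0
        dz /= B
        h_last = caches[-1][3] if caches else X
        gW = [None] * len(self.W)
        gW[-1] = h_last.T @ dz + self._reg_grad(self.W[-1])
        gb_out = dz.sum(axis=0)
        dh = dz @ self.W[-1].T
        gGamma = [None] * len(self.hidden)
        gBeta = [None] * len(self.hidden)
        for i in range(len(self.hidden) - 1, -1, -1):
            h_in, zhat, ivar, a = caches[i]
            dpre = dh * (1.0 - a**2)  # tanh'
            gGamma[i] = (dpre * zhat).sum(axis=0)
            gBeta[i] = dpre.sum(axis=0)
            dzhat = dpre * self.gamma[i]
            dz_lin = (ivar / B) * (
                B * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0)
            )
            gW[i] = h_in.T @ dz_lin + self._reg_grad(self.W[i])
            dh = dz_lin @ self.W[i].T
        return [*gW, gb_out, *gGamma, *gBeta]

    def _adam_step(self, grads: list[np.ndarray], lr: float) -> None:
        self._init_adam()
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(self._params(), grads, self._adam_m, self._adam_v):
            m *= _ADAM_B1
            m += (1 - _ADAM_B1) * g
            v *= _ADAM_B2
            v += (1 - _ADAM_B2) * g**2
            mhat = m / (1 - _ADAM_B1**t)
            vhat = v / (1 - _ADAM_B2**t)
            p -= lr * mhat / (np.sqrt(vhat) + _ADAM_EPS)

    # ---- training ---------------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int,
        lr: float,
        batch_size: int = 64,
        rng: np.random.Generator,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        trace: list | None = None,
    ) -> "MLP":
        X = np.asarray(X, np.float64)
        y = np.asarray(y, np.int64)
        n = X.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                sel = order[start : start + batch_size]
                logits, caches = self._forward(X[sel], training=True)
                grads = self._backward(X[sel], y[sel], logits, caches)
                self._adam_step(grads, lr)
            if trace is not None:
                rec = {
                    "train_loss": self.loss(X, y),
                    "train_acc": self.accuracy(X, y),
                }
                if X_val is not None and len(X_val):
                    rec["val_loss"] = self.loss(X_val, y_val)
                    rec["val_acc"] = self.accuracy(X_val, y_val)
                trace.append(rec)
        return self
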