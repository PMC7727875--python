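"""Count autoencoder with a zero-inflated negative-binomial noise model.

A small fully-connected autoencoder trained directly against raw counts.
The encoder consumes size-factor-normalized, log1p-transformed, per-gene
z-scored expression; the decoder parameterizes, per gene and cell, the mean
mu (exponential output scaled by the cell's library-size factor), the
dispersion theta (softplus) and — for the zinb model — the dropout
probability pi (sigmoid). The training loss is the negative log-likelihood
of the raw counts:

    NB(x; mu, theta) = Gamma(x+theta) / (Gamma(theta) x!)
                       * (theta/(theta+mu))^theta * (mu/(theta+mu))^x
    ZINB(x) = pi * 1[x=0] + (1 - pi) * NB(x)

Hidden layers are dense + batch normalization + ReLU, in the style of
published count autoencoders; the bottleneck (smallest) layer is a plain
linear layer, and its activations are the per-cell manifold coordinates.
Optimization is Adam with minibatches, learning-rate halving on validation
plateau, and early stopping with best-weight restore.

Everything here is plain numpy with hand-derived gradients; the analytic
gradient is checked against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, digamma

_EPS = 1e-8
_BN_EPS = 1e-5
_THETA_FLOOR = 1e-4
_ACT_CLIP = 15.0  # pre-activation clip for the exponential mean head


def nb_log_likelihood(x: np.ndarray, mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Element-wise log-pmf of the negative binomial in (mean, dispersion) form."""
    t = theta
    return (
        gammaln(x + t) - gammaln(t) - gammaln(x + 1.0)
        + t * (np.log(t) - np.log(t + mu))
        + x * (np.log(mu + _EPS) - np.log(t + mu))
    )


def zinb_log_likelihood(
    x: np.ndarray, mu: np.ndarray, theta: np.ndarray, pi: np.ndarray
) -> np.ndarray:
    """Element-wise ZINB log-likelihood; pi is the structural-zero probability."""
    nb_ll = nb_log_likelihood(x, mu, theta)
    zero_case = np.log(
        pi + (1.0 - pi) * np.exp(theta * (np.log(theta) - np.log(theta + mu))) + _EPS
    )
    return np.where(x < 0.5, zero_case, np.log1p(-pi + _EPS) + nb_ll)


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; advise a smaller learning rate."""


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class CountAutoencoder:
    """ZINB/NB denoising autoencoder for a gene-set count submatrix.

    Parameters
    ----------
    n_genes
        Number of input genes (features).
    hidden_layers
        Symmetric layer widths around the bottleneck, e.g. ``(64, 2, 64)``.
        The middle (smallest) entry is the bottleneck dimension.
    noise_model
        ``"zinb"`` (default) or ``"nb"`` (no dropout head).
    batchnorm
        Batch-normalize the non-bottleneck hidden layers (default True).
    """

    def __init__(
        self,
        n_genes: int,
        hidden_layers: tuple[int, ...] = (64, 2, 64),
        noise_model: str = "zinb",
        batchnorm: bool = True,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ) -> None:
        if len(hidden_layers) % 2 == 0:
            raise ValueError("hidden_layers must have odd length (symmetric around bottleneck)")
        if noise_model not in ("zinb", "nb"):
            raise ValueError(f"unknown noise model {noise_model!r}")
        self.n_genes = n_genes
        self.hidden_layers = tuple(int(h) for h in hidden_layers)
        self.mid = len(self.hidden_layers) // 2
        self.noise_model = noise_model
        self.batchnorm = batchnorm
        self.learning_rate = learning_rate
        self.rng = np.random.default_rng(seed)
        self._init_params()
        self.train_loss_history: list[float] = []
        self.val_loss_history: list[float] = []

    # -- parameters ---------------------------------------------------------

    def _glorot(self, fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return self.rng.uniform(-limit, limit, size=(fan_in, fan_out))

    def _has_bn(self, l: int) -> bool:
        return self.batchnorm and l != self.mid

    def _init_params(self) -> None:
        sizes = [self.n_genes, *self.hidden_layers]
        self.W, self.b, self.gamma, self.beta = [], [], [], []
        self.run_mean, self.run_var = [], []
        for l in range(len(sizes) - 1):
            self.W.append(self._glorot(sizes[l], sizes[l + 1]))
            if self._has_bn(l):
                # bias is absorbed by the batchnorm shift
                self.b.append(None)
                self.gamma.append(np.ones(sizes[l + 1]))
                self.beta.append(np.zeros(sizes[l + 1]))
                self.run_mean.append(np.zeros(sizes[l + 1]))
                self.run_var.append(np.ones(sizes[l + 1]))
            else:
                # small positive bias keeps ReLU units off their kink at init
                self.b.append(np.full(sizes[l + 1], 0.01))
                self.gamma.append(None)
                self.beta.append(None)
                self.run_mean.append(None)
                self.run_var.append(None)
        last = self.hidden_layers[-1]
        heads = ["mean", "disp"] + (["drop"] if self.noise_model == "zinb" else [])
        self.head_W = {h: self._glorot(last, self.n_genes) for h in heads}
        self.head_b = {h: np.zeros(self.n_genes) for h in heads}

    def _params(self) -> list[np.ndarray]:
        out = []
        for l in range(len(self.W)):
            out.append(self.W[l])
            if self._has_bn(l):
                out += [self.gamma[l], self.beta[l]]
            else:
                out.append(self.b[l])
        for h in sorted(self.head_W):
            out += [self.head_W[h], self.head_b[h]]
        return out

    def _snapshot_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self._params()] + [
            m.copy() for m in self.run_mean if m is not None
        ] + [v.copy() for v in self.run_var if v is not None]

    def _restore_state(self, state: list[np.ndarray]) -> None:
        params = self._params()
        for p, s in zip(params, state):
            p[...] = s
        rest = state[len(params):]
        k = 0
        for m in self.run_mean:
            if m is not None:
                m[...] = rest[k]
                k += 1
        for v in self.run_var:
            if v is not None:
                v[...] = rest[k]
                k += 1

    # -- forward ------------------------------------------------------------

    def _trunk(self, X: np.ndarray, train: bool, cache: dict | None = None) -> np.ndarray:
        a = X
        for l in range(len(self.W)):
            z = a @ self.W[l]
            if self._has_bn(l):
                if train:
                    m, v = z.mean(axis=0), z.var(axis=0)
                    self.run_mean[l] = 0.9 * self.run_mean[l] + 0.1 * m
                    self.run_var[l] = 0.9 * self.run_var[l] + 0.1 * v
                else:
                    m, v = self.run_mean[l], self.run_var[l]
                zhat = (z - m) / np.sqrt(v + _BN_EPS)
                pre = self.gamma[l] * zhat + self.beta[l]
                a_next = _relu(pre)
            else:
                zhat = None
                pre = z + self.b[l]
                a_next = pre if l == self.mid else _relu(pre)
            if cache is not None:
                cache[l] = {"a_in": a, "zhat": zhat, "pre": pre,
                            "var": v if self._has_bn(l) else None}
            a = a_next
        return a

    def _heads(self, H: np.ndarray, s: np.ndarray) -> dict:
        out = {"H": H}
        am = np.clip(H @ self.head_W["mean"] + self.head_b["mean"], -_ACT_CLIP, _ACT_CLIP)
        out["am"] = am
        out["mu"] = s[:, None] * np.exp(am)
        ad = np.clip(H @ self.head_W["disp"] + self.head_b["disp"], -_ACT_CLIP, _ACT_CLIP)
        out["ad"] = ad
        out["theta"] = _softplus(ad) + _THETA_FLOOR
        if self.noise_model == "zinb":
            ap = np.clip(H @ self.head_W["drop"] + self.head_b["drop"], -_ACT_CLIP, _ACT_CLIP)
            out["ap"] = ap
            out["pi"] = _sigmoid(ap)
        return out

    def _log_likelihood(self, Y: np.ndarray, f: dict) -> np.ndarray:
        if self.noise_model == "zinb":
            return zinb_log_likelihood(Y, f["mu"], f["theta"], f["pi"])
        return nb_log_likelihood(Y, f["mu"], f["theta"])

    def loss(self, X: np.ndarray, Y: np.ndarray, s: np.ndarray, train: bool = False) -> float:
        """Mean negative log-likelihood; ``train`` selects batch-stat normalization."""
        H = self._trunk(X, train=train)
        return float(-np.mean(self._log_likelihood(Y, self._heads(H, s))))

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Bottleneck activations (cells x bottleneck_dim), inference mode."""
        a = X
        for l in range(self.mid + 1):
            z = a @ self.W[l]
            if self._has_bn(l):
                zhat = (z - self.run_mean[l]) / np.sqrt(self.run_var[l] + _BN_EPS)
                a = _relu(self.gamma[l] * zhat + self.beta[l])
            else:
                pre = z + self.b[l]
                a = pre if l == self.mid else _relu(pre)
        return a

    # -- gradients ----------------------------------------------------------

    def _loss_and_grads(
        self, X: np.ndarray, Y: np.ndarray, s: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        cache: dict = {}
        H = self._trunk(X, train=True, cache=cache)
        f = self._heads(H, s)
        mu, theta = f["mu"], f["theta"]
        n = Y.size
        zero = Y < 0.5
        tm = theta + mu

        if self.noise_model == "zinb":
            pi = f["pi"]
            nb0 = theta * (np.log(theta) - np.log(tm))
            e0 = np.exp(nb0)
            L0 = pi + (1.0 - pi) * e0 + _EPS
            r = (1.0 - pi) * e0 / L0
            dmu = np.where(zero, r * (-theta / tm), Y / (mu + _EPS) - (Y + theta) / tm)
            dtheta = np.where(
                zero,
                r * (np.log(theta) + 1.0 - np.log(tm) - theta / tm),
                digamma(Y + theta) - digamma(theta)
                + np.log(theta) + 1.0 - np.log(tm) - (theta + Y) / tm,
            )
            dpi = np.where(zero, (1.0 - e0) / L0, -1.0 / (1.0 - pi + _EPS))
            ll = np.where(zero, np.log(L0), np.log1p(-pi + _EPS) + nb_log_likelihood(Y, mu, theta))
        else:
            dmu = Y / (mu + _EPS) - (Y + theta) / tm
            dtheta = (
                digamma(Y + theta) - digamma(theta)
                + np.log(theta) + 1.0 - np.log(tm) - (theta + Y) / tm
            )
            dpi = None
            ll = nb_log_likelihood(Y, mu, theta)
        loss = float(-np.mean(ll))

        d_am = (-dmu * mu) / n
        d_ad = (-dtheta * _sigmoid(f["ad"])) / n
        head_grads = {
            "mean": (H.T @ d_am, d_am.sum(0)),
            "disp": (H.T @ d_ad, d_ad.sum(0)),
        }
        dH = d_am @ self.head_W["mean"].T + d_ad @ self.head_W["disp"].T
        if self.noise_model == "zinb":
            pi = f["pi"]
            d_ap = (-dpi * pi * (1.0 - pi)) / n
            head_grads["drop"] = (H.T @ d_ap, d_ap.sum(0))
            dH += d_ap @ self.head_W["drop"].T

        flat_trunk: list[np.ndarray] = []
        da = dH
        per_layer: list[list[np.ndarray]] = [None] * len(self.W)
        for l in range(len(self.W) - 1, -1, -1):
            c = cache[l]
            if self._has_bn(l):
                dpre = da * (c["pre"] > 0)
                g_gamma = (dpre * c["zhat"]).sum(0)
                g_beta = dpre.sum(0)
                dzhat = dpre * self.gamma[l]
                inv = 1.0 / np.sqrt(c["var"] + _BN_EPS)
                # batch-stat backprop: remove mean and variance components
                dz = inv * (
                    dzhat - dzhat.mean(0) - c["zhat"] * (dzhat * c["zhat"]).mean(0)
                )
                per_layer[l] = [c["a_in"].T @ dz, g_gamma, g_beta]
            else:
                dpre = da if l == self.mid else da * (c["pre"] > 0)
                dz = dpre
                per_layer[l] = [c["a_in"].T @ dz, dz.sum(0)]
            da = dz @ self.W[l].T
        for l in range(len(self.W)):
            flat_trunk += per_layer[l]
        for h in sorted(self.head_W):
            flat_trunk += [head_grads[h][0], head_grads[h][1]]
        return loss, flat_trunk

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        size_factors: np.ndarray,
        epochs: int = 300,
        patience: int = 15,
        batch_size: int = 32,
        validation_split: float = 0.1,
        lr_patience: int = 8,
        lr_factor: float = 0.5,
    ) -> "CountAutoencoder":
        """Train on preprocessed input ``X`` against raw counts ``Y`` (both cells x genes).

        The learning rate is halved whenever the validation loss plateaus for
        ``lr_patience`` epochs; training stops after ``epochs`` or when the
        validation loss has not improved for ``patience`` consecutive epochs,
        and the best weights (with their batchnorm statistics) are restored.
        """
        n_cells = X.shape[0]
        perm = self.rng.permutation(n_cells)
        n_val = max(1, int(round(validation_split * n_cells))) if n_cells >= 10 else 0
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xt, Yt, st = X[train_idx], Y[train_idx], size_factors[train_idx]
        if n_val:
            Xv, Yv, sv = X[val_idx], Y[val_idx], size_factors[val_idx]
        n_train = len(train_idx)
        if batch_size > n_train:
            batch_size = n_train

        params = self._params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = np.inf
        best_state = self._snapshot_state()
        stall = 0
        lr_stall = 0
        lr = self.learning_rate
        for epoch in range(epochs):
            order = self.rng.permutation(n_train)
            epoch_losses = []
            for start in range(0, n_train, batch_size):
                idx = order[start : start + batch_size]
                if self.batchnorm and len(idx) < 2:
                    continue  # batch statistics undefined for a single cell
                loss, grads = self._loss_and_grads(Xt[idx], Yt[idx], st[idx])
                if not np.isfinite(loss):
                    raise TrainingDiverged(
                        "training loss is non-finite; try a smaller learning rate"
                    )
                epoch_losses.append(loss)
                t += 1
                lr_t = lr * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    p -= lr_t * mi / (np.sqrt(vi) + eps)
            self.train_loss_history.append(float(np.mean(epoch_losses)))
            val_loss = self.loss(Xv, Yv, sv) if n_val else self.train_loss_history[-1]
            self.val_loss_history.append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = self._snapshot_state()
                stall = 0
                lr_stall = 0
            else:
                stall += 1
                lr_stall += 1
                if lr_stall >= lr_patience:
                    lr *= lr_factor
                    lr_stall = 0
                if stall >= patience:
                    break
        self._restore_state(best_state)
        return self
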