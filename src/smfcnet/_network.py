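"""NumPy implementation of the two-layer connectome-convolution network.

Each of the d input connectivity matrices feeds its own branch:

* layer 1 ("regional connectivity"): a 1 x N kernel with H channels sweeps
  the rows of the N x N matrix — output N x 1 x H, i.e. each ROI's row of
  correlations is linearly mixed into H features;
* layer 2 ("spatial integration"): an N x 1 kernel with V channels collapses
  the ROI axis — output 1 x 1 x V.

The d branch outputs are concatenated (d*V features) and passed through two
dense layers and a 2-way softmax. Cross-shaped kernels of this kind act on
a node's full set of connections rather than on square image neighborhoods,
which is the appropriate receptive field for connectome matrices.

Training is plain mini-batch Adam on the cross-entropy loss with an L2
penalty on the convolution kernels and inverted dropout after concatenation
and after the first dense layer. Everything is seeded and single-threaded
deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FCConvNetwork"]


def _relu(z):
    return np.maximum(z, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class FCConvNetwork:
    """The d-branch FC-Conv classifier head, with manual backprop and Adam.

    Parameters follow the published configuration: H regional-connectivity
    channels, V spatial-integration channels, dense widths D1 and D2,
    dropout rate after concatenation and after the first dense layer, and an
    L2 coefficient applied to both convolution kernels. Convolution kernels
    are he_normal-initialized; dense layers use Glorot-uniform.
    """

    def __init__(self, n_rois: int, n_branches: int, H: int = 64, V: int = 32,
                 D1: int = 128, D2: int = 64, dropout: float = 0.2,
                 l2_coeff: float = 1e-5, lr: float = 1e-3, seed: int = 0):
        if not 0 <= dropout < 1:
            raise ValueError(f"dropout must be in [0, 1), got {dropout}")
        self.N, self.d = int(n_rois), int(n_branches)
        self.H, self.V, self.D1, self.D2 = int(H), int(V), int(D1), int(D2)
        self.dropout = float(dropout)
        self.l2_coeff = float(l2_coeff)
        self.lr = float(lr)
        self.rng = np.random.default_rng(seed)
        self._init_params()
        self._init_adam()

    # -- parameters ---------------------------------------------------------

    #: parameters and activations are float32 (the convention of the deep
    #: learning stacks this architecture comes from; halves memory traffic)
    DTYPE = np.float32

    def _init_params(self):
        rng, N, d, H, V, D1, D2 = self.rng, self.N, self.d, self.H, self.V, self.D1, self.D2
        f32 = self.DTYPE
        he = lambda fan_in, shape: rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(f32)

        def glorot(fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, (fan_in, fan_out)).astype(f32)

        self.params = {
            "K1": he(N, (d, H, N)),          # 1 x N kernels, H channels, per branch
            "b1": np.zeros((d, H), f32),
            "K2": he(N * H, (d, V, N, H)),   # N x 1 kernels over the H maps, V channels
            "b2": np.zeros((d, V), f32),
            "W1": glorot(d * V, D1),
            "c1": np.zeros(D1, f32),
            "W2": glorot(D1, D2),
            "c2": np.zeros(D2, f32),
            "W3": glorot(D2, 2),
            "c3": np.zeros(2, f32),
        }

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def parameter_checksum(self) -> float:
        """Order-independent fingerprint of the weights (for no-update asserts)."""
        return float(sum(np.abs(p).sum() for p in self.params.values()))

    def _init_adam(self):
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0

    # -- forward ------------------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False, return_cache: bool = False):
        """Probabilities for a batch of stacks ``X`` of shape (B, d, N, N).

        In training mode dropout masks are sampled from the network RNG; in
        eval mode the forward pass is deterministic.
        """
        p = self.params
        X = np.asarray(X, dtype=self.DTYPE)
        Z1 = np.einsum("bdnm,dhm->bdnh", X, p["K1"], optimize=True) + p["b1"][None, :, None, :]
        A1 = _relu(Z1)                                           # (B, d, N, H)
        Z2 = np.einsum("bdnh,dvnh->bdv", A1, p["K2"], optimize=True) + p["b2"][None]
        A2 = _relu(Z2)                                           # (B, d, V)
        F0 = A2.reshape(X.shape[0], self.d * self.V)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            m1 = ((self.rng.random(F0.shape) < keep) / keep).astype(self.DTYPE)
        else:
            m1 = 1.0
        F1 = F0 * m1
        Zf1 = F1 @ p["W1"] + p["c1"]
        Af1 = _relu(Zf1)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            m2 = ((self.rng.random(Af1.shape) < keep) / keep).astype(self.DTYPE)
        else:
            m2 = 1.0
        F2 = Af1 * m2
        Zf2 = F2 @ p["W2"] + p["c2"]
        Af2 = _relu(Zf2)
        logits = Af2 @ p["W3"] + p["c3"]
        probs = _softmax(logits)
        if not return_cache:
            return probs
        cache = dict(X=X, Z1=Z1, A1=A1, Z2=Z2, F1=F1, m1=m1, Zf1=Zf1, m2=m2,
                     F2=F2, Zf2=Zf2, Af2=Af2, probs=probs)
        return probs, cache

    def intermediate_shapes(self, X: np.ndarray) -> dict:
        """Shapes along the branch chain, for contract checks."""
        _, cache = self.forward(X[:1], train=False, return_cache=True)
        return {
            "input": cache["X"].shape[1:],            # (d, N, N)
            "regional": cache["A1"].shape[1:],        # (d, N, H)  ~ d x (N x 1 x H)
            "spatial": cache["Z2"].shape[1:],         # (d, V)     ~ d x (1 x 1 x V)
            "concat": (self.d * self.V,),
            "dense1": (self.D1,),
            "dense2": (self.D2,),
            "softmax": (2,),
        }

    # -- backward / training ------------------------------------------------

    def loss(self, probs: np.ndarray, y: np.ndarray) -> float:
        ce = -np.mean(np.log(probs[np.arange(y.size), y] + 1e-12))
        reg = self.l2_coeff * (np.sum(self.params["K1"] ** 2) + np.sum(self.params["K2"] ** 2))
        return float(ce + reg)

    def _gradients(self, cache: dict, y: np.ndarray) -> dict:
        p = self.params
        B = y.size
        dlogits = cache["probs"].copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        g = {}
        g["W3"] = cache["Af2"].T @ dlogits
        g["c3"] = dlogits.sum(0)
        dAf2 = dlogits @ p["W3"].T
        dZf2 = dAf2 * (cache["Zf2"] > 0)
        g["W2"] = cache["F2"].T @ dZf2
        g["c2"] = dZf2.sum(0)
        dF2 = dZf2 @ p["W2"].T
        dAf1 = dF2 * cache["m2"]
        dZf1 = dAf1 * (cache["Zf1"] > 0)
        g["W1"] = cache["F1"].T @ dZf1
        g["c1"] = dZf1.sum(0)
        dF1 = dZf1 @ p["W1"].T
        dF0 = dF1 * cache["m1"]
        dA2 = dF0.reshape(B, self.d, self.V)
        dZ2 = dA2 * (cache["Z2"] > 0)
        g["K2"] = np.einsum("bdv,bdnh->dvnh", dZ2, cache["A1"], optimize=True) + 2 * self.l2_coeff * p["K2"]
        g["b2"] = dZ2.sum(0)
        dA1 = np.einsum("bdv,dvnh->bdnh", dZ2, p["K2"], optimize=True)
        dZ1 = dA1 * (cache["Z1"] > 0)
        g["K1"] = np.einsum("bdnh,bdnm->dhm", dZ1, cache["X"], optimize=True) + 2 * self.l2_coeff * p["K1"]
        g["b1"] = dZ1.sum(axis=(0, 2))
        return g

    def _adam_step(self, grads: dict, beta1=0.9, beta2=0.999, eps=1e-7):
        self._t += 1
        lr_t = self.DTYPE(self.lr * np.sqrt(1 - beta2**self._t) / (1 - beta1**self._t))
        b1, b2 = self.DTYPE(beta1), self.DTYPE(beta2)
        for k, gk in grads.items():
            m, v = self._m[k], self._v[k]
            m *= b1
            m += (1 - b1) * gk
            v *= b2
            v += (1 - b2) * np.square(gk)
            self.params[k] -= lr_t * m / (np.sqrt(v) + self.DTYPE(eps))

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 200,
            batch_size: int = 20) -> list[float]:
        """Mini-batch Adam training; returns the per-epoch mean training loss."""
        X = np.ascontiguousarray(X, dtype=self.DTYPE)
        n = y.size
        history = []
        for _ in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                probs, cache = self.forward(X[idx], train=True, return_cache=True)
                losses.append(self.loss(probs, y[idx]))
                self._adam_step(self._gradients(cache, y[idx]))
            history.append(float(np.mean(losses)))
        return history
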