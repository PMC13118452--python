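"""A small, fully seeded numpy MLP with batch-norm, dropout and focal loss.

Just enough neural network for the mass-defect-filter classifier: dense
layers with He initialization, batch normalization placed after each
linear layer and before the ReLU, inverted dropout, an Adam optimizer
with L2 regularization, and a softmax head trained with focal loss.
Float32 throughout; all randomness flows from one numpy Generator so
identical seeds give identical training histories.

Two implementation choices exist purely for single-core speed: every
trainable parameter is a view into one flat buffer so Adam runs as a
handful of long vector operations, and inference-mode batch norm is
folded into a single ``x * a + b``.

Gradient correctness of the full stack (including the batch-norm and
focal-loss backward passes) is verified against finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MlpNetwork", "AdamOptimizer", "focal_loss", "softmax"]

_EPS = 1e-12


def softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def focal_loss(
    probs: np.ndarray, labels: np.ndarray, alpha: float = 0.25, gamma: float = 2.0
) -> float:
    """Mean focal loss  -alpha * (1 - p_t)^gamma * log(p_t)  over samples.

    ``probs`` are class probabilities (n, k); ``labels`` integer classes.
    With gamma=0 and alpha=1 this reduces to mean cross-entropy.
    """
    p_t = np.clip(probs[np.arange(len(labels)), labels], _EPS, 1.0)
    return float(np.mean(-alpha * (1.0 - p_t) ** gamma * np.log(p_t)))


def _focal_grad_logits(
    probs: np.ndarray, labels: np.ndarray, alpha: float, gamma: float
) -> np.ndarray:
    """d(mean focal loss)/d(logits) for a softmax head.

    With t the true class, p_t its probability and dL/dp_t =
    -alpha * [ (1-p_t)^gamma / p_t - gamma (1-p_t)^(gamma-1) log p_t ],
    the chain rule through softmax gives
    dL/dz_j = dL/dp_t * p_t * (delta_tj - p_j).
    """
    n = len(labels)
    idx = np.arange(n)
    p_t = np.clip(probs[idx, labels], _EPS, 1.0)
    one_m = np.clip(1.0 - p_t, 0.0, 1.0)
    dl_dpt = -alpha * (one_m**gamma / p_t - gamma * one_m ** max(gamma - 1.0, 0.0) * np.log(p_t))
    grad = probs * (-(dl_dpt * p_t))[:, None]
    grad[idx, labels] += dl_dpt * p_t
    return (grad / n).astype(probs.dtype)


class MlpNetwork:
    """Dense -> BN -> ReLU -> Dropout stack with a linear softmax head.

    Parameter layout (per hidden layer, in order): W, b, gamma, beta;
    then the head W, b.  All parameters are views into ``_flat``.
    """

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(
        self,
        input_dim: int,
        hidden: tuple[int, ...],
        output_dim: int = 2,
        dropout: float = 0.01,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if dropout < 0 or dropout >= 1:
            raise ValueError("dropout must lie in [0, 1)")
        rng = rng or np.random.default_rng(0)
        self.dropout = dropout
        self.dtype = dtype
        self.hidden = tuple(hidden)
        dims = (input_dim, *hidden)

        shapes: list[tuple[int, ...]] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            shapes += [(d_in, d_out), (d_out,), (d_out,), (d_out,)]
        shapes += [(dims[-1], output_dim), (output_dim,)]
        total = sum(int(np.prod(s)) for s in shapes)
        self._flat = np.zeros(total, dtype=dtype)
        self._params: list[np.ndarray] = []
        offset = 0
        for s in shapes:
            size = int(np.prod(s))
            self._params.append(self._flat[offset : offset + size].reshape(s))
            offset += size

        for li, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
            w, _, gamma, _ = self._params[4 * li : 4 * li + 4]
            w[...] = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
            gamma[...] = 1.0
        head_w = self._params[-2]
        head_w[...] = rng.normal(0.0, np.sqrt(2.0 / dims[-1]), size=head_w.shape)

        self.running_mean = [np.zeros(d, dtype=dtype) for d in hidden]
        self.running_var = [np.ones(d, dtype=dtype) for d in hidden]
        self._cache: list[tuple] = []

    # ------------------------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return self._params

    @property
    def flat_parameters(self) -> np.ndarray:
        return self._flat

    def get_state(self) -> dict[str, list[np.ndarray] | np.ndarray]:
        return {
            "flat": self._flat.copy(),
            "running_mean": [m.copy() for m in self.running_mean],
            "running_var": [v.copy() for v in self.running_var],
        }

    def set_state(self, state) -> None:
        self._flat[...] = state["flat"]
        for dst, src in zip(self.running_mean, state["running_mean"]):
            dst[...] = src
        for dst, src in zip(self.running_var, state["running_var"]):
            dst[...] = src

    def _layer_params(self, li: int):
        return self._params[4 * li : 4 * li + 4]

    # ------------------------------------------------------------------
    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        self._cache = []
        inv_keep = 1.0 / (1.0 - self.dropout) if self.dropout else 1.0
        for li in range(len(self.hidden)):
            w, b, gamma, beta = self._layer_params(li)
            z = x @ w
            z += b
            if training:
                mean = z.mean(axis=0)
                var = z.var(axis=0)
                rm, rv = self.running_mean[li], self.running_var[li]
                rm *= 1.0 - self.BN_MOMENTUM
                rm += self.BN_MOMENTUM * mean
                rv *= 1.0 - self.BN_MOMENTUM
                rv += self.BN_MOMENTUM * var
                inv_std = 1.0 / np.sqrt(var + self.BN_EPS)
                x_hat = z
                x_hat -= mean
                x_hat *= inv_std
                h = x_hat * gamma
                h += beta
                relu_mask = h > 0
                np.multiply(h, relu_mask, out=h)
                if self.dropout:
                    keep = rng.random(h.shape, dtype=np.float32) >= self.dropout
                    np.multiply(h, keep, out=h)
                    h *= inv_keep
                else:
                    keep = None
                self._cache.append((x, x_hat, inv_std, relu_mask, keep))
                x = h
            else:
                # folded inference BN: z * a + b2
                inv_std = 1.0 / np.sqrt(self.running_var[li] + self.BN_EPS)
                a = gamma * inv_std
                z *= a
                z += beta - self.running_mean[li] * a
                np.maximum(z, 0.0, out=z)
                x = z
        head_w, head_b = self._params[-2], self._params[-1]
        if training:
            self._head_input = x
        return x @ head_w + head_b

    def backward(self, grad_logits: np.ndarray) -> list[np.ndarray]:
        """Gradients in the same order as :meth:`parameters` (after a
        training-mode forward pass)."""
        grad_logits = grad_logits.astype(self.dtype)
        # flush underflowing per-sample gradients to exact zero: once focal
        # loss makes easy samples' gradients vanish, denormal float32 values
        # would otherwise leak into every GEMM of the backward pass and slow
        # training by an order of magnitude on x86
        np.multiply(grad_logits, np.abs(grad_logits) >= 1e-30, out=grad_logits)
        head_w = self._params[-2]
        g_head_w = self._head_input.T @ grad_logits
        g_head_b = grad_logits.sum(axis=0)
        grad = grad_logits @ head_w.T
        grads_rev: list[np.ndarray] = [g_head_b, g_head_w]
        inv_keep = 1.0 / (1.0 - self.dropout) if self.dropout else 1.0
        for li in range(len(self.hidden) - 1, -1, -1):
            w, _, gamma, _ = self._layer_params(li)
            x_in, x_hat, inv_std, relu_mask, keep = self._cache[li]
            if keep is not None:
                np.multiply(grad, keep, out=grad)
                grad *= inv_keep
            np.multiply(grad, relu_mask, out=grad)
            g_gamma = (grad * x_hat).sum(axis=0)
            g_beta = grad.sum(axis=0)
            # batch-norm backward
            n = grad.shape[0]
            g_xhat = grad * gamma
            term = g_xhat.sum(axis=0) + x_hat * (g_xhat * x_hat).sum(axis=0)
            g_z = g_xhat
            g_z *= n
            g_z -= term
            g_z *= inv_std / n
            g_w = x_in.T @ g_z
            g_b = g_z.sum(axis=0)
            grad = g_z @ w.T
            grads_rev += [g_beta, g_gamma, g_b, g_w]
        return grads_rev[::-1]

    def flat_gradients(self, grad_logits: np.ndarray, out: np.ndarray) -> np.ndarray:
        """Backward pass packed into the flat layout used by the optimizer."""
        grads = self.backward(grad_logits)
        offset = 0
        for g in grads:
            size = g.size
            out[offset : offset + size] = g.ravel()
            offset += size
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False).astype(np.float64))


class AdamOptimizer:
    """Adam over one flat parameter vector; L2 applies to weight matrices
    only (a mask excludes biases and batch-norm affine parameters)."""

    def __init__(self, network: MlpNetwork, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, l2: float = 0.0):
        self.flat = network.flat_parameters
        self.lr, self.beta1, self.beta2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.m = np.zeros_like(self.flat)
        self.v = np.zeros_like(self.flat)
        self.t = 0
        mask = np.zeros_like(self.flat)
        offset = 0
        for p in network.parameters():
            if p.ndim > 1:
                mask[offset : offset + p.size] = 1.0
            offset += p.size
        self._l2_mask = mask

    def step(self, flat_grads: np.ndarray) -> None:
        self.t += 1
        g = flat_grads
        # drop negligible gradient components (far below Adam's eps) so the
        # second-moment update g*g never produces denormal float32 values;
        # the exponential decay of m and v is floored the same way
        np.multiply(g, np.abs(g) >= 1e-16, out=g)
        if self.l2:
            g = g + self.l2 * self._l2_mask * self.flat
        self.m *= self.beta1
        self.m += (1.0 - self.beta1) * g
        self.v *= self.beta2
        self.v += (1.0 - self.beta2) * g * g
        np.multiply(self.m, np.abs(self.m) >= 1e-24, out=self.m)
        np.multiply(self.v, np.abs(self.v) >= 1e-32, out=self.v)
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        denom = np.sqrt(self.v / b2t)
        denom += self.eps
        update = self.m / b1t
        update /= denom
        update *= self.lr
        self.flat -= update
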