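"""The projection head and the soft-margin contrastive loss.

A two-layer feed-forward network maps fixed-size input embeddings (any
dimension D, e.g. 1024 for transformer protein language models) to a
learned 128-dimensional space:

    z = W2 @ tanh(W1 @ x + b1) + b2

The non-linearity sits *between* the layers only; the output layer is
affine, so learned-space Euclidean distances are unbounded.  Training
minimises the soft-margin triplet loss

    L = mean_t log(1 + exp(-d_t)),   d_t = ||z_a - z_n|| - ||z_a - z_p||

where positive d means the negative already sits farther from the anchor
than the positive — the configuration training pushes toward.

Everything here is plain numpy: the model is two small matrices, and the
exact gradients are short enough to write by hand (they are checked
against finite differences in the test-suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ProjectionConfig:
    input_dim: int
    hidden_dim: int = 256
    output_dim: int = 128

    def __post_init__(self) -> None:
        for name in ("input_dim", "hidden_dim", "output_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")


class ProjectionNetwork:
    """Two affine layers with tanh between them; parameters in float64.

    Weight initialisation is uniform with fan-in scaling,
    U(-1/sqrt(fan_in), 1/sqrt(fan_in)), driven by the supplied generator.
    """

    def __init__(self, config: ProjectionConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(0)
        b1 = 1.0 / np.sqrt(config.input_dim)
        b2 = 1.0 / np.sqrt(config.hidden_dim)
        self.params = {
            "W1": rng.uniform(-b1, b1, size=(config.hidden_dim, config.input_dim)),
            "b1": rng.uniform(-b1, b1, size=config.hidden_dim),
            "W2": rng.uniform(-b2, b2, size=(config.output_dim, config.hidden_dim)),
            "b2": rng.uniform(-b2, b2, size=config.output_dim),
        }

    # --- forward ----------------------------------------------------------

    def project(self, x: np.ndarray) -> np.ndarray:
        """Map a D-vector or an NxD matrix into the learned space."""
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input dimension mismatch: expected {self.config.input_dim}, "
                f"got {x.shape[1]}"
            )
        z = self._forward(x)[0]
        return z[0] if single else z

    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.tanh(x @ self.params["W1"].T + self.params["b1"])
        z = h @ self.params["W2"].T + self.params["b2"]
        return z, h

    def _backward(self, x: np.ndarray, h: np.ndarray, dz: np.ndarray
                  ) -> dict[str, np.ndarray]:
        dW2 = dz.T @ h
        db2 = dz.sum(axis=0)
        dh = (dz @ self.params["W2"]) * (1.0 - h * h)
        dW1 = dh.T @ x
        db1 = dh.sum(axis=0)
        return {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: np.asarray(v, dtype=np.float64).copy() for k, v in params.items()}

    # --- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {"version": CHECKPOINT_VERSION, "config": asdict(self.config)}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path, expected_input_dim: int | None = None
             ) -> "ProjectionNetwork":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
            config = ProjectionConfig(**meta["config"])
            if expected_input_dim is not None and config.input_dim != expected_input_dim:
                raise ValueError(
                    f"checkpoint input_dim {config.input_dim} does not match "
                    f"embeddings with dimension {expected_input_dim}"
                )
            net = cls(config)
            net.set_params({k: data[k] for k in ("W1", "b1", "W2", "b2")})
        return net


# --- loss -------------------------------------------------------------------


def triplet_margins(anchors: np.ndarray, positives: np.ndarray,
                    negatives: np.ndarray) -> np.ndarray:
    """Per-triplet margin d = ||a - n|| - ||a - p|| on projected vectors."""
    a = np.atleast_2d(np.asarray(anchors, dtype=np.float64))
    p = np.atleast_2d(np.asarray(positives, dtype=np.float64))
    n = np.atleast_2d(np.asarray(negatives, dtype=np.float64))
    if not (a.shape == p.shape == n.shape):
        raise ValueError(f"shape mismatch: {a.shape}, {p.shape}, {n.shape}")
    d_an = np.linalg.norm(a - n, axis=1)
    d_ap = np.linalg.norm(a - p, axis=1)
    return d_an - d_ap


def soft_margin_loss(d: np.ndarray) -> float:
    """Mean over triplets of log(1 + exp(-d)), via the stable softplus."""
    d = np.asarray(d, dtype=np.float64)
    if d.size == 0:
        raise ValueError("no triplets in batch")
    return float(np.logaddexp(0.0, -d).mean())


def soft_margin_loss_grad(d: np.ndarray) -> np.ndarray:
    """dL/dd for the mean soft-margin loss: -sigmoid(-d) / T."""
    d = np.asarray(d, dtype=np.float64)
    from scipy.special import expit
    return -expit(-d) / d.size


class Adam:
    """Adam optimiser over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
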