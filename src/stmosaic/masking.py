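"""Spot masking: sample the masked vertex set and substitute a learnable vector.

A fixed-size subset of spots (floor(rate * n)) has its reduced-expression
row replaced by a single trainable vector shared across all masked spots;
the reconstruction loss is evaluated only on those rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Parameter, Tensor

__all__ = ["MaskSpec", "sample_mask", "apply_mask", "apply_mask_tensor"]


@dataclass
class MaskSpec:
    rho: float
    V_m: np.ndarray  # sorted unique masked spot indices
    seed: int
    n: int
    mask_vector: np.ndarray | None = None  # (m,) current learnable vector (numpy view)

    def __post_init__(self):
        self.V_m = np.asarray(self.V_m, dtype=int)
        if len(np.unique(self.V_m)) != len(self.V_m):
            raise ValueError("masked indices must be unique")
        if self.V_m.size and (self.V_m.min() < 0 or self.V_m.max() >= self.n):
            raise ValueError("masked index out of range")

    @property
    def indicator(self) -> np.ndarray:
        ind = np.zeros(self.n, dtype=bool)
        ind[self.V_m] = True
        return ind


def sample_mask(n: int, rho: float, seed: int) -> MaskSpec:
    """Uniform sample without replacement of floor(rho*n) spots."""
    if not 0.0 <= rho < 1.0:
        raise ValueError(
            f"mask rate must be in [0, 1): at least one unmasked spot required (got {rho})"
        )
    size = int(np.floor(rho * n))
    rng = np.random.Generator(np.random.PCG64(seed))
    V_m = np.sort(rng.choice(n, size=size, replace=False))
    return MaskSpec(rho=rho, V_m=V_m, seed=seed, n=n)


def apply_mask(X: np.ndarray, spec: MaskSpec, mask_vector: np.ndarray | None = None) -> np.ndarray:
    """Copy of X with masked rows replaced by the mask vector (zeros if unset)."""
    if spec.n != X.shape[0]:
        raise ValueError(f"mask built for n={spec.n} but X has {X.shape[0]} rows")
    vec = mask_vector if mask_vector is not None else spec.mask_vector
    if vec is None:
        vec = np.zeros(X.shape[1])
    X_mask = X.copy()
    X_mask[spec.V_m] = np.asarray(vec)
    return X_mask


def apply_mask_tensor(X: np.ndarray, spec: MaskSpec, mask_vector: Parameter) -> Tensor:
    """Differentiable masking: unmasked rows constant, masked rows tied to the
    trainable mask vector (gradients accumulate into it)."""
    base = X.copy()
    base[spec.V_m] = 0.0
    indicator = np.zeros((X.shape[0], 1))
    indicator[spec.V_m] = 1.0
    return Tensor(base) + Tensor(indicator) * mask_vector
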