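"""Monotone likelihood warps mapping a non-Gaussian response to a Gaussian latent space.

The working family is sinh-arcsinh composed with an affine transform:

    t = sinh( delta * asinh((y - xi) / eta) - epsilon )

with location ``xi``, scale ``eta > 0``, skew ``epsilon`` and tail parameter
``delta > 0``.  The transform is strictly increasing in ``y`` for any
admissible parameters, so centiles commute with it.  ``epsilon = 0, delta = 1``
reduces it to the affine map ``(y - xi) / eta`` (the identity warp up to
standardisation), which is the special case used by the closed-form
conjugate-Gaussian oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class WarpParams:
    """Parameters of the sinh-arcsinh warp.

    Attributes
    ----------
    xi, eta : float
        Affine location and scale applied to the response before warping.
    epsilon : float
        Skew parameter; 0 means symmetric residuals.
    delta : float
        Tail-weight parameter; 1 means Gaussian-like tails.
    """

    xi: float = 0.0
    eta: float = 1.0
    epsilon: float = 0.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError(f"warp scale eta must be positive, got {self.eta}")
        if self.delta <= 0:
            raise ValueError(f"warp tail delta must be positive, got {self.delta}")

    @property
    def is_identity_shape(self) -> bool:
        return self.epsilon == 0.0 and self.delta == 1.0

    def forward(self, y: np.ndarray) -> np.ndarray:
        """Map observations to the Gaussian latent space."""
        u = (np.asarray(y, dtype=float) - self.xi) / self.eta
        return np.sinh(self.delta * np.arcsinh(u) - self.epsilon)

    def inverse(self, t: np.ndarray) -> np.ndarray:
        """Map latent values back to measurement units."""
        t = np.asarray(t, dtype=float)
        return self.xi + self.eta * np.sinh((np.arcsinh(t) + self.epsilon) / self.delta)

    def log_jacobian(self, y: np.ndarray) -> np.ndarray:
        """log |dt/dy| evaluated at each observation (likelihood change of variables)."""
        u = (np.asarray(y, dtype=float) - self.xi) / self.eta
        inner = self.delta * np.arcsinh(u) - self.epsilon
        # dt/dy = delta * cosh(inner) / (eta * sqrt(1 + u^2)); overflow-safe log cosh
        a = np.abs(inner)
        log_cosh = a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)
        return (
            np.log(self.delta)
            + log_cosh
            - np.log(self.eta)
            - 0.5 * np.log1p(u * u)
        )


def identity_warp(xi: float = 0.0, eta: float = 1.0) -> WarpParams:
    """An affine-only warp (no skew, Gaussian tails)."""
    return WarpParams(xi=xi, eta=eta, epsilon=0.0, delta=1.0)
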