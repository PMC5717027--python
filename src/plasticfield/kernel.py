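"""The dent kernel: the bell-shaped imprint a single stimulus leaves on the
energy landscape.

The one-dimensional kernel is

    g(z) = (2 pi sigma_z^2)^(-1/2) * exp(-z^2 / sigma_z^2),

a Gaussian *shape* with a non-standard exponent: the usual factor 1/2 is
absent, so ``g`` is not a probability density (its integral is 1/sqrt(2),
and its standard deviation is sigma_z/sqrt(2)).  The m-dimensional kernel is
the product of the 1-D kernel over coordinates, all sharing the same width.
Nothing downstream relies on a unit integral: the asymptotic landscape is
the convolution -(g * p), which carries the same normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["Kernel", "kernel_eval", "kernel_grad"]


@dataclass(frozen=True)
class Kernel:
    """Product bell kernel with width ``sigma_z`` in each of ``dim`` coordinates.

    Parameters
    ----------
    sigma_z:
        Width of the dent, in stimulus units.  Must be positive.
    dim:
        Dimension m of the stimulus space.  Must be a positive integer.
    """

    sigma_z: float
    dim: int = 1

    def __post_init__(self):
        if not np.isfinite(self.sigma_z) or self.sigma_z <= 0:
            raise InvalidInputError(f"sigma_z must be positive and finite, got {self.sigma_z}")
        if int(self.dim) != self.dim or self.dim < 1:
            raise InvalidInputError(f"dim must be a positive integer, got {self.dim}")
        object.__setattr__(self, "dim", int(self.dim))

    @property
    def g0(self) -> float:
        """Peak value g(0) = (2 pi sigma_z^2)^(-dim/2), the depth scale of one dent."""
        return float((2.0 * np.pi * self.sigma_z**2) ** (-self.dim / 2.0))

    def _as_displacements(self, z) -> np.ndarray:
        """Coerce ``z`` to an array of shape (..., dim)."""
        z = np.asarray(z, dtype=float)
        if self.dim == 1:
            if z.ndim == 0 or z.shape[-1] != 1:
                z = z[..., np.newaxis]
        elif z.ndim == 0 or z.shape[-1] != self.dim:
            raise InvalidInputError(
                f"displacement has trailing dimension {z.shape[-1] if z.ndim else 0}, "
                f"kernel expects {self.dim}"
            )
        if not np.all(np.isfinite(z)):
            raise InvalidInputError("displacement contains non-finite entries")
        return z

    def __call__(self, z) -> np.ndarray | float:
        """Evaluate g at displacement(s) ``z`` (shape (..., dim); returns shape (...))."""
        zz = self._as_displacements(z)
        norm = (2.0 * np.pi * self.sigma_z**2) ** (-self.dim / 2.0)
        out = norm * np.exp(-np.sum(zz**2, axis=-1) / self.sigma_z**2)
        return float(out) if out.ndim == 0 else out

    def grad(self, z) -> np.ndarray:
        """Analytic gradient of g: component j equals g(z) * (-2 z_j / sigma_z^2)."""
        zz = self._as_displacements(z)
        g = np.asarray(self(z))[..., np.newaxis]
        return g * (-2.0 * zz / self.sigma_z**2)

    def g1d(self, dz) -> np.ndarray:
        """The 1-D factor of the product kernel, for separable grid evaluation."""
        dz = np.asarray(dz, dtype=float)
        return (2.0 * np.pi * self.sigma_z**2) ** (-0.5) * np.exp(-dz**2 / self.sigma_z**2)


def kernel_eval(z, kernel: Kernel):
    """Evaluate the dent kernel at displacement ``z``."""
    return kernel(z)


def kernel_grad(z, kernel: Kernel) -> np.ndarray:
    """Analytic gradient of the dent kernel at displacement ``z``."""
    return kernel.grad(z)
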