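"""Analytic 1D normalizing flow: empirical-CDF Gaussianization.

The latent distribution is mapped to U(0,1) through a piecewise-linear
interpolation of the empirical distribution function (plotting positions
(i - 0.5)/n, clipped away from {0, 1}) and then to N(0,1) via the standard
normal quantile function.  Both directions are analytic and strictly
monotone on the fitted support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri


@dataclass
class NormalizingFlow1D:
    knots: np.ndarray               # sorted latent values
    positions: np.ndarray           # plotting positions in (0, 1)
    eps: float = 1e-4
    clip_margin: float = 0.0        # extra Gaussian-space margin before clipping
    n_clipped: int = field(default=0, init=False)

    @classmethod
    def fit(cls, latent_samples: np.ndarray, eps: float = 1e-4) -> "NormalizingFlow1D":
        z = np.sort(np.asarray(latent_samples, float).ravel())
        if len(z) < 20:
            raise ValueError("need at least 20 samples to fit the flow")
        if not np.all(np.isfinite(z)):
            raise ValueError("latent samples must be finite")
        if z[-1] - z[0] <= 1e-12 * max(1.0, abs(z[0])):
            raise ValueError("constant latent samples: degenerate manifold")
        n = len(z)
        pos = (np.arange(1, n + 1) - 0.5) / n
        pos = np.clip(pos, eps, 1.0 - eps)
        # deduplicate ties so the map is strictly monotone
        keep = np.concatenate([[True], np.diff(z) > 0])
        z, pos = z[keep], pos[keep]
        if len(z) < 2:
            raise ValueError("degenerate latent distribution")
        return cls(knots=z, positions=pos, eps=eps)

    # -- forward: latent -> standard normal ---------------------------------

    def cdf(self, z: np.ndarray) -> np.ndarray:
        return np.interp(z, self.knots, self.positions)

    def forward(self, z: np.ndarray) -> np.ndarray:
        return ndtri(self.cdf(z))

    # -- inverse: standard normal -> latent ---------------------------------

    def inverse(self, x: np.ndarray) -> np.ndarray:
        u = ndtr(np.asarray(x, float))
        lo, hi = self.positions[0], self.positions[-1]
        clipped = (u < lo) | (u > hi)
        self.n_clipped += int(np.sum(clipped))
        u = np.clip(u, lo, hi)
        return np.interp(u, self.positions, self.knots)

    def gaussian_range(self) -> tuple[float, float]:
        return float(ndtri(self.positions[0])), float(ndtri(self.positions[-1]))


def composed_transfer_knots(src: NormalizingFlow1D,
                            dst: NormalizingFlow1D) -> tuple[np.ndarray, np.ndarray]:
    """Knots of the piecewise-linear composition dst^{-1} o src, mapping the
    source latent space to the destination latent space via the shared
    uniform space (the Gaussian legs cancel exactly)."""
    u = src.positions
    z_dst = np.interp(u, dst.positions, dst.knots)
    return src.knots, z_dst
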