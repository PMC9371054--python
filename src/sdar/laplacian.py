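"""Spherical-spline surface Laplacian (current source density) filter.

The surface Laplacian estimates the second spatial derivative of the
scalp potential, attenuating spatially broad, volume-conducted activity
while preserving focal sources.  Electrode positions are taken on the
unit sphere and the potential field is interpolated with spherical
splines built from Legendre polynomial series:

    g(x) = (1/4pi) sum_{n=1..o} (2n+1) P_n(x) / (n(n+1))^rho
    h(x) = (1/4pi) sum_{n=1..o} (2n+1) P_n(x) / (n(n+1))^(rho-1)

where ``x`` is the cosine of the angle between two electrodes
(``cosdist(e, e') = 1 - |e - e'|^2 / 2``), ``o`` is the truncation order
and ``rho`` the smoothness constant.  Per time sample the spline
coefficients are solved against the regularized Gram matrix
``Gs = G + lambda*I`` with the constant-offset term removed, and the
Laplacian is read out through ``H``.  By construction the response to a
spatially constant field is exactly zero.

Output amplitudes follow the unnormalized spline convention (no head
radius scaling); downstream features are standardized, so the overall
scale is immaterial to classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import TrialSet

__all__ = ["SplineMatrices", "legendre_kernel", "cosine_distance",
           "build_spline_matrices", "surface_laplacian"]


def legendre_kernel(cos_angle, order_o: int = 10, exponent: float = 4.0):
    """Truncated Legendre series kernel of the spherical spline.

    Evaluates ``(1/4pi) sum_{n=1..order_o} (2n+1) P_n(cos_angle) /
    (n(n+1))**exponent`` with the polynomials generated by the stable
    three-term recurrence.  Use ``exponent = rho`` for the g-kernel and
    ``rho - 1`` for the h-kernel.
    """
    if order_o < 1:
        raise ValueError("order_o must be >= 1")
    x = np.asarray(cos_angle, dtype=np.float64)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("cos_angle must lie in [-1, 1]")
    x = np.clip(x, -1.0, 1.0)

    total = np.zeros_like(x)
    p_nm1 = np.ones_like(x)   # P_0
    p_n = x.copy()            # P_1
    for n in range(1, order_o + 1):
        total += (2 * n + 1) * p_n / float(n * (n + 1)) ** exponent
        # Bonnet recurrence: (n+1) P_{n+1} = (2n+1) x P_n - n P_{n-1}
        p_np1 = ((2 * n + 1) * x * p_n - n * p_nm1) / (n + 1)
        p_nm1, p_n = p_n, p_np1
    return total / (4.0 * np.pi)


def cosine_distance(positions: np.ndarray) -> np.ndarray:
    """Pairwise ``1 - |e - e'|^2 / 2`` for unit-norm rows.

    Equals the dot product on the unit sphere: 1 for identical
    electrodes, -1 for antipodal ones.
    """
    p = np.asarray(positions, dtype=np.float64)
    sq = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=-1)
    return 1.0 - sq / 2.0


@dataclass
class SplineMatrices:
    """Precomputed spline operators for a fixed montage."""

    G: np.ndarray
    H: np.ndarray
    Gs_inverse: np.ndarray
    order_o: int
    smoothness_rho: float
    lambda_reg: float

    @property
    def n_channels(self) -> int:
        return self.G.shape[0]


def build_spline_matrices(
    positions: np.ndarray,
    order_o: int = 10,
    rho: float = 4.0,
    lambda_reg: float = 1e-5,
) -> SplineMatrices:
    """Build G, H and the regularized inverse for a montage.

    Defaults (order 10, rho 4, lambda 1e-5) are the standard settings for
    scalp current-source-density estimation.
    """
    positions = np.asarray(positions, dtype=np.float64)
    norms = np.linalg.norm(positions, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("electrode positions must be unit-norm")
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be non-negative")

    cosang = np.clip(cosine_distance(positions), -1.0, 1.0)
    off_diag = cosang - np.eye(len(positions))
    if np.any(off_diag > 1.0 - 1e-12):
        warnings.warn("duplicate electrode positions detected; spline matrices "
                      "may be ill-conditioned", RuntimeWarning)

    G = legendre_kernel(cosang, order_o, rho)
    H = legendre_kernel(cosang, order_o, rho - 1.0)
    Gs = G + lambda_reg * np.eye(len(positions))
    try:
        Gs_inverse = np.linalg.inv(Gs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"G + lambda*I is singular: {err}") from err
    return SplineMatrices(G=G, H=H, Gs_inverse=Gs_inverse,
                          order_o=order_o, smoothness_rho=rho,
                          lambda_reg=lambda_reg)


def surface_laplacian(trials: TrialSet, sm: SplineMatrices) -> TrialSet:
    """Apply the surface Laplacian to every trial.

    Per time sample the spline coefficients are ``c = Gi @ v - (Gi @ 1) *
    (1' Gi v) / (1' Gi 1)`` with ``Gi = (G + lambda I)^-1``; the filtered
    potential is ``H @ c``.  The constant (common-mode) component is
    removed exactly, so a spatially uniform field maps to zero.
    """
    if trials.n_channels != sm.n_channels:
        raise ValueError(
            f"channel mismatch: data has {trials.n_channels} channels, "
            f"spline matrices were built for {sm.n_channels}")
    Gi = sm.Gs_inverse
    X = trials.data                                   # (n, C, T)
    A = np.einsum("ij,njt->nit", Gi, X)               # Gi @ x per sample
    col_sum = A.sum(axis=1)                           # 1' Gi x, (n, T)
    gi_ones = Gi.sum(axis=1)                          # Gi @ 1, (C,)
    denom = Gi.sum()                                  # 1' Gi 1
    coeff = A - gi_ones[None, :, None] * (col_sum[:, None, :] / denom)
    lap = np.einsum("ij,njt->nit", sm.H, coeff)
    return trials.with_data(lap)
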