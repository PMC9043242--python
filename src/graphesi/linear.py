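"""Classical linear inverse operators: MNE, dSPM, sLORETA.

All three share the Tikhonov-regularized minimum-norm kernel

    K = H^T (H H^T + lambda2 I)^{-1}

(identity source and noise covariances).  dSPM noise-normalizes each row by
``sqrt((K C K^T)_ii)``; sLORETA standardizes each row by the corresponding
diagonal entry of the resolution matrix ``K H``, which gives it zero
localization bias for single sources in the noiseless case.  With identity
covariances the three kernels differ only by positive per-row scaling.

The regularization default follows the standard SNR heuristic
``lambda2 = trace(H H^T) / (n * 10**(snr_db / 10))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .source_space import LeadField

__all__ = [
    "InverseKernel",
    "lambda2_from_snr",
    "mne_kernel",
    "dspm_kernel",
    "sloreta_kernel",
    "apply_kernel",
    "LinearInverseSolver",
]

#: floor for nonpositive resolution-matrix diagonal entries (sLORETA)
RESOLUTION_FLOOR = 1e-12


@dataclass
class InverseKernel:
    """Linear inverse operator ``s_hat = K x``."""

    K: np.ndarray  # (m, n)
    method: str
    lambda2: float


def lambda2_from_snr(leadfield: LeadField, snr_db: float) -> float:
    """SNR-matched Tikhonov parameter: trace(H H^T) / (n * 10^(SNR/10))."""
    h = leadfield.gain
    return float(np.trace(h @ h.T) / (h.shape[0] * 10.0 ** (snr_db / 10.0)))


def _gram_inverse(h: np.ndarray, lambda2: float) -> np.ndarray:
    n = h.shape[0]
    gram = h @ h.T + lambda2 * np.eye(n)
    try:
        return np.linalg.inv(gram)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            f"sensor gram matrix singular even with lambda2={lambda2}"
        ) from exc


def mne_kernel(leadfield: LeadField, lambda2: float) -> InverseKernel:
    """Minimum-norm estimate kernel ``H^T (H H^T + lambda2 I)^{-1}``."""
    if lambda2 <= 0:
        raise ValueError("lambda2 must be positive")
    k = leadfield.gain.T @ _gram_inverse(leadfield.gain, lambda2)
    return InverseKernel(K=k, method="mne", lambda2=lambda2)


def dspm_kernel(
    leadfield: LeadField, lambda2: float, noise_cov: np.ndarray | None = None
) -> InverseKernel:
    """dSPM: MNE kernel with each row i scaled by 1/sqrt((K C K^T)_ii)."""
    base = mne_kernel(leadfield, lambda2)
    c = np.eye(leadfield.n) if noise_cov is None else np.asarray(noise_cov, float)
    row_var = np.einsum("in,nj,ij->i", base.K, c, base.K)
    if np.any(row_var <= 0):
        raise ValueError("dSPM normalization hit a zero row variance")
    k = base.K / np.sqrt(row_var)[:, None]
    return InverseKernel(K=k, method="dspm", lambda2=lambda2)


def sloreta_kernel(leadfield: LeadField, lambda2: float) -> InverseKernel:
    """sLORETA: MNE kernel with each row i scaled by 1/sqrt((K H)_ii)."""
    base = mne_kernel(leadfield, lambda2)
    resolution_diag = np.einsum("in,ni->i", base.K, leadfield.gain)
    if np.any(resolution_diag <= RESOLUTION_FLOOR):
        warnings.warn(
            "sLORETA resolution diagonal has nonpositive entries; flooring",
            RuntimeWarning,
            stacklevel=2,
        )
        resolution_diag = np.maximum(resolution_diag, RESOLUTION_FLOOR)
    k = base.K / np.sqrt(resolution_diag)[:, None]
    return InverseKernel(K=k, method="sloreta", lambda2=lambda2)


_KERNELS = {"mne": mne_kernel, "dspm": dspm_kernel, "sloreta": sloreta_kernel}


def apply_kernel(kernel: InverseKernel, x: np.ndarray) -> np.ndarray:
    """``s_hat = K x`` for one trial (n, T) or a batch (trials, n, T)."""
    x = np.asarray(x, dtype=float)
    n = kernel.K.shape[1]
    if x.shape[-2] != n:
        raise ValueError(f"x has {x.shape[-2]} channels, kernel expects {n}")
    if x.ndim == 2:
        return kernel.K @ x
    if x.ndim == 3:
        return np.einsum("mn,bnt->bmt", kernel.K, x)
    raise ValueError("x must be (n, T) or (trials, n, T)")


class LinearInverseSolver(BaseEstimator):
    """Linear distributed inverse solver (scikit-learn style).

    Parameters
    ----------
    method : {"mne", "dspm", "sloreta"}
    lambda2 : float, optional
        Tikhonov regularization; if omitted, derived from ``snr_db``.
    snr_db : float, default 20.0
        Assumed sensor SNR for the regularization heuristic.
    """

    def __init__(
        self,
        method: str = "sloreta",
        lambda2: float | None = None,
        snr_db: float = 20.0,
    ):
        self.method = method
        self.lambda2 = lambda2
        self.snr_db = snr_db

    def fit(self, leadfield: LeadField, y=None):
        """Build the inverse kernel from a lead field."""
        if self.method not in _KERNELS:
            raise ValueError(f"unknown method {self.method!r}")
        lam = (
            self.lambda2
            if self.lambda2 is not None
            else lambda2_from_snr(leadfield, self.snr_db)
        )
        self.kernel_ = _KERNELS[self.method](leadfield, lam)
        self.lambda2_ = lam
        return self

    def predict(self, X):
        """Apply the kernel to EEG trials (n, T) or (trials, n, T)."""
        return apply_kernel(self.kernel_, X)
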