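"""The graph-spectral BiLSTM inverse solver.

Training pipeline: project ground-truth source movies onto the low-band
Laplacian eigenbasis (graph Fourier coefficients), train the BiLSTM to map
EEG sequences to those coefficients, and at inference expand the predicted
coefficients back to the vertex domain with the truncated inverse GFT —
so every reconstruction lies, by construction, in the spatially smooth
subspace spanned by the first ``k`` eigenvectors.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .bilstm import BiLSTMModel, BiLSTMRegressor, bilstm_forward
from .simulate import Dataset
from .spectral import GraphLowBandTransform, SpectralBasis
from .source_space import SourceGraph

__all__ = ["GFTBiLSTMSolver", "prepare_targets", "recover_sources"]


def prepare_targets(
    transform: GraphLowBandTransform, dataset: Dataset, split: str
) -> tuple[np.ndarray, np.ndarray]:
    """EEG inputs and low-band coefficient targets for one split.

    Returns ``X`` (trials, n, T) — the noisy EEG — and ``Y`` (trials, k, T),
    the first ``k`` graph Fourier coefficients of the true source movies.
    """
    samples = dataset.subset(split)
    if not samples:
        raise ValueError(f"split '{split}' is empty")
    if samples[0].s_true.shape[0] != transform.basis_.m:
        raise ValueError(
            f"dataset sources ({samples[0].s_true.shape[0]}) do not match the "
            f"spectral basis ({transform.basis_.m})"
        )
    X = np.stack([s.x_noisy for s in samples])
    S = np.stack([s.s_true for s in samples])
    Y = transform.transform(S)
    return X, Y


def recover_sources(
    model: BiLSTMModel | BiLSTMRegressor,
    basis: SpectralBasis,
    x: np.ndarray,
    input_scaler=None,
    target_scaler=None,
) -> np.ndarray:
    """Reconstruct source movies from EEG: predict low-band coefficients,
    inverse-standardize, and expand with the first ``k`` eigenvectors."""
    if isinstance(model, BiLSTMRegressor):
        k_out = model.model_.k_out
        if basis.k != k_out:
            raise ValueError(f"basis k={basis.k} but model k_out={k_out}")
        coeffs = model.predict(x)
    else:
        if basis.k != model.k_out:
            raise ValueError(f"basis k={basis.k} but model k_out={model.k_out}")
        xs = x if input_scaler is None else input_scaler.transform(x)
        coeffs = bilstm_forward(model, xs)
        if target_scaler is not None:
            coeffs = target_scaler.inverse_transform(coeffs)
    if coeffs.ndim == 2:
        return basis.U_k @ coeffs
    return np.einsum("mk,bkt->bmt", basis.U_k, coeffs)


class GFTBiLSTMSolver(BaseEstimator):
    """End-to-end graph-spectral BiLSTM source-imaging estimator.

    ``fit(X, S)`` takes EEG trials (n_trials, n, T) and the matching true
    source movies (n_trials, m, T); ``predict(X)`` returns reconstructed
    source movies (n_trials, m, T) confined to the low graph-frequency band.

    Parameters
    ----------
    adjacency : (m, m) array
        Source-graph adjacency (see
        :func:`graphesi.source_space.adjacency_from_mesh`).
    k : int, optional
        Low-band size; default ``round(k_frac * m)``.
    k_frac : float, default 0.3
        Fraction of the spectrum kept when ``k`` is not given (the
        reference configuration keeps 615 of 2,052 eigenvectors, ~30%).
    hidden_size, epochs, batch_size, learning_rate, patience,
    output_activation, standardize, random_state :
        Passed to :class:`graphesi.bilstm.BiLSTMRegressor`.
    """

    def __init__(
        self,
        adjacency: np.ndarray | SourceGraph | None = None,
        k: int | None = None,
        k_frac: float = 0.3,
        hidden_size: int = 256,
        epochs: int = 200,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        patience: int = 20,
        lr_decay: float = 0.5,
        lr_patience: int = 6,
        output_activation: str = "identity",
        standardize: bool = True,
        target_scaling: str = "global",
        random_state: int = 0,
    ):
        self.adjacency = adjacency
        self.k = k
        self.k_frac = k_frac
        self.hidden_size = hidden_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.lr_decay = lr_decay
        self.lr_patience = lr_patience
        self.output_activation = output_activation
        self.standardize = standardize
        self.target_scaling = target_scaling
        self.random_state = random_state

    def _adjacency_array(self) -> np.ndarray:
        if self.adjacency is None:
            raise ValueError("adjacency is required")
        if isinstance(self.adjacency, SourceGraph):
            return self.adjacency.adjacency
        return np.asarray(self.adjacency, dtype=float)

    def fit(self, X, S, validation_data=None):
        """Fit on EEG ``X`` (trials, n, T) and true sources ``S``
        (trials, m, T).  ``validation_data=(X_val, S_val)`` drives early
        stopping on the coefficient MSE."""
        X = np.asarray(X)
        S = np.asarray(S)
        self.transform_ = GraphLowBandTransform(k=self.k, k_frac=self.k_frac).fit(
            self._adjacency_array()
        )
        if S.shape[1] != self.transform_.basis_.m:
            raise ValueError(
                f"S has {S.shape[1]} sources but the graph has "
                f"{self.transform_.basis_.m} vertices"
            )
        Y = self.transform_.transform(S)
        val = None
        if validation_data is not None:
            Xv = np.asarray(validation_data[0])
            Yv = self.transform_.transform(np.asarray(validation_data[1]))
            val = (Xv, Yv)
        self.regressor_ = BiLSTMRegressor(
            hidden_size=self.hidden_size,
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            patience=self.patience,
            lr_decay=self.lr_decay,
            lr_patience=self.lr_patience,
            output_activation=self.output_activation,
            standardize=self.standardize,
            target_scaling=self.target_scaling,
            random_state=self.random_state,
        ).fit(X, Y, validation_data=val)
        self.basis_ = self.transform_.basis_
        self.k_ = self.basis_.k
        self.history_ = self.regressor_.history_
        return self

    def fit_dataset(self, dataset: Dataset):
        """Fit from a simulated :class:`~graphesi.simulate.Dataset`, using
        its train split for optimization and val split for early stopping."""
        X, _ = _split_arrays(dataset, "train")
        Xv, Sv = _split_arrays(dataset, "val")
        _, S = _split_arrays(dataset, "train")
        return self.fit(X, S, validation_data=(Xv, Sv))

    def predict(self, X):
        """Reconstruct source movies (trials, m, T) from EEG trials."""
        coeffs = self.regressor_.predict(np.asarray(X))
        return self.transform_.inverse_transform(coeffs)


def _split_arrays(dataset: Dataset, split: str) -> tuple[np.ndarray, np.ndarray]:
    samples = dataset.subset(split)
    X = np.stack([s.x_noisy for s in samples])
    S = np.stack([s.s_true for s in samples])
    return X, S
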