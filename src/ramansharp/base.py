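"""Shared estimator base for the resolution-enhancement transformers.

All enhancement methods are scikit-learn transformers operating on
arrays of shape (n_spectra, n_channels): ``transform`` maps each row
(one spectrum) to its resolution-enhanced version on the same channel
grid.  A single spectrum may be passed as a 1-D array and is returned
as a (1, n_channels) array, matching scikit-learn conventions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .spectrum import Spectrum

__all__ = ["SpectrumTransformer", "as_matrix", "apply_to_spectrum"]


def as_matrix(X) -> np.ndarray:
    """Coerce input to a 2-D float array (n_spectra, n_channels)."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError(f"expected 1-D or 2-D input, got shape {arr.shape}")
    if arr.shape[1] < 3:
        raise ValueError("spectra must have at least 3 channels")
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    return arr


class SpectrumTransformer(TransformerMixin, BaseEstimator):
    """Base class: per-row spectral transform with sklearn fit/transform."""

    def fit(self, X, y=None):
        X = as_matrix(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = as_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} channels, got {X.shape[1]}"
            )
        return np.vstack([self._transform_one(row) for row in X])

    def _transform_one(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def apply_to_spectrum(estimator: SpectrumTransformer, s: Spectrum) -> Spectrum:
    """Run a transformer on one Spectrum, preserving its axis."""
    out = estimator.fit(s.intensities).transform(s.intensities)
    return s.with_intensities(out[0])
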