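"""PCA noise reduction of fused features and per-pair input assembly.

The 800-entry fused descriptors are centred and projected onto the top-d
principal components (d = 80 by default; 20 in cross-species mode, where
extra noise suppression helps transfer). Component signs are canonicalised
(largest-magnitude loading positive) so fits are deterministic. A protein
pair becomes one classifier input by concatenating the two reduced
per-protein vectors in pair order; an optional symmetrised prediction mode
averages scores over both orders downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .sequence_io import Pair

D_WITHIN_SPECIES: int = 80
D_CROSS_SPECIES: int = 20


@dataclass
class PCAModel:
    """Fitted mean + orthonormal component matrix (d x p)."""

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    fitted_ids: tuple[str, ...] = ()  # instrumentation: which proteins the fit saw

    @property
    def d(self) -> int:
        return self.components.shape[0]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            mean=self.mean,
            components=self.components,
            explained_variance=self.explained_variance,
            fitted_ids=np.array(self.fitted_ids, dtype=object),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        with np.load(path, allow_pickle=True) as z:
            return cls(
                mean=z["mean"],
                components=z["components"],
                explained_variance=z["explained_variance"],
                fitted_ids=tuple(z["fitted_ids"].tolist()),
            )


def _canonicalize_signs(components: np.ndarray) -> np.ndarray:
    flips = np.sign(components[np.arange(len(components)), np.abs(components).argmax(axis=1)])
    flips[flips == 0] = 1.0
    return components * flips[:, None]


def fit_pca(X: np.ndarray, d: int, fitted_ids: Sequence[str] = ()) -> PCAModel:
    """Fit a top-d PCA on the rows of X (samples x features)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite entries")
    if d < 1 or d > min(X.shape):
        raise ValueError(f"d={d} outside [1, min(n_samples, n_features)={min(X.shape)}]")
    pca = PCA(n_components=d, svd_solver="full")
    pca.fit(X)
    return PCAModel(
        mean=pca.mean_,
        components=_canonicalize_signs(pca.components_),
        explained_variance=pca.explained_variance_,
        fitted_ids=tuple(fitted_ids),
    )


def transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X onto the fitted components: (X - mean) @ components.T."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.mean.shape[0]})"
        )
    return (X - model.mean) @ model.components.T


def inverse_transform(model: PCAModel, Z: np.ndarray) -> np.ndarray:
    """Best rank-d reconstruction of reduced rows Z."""
    return np.atleast_2d(Z) @ model.components + model.mean


def make_pair_features(
    pairs: Sequence[Pair], reduced: Mapping[str, np.ndarray]
) -> np.ndarray:
    """One row per pair: [reduced(id_a); reduced(id_b)], length 2d."""
    rows = []
    for p in pairs:
        for pid in (p.id_a, p.id_b):
            if pid not in reduced:
                raise KeyError(f"no reduced features for protein {pid!r}")
        rows.append(np.concatenate([reduced[p.id_a], reduced[p.id_b]]))
    d = next(iter(reduced.values())).shape[0] if reduced else 0
    return np.array(rows).reshape(len(rows), 2 * d)
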