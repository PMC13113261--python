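"""scikit-learn estimator interfaces over the pipeline stages.

`PairAngleTransformer` and `AsymmetryScorer` are stateless transformers
(fit is a no-op, like sklearn's Normalizer); `EtaThresholdPairSelector`
(defined in :mod:`facesym.selection`) is the data-driven stage. Together
they compose into sklearn pipelines, e.g.::

    Pipeline([
        ("angles", PairAngleTransformer(registry="dense-225")),
        ("select", EtaThresholdPairSelector()),
    ])
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import alignment, asymmetry
from .landmarks import LandmarkSet, load_registry
from .selection import EtaThresholdPairSelector

__all__ = ["PairAngleTransformer", "AsymmetryScorer", "EtaThresholdPairSelector"]


class PairAngleTransformer(TransformerMixin, BaseEstimator):
    """Map landmark sets to signed pair-angle vectors (degrees).

    Parameters
    ----------
    registry : str or PairRegistry, default "dense-225"
    align : bool, default True
        Apply midline-based head alignment before measuring angles.

    ``transform`` takes a sequence of :class:`LandmarkSet` and returns an
    (n_images, n_pairs) float array. Stateless; ``fit`` only validates.
    """

    def __init__(self, registry="dense-225", align: bool = True):
        self.registry = registry
        self.align = align

    def fit(self, X: Sequence[LandmarkSet], y=None):
        self.registry_ = load_registry(self.registry)
        self.n_features_in_ = None  # input is a sequence of landmark sets
        return self

    def transform(self, X: Sequence[LandmarkSet]) -> np.ndarray:
        registry = getattr(self, "registry_", None) or load_registry(self.registry)
        out = np.empty((len(X), registry.n_pairs))
        for i, ls in enumerate(X):
            if self.align:
                ls = alignment.align(ls, registry.midline_indices).aligned
            out[i] = asymmetry.pair_angles(ls, registry).theta
        return out


class AsymmetryScorer(TransformerMixin, BaseEstimator):
    """Reduce angle vectors to the mean-absolute-angle score (degrees).

    ``transform`` maps an (n_images, n_pairs) angle matrix to an
    (n_images, 1) score column over the configured pair ordinals.
    """

    def __init__(self, registry="dense-225", subset=None):
        self.registry = registry
        self.subset = subset

    def fit(self, X, y=None):
        registry = load_registry(self.registry)
        self.ordinals_ = registry.subset_ordinals(self.subset)
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        ordinals = (
            self.ordinals_
            if hasattr(self, "ordinals_")
            else load_registry(self.registry).subset_ordinals(self.subset)
        )
        return np.mean(np.abs(X[:, ordinals]), axis=1, keepdims=True)
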