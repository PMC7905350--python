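"""Evaluate a trained Gaussian RBF network and apply the 0.5 decision rule."""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .rols import RBFNetwork

DECISION_THRESHOLD = 0.5


def predict(net: RBFNetwork, X: np.ndarray) -> np.ndarray:
    """Continuous network output for each feature row.

    ``y(x) = sum_i theta_i * exp(-|x - c_i|^2 / rho)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != net.centers.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match network centers "
            f"({net.centers.shape[1]})"
        )
    sq = cdist(X, net.centers, metric="sqeuclidean")
    return np.exp(-sq / net.rho) @ net.theta


def classify(net: RBFNetwork, X: np.ndarray) -> np.ndarray:
    """Binary labels: 1 (fatigue) iff the continuous output is strictly > 0.5."""
    return (predict(net, X) > DECISION_THRESHOLD).astype(int)
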