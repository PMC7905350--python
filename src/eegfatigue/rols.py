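"""Sparse Gaussian RBF training by regularized orthogonal forward selection.

Every training input is a candidate center; candidate columns are greedily
orthogonalized (modified Gram-Schmidt) and scored by a combined criterion
that trades residual reduction, a ridge penalty on the orthogonal weights,
and a determinant-maximizing (D-optimality) term rewarding well-conditioned
regressor subsets. Selection stops when no remaining candidate has a
positive combined error-reduction ratio. Output weights are recovered by
back-substitution through the unit upper-triangular factor.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class CandidateModel:
    """Full candidate regression problem: Phi[k, i] = exp(-|x(k)-x(i)|^2 / rho)."""

    Phi: np.ndarray
    centers: np.ndarray
    rho: float
    y: np.ndarray


@dataclass
class SelectionTrace:
    """Everything recorded during forward selection, enough to recover weights."""

    selected: list  # candidate indices in selection order
    W: np.ndarray  # (N, n_s) orthogonal columns
    A: np.ndarray  # (n_s, n_s) unit upper triangular
    g: np.ndarray  # orthogonal-space weights
    crerr: np.ndarray  # per-step combined error reduction ratio
    lam: float
    beta: float
    stop_reason: str  # no_positive_crerr | max_terms | all_selected | all_collinear

    @property
    def n_selected(self) -> int:
        return len(self.selected)


@dataclass
class RBFNetwork:
    """Gaussian RBF model: y(x) = sum_i theta_i exp(-|x - c_i|^2 / rho)."""

    centers: np.ndarray
    rho: float
    theta: np.ndarray
    lam: float = 0.0
    beta: float = 0.0
    selected_indices: list = field(default_factory=list)
    pipeline_params: Optional[dict] = None


def build_candidates(X: np.ndarray, y: np.ndarray, rho: float) -> CandidateModel:
    """Form the N x N Gaussian regression matrix with every input as a center."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if rho <= 0:
        raise ValueError(f"width rho must be positive, got {rho}")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    sq = cdist(X, X, metric="sqeuclidean")
    if np.any(sq[np.triu_indices_from(sq, k=1)] == 0.0):
        warnings.warn("duplicate input rows: identical candidate columns", stacklevel=2)
    Phi = np.exp(-sq / rho)
    return CandidateModel(Phi=Phi, centers=X, rho=rho, y=y)


def forward_select(
    model: CandidateModel,
    lam: float,
    beta: float,
    max_terms: Optional[int] = None,
) -> SelectionTrace:
    """Greedy regularized orthogonal forward selection with D-optimality score.

    At each step the unselected candidate columns (already deflated against
    the chosen orthogonal directions) compete on

        crerr_i = ((w_i^T w_i + lam) g_i^2 + beta * log(w_i^T w_i)) / y^T y

    with g_i = w_i^T y / (w_i^T w_i + lam); the maximizer is chosen, ties
    broken by lowest candidate index. Selection stops when the best remaining
    crerr is <= 0, when ``max_terms`` is reached, or when every candidate is
    either selected or numerically collinear with the chosen subset.
    """
    if lam < 0 or beta < 0:
        raise ValueError("lambda and beta must be non-negative")
    Phi, y = model.Phi, model.y
    N = Phi.shape[0]
    if max_terms is None:
        max_terms = N
    if not (1 <= max_terms <= N):
        raise ValueError(f"max_terms must be in [1, {N}], got {max_terms}")

    yty = float(y @ y)
    if yty == 0.0:
        yty = 1.0  # all-zero target: any crerr is 0 and nothing gets selected
    # collinearity floor, scaled to the problem
    tol = 1e-12 * float(np.sum(Phi**2)) / N

    R = Phi.copy()  # residual (deflated) candidate columns
    selected: list[int] = []
    W_cols, g_sel, crerr_sel = [], [], []
    proj_rows = []  # per-step projection coefficients onto *all* candidates
    available = np.ones(N, dtype=bool)
    stop_reason = "all_selected"

    while len(selected) < max_terms:
        wtw = np.einsum("ij,ij->j", R, R)
        eligible = available & (wtw > tol)
        if not eligible.any():
            stop_reason = "all_collinear" if available.any() else "all_selected"
            break
        wty = R.T @ y
        with np.errstate(divide="ignore", invalid="ignore"):
            g_all = wty / (wtw + lam)
            crerr_all = ((wtw + lam) * g_all**2 + beta * np.log(wtw)) / yty
        crerr_all[~eligible] = -np.inf
        best = int(np.argmax(crerr_all))  # argmax takes the lowest index on ties
        if crerr_all[best] <= 0.0:
            stop_reason = "no_positive_crerr"
            break
        w = R[:, best].copy()
        denom = wtw[best]
        coeff = (w @ R) / denom  # w^T R_k / w^T w; equals w^T Phi_k (MGS)
        R -= np.outer(w, coeff)
        R[:, best] = 0.0
        available[best] = False
        selected.append(best)
        W_cols.append(w)
        g_sel.append(float(g_all[best]))
        crerr_sel.append(float(crerr_all[best]))
        proj_rows.append(coeff)
    else:
        stop_reason = "max_terms" if max_terms < N else "all_selected"

    n_s = len(selected)
    W = np.column_stack(W_cols) if n_s else np.zeros((N, 0))
    A = np.eye(n_s)
    for i in range(n_s):
        for j in range(i + 1, n_s):
            A[i, j] = proj_rows[i][selected[j]]
    if n_s > 1:
        # one re-orthogonalization pass if MGS drifted
        G = W.T @ W
        off = np.abs(G - np.diag(np.diag(G)))
        norms = np.sqrt(np.diag(G))
        if np.max(off / np.outer(norms, norms)) > 1e-10:
            Q, Rq = np.linalg.qr(W)
            d = np.diag(Rq).copy()
            W = Q * d
            A = np.triu((Rq / d[:, None]) @ A)
            np.fill_diagonal(A, 1.0)
            wtw_sel = np.einsum("ij,ij->j", W, W)
            g_sel = list((W.T @ y) / (wtw_sel + lam))
    return SelectionTrace(
        selected=selected,
        W=W,
        A=A,
        g=np.asarray(g_sel, dtype=float),
        crerr=np.asarray(crerr_sel, dtype=float),
        lam=lam,
        beta=beta,
        stop_reason=stop_reason,
    )


def recover_weights(trace: SelectionTrace) -> np.ndarray:
    """Solve the unit-upper-triangular system A theta = g by back-substitution."""
    n = trace.n_selected
    if n < 1:
        raise ValueError("empty selection: no weights to recover")
    A, g = trace.A, trace.g
    theta = np.zeros(n)
    for i in range(n - 1, -1, -1):
        theta[i] = g[i] - A[i, i + 1 :] @ theta[i + 1 :]
    return theta


def fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    rho: float,
    beta: float,
    max_terms: Optional[int] = None,
    pipeline_params: Optional[dict] = None,
):
    """Full lower-level training: candidates -> forward selection -> weights.

    Returns ``(RBFNetwork, SelectionTrace)``. Raises if the selection ends
    empty (lower ``beta`` or raise ``max_terms``).
    """
    model = build_candidates(X, y, rho)
    trace = forward_select(model, lam, beta, max_terms)
    if trace.n_selected == 0:
        raise EmptySelectionError(
            "forward selection chose no terms (stop_reason="
            f"{trace.stop_reason}); lower beta or raise max_terms"
        )
    theta = recover_weights(trace)
    net = RBFNetwork(
        centers=model.centers[trace.selected].copy(),
        rho=rho,
        theta=theta,
        lam=lam,
        beta=beta,
        selected_indices=list(trace.selected),
        pipeline_params=pipeline_params,
    )
    return net, trace


class EmptySelectionError(RuntimeError):
    """Forward selection terminated with zero selected terms."""
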