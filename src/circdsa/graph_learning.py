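"""Graph structure learning with dual views and confidence-guided
pseudo-labeling.

The bipartite adjacency A = [[0, Y], [Y^T, 0]] seeds a full-graph-
parameterization (FGP) learner: every potential edge weight is a free
parameter Omega, mapped through a strictly-positive activation to the learned
structure S = sigma(Omega), then symmetrized and degree-normalized.  Two
views — a refined view anchored on A and an inference view on the learned
structure — are stochastically augmented (shared edge dropout, per-view
feature masking), encoded by per-view GCN encoders and MLP projectors, and
coupled by a pseudo-label cross-entropy loss gated on prediction confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, glorot, log_softmax, l2_normalize_rows, parameter
from .data_io import AssociationMatrix


@dataclass(frozen=True)
class BipartiteAdjacency:
    """(n+m)x(n+m) adjacency with zero within-type blocks."""

    values: np.ndarray
    n_circ: int
    n_drug: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n, m = self.n_circ, self.n_drug
        if v.shape != (n + m, n + m):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(v, v.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(v[:n, :n]) or np.any(v[n:, n:]):
            raise ValueError("within-type blocks must be zero")


def build_bipartite_adjacency(Y) -> BipartiteAdjacency:
    """A = [[0, Y], [Y^T, 0]]; circRNA i -> node i, drug j -> node n+j.

    Accepts an AssociationMatrix or any binary 2-D array.
    """
    vals = Y.values if isinstance(Y, AssociationMatrix) else np.asarray(Y)
    n, m = vals.shape
    A = np.zeros((n + m, n + m))
    A[:n, n:] = vals
    A[n:, :n] = vals.T
    return BipartiteAdjacency(A, n, m)


# ---------------------------------------------------------------------------
# FGP learner
# ---------------------------------------------------------------------------

_ACTS = {
    "elu1": lambda t: t.elu() + 1.0,
    "relu": lambda t: t.relu(),
    "sigmoid": lambda t: t.sigmoid(),
}


class FgpLearner:
    """Free edge-weight matrix Omega initialized from the bipartite adjacency.

    The default affine initialization Omega = init_scale*A + init_shift maps
    observed edges to a clearly positive weight and non-edges to a clearly
    negative one, so sigma(Omega) starts with strong edge/non-edge contrast
    instead of a nearly uniform graph (ELU(0)+1 = 1 would otherwise give
    every absent edge almost half the weight of a present one).
    ``init_scale=1, init_shift=0`` recovers the plain Omega = A start.
    """

    def __init__(self, A: np.ndarray, activation: str = "elu1",
                 init_scale: float = 4.0, init_shift: float = -2.0):
        if activation not in _ACTS:
            raise ValueError(f"unknown learner activation {activation!r}")
        self.omega = parameter(np.asarray(A, dtype=float) * init_scale + init_shift)
        self.activation = activation

    def forward(self) -> Tensor:
        return learner_forward(self)


def learner_forward(learner: FgpLearner) -> Tensor:
    """S = sigma(Omega): elementwise non-negative, differentiable in Omega."""
    return _ACTS[learner.activation](learner.omega)


def normalize_adjacency(S, activation: str = "identity"):
    """Symmetrize then degree-normalize: Shat = D^{-1/2} (S+S^T)/2 D^{-1/2}.

    Accepts a numpy array or an autodiff Tensor (the Tensor path is used
    inside training so gradients flow to the learner).  An activation is
    applied first only when requested; with already non-negative input the
    default identity keeps the map scale-covariant, so the normalized output
    is invariant to positive rescaling.  Zero-degree rows stay zero rows.
    """
    if isinstance(S, Tensor):
        if activation != "identity":
            S = _ACTS[activation](S)
        sym = (S + S.T) * 0.5
        deg = sym.sum(axis=1, keepdims=True)
        dinv = (deg + 1e-12) ** -0.5
        return sym * dinv * dinv.T
    S = np.asarray(S, dtype=float)
    if activation != "identity":
        S = _ACTS[activation](Tensor(S)).data
    sym = 0.5 * (S + S.T)
    deg = sym.sum(axis=1)
    dinv = np.where(deg > 0, np.maximum(deg, 1e-300), 1.0) ** -0.5
    dinv = np.where(deg > 0, dinv, 0.0)
    return dinv[:, None] * sym * dinv[None, :]


def extract_learned_structure(learner: FgpLearner, top_k: int | None = None) -> np.ndarray:
    """Normalized learned structure S', optionally row-wise top-k sparsified."""
    S = learner_forward(learner).data
    if top_k is not None:
        keep = np.zeros_like(S, dtype=bool)
        idx = np.argpartition(-S, min(top_k, S.shape[1] - 1), axis=1)[:, :top_k]
        np.put_along_axis(keep, idx, True, axis=1)
        S = np.where(keep, S, 0.0)
    return normalize_adjacency(S)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationSpec:
    p_mr: float = 0.1
    p_mi: float = 0.4
    p_e: float = 0.1

    def __post_init__(self):
        for name in ("p_mr", "p_mi", "p_e"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def feature_mask(n_features: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """One Bernoulli(keep=1-p) mask over feature dimensions, shared by all rows."""
    return (rng.random(n_features) >= p).astype(float)


def mask_features(X, p: float, rng: np.random.Generator):
    """Zero a random subset of feature dimensions (the same columns in every row)."""
    X_arr = X.data if isinstance(X, Tensor) else np.asarray(X, float)
    beta = feature_mask(X_arr.shape[1], p, rng)
    if isinstance(X, Tensor):
        return X * Tensor(beta[None, :])
    return X_arr * beta[None, :]


def edge_mask(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric Bernoulli(keep=1-p) mask: upper triangle sampled, mirrored;
    diagonal sampled independently."""
    keep = rng.random((n, n)) >= p
    out = np.triu(keep, k=1)
    out = out + out.T
    np.fill_diagonal(out, np.diag(keep))
    return out.astype(float)


def drop_edges(adj, mask: np.ndarray):
    """Apply a (symmetric) edge mask elementwise; Tensor-aware."""
    if isinstance(adj, Tensor):
        return adj * Tensor(mask)
    return np.asarray(adj, float) * mask


def build_views(A: np.ndarray, S_hat, X, spec: AugmentationSpec,
                rng: np.random.Generator):
    """Augmented (refined, inference) views sharing one realized edge mask.

    Refined view: (A with edges dropped, X masked at p_mr).
    Inference view: (S_hat with the SAME edge mask, X masked at p_mi).
    """
    n = A.shape[0]
    emask = edge_mask(n, spec.p_e, rng)
    rv = (drop_edges(A, emask), mask_features(X, spec.p_mr, rng))
    iv = (drop_edges(S_hat, emask), mask_features(X, spec.p_mi, rng))
    return rv, iv


# ---------------------------------------------------------------------------
# view encoders
# ---------------------------------------------------------------------------

class ViewEncoder:
    """Two-layer GCN encoder followed by a two-layer MLP projector."""

    def __init__(self, in_dim: int, hidden: int, embed: int, proj: int,
                 rng: np.random.Generator):
        self.W1 = glorot(rng, in_dim, hidden)
        self.W2 = glorot(rng, hidden, embed)
        self.M1 = glorot(rng, embed, proj)
        self.M2 = glorot(rng, proj, proj)

    @property
    def params(self):
        return [self.W1, self.W2, self.M1, self.M2]

    def __call__(self, adj, X):
        return encode_view(adj, X, self)


def _gcn_norm_t(adj) -> Tensor:
    """Self-loop degree normalization, Tensor-aware and differentiable."""
    if not isinstance(adj, Tensor):
        adj = Tensor(np.asarray(adj, float))
    n = adj.shape[0]
    A = adj + Tensor(np.eye(n))
    deg = A.sum(axis=1, keepdims=True)
    dinv = (deg + 1e-12) ** -0.5
    return A * dinv * dinv.T


def encode_view(adj, X, enc: ViewEncoder):
    """(H, Z): GCN node representations and their MLP projections."""
    Ahat = _gcn_norm_t(adj)
    Xt = X if isinstance(X, Tensor) else Tensor(np.asarray(X, float))
    H = (Ahat @ ((Ahat @ (Xt @ enc.W1)).elu() @ enc.W2)).elu()
    Z = (H @ enc.M1).elu() @ enc.M2
    if not (np.all(np.isfinite(H.data)) and np.all(np.isfinite(Z.data))):
        raise ValueError("non-finite view encoding")
    return H, Z


# ---------------------------------------------------------------------------
# confidence-guided pseudo-label loss
# ---------------------------------------------------------------------------

def _pseudo_targets(Z: np.ndarray, tau: float):
    """Pseudo-labels (row argmax of the L2-normalized projections, ties to the
    lowest index) and a confidence gate by max softmax probability."""
    norm = Z / np.maximum(np.linalg.norm(Z, axis=1, keepdims=True), 1e-12)
    targets = norm.argmax(axis=1)
    shifted = Z - Z.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    conf = probs.max(axis=1)
    retained = conf >= tau if tau > 0 else np.ones(Z.shape[0], dtype=bool)
    if tau >= 1.0:
        retained = conf >= 1.0
    return targets, retained


def pseudo_label_loss(Zrv, Ziv, tau: float = 0.8, stop_grad: bool = True):
    """L_cpl = 1/2 (CE(Zrv, Trv) + CE(Ziv, Tiv)) over confidence-gated rows.

    A row enters either term only if its max softmax probability reaches tau
    in BOTH views; with no retained rows the loss is 0.  Targets are detached
    from the gradient by default.  Accepts Tensors (returns a Tensor) or
    arrays (returns a float).
    """
    was_array = not isinstance(Zrv, Tensor)
    Zr = Zrv if isinstance(Zrv, Tensor) else Tensor(np.asarray(Zrv, float))
    Zi = Ziv if isinstance(Ziv, Tensor) else Tensor(np.asarray(Ziv, float))
    if Zr.shape != Zi.shape or Zr.shape[1] < 2:
        raise ValueError("projections must share shape with >= 2 dimensions")
    t_rv, keep_rv = _pseudo_targets(Zr.data, tau)
    t_iv, keep_iv = _pseudo_targets(Zi.data, tau)
    keep = keep_rv & keep_iv
    if not keep.any():
        return 0.0 if was_array else Tensor(0.0)
    rows = np.nonzero(keep)[0]
    # targets are integer argmaxes: piecewise constant, so detaching them is
    # the only differentiable reading; stop_grad is kept in the signature for
    # protocol symmetry with the config flag
    ce_r = -log_softmax(Zr.rows(rows)).gather(np.arange(rows.size), t_rv[rows]).mean()
    ce_i = -log_softmax(Zi.rows(rows)).gather(np.arange(rows.size), t_iv[rows]).mean()
    loss = (ce_r + ce_i) * 0.5
    return loss.item() if was_array else loss
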