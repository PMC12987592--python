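"""Shared-constraint collaborative feature learning.

Each similarity network of an entity type (three for circRNAs, three for
drugs) is compressed by its own two-layer graph-convolutional autoencoder.
After a reconstruction-only warm-up, pairs of nodes whose embeddings are
highly correlated in EVERY source ("must-link" pairs, intersected across
sources) are mined once and frozen; training then continues on the joint
objective L = L_reco + lambda * L_mc, which pulls constrained pairs together
in all sources simultaneously.  The final per-source embeddings are arranged
into a block feature matrix X with zero blocks separating circRNA and drug
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Tensor, glorot, parameter
from .data_io import RunConfig
from .similarity import SimilarityMatrix


class TrainingError(RuntimeError):
    """Raised when a loss becomes non-finite during optimization."""


@dataclass(frozen=True)
class SourceEmbedding:
    """Embedding of all entities of one type under one similarity source."""

    values: np.ndarray
    kernel: str
    axis: str  # circ | drug

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("embedding has non-finite entries")


@dataclass(frozen=True)
class MustLinkConstraints:
    """Symmetric binary matrix of high-confidence same-cluster pairs."""

    values: np.ndarray
    axis: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("constraint matrix must be square")
        if np.any((v != 0) & (v != 1)):
            raise ValueError("constraint entries must be binary")
        if not np.array_equal(v, v.T):
            raise ValueError("constraint matrix must be symmetric")
        if np.any(np.diag(v)):
            raise ValueError("constraint diagonal must be zero")

    @property
    def n_pairs(self) -> int:
        return int(self.values.sum() // 2)


@dataclass(frozen=True)
class BlockFeatureMatrix:
    """(n+m) x (sum of source dims) block matrix: circ rows then drug rows.

    Column layout [Hcs 0 Hce 0 Hcg 0; 0 Hds 0 Hde 0 Hdg] — circRNA rows are
    exactly zero in drug-source columns and vice versa.
    """

    values: np.ndarray
    n_circ: int
    n_drug: int
    block_dims: tuple  # (d_cs, d_ds, d_ce, d_de, d_cg, d_dg)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "block_dims", tuple(self.block_dims))
        if self.values.shape != (self.n_circ + self.n_drug, sum(self.block_dims)):
            raise ValueError("block matrix shape inconsistent with layout")


def gcn_normalize(S: np.ndarray) -> np.ndarray:
    """Self-loop degree normalization D^{-1/2} (S + I) D^{-1/2}."""
    A = np.asarray(S, dtype=float) + np.eye(S.shape[0])
    d = A.sum(axis=1)
    dinv = np.where(d > 0, d, 1.0) ** -0.5
    return dinv[:, None] * A * dinv[None, :]


def gcn_encode(network: SimilarityMatrix, W1: np.ndarray, W2: np.ndarray,
               activation: str = "elu", axis: str = "circ") -> SourceEmbedding:
    """Two-layer GCN encoder H = act(Shat act(Shat X0 W1) W2), X0 = S itself."""
    S = network.values
    if not np.all(np.isfinite(S)):
        raise ValueError("network has non-finite entries")
    act = _np_act(activation)
    Shat = gcn_normalize(S)
    H = act(Shat @ (act(Shat @ S @ W1) @ W2))
    return SourceEmbedding(H, network.kernel, axis)


def _np_act(name: str):
    if name == "elu":
        return lambda x: np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
    if name == "relu":
        return lambda x: np.maximum(x, 0.0)
    if name == "linear":
        return lambda x: x
    raise ValueError(f"unknown activation {name!r}")


def pearson_matrix(H: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows correlate 0 with all.

    Diagonal is 1 for variance-positive rows, 0 for degenerate rows.
    """
    H = np.asarray(H, dtype=float)
    C = H - H.mean(axis=1, keepdims=True)
    sd = np.sqrt((C * C).sum(axis=1))
    ok = sd > 1e-12
    Cn = np.zeros_like(C)
    Cn[ok] = C[ok] / sd[ok, None]
    P = Cn @ Cn.T
    np.fill_diagonal(P, np.where(ok, 1.0, 0.0))
    return np.clip(P, -1.0, 1.0)


def must_link_from_pcc(P: np.ndarray, quantile: float, axis: str = "circ") -> MustLinkConstraints:
    """Select off-diagonal pairs with correlation strictly above the given
    quantile of all off-diagonal values; symmetrize, zero diagonal."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = P[off]
    if np.ptp(vals) == 0:
        warnings.warn("all off-diagonal correlations equal; empty must-link set")
        return MustLinkConstraints(np.zeros((n, n), dtype=np.int8), axis)
    thr = np.quantile(vals, quantile)
    M = ((P > thr) & off)
    M = (M | M.T).astype(np.int8)
    return MustLinkConstraints(M, axis)


def shared_must_link(mls) -> MustLinkConstraints:
    """Intersection (elementwise AND) of per-source constraint matrices."""
    mls = list(mls)
    if not mls:
        raise ValueError("need at least one constraint matrix")
    axis = mls[0].axis
    shape = mls[0].values.shape
    out = np.ones(shape, dtype=np.int8)
    for ml in mls:
        if ml.values.shape != shape or ml.axis != axis:
            raise ValueError("constraint matrices differ in shape or axis")
        out &= ml.values
    return MustLinkConstraints(out, axis)


def reconstruction_loss(originals, reconstructions) -> float:
    """Mean over sources of the squared Frobenius reconstruction error."""
    originals = list(originals)
    reconstructions = list(reconstructions)
    if len(originals) != len(reconstructions):
        raise ValueError("source count mismatch")
    total = 0.0
    for O, R in zip(originals, reconstructions):
        O, R = np.asarray(O, float), np.asarray(R, float)
        if O.shape != R.shape:
            raise ValueError("shape mismatch between original and reconstruction")
        total += float(((O - R) ** 2).sum())
    return total / len(originals)


def must_link_loss(H: np.ndarray, smlm: MustLinkConstraints) -> float:
    """Mean squared embedding distance over constrained (unordered) pairs."""
    H = np.asarray(H, dtype=float)
    iu, ju = np.triu_indices_from(smlm.values, k=1)
    sel = smlm.values[iu, ju] == 1
    if not sel.any():
        return 0.0
    d = H[iu[sel]] - H[ju[sel]]
    return float((d * d).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class _SourceAutoencoder:
    """GCN encoder + dense mirror decoder for one similarity network."""

    def __init__(self, S: np.ndarray, hidden: int, embed: int,
                 rng: np.random.Generator):
        n = S.shape[0]
        self.S = Tensor(S)                       # input features = the network
        self.Shat = Tensor(gcn_normalize(S))     # fixed propagation matrix
        self.W1 = glorot(rng, n, hidden)
        self.W2 = glorot(rng, hidden, embed)
        self.V1 = glorot(rng, embed, hidden)
        self.V2 = glorot(rng, hidden, n)

    @property
    def params(self):
        return [self.W1, self.W2, self.V1, self.V2]

    def encode(self) -> Tensor:
        h = (self.Shat @ (self.S @ self.W1)).elu()
        return (self.Shat @ (h @ self.W2)).elu()

    def decode(self, H: Tensor) -> Tensor:
        return (H @ self.V1).elu() @ self.V2


def _ml_loss_t(H: Tensor, smlm: MustLinkConstraints) -> Tensor:
    iu, ju = np.triu_indices_from(smlm.values, k=1)
    sel = smlm.values[iu, ju] == 1
    if not sel.any():
        return Tensor(0.0)
    d = H.rows(iu[sel]) - H.rows(ju[sel])
    return (d * d).sum(axis=1).mean()


def train_collab(networks: dict, config: RunConfig, rng: np.random.Generator):
    """Train all per-source autoencoders jointly.

    ``networks`` maps axis ('circ'|'drug') to a list of SimilarityMatrix.
    Returns (embeddings, info): embeddings maps axis to a list of
    SourceEmbedding in input order; info carries the loss trace and the mined
    shared must-link constraints per axis.
    """
    aes, meta = {}, []
    for axis, nets in networks.items():
        aes[axis] = []
        for net in nets:
            aes[axis].append(_SourceAutoencoder(
                net.values, config.hidden_dim, config.embed_dim, rng))
            meta.append((axis, net.kernel))
    all_aes = [ae for axis in aes for ae in aes[axis]]
    opt = Adam([p for ae in all_aes for p in ae.params], lr=config.lr)
    k = len(all_aes)
    smlms = {axis: None for axis in aes}
    trace = []
    for epoch in range(config.collab_epochs):
        embeddings = {axis: [ae.encode() for ae in aes[axis]] for axis in aes}
        loss = Tensor(0.0)
        for axis in aes:
            for ae, H in zip(aes[axis], embeddings[axis]):
                diff = ae.decode(H) - ae.S
                loss = loss + (diff * diff).sum() * (1.0 / k)
        if epoch == config.warmup_epochs:
            # one-shot constraint mining on the warm embeddings, then frozen
            for axis in aes:
                mls = [must_link_from_pcc(pearson_matrix(H.data),
                                          config.mustlink_quantile, axis)
                       for H in embeddings[axis]]
                smlms[axis] = shared_must_link(mls)
        if epoch >= config.warmup_epochs:
            for axis in aes:
                for H in embeddings[axis]:
                    loss = loss + config.lambda_mc * _ml_loss_t(H, smlms[axis])
        lval = loss.item()
        if not np.isfinite(lval):
            raise TrainingError(f"collaborative loss diverged at epoch {epoch}")
        trace.append(lval)
        opt.zero_grad()
        loss.backward()
        opt.step()
    out = {}
    i = 0
    for axis in aes:
        out[axis] = []
        for ae in aes[axis]:
            out[axis].append(SourceEmbedding(ae.encode().data, meta[i][1], axis))
            i += 1
    return out, {"loss_trace": trace, "smlm": smlms}


def assemble_block_matrix(circ_embeddings, drug_embeddings) -> BlockFeatureMatrix:
    """Arrange per-source embeddings into the zero-padded block matrix X."""
    circ = [np.asarray(e.values if isinstance(e, SourceEmbedding) else e, float)
            for e in circ_embeddings]
    drug = [np.asarray(e.values if isinstance(e, SourceEmbedding) else e, float)
            for e in drug_embeddings]
    if len(circ) != len(drug):
        raise ValueError("need matching source counts per entity type")
    n = circ[0].shape[0]
    m = drug[0].shape[0]
    if any(c.shape[0] != n for c in circ) or any(d.shape[0] != m for d in drug):
        raise ValueError("row-count mismatch within an entity type")
    blocks_top, blocks_bot, dims = [], [], []
    for c, d in zip(circ, drug):
        blocks_top += [c, np.zeros((n, d.shape[1]))]
        blocks_bot += [np.zeros((m, c.shape[1])), d]
        dims += [c.shape[1], d.shape[1]]
    X = np.vstack([np.hstack(blocks_top), np.hstack(blocks_bot)])
    return BlockFeatureMatrix(X, n, m, tuple(dims))


def raw_similarity_features(sims: dict) -> BlockFeatureMatrix:
    """Ablation path: block matrix built from raw similarity rows directly."""
    circ = [sims["css"].values, sims["ces"].values, sims["cgs"].values]
    drug = [sims["dss"].values, sims["des"].values, sims["dgs"].values]
    circ = [SourceEmbedding(c, k, "circ")
            for c, k in zip(circ, ("sequence", "entropy", "gip"))]
    drug = [SourceEmbedding(d, k, "drug")
            for d, k in zip(drug, ("structure", "entropy", "gip"))]
    return assemble_block_matrix(circ, drug)
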