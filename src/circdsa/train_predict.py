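"""Prediction head, negative sampling, training orchestration and k-fold
cross-validation.

Training is staged.  Stage A runs collaborative feature learning on the six
similarity networks and assembles the block feature matrix X (skipped under
the no_cfe ablation, where X holds raw similarity rows).  Stage B jointly
optimizes the FGP structure learner, the two view encoders and the GCN
prediction head under L = L_pre + lambda_cpl * L_cpl, where L_pre is the MSE
over 1:1 sampled train pairs and L_cpl the confidence-guided pseudo-label
loss (dropped under no_cgpl).  Cross-validation holds out each positive fold,
zeroes held-out edges in every training input (association-derived kernels
included, unless gip_full_matrix is set) and scores held-out positives
against freshly sampled negatives.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (accuracy_score, average_precision_score,
                             f1_score, recall_score, roc_auc_score)

from ._autodiff import Adam, Tensor, glorot
from .collab_features import (BlockFeatureMatrix, TrainingError,
                              assemble_block_matrix, raw_similarity_features,
                              train_collab)
from .data_io import AssociationMatrix, RunConfig, ScoreMatrix
from .graph_learning import (AugmentationSpec, FgpLearner, ViewEncoder,
                             build_bipartite_adjacency, build_views,
                             extract_learned_structure, learner_forward,
                             normalize_adjacency, pseudo_label_loss,
                             _gcn_norm_t)
from .similarity import all_similarities
from .synthetic_data import Dataset


class MetricError(ValueError):
    """A metric is undefined for the provided labels."""


class SamplingError(ValueError):
    """Not enough candidate cells to satisfy the sampling request."""


@dataclass(frozen=True)
class LabeledPairSet:
    """(circ index, drug index, label) triples with a train/test role tag."""

    pairs: np.ndarray  # (N, 2) int
    labels: np.ndarray  # (N,) in {0, 1}
    role: str = "train"

    def __post_init__(self):
        p = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        l = np.asarray(self.labels, dtype=np.int8)
        object.__setattr__(self, "pairs", p)
        object.__setattr__(self, "labels", l)
        if p.shape[0] != l.size:
            raise ValueError("pair/label count mismatch")
        if np.any((l != 0) & (l != 1)):
            raise ValueError("labels must be binary")
        if len({(a, b) for a, b in map(tuple, p)}) != p.shape[0]:
            raise ValueError("duplicate pairs")

    def __len__(self):
        return self.labels.size


@dataclass
class EvalReport:
    auc: float
    aupr: float
    accuracy: float
    f1: float
    recall: float
    per_fold: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# prediction head
# ---------------------------------------------------------------------------

class PredictionHead:
    """Two-layer GCN over (X, S') with an inner-product logistic decoder."""

    def __init__(self, in_dim: int, hidden: int, embed: int,
                 rng: np.random.Generator):
        self.W1 = glorot(rng, in_dim, hidden)
        self.W2 = glorot(rng, hidden, embed)

    @property
    def params(self):
        return [self.W1, self.W2]

    def node_embeddings(self, S_hat, X) -> Tensor:
        A = _gcn_norm_t(S_hat)
        Xt = X if isinstance(X, Tensor) else Tensor(np.asarray(X, float))
        return (A @ ((A @ (Xt @ self.W1)).elu() @ self.W2)).elu()

    def pair_scores(self, S_hat, X, pairs: np.ndarray, n_circ: int) -> Tensor:
        Z = self.node_embeddings(S_hat, X)
        zc = Z.rows(pairs[:, 0])
        zd = Z.rows(n_circ + pairs[:, 1])
        return (zc * zd).sum(axis=1).sigmoid()


def predict_scores(X: BlockFeatureMatrix, S_prime: np.ndarray,
                   head: PredictionHead, circ_ids, drug_ids) -> ScoreMatrix:
    """Score every circRNA-drug pair through the trained head."""
    Z = head.node_embeddings(Tensor(S_prime), X.values).data
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite node embeddings")
    n = X.n_circ
    logits = Z[:n] @ Z[n:].T
    scores = 1.0 / (1.0 + np.exp(-logits))
    return ScoreMatrix(scores, circ_ids, drug_ids)


def prediction_loss(scores, labels) -> float:
    """Mean squared error between predicted scores and binary labels."""
    s = np.asarray(scores, float)
    l = np.asarray(labels, float)
    if s.shape != l.shape:
        raise ValueError("length mismatch")
    return float(((s - l) ** 2).mean())


# ---------------------------------------------------------------------------
# sampling and splits
# ---------------------------------------------------------------------------

def sample_negatives(Y: AssociationMatrix, ratio: float,
                     rng: np.random.Generator, exclude=()) -> LabeledPairSet:
    """Uniform sample (without replacement) of zero cells, avoiding
    ``exclude``; count = round(ratio * number of positives)."""
    zeros = np.argwhere(Y.values == 0)
    if exclude:
        excl = {tuple(p) for p in exclude}
        zeros = np.array([p for p in map(tuple, zeros) if p not in excl],
                         dtype=int).reshape(-1, 2)
    n_pos = int(Y.values.sum())
    want = int(round(ratio * n_pos))
    if zeros.shape[0] < want:
        raise SamplingError(
            f"need {want} negative cells, only {zeros.shape[0]} available")
    idx = rng.choice(zeros.shape[0], size=want, replace=False)
    return LabeledPairSet(zeros[idx], np.zeros(want, dtype=np.int8), "train")


def kfold_split(positives: np.ndarray, k: int, rng: np.random.Generator):
    """Shuffle positives and split into k folds with sizes differing by <= 1."""
    positives = np.asarray(positives, dtype=int).reshape(-1, 2)
    if k < 2:
        raise ValueError("k must be >= 2")
    if positives.shape[0] < k:
        raise ValueError(f"cannot split {positives.shape[0]} positives into {k} folds")
    order = np.lexsort((positives[:, 1], positives[:, 0]))
    canon = positives[order]
    perm = rng.permutation(canon.shape[0])
    return [canon[fold] for fold in np.array_split(perm, k)]


def compute_metrics(scores, labels, threshold: float = 0.5,
                    config: dict | None = None, seed: int = 0) -> EvalReport:
    """AUC (rank-based), AUPR (step interpolation), and thresholded
    accuracy/F1/recall."""
    s = np.asarray(scores, float)
    l = np.asarray(labels, int)
    if len(np.unique(l)) < 2:
        raise MetricError("AUC/AUPR undefined: labels contain a single class")
    pred = (s >= threshold).astype(int)
    return EvalReport(
        auc=float(roc_auc_score(l, s)),
        aupr=float(average_precision_score(l, s)),
        accuracy=float(accuracy_score(l, pred)),
        f1=float(f1_score(l, pred, zero_division=0)),
        recall=float(recall_score(l, pred, zero_division=0)),
        config=config or {},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    head: PredictionHead
    learner: FgpLearner
    X: BlockFeatureMatrix
    scores: ScoreMatrix
    losses: dict
    config: RunConfig


def _build_features(train_Y: AssociationMatrix, dataset: Dataset,
                    config: RunConfig, rng: np.random.Generator,
                    css=None, dss=None):
    sims = all_similarities(train_Y, dataset.sequences, dataset.fingerprints,
                            css=css, dss=dss)
    if config.no_cfe:
        return raw_similarity_features(sims), {"loss_trace": []}
    networks = {"circ": [sims["css"], sims["ces"], sims["cgs"]],
                "drug": [sims["dss"], sims["des"], sims["dgs"]]}
    emb, info = train_collab(networks, config, rng)
    X = assemble_block_matrix(emb["circ"], emb["drug"])
    return X, info


def train_full(dataset: Dataset, config: RunConfig,
               train_Y: AssociationMatrix | None = None,
               train_pairs: LabeledPairSet | None = None,
               css=None, dss=None) -> TrainedModel:
    """Run both training stages and return the trained model with full scores.

    ``train_Y`` (default: the dataset's full matrix) is the supervision
    actually visible to training — cross-validation passes the fold-masked
    matrix so held-out edges never enter kernels, adjacency or loss.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 101)))
    Y = train_Y if train_Y is not None else dataset.Y
    kernel_Y = dataset.Y if config.gip_full_matrix else Y

    X, collab_info = _build_features(kernel_Y, dataset, config, rng, css, dss)

    if train_pairs is None:
        pos = np.argwhere(Y.values == 1)
        neg = sample_negatives(Y, config.neg_ratio, rng)
        pairs = np.vstack([pos, neg.pairs])
        labels = np.concatenate([np.ones(len(pos), np.int8), neg.labels])
        train_pairs = LabeledPairSet(pairs, labels, "train")

    labels = train_pairs.labels.astype(float)
    if config.shuffle_labels:
        labels = rng.permutation(labels)

    n, m = Y.shape
    A = build_bipartite_adjacency(Y).values
    learner = FgpLearner(A, config.learner_activation)
    aug = AugmentationSpec(p_mr=config.p_mr, p_mi=config.p_mi, p_e=config.p_e)
    in_dim = X.values.shape[1]
    enc_rv = ViewEncoder(in_dim, config.view_hidden, config.view_embed,
                         config.proj_dim, rng)
    enc_iv = ViewEncoder(in_dim, config.view_hidden, config.view_embed,
                         config.proj_dim, rng)
    head = PredictionHead(in_dim, config.head_hidden, config.head_embed, rng)

    params = [learner.omega] + head.params
    if not config.no_cgpl and config.lambda_cpl != 0.0:
        params += enc_rv.params + enc_iv.params
    opt = Adam(params, lr=config.lr)

    Xt = Tensor(X.values)
    y_t = labels
    pre_trace, cpl_trace, total_trace = [], [], []
    best, best_epoch = np.inf, 0
    for epoch in range(config.stageb_epochs):
        S = learner_forward(learner)
        S_hat = normalize_adjacency(S)
        loss = Tensor(0.0)
        if not config.no_cgpl and config.lambda_cpl != 0.0:
            (adj_rv, x_rv), (adj_iv, x_iv) = build_views(A, S_hat, Xt, aug, rng)
            _, Zrv = enc_rv(adj_rv, x_rv)
            _, Ziv = enc_iv(adj_iv, x_iv)
            # confidence bootstrap: the gate anneals from 0 to tau so early
            # (uniformly unconfident) projections still receive gradient and
            # can sharpen before gating takes effect
            ramp = max(config.tau_ramp_epochs, 1)
            tau_e = config.tau * min(1.0, epoch / ramp)
            lcpl = pseudo_label_loss(Zrv, Ziv, tau_e, config.stop_grad)
            loss = loss + config.lambda_cpl * lcpl
            cpl_trace.append(lcpl.item() if isinstance(lcpl, Tensor) else lcpl)
        else:
            cpl_trace.append(0.0)
        scores_t = head.pair_scores(S_hat, Xt, train_pairs.pairs, n)
        diff = scores_t - Tensor(y_t)
        lpre = (diff * diff).mean()
        loss = loss + lpre
        pre_trace.append(lpre.item())
        total = loss.item()
        total_trace.append(total)
        if not np.isfinite(total):
            raise TrainingError(f"stage-B loss diverged at epoch {epoch}")
        if total < best - 1e-6:
            best, best_epoch = total, epoch
        elif epoch - best_epoch >= config.patience:
            break
        opt.zero_grad()
        loss.backward()
        opt.step()

    S_prime = extract_learned_structure(learner, config.top_k)
    scores = predict_scores(X, S_prime, head, Y.circ_ids, Y.drug_ids)
    losses = {"pre": pre_trace, "cpl": cpl_trace, "total": total_trace,
              "collab": collab_info["loss_trace"]}
    return TrainedModel(head, learner, X, scores, losses, config)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(dataset: Dataset, config: RunConfig,
                   css=None, dss=None) -> EvalReport:
    """k-fold CV over positives with 1:1 negative sampling per fold.

    Sequence and structure kernels do not depend on Y; callers may pass them
    precomputed and only the association-derived kernels are rebuilt per fold.
    """
    Y = dataset.Y
    if css is None or dss is None:
        from .similarity import sequence_similarity, structure_similarity
        css = css or sequence_similarity(dataset.sequences, Y.circ_ids)
        dss = dss or structure_similarity(dataset.fingerprints, Y.drug_ids)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    positives = np.argwhere(Y.values == 1)
    folds = kfold_split(positives, config.folds, rng)
    per_fold = []
    all_scores, all_labels = [], []
    for f_idx, test_pos in enumerate(folds):
        fold_rng = np.random.default_rng(
            np.random.SeedSequence((config.seed, 7, f_idx)))
        mask = np.ones(Y.values.shape, dtype=np.int8)
        mask[test_pos[:, 0], test_pos[:, 1]] = 0
        train_values = Y.values * mask
        train_Y = AssociationMatrix(train_values, Y.circ_ids, Y.drug_ids)

        train_pos = np.argwhere(train_values == 1)
        n_train, n_test = train_pos.shape[0], test_pos.shape[0]
        # negatives drawn from cells with no association at all, split
        # disjointly between train and test
        n_neg_train = int(round(config.neg_ratio * n_train))
        n_neg_test = int(round(config.neg_ratio * n_test))
        neg_all = sample_negatives(
            Y, (n_neg_train + n_neg_test) / max(Y.values.sum(), 1), fold_rng)
        train_neg = neg_all.pairs[:n_neg_train]
        test_neg = neg_all.pairs[n_neg_train:]

        pairs = np.vstack([train_pos, train_neg])
        labels = np.concatenate([np.ones(n_train, np.int8),
                                 np.zeros(len(train_neg), np.int8)])
        fold_config = config.replace(seed=int(config.seed * 1000 + f_idx) % (2**31))
        model = train_full(dataset, fold_config, train_Y,
                           LabeledPairSet(pairs, labels, "train"),
                           css=css, dss=dss)
        test_pairs = np.vstack([test_pos, test_neg])
        test_labels = np.concatenate([np.ones(n_test, np.int8),
                                      np.zeros(len(test_neg), np.int8)])
        s = model.scores.values[test_pairs[:, 0], test_pairs[:, 1]]
        rep = compute_metrics(s, test_labels, config.threshold,
                              seed=config.seed)
        per_fold.append(rep)
        all_scores.append(s)
        all_labels.append(test_labels)
    mean = {k: float(np.mean([getattr(r, k) for r in per_fold]))
            for k in ("auc", "aupr", "accuracy", "f1", "recall")}
    return EvalReport(per_fold=[r.as_dict() for r in per_fold],
                      config=dataclasses.asdict(config), seed=config.seed,
                      **mean)


def holdout_evaluate(dataset: Dataset, config: RunConfig, test_fraction: float = 0.2,
                     css=None, dss=None) -> EvalReport:
    """Single stratified holdout split; used for quick diagnostics such as
    the label-shuffle null."""
    Y = dataset.Y
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 13)))
    positives = np.argwhere(Y.values == 1)
    k = max(2, int(round(1.0 / test_fraction)))
    folds = kfold_split(positives, k, rng)
    test_pos = folds[0]
    mask = np.ones(Y.values.shape, dtype=np.int8)
    mask[test_pos[:, 0], test_pos[:, 1]] = 0
    train_Y = AssociationMatrix(Y.values * mask, Y.circ_ids, Y.drug_ids)
    train_pos = np.argwhere(train_Y.values == 1)
    neg_all = sample_negatives(
        Y, (train_pos.shape[0] + test_pos.shape[0]) / max(Y.values.sum(), 1), rng)
    train_neg = neg_all.pairs[:train_pos.shape[0]]
    test_neg = neg_all.pairs[train_pos.shape[0]:]
    pairs = np.vstack([train_pos, train_neg])
    labels = np.concatenate([np.ones(len(train_pos), np.int8),
                             np.zeros(len(train_neg), np.int8)])
    model = train_full(dataset, config, train_Y,
                       LabeledPairSet(pairs, labels, "train"), css=css, dss=dss)
    test_pairs = np.vstack([test_pos, test_neg])
    test_labels = np.concatenate([np.ones(len(test_pos), np.int8),
                                  np.zeros(len(test_neg), np.int8)])
    s = model.scores.values[test_pairs[:, 0], test_pairs[:, 1]]
    return compute_metrics(s, test_labels, config.threshold,
                           config=dataclasses.asdict(config), seed=config.seed)


def degree_product_baseline(Y: AssociationMatrix) -> np.ndarray:
    """Scores proportional to (row degree x column degree); a structure-free
    baseline for sanity comparisons."""
    r = Y.values.sum(axis=1, keepdims=True).astype(float)
    c = Y.values.sum(axis=0, keepdims=True).astype(float)
    s = r @ c
    return s / max(s.max(), 1.0)
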