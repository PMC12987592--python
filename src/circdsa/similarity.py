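"""The six similarity kernels over circRNAs and drugs.

circRNAs get a sequence kernel (normalized Levenshtein over host-gene
sequences), drugs a structure kernel (Tanimoto over binary topological
fingerprints); both entity types additionally get an entropy-profile kernel
and a Gaussian interaction profile (GIP) kernel derived from the binary
association matrix Y.

Edge-case conventions (entities with no associations, all-zero fingerprints)
are documented on each function; they keep every kernel total and [0,1]-valued
instead of producing NaNs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import AssociationMatrix, FingerprintSet, SequenceSet

KERNELS = ("sequence", "structure", "entropy", "gip")


class DegenerateInputError(ValueError):
    """Raised when a kernel is undefined for the given input (e.g. all-zero Y)."""


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric [0,1] similarity matrix over one entity type."""

    values: np.ndarray
    entity_ids: tuple
    kernel: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "entity_ids", tuple(self.entity_ids))
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if v.shape[0] != len(self.entity_ids):
            raise ValueError("entity id count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# sequence kernel
# ---------------------------------------------------------------------------

def levenshtein_distance(s1: str, s2: str) -> int:
    """Unit-cost edit distance by the classic dynamic-programming recurrence.

    The DP rows are vectorized with numpy; the left-neighbor (insertion)
    dependency is resolved with a prefix-minimum scan, which is exact for
    unit costs.
    """
    if not s1 or not s2:
        return max(len(s1), len(s2))
    a = np.frombuffer(s1.encode("utf-8"), dtype=np.uint8)
    b = np.frombuffer(s2.encode("utf-8"), dtype=np.uint8)
    if len(s1.encode()) != len(s1) or len(s2.encode()) != len(s2):
        # non-ASCII: fall back to codepoint arrays
        a = np.array([ord(c) for c in s1])
        b = np.array([ord(c) for c in s2])
    m = b.size
    prev = np.arange(m + 1, dtype=np.int64)
    idx = np.arange(1, m + 1, dtype=np.int64)
    cur = np.empty(m + 1, dtype=np.int64)
    for i, ch in enumerate(a, 1):
        cur[0] = i
        # deletion vs substitution first; insertion fixed by a min-scan
        cur[1:] = np.minimum(prev[1:] + 1, prev[:-1] + (b != ch))
        np.minimum.accumulate(cur - np.arange(m + 1), out=cur)
        cur += np.arange(m + 1)
        prev, cur = cur, prev
    return int(prev[-1])


def sequence_similarity(seqs: SequenceSet, ids) -> SimilarityMatrix:
    """CSS_ij = 1 - LD(s_i, s_j) / max(|s_i|, |s_j|)."""
    ids = tuple(ids)
    missing = [i for i in ids if i not in seqs.records]
    if missing:
        raise KeyError(f"no sequence for ids: {missing}")
    n = len(ids)
    css = np.eye(n)
    for i in range(n):
        si = seqs[ids[i]]
        for j in range(i + 1, n):
            sj = seqs[ids[j]]
            d = levenshtein_distance(si, sj)
            css[i, j] = css[j, i] = 1.0 - d / max(len(si), len(sj))
    return SimilarityMatrix(np.clip(css, 0.0, 1.0), ids, "sequence")


# ---------------------------------------------------------------------------
# structure kernel
# ---------------------------------------------------------------------------

def tanimoto(d1: np.ndarray, d2: np.ndarray) -> float:
    """Tanimoto coefficient d1.d2 / (|d1|^2 + |d2|^2 - d1.d2).

    Two all-zero fingerprints make the ratio 0/0; that pair is reported as
    similarity 0 with a warning (maximally dissimilar rather than undefined).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("fingerprint lengths differ")
    dot = float(d1 @ d2)
    denom = float(d1 @ d1) + float(d2 @ d2) - dot
    if denom == 0.0:
        warnings.warn("Tanimoto of two all-zero fingerprints; returning 0")
        return 0.0
    return dot / denom


def structure_similarity(fps: FingerprintSet, ids) -> SimilarityMatrix:
    """DSS: pairwise Tanimoto over binary fingerprints, unit diagonal."""
    ids = tuple(ids)
    missing = [i for i in ids if i not in fps.records]
    if missing:
        raise KeyError(f"no fingerprint for ids: {missing}")
    B = np.stack([fps[i] for i in ids]).astype(float)
    dot = B @ B.T
    sq = np.diag(dot)
    denom = sq[:, None] + sq[None, :] - dot
    with np.errstate(invalid="ignore", divide="ignore"):
        dss = np.where(denom > 0, dot / np.maximum(denom, 1e-300), 0.0)
    np.fill_diagonal(dss, 1.0)
    return SimilarityMatrix(np.clip(dss, 0.0, 1.0), ids, "structure")


# ---------------------------------------------------------------------------
# entropy kernel
# ---------------------------------------------------------------------------

def _profiles(Y: AssociationMatrix, axis: str) -> np.ndarray:
    if axis == "circ":
        return Y.values.astype(float)
    if axis == "drug":
        return Y.values.T.astype(float)
    raise ValueError("axis must be 'circ' or 'drug'")


def _entropy_weights(P: np.ndarray) -> np.ndarray:
    """Per-partner term w_k = -p_k log2 p_k with p_k = partner degree / N."""
    N = P.sum()
    deg = P.sum(axis=0)  # degree of each partner
    p = deg / N
    w = np.zeros_like(p)
    nz = p > 0
    w[nz] = -p[nz] * np.log2(p[nz])
    return w


def profile_entropy(profile, Y: AssociationMatrix, axis: str = "circ") -> float:
    """Shannon entropy of one association profile.

    ``profile`` is a set of partner indices; each contributes
    ``-p_k log2 p_k`` where ``p_k`` is the partner's global degree over the
    total number of known associations N.  The empty profile has entropy 0.
    """
    P = _profiles(Y, axis)
    w = _entropy_weights(P)
    prof = list(profile)
    idx = np.fromiter(prof, dtype=int) if prof else np.array([], dtype=int)
    return float(w[idx].sum())


def entropy_similarity(Y: AssociationMatrix, axis: str = "circ") -> SimilarityMatrix:
    """Entropy-profile similarity 2*H(S_i & S_j) / (H(S_i) + H(S_j)).

    The intersection entropy uses the same global partner probabilities
    restricted to the shared partner set (no renormalization).  Pairs with
    zero denominator — isolated entities, or profiles whose only partners
    have probability 1 — get similarity 0 rather than NaN; diagonals are 1
    exactly when H(S_i) > 0.
    """
    P = _profiles(Y, axis)
    w = _entropy_weights(P)
    H = P @ w                      # entropy of each profile
    Hint = (P * w) @ P.T           # entropy restricted to pairwise intersections
    denom = H[:, None] + H[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, 2.0 * Hint / np.maximum(denom, 1e-300), 0.0)
    sim = 0.5 * (sim + sim.T)
    ids = Y.circ_ids if axis == "circ" else Y.drug_ids
    return SimilarityMatrix(np.clip(sim, 0.0, 1.0), ids, "entropy")


# ---------------------------------------------------------------------------
# GIP kernel
# ---------------------------------------------------------------------------

def gip_bandwidth(Y: AssociationMatrix, axis: str = "circ") -> float:
    """Bandwidth theta = 1 / mean squared profile norm (= mean degree for binary Y)."""
    P = _profiles(Y, axis)
    mean_sq = P.sum(axis=1).mean()  # ||binary profile||^2 == degree
    if mean_sq == 0:
        raise DegenerateInputError(f"all profiles empty on axis {axis!r}")
    return float(1.0 / mean_sq)


def gip_similarity(Y: AssociationMatrix, axis: str = "circ") -> SimilarityMatrix:
    """Gaussian interaction profile kernel K_ij = exp(-theta ||y_i - y_j||^2)."""
    P = _profiles(Y, axis)
    theta = gip_bandwidth(Y, axis)
    deg = P.sum(axis=1)
    sqdist = deg[:, None] + deg[None, :] - 2.0 * (P @ P.T)
    sim = np.exp(-theta * np.maximum(sqdist, 0.0))
    sim = 0.5 * (sim + sim.T)
    np.fill_diagonal(sim, 1.0)
    ids = Y.circ_ids if axis == "circ" else Y.drug_ids
    return SimilarityMatrix(sim, ids, "gip")


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def all_similarities(Y: AssociationMatrix, seqs: SequenceSet, fps: FingerprintSet,
                     css: SimilarityMatrix | None = None,
                     dss: SimilarityMatrix | None = None) -> dict:
    """Compute the full kernel set.

    ``css``/``dss`` may be passed in precomputed — they do not depend on Y,
    so cross-validation recomputes only the Y-derived kernels per fold.
    """
    if css is None:
        css = sequence_similarity(seqs, Y.circ_ids)
    if dss is None:
        dss = structure_similarity(fps, Y.drug_ids)
    return {
        "css": css,
        "dss": dss,
        "ces": entropy_similarity(Y, "circ"),
        "des": entropy_similarity(Y, "drug"),
        "cgs": gip_similarity(Y, "circ"),
        "dgs": gip_similarity(Y, "drug"),
    }
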