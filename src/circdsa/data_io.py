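"""Readers and writers for the external formats, core domain types and run
configuration.

Conventions
-----------
The association matrix is always oriented rows = circRNAs, columns = drugs:
``Y[i, j] = 1`` means circRNA *i* is associated with the sensitivity of drug
*j*.  All tabular formats are plain CSV/TSV with identifier headers, sequences
are FASTA, and the run configuration is a flat YAML mapping.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class DataFormatError(ValueError):
    """Malformed input file (missing header, ragged rows, empty record...)."""


class DuplicateIdError(ValueError):
    """An identifier occurs more than once where uniqueness is required."""


class MatrixValueError(ValueError):
    """A cell failed binary validation; message names the offending cell."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationMatrix:
    """Binary circRNA x drug association matrix with identifier axes."""

    values: np.ndarray
    circ_ids: tuple
    drug_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values)
        object.__setattr__(self, "values", v.astype(np.int8))
        object.__setattr__(self, "circ_ids", tuple(self.circ_ids))
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        if v.ndim != 2:
            raise MatrixValueError("association matrix must be 2-D")
        n, m = v.shape
        if n < 2 or m < 2:
            raise MatrixValueError(f"need at least 2 circRNAs and 2 drugs, got {n}x{m}")
        if len(self.circ_ids) != n or len(self.drug_ids) != m:
            raise MatrixValueError("identifier counts do not match matrix shape")
        for ids, what in ((self.circ_ids, "circRNA"), (self.drug_ids, "drug")):
            if len(set(ids)) != len(ids):
                dup = sorted({x for x in ids if list(ids).count(x) > 1})
                raise DuplicateIdError(f"duplicate {what} ids: {dup}")
        bad = np.argwhere((v != 0) & (v != 1))
        if bad.size:
            i, j = bad[0]
            raise MatrixValueError(
                f"non-binary cell at row {self.circ_ids[i]!r}, col {self.drug_ids[j]!r}")
        if v.sum() == 0:
            raise MatrixValueError("association matrix has no nonzero entries")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_circ(self) -> int:
        return self.values.shape[0]

    @property
    def n_drug(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SequenceSet:
    """circRNA host-gene nucleotide sequences keyed by circRNA id."""

    records: Mapping[str, str]

    def __post_init__(self):
        recs = dict(self.records)
        for cid, seq in recs.items():
            if not seq:
                raise DataFormatError(f"empty sequence for id {cid!r}")
            up = seq.upper()
            if set(up) - set("ACGTN"):
                raise DataFormatError(
                    f"sequence for {cid!r} has characters outside ACGTN")
            recs[cid] = up
        object.__setattr__(self, "records", recs)

    def __getitem__(self, cid: str) -> str:
        return self.records[cid]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FingerprintSet:
    """Fixed-length binary topological fingerprints keyed by drug id."""

    records: Mapping[str, np.ndarray]

    def __post_init__(self):
        recs = {}
        length = None
        for did, bits in dict(self.records).items():
            arr = np.asarray(bits, dtype=np.int8)
            if length is None:
                length = arr.size
                if length < 8:
                    raise DataFormatError(f"fingerprint length {length} < 8")
            elif arr.size != length:
                raise DataFormatError(
                    f"ragged fingerprint for {did!r}: {arr.size} != {length}")
            if np.any((arr != 0) & (arr != 1)):
                raise DataFormatError(f"non-binary fingerprint for {did!r}")
            recs[did] = arr
        object.__setattr__(self, "records", recs)

    @property
    def n_bits(self) -> int:
        return next(iter(self.records.values())).size

    def __getitem__(self, did: str) -> np.ndarray:
        return self.records[did]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued prediction scores in [0, 1], axes as AssociationMatrix."""

    values: np.ndarray
    circ_ids: tuple
    drug_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "circ_ids", tuple(self.circ_ids))
        object.__setattr__(self, "drug_ids", tuple(self.drug_ids))
        if not np.all(np.isfinite(v)):
            raise MatrixValueError("score matrix has non-finite entries")
        if v.min() < 0 or v.max() > 1:
            raise MatrixValueError("scores must lie in [0, 1]")


@dataclass
class RunConfig:
    """All tunable hyperparameters with their defaults.

    Augmentation defaults (`p_e`, `p_mr`, `p_mi`) follow the sensitivity
    analysis optimum; optimizer settings are shared by both training stages.
    """

    # collaborative feature learning
    embed_dim: int = 32
    hidden_dim: int = 64
    collab_epochs: int = 100
    warmup_epochs: int = 40
    mustlink_quantile: float = 0.90
    lambda_mc: float = 1.0
    # graph structure learning
    view_hidden: int = 64
    view_embed: int = 32
    proj_dim: int = 64
    head_hidden: int = 64
    head_embed: int = 32
    stageb_epochs: int = 150
    patience: int = 30
    p_e: float = 0.1
    p_mr: float = 0.1
    p_mi: float = 0.4
    tau: float = 0.8
    tau_ramp_epochs: int = 50
    lambda_cpl: float = 1.0
    stop_grad: bool = True
    learner_activation: str = "elu1"  # relu | elu1 | sigmoid
    top_k: int | None = None          # optional row-wise sparsification of S'
    # training / evaluation protocol
    lr: float = 5e-3
    neg_ratio: float = 1.0
    folds: int = 5
    seed: int = 0
    threshold: float = 0.5
    # ablations and protocol switches
    no_cfe: bool = False
    no_cgpl: bool = False
    gip_full_matrix: bool = False
    shuffle_labels: bool = False      # diagnostic: permute training labels

    def __post_init__(self):
        for name in ("p_e", "p_mr", "p_mi", "tau", "mustlink_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise DataFormatError(f"config {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataFormatError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_association_matrix(path) -> AssociationMatrix:
    """Read a labeled CSV/TSV association table (rows circRNAs, cols drugs)."""
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0 or df.index.name is None and df.columns.size == 0:
        raise DataFormatError(f"{path}: missing header row of drug ids")
    circ_ids = [str(x) for x in df.index]
    drug_ids = [str(x) for x in df.columns]
    vals = df.to_numpy()
    num = pd.DataFrame(vals).apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.argwhere(~np.isin(num, (0.0, 1.0)) | ~np.isfinite(num))
    if bad.size:
        i, j = bad[0]
        raise MatrixValueError(
            f"{path}: non-binary cell {vals[i, j]!r} at row {circ_ids[i]!r}, "
            f"col {drug_ids[j]!r}")
    return AssociationMatrix(num.astype(np.int8), circ_ids, drug_ids)


def write_association_matrix(mat: AssociationMatrix, path) -> None:
    df = pd.DataFrame(mat.values, index=list(mat.circ_ids),
                      columns=list(mat.drug_ids))
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep)


def read_fasta(path) -> SequenceSet:
    """Read FASTA; id = header token before the first whitespace."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise DataFormatError(f"empty sequence for id {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise DataFormatError(f"{path}: no FASTA records found")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=cid, description="")
            for cid, s in seqs.records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fingerprints(path, smiles: bool = False, n_bits: int = 2048) -> FingerprintSet:
    """Read a two-column TSV of drug_id and bitstring (or SMILES).

    With ``smiles=True`` each second column is parsed as a SMILES string and
    converted to an RDKit topological (Daylight-style) fingerprint of
    ``n_bits`` bits; this path requires the optional chemistry extra.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataFormatError(f"{path}:{ln}: expected 2 tab-separated fields")
            rows.append((parts[0], parts[1]))
    if not rows:
        raise DataFormatError(f"{path}: no fingerprint records")
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        dup = sorted({x for x in ids if ids.count(x) > 1})
        raise DuplicateIdError(f"duplicate drug ids: {dup}")
    records = {}
    if smiles:
        records = {did: smiles_to_fingerprint(smi, n_bits) for did, smi in rows}
    else:
        length = len(rows[0][1])
        for did, bits in rows:
            if len(bits) != length:
                raise DataFormatError(
                    f"ragged bitstring for {did!r}: length {len(bits)} != {length}")
            if set(bits) - {"0", "1"}:
                raise DataFormatError(f"non-binary bitstring for {did!r}")
            records[did] = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    return FingerprintSet(records)


def smiles_to_fingerprint(smi: str, n_bits: int = 2048) -> np.ndarray:
    """Convert one SMILES string to a binary topological fingerprint."""
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SMILES support needs the 'chem' extra (rdkit)") from exc
    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise DataFormatError(f"unparseable SMILES: {smi!r}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.int8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def write_fingerprints(fps: FingerprintSet, path) -> None:
    with open(path, "w") as fh:
        for did, bits in fps.records.items():
            fh.write(did + "\t" + "".join(map(str, bits.tolist())) + "\n")


def _ranked_rows(scores: ScoreMatrix):
    n, m = scores.values.shape
    rows = [(scores.circ_ids[i], scores.drug_ids[j], float(scores.values[i, j]))
            for i in range(n) for j in range(m)]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows


def write_predictions(scores: ScoreMatrix, path, top_k_per_drug: int | None = None) -> None:
    """Write ranked predictions as TSV: circ_id, drug_id, score, rank.

    Rank is the 1-based position under descending score with ties broken by
    (circ_id, drug_id) lexicographic order, so output is deterministic.  With
    ``top_k_per_drug`` only the top-k rows of each drug are kept (ranks are
    still global).
    """
    rows = _ranked_rows(scores)
    if top_k_per_drug is not None:
        kept, counts = [], {}
        for rank, (c, d, s) in enumerate(rows, 1):
            if counts.get(d, 0) < top_k_per_drug:
                counts[d] = counts.get(d, 0) + 1
                kept.append((c, d, s, rank))
        out = kept
    else:
        out = [(c, d, s, rank) for rank, (c, d, s) in enumerate(rows, 1)]
    with open(path, "w") as fh:
        fh.write("circ_id\tdrug_id\tscore\trank\n")
        for c, d, s, rank in out:
            fh.write(f"{c}\t{d}\t{s:.6f}\t{rank}\n")


def top_k_for_drug(scores: ScoreMatrix, drug_id: str, k: int):
    """Top-k (circ_id, score) rows for one drug, descending, ties lexicographic."""
    j = list(scores.drug_ids).index(drug_id)
    pairs = [(scores.circ_ids[i], float(scores.values[i, j]))
             for i in range(len(scores.circ_ids))]
    pairs.sort(key=lambda r: (-r[1], r[0]))
    return pairs[:k]
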