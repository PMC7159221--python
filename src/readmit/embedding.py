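"""Record-level code co-occurrence and GloVe embeddings.

Two medical codes co-occur when they appear in the same admission record
(presence-based: records are unordered code sets, so there is no context
window and no distance weighting). The co-occurrence counts are
factorized with the GloVe objective

    J = sum_{(i,j): X_ij > 0} f(X_ij) (w_i . wc_j + b_i + bc_j - log X_ij)^2,
    f(x) = (x / x_max)^alpha  for x < x_max, else 1,

minimized by seeded stochastic gradient descent with AdaGrad
per-parameter learning rates over the nonzero entries. The embedding of
code i is w_i + wc_i. Diagnosis and procedure codes are fitted
separately (200- and 50-dimensional by default) on the dx-dx and
proc-proc sub-blocks of the joint matrix; training always uses the
train+validation records only, never the test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.sparse import csr_matrix

from .synthetic_claims import incidence_matrix

__all__ = [
    "CooccurrenceMatrix",
    "GloveParams",
    "EmbeddingTable",
    "count_cooccurrences",
    "fit_glove",
    "embed_record",
    "glove_objective",
    "nn_cluster_purity",
]

logger = logging.getLogger(__name__)


class InputError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass
class CooccurrenceMatrix:
    """Symmetric nonnegative record-level co-occurrence counts."""

    vocabulary: list[str]
    X: csr_matrix  # symmetric, zero diagonal

    def subblock(self, codes: list[str]) -> "CooccurrenceMatrix":
        """Restrict to a code subset (e.g. the dx-dx block)."""
        pos = {c: j for j, c in enumerate(self.vocabulary)}
        idx = np.array([pos[c] for c in codes], dtype=np.int64)
        sub = self.X[idx][:, idx].tocsr()
        return CooccurrenceMatrix(list(codes), sub)


@dataclass(frozen=True)
class GloveParams:
    """GloVe hyperparameters (canonical defaults x_max=100, alpha=0.75)."""

    dim: int
    x_max: float = 100.0
    alpha: float = 0.75
    learning_rate: float = 0.05
    n_epochs: int = 15
    seed: int = 0

    def validate(self) -> None:
        if self.dim <= 0:
            raise InputError("embedding dimension must be positive")
        if not (0.0 < self.alpha <= 1.0):
            raise InputError("alpha must lie in (0, 1]")
        if self.x_max <= 0:
            raise InputError("x_max must be positive")


@dataclass
class EmbeddingTable:
    """Code -> dense vector lookup with an out-of-vocabulary policy.

    OOV secondary/procedure codes are skipped (treated as absent); an OOV
    principal code yields a zero vector and a logged warning by default,
    or an error when ``oov_policy`` is "error".
    """

    codes: list[str]
    vectors: np.ndarray  # (n_codes, dim)
    oov_policy: str = "zero"
    epoch_losses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self._index = {c: i for i, c in enumerate(self.codes)}
        if not np.all(np.isfinite(self.vectors)):
            raise InputError("embedding vectors must be finite")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def get(self, code: str) -> np.ndarray | None:
        i = self._index.get(code)
        return None if i is None else self.vectors[i]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.vectors)
        df.insert(0, "code", self.codes)
        df.to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path) -> "EmbeddingTable":
        df = pd.read_csv(path, sep="\t", header=None)
        return cls(df.iloc[:, 0].astype(str).tolist(),
                   df.iloc[:, 1:].to_numpy(dtype=np.float64))


def count_cooccurrences(records: pd.DataFrame,
                        vocabulary: list[str]) -> CooccurrenceMatrix:
    """Count, for each unordered pair of distinct in-vocabulary codes, the
    number of records in which both appear.

    Principal and secondary diagnosis codes and procedure codes all
    participate; each record contributes at most 1 to a pair (presence,
    not multiplicity). X is symmetric with a zero diagonal.
    """
    if not vocabulary:
        raise InputError("empty vocabulary")
    M = incidence_matrix(records, vocabulary).astype(np.int64)
    X = (M.T @ M).tocsr()
    X.setdiag(0)
    X.eliminate_zeros()
    return CooccurrenceMatrix(list(vocabulary), X)


def serialize_cooccurrence(cm: CooccurrenceMatrix, path) -> None:
    """Coordinate-triplet text format: code_i<TAB>code_j<TAB>count (i < j)."""
    coo = cm.X.tocoo()
    with open(path, "w") as fh:
        fh.write("\t".join(cm.vocabulary) + "\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if i < j:
                fh.write(f"{i}\t{j}\t{int(v)}\n")


def deserialize_cooccurrence(path) -> CooccurrenceMatrix:
    with open(path) as fh:
        vocab = fh.readline().rstrip("\n").split("\t")
        rows, cols, vals = [], [], []
        for line in fh:
            i, j, v = line.split("\t")
            rows.append(int(i))
            cols.append(int(j))
            vals.append(int(v))
    n = len(vocab)
    upper = csr_matrix((vals, (rows, cols)), shape=(n, n), dtype=np.int64)
    return CooccurrenceMatrix(vocab, (upper + upper.T).tocsr())


def glove_objective(W: np.ndarray, Wc: np.ndarray, b: np.ndarray,
                    bc: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                    logx: np.ndarray, fw: np.ndarray,
                    with_grad: bool = False):
    """Vectorized GloVe loss (and optionally its analytic gradient).

    Independent of the SGD training path; used for loss reporting and as
    the reference in gradient checks. ``rows``/``cols``/``logx``/``fw``
    enumerate the nonzero entries.
    """
    diff = (np.sum(W[rows] * Wc[cols], axis=1) + b[rows] + bc[cols] - logx)
    J = float(np.sum(fw * diff * diff))
    if not with_grad:
        return J
    coef = 2.0 * fw * diff
    gW = np.zeros_like(W)
    gWc = np.zeros_like(Wc)
    gb = np.zeros_like(b)
    gbc = np.zeros_like(bc)
    np.add.at(gW, rows, coef[:, None] * Wc[cols])
    np.add.at(gWc, cols, coef[:, None] * W[rows])
    np.add.at(gb, rows, coef)
    np.add.at(gbc, cols, coef)
    return J, (gW, gWc, gb, gbc)


@njit(cache=True)
def _glove_sgd(rows, cols, logx, fw, W, Wc, b, bc, lr, n_epochs, shuffle_seed):
    """AdaGrad SGD over nonzero entries; returns per-epoch loss."""
    nnz = rows.shape[0]
    dim = W.shape[1]
    GW = np.ones(W.shape)
    GWc = np.ones(Wc.shape)
    Gb = np.ones(b.shape)
    Gbc = np.ones(bc.shape)
    losses = np.empty(n_epochs)
    order = np.arange(nnz)
    np.random.seed(shuffle_seed)
    for ep in range(n_epochs):
        np.random.shuffle(order)
        total = 0.0
        for t in range(nnz):
            k = order[t]
            i = rows[k]
            j = cols[k]
            dot = b[i] + bc[j] - logx[k]
            for d in range(dim):
                dot += W[i, d] * Wc[j, d]
            f = fw[k]
            total += f * dot * dot
            g = 2.0 * f * dot
            for d in range(dim):
                gwi = g * Wc[j, d]
                gwj = g * W[i, d]
                W[i, d] -= lr * gwi / np.sqrt(GW[i, d])
                Wc[j, d] -= lr * gwj / np.sqrt(GWc[j, d])
                GW[i, d] += gwi * gwi
                GWc[j, d] += gwj * gwj
            b[i] -= lr * g / np.sqrt(Gb[i])
            bc[j] -= lr * g / np.sqrt(Gbc[j])
            Gb[i] += g * g
            Gbc[j] += g * g
        losses[ep] = total
    return losses


def fit_glove(cm: CooccurrenceMatrix, params: GloveParams) -> EmbeddingTable:
    """Fit GloVe embeddings on a co-occurrence matrix.

    Iterates over all stored nonzero cells of the symmetric matrix (each
    unordered pair appears in both orders, so main and context roles are
    trained symmetrically). Final embedding of code i is w_i + wc_i.
    """
    params.validate()
    coo = cm.X.tocoo()
    if coo.nnz == 0:
        raise InputError("co-occurrence matrix has no nonzero entries")
    rows = coo.row.astype(np.int64)
    cols = coo.col.astype(np.int64)
    x = coo.data.astype(np.float64)
    logx = np.log(x)
    fw = np.minimum((x / params.x_max) ** params.alpha, 1.0)

    n = len(cm.vocabulary)
    rng = np.random.default_rng(params.seed)
    scale = 0.5 / np.sqrt(params.dim)
    W = rng.uniform(-scale, scale, (n, params.dim))
    Wc = rng.uniform(-scale, scale, (n, params.dim))
    b = rng.uniform(-scale, scale, n)
    bc = rng.uniform(-scale, scale, n)

    j0 = glove_objective(W, Wc, b, bc, rows, cols, logx, fw)
    shuffle_seed = int(rng.integers(2 ** 31 - 1))
    losses = _glove_sgd(rows, cols, logx, fw, W, Wc, b, bc,
                        params.learning_rate, params.n_epochs, shuffle_seed)
    if not np.all(np.isfinite(losses)):
        raise DivergenceError(
            f"GloVe training diverged (learning_rate={params.learning_rate})")
    logger.info("GloVe: loss %.4g -> %.4g over %d epochs (nnz=%d, dim=%d)",
                j0, losses[-1], params.n_epochs, coo.nnz, params.dim)
    return EmbeddingTable(list(cm.vocabulary), W + Wc,
                          epoch_losses=np.concatenate(([j0], losses)))


def embed_record(record, dx_table: EmbeddingTable, proc_table: EmbeddingTable):
    """Look up (principal vector, secondary vectors, procedure vectors).

    Out-of-vocabulary secondary/procedure codes are skipped. An OOV
    principal code returns a zero vector (logged) or raises, depending on
    the table's ``oov_policy``.
    """
    prin = dx_table.get(record["principal_dx"])
    if prin is None:
        if dx_table.oov_policy == "error":
            raise InputError(
                f"principal diagnosis {record['principal_dx']!r} out of vocabulary")
        logger.warning("principal diagnosis %r out of vocabulary; using zeros",
                       record["principal_dx"])
        prin = np.zeros(dx_table.dim)
    sec = [v for v in (dx_table.get(c) for c in record["secondary_dx"])
           if v is not None]
    proc = [v for v in (proc_table.get(c) for c in record["procedures"])
            if v is not None]
    return prin, sec, proc


def nn_cluster_purity(table: EmbeddingTable, cluster_of: dict[str, int]) -> float:
    """Fraction of codes whose nearest neighbor (cosine) shares their
    latent cluster — a scalar stand-in for 'related codes embed nearby'."""
    V = table.vectors
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    U = V / np.maximum(norms, 1e-12)
    S = U @ U.T
    np.fill_diagonal(S, -np.inf)
    nn = np.argmax(S, axis=1)
    labels = np.array([cluster_of[c] for c in table.codes])
    return float(np.mean(labels == labels[nn]))
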