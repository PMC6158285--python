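"""STATIS: multi-table analysis via weighted compromise of cross-products.

Given K centered, normalized tables X_l (stages × metabolites), STATIS

1. forms the cross-product matrices S_l = X_l X_lᵀ (unit Frobenius norm),
2. measures table agreement through the interstructure matrix C whose entries
   are the elementwise inner products of the S_l — for unit-norm PSD matrices
   this inner product *is* the Rv coefficient, the cosine between tables,
3. takes the leading eigenvector α of C (unit Euclidean norm, non-negative by
   Perron–Frobenius) as table weights,
4. analyzes the compromise S = Σ α_l S_l by an eigen-decomposition under the
   masses metric, giving consensus row (stage) scores, and
5. reports each table's weight and squared Rv to the compromise — the
   table-contribution display — plus interstructure projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import AccessionTable


@dataclass
class CrossProductMatrix:
    accession: str
    S: np.ndarray
    normalized: bool

    def __post_init__(self):
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ValueError("cross-product matrix must be symmetric")


@dataclass
class StatisResult:
    accessions: list
    C: np.ndarray                    # K × K inner products
    rv: np.ndarray                   # K × K Rv coefficients
    alpha: np.ndarray                # unit-norm table weights
    inter_eigenvalues: np.ndarray
    table_projections: np.ndarray    # K × k interstructure coordinates
    compromise: np.ndarray           # t × t
    eigenvalues: np.ndarray          # compromise spectrum, non-increasing
    row_scores: np.ndarray           # t × k principal coordinates
    table_rv2_to_compromise: np.ndarray


def cross_product(table: AccessionTable, normalize: bool = True
                  ) -> CrossProductMatrix:
    """S = X Xᵀ over the table's rows, optionally unit-Frobenius-normalized."""
    X = np.asarray(table.X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError(f"table {table.accession} has non-finite entries")
    S = X @ X.T
    if normalize:
        nrm = np.linalg.norm(S)
        if nrm > 0:
            S = S / nrm
    return CrossProductMatrix(accession=table.accession, S=S,
                              normalized=normalize)


def rv_coefficient(S1: CrossProductMatrix, S2: CrossProductMatrix) -> float:
    """Cosine between two normalized cross-product matrices: the elementwise
    double-sum inner product Σ_p Σ_q s_pq^(1) s_pq^(2)."""
    if S1.S.shape != S2.S.shape:
        raise ValueError(f"dimension mismatch: {S1.S.shape} vs {S2.S.shape}")
    return float(np.sum(S1.S * S2.S))


def _orient(v: np.ndarray) -> np.ndarray:
    """Fix eigenvector sign: largest-magnitude loading positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def interstructure(cross_products):
    """Interstructure of K tables.

    Returns ``(C, rv, alpha, eigenvalues, table_projections)`` where C is the
    K × K inner-product matrix (equal to the Rv matrix for normalized inputs),
    alpha the unit-norm leading eigenvector of C with non-negative
    orientation, and the projections place each table on the eigenvectors of
    C scaled by the square roots of their eigenvalues.
    """
    if len(cross_products) == 0:
        raise ValueError("interstructure requires at least one table")
    K = len(cross_products)
    mats = [cp.S for cp in cross_products]
    C = np.empty((K, K))
    for i in range(K):
        for j in range(i, K):
            C[i, j] = C[j, i] = float(np.sum(mats[i] * mats[j]))
    rv = C.copy()  # equals Rv when inputs are unit-Frobenius-normalized
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    alpha = _orient(evecs[:, 0])
    alpha = np.clip(alpha, 0.0, None)
    nrm = np.linalg.norm(alpha)
    if nrm > 0:
        alpha = alpha / nrm
    proj = np.column_stack([
        _orient(evecs[:, i]) * np.sqrt(max(evals[i], 0.0))
        for i in range(K)])
    return C, rv, alpha, evals, proj


def compromise(cross_products, alpha, masses=None):
    """α-weighted compromise and its eigen-analysis under the masses metric.

    Returns ``(S, eigenvalues, row_scores, table_rv2_to_compromise)``. Row
    scores are mass-weighted principal coordinates; components are truncated
    at eigenvalues above 1e−12. The per-table squared Rv is computed against
    the unit-Frobenius-normalized compromise.
    """
    alpha = np.asarray(alpha, dtype=float)
    if len(alpha) != len(cross_products):
        raise ValueError("alpha length must equal the number of tables")
    if (alpha < 0).any():
        raise ValueError("alpha entries must be non-negative")
    S = sum(a * cp.S for a, cp in zip(alpha, cross_products))
    t = S.shape[0]
    m = np.full(t, 1.0 / t) if masses is None else np.asarray(masses, float)
    sq = np.sqrt(m)
    B = (sq[:, None] * S) * sq[None, :]
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = int(np.sum(evals > 1e-12))
    k = max(k, 1)
    V = np.column_stack([_orient(evecs[:, i]) for i in range(k)])
    scores = (V * np.sqrt(np.clip(evals[:k], 0.0, None))) / sq[:, None]
    s_norm = np.linalg.norm(S)
    Sn = S / s_norm if s_norm > 0 else S
    rv2 = np.array([
        float(np.sum(cp.S * Sn)) ** 2 for cp in cross_products])
    return S, evals, scores, rv2


def statis_analysis(tables) -> StatisResult:
    """Run the full STATIS sequence on a list of accession tables."""
    cps = [cross_product(tb, normalize=True) for tb in tables]
    C, rv, alpha, inter_evals, proj = interstructure(cps)
    masses = np.asarray(tables[0].masses, dtype=float)
    S, evals, scores, rv2 = compromise(cps, alpha, masses=masses)
    return StatisResult(
        accessions=[tb.accession for tb in tables],
        C=C, rv=rv, alpha=alpha, inter_eigenvalues=inter_evals,
        table_projections=proj, compromise=S, eigenvalues=evals,
        row_scores=scores, table_rv2_to_compromise=rv2)
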