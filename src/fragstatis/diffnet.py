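"""Stage-wise correlation networks and differential connectivity.

For each ripening stage, a domesticated (D) and a wild (W) network are built
from pairwise Pearson correlations whose Benjamini–Hochberg-adjusted p-values
(t transform, n − 2 df) fall below the FDR cutoff. Per metabolite,
differential connectivity is

    DC_i = deg_i(D)/max_deg(D) − deg_i(W)/max_deg(W),

its significance assessed against an empirical null obtained by reassigning
whole accessions (all replicates together) to the two groups, preserving the
original group sizes. Abundance differences get two-tailed Welch t-tests, and
metabolites significant on both axes are classified into the four
connectivity × abundance quadrants. A Yates-corrected χ² tests whether
primary vs secondary metabolites associate with gain vs loss of connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class InsufficientDataError(ValueError):
    pass


class DegenerateTableError(ValueError):
    pass


QUADRANTS = ("top_right", "top_left", "bottom_left", "bottom_right", "ns")


@dataclass
class DCRecord:
    metabolite_id: str
    deg_D: float
    deg_W: float
    dc: float
    p_perm: float
    q_perm: float
    t_stat: float
    q_t: float
    abundance_direction: str
    quadrant: str = "ns"


class CorrelationNetwork:
    """Metabolite graph from FDR-thresholded Pearson correlations."""

    def __init__(self, nodes, r, p, q, adjacency, group=None, stage=None,
                 constant_nodes=()):
        self.nodes = list(nodes)
        self.r = r
        self.p = p
        self.q = q
        self.adjacency = adjacency
        self.group = group
        self.stage = stage
        self.constant_nodes = list(constant_nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def edges(self):
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        return {(self.nodes[i], self.nodes[j]) for i, j in zip(ii, jj)}

    def edge_records(self, with_p: bool = False):
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        for i, j in zip(ii, jj):
            rec = ((self.nodes[i], self.nodes[j]), self.r[i, j], self.q[i, j])
            yield rec + ((self.p[i, j],) if with_p else ())

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    @property
    def density(self) -> float:
        return network_density(self)


def _pearson_matrix(X: np.ndarray):
    """Pairwise r and two-sided p (t transform, n−2 df); constant columns NaN."""
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc ** 2).sum(axis=0))
    const = denom <= 0
    denom_safe = np.where(const, 1.0, denom)
    r = (Xc.T @ Xc) / np.outer(denom_safe, denom_safe)
    r = np.clip(r, -1.0, 1.0)
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, np.where(const, np.nan, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = r * r * (n - 2) / (1.0 - r * r)
    pval = np.where(np.isclose(np.abs(r), 1.0), 0.0,
                    2.0 * stats.t.sf(np.sqrt(np.abs(t2)), n - 2))
    pval = np.where(np.isnan(r), np.nan, pval)
    return r, pval, const


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjustment; NaN entries stay NaN."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _adjacency_from_data(X: np.ndarray, fdr: float):
    """Fast path: boolean adjacency of the FDR-thresholded network."""
    n, p = X.shape
    r, pval, const = _pearson_matrix(X)
    iu = np.triu_indices(p, 1)
    q_flat = bh_adjust(pval[iu])
    adj = np.zeros((p, p), dtype=bool)
    with np.errstate(invalid="ignore"):
        sig = q_flat < fdr
    adj[iu[0][sig], iu[1][sig]] = True
    adj |= adj.T
    q = np.full((p, p), np.nan)
    q[iu] = q_flat
    q.T[iu] = q_flat
    return adj, r, pval, q, const


def correlation_network(data, fdr: float = 0.05, nodes=None, group=None,
                        stage=None) -> CorrelationNetwork:
    """Build the correlation network for one group at one stage.

    ``data`` is a samples × metabolites DataFrame (or array with ``nodes``)
    of values on the scale at which correlations are computed. Constant
    metabolites have undefined correlations, carry no edges, and are flagged
    in ``constant_nodes``.
    """
    if isinstance(data, pd.DataFrame):
        nodes = data.columns.tolist()
        X = data.to_numpy(float)
    else:
        X = np.asarray(data, float)
        nodes = list(nodes) if nodes is not None else list(range(X.shape[1]))
    if X.shape[0] < 4:
        raise InsufficientDataError(
            f"need at least 4 samples, got {X.shape[0]}")
    adj, r, pval, q, const = _adjacency_from_data(X, fdr)
    return CorrelationNetwork(nodes, r, pval, q, adj, group=group, stage=stage,
                              constant_nodes=[nodes[i] for i in
                                              np.nonzero(const)[0]])


def network_density(net: CorrelationNetwork) -> float:
    """Observed edges over all possible node pairs."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    n_edges = int(np.triu(net.adjacency, 1).sum())
    return n_edges / (n * (n - 1) / 2)


def _normalized_degrees(adj: np.ndarray) -> np.ndarray:
    deg = adj.sum(axis=0).astype(float)
    mx = deg.max() if deg.size else 0.0
    return deg / mx if mx > 0 else np.zeros_like(deg)


def differential_connectivity(net_D: CorrelationNetwork,
                              net_W: CorrelationNetwork) -> np.ndarray:
    """DC per metabolite: max-normalized degree in D minus that in W.

    An empty network contributes normalized degree 0 for every node.
    """
    if net_D.nodes != net_W.nodes:
        raise ValueError("node sets of the two networks do not match")
    return _normalized_degrees(net_D.adjacency) - _normalized_degrees(
        net_W.adjacency)


def _dc_from_matrices(X_D: np.ndarray, X_W: np.ndarray, fdr: float
                      ) -> np.ndarray:
    adj_D = _adjacency_from_data(X_D, fdr)[0]
    adj_W = _adjacency_from_data(X_W, fdr)[0]
    return _normalized_degrees(adj_D) - _normalized_degrees(adj_W)


def dc_permutation_test(data_D, data_W, accessions_D, accessions_W,
                        B: int = 1000, fdr: float = 0.05, seed: int = 0):
    """Permutation test of differential connectivity.

    Accession labels (each with all of its replicates) are reassigned to the
    two groups ``B`` times, preserving the original group sizes; the two
    networks and DC are recomputed each time. Per metabolite the empirical
    two-sided p-value uses the add-one estimator
    ``(1 + #{|DC_b| ≥ |DC_obs|}) / (B + 1)``, adjusted by Benjamini–Hochberg.

    Returns ``(dc_obs, p_perm, q_perm)``.
    """
    X_D = np.asarray(data_D, float)
    X_W = np.asarray(data_W, float)
    acc_D = np.asarray(accessions_D)
    acc_W = np.asarray(accessions_W)
    if B < 1:
        raise ValueError("B must be >= 1")
    uD, uW = sorted(set(acc_D)), sorted(set(acc_W))
    if len(uD) < 2 or len(uW) < 2:
        raise InsufficientDataError("need at least 2 accessions per group")
    rng = np.random.default_rng(seed)
    dc_obs = _dc_from_matrices(X_D, X_W, fdr)

    X_all = np.vstack([X_D, X_W])
    acc_all = np.concatenate([acc_D, acc_W])
    uniq = np.array(uD + uW)
    n_take = len(uD)
    count = np.zeros(X_all.shape[1])
    abs_obs = np.abs(dc_obs)
    for _ in range(B):
        perm = rng.permutation(uniq)
        in_a = np.isin(acc_all, perm[:n_take])
        dc_b = _dc_from_matrices(X_all[in_a], X_all[~in_a], fdr)
        count += np.abs(dc_b) >= abs_obs - 1e-12
    p_perm = (1.0 + count) / (B + 1.0)
    q_perm = bh_adjust(p_perm)
    return dc_obs, p_perm, q_perm


def abundance_tests(data_D, data_W, fdr: float = 0.05,
                    log_transform: bool = True):
    """Per-metabolite two-tailed Welch t-tests of D vs W abundance.

    Returns ``(t_stat, p, q, direction)`` with direction
    ``up_in_D``/``down_in_D`` from the sign of mean(D) − mean(W). Metabolites
    with zero variance in both groups and equal means get t = 0, p = 1.
    """
    X_D = np.asarray(data_D, float)
    X_W = np.asarray(data_W, float)
    if X_D.shape[0] < 2 or X_W.shape[0] < 2:
        raise InsufficientDataError("need at least 2 samples per group")
    if log_transform:
        pos = np.concatenate([X_D.ravel(), X_W.ravel()])
        pos = pos[np.isfinite(pos) & (pos > 0)]
        eps = pos.min() / 2.0 if pos.size else 1.0
        X_D, X_W = np.log10(X_D + eps), np.log10(X_W + eps)
    t_stat, p = stats.ttest_ind(X_D, X_W, axis=0, equal_var=False)
    diff = X_D.mean(axis=0) - X_W.mean(axis=0)
    degenerate = np.isnan(t_stat)
    t_stat = np.where(degenerate & (np.abs(diff) <= 1e-12), 0.0, t_stat)
    p = np.where(degenerate & (np.abs(diff) <= 1e-12), 1.0, p)
    # zero variance but different means: certain difference
    t_stat = np.where(np.isnan(t_stat), np.sign(diff) * np.inf, t_stat)
    p = np.where(np.isnan(p), 0.0, p)
    q = bh_adjust(p)
    direction = np.where(diff >= 0, "up_in_D", "down_in_D")
    return t_stat, p, q, direction


def classify_quadrants(records: pd.DataFrame, threshold: float = 0.05
                       ) -> pd.DataFrame:
    """Assign connectivity × abundance quadrants.

    A metabolite is classified only if both q_perm and q_t fall below the
    threshold; otherwise it is ``ns``. Gain of connectivity in D (dc > 0)
    with increased abundance in D is the top-right quadrant.
    """
    rec = records.copy()
    sig = (rec["q_perm"] < threshold) & (rec["q_t"] < threshold)
    up = rec["abundance_direction"] == "up_in_D"
    gain = rec["dc"] > 0
    quad = np.full(len(rec), "ns", dtype=object)
    quad[(sig & gain & up).to_numpy()] = "top_right"
    quad[(sig & gain & ~up).to_numpy()] = "top_left"
    quad[(sig & ~gain & ~up).to_numpy()] = "bottom_left"
    quad[(sig & ~gain & up).to_numpy()] = "bottom_right"
    quad[(sig & (rec["dc"] == 0)).to_numpy()] = "ns"  # no connectivity change
    rec["quadrant"] = quad
    return rec


def class_association_chi2(met_class, dc, significant=None,
                           scope: str = "significant_only"):
    """Yates-corrected χ² of metabolite class vs gain/loss of connectivity.

    Builds the 2×2 table (primary, secondary) × (dc > 0, dc < 0) over either
    all metabolites with non-zero DC or only those with significant DC.
    Returns ``(chi2, p, table)``.
    """
    met_class = np.asarray(met_class)
    dc = np.asarray(dc, float)
    if scope == "significant_only":
        if significant is None:
            raise ValueError("scope='significant_only' needs a mask")
        mask = np.asarray(significant, bool) & (dc != 0)
    elif scope == "all_nonzero_dc":
        mask = dc != 0
    else:
        raise ValueError(f"unknown scope {scope!r}")
    table = pd.DataFrame(
        [[int(((met_class == c) & mask & (dc > 0)).sum()),
          int(((met_class == c) & mask & (dc < 0)).sum())]
         for c in ("primary", "secondary")],
        index=["primary", "secondary"], columns=["gain", "loss"])
    arr = table.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"zero marginal in table:\n{table}")
    res = stats.chi2_contingency(arr, correction=True)
    return float(res.statistic), float(res.pvalue), table
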