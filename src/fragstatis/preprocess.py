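"""Missingness filtering, imputation, and STATIS table construction.

The network analysis excludes metabolites with more than 20% missing values
and imputes the rest with a probabilistic low-rank (Bayesian-PCA-style) fit
with five components, on log10 scale. The multi-table STATIS analysis instead
uses the undetected-equals-zero rule: missing cells become 0 before the
per-accession stage × metabolite tables are centered and normalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import STAGES, AbundanceDataset


class EmptyResultError(ValueError):
    pass


class StructuralError(ValueError):
    pass


@dataclass
class AccessionTable:
    """One STATIS input table: stages (rows) × metabolites (columns).

    ``X`` is column-centered and scaled so that the Frobenius norm of its
    cross-product matrix X Xᵀ equals 1; ``masses`` are equal row weights
    summing to one.
    """

    accession: str
    group: str
    stages: list
    metabolites: list
    X: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        t = self.X.shape[0]
        if len(self.masses) != t:
            raise ValueError("masses length must equal the row count")
        if abs(self.masses.sum() - 1.0) > 1e-12:
            raise ValueError("masses must sum to 1")


def filter_missing(dataset: AbundanceDataset, max_missing_frac: float = 0.20):
    """Drop metabolites whose missing fraction is strictly above the cutoff.

    Returns ``(filtered dataset, removal report)``; the report lists every
    metabolite with its missing fraction and whether it was removed.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = dataset.missing_fraction()
    removed = frac.index[frac > max_missing_frac].tolist()
    keep = [m for m in dataset.metabolite_ids if m not in set(removed)]
    if not keep:
        raise EmptyResultError("all metabolites exceed the missingness cutoff")
    report = pd.DataFrame({
        "metabolite_id": frac.index,
        "missing_frac": frac.to_numpy(),
        "removed": frac.to_numpy() > max_missing_frac,
    })
    return dataset.subset_metabolites(keep), report


def log_epsilon(values: np.ndarray) -> float:
    """Half the smallest positive observed value (log-transform offset)."""
    pos = values[np.isfinite(values) & (values > 0)]
    return float(pos.min()) / 2.0 if pos.size else 1.0


def impute_bpca(dataset: AbundanceDataset, n_components: int = 5,
                seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
                log_transform: bool = True):
    """Impute missing cells with an EM-style probabilistic low-rank fit.

    The model is the Bayesian/probabilistic-PCA family: values (log10 scale by
    default) are approximated by a rank-``n_components`` reconstruction, and
    missing cells are iterated to the model estimate (expectation step =
    fill-in, maximization step = truncated SVD of the completed, centered
    matrix). Observed cells are never altered.

    Returns ``(imputed dataset, report dict)`` with keys ``converged``,
    ``n_iter`` and ``n_imputed``.
    """
    ds = dataset.copy()
    raw = ds.values.to_numpy(float)
    mask = np.isnan(raw)
    n_missing = int(mask.sum())
    if n_missing == 0:
        return ds, {"converged": True, "n_iter": 0, "n_imputed": 0}
    if ds.n_samples < n_components + 1:
        raise ValueError("need at least n_components + 1 samples")

    eps = log_epsilon(raw)
    X = np.log10(raw + eps) if log_transform else raw.copy()
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X[mask] = np.take(col_mean, np.nonzero(mask)[1])

    k = min(n_components, min(X.shape) - 1)
    converged, it = False, 0
    for it in range(1, max_iter + 1):
        mu = X.mean(axis=0)
        Xc = X - mu
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        recon = (U[:, :k] * s[:k]) @ Vt[:k] + mu
        new = recon[mask]
        delta = np.sqrt(np.mean((new - X[mask]) ** 2))
        scale = max(np.sqrt(np.mean(X[mask] ** 2)), 1e-12)
        X[mask] = new
        if delta / scale < tol:
            converged = True
            break

    if log_transform:
        filled = 10.0 ** X - eps
        filled = np.clip(filled, 0.0, None)
    else:
        filled = X
    out = raw.copy()
    out[mask] = filled[mask]
    ds.values.iloc[:, :] = out
    return ds, {"converged": converged, "n_iter": it, "n_imputed": n_missing}


def build_statis_tables(dataset: AbundanceDataset,
                        row_mode: str = "stage_means",
                        log_transform: bool = True):
    """Build one centered, normalized table per accession for STATIS.

    Missing cells are zero-filled (an undetected metabolite has abundance
    zero), values are log10(1 + x)-transformed by default, replicates are
    averaged within stage (``row_mode="stage_means"``, t = 3 rows) or kept as
    separate rows (``row_mode="stage_by_rep"``), each column is centered, and
    the table is scaled so the Frobenius norm of X Xᵀ is 1. Equal masses 1/t.
    """
    if row_mode not in ("stage_means", "stage_by_rep"):
        raise ValueError(f"unknown row_mode {row_mode!r}")
    mets = dataset.metabolite_ids
    vals = dataset.values.fillna(0.0)
    if log_transform:
        vals = np.log10(1.0 + vals)
    tables = []
    accessions = dataset.samples["accession"].unique().tolist()
    for acc in accessions:
        sub = dataset.samples[dataset.samples["accession"] == acc]
        group = sub["group"].iloc[0]
        present = set(sub["stage"])
        absent = [s for s in STAGES if s not in present]
        if absent:
            raise StructuralError(f"accession {acc} lacks stage(s) {absent}")
        v = vals.loc[sub.index]
        if row_mode == "stage_means":
            stage_order = pd.Categorical(sub["stage"], categories=STAGES,
                                         ordered=True)
            X = (v.groupby(stage_order, observed=True).mean()
                 .reindex(STAGES).to_numpy())
            row_labels = list(STAGES)
        else:
            key = sub.assign(_stage=pd.Categorical(sub["stage"],
                                                   categories=STAGES,
                                                   ordered=True))
            order = key.sort_values(["_stage", "replicate"]).index
            X = v.loc[order].to_numpy()
            key = key.loc[order]
            row_labels = [f"{s}_{r}" for s, r in
                          zip(key["stage"], key["replicate"])]
        X = X - X.mean(axis=0, keepdims=True)
        nrm = np.linalg.norm(X @ X.T)
        if nrm > 0:
            X = X / np.sqrt(nrm)
        t = X.shape[0]
        tables.append(AccessionTable(
            accession=acc, group=group, stages=row_labels,
            metabolites=list(mets), X=X, masses=np.full(t, 1.0 / t)))
    return tables
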