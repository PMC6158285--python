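"""End-to-end pipeline: data → preprocess → STATIS → networks → biomarkers.

One master seed drives every stochastic step through deterministically
derived child seeds, so identical config + seed reproduces every output file
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .datamodel import STAGES, AbundanceDataset
from .biomarker import screen_biomarkers
from .diffnet import (DegenerateTableError, abundance_tests,
                      class_association_chi2, classify_quadrants,
                      correlation_network, dc_permutation_test,
                      differential_connectivity, network_density)
from .preprocess import build_statis_tables, filter_missing, impute_bpca, \
    log_epsilon
from .statis import statis_analysis
from .synthetic import GeneratorConfig, generate_dataset


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of input_path/generator is set."""

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    metabolite_meta: str | None = None
    fdr: float = 0.05
    permutations: int = 1000
    seed: int = 17
    row_mode: str = "stage_means"
    log_transform: bool = True
    max_missing_frac: float = 0.20
    n_components: int = 5
    alpha: float = 0.05
    output_dir: str | None = None

    def validate(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError(
                "exactly one of input_path / generator must be given")
        for name in ("fdr", "alpha"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "generator"}
        d["generator"] = self.generator.to_dict() if self.generator else None
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def global_pca(dataset: AbundanceDataset, n_components: int = 3,
               log_transform: bool = True, scale: bool = False):
    """PCA of all samples on the complete (imputed) metabolite profiles.

    Returns ``(scores, explained_variance_fractions)``; scores carry the
    stage/group annotations for plotting. Components beyond the matrix rank
    are truncated.
    """
    X = dataset.values.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("global_pca needs a complete dataset")
    if log_transform:
        X = np.log10(X + log_epsilon(X))
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(n_components, rank)
    var = s ** 2 / max(np.sum(s ** 2), np.finfo(float).tiny)
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        index=dataset.values.index,
        columns=[f"PC{i + 1}" for i in range(k)])
    for c in ("accession", "group", "stage"):
        scores[c] = dataset.samples[c]
    return scores, var[:k]


def _stage_group_matrix(dataset: AbundanceDataset, stage: str, group: str,
                        eps: float, log_transform: bool):
    sel = dataset.samples.query("stage == @stage and group == @group")
    v = dataset.values.loc[sel.index]
    if log_transform:
        v = np.log10(v + eps)
    return v, sel["accession"].to_numpy()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the result bundle and summary.

    With ``output_dir`` set, all result tables, networks and the JSON summary
    and manifest are written there (subdirectories ``statis``, ``networks``,
    ``dc``, ``biomarkers``, ``report``). Nothing is written if any stage
    fails.
    """
    config.validate()
    seeds = child_seeds(config.seed, 6)

    # --- data -----------------------------------------------------------
    if config.generator is not None:
        gen = GeneratorConfig(**{**config.generator.to_dict(),
                                 "seed": seeds[0]})
        dataset, truth = generate_dataset(gen)
    else:
        dataset = fio.read_abundance_table(
            config.input_path, metabolite_meta=config.metabolite_meta)
        truth = None

    # --- preprocess (network/biomarker branch) --------------------------
    filtered, removal = filter_missing(dataset, config.max_missing_frac)
    imputed, impute_report = impute_bpca(
        filtered, n_components=config.n_components, seed=seeds[1],
        log_transform=config.log_transform)

    # --- STATIS (zero-fill branch, all metabolites) ---------------------
    tables = build_statis_tables(dataset, row_mode=config.row_mode)
    st = statis_analysis(tables)

    # --- global PCA -----------------------------------------------------
    pca_scores, pca_var = global_pca(imputed,
                                     log_transform=config.log_transform)

    # --- stage-wise differential networks -------------------------------
    eps = log_epsilon(imputed.values.to_numpy(float))
    met_class = imputed.metabolites["met_class"].to_numpy()
    networks, dc_tables, chi2_rows, densities = {}, {}, [], {}
    for si, stage in enumerate(STAGES):
        vD, accD = _stage_group_matrix(imputed, stage, "D", eps,
                                       config.log_transform)
        vW, accW = _stage_group_matrix(imputed, stage, "W", eps,
                                       config.log_transform)
        net_D = correlation_network(vD, fdr=config.fdr, group="D", stage=stage)
        net_W = correlation_network(vW, fdr=config.fdr, group="W", stage=stage)
        networks[(stage, "D")], networks[(stage, "W")] = net_D, net_W
        densities[(stage, "D")] = network_density(net_D)
        densities[(stage, "W")] = network_density(net_W)
        dc = differential_connectivity(net_D, net_W)
        _, p_perm, q_perm = dc_permutation_test(
            vD.to_numpy(float), vW.to_numpy(float), accD, accW,
            B=config.permutations, fdr=config.fdr, seed=seeds[2] + si)
        t_stat, p_t, q_t, direction = abundance_tests(
            vD.to_numpy(float), vW.to_numpy(float), fdr=config.fdr,
            log_transform=False)  # already on log scale
        rec = pd.DataFrame({
            "metabolite_id": imputed.metabolite_ids,
            "met_class": met_class,
            "stage": stage,
            "deg_D": net_D.degrees(),
            "deg_W": net_W.degrees(),
            "dc": dc,
            "p_perm": p_perm,
            "q_perm": q_perm,
            "t_stat": t_stat,
            "p_t": p_t,
            "q_t": q_t,
            "abundance_direction": direction,
        })
        rec = classify_quadrants(rec, threshold=config.fdr)
        dc_tables[stage] = rec
        for scope in ("significant_only", "all_nonzero_dc"):
            try:
                chi2, pchi, table = class_association_chi2(
                    met_class, dc, significant=(q_perm < config.fdr),
                    scope=scope)
                chi2_rows.append((stage, scope, chi2, pchi,
                                  *table.to_numpy().ravel()))
            except DegenerateTableError:
                chi2_rows.append((stage, scope, np.nan, np.nan,
                                  *[np.nan] * 4))
    chi2_table = pd.DataFrame(
        chi2_rows, columns=["stage", "scope", "chi2", "p",
                            "primary_gain", "primary_loss",
                            "secondary_gain", "secondary_loss"])

    # --- biomarker screen -----------------------------------------------
    biomarkers = screen_biomarkers(imputed, alpha=config.alpha,
                                   log_transform=config.log_transform)

    # --- summary ---------------------------------------------------------
    n_classes = imputed.metabolites["met_class"].value_counts()
    summary = {
        "n_samples": dataset.n_samples,
        "n_metabolites_input": dataset.n_metabolites,
        "n_metabolites_retained": imputed.n_metabolites,
        "n_primary_retained": int(n_classes.get("primary", 0)),
        "n_secondary_retained": int(n_classes.get("secondary", 0)),
        "imputation": impute_report,
        "densities": {f"{s}_{g}": densities[(s, g)]
                      for s in STAGES for g in ("D", "W")},
        "dc_significant": {
            s: int((dc_tables[s]["q_perm"] < config.fdr).sum())
            for s in STAGES},
        "dc_and_abundance_significant": {
            s: int((dc_tables[s]["quadrant"] != "ns").sum()) for s in STAGES},
        "chi2": {f"{r.stage}_{r.scope}": [r.chi2, r.p]
                 for r in chi2_table.itertuples()},
        "n_biomarkers_significant": int(biomarkers["significant"].sum()),
        "n_biomarkers_significant_raw":
            int(biomarkers["significant_raw"].sum()),
        "biomarkers_by_class": {
            c: int(((biomarkers["met_class"] == c)
                    & biomarkers["significant"]).sum())
            for c in ("primary", "secondary")},
        "statis_alpha": st.alpha.tolist(),
        "statis_accessions": st.accessions,
        "statis_rv": st.rv.tolist(),
        "pca_explained_variance": pca_var.tolist(),
        "seed": config.seed,
    }

    bundle = {
        "dataset": dataset, "truth": truth, "imputed": imputed,
        "removal_report": removal, "statis": st, "tables": tables,
        "networks": networks, "dc_tables": dc_tables,
        "chi2_table": chi2_table, "biomarkers": biomarkers,
        "pca_scores": pca_scores, "summary": summary,
    }

    if config.output_dir is not None:
        _export(bundle, config)
    return bundle


def _export(bundle: dict, config: RunConfig) -> None:
    out = Path(config.output_dir)
    # the config hash covers semantic settings only, not output location
    cfg = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    st = bundle["statis"]
    statis_exports = {
        "rv_matrix": pd.DataFrame(st.rv, index=st.accessions,
                                  columns=st.accessions).reset_index(
                                      names="accession"),
        "alpha": pd.DataFrame({"accession": st.accessions,
                               "alpha": st.alpha,
                               "rv2_to_compromise":
                                   st.table_rv2_to_compromise}),
        "compromise_eigen": pd.DataFrame(
            {"component": np.arange(1, len(st.eigenvalues) + 1),
             "eigenvalue": st.eigenvalues}),
        "table_contributions": pd.DataFrame(
            st.table_projections,
            columns=[f"PC{i + 1}" for i in
                     range(st.table_projections.shape[1])]
        ).assign(accession=st.accessions),
    }
    fio.export_results(statis_exports, out / "statis", seed=config.seed,
                       config=cfg)
    nets = {f"net_{stage}_{grp}": net
            for (stage, grp), net in bundle["networks"].items()}
    fio.export_results(nets, out / "networks", seed=config.seed,
                       config=cfg)
    dc_all = pd.concat(bundle["dc_tables"].values(), ignore_index=True)
    fio.export_results({"dc_results": dc_all,
                        "chi2_summary": bundle["chi2_table"]},
                       out / "dc", seed=config.seed, config=cfg)
    fio.export_results({"biomarkers": bundle["biomarkers"]},
                       out / "biomarkers", seed=config.seed,
                       config=cfg)
    fio.export_results({"summary": bundle["summary"],
                        "pca_scores": bundle["pca_scores"].reset_index(),
                        "removal_report": bundle["removal_report"]},
                       out / "report", seed=config.seed,
                       config=cfg)
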