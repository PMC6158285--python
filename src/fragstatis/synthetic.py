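"""Synthetic strawberry-metabolome generator with planted ground truth.

Emulates the study design the pipeline assumes: 14 accessions (7 domesticated,
7 wild), three ripening stages (G/W/R), three biological replicates, and 130
metabolites (43 primary, 87 secondary). Log10-scale abundances are drawn from
a multivariate normal with group-specific correlation structure and
exponentiated, giving positive, right-skewed (lognormal) intensities.

Planted structure, all recorded in :class:`GroundTruth`:

* **Group-specific co-regulation.** Correlation matrices are unions of
  disjoint equicorrelated cliques ("modules") at ``base_corr`` — positive
  semidefinite by construction. Modules are shared between groups; the wild
  matrix *coarsens* the partition by bounded pairwise merges, so wild
  secondary co-regulation is strictly denser. With equal density targets and
  no hubs the two group matrices are identical (the exchangeable null).
* **Wild-only hub metabolites**, isolated in the domesticated structure. In
  the presence of background modules each hub joins one merged wild module
  at ``hub_corr``; with no background (``hub_mode="dedicated"``) the hubs
  form a wild-only co-regulation program built from an explicit factor
  model: a mutually correlated hub core, one tight partner module of
  ``hub_partner_count`` metabolites per hub, and the minimal cross terms the
  geometry forces (any node correlated at r with k partners drags the
  partners' mutual correlation up to ``(k·r² − 1)/(k − 1)``).
* **Domestication biomarkers**: metabolites shifted between groups by a fixed
  number of residual standard deviations (on log scale).
* **A shared ripening trend** (G→W→R) on a random subset of metabolites.
* **Wild heterogeneity**: wild noise is ``wild_dispersion_scale`` times more
  dispersed for secondary metabolites, and accession-level random offsets
  (stable and accession×stage) are larger for wild accessions. Offsets are
  drawn with the *same* group correlation structure as replicate noise and
  kept a minor variance share, so the planted correlations are empirically
  realized in finite samples.
* **Missingness**: a below-quantile (limit-of-detection-like) plus uniform
  mechanism, with a configurable number of metabolites forced above the 20%
  missingness filter so the filter is exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .datamodel import AbundanceDataset, STAGES

WILD_SPECIES = ("F_vesca", "F_chiloensis", "F_moschata")


class GenerationError(RuntimeError):
    pass


@dataclass
class GeneratorConfig:
    """Study-design and effect-size parameters of the generator.

    Defaults encode the emulated study: 7+7 accessions × 3 stages × 3
    replicates, 43 primary + 87 secondary metabolites, structural density
    targets denser for wild secondary co-regulation, 29 planted domestication
    biomarkers (26 secondary, 3 primary) and 5 wild-only hubs, and 4 primary +
    6 secondary metabolites pushed past the 20% missingness filter.
    """

    n_accessions_D: int = 7
    n_accessions_W: int = 7
    n_stages: int = 3
    n_reps: int = 3
    n_primary: int = 43
    n_secondary: int = 87
    # co-regulation structure
    target_density_D: float = 0.115
    target_density_W: float = 0.288
    base_corr: float = 0.7
    n_planted_hubs: int = 5
    hub_partner_count: int = 8
    hub_corr: float = 0.8
    hub_mode: str = "auto"  # auto | dedicated | module
    # abundance effects (log10 scale; *_sd_units are multiples of residual_sd)
    n_planted_biomarkers_primary: int = 3
    n_planted_biomarkers_secondary: int = 26
    biomarker_effect_sd_units: float = 3.0
    stage_effect_sd_units: float = 1.0
    stage_trend_frac: float = 0.5
    residual_sd: float = 0.2
    accession_sd_D: float = 0.03
    accession_sd_W: float = 0.08
    accession_stage_sd_D: float = 0.02
    accession_stage_sd_W: float = 0.05
    # coherent per-accession×stage activation of secondary metabolism:
    # one scalar shifting all secondary metabolites together
    secondary_response_sd_D: float = 0.03
    secondary_response_sd_W: float = 0.15
    wild_dispersion_scale: float = 3.0
    baseline_mean: float = 3.0
    baseline_sd: float = 0.5
    # missingness
    missing_rate: float = 0.03
    lod_quantile: float = 0.5
    n_high_missing_primary: int = 4
    n_high_missing_secondary: int = 6
    high_missing_rate: float = 0.35
    seed: int = 0

    @property
    def n_planted_biomarkers(self) -> int:
        return self.n_planted_biomarkers_primary + self.n_planted_biomarkers_secondary

    def validate(self) -> None:
        for name in ("n_accessions_D", "n_accessions_W", "n_stages", "n_reps",
                     "n_primary", "n_secondary"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_stages != 3:
            raise ValueError("the study design has exactly 3 ripening stages")
        for name in ("target_density_D", "target_density_W", "missing_rate",
                     "lod_quantile", "high_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("base_corr", "hub_corr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.target_density_W < self.target_density_D:
            raise ValueError("target_density_W must be >= target_density_D "
                             "(wild structure is a coarsening of domesticated)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    seed: int
    hub_ids: list
    hub_partners: dict          # hub id -> list of partner ids
    biomarker_ids: list
    biomarker_signs: dict       # id -> +1 (up in D) / -1 (down in D)
    stage_trend_ids: list
    high_missing_ids: list
    group_corr_specs: dict      # R_D, R_W, achieved densities, module lists


# ---------------------------------------------------------------------------
# correlation-structure construction


def _clique_partition(nodes, target_edges, rng, cap=None):
    """Greedy partition of ``nodes`` into disjoint cliques totalling
    approximately ``target_edges`` edges. Returns a list of cliques (lists);
    unassigned nodes are left out (they stay singletons)."""
    nodes = list(nodes)
    rng.shuffle(nodes)
    m, e_left = len(nodes), int(target_edges)
    if cap is None and m > 0 and e_left > 0:
        cap = max(3, math.ceil(2 * e_left / m) + 2)
    cliques, pos = [], 0
    while e_left >= 1 and m - pos >= 2:
        k_max = int((1 + math.sqrt(1 + 8 * e_left)) // 2)
        k = min(cap, m - pos, k_max)
        if k < 2:
            break
        cliques.append(nodes[pos:pos + k])
        e_left -= k * (k - 1) // 2
        pos += k
    return cliques


def _apply_cliques(R, cliques, corr):
    for cl in cliques:
        ix = np.array(cl)
        block = np.full((len(ix), len(ix)), corr)
        np.fill_diagonal(block, 1.0)
        R[np.ix_(ix, ix)] = block
    return R


def hub_block_partner_corr(k: int, r: float, margin: float = 0.02) -> float:
    """Smallest feasible partner-partner correlation (plus a PSD margin) for a
    block in which one hub correlates at ``r`` with ``k`` partners.

    Any correlation matrix with one node at correlation ``r`` to ``k``
    partners forces the partners' average mutual correlation up to
    ``(k·r² − 1)/(k − 1)`` (a Gram-matrix constraint): strongly connected
    hubs necessarily drag their partners into co-regulation.
    """
    if k < 2:
        return 0.0
    return min(0.97, max(0.0, (k * r * r - 1.0) / (k - 1.0)) + margin)


def _apply_hub_program(R, hubs, hub_partners, r, module_corr_boost=0.26):
    """Wild-only co-regulation program built from an explicit factor model.

    The hubs form a mutually correlated core (hub–hub = r) around a global
    factor g (h_i = √r·g + √(1−r)·e_i); each hub correlates at r with its
    own partner module, whose internal correlation sits well above the Gram
    floor (a tight pathway module). Writing a partner as
    p = s·g + t·e_i + w·u with s = √r·r − √(1−r)·√(ρ_w − r²) (the smaller
    root, minimizing global loading), every remaining entry follows:
    cross-module partners s_i·s_j, hub_j–partner_i s_i·√r. The construction
    is a Gram matrix, hence positive semidefinite, and hubs carry strictly
    the highest connectivity in the block.
    """
    act = [h for h in hubs if hub_partners[h]]
    if not act:
        return R
    A, Bc = math.sqrt(r), math.sqrt(1.0 - r)
    s_of, rho_of = {}, {}
    for h in act:
        k = len(hub_partners[h])
        rho = min(0.95, max(hub_block_partner_corr(k, r),
                            r * r + module_corr_boost))
        rho_of[h] = rho
        s_of[h] = A * r - Bc * math.sqrt(max(rho - r * r, 0.0))
    # cross-module partner blocks
    for i, h1 in enumerate(act):
        for h2 in act[i + 1:]:
            ix1, ix2 = np.array(hub_partners[h1]), np.array(hub_partners[h2])
            R[np.ix_(ix1, ix2)] = s_of[h1] * s_of[h2]
            R[np.ix_(ix2, ix1)] = s_of[h1] * s_of[h2]
    # within-module blocks and hub rows
    for h in act:
        _apply_cliques(R, [hub_partners[h]], rho_of[h])
        own = np.array(hub_partners[h])
        for h2 in act:
            val = r if h2 == h else s_of[h] * A
            R[h2, own] = val
            R[own, h2] = val
    ix_h = np.array(act)
    hub_block = np.full((len(ix_h), len(ix_h)), r)
    np.fill_diagonal(hub_block, 1.0)
    R[np.ix_(ix_h, ix_h)] = hub_block
    np.fill_diagonal(R, 1.0)
    return R


def sample_group_covariance(n_met: int, target_density: float,
                            base_corr: float, seed: int,
                            max_retries: int = 10) -> np.ndarray:
    """Random correlation matrix with ~``target_density`` co-regulated pairs.

    Off-diagonal support is a union of disjoint equicorrelated cliques placed
    on randomly chosen metabolites, which is positive semidefinite by
    construction for any ``base_corr`` in (0, 1). ``target_density`` is the
    fraction of metabolite pairs carrying a non-zero correlation.
    """
    if n_met < 2:
        raise ValueError("n_met must be >= 2")
    if not 0.0 <= target_density <= 1.0:
        raise ValueError("target_density must be in [0, 1]")
    if not 0.0 < base_corr < 1.0:
        raise ValueError("base_corr must be in (0, 1)")
    rng = np.random.default_rng(seed)
    total_pairs = n_met * (n_met - 1) // 2
    target_edges = round(target_density * total_pairs)
    for _ in range(max_retries):
        R = np.eye(n_met)
        cliques = _clique_partition(range(n_met), target_edges, rng)
        _apply_cliques(R, cliques, base_corr)
        if np.linalg.eigvalsh(R)[0] >= -1e-10:
            return R
    raise GenerationError("could not construct a PSD correlation matrix")


def _merge_for_density(cliques, singletons, extra_edges, rng, max_size=None):
    """Coarsen a clique partition by pairwise merges (largest first, merged
    size capped) until roughly ``extra_edges`` additional edges are created;
    leftover singletons are absorbed last. Returns the new partition."""
    groups = sorted([list(c) for c in cliques], key=len, reverse=True)
    free_singles = [[s] for s in singletons]
    e_left = int(extra_edges)
    if max_size is None:
        max_size = max((len(g) for g in groups), default=2) * 2 + 2
    merged = True
    while e_left > 0 and merged and len(groups) > 1:
        merged = False
        groups.sort(key=len, reverse=True)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                cost = len(groups[i]) * len(groups[j])
                size = len(groups[i]) + len(groups[j])
                if cost <= e_left and size <= max_size:
                    groups[i].extend(groups.pop(j))
                    e_left -= cost
                    merged = True
                    break
            if merged:
                break
    # absorb singletons into existing groups while budget remains
    for s in free_singles:
        placed = False
        if e_left > 0:
            for g in sorted(groups, key=len, reverse=True):
                if len(g) <= e_left and len(g) + 1 <= max_size:
                    g.extend(s)
                    e_left -= len(g) - 1
                    placed = True
                    break
        if not placed:
            groups.append(s)
    return [g for g in groups if len(g) >= 2]


def _build_group_structures(cfg: GeneratorConfig, rng):
    """Build R_D and R_W (p × p) plus the planted-structure bookkeeping.

    Shared modules (equicorrelated cliques at ``base_corr``) appear in both
    groups; the wild matrix coarsens that partition by bounded pairwise
    merges and additionally attaches each hub metabolite — a singleton in the
    domesticated structure — to one wild module at ``hub_corr``. With no
    shared modules (zero domesticated density target) hubs instead get
    dedicated one-factor blocks with exactly ``hub_partner_count`` partners,
    a purely wild-only structure.
    """
    p = cfg.n_primary + cfg.n_secondary
    pri = list(range(cfg.n_primary))
    sec = list(range(cfg.n_primary, p))
    sec_pairs = len(sec) * (len(sec) - 1) // 2 if len(sec) > 1 else 1

    # hubs are reserved first: isolated in D, connected in W
    hubs = [int(h) for h in
            rng.choice(sec, size=cfg.n_planted_hubs, replace=False)]
    free_sec = [s for s in sec if s not in set(hubs)]

    sec_target = round(cfg.target_density_D * sec_pairs)
    if cfg.hub_mode == "auto":
        dedicated = cfg.n_planted_hubs > 0 and sec_target == 0
    else:
        dedicated = cfg.hub_mode == "dedicated" and cfg.n_planted_hubs > 0

    hub_partners = {}
    if dedicated:
        # dedicated wild-only one-factor hub blocks, reserved before any
        # background modules so each hub has exactly hub_partner_count
        # partners
        need = cfg.n_planted_hubs * cfg.hub_partner_count
        if need > len(free_sec):
            raise GenerationError("hub blocks need more secondary "
                                  "metabolites than available")
        pool = list(rng.choice(free_sec, size=need, replace=False))
        for i, h in enumerate(hubs):
            hub_partners[h] = pool[i * cfg.hub_partner_count:
                                   (i + 1) * cfg.hub_partner_count]
        free_sec = [s for s in free_sec if s not in set(pool)]

    # shared co-regulation modules (identical in both groups)
    pri_pairs = len(pri) * (len(pri) - 1) // 2
    pri_cliques = _clique_partition(
        pri, round(cfg.target_density_D * pri_pairs), rng)
    sec_cliques = _clique_partition(free_sec, sec_target, rng)
    shared_edges = sum(len(c) * (len(c) - 1) // 2 for c in sec_cliques)

    if dedicated:
        w_sec_cliques = list(sec_cliques)
    else:
        # coarsen the shared partition for the wild group
        w_target = (round(cfg.target_density_W * sec_pairs) - shared_edges
                    - cfg.n_planted_hubs * 2 * cfg.hub_partner_count)
        in_cliques = {n for c in sec_cliques for n in c}
        singles = [s for s in free_sec if s not in in_cliques]
        w_sec_cliques = _merge_for_density(sec_cliques, singles,
                                           max(0, w_target), rng)
        # each hub joins one wild module (largest modules first)
        for h, grp in zip(hubs, sorted(w_sec_cliques, key=len, reverse=True)):
            hub_partners[h] = list(grp)
        for h in hubs[len(w_sec_cliques):]:
            hub_partners[h] = []
    hub_edges = sum(len(v) for v in hub_partners.values())
    if dedicated:
        hub_edges += sum(len(v) * (len(v) - 1) // 2
                         for v in hub_partners.values())
    w_extra_edges = (sum(len(c) * (len(c) - 1) // 2 for c in w_sec_cliques)
                     - shared_edges)

    R_D = _apply_cliques(np.eye(p), pri_cliques + sec_cliques, cfg.base_corr)
    R_W = _apply_cliques(np.eye(p), pri_cliques + w_sec_cliques, cfg.base_corr)
    if dedicated and hubs:
        _apply_hub_program(R_W, hubs, hub_partners, cfg.hub_corr)
    else:
        for h in hubs:
            if not hub_partners[h]:
                continue
            ix = np.array(hub_partners[h])
            R_W[h, ix] = cfg.hub_corr
            R_W[ix, h] = cfg.hub_corr

    for name, R in (("D", R_D), ("W", R_W)):
        if np.linalg.eigvalsh(R)[0] < -1e-8:
            raise GenerationError(f"group {name} correlation matrix not PSD")

    dens = {
        "achieved_density_sec_D": shared_edges / sec_pairs,
        "achieved_density_sec_W": (shared_edges + hub_edges + w_extra_edges)
                                   / sec_pairs,
    }
    return R_D, R_W, hubs, hub_partners, dens


# ---------------------------------------------------------------------------
# dataset generation


def _round_sig(values: np.ndarray, digits: int = 12) -> np.ndarray:
    """Round to ``digits`` significant figures via decimal formatting (the
    on-disk precision), so write→read round-trips are bit-exact."""
    fmt = np.vectorize(lambda v: float(f"{v:.{digits}g}")
                       if np.isfinite(v) else v)
    return fmt(values).astype(float)


def generate_dataset(config: GeneratorConfig):
    """Draw one synthetic dataset; returns ``(AbundanceDataset, GroundTruth)``.

    Sample count is (n_D + n_W) × n_stages × n_reps; identical seeds give
    bit-identical datasets.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p = cfg.n_primary + cfg.n_secondary

    met_ids = ([f"pri_{i + 1:03d}" for i in range(cfg.n_primary)]
               + [f"sec_{i + 1:03d}" for i in range(cfg.n_secondary)])
    met_class = (["primary"] * cfg.n_primary + ["secondary"] * cfg.n_secondary)

    R_D, R_W, hub_ix, partner_ix, dens = _build_group_structures(cfg, rng)
    L = {"D": np.linalg.cholesky(R_D + 1e-10 * np.eye(p)),
         "W": np.linalg.cholesky(R_W + 1e-10 * np.eye(p))}

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=p)

    # shared ripening trend on a random subset, excluding hub-block members
    hub_members = set(hub_ix) | {q for v in partner_ix.values() for q in v}
    trend_pool = [j for j in range(p) if j not in hub_members]
    n_trend = round(cfg.stage_trend_frac * p)
    trend_ix = sorted(rng.choice(trend_pool, size=min(n_trend, len(trend_pool)),
                                 replace=False))
    slopes = np.zeros(p)
    slopes[trend_ix] = rng.normal(
        0.0, cfg.stage_effect_sd_units * cfg.residual_sd, size=len(trend_ix))

    # planted biomarkers (group mean shift), split by class as configured
    bio_pri = list(rng.choice(cfg.n_primary,
                              size=min(cfg.n_planted_biomarkers_primary,
                                       cfg.n_primary), replace=False))
    bio_sec = list(cfg.n_primary + rng.choice(
        cfg.n_secondary, size=min(cfg.n_planted_biomarkers_secondary,
                                  cfg.n_secondary), replace=False))
    bio_ix = sorted(int(j) for j in bio_pri + bio_sec)
    bio_sign = {j: int(s) for j, s in
                zip(bio_ix, rng.choice([-1, 1], size=len(bio_ix)))}
    shift = np.zeros(p)
    for j in bio_ix:
        shift[j] = bio_sign[j] * cfg.biomarker_effect_sd_units * cfg.residual_sd

    accessions = ([(f"D{i + 1:02d}", "D") for i in range(cfg.n_accessions_D)]
                  + [(f"W{i + 1:02d}", "W") for i in range(cfg.n_accessions_W)])
    species = {}
    for i, (acc, grp) in enumerate(accessions):
        species[acc] = ("F_ananassa" if grp == "D"
                        else WILD_SPECIES[i % len(WILD_SPECIES)])

    acc_sd = {"D": cfg.accession_sd_D, "W": cfg.accession_sd_W}
    acc_stage_sd = {"D": cfg.accession_stage_sd_D, "W": cfg.accession_stage_sd_W}
    stage_x = {s: x for s, x in zip(STAGES, (-1.0, 0.0, 1.0))}
    # wild secondary metabolism is far more dispersed than domesticated:
    # scale every wild noise layer for secondary metabolites
    disp = {"D": np.ones(p),
            "W": np.concatenate([np.ones(cfg.n_primary),
                                 np.full(cfg.n_secondary,
                                         cfg.wild_dispersion_scale)])}

    resp_sd = {"D": cfg.secondary_response_sd_D,
               "W": cfg.secondary_response_sd_W}
    sec_mask = np.concatenate([np.zeros(cfg.n_primary),
                               np.ones(cfg.n_secondary)])

    rows, meta_rows = [], []
    for acc, grp in accessions:
        stable = acc_sd[grp] * disp[grp] * (L[grp] @ rng.standard_normal(p))
        for stage in STAGES:
            interact = (acc_stage_sd[grp] * disp[grp]
                        * (L[grp] @ rng.standard_normal(p)))
            interact = interact + (resp_sd[grp] * rng.standard_normal()
                                   * sec_mask)
            for rep in range(1, cfg.n_reps + 1):
                resid = (cfg.residual_sd * disp[grp]
                         * (L[grp] @ rng.standard_normal(p)))
                logv = (baseline + slopes * stage_x[stage]
                        + (0.5 if grp == "D" else -0.5) * shift
                        + stable + interact + resid)
                rows.append(10.0 ** logv)
                meta_rows.append((f"{acc}_{stage}_{rep}", acc, grp,
                                  species[acc], stage, rep))

    values = _round_sig(np.asarray(rows))
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "accession", "group", "species",
                            "stage", "replicate"]).set_index("sample_id")
    metabolites = pd.DataFrame(
        {"met_class": met_class, "annotation": ["synthetic"] * p},
        index=pd.Index(met_ids, name="metabolite_id"))
    dataset = AbundanceDataset(
        samples, metabolites,
        pd.DataFrame(values, index=samples.index, columns=metabolites.index))

    # forced high-missingness metabolites: avoid planted hubs and biomarkers
    # (module partners stay eligible; losing one thins a module slightly)
    protected = set(hub_ix) | set(bio_ix)
    hm_pri = [j for j in range(cfg.n_primary) if j not in protected]
    hm_sec = [j for j in range(cfg.n_primary, p) if j not in protected]
    high_ix = (list(rng.choice(hm_pri, size=min(cfg.n_high_missing_primary,
                                                len(hm_pri)), replace=False))
               + list(rng.choice(hm_sec, size=min(cfg.n_high_missing_secondary,
                                                  len(hm_sec)), replace=False)))
    high_ids = [met_ids[int(j)] for j in high_ix]

    miss_seed = int(rng.integers(2 ** 31))
    dataset = inject_missingness(dataset, cfg.missing_rate, cfg.lod_quantile,
                                 miss_seed, force_high_ids=high_ids,
                                 force_high_rate=cfg.high_missing_rate)

    truth = GroundTruth(
        seed=cfg.seed,
        hub_ids=[met_ids[h] for h in hub_ix],
        hub_partners={met_ids[h]: [met_ids[q] for q in partner_ix[h]]
                      for h in hub_ix},
        biomarker_ids=[met_ids[j] for j in bio_ix],
        biomarker_signs={met_ids[j]: bio_sign[j] for j in bio_ix},
        stage_trend_ids=[met_ids[int(j)] for j in trend_ix],
        high_missing_ids=high_ids,
        group_corr_specs={"R_D": R_D, "R_W": R_W, **dens},
    )
    return dataset, truth


def inject_missingness(dataset: AbundanceDataset, missing_rate: float,
                       lod_quantile: float, seed: int,
                       force_high_ids=(), force_high_rate: float = 0.35
                       ) -> AbundanceDataset:
    """Mark cells missing (NaN).

    A fraction ``lod_quantile`` of the planted missing cells is drawn from the
    low-abundance pool (below each metabolite's 25% quantile — a limit-of-
    detection mechanism); the rest are uniform at random. The total planted
    count is ``round(missing_rate × eligible cells)``. Metabolites listed in
    ``force_high_ids`` additionally lose ``force_high_rate`` of their cells,
    pushing them past the downstream 20% missingness filter.
    """
    if not 0.0 <= missing_rate <= 1.0 or not 0.0 <= lod_quantile <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    ds = dataset.copy()
    rng = np.random.default_rng(seed)
    vals = ds.values.to_numpy(float)
    n, p = vals.shape
    col_of = {m: j for j, m in enumerate(ds.metabolite_ids)}

    for m in force_high_ids:
        j = col_of[m]
        k = round(force_high_rate * n)
        ix = rng.choice(n, size=k, replace=False)
        vals[ix, j] = np.nan

    forced = {col_of[m] for m in force_high_ids}
    elig_cols = np.array([j for j in range(p) if j not in forced], dtype=int)
    if missing_rate > 0 and elig_cols.size:
        sub = vals[:, elig_cols]
        observed = np.flatnonzero(~np.isnan(sub).ravel())
        n_plant = round(missing_rate * sub.size)
        n_plant = min(n_plant, observed.size)
        with np.errstate(invalid="ignore"):
            q25 = np.nanquantile(sub, 0.25, axis=0)
        low_mask = (sub <= q25).ravel()
        low_pool = observed[low_mask[observed]]
        n_lod = min(round(lod_quantile * n_plant), low_pool.size)
        chosen = set(rng.choice(low_pool, size=n_lod, replace=False).tolist())
        rest_pool = np.array([c for c in observed if c not in chosen])
        n_rest = n_plant - len(chosen)
        if n_rest > 0:
            chosen |= set(rng.choice(rest_pool, size=n_rest,
                                     replace=False).tolist())
        flat_ix = np.array(sorted(chosen), dtype=int)
        rows_ix, cols_ix = np.unravel_index(flat_ix, sub.shape)
        vals[rows_ix, elig_cols[cols_ix]] = np.nan

    ds.values.iloc[:, :] = vals
    return ds
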