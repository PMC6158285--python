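#!/usr/bin/env python
"""Stage-wise differential correlation-network analysis.

For each ripening stage, builds the domesticated (D) and wild (W) networks
from FDR-thresholded Pearson correlations (21 samples per group), compares
their densities, computes each metabolite's differential connectivity
DC = deg_D/max_D − deg_W/max_W, tests it against a 1,000-permutation
accession-relabeling null, runs Welch t-tests on abundance, classifies
metabolites significant on both axes into quadrants, and tests the
primary/secondary × gain/loss association with a Yates-corrected χ².
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fragstatis import io as fio
from fragstatis.datamodel import STAGES
from fragstatis.diffnet import (abundance_tests, class_association_chi2,
                                classify_quadrants, correlation_network,
                                dc_permutation_test,
                                differential_connectivity, network_density,
                                DegenerateTableError)
from fragstatis.preprocess import log_epsilon

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
B = 1000


def main():
    ds = fio.read_abundance_table(OUT / "imputed.tsv",
                                  metabolite_meta=OUT / "metabolites.tsv")
    eps = log_epsilon(ds.values.to_numpy(float))
    met_class = ds.metabolites["met_class"].to_numpy()
    nets, tables, chi2_rows = {}, [], []
    for si, stage in enumerate(STAGES):
        mats, accs = {}, {}
        for grp in ("D", "W"):
            sel = ds.samples.query("stage == @stage and group == @grp")
            mats[grp] = np.log10(ds.values.loc[sel.index] + eps)
            accs[grp] = sel["accession"].to_numpy()
        net_d = correlation_network(mats["D"], group="D", stage=stage)
        net_w = correlation_network(mats["W"], group="W", stage=stage)
        nets[f"net_{stage}_D"], nets[f"net_{stage}_W"] = net_d, net_w
        dc = differential_connectivity(net_d, net_w)
        _, p_perm, q_perm = dc_permutation_test(
            mats["D"].to_numpy(), mats["W"].to_numpy(), accs["D"], accs["W"],
            B=B, seed=100 + si)
        t, p_t, q_t, direction = abundance_tests(
            mats["D"].to_numpy(), mats["W"].to_numpy(), log_transform=False)
        rec = classify_quadrants(pd.DataFrame({
            "metabolite_id": ds.metabolite_ids, "met_class": met_class,
            "stage": stage, "deg_D": net_d.degrees(),
            "deg_W": net_w.degrees(), "dc": dc, "p_perm": p_perm,
            "q_perm": q_perm, "t_stat": t, "q_t": q_t,
            "abundance_direction": direction}))
        tables.append(rec)
        try:
            chi2, pchi, _ = class_association_chi2(
                met_class, dc, scope="all_nonzero_dc")
        except DegenerateTableError:
            chi2, pchi = np.nan, np.nan
        chi2_rows.append((stage, chi2, pchi))
        n_both = int((rec["quadrant"] != "ns").sum())
        print(f"stage {stage}: density D={network_density(net_d):.3f} "
              f"W={network_density(net_w):.3f}; "
              f"DC significant={int((q_perm < 0.05).sum())}; "
              f"both metrics significant={n_both}; "
              f"chi2(class×gain/loss)={chi2:.2f} (P={pchi:.3f})")
    dc_all = pd.concat(tables, ignore_index=True)
    fio.export_results(
        {**nets, "dc_results": dc_all,
         "chi2_summary": pd.DataFrame(chi2_rows,
                                      columns=["stage", "chi2", "p"])},
        OUT / "networks", seed=17)


if __name__ == "__main__":
    main()
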