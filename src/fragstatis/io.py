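"""Reading and writing of abundance tables, result tables, and networks.

Canonical on-disk layout is the *wide* table: one row per sample, reserved
metadata columns ``sample_id, accession, group, species, stage, replicate``,
then one column per metabolite. A *long* table with columns
``sample_id, metabolite_id, value`` is converted on read. Metabolite classes
ride along in a sidecar table (``metabolite_id, met_class, annotation``); when
absent, ids prefixed ``sec`` are classed secondary and everything else primary
(the convention used by the synthetic generator).

All numeric output is written with 12 significant digits and a fixed column
order so that repeated exports of the same results are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import (MET_META_COLS, SAMPLE_META_COLS, AbundanceDataset,
                        SchemaError)

FLOAT_FMT = "%.12g"


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def infer_met_class(metabolite_id: str) -> str:
    return "secondary" if str(metabolite_id).startswith("sec") else "primary"


def read_abundance_table(path, format_hint: str = "auto",
                         metabolite_meta=None, sample_meta=None) -> AbundanceDataset:
    """Read a wide or long abundance table into an :class:`AbundanceDataset`.

    Parameters
    ----------
    path
        CSV/TSV file (separator inferred from the extension).
    format_hint
        ``"wide"``, ``"long"`` or ``"auto"`` (detect from the header).
    metabolite_meta
        Optional path to a metabolite metadata table
        (``metabolite_id, met_class, annotation``).
    sample_meta
        Path to a sample metadata table (``sample_id`` + the reserved
        metadata columns); required for long input, ignored for wide input
        (whose metadata travel in the reserved columns).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    cols = list(df.columns)
    if format_hint == "auto":
        if set(cols) == {"sample_id", "metabolite_id", "value"}:
            format_hint = "long"
        elif "sample_id" in cols and "accession" in cols:
            format_hint = "wide"
        else:
            raise SchemaError(
                f"cannot infer table format from header {cols[:8]}")
    if format_hint == "long":
        required = {"sample_id", "metabolite_id", "value"}
        if not required <= set(cols):
            raise SchemaError(f"long table must have columns {sorted(required)}")
        if sample_meta is None:
            raise SchemaError("long format requires a sample_meta sidecar table")
        if df.duplicated(["sample_id", "metabolite_id"]).any():
            raise SchemaError("duplicate (sample_id, metabolite_id) pair")
        wide = df.pivot_table(index="sample_id", columns="metabolite_id",
                              values="value", aggfunc="first", sort=False)
        sm = pd.read_csv(Path(sample_meta), sep=_sep_for(Path(sample_meta)),
                         dtype={"sample_id": str})
        if sm["sample_id"].duplicated().any():
            raise SchemaError("duplicate sample_id in sample metadata")
        df = sm.merge(wide.reset_index(), on="sample_id", how="inner")
        cols = list(df.columns)
    # wide
    missing = [c for c in ["sample_id"] + SAMPLE_META_COLS if c not in cols]
    if missing:
        raise SchemaError(f"wide table missing metadata columns {missing}")
    if len(df) == 0:
        raise SchemaError("table has a header but no samples")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"duplicate sample_id: {dup}")
    met_cols = [c for c in cols if c not in ["sample_id"] + SAMPLE_META_COLS]
    samples = df.set_index("sample_id")[SAMPLE_META_COLS].copy()
    samples["replicate"] = samples["replicate"].astype(int)
    values = df.set_index("sample_id")[met_cols].astype(float)
    arr = values.to_numpy()
    if arr.size and not np.isnan(arr).all():
        if np.nanmin(arr) < 0:
            raise ValueError("negative abundance in input table")
    if metabolite_meta is not None:
        mm = pd.read_csv(Path(metabolite_meta), sep=_sep_for(Path(metabolite_meta)))
        mm = mm.set_index("metabolite_id")
        if "annotation" not in mm.columns:
            mm["annotation"] = ""
        mm["annotation"] = mm["annotation"].fillna("")
        metabolites = mm.loc[met_cols, MET_META_COLS].copy()
    else:
        metabolites = pd.DataFrame(
            {"met_class": [infer_met_class(c) for c in met_cols],
             "annotation": ["" for _ in met_cols]},
            index=pd.Index(met_cols, name="metabolite_id"),
        )
    return AbundanceDataset(samples, metabolites, values)


def write_abundance_table(dataset: AbundanceDataset, path,
                          metabolite_meta_path=None) -> None:
    """Write the dataset as a canonical wide table (NaN → empty cell)."""
    path = Path(path)
    out = pd.concat([dataset.samples[SAMPLE_META_COLS], dataset.values],
                    axis=1)
    out.index.name = "sample_id"
    out.reset_index().to_csv(path, sep=_sep_for(path), index=False,
                             float_format=FLOAT_FMT, na_rep="")
    if metabolite_meta_path is not None:
        mm = dataset.metabolites[MET_META_COLS].copy()
        mm.index.name = "metabolite_id"
        mm.reset_index().to_csv(Path(metabolite_meta_path),
                                sep=_sep_for(Path(metabolite_meta_path)),
                                index=False)


# ---------------------------------------------------------------------------
# result export


def network_to_graphml(net, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for (a, b), r, q in net.edge_records():
        g.add_edge(a, b, r=float(r), q=float(q))
    nx.write_graphml(g, path)


def network_edge_table(net) -> pd.DataFrame:
    rows = [(a, b, r, p, q) for (a, b), r, q, p in net.edge_records(with_p=True)]
    return pd.DataFrame(rows, columns=["source", "target", "r", "p", "q"])


def write_table(df: pd.DataFrame, path) -> None:
    """Deterministic TSV writer: fixed column order, 12 significant digits."""
    df.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FMT)


def config_hash(config) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def export_results(bundle: dict, out_dir, seed=None, config=None) -> dict:
    """Write a result collection and return the manifest (also written).

    ``bundle`` maps names to exportable objects: DataFrames become TSV files,
    dicts/lists become JSON, and correlation networks are written both as
    GraphML and as TSV edge lists. The manifest records the seed, a config
    hash, and every file written; it carries no timestamps so repeated
    exports of identical results are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(bundle):
        obj = bundle[name]
        if isinstance(obj, pd.DataFrame):
            fn = out_dir / f"{name}.tsv"
            write_table(obj, fn)
            written.append(fn.name)
        elif hasattr(obj, "edge_records"):  # CorrelationNetwork
            fn = out_dir / f"{name}.graphml"
            network_to_graphml(obj, fn)
            written.append(fn.name)
            fn2 = out_dir / f"{name}_edges.tsv"
            write_table(network_edge_table(obj), fn2)
            written.append(fn2.name)
        else:
            fn = out_dir / f"{name}.json"
            fn.write_text(json.dumps(obj, sort_keys=True, indent=1,
                                     default=_json_default) + "\n")
            written.append(fn.name)
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "files": sorted(written),
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    manifest["files"] = sorted(written + ["run_manifest.json"])
    return manifest


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
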