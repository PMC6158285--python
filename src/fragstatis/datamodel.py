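"""Core data model for sample × metabolite relative-abundance datasets.

The pipeline's universal input is an :class:`AbundanceDataset`: a samples ×
metabolites matrix of non-negative relative abundances together with sample
metadata (accession, domestication group, species, ripening stage, replicate)
and metabolite metadata (primary/secondary class, annotation).

Missing measurements are encoded as NaN. A literal 0 is a *measured* abundance
(an undetected-but-quantified metabolite), distinct from a missing cell; the
two are treated differently downstream (zero-fill for the multi-table STATIS
analysis vs filtering/imputation for the network analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("D", "W")
STAGES = ("G", "W", "R")  # green, white, red (ripe)
MET_CLASSES = ("primary", "secondary")

#: Reserved metadata columns of the canonical wide table, in canonical order.
SAMPLE_META_COLS = ["accession", "group", "species", "stage", "replicate"]
MET_META_COLS = ["met_class", "annotation"]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample (one biological replicate pool)."""

    sample_id: str
    accession: str
    group: str
    species: str
    stage: str
    replicate: int

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if int(self.replicate) <= 0:
            raise ValueError("replicate must be a positive integer")


@dataclass(frozen=True)
class MetaboliteMeta:
    """Metadata for one metabolite."""

    metabolite_id: str
    met_class: str
    annotation: str = ""

    def __post_init__(self):
        if self.met_class not in MET_CLASSES:
            raise ValueError(
                f"met_class must be one of {MET_CLASSES}, got {self.met_class!r}"
            )


class AbundanceDataset:
    """Samples × metabolites relative-abundance matrix with metadata.

    Parameters
    ----------
    samples
        DataFrame indexed by ``sample_id`` with columns
        ``accession, group, species, stage, replicate``.
    metabolites
        DataFrame indexed by ``metabolite_id`` with columns
        ``met_class, annotation``.
    values
        DataFrame of non-negative floats (NaN = missing) whose index equals
        ``samples.index`` and whose columns equal ``metabolites.index``.
    """

    def __init__(self, samples: pd.DataFrame, metabolites: pd.DataFrame,
                 values: pd.DataFrame):
        self.samples = samples
        self.metabolites = metabolites
        self.values = values
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        s, m, v = self.samples, self.metabolites, self.values
        if len(s) == 0:
            raise SchemaError("dataset has no samples")
        if not s.index.is_unique:
            dup = s.index[s.index.duplicated()].tolist()
            raise SchemaError(f"duplicate sample_id: {dup}")
        if not m.index.is_unique:
            dup = m.index[m.index.duplicated()].tolist()
            raise SchemaError(f"duplicate metabolite_id: {dup}")
        for col in SAMPLE_META_COLS:
            if col not in s.columns:
                raise SchemaError(f"sample metadata missing column {col!r}")
        for col in ["met_class"]:
            if col not in m.columns:
                raise SchemaError(f"metabolite metadata missing column {col!r}")
        bad = set(s["group"]) - set(GROUPS)
        if bad:
            raise SchemaError(f"unknown group labels: {sorted(bad)}")
        bad = set(s["stage"]) - set(STAGES)
        if bad:
            raise SchemaError(f"unknown stage labels: {sorted(bad)}")
        bad = set(m["met_class"]) - set(MET_CLASSES)
        if bad:
            raise SchemaError(f"unknown met_class labels: {sorted(bad)}")
        if (pd.to_numeric(s["replicate"]) <= 0).any():
            raise SchemaError("replicate must be positive")
        # group constant within accession
        ngrp = s.groupby("accession")["group"].nunique()
        if (ngrp > 1).any():
            raise SchemaError(
                f"group not constant within accession: {ngrp[ngrp > 1].index.tolist()}"
            )
        if v.shape != (len(s), len(m)):
            raise SchemaError(
                f"values shape {v.shape} does not match metadata "
                f"({len(s)} samples × {len(m)} metabolites)"
            )
        if not v.index.equals(s.index) or not v.columns.equals(m.index):
            raise SchemaError("values index/columns do not match metadata")
        arr = v.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("abundances must be finite or missing (NaN)")
        if arr.size and not np.isnan(arr).all():
            with np.errstate(invalid="ignore"):
                if np.nanmin(arr) < 0:
                    raise ValueError("negative abundance encountered")

    # -- convenience -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def sample_ids(self) -> list:
        return self.samples.index.tolist()

    @property
    def metabolite_ids(self) -> list:
        return self.metabolites.index.tolist()

    def missing_fraction(self) -> pd.Series:
        """Per-metabolite fraction of missing (NaN) cells."""
        return self.values.isna().mean(axis=0)

    def subset_metabolites(self, keep) -> "AbundanceDataset":
        keep = list(keep)
        return AbundanceDataset(
            self.samples.copy(), self.metabolites.loc[keep].copy(),
            self.values[keep].copy(),
        )

    def subset_samples(self, keep) -> "AbundanceDataset":
        keep = list(keep)
        return AbundanceDataset(
            self.samples.loc[keep].copy(), self.metabolites.copy(),
            self.values.loc[keep].copy(),
        )

    def copy(self) -> "AbundanceDataset":
        return AbundanceDataset(
            self.samples.copy(), self.metabolites.copy(), self.values.copy()
        )

    def equals(self, other: "AbundanceDataset") -> bool:
        """Field-by-field equality (NaN == NaN in the value matrix)."""
        return (
            self.samples.index.equals(other.samples.index)
            and self.metabolites.index.equals(other.metabolites.index)
            and self.samples[SAMPLE_META_COLS].astype(str).equals(
                other.samples[SAMPLE_META_COLS].astype(str))
            and self.metabolites["met_class"].equals(other.metabolites["met_class"])
            and np.array_equal(
                self.values.to_numpy(float), other.values.to_numpy(float),
                equal_nan=True,
            )
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"AbundanceDataset({self.n_samples} samples × "
                f"{self.n_metabolites} metabolites, "
                f"{self.values.isna().to_numpy().sum()} missing cells)")
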