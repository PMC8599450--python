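"""Reading, validation and pooling of bulk TCR-seq clone tables.

A *repertoire* is the clone table of one sequencing sample: one row per
TCR clonotype with its UMI-corrected molecule count.  Two input dialects
are supported:

``airr``
    AIRR Rearrangement TSV using the standard column names
    ``junction_aa``, ``v_call``, ``j_call``, ``duplicate_count`` and,
    when available, the nucleotide ``junction``.

``simple_tsv``
    A minimal four/five-column TSV with ``cdr3_aa``, ``v_call``,
    ``j_call``, ``umi_count`` (and optionally ``junction``).

Clone identity is configurable (``key_mode``): by default the key is
(v_call, j_call, nucleotide junction) when a nucleotide junction is
present and (v_call, j_call, cdr3_aa) otherwise.  Keying purely on the
CDR3 amino-acid sequence is available for cross-sample comparisons that
should ignore V/J assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIMEPOINTS = ("pre", "post")
COMPARTMENTS = ("tumor", "pbmc")

#: region_id sentinel assigned to pooled (multi-region) repertoires
POOLED_REGION = "pooled"

KEY_MODES = ("auto", "vj_junction", "vj_cdr3aa", "cdr3_aa")

_AIRR_REQUIRED = ("junction_aa", "duplicate_count", "v_call", "j_call")
_SIMPLE_REQUIRED = ("cdr3_aa", "v_call", "j_call", "umi_count")


class FormatError(ValueError):
    """A required column is missing or a value is malformed."""


class EmptyInputError(ValueError):
    """No usable clone rows survived filtering."""


class MetadataError(ValueError):
    """Sample metadata is inconsistent with the requested operation."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequencing sample.

    ``region_id`` distinguishes multi-region samples of the same tumour;
    pooled repertoires carry the sentinel :data:`POOLED_REGION`.
    """

    patient_id: str
    timepoint: str
    compartment: str = "tumor"
    region_id: str = "R1"

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise MetadataError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        if self.compartment not in COMPARTMENTS:
            raise MetadataError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )


@dataclass
class Repertoire:
    """One sample's clone table with derived abundances.

    ``table`` has columns ``clone_key``, ``cdr3_aa``, ``v_call``,
    ``j_call``, ``umi_count`` (plus ``junction`` when known), sorted by
    ``clone_key`` for reproducible downstream vector math.
    """

    meta: SampleMeta
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"clone_key", "cdr3_aa", "umi_count"} - set(self.table.columns)
        if missing:
            raise FormatError(f"repertoire table missing columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise EmptyInputError("repertoire has no clones")
        if self.table["clone_key"].duplicated().any():
            raise FormatError("clone_key not unique within repertoire")
        if (self.table["umi_count"] < 1).any():
            raise FormatError("stored clone records must have umi_count >= 1")
        self.table = (
            self.table.sort_values("clone_key", kind="mergesort").reset_index(drop=True)
        )
        self.table["umi_count"] = self.table["umi_count"].astype(np.int64)

    @property
    def n_clones(self) -> int:
        return len(self.table)

    @property
    def counts(self) -> np.ndarray:
        return self.table["umi_count"].to_numpy()

    @property
    def total_umi(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        c = self.counts
        return c / c.sum()

    @property
    def clone_keys(self) -> list[str]:
        return self.table["clone_key"].tolist()

    def count_map(self) -> dict[str, int]:
        return dict(zip(self.table["clone_key"], self.table["umi_count"]))

    def frequency_map(self) -> dict[str, float]:
        return dict(zip(self.table["clone_key"], self.frequencies))

    def cdr3_of(self) -> dict[str, str]:
        """clone_key -> CDR3 amino-acid sequence."""
        return dict(zip(self.table["clone_key"], self.table["cdr3_aa"]))


@dataclass
class AbundancePair:
    """Union-indexed paired count vectors for two repertoires.

    Keys are ordered lexicographically; a clone absent from one
    repertoire carries count 0 there.
    """

    union_keys: list[str]
    counts_a: np.ndarray
    counts_b: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.union_keys) == len(self.counts_a) == len(self.counts_b)):
            raise ValueError("union_keys and count vectors must have equal length")


def _make_keys(df: pd.DataFrame, key_mode: str) -> pd.Series:
    if key_mode not in KEY_MODES:
        raise ValueError(f"key_mode must be one of {KEY_MODES}, got {key_mode!r}")
    has_junction = "junction" in df.columns and df["junction"].notna().all()
    if key_mode == "auto":
        key_mode = "vj_junction" if has_junction else "vj_cdr3aa"
    if key_mode == "vj_junction":
        if not has_junction:
            raise FormatError("key_mode 'vj_junction' requires a complete 'junction' column")
        parts = [df["v_call"], df["j_call"], df["junction"]]
    elif key_mode == "vj_cdr3aa":
        parts = [df["v_call"], df["j_call"], df["cdr3_aa"]]
    else:  # cdr3_aa
        parts = [df["cdr3_aa"]]
    key = parts[0].astype(str)
    for p in parts[1:]:
        key = key + "|" + p.astype(str)
    logger.debug("clone keys built with key_mode=%s", key_mode)
    return key


def read_repertoire(
    path: str | Path,
    format: str = "simple_tsv",
    meta: SampleMeta | None = None,
    key_mode: str = "auto",
) -> Repertoire:
    """Read one clone table, merging duplicate keys and dropping unusable rows.

    Rows with zero count or an empty CDR3 are dropped with a logged
    warning; duplicate clone keys are merged by summing counts.
    """
    path = Path(path)
    if meta is None:
        meta = SampleMeta(patient_id=path.stem, timepoint="pre")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if format == "airr":
        missing = [c for c in _AIRR_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"AIRR table {path} missing required columns {missing}")
        rename = {"junction_aa": "cdr3_aa", "duplicate_count": "umi_count"}
        df = df.rename(columns=rename)
    elif format == "simple_tsv":
        missing = [c for c in _SIMPLE_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"simple_tsv table {path} missing required columns {missing}")
    else:
        raise ValueError(f"unknown format {format!r}")

    keep = [c for c in ("cdr3_aa", "v_call", "j_call", "umi_count", "junction") if c in df.columns]
    df = df[keep].copy()
    df["umi_count"] = pd.to_numeric(df["umi_count"], errors="raise").astype(np.int64)
    df["cdr3_aa"] = df["cdr3_aa"].fillna("").str.strip().str.upper()

    n_before = len(df)
    df = df[(df["umi_count"] > 0) & (df["cdr3_aa"] != "")]
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d rows with zero count or empty CDR3", path, n_dropped)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no usable clone rows after filtering")

    df["clone_key"] = _make_keys(df, key_mode)
    agg = {"umi_count": "sum", "cdr3_aa": "first", "v_call": "first", "j_call": "first"}
    if "junction" in df.columns:
        agg["junction"] = "first"
    merged = df.groupby("clone_key", as_index=False, sort=True).agg(agg)
    return Repertoire(meta=meta, table=merged)


def write_repertoire(rep: Repertoire, path: str | Path, format: str = "simple_tsv") -> None:
    """Write a clone table back out in either supported dialect."""
    df = rep.table.copy()
    if format == "airr":
        df = df.rename(columns={"cdr3_aa": "junction_aa", "umi_count": "duplicate_count"})
        cols = ["junction_aa", "v_call", "j_call", "duplicate_count"]
        if "junction" in df.columns:
            cols.append("junction")
    elif format == "simple_tsv":
        cols = ["cdr3_aa", "v_call", "j_call", "umi_count"]
        if "junction" in df.columns:
            cols.append("junction")
    else:
        raise ValueError(f"unknown format {format!r}")
    df[cols].to_csv(path, sep="\t", index=False)


def pool_repertoires(repertoires: Sequence[Repertoire]) -> Repertoire:
    """Sum clone counts across regions of one patient/timepoint/compartment.

    The pooled abundance of a clone is its summed count divided by the
    summed total; total UMI count is conserved exactly.
    """
    if len(repertoires) == 0:
        raise MetadataError("pool_repertoires requires at least one repertoire")
    metas = {(r.meta.patient_id, r.meta.timepoint, r.meta.compartment) for r in repertoires}
    if len(metas) != 1:
        raise MetadataError(f"cannot pool repertoires with mixed metadata: {sorted(metas)}")
    if len(repertoires) == 1:
        r = repertoires[0]
        return Repertoire(meta=replace(r.meta, region_id=POOLED_REGION), table=r.table.copy())
    cat = pd.concat([r.table for r in repertoires], ignore_index=True)
    agg = {"umi_count": "sum", "cdr3_aa": "first", "v_call": "first", "j_call": "first"}
    if "junction" in cat.columns:
        agg["junction"] = "first"
    merged = cat.groupby("clone_key", as_index=False, sort=True).agg(agg)
    meta = replace(repertoires[0].meta, region_id=POOLED_REGION)
    return Repertoire(meta=meta, table=merged)


def abundance_pair(rep_a: Repertoire, rep_b: Repertoire, key_mode: str = "full_key") -> AbundancePair:
    """Build union-indexed paired count vectors for two repertoires.

    ``key_mode='full_key'`` pairs on the stored clone keys;
    ``key_mode='cdr3_aa'`` first merges same-CDR3 clones (summing
    counts) so that clones differing only in V/J assignment are
    identified across the pair.
    """
    if key_mode == "full_key":
        map_a, map_b = rep_a.count_map(), rep_b.count_map()
    elif key_mode == "cdr3_aa":
        map_a = rep_a.table.groupby("cdr3_aa")["umi_count"].sum().to_dict()
        map_b = rep_b.table.groupby("cdr3_aa")["umi_count"].sum().to_dict()
    else:
        raise ValueError("key_mode must be 'full_key' or 'cdr3_aa'")
    union = sorted(set(map_a) | set(map_b))
    a = np.array([map_a.get(k, 0) for k in union], dtype=np.int64)
    b = np.array([map_b.get(k, 0) for k in union], dtype=np.int64)
    return AbundancePair(union_keys=union, counts_a=a, counts_b=b)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a samples manifest TSV.

    Required columns: patient_id, timepoint, compartment, region_id,
    path, format.  Paths are resolved relative to the manifest's parent
    directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "timepoint", "compartment", "region_id", "path", "format"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    df["path"] = [str((path.parent / p).resolve()) for p in df["path"]]
    return df


def load_cohort(manifest: pd.DataFrame, key_mode: str = "auto") -> list[Repertoire]:
    """Load every sample listed in a manifest into Repertoire objects."""
    reps = []
    for row in manifest.itertuples(index=False):
        meta = SampleMeta(
            patient_id=row.patient_id,
            timepoint=row.timepoint,
            compartment=row.compartment,
            region_id=row.region_id,
        )
        reps.append(read_repertoire(row.path, format=row.format, meta=meta, key_mode=key_mode))
    return reps
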