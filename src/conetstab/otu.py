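"""OTU count tables, sample metadata and network I/O.

All downstream stages consume the in-memory containers defined here; no
stage re-reads raw files. Tables are tab-delimited UTF-8 text with ``#``
comment lines; taxa are rows and samples are columns, following common
amplicon practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("conetstab")

ORGANISM_TAGS = ("bacteria_like", "fungi_like", "other")
TREATMENTS = ("control", "drought")
SAMPLINGS = ("pre_drought", "end_drought", "early_recovery", "late_recovery")

#: required metadata columns, in canonical order
META_REQUIRED = ("sample_id", "treatment", "sampling", "block")


class TableError(ValueError):
    """Raised for malformed tables or metadata."""


@dataclass
class OtuTable:
    """Integer taxa x samples count matrix with string ids.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix; index = taxon ids, columns = sample ids.
    organism_tag : str
        One of ``bacteria_like``, ``fungi_like``, ``other``.
    """

    counts: pd.DataFrame
    organism_tag: str = "other"

    def __post_init__(self) -> None:
        if self.organism_tag not in ORGANISM_TAGS:
            raise TableError(f"unknown organism_tag {self.organism_tag!r}")
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise TableError("empty OTU table")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise TableError(f"duplicate taxon id {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise TableError(f"duplicate sample id {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                i, j = np.argwhere(~(np.isfinite(arr) & (arr == np.floor(arr))))[0]
                raise TableError(
                    "non-integer count at taxon "
                    f"{self.counts.index[i]!r}, sample {self.counts.columns[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise TableError(
                f"negative count at taxon {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )

    # -- convenience views -------------------------------------------------
    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def matrix(self) -> np.ndarray:
        """Counts as a (taxa, samples) integer array."""
        return self.counts.to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        """Column-wise relative abundances (each sample sums to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise TableError(f"sample {bad!r} has zero total reads")
        return self.counts / totals

    def subset_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        ids = [s for s in sample_ids]
        return OtuTable(self.counts.loc[:, ids].copy(), self.organism_tag)

    def subset_taxa(self, taxon_ids: Iterable[str]) -> "OtuTable":
        ids = [t for t in taxon_ids]
        return OtuTable(self.counts.loc[ids, :].copy(), self.organism_tag)

    def canonical(self) -> "OtuTable":
        """Copy with taxa and samples sorted lexicographically."""
        c = self.counts.sort_index(axis=0).sort_index(axis=1)
        return OtuTable(c, self.organism_tag)


def read_otu_table(path: str | Path, organism_tag: str = "other") -> OtuTable:
    """Read a taxa x samples TSV (first column taxon ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise TableError(f"{path}: empty table")
    try:
        counts = df.apply(pd.to_numeric)
    except ValueError as exc:
        raise TableError(f"{path}: non-numeric cell ({exc})") from exc
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    counts.index.name = None
    counts.columns.name = None
    return OtuTable(counts, organism_tag)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.counts.rename_axis("taxon_id").to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV.

    Required columns: sample_id, treatment, sampling, block. Treatment and
    sampling levels are case-folded before validation (a level such as
    ``Drought`` is accepted and logged). Unknown columns are preserved as
    covariates.
    """
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    for col in META_REQUIRED:
        if col not in meta.columns:
            raise TableError(f"metadata missing required column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableError(f"duplicate sample_id {dup!r} in metadata")
    for col, levels in (("treatment", TREATMENTS), ("sampling", SAMPLINGS)):
        raw = meta[col].astype(str)
        folded = raw.str.lower().str.strip()
        changed = (raw != folded).sum()
        if changed:
            logger.info("metadata: case-folded %d %s values", changed, col)
        bad = sorted(set(folded) - set(levels))
        if bad:
            raise TableError(f"unknown {col} level(s) {bad} in metadata")
        meta[col] = pd.Categorical(folded, categories=levels, ordered=True)
    meta["block"] = meta["block"].astype(int)
    for col in meta.columns:
        if col not in META_REQUIRED and col != "plant_treatment":
            try:
                meta[col] = pd.to_numeric(meta[col])
            except (ValueError, TypeError):
                pass  # non-numeric covariate stays as text
    return meta.set_index("sample_id", drop=False)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def join_metadata(table: OtuTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Metadata rows aligned to the table's samples; every sample must resolve."""
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise TableError(f"samples missing from metadata: {missing[:5]}")
    return meta.loc[table.sample_ids]


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Optional taxonomy TSV with a taxon_id column plus rank columns."""
    tax = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "taxon_id" not in tax.columns:
        raise TableError("taxonomy missing required column 'taxon_id'")
    return tax.set_index("taxon_id", drop=False)


# -- network output --------------------------------------------------------

def write_network(graph: nx.Graph, path: str | Path, format: str = "edge_list_tsv") -> None:
    """Write a co-occurrence network as an edge-list TSV or GraphML.

    Edge-list rows are ``taxon_a  taxon_b  rho``; GraphML carries every node
    and edge attribute present on the graph. An empty network yields a
    header-only edge list.
    """
    path = Path(path)
    if format == "edge_list_tsv":
        rows = [
            {"taxon_a": u, "taxon_b": v, "rho": d.get("rho", float("nan"))}
            for u, v, d in graph.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho"]).to_csv(
            path, sep="\t", index=False
        )
    elif format == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    else:
        raise ValueError(f"unknown network format {format!r}")
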