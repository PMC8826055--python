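"""Shared domain types and readers/writers for every external format the toolkit touches.

The central in-memory objects are deliberately thin:

* :class:`OtuTable` — a validated samples × OTUs count matrix.
* phylogenies — :class:`skbio.TreeNode` (rooted, branch lengths required).
* sample metadata — a validated :class:`pandas.DataFrame` keyed by ``sample_id``.
* :class:`DepletionSeries` — one microcosm's headspace CH4 time series.
* distance matrices — :class:`skbio.DistanceMatrix`.

All tabular output is tab-separated UTF-8 with a single header row; floats are
printed with 6 significant digits.  Sample and OTU ids are case-sensitive exact
strings — no normalization is ever applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "FormatError",
    "OtuTable",
    "DepletionSeries",
    "FLOAT_FORMAT",
    "WETLAND_TYPES",
    "read_otu_table",
    "write_otu_table",
    "read_tree_newick",
    "write_tree_newick",
    "read_metadata",
    "write_metadata",
    "read_gas_csv",
    "write_gas_csv",
    "align_table_tree",
]

#: printf-style format used for every floating-point cell the toolkit writes.
FLOAT_FORMAT = "%.6g"

WETLAND_TYPES = ("paddy", "natural")


class FormatError(ValueError):
    """An input file violates a structural invariant (duplicate ids, negative
    counts, inconsistent metadata, ...).  The message names the offending
    row/column."""


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OtuTable:
    """Samples × OTUs matrix of non-negative integer read counts.

    ``counts[i, j]`` is the number of reads of OTU ``otu_ids[j]`` observed in
    sample ``sample_ids[i]``.
    """

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.number):
            raise FormatError("counts must be numeric")
        if not np.all(np.isfinite(counts)):
            raise FormatError("counts contain non-finite values")
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        if np.any(counts != np.round(counts)):
            raise FormatError("counts must be integers")
        counts = counts.astype(np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.otu_ids, "OTU id")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )

    # -- convenience views --------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized counts.  All-zero samples yield all-zero rows."""
        totals = self.sample_sums().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / totals[:, None]
        rel[totals == 0] = 0.0
        return rel

    def presence(self) -> np.ndarray:
        return self.counts > 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.otu_ids)
        )

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OtuTable(self.counts[:, idx], self.sample_ids, tuple(otu_ids))

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(self.counts[idx, :], tuple(sample_ids), self.otu_ids)


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what}: {i!r}")
        seen.add(i)


def read_otu_table(path: str | Path, orientation: str = "samples_as_rows") -> OtuTable:
    """Read a tab-separated OTU table.

    ``orientation`` must be given explicitly (``samples_as_rows`` or
    ``otus_as_rows``); auto-detection is deliberately not attempted.  A leading
    ``#OTU ID`` header cell (QIIME classic convention) is accepted when
    ``orientation='otus_as_rows'``.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], f"{path} header column")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    df.index = df.index.astype(str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell in OTU table ({exc})") from exc
    if orientation == "otus_as_rows":
        values = values.T
        sample_ids, otu_ids = list(df.columns), list(df.index)
    else:
        sample_ids, otu_ids = list(df.index), list(df.columns)
    try:
        return OtuTable(values, tuple(sample_ids), tuple(otu_ids))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_otu_table(
    table: OtuTable, path: str | Path, orientation: str = "samples_as_rows"
) -> None:
    df = table.to_dataframe()
    if orientation == "otus_as_rows":
        df = df.T
        df.index.name = "#OTU ID"
    elif orientation == "samples_as_rows":
        df.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def _validate_tree(tree: TreeNode) -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) == 0:
        raise FormatError("tree has no tips")
    if any(t is None for t in tips):
        raise FormatError("tree has unnamed tips")
    _check_unique(tips, "tip label")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise FormatError(f"negative branch length at node {node.name!r}")
    if n_missing:
        warnings.warn(
            f"{n_missing} branch length(s) missing; treated as 0", stacklevel=3
        )
    if tree.length is None:
        tree.length = 0.0
    return tree


def read_tree_newick(path: str | Path) -> TreeNode:
    """Read a rooted newick tree with branch lengths.

    Missing branch lengths are set to 0 with a warning; duplicate tip labels
    and negative branch lengths are rejected.  Underscores in labels are
    preserved verbatim.
    """
    try:
        tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"{path}: cannot parse newick ({exc})") from exc
    return _validate_tree(tree)


def parse_tree_newick(newick: str) -> TreeNode:
    """Parse a newick string (same validation as :func:`read_tree_newick`)."""
    try:
        tree = TreeNode.read([newick], format="newick", convert_underscores=False)
    except Exception as exc:
        raise FormatError(f"cannot parse newick ({exc})") from exc
    return _validate_tree(tree)


def write_tree_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_REQUIRED_META = ("sample_id", "site", "wetland_type")
_OPTIONAL_META = ("replicate", "fraction", "mop")


def _validate_metadata(df: pd.DataFrame, origin: str = "metadata") -> pd.DataFrame:
    for col in _REQUIRED_META:
        if col not in df.columns:
            raise FormatError(f"{origin}: missing required column {col!r}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    _check_unique(df["sample_id"], "sample_id")
    bad_type = sorted(set(df["wetland_type"]) - set(WETLAND_TYPES))
    if bad_type:
        raise FormatError(
            f"{origin}: unknown wetland_type {bad_type[0]!r} "
            f"(expected one of {WETLAND_TYPES})"
        )
    mapping = df.groupby("site")["wetland_type"].nunique()
    inconsistent = mapping[mapping > 1]
    if len(inconsistent):
        raise FormatError(
            f"{origin}: site {inconsistent.index[0]!r} is mapped to more than "
            "one wetland_type"
        )
    for col in ("replicate", "fraction"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    if "mop" in df.columns:
        df["mop"] = pd.to_numeric(df["mop"], errors="raise")
        if (df["mop"].dropna() < 0).any():
            raise FormatError(f"{origin}: negative mop value")
    else:
        df["mop"] = np.nan
    return df.set_index("sample_id", drop=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read per-sample metadata (CSV with header).

    Required columns: ``sample_id``, ``site``, ``wetland_type``.  Optional:
    ``replicate``, ``fraction``, ``mop`` (μg CH4 g⁻¹ dry soil h⁻¹); a missing
    ``mop`` column is filled with NaN.
    """
    df = pd.read_csv(path)
    return _validate_metadata(df, origin=str(path))


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Gas depletion series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepletionSeries:
    """Headspace CH4 concentration time series for one microcosm.

    ``times`` are hours since the start of the incubation, strictly
    increasing; ``concentrations`` are ppmv.  The physical constants default to
    the microcosm setup this toolkit emulates: a 120-ml serum bottle holding
    5 g dry soil (≈115 ml headspace) incubated at 28 °C.
    """

    microcosm_id: str
    times: np.ndarray
    concentrations: np.ndarray
    headspace_volume: float = 115.0  # ml
    soil_mass: float = 5.0  # g dry weight
    temperature: float = 28.0  # °C

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        if times.shape != conc.shape or times.ndim != 1:
            raise FormatError(
                f"{self.microcosm_id}: times and concentrations must be "
                "1-D and equally long"
            )
        if len(times) < 2:
            raise FormatError(f"{self.microcosm_id}: need at least 2 observations")
        if np.any(np.diff(times) <= 0):
            raise FormatError(f"{self.microcosm_id}: times must strictly increase")
        if np.any(conc < 0):
            raise FormatError(f"{self.microcosm_id}: negative concentration")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", conc)


def read_gas_csv(
    path: str | Path,
    headspace_volume: float = 115.0,
    soil_mass: float = 5.0,
    temperature: float = 28.0,
) -> dict[str, DepletionSeries]:
    """Read headspace CH4 series (CSV: microcosm_id, time_h, ch4_ppmv).

    Physical constants are not stored in the CSV; pass them here (typically
    from the run configuration).
    """
    df = pd.read_csv(path)
    for col in ("microcosm_id", "time_h", "ch4_ppmv"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out: dict[str, DepletionSeries] = {}
    for mid, grp in df.groupby("microcosm_id", sort=True):
        grp = grp.sort_values("time_h")
        out[str(mid)] = DepletionSeries(
            microcosm_id=str(mid),
            times=grp["time_h"].to_numpy(float),
            concentrations=grp["ch4_ppmv"].to_numpy(float),
            headspace_volume=headspace_volume,
            soil_mass=soil_mass,
            temperature=temperature,
        )
    return out


def write_gas_csv(series: Iterable[DepletionSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for t, c in zip(s.times, s.concentrations):
            rows.append({"microcosm_id": s.microcosm_id, "time_h": t, "ch4_ppmv": c})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Table / tree alignment
# ---------------------------------------------------------------------------

def align_table_tree(table: OtuTable, tree: TreeNode) -> tuple[OtuTable, TreeNode]:
    """Restrict a table and tree to their shared OTU set.

    The returned tree is pruned (sheared) to the shared tips, preserving
    patristic distances among them; the table keeps its sample order and the
    shared OTUs in their original column order.  Dropped ids on either side
    are reported via a warning.  An empty intersection is an error.
    """
    tips = {t.name for t in tree.tips()}
    shared = [o for o in table.otu_ids if o in tips]
    if not shared:
        raise FormatError("table OTUs and tree tips are disjoint")
    dropped_table = [o for o in table.otu_ids if o not in tips]
    dropped_tree = sorted(tips - set(shared))
    if dropped_table or dropped_tree:
        warnings.warn(
            f"align_table_tree: dropped {len(dropped_table)} table OTU(s) "
            f"and {len(dropped_tree)} tree tip(s) outside the intersection",
            stacklevel=2,
        )
    sub_table = table.select_otus(shared)
    sub_tree = tree.shear(shared) if dropped_tree else tree
    _validate_tree(sub_tree)
    return sub_table, sub_tree
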