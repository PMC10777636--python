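"""Typed containers and TSV readers/writers for the pipeline's tables.

All tables travel as tab-separated UTF-8 text with a header row. Sample
order is canonicalized lexicographically by sample id so that every
downstream matrix (distances, networks, regressions) inherits a single
deterministic ordering. Zeros are kept exact; no pseudocounts are added
at this layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# "relative_subset" marks a row-slice of a relative table: values are still
# on the relative scale but columns no longer sum to one
Kind = Literal["counts", "relative", "relative_subset"]

_REL_TOL = 1e-9


class FormatError(ValueError):
    """A table on disk or in memory violates the format contract."""


class DegenerateSampleError(ValueError):
    """A sample column cannot be normalized (all-zero)."""


class AlignmentError(ValueError):
    """Tables share no sample ids."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OtuTable:
    """Taxa x samples abundance matrix.

    ``kind`` records whether values are raw counts or per-sample relative
    abundances (columns summing to one).
    """

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_taxa, n_samples), non-negative
    kind: Kind = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.otu_ids)} OTUs x {len(self.sample_ids)} samples"
            )
        _check_unique(self.otu_ids, "OTU")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite cell in OTU table")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise FormatError(
                f"negative abundance at OTU {self.otu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.kind == "relative":
            sums = self.values.sum(axis=0)
            if not np.allclose(sums, 1.0, rtol=0, atol=_REL_TOL):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise FormatError(
                    f"relative-abundance column {self.sample_ids[bad]!r} "
                    f"sums to {sums[bad]!r}, not 1"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.otu_ids, columns=self.sample_ids)

    def subset_taxa(self, otu_ids) -> "OtuTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        missing = [o for o in otu_ids if o not in idx]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing[:5]}")
        rows = [idx[o] for o in otu_ids]
        kind = self.kind
        if kind == "relative" and len(rows) < self.n_taxa:
            kind = "relative_subset"
        return OtuTable(list(otu_ids), list(self.sample_ids),
                        self.values[rows, :], kind)

    def reorder_samples(self, sample_ids) -> "OtuTable":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return OtuTable(list(self.otu_ids), list(sample_ids),
                        self.values[:, cols], self.kind)


@dataclass
class TaxonomyTable:
    """Per-OTU kingdom and phylum assignment."""

    assignments: dict[str, tuple[str, str]]  # otu_id -> (kingdom, phylum)

    def kingdom(self, otu_id: str) -> str:
        return self.assignments[otu_id][0]

    def phylum(self, otu_id: str) -> str:
        return self.assignments[otu_id][1]

    def covers(self, otu_ids) -> bool:
        return all(o in self.assignments for o in otu_ids)


@dataclass
class SampleMetadata:
    """Sample -> (zone, replicate) mapping with a declared zone label set."""

    zones: dict[str, str]  # sample_id -> zone
    replicates: dict[str, int]
    zone_labels: tuple[str, ...] = ("AL", "RZ", "TZ")

    def __post_init__(self) -> None:
        for s, z in self.zones.items():
            if z not in self.zone_labels:
                raise FormatError(
                    f"sample {s!r} has zone {z!r} outside {self.zone_labels}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.zones)

    def groups(self, sample_ids=None) -> dict[str, list[str]]:
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        out: dict[str, list[str]] = {}
        for s in ids:
            out.setdefault(self.zones[s], []).append(s)
        return out

    def zone_vector(self, sample_ids) -> list[str]:
        return [self.zones[s] for s in sample_ids]


@dataclass
class FunctionTable:
    """Samples x soil-function variables (nutrients, fertility, enzyme activities)."""

    sample_ids: list[str]
    function_names: list[str]
    values: np.ndarray  # (n_samples, n_functions)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.function_names)):
            raise FormatError("function matrix shape mismatch")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.function_names, "function")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("non-finite cell in function table")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.function_names)

    def degenerate_functions(self) -> list[str]:
        """Functions with fewer than two distinct values across samples."""
        out = []
        for j, name in enumerate(self.function_names):
            if np.unique(self.values[:, j]).size < 2:
                out.append(name)
        return out

    def reorder_samples(self, sample_ids) -> "FunctionTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return FunctionTable(list(sample_ids), list(self.function_names),
                             self.values[rows, :])


# ---------------------------------------------------------------------------
# TSV I/O


def _read_numeric_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    body = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                body[i, j] = float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric cell {raw!r} at row {df.index[i]!r}, "
                    f"column {col!r} in {path}"
                ) from None
    return pd.DataFrame(body, index=df.index, columns=[str(c) for c in df.columns])


def read_otu_table(path, kind: Kind = "counts") -> OtuTable:
    """Read a taxa x samples TSV (first column OTU ids, header sample ids)."""
    df = _read_numeric_tsv(path)
    return OtuTable(list(df.index), list(df.columns), df.to_numpy(), kind)


def write_otu_table(table: OtuTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="otu_id",
                            float_format="%.12g")


def read_taxonomy_table(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"otu_id", "kingdom", "phylum"}
    if not required.issubset(df.columns):
        raise FormatError(f"taxonomy table needs columns {sorted(required)}")
    _check_unique(df["otu_id"], "OTU")
    return TaxonomyTable({
        r.otu_id: (r.kingdom, r.phylum) for r in df.itertuples()
    })


def write_taxonomy_table(tax: TaxonomyTable, path) -> None:
    pd.DataFrame(
        [(o, k, p) for o, (k, p) in tax.assignments.items()],
        columns=["otu_id", "kingdom", "phylum"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path, zone_column: str = "zone",
                         replicate_column: str = "replicate",
                         zone_labels=("AL", "RZ", "TZ")) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or zone_column not in df.columns:
        raise FormatError("metadata needs 'sample_id' and zone columns")
    _check_unique(df["sample_id"], "sample")
    reps = {}
    if replicate_column in df.columns:
        reps = {r: int(v) for r, v in zip(df["sample_id"], df[replicate_column])}
    else:
        reps = {s: i + 1 for i, s in enumerate(df["sample_id"])}
    return SampleMetadata(dict(zip(df["sample_id"], df[zone_column])), reps,
                          tuple(zone_labels))


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    pd.DataFrame({
        "sample_id": meta.sample_ids,
        "zone": [meta.zones[s] for s in meta.sample_ids],
        "replicate": [meta.replicates.get(s, 1) for s in meta.sample_ids],
    }).to_csv(path, sep="\t", index=False)


def read_function_table(path) -> FunctionTable:
    df = _read_numeric_tsv(path)
    return FunctionTable(list(df.index), list(df.columns), df.to_numpy())


def write_function_table(fx: FunctionTable, path) -> None:
    fx.to_frame().to_csv(path, sep="\t", index_label="sample_id",
                         float_format="%.12g")


# ---------------------------------------------------------------------------
# Normalization and alignment


def to_relative(table: OtuTable) -> OtuTable:
    """Convert counts to per-sample relative abundances.

    Guarded against double normalization: a table already marked
    ``relative`` is rejected rather than divided again.
    """
    if table.kind in ("relative", "relative_subset"):
        raise FormatError("table is already relative; refusing to renormalize")
    sums = table.values.sum(axis=0)
    if np.any(sums <= 0):
        bad = table.sample_ids[int(np.argmax(sums <= 0))]
        raise DegenerateSampleError(f"sample {bad!r} has zero total abundance")
    return OtuTable(list(table.otu_ids), list(table.sample_ids),
                    table.values / sums, "relative")


def ensure_relative(table: OtuTable) -> OtuTable:
    return to_relative(table) if table.kind == "counts" else table


def align_tables(otu: OtuTable, meta: SampleMetadata, fx: FunctionTable | None = None):
    """Restrict all tables to their common samples, in lexicographic order.

    Returns ``(otu, meta, fx)`` with identical sample ordering; ``fx`` may
    be None. Dropped sample ids are logged.
    """
    common = set(otu.sample_ids) & set(meta.sample_ids)
    if fx is not None:
        common &= set(fx.sample_ids)
    if not common:
        raise AlignmentError("no samples shared by the input tables")
    order = sorted(common)
    for name, ids in [("otu", otu.sample_ids), ("metadata", meta.sample_ids)] + (
            [("functions", fx.sample_ids)] if fx is not None else []):
        dropped = sorted(set(ids) - common)
        if dropped:
            logger.info("align_tables: dropping %d sample(s) from %s: %s",
                        len(dropped), name, dropped)
    otu2 = otu.reorder_samples(order)
    meta2 = SampleMetadata({s: meta.zones[s] for s in order},
                           {s: meta.replicates.get(s, 1) for s in order},
                           meta.zone_labels)
    fx2 = fx.reorder_samples(order) if fx is not None else None
    return otu2, meta2, fx2
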