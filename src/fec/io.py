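"""Core domain types and file I/O for endophyte community tables.

The central object is the :class:`CountTable` — a taxa × samples matrix of
non-negative integer read counts, the state of an amplicon dataset after
denoising and taxonomic assignment.  Samples are columns and taxa are rows,
following the usual feature-table convention.  All downstream stages
(filtering, diversity, dissimilarity, networks) consume this object or one
of its derived forms (:class:`AbundanceTable`, :class:`IncidenceMatrix`).

TSV is the canonical interchange format; BIOM 2.1 (HDF5) tables are accepted
read-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing taxonomic assignment at some rank.  Using an explicit
#: sentinel (never the empty string) keeps rank-based filters unambiguous.
UNASSIGNED = "UNASSIGNED"

#: Taxonomic ranks, highest to lowest.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class FecError(ValueError):
    """Raised on contract violations in user-supplied data."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen = set()
    dups = [i for i in ids if i in seen or seen.add(i)]
    if dups:
        raise FecError(f"duplicate {what} ids: {sorted(set(dups))[:5]}")
    return ids


@dataclass
class CountTable:
    """Taxa × samples matrix of non-negative integer read counts."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = _check_unique(self.taxon_ids, "taxon")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FecError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa × {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                bad = np.argwhere(self.counts != as_int)
                r, c = bad[0]
                raise FecError(
                    f"non-integer count at taxon {self.taxon_ids[r]!r}, "
                    f"sample {self.sample_ids[c]!r}: {self.counts[r, c]!r}"
                )
            self.counts = as_int
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            r, c = np.argwhere(self.counts < 0)[0]
            raise FecError(
                f"negative count at taxon {self.taxon_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}: {self.counts[r, c]}"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def total_reads(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        sample_ids = list(sample_ids)
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise FecError(f"unknown sample ids: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return CountTable(list(self.taxon_ids), sample_ids, self.counts[:, idx])

    def select_taxa(self, taxon_ids: Iterable[str]) -> "CountTable":
        taxon_ids = list(taxon_ids)
        pos = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in taxon_ids if t not in pos]
        if missing:
            raise FecError(f"unknown taxon ids: {missing[:5]}")
        idx = [pos[t] for t in taxon_ids]
        return CountTable(taxon_ids, list(self.sample_ids), self.counts[idx, :])


@dataclass
class SampleMetadata:
    """Per-sample host species and collection site.

    A (host, site) pair defines a *population* — all plants of one host
    species collected at one site.
    """

    table: pd.DataFrame  # index sample_id, columns host, site

    def __post_init__(self) -> None:
        for col in ("host", "site"):
            if col not in self.table.columns:
                raise FecError(f"metadata missing required column {col!r}")
        _check_unique(list(self.table.index), "sample")
        self.table = self.table[["host", "site"]].astype(str)
        self.table.index = self.table.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def hosts(self) -> list[str]:
        return sorted(self.table["host"].unique())

    def sites(self) -> list[str]:
        return sorted(self.table["site"].unique())

    def host_of(self) -> pd.Series:
        return self.table["host"]

    def populations(self, sample_ids: Sequence[str] | None = None) -> dict[tuple[str, str], list[str]]:
        """Map (host, site) -> member sample ids, in stable order."""
        tab = self.table if sample_ids is None else self.table.loc[list(sample_ids)]
        out: dict[tuple[str, str], list[str]] = {}
        for sid, row in tab.iterrows():
            out.setdefault((row["host"], row["site"]), []).append(sid)
        return out

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


@dataclass
class Taxonomy:
    """Taxonomic assignments, kingdom → species, per taxon.

    Any rank may carry the :data:`UNASSIGNED` sentinel; once a rank is
    unassigned every lower rank must be unassigned too.
    """

    table: pd.DataFrame  # index taxon_id, columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.table.columns]
        if missing:
            raise FecError(f"taxonomy missing rank columns {missing}")
        _check_unique(list(self.table.index), "taxon")
        self.table = self.table[list(RANKS)].astype(str)
        self.table.index = self.table.index.astype(str)
        vals = self.table.to_numpy()
        unassigned = vals == UNASSIGNED
        for i in range(len(RANKS) - 1):
            bad = unassigned[:, i] & ~unassigned[:, i + 1]
            if bad.any():
                tid = self.table.index[np.argmax(bad)]
                raise FecError(
                    f"taxon {tid!r} assigned at {RANKS[i + 1]} but not at {RANKS[i]}"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.table.index)

    def rank(self, name: str) -> pd.Series:
        if name not in RANKS:
            raise FecError(f"unknown rank {name!r}")
        return self.table[name]

    def subset(self, taxon_ids: Sequence[str]) -> "Taxonomy":
        return Taxonomy(self.table.loc[list(taxon_ids)].copy())


@dataclass
class AbundanceTable:
    """Taxa × samples matrix of transformed (non-negative real) abundances."""

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    transform: str = "none"  # hellinger | relative | none

    def __post_init__(self) -> None:
        self.taxon_ids = _check_unique(self.taxon_ids, "taxon")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FecError("values shape inconsistent with ids")
        if (self.values < 0).any():
            raise FecError("negative abundance value")
        if self.transform not in ("hellinger", "relative", "none"):
            raise FecError(f"unknown transform {self.transform!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class IncidenceMatrix:
    """Taxa × samples presence/absence (1 = at least one read)."""

    taxon_ids: list[str]
    sample_ids: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = _check_unique(self.taxon_ids, "taxon")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.incidence = np.asarray(self.incidence)
        if self.incidence.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FecError("incidence shape inconsistent with ids")
        if not np.isin(self.incidence, (0, 1)).all():
            raise FecError("incidence entries must be 0 or 1")
        self.incidence = self.incidence.astype(np.int8)


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with zero diagonal, in [0, 1]."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "item")
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise FecError(f"distance matrix shape {self.d.shape} for {n} ids")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-12:
            raise FecError("distance matrix diagonal is not zero")
        if np.abs(self.d - self.d.T).max(initial=0.0) > 1e-12:
            raise FecError("distance matrix is asymmetric beyond 1e-12")
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)
        if self.d.min(initial=0.0) < -1e-12 or self.d.max(initial=0.0) > 1 + 1e-12:
            raise FecError("distances outside [0, 1]")

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[s] for s in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)])

    def block(self, ids_a: Sequence[str], ids_b: Sequence[str]) -> np.ndarray:
        """Rectangular between-group block of distances."""
        pos = {s: i for i, s in enumerate(self.ids)}
        ia = [pos[s] for s in ids_a]
        ib = [pos[s] for s in ids_b]
        return self.d[np.ix_(ia, ib)]


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def hellinger_transform(ct: CountTable) -> AbundanceTable:
    """Square root of within-sample relative abundance.

    value(i, j) = sqrt(count(i, j) / total(j)); per-sample squared values sum
    to one, which damps the dominance of highly abundant taxa in
    Euclidean-style comparisons.
    """
    totals = ct.sample_totals()
    if (totals == 0).any():
        bad = [s for s, t in zip(ct.sample_ids, totals) if t == 0]
        raise FecError(f"cannot Hellinger-transform zero-total samples: {bad}")
    vals = np.sqrt(ct.counts / totals[np.newaxis, :])
    return AbundanceTable(list(ct.taxon_ids), list(ct.sample_ids), vals, "hellinger")


def relative_abundance(ct: CountTable) -> AbundanceTable:
    totals = ct.sample_totals()
    if (totals == 0).any():
        bad = [s for s, t in zip(ct.sample_ids, totals) if t == 0]
        raise FecError(f"cannot normalize zero-total samples: {bad}")
    vals = ct.counts / totals[np.newaxis, :]
    return AbundanceTable(list(ct.taxon_ids), list(ct.sample_ids), vals, "relative")


def to_incidence(ct: CountTable | AbundanceTable) -> IncidenceMatrix:
    """Presence/absence matrix: 1 wherever the count is positive."""
    mat = ct.counts if isinstance(ct, CountTable) else ct.values
    return IncidenceMatrix(list(ct.taxon_ids), list(ct.sample_ids), (mat > 0).astype(np.int8))


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a feature table; first column taxon ids, header sample ids."""
    if format == "biom":
        return _read_biom(path)
    if format != "tsv":
        raise FecError(f"unknown count-table format {format!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    taxa = [str(t) for t in df.index]
    samples = [str(s) for s in df.columns]
    try:
        counts = df.to_numpy(dtype=np.int64)
    except (TypeError, ValueError):
        # slow path only to locate and report the offending cell
        for j, col in enumerate(df.columns):
            for i, raw in enumerate(df[col]):
                try:
                    int(str(raw))
                except (TypeError, ValueError):
                    raise FecError(
                        f"non-integer count {raw!r} at taxon {taxa[i]!r}, "
                        f"sample {samples[j]!r}"
                    ) from None
        raise
    if (counts < 0).any():
        i, j = np.argwhere(counts < 0)[0]
        raise FecError(
            f"negative count {counts[i, j]} at taxon {taxa[i]!r}, sample {samples[j]!r}"
        )
    return CountTable(taxa, samples, counts)


def write_count_table(ct: CountTable, path: str | Path) -> None:
    ct.to_frame().to_csv(path, sep="\t", index_label="taxon_id")


def _read_biom(path: str | Path) -> CountTable:
    """Read a BIOM 2.1 (HDF5) table: CSR by observation (taxon) rows."""
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as f:
        taxa = [t.decode() if isinstance(t, bytes) else str(t) for t in f["observation/ids"][:]]
        samples = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample/ids"][:]]
        grp = f["observation/matrix"]
        mat = csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(taxa), len(samples)),
        )
    dense = np.asarray(mat.todense())
    return CountTable(taxa, samples, dense)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FecError("metadata TSV must have a sample_id column")
    return SampleMetadata(df.set_index("sample_id"))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "taxon_id" not in df.columns:
        raise FecError("taxonomy TSV must have a taxon_id column")
    return Taxonomy(df.set_index("taxon_id"))


def write_taxonomy(tax: Taxonomy, path: str | Path) -> None:
    tax.table.to_csv(path, sep="\t", index_label="taxon_id")


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.d, index=dm.ids, columns=dm.ids)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.12g")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FecError("distance matrix row and column labels differ")
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))
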