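"""Readers and writers for every on-disk format the pipeline touches.

All files are plain tab-separated text.  Readers validate and *reject*
malformed input rather than coercing it; every error names the file, the
line and the violated rule.  Positions in sync files are 1-based everywhere.

Formats
-------
count matrix     TSV, first column gene id, header row of sample ids
sync             PoPoolation2: contig, pos, ref, then one ``A:T:C:G:N:del``
                 colon-separated sextuple of read counts per pool
design           TSV with sample_id / origin_pco2 / destination_pco2 /
                 replicate / pool_size columns
annotation       TSV with contig_id / component_id / annotation / go_terms
                 (semicolon-separated GO ids, may be empty)
GO map           two-column TSV, one (gene, term) pair per line
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .design import Sample, SampleDesign
from .errors import CrossReferenceError, FormatError

SYNC_COLUMNS = ("A", "T", "C", "G", "N", "del")
#: Indices of true nucleotide columns within a sync sextuple (N/del excluded).
NUCLEOTIDES = ("A", "T", "C", "G")


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(path) -> pd.DataFrame:
    """Read a genes x samples count table.

    Returns a DataFrame indexed by gene id with one column per sample.
    Values may be integers (raw counts) or reals (normalized counts).
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise FormatError("empty count matrix file", path=path) from None
    if df.shape[1] == 0:
        raise FormatError("count matrix has no sample columns", path=path)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"duplicate gene ids: {dupes[:5]}", path=path)
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample ids in header", path=path)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise FormatError(
                f"non-numeric count at gene {bad!r}, sample {col!r}", path=path
            ) from None
    out = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns)
    if not np.isfinite(out.to_numpy()).all():
        raise FormatError("non-finite count values", path=path)
    if (out.to_numpy() < 0).any():
        gi, sj = np.argwhere(out.to_numpy() < 0)[0]
        raise FormatError(
            f"negative count at gene {out.index[gi]!r}, sample {out.columns[sj]!r}",
            path=path,
        )
    # keep integer dtype when the file held integers
    arr = out.to_numpy()
    if np.array_equal(arr, np.round(arr)) and np.abs(arr).max(initial=0) < 2**53:
        out = out.astype(np.int64) if (arr == np.floor(arr)).all() else out
    out.index.name = "gene_id"
    return out


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix = matrix.copy()
    matrix.index.name = "gene_id"
    matrix.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# sync files


@dataclass
class SyncSite:
    """Per-site read counts for every pool, PoPoolation2 sync layout."""

    contig: str
    position: int  # 1-based
    ref: str
    pools: np.ndarray  # (n_pools, 6) int array, columns A:T:C:G:N:del

    def __post_init__(self):
        self.pools = np.asarray(self.pools, dtype=np.int64)
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position}")
        if self.pools.ndim != 2 or self.pools.shape[1] != 6:
            raise FormatError("pool counts must be an (n_pools, 6) array")
        if (self.pools < 0).any():
            raise FormatError("negative read count in sync site")


def _parse_sextuple(field: str, path, lineno: int) -> list[int]:
    parts = field.split(":")
    if len(parts) != 6:
        raise FormatError(
            f"expected 6 colon-separated counts, got {len(parts)} in {field!r}",
            path=path,
            line=lineno,
        )
    try:
        counts = [int(p) for p in parts]
    except ValueError:
        raise FormatError(
            f"non-integer count in sextuple {field!r}", path=path, line=lineno
        ) from None
    if any(c < 0 for c in counts):
        raise FormatError(f"negative count in sextuple {field!r}", path=path, line=lineno)
    return counts


def read_sync(path, n_pools: int | None = None) -> Iterator[SyncSite]:
    """Stream :class:`SyncSite` records from a sync file.

    ``n_pools`` fixes the expected number of pool columns; when omitted it is
    inferred from the first line and enforced for the rest of the file.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"expected at least 4 tab-separated fields, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            contig, pos_s, ref = fields[0], fields[1], fields[2]
            if n_pools is None:
                n_pools = len(fields) - 3
            if len(fields) - 3 != n_pools:
                raise FormatError(
                    f"expected {n_pools} pool columns, got {len(fields) - 3}",
                    path=path,
                    line=lineno,
                )
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(
                    f"non-integer position {pos_s!r}", path=path, line=lineno
                ) from None
            if pos < 1:
                raise FormatError(
                    f"positions are 1-based; got {pos}", path=path, line=lineno
                )
            if ref not in ("A", "C", "G", "T", "N"):
                raise FormatError(
                    f"reference base must be one of A/C/G/T/N, got {ref!r}",
                    path=path,
                    line=lineno,
                )
            pools = np.array(
                [_parse_sextuple(f, path, lineno) for f in fields[3:]], dtype=np.int64
            )
            yield SyncSite(contig=contig, position=pos, ref=ref, pools=pools)


def write_sync(sites: Iterable[SyncSite], path) -> None:
    with open(path, "w") as fh:
        for site in sites:
            cols = "\t".join(":".join(str(int(c)) for c in row) for row in site.pools)
            fh.write(f"{site.contig}\t{site.position}\t{site.ref}\t{cols}\n")


@dataclass
class SyncTable:
    """In-memory sync data as dense arrays, one row per site.

    ``counts`` has shape ``(n_sites, n_pools, 6)`` in sync column order.
    ``sample_ids`` names the pool columns; it is optional in the on-disk
    format (plain sync has no header) and is supplied from the design.
    """

    contigs: np.ndarray  # (n_sites,) str
    positions: np.ndarray  # (n_sites,) int, 1-based
    refs: np.ndarray  # (n_sites,) str
    counts: np.ndarray  # (n_sites, n_pools, 6) int
    sample_ids: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.contigs)
        if self.counts.shape != (n, len(self.sample_ids), 6):
            raise FormatError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{n} sites x {len(self.sample_ids)} pools"
            )

    @property
    def n_sites(self) -> int:
        return len(self.contigs)

    @property
    def n_pools(self) -> int:
        return len(self.sample_ids)

    def pool_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise CrossReferenceError(
                f"sample {sample_id!r} not present in sync table"
            ) from None

    def sites(self) -> Iterator[SyncSite]:
        for i in range(self.n_sites):
            yield SyncSite(
                contig=str(self.contigs[i]),
                position=int(self.positions[i]),
                ref=str(self.refs[i]),
                pools=self.counts[i],
            )

    @classmethod
    def from_sites(cls, sites: Iterable[SyncSite], sample_ids: list[str]) -> "SyncTable":
        sites = list(sites)
        return cls(
            contigs=np.array([s.contig for s in sites], dtype=object),
            positions=np.array([s.position for s in sites], dtype=np.int64),
            refs=np.array([s.ref for s in sites], dtype=object),
            counts=np.stack([s.pools for s in sites])
            if sites
            else np.zeros((0, len(sample_ids), 6), dtype=np.int64),
            sample_ids=list(sample_ids),
        )

    @classmethod
    def read(cls, path, sample_ids: list[str]) -> "SyncTable":
        return cls.from_sites(read_sync(path, n_pools=len(sample_ids)), sample_ids)

    def write(self, path) -> None:
        write_sync(self.sites(), path)


# ---------------------------------------------------------------------------
# design


def read_design(path) -> SampleDesign:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError("empty design file", path=path) from None
    required = ["sample_id", "origin_pco2", "destination_pco2", "replicate", "pool_size"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"design file is missing columns {missing}", path=path)
    samples = []
    for i, row in df.iterrows():
        try:
            samples.append(
                Sample(
                    sample_id=str(row["sample_id"]),
                    origin_pco2=int(row["origin_pco2"]),
                    destination_pco2=int(row["destination_pco2"]),
                    replicate=str(row["replicate"]),
                    pool_size=int(row["pool_size"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"bad design row: {exc}", path=path, line=i + 2) from None
    return SampleDesign(samples=samples)


def write_design(design: SampleDesign, path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "origin_pco2": [s.origin_pco2 for s in design],
            "destination_pco2": [s.destination_pco2 for s in design],
            "replicate": [s.replicate for s in design],
            "pool_size": [s.pool_size for s in design],
        }
    ).to_csv(path, sep="\t", index=False)


def check_samples_in_design(matrix: pd.DataFrame, design: SampleDesign) -> None:
    """Raise :class:`CrossReferenceError` if a count column has no design row."""
    known = set(design.sample_ids)
    unknown = [c for c in matrix.columns if c not in known]
    if unknown:
        raise CrossReferenceError(
            f"samples in count matrix absent from design: {unknown}"
        )


# ---------------------------------------------------------------------------
# annotation and GO maps


def read_annotation(path) -> pd.DataFrame:
    """Read a contig annotation table (contig -> component, annotation, GO ids).

    ``go_terms`` is parsed into a list of opaque GO id strings.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError("empty annotation file", path=path) from None
    required = ["contig_id", "component_id", "annotation"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file is missing columns {missing}", path=path)
    if df["contig_id"].duplicated().any():
        dupes = sorted(df.loc[df["contig_id"].duplicated(), "contig_id"].unique())
        raise FormatError(f"duplicate contig ids: {dupes[:5]}", path=path)
    if "go_terms" not in df.columns:
        df["go_terms"] = ""
    df["go_terms"] = [
        [t for t in cell.split(";") if t] for cell in df["go_terms"].astype(str)
    ]
    return df.set_index("contig_id", drop=False)


def write_annotation(annot: pd.DataFrame, path) -> None:
    out = annot.reset_index(drop=True).copy()
    out["go_terms"] = [";".join(ts) for ts in out["go_terms"]]
    out.to_csv(path, sep="\t", index=False)


def read_go_map(path) -> dict[str, set[str]]:
    """Read a flat gene -> GO-term map (two-column TSV, one pair per line)."""
    path = Path(path)
    go_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"expected 2 tab-separated fields, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            gene, term = fields
            if not gene or not term:
                raise FormatError("empty gene or term field", path=path, line=lineno)
            go_map.setdefault(gene, set()).add(term)
    return go_map


def write_go_map(go_map: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")
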