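"""Repertoire data model, table I/O, lineage clustering and divergence.

One :class:`UmiRecord` corresponds to one sequenced molecule (UMI), treated
as the readout of a single B cell. Records live either inside a follicle
(integer ``follicle_id``) or in extrafollicular space (the
:data:`EXTRAFOLLICULAR` sentinel, spelled ``EF`` in the on-disk dialect).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Optional, Sequence

import numpy as np

#: Sentinel follicle id for records outside all follicles.
EXTRAFOLLICULAR = -1

#: On-disk spelling of :data:`EXTRAFOLLICULAR`.
EF_TOKEN = "EF"

#: Allowed compartment labels.
COMPARTMENTS = ("GC", "ASC", "OTHER")

#: Column order of the repertoire TSV dialect.
TABLE_COLUMNS = (
    "umi_id",
    "sequence",
    "v_sequence",
    "germline_v",
    "v_call",
    "j_call",
    "junction",
    "follicle_id",
    "compartment",
    "x",
    "y",
    "section",
    "lineage_id",
    "root_divergence",
)

_UNAMBIGUOUS = frozenset(b"ACGT")


class RepertoireError(ValueError):
    """Base error for repertoire parsing/validation problems."""


class RowParseError(RepertoireError):
    """A malformed row; carries the 1-based data row index and column name."""

    def __init__(self, row_index: int, column: str, message: str):
        self.row_index = row_index
        self.column = column
        super().__init__(f"row {row_index}, column {column!r}: {message}")


@dataclass
class UmiRecord:
    """One sequenced molecule and its spatial/lineage annotations."""

    umi_id: str
    sequence: str
    v_sequence: str
    germline_v: str = ""
    v_call: str = ""
    j_call: str = ""
    junction: str = ""
    follicle_id: int = EXTRAFOLLICULAR
    compartment: str = "GC"
    x: float = 0.0
    y: float = 0.0
    section: int = 0
    lineage_id: Optional[int] = None
    root_divergence: Optional[float] = None

    @property
    def intrafollicular(self) -> bool:
        return self.follicle_id != EXTRAFOLLICULAR

    def validate(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise RepertoireError(
                f"{self.umi_id}: unknown compartment {self.compartment!r}"
            )
        if self.root_divergence is not None and not (
            0.0 <= self.root_divergence <= 1.0
        ):
            raise RepertoireError(
                f"{self.umi_id}: root_divergence outside [0, 1]"
            )
        if self.compartment == "ASC" and self.intrafollicular:
            raise RepertoireError(
                f"{self.umi_id}: ASC records must be extrafollicular"
            )


@dataclass
class FollicleMap:
    """Follicle centroids and the within-follicle distance normalizer."""

    follicle_ids: list
    centroids: dict  # follicle_id -> (x, y) in micrometres
    intra_median: float = float("nan")
    radius: float = 50.0

    def distance(self, a: int, b: int) -> float:
        xa, ya = self.centroids[a]
        xb, yb = self.centroids[b]
        return math.hypot(xa - xb, ya - yb)


@dataclass
class Lineage:
    """Summary of one clonal family."""

    lineage_id: int
    members: list = field(default_factory=list)  # umi_ids
    germline_v: str = ""
    n_follicles: int = 0
    n_umis_intra: int = 0


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _format_float(value: Optional[float]) -> str:
    if value is None:
        return ""
    return repr(float(value))


def _parse_float(token: str, row: int, column: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise RowParseError(row, column, f"not a number: {token!r}") from None


def read_repertoire_table(path) -> list[UmiRecord]:
    """Read the tab-separated repertoire dialect into records.

    Missing optional columns are tolerated; rows lacking both ``germline_v``
    and ``root_divergence`` are accepted but counted (see the returned
    records' attributes). Malformed rows raise :class:`RowParseError` naming
    the 1-based data row and offending column.
    """
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise RepertoireError(f"{path}: empty file") from None
        unknown = set(header) - set(TABLE_COLUMNS)
        if unknown:
            raise RepertoireError(f"{path}: unknown columns {sorted(unknown)}")
        if "umi_id" not in header:
            raise RepertoireError(f"{path}: missing required column 'umi_id'")
        records = []
        for i, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0]):
                continue
            if len(row) != len(header):
                raise RowParseError(i, "<row>", "wrong number of fields")
            data = dict(zip(header, row))
            rec = _record_from_strings(data, i)
            records.append(rec)
    if not records:
        raise RepertoireError(f"{path}: no data rows")
    return records


def _record_from_strings(data: dict, row: int) -> UmiRecord:
    kwargs = {}
    for key in ("umi_id", "sequence", "v_sequence", "germline_v", "v_call",
                "j_call", "junction"):
        if key in data:
            kwargs[key] = data[key]
    tok = data.get("follicle_id", EF_TOKEN)
    if tok == EF_TOKEN or tok == "":
        kwargs["follicle_id"] = EXTRAFOLLICULAR
    else:
        try:
            kwargs["follicle_id"] = int(tok)
        except ValueError:
            raise RowParseError(row, "follicle_id",
                                f"not an integer or {EF_TOKEN!r}: {tok!r}") from None
    comp = data.get("compartment", "GC")
    if comp not in COMPARTMENTS:
        raise RowParseError(row, "compartment", f"unknown value {comp!r}")
    kwargs["compartment"] = comp
    for key in ("x", "y"):
        if key in data:
            kwargs[key] = _parse_float(data[key], row, key)
    if data.get("section", ""):
        try:
            kwargs["section"] = int(data["section"])
        except ValueError:
            raise RowParseError(row, "section", "not an integer") from None
    if data.get("lineage_id", ""):
        try:
            kwargs["lineage_id"] = int(data["lineage_id"])
        except ValueError:
            raise RowParseError(row, "lineage_id", "not an integer") from None
    if data.get("root_divergence", ""):
        kwargs["root_divergence"] = _parse_float(
            data["root_divergence"], row, "root_divergence")
    rec = UmiRecord(**kwargs)
    try:
        rec.validate()
    except RepertoireError as exc:
        raise RowParseError(row, "compartment", str(exc)) from None
    return rec


def write_repertoire_table(records: Iterable[UmiRecord], path) -> None:
    """Write records in the canonical TSV dialect (inverse of the reader)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TABLE_COLUMNS)
        for rec in records:
            writer.writerow([
                rec.umi_id,
                rec.sequence,
                rec.v_sequence,
                rec.germline_v,
                rec.v_call,
                rec.j_call,
                rec.junction,
                EF_TOKEN if rec.follicle_id == EXTRAFOLLICULAR else rec.follicle_id,
                rec.compartment,
                _format_float(rec.x),
                _format_float(rec.y),
                rec.section,
                "" if rec.lineage_id is None else rec.lineage_id,
                _format_float(rec.root_divergence),
            ])


# ---------------------------------------------------------------------------
# Divergence
# ---------------------------------------------------------------------------

def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def pairwise_divergence(a: str, b: str) -> float:
    """Fraction of mismatching sites among positions unambiguous in both.

    Positions carrying any non-ACGT code in either sequence are ignored.
    Symmetric by construction.
    """
    if len(a) != len(b):
        raise RepertoireError(
            f"length mismatch: {len(a)} vs {len(b)} (sequences must be aligned)")
    xa, xb = _as_bytes(a), _as_bytes(b)
    ok = np.isin(xa, list(_UNAMBIGUOUS)) & np.isin(xb, list(_UNAMBIGUOUS))
    n = int(ok.sum())
    if n == 0:
        raise RepertoireError("no comparable (unambiguous) positions")
    return float((xa[ok] != xb[ok]).sum() / n)


def root_divergence(record: UmiRecord) -> float:
    """Divergence of a record's V sequence from its germline ancestor.

    Returns the precomputed value when present, otherwise computes and
    stores it on the record.
    """
    if record.root_divergence is not None:
        return record.root_divergence
    if not record.germline_v:
        raise RepertoireError(
            f"{record.umi_id}: neither germline_v nor root_divergence available")
    d = pairwise_divergence(record.v_sequence, record.germline_v)
    record.root_divergence = d
    return d


def assign_root_divergences(records: Sequence[UmiRecord]) -> None:
    for rec in records:
        root_divergence(rec)


# ---------------------------------------------------------------------------
# Lineage clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _junction_identity(a: str, b: str) -> float:
    # equal lengths guaranteed by the grouping gate
    xa, xb = _as_bytes(a), _as_bytes(b)
    return float((xa == xb).mean())


def cluster_lineages(
    records: Sequence[UmiRecord],
    junction_identity_min: float = 0.85,
    require_same_vj: bool = True,
) -> int:
    """Assign dense lineage ids by single-linkage clonal grouping.

    Two records are linked iff they share V gene, J gene and junction length
    (when ``require_same_vj``) and their junction Hamming identity is at
    least ``junction_identity_min``. Single-linkage closure defines the
    lineages. Records without a junction become singleton lineages; their
    number is returned as a warning count.

    The assignment is invariant to input row order: records are canonically
    sorted by ``umi_id`` before linking, and lineage ids are dense from 0 in
    order of each cluster's smallest ``umi_id``.
    """
    order = sorted(range(len(records)), key=lambda i: records[i].umi_id)
    uf = _UnionFind(len(records))
    missing_junction = 0

    groups: dict = {}
    for idx in order:
        rec = records[idx]
        if not rec.junction:
            missing_junction += 1
            continue
        if require_same_vj:
            key = (rec.v_call, rec.j_call, len(rec.junction))
        else:
            key = (len(rec.junction),)
        groups.setdefault(key, []).append(idx)

    for members in groups.values():
        for i_pos, i in enumerate(members):
            ji = records[i].junction
            for j in members[i_pos + 1:]:
                if uf.find(i) == uf.find(j):
                    continue
                if _junction_identity(ji, records[j].junction) >= junction_identity_min:
                    uf.union(i, j)

    # dense ids ordered by the smallest umi_id in each cluster
    root_first: dict = {}
    for idx in order:
        root = uf.find(idx)
        root_first.setdefault(root, records[idx].umi_id)
    ranked = sorted(root_first, key=lambda r: root_first[r])
    dense = {root: k for k, root in enumerate(ranked)}
    for idx in range(len(records)):
        records[idx].lineage_id = dense[uf.find(idx)]
    return missing_junction


def lineage_summaries(records: Sequence[UmiRecord]) -> dict[int, Lineage]:
    """Tabulate per-lineage membership, follicle spread and sizes."""
    out: dict[int, Lineage] = {}
    for rec in records:
        if rec.lineage_id is None:
            raise RepertoireError("lineage_id not assigned; run cluster_lineages")
        lin = out.setdefault(rec.lineage_id, Lineage(lineage_id=rec.lineage_id))
        lin.members.append(rec.umi_id)
        if rec.germline_v and not lin.germline_v:
            lin.germline_v = rec.germline_v
    follicles: dict[int, set] = {lid: set() for lid in out}
    for rec in records:
        if rec.intrafollicular:
            follicles[rec.lineage_id].add(rec.follicle_id)
            out[rec.lineage_id].n_umis_intra += 1
    for lid, lin in out.items():
        lin.n_follicles = len(follicles[lid])
    return out


def follicle_map_from_records(
    records: Sequence[UmiRecord], max_pairs_per_follicle: int = 2000
) -> FollicleMap:
    """Centroids (member means) and the pooled median intra-follicle distance.

    For follicles with many members the pairwise distance set is estimated
    from the first ``max_pairs_per_follicle`` members (deterministic).
    """
    by_follicle: dict[int, list] = {}
    for rec in records:
        if rec.intrafollicular:
            by_follicle.setdefault(rec.follicle_id, []).append((rec.x, rec.y))
    if not by_follicle:
        raise RepertoireError("no intrafollicular records")
    centroids = {}
    dists = []
    for fid, pts in sorted(by_follicle.items()):
        arr = np.asarray(pts, dtype=float)
        centroids[fid] = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
        if len(arr) >= 2:
            sub = arr[:max_pairs_per_follicle]
            diff = sub[:, None, :] - sub[None, :, :]
            dmat = np.sqrt((diff ** 2).sum(axis=2))
            iu = np.triu_indices(len(sub), k=1)
            dists.append(dmat[iu])
    intra_median = float(np.median(np.concatenate(dists))) if dists else float("nan")
    return FollicleMap(
        follicle_ids=sorted(by_follicle),
        centroids=centroids,
        intra_median=intra_median,
    )
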