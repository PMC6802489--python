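"""Shared data model and readers/writers for every tabular and graph format
the pipeline touches.

Identifiers are treated as opaque strings and normalized on ingestion:
trimmed, case-folded, internal whitespace collapsed. The original spelling is
preserved as ``display_name``. A compound appearing under several herbs is a
single record whose ``herb_ids`` is the union of its memberships.
"""

from __future__ import annotations

import io as _stdio
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, InputError

logger = logging.getLogger(__name__)

INTERACTION_KINDS = ("compound-target", "target-disease", "target-pathway")

DESCRIPTOR_PREFIX = "desc_"


def normalize_id(raw: str) -> str:
    """Trim, collapse internal whitespace, and case-fold an identifier."""
    return " ".join(str(raw).strip().split()).casefold()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """One herb ingredient with its descriptors and pharmacokinetic scores.

    ``ob`` is the oral bioavailability in percent; ``dl`` the drug-likeness
    Tanimoto index in [0, 1], or ``None`` when not yet scored.
    """

    compound_id: str
    display_name: str
    herb_ids: frozenset[str]
    descriptors: tuple[float, ...]
    ob: float
    dl: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise InputError("compound_id must be non-empty")
        if not self.herb_ids:
            raise InputError(f"compound {self.compound_id!r}: herb_ids must be non-empty")
        if not all(np.isfinite(self.descriptors)):
            raise InputError(f"compound {self.compound_id!r}: non-finite descriptor")
        if not (np.isfinite(self.ob) and self.ob >= 0):
            raise InputError(f"compound {self.compound_id!r}: ob must be finite and >= 0")


@dataclass(frozen=True)
class CompoundTable:
    """An ordered collection of :class:`CompoundRecord` with shared descriptor names."""

    records: tuple[CompoundRecord, ...]
    descriptor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.compound_id in seen:
                raise InputError(f"duplicate compound_id {r.compound_id!r} after normalization")
            seen.add(r.compound_id)
            if len(r.descriptors) != len(self.descriptor_names):
                raise SchemaError(
                    f"compound {r.compound_id!r}: {len(r.descriptors)} descriptors, "
                    f"expected {len(self.descriptor_names)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {
                "compound_id": r.display_name,
                "herb": "|".join(sorted(r.herb_ids)),
                "ob": r.ob,
            }
            if r.dl is not None:
                row["dl"] = r.dl
            for name, v in zip(self.descriptor_names, r.descriptors):
                row[name] = v
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class HerbCatalog:
    """herb_id -> (display name, ordered compound id list), no duplicates per herb."""

    herbs: Mapping[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for hid, (_, cids) in self.herbs.items():
            if len(cids) != len(set(cids)):
                raise InputError(f"herb {hid!r}: duplicate compound ids in catalog")

    def herb_ids(self) -> list[str]:
        return sorted(self.herbs)

    def compounds_of(self, herb_id: str) -> tuple[str, ...]:
        return self.herbs[herb_id][1]

    def validate_against(self, table: CompoundTable) -> None:
        known = set(table.ids())
        for hid, (_, cids) in self.herbs.items():
            missing = [c for c in cids if c not in known]
            if missing:
                raise InputError(f"herb {hid!r}: unknown compound ids {missing}")


def catalog_from_table(table: CompoundTable) -> HerbCatalog:
    """Derive the herb catalog from compound herb memberships (sorted, deterministic)."""
    herbs: dict[str, list[str]] = {}
    for r in table.records:
        for h in r.herb_ids:
            herbs.setdefault(h, []).append(r.compound_id)
    return HerbCatalog({h: (h, tuple(sorted(cids))) for h, cids in sorted(herbs.items())})


@dataclass(frozen=True)
class InteractionRecord:
    """A single edge of one of the three bipartite relations."""

    left_id: str
    right_id: str
    kind: str
    evidence: frozenset[str] = frozenset()
    scores: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.left_id or not self.right_id:
            raise InputError("interaction endpoints must be non-empty")
        if self.kind not in INTERACTION_KINDS:
            raise InputError(f"unknown interaction kind {self.kind!r}")


@dataclass(frozen=True)
class AnnotationSet:
    """term_id -> (term name, member target ids), plus the background universe."""

    terms: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise InputError(f"term {tid!r} has no members")
            if not members <= self.universe:
                raise InputError(f"term {tid!r}: members outside declared universe")

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return "\t"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str, skip_blank_lines=True)
    df.columns = [str(c).strip() for c in df.columns]
    return df


DEFAULT_COMPOUND_SCHEMA = {"compound_id": "compound_id", "herb": "herb", "ob": "ob", "dl": "dl"}


def read_compound_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> CompoundTable:
    """Read a compound property table (TSV/CSV auto-detected, '#' comments skipped).

    Mandatory columns: compound id, herb, OB. Optional: dl. Descriptor columns
    are those prefixed ``desc_``. Rows whose normalized compound id coincides
    are merged into one record with the union of their herb memberships.
    """
    sch = dict(DEFAULT_COMPOUND_SCHEMA)
    if schema:
        sch.update(schema)
    df = _read_table(path)
    for key in ("compound_id", "herb", "ob"):
        if sch[key] not in df.columns:
            raise SchemaError(f"missing mandatory column {sch[key]!r}")
    desc_cols = [c for c in df.columns if c.startswith(DESCRIPTOR_PREFIX)]

    def _num(cell: str, col: str, row: int) -> float:
        try:
            return float(cell)
        except (TypeError, ValueError):
            raise ParseError(f"non-numeric value {cell!r} in column {col!r}, data row {row}")

    merged: dict[str, dict] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        cid = normalize_id(rec[sch["compound_id"]])
        if not cid:
            raise ParseError(f"blank compound id at data row {i}")
        herb = normalize_id(rec[sch["herb"]])
        ob = _num(rec[sch["ob"]], sch["ob"], i)
        dl = None
        if sch["dl"] in df.columns and pd.notna(rec.get(sch["dl"])) and str(rec.get(sch["dl"])).strip():
            dl = _num(rec[sch["dl"]], sch["dl"], i)
        descs = tuple(_num(rec[c], c, i) for c in desc_cols)
        if cid in merged:
            merged[cid]["herbs"].add(herb)
        else:
            order.append(cid)
            merged[cid] = {
                "display": str(rec[sch["compound_id"]]).strip(),
                "herbs": {herb},
                "ob": ob,
                "dl": dl,
                "descs": descs,
            }
    records = tuple(
        CompoundRecord(
            compound_id=cid,
            display_name=m["display"],
            herb_ids=frozenset(m["herbs"]),
            descriptors=m["descs"],
            ob=m["ob"],
            dl=m["dl"],
            source=str(path),
        )
        for cid, m in ((c, merged[c]) for c in order)
    )
    return CompoundTable(records=records, descriptor_names=tuple(desc_cols))


def read_edge_list(path: str | Path, kind: str) -> list[InteractionRecord]:
    """Read a two-column edge list with optional evidence/score columns.

    Exact duplicate (left, right) pairs are collapsed: evidence tags are
    unioned and the first-seen scores kept.
    """
    if kind not in INTERACTION_KINDS:
        raise InputError(f"unknown interaction kind {kind!r}")
    df = _read_table(path)
    if "left_id" not in df.columns or "right_id" not in df.columns:
        raise SchemaError("edge list needs columns 'left_id' and 'right_id'")
    score_cols = [c for c in df.columns if c not in ("left_id", "right_id", "evidence", "source")]
    merged: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        left = normalize_id(rec["left_id"]) if pd.notna(rec["left_id"]) else ""
        right = normalize_id(rec["right_id"]) if pd.notna(rec["right_id"]) else ""
        if not left or not right:
            raise ParseError(f"blank id at data row {i}")
        ev = set()
        for col in ("evidence", "source"):
            if col in df.columns and pd.notna(rec.get(col)) and str(rec[col]).strip():
                ev.update(t.strip() for t in str(rec[col]).split("|") if t.strip())
        scores = {}
        for c in score_cols:
            if pd.notna(rec.get(c)) and str(rec[c]).strip():
                try:
                    scores[c] = float(rec[c])
                except ValueError:
                    raise ParseError(f"non-numeric score {rec[c]!r} in column {c!r}, data row {i}")
        key = (left, right)
        if key in merged:
            merged[key]["ev"] |= ev
        else:
            order.append(key)
            merged[key] = {"ev": ev, "scores": scores}
    return [
        InteractionRecord(
            left_id=l,
            right_id=r,
            kind=kind,
            evidence=frozenset(merged[(l, r)]["ev"]),
            scores=merged[(l, r)]["scores"] or None,
        )
        for l, r in order
    ]


def read_annotation_gmt(
    path: str | Path, universe: Iterable[str] | None = None
) -> AnnotationSet:
    """Read a GMT file: ``term<TAB>description<TAB>member...`` per line.

    Terms with zero members are dropped with a logged warning. Unless a
    universe is supplied, it defaults to the union of all members.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
            tid = normalize_id(fields[0])
            name = fields[1].strip()
            members = frozenset(normalize_id(m) for m in fields[2:] if m.strip())
            if not members:
                logger.warning("GMT line %d: term %r has no members, dropped", lineno, tid)
                continue
            terms[tid] = (name, members)
    all_members = frozenset().union(*(m for _, m in terms.values())) if terms else frozenset()
    uni = frozenset(normalize_id(u) for u in universe) if universe is not None else all_members
    return AnnotationSet(terms=terms, universe=uni)


# ---------------------------------------------------------------------------
# network writers / readers (SIF, GraphML, edge-TSV)
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def write_network(net, path: str | Path, format: str = "tsv") -> Path:
    """Serialize a bipartite network.

    SIF is ``left<TAB>kind<TAB>right`` one edge per line; GraphML carries the
    partition kind and degree as node attributes; edge-TSV is a headered
    two-column table. ``read_network(write_network(net))`` reproduces the same
    node and edge sets.
    """
    import networkx as nx

    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise InputError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    edges = sorted(net.edges)
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for l, r in edges:
                fh.write(f"{l}\t{net.edge_kind}\t{r}\n")
    elif fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("left_id\tright_id\tkind\n")
            for l, r in edges:
                fh.write(f"{l}\t{r}\t{net.edge_kind}\n")
    else:
        g = nx.Graph(edge_kind=net.edge_kind)
        for n in sorted(net.left):
            g.add_node(n, partition=net.left_kind, degree=net.degree(n))
        for n in sorted(net.right):
            g.add_node(n, partition=net.right_kind, degree=net.degree(n))
        g.add_edges_from(edges)
        nx.write_graphml(g, path)
    return path


def read_network(path: str | Path, format: str = "tsv"):
    """Read back a network written by :func:`write_network`."""
    import networkx as nx

    from .networks import BipartiteNetwork

    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise InputError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        kinds = sorted({d["partition"] for _, d in g.nodes(data=True)})
        edge_kind = g.graph.get("edge_kind", "compound-target")
        left_kind, right_kind = edge_kind.split("-", 1)
        left = {n for n, d in g.nodes(data=True) if d["partition"] == left_kind}
        right = {n for n, d in g.nodes(data=True) if d["partition"] == right_kind}
        edges = set()
        for u, v in g.edges():
            edges.add((u, v) if u in left else (v, u))
        return BipartiteNetwork(
            left=frozenset(left), right=frozenset(right),
            edges=frozenset(edges), left_kind=left_kind, right_kind=right_kind,
        )
    pairs: list[tuple[str, str]] = []
    kind = None
    with open(path, "r", encoding="utf-8") as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if fmt == "tsv":
        lines = lines[1:]  # header
        for l in lines:
            a, b, k = l.split("\t")
            pairs.append((a, b))
            kind = k
    else:
        for l in lines:
            a, k, b = l.split("\t")
            pairs.append((a, b))
            kind = k
    kind = kind or "compound-target"
    left_kind, right_kind = kind.split("-", 1)
    return BipartiteNetwork(
        left=frozenset(p[0] for p in pairs),
        right=frozenset(p[1] for p in pairs),
        edges=frozenset(pairs),
        left_kind=left_kind,
        right_kind=right_kind,
    )


def write_compound_table(table: CompoundTable, path: str | Path) -> Path:
    """Write a compound table as TSV in the dialect :func:`read_compound_table` reads.

    Multi-herb records are expanded to one row per herb so that re-reading
    merges them back into identical records.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in table.records:
        for h in sorted(r.herb_ids):
            row = {"compound_id": r.display_name, "herb": h, "ob": repr(r.ob)}
            if r.dl is not None:
                row["dl"] = repr(r.dl)
            for name, v in zip(table.descriptor_names, r.descriptors):
                row[name] = repr(v)
            rows.append(row)
    cols = ["compound_id", "herb", "ob"]
    if any("dl" in r for r in rows):
        cols.append("dl")
    cols += list(table.descriptor_names)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    return path


def write_edge_list(records: Sequence[InteractionRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        row: dict = {"left_id": rec.left_id, "right_id": rec.right_id}
        if rec.evidence:
            row["evidence"] = "|".join(sorted(rec.evidence))
        if rec.scores:
            row.update({k: repr(v) for k, v in rec.scores.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
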