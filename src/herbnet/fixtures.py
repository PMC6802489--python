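"""Bundled fixture of the W-LHIT study's printed compound values, plus
loaders for its supplementary tables when the user supplies them.

The study prints 18 named compounds with their oral bioavailability (percent)
and drug-likeness values in the results text; those triples are packaged here
as a pass-through compound table (DL already set, so screening runs without
the original descriptor set). The full supplementary tables (SM1: the 51
active compounds; SM2: the 111 targets with compound-target and
target-disease interactions) are not redistributable and must be supplied as
CSV/TSV exports; :func:`load_sm1` and :func:`load_sm2` map them onto the
package's data model with flexible column matching.

The small demo edge list is synthetic: hand-built around the fixture
compounds so network statistics can be asserted by enumeration. It is not
the study's network.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ParseError, SchemaError
from .io import (
    CompoundRecord,
    CompoundTable,
    HerbCatalog,
    InteractionRecord,
    catalog_from_table,
    normalize_id,
    _read_table,
)
from .targets import DiseaseAnnotation

__all__ = ["wlhit_fixture", "FixtureStudy", "load_sm1", "load_sm2"]

# (display name, herb, OB %, DL) as printed in the study's results text
WLHIT_PRINTED_COMPOUNDS: tuple[tuple[str, str, float, float], ...] = (
    ("epoxyganoderiol B", "Ling Zhi", 42.30, 0.83),
    ("ganoderal B", "Ling Zhi", 42.19, 0.81),
    ("lucialdehyde C", "Ling Zhi", 42.26, 0.81),
    ("ergosterol peroxide", "Ling Zhi", 44.39, 0.82),
    ("corchoroside A", "Huang Lian", 104.95, 0.78),
    ("(R)-canadine", "Huang Lian", 55.37, 0.77),
    ("epiberberine", "Huang Lian", 43.09, 0.78),
    ("formononetin", "Huang Qi", 69.67, 0.21),
    ("folic acid", "Huang Qi", 68.96, 0.71),
    ("isomucronulatol", "Huang Qi", 67.67, 0.26),
    ("kaempferol", "Huang Qi", 41.88, 0.24),
    ("machiline", "He Ye", 79.64, 0.24),
    ("armepavine", "He Ye", 69.31, 0.29),
    ("isorhamnetin", "He Ye", 49.60, 0.31),
    ("betulinic acid", "Mu Gua", 55.38, 0.78),
    ("epicatechin", "Mu Gua", 48.96, 0.24),
    ("hesperetin", "Zhi Qiao", 70.31, 0.27),
    ("naringenin", "Zhi Qiao", 59.29, 0.21),
)

# synthetic demo network around the fixture compounds: 6 targets, 14 edges
_DEMO_EDGES: tuple[tuple[str, str], ...] = (
    ("hesperetin", "PTGS2"),
    ("naringenin", "PTGS2"),
    ("kaempferol", "PTGS2"),
    ("epicatechin", "PTGS2"),
    ("armepavine", "PTGS2"),
    ("machiline", "PTGS2"),
    ("(r)-canadine", "PPARG"),
    ("kaempferol", "PPARG"),
    ("isorhamnetin", "PPARG"),
    ("(r)-canadine", "DPP4"),
    ("hesperetin", "DPP4"),
    ("kaempferol", "ACHE"),
    ("epicatechin", "NOS2"),
    ("naringenin", "GSK3B"),
)


@dataclass(frozen=True)
class FixtureStudy:
    compounds: CompoundTable
    catalog: HerbCatalog
    demo_edges: tuple[InteractionRecord, ...]


def wlhit_fixture() -> FixtureStudy:
    """The packaged fixture: printed OB/DL triples plus a synthetic demo edge list."""
    records = tuple(
        CompoundRecord(
            compound_id=normalize_id(name),
            display_name=name,
            herb_ids=frozenset({normalize_id(herb)}),
            descriptors=(),
            ob=ob,
            dl=dl,
            source="printed-results",
        )
        for name, herb, ob, dl in WLHIT_PRINTED_COMPOUNDS
    )
    table = CompoundTable(records=records, descriptor_names=())
    edges = tuple(
        InteractionRecord(left_id=normalize_id(c), right_id=t, kind="compound-target",
                          evidence=frozenset({"demo"}))
        for c, t in _DEMO_EDGES
    )
    return FixtureStudy(compounds=table, catalog=catalog_from_table(table), demo_edges=edges)


def _find_column(df: pd.DataFrame, patterns: list[str], what: str, path) -> str:
    for pat in patterns:
        rx = re.compile(pat, re.IGNORECASE)
        for c in df.columns:
            if rx.search(str(c)):
                return c
    raise SchemaError(f"{path}: could not find a column for {what}; columns = {list(df.columns)}")


def load_sm1(path: str | Path) -> CompoundTable:
    """Load a user-supplied export of the active-compound supplementary table.

    Expects columns naming the molecule, its herb, OB and DL (matched
    case-insensitively; e.g. 'Molecule Name', 'Herb', 'OB (%)', 'DL').
    Returns a pass-through compound table ready for screening.
    """
    df = _read_table(path)
    col_name = _find_column(df, [r"molecul", r"compound", r"^name$", r"ingredient"], "compound name", path)
    col_herb = _find_column(df, [r"herb", r"source"], "herb", path)
    col_ob = _find_column(df, [r"\bob\b", r"bioavail"], "OB", path)
    col_dl = _find_column(df, [r"\bdl\b", r"drug.?lik"], "DL", path)
    merged: dict[str, dict] = {}
    order: list[str] = []
    for i, row in df.iterrows():
        name = str(row[col_name]).strip()
        if not name or name.lower() == "nan":
            raise ParseError(f"{path}: blank compound name at data row {i + 1}")
        cid = normalize_id(name)
        try:
            ob = float(row[col_ob])
            dl = float(row[col_dl])
        except (TypeError, ValueError):
            raise ParseError(f"{path}: non-numeric OB/DL at data row {i + 1}")
        herb = normalize_id(row[col_herb])
        if cid in merged:
            merged[cid]["herbs"].add(herb)
        else:
            order.append(cid)
            merged[cid] = {"display": name, "herbs": {herb}, "ob": ob, "dl": dl}
    records = tuple(
        CompoundRecord(
            compound_id=cid,
            display_name=m["display"],
            herb_ids=frozenset(m["herbs"]),
            descriptors=(),
            ob=m["ob"],
            dl=m["dl"],
            source=str(path),
        )
        for cid, m in ((c, merged[c]) for c in order)
    )
    return CompoundTable(records=records, descriptor_names=())


def load_sm2(
    ct_path: str | Path, td_path: str | Path | None = None
) -> tuple[list[InteractionRecord], list[DiseaseAnnotation]]:
    """Load user-supplied exports of the interaction supplementary tables.

    ``ct_path`` holds compound-target pairs (columns naming the molecule and
    the target); ``td_path`` optionally holds target-disease pairs. Returns
    deduplicated compound-target records and disease annotations.
    """
    df = _read_table(ct_path)
    col_c = _find_column(df, [r"molecul", r"compound", r"ingredient"], "compound", ct_path)
    col_t = _find_column(df, [r"target", r"protein", r"gene"], "target", ct_path)
    seen: set[tuple[str, str]] = set()
    ct: list[InteractionRecord] = []
    for i, row in df.iterrows():
        c = normalize_id(row[col_c])
        t = normalize_id(row[col_t])
        if not c or not t or c == "nan" or t == "nan":
            raise ParseError(f"{ct_path}: blank id at data row {i + 1}")
        if (c, t) in seen:
            continue
        seen.add((c, t))
        ct.append(InteractionRecord(left_id=c, right_id=t, kind="compound-target",
                                    evidence=frozenset({"sm2"})))
    annotations: list[DiseaseAnnotation] = []
    if td_path is not None:
        df2 = _read_table(td_path)
        col_t2 = _find_column(df2, [r"target", r"protein", r"gene"], "target", td_path)
        col_d = _find_column(df2, [r"disease"], "disease", td_path)
        for i, row in df2.iterrows():
            t = normalize_id(row[col_t2])
            d = normalize_id(row[col_d])
            if not t or not d or t == "nan" or d == "nan":
                raise ParseError(f"{td_path}: blank id at data row {i + 1}")
            annotations.append(DiseaseAnnotation(target_id=t, disease_id=d, evidence="sm2"))
    return ct, annotations
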