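"""OB/DL threshold screening that selects the "active compound" set.

Two pharmacokinetic filters run jointly: oral bioavailability (OB, percent)
and drug-likeness (DL, Tanimoto index). A compound is retained iff
OB >= ob_min and DL >= dl_min, both inclusive. The defaults (40%, 0.18) are
the criteria the study outputs obey; a stricter OB >= 50% variant is also in
circulation for herbal screens and is available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConsistencyError, InputError
from .io import CompoundRecord, CompoundTable, HerbCatalog

__all__ = ["ScreenConfig", "ScreenReport", "screen_compounds", "per_herb_summary"]


@dataclass(frozen=True)
class ScreenConfig:
    ob_min: float = 40.0
    dl_min: float = 0.18

    def __post_init__(self) -> None:
        if self.ob_min < 0:
            raise InputError("ob_min must be >= 0")
        if not (0.0 <= self.dl_min <= 1.0):
            raise InputError("dl_min must be in [0, 1]")


@dataclass(frozen=True)
class ScreenReport:
    """Retained and rejected compounds plus per-herb retained counts.

    ``rejected_reasons`` names every failed criterion per rejected compound.
    A compound belonging to several herbs counts once towards each herb.
    """

    retained: tuple[CompoundRecord, ...]
    rejected: tuple[CompoundRecord, ...]
    rejected_reasons: dict[str, tuple[str, ...]]
    per_herb_counts: dict[str, int]
    config: ScreenConfig

    def summary(self) -> dict:
        return {
            "n_input": len(self.retained) + len(self.rejected),
            "n_retained": len(self.retained),
            "n_rejected": len(self.rejected),
            "ob_min": self.config.ob_min,
            "dl_min": self.config.dl_min,
            "per_herb_counts": dict(sorted(self.per_herb_counts.items())),
        }


def screen_compounds(table: CompoundTable, cfg: ScreenConfig | None = None) -> ScreenReport:
    """Apply the joint OB/DL filter, preserving input order.

    Every record must carry a finite DL (scored upstream or supplied in the
    input table); an unset DL is an input error naming the compound.
    """
    cfg = cfg or ScreenConfig()
    retained: list[CompoundRecord] = []
    rejected: list[CompoundRecord] = []
    reasons: dict[str, tuple[str, ...]] = {}
    per_herb: dict[str, int] = {}
    for rec in table.records:
        if rec.dl is None or pd.isna(rec.dl):
            raise InputError(f"compound {rec.compound_id!r} has no DL value; score it first")
        failed = []
        if rec.ob < cfg.ob_min:
            failed.append(f"ob {rec.ob:g} < {cfg.ob_min:g}")
        if rec.dl < cfg.dl_min:
            failed.append(f"dl {rec.dl:g} < {cfg.dl_min:g}")
        if failed:
            rejected.append(rec)
            reasons[rec.compound_id] = tuple(failed)
        else:
            retained.append(rec)
            for h in rec.herb_ids:
                per_herb[h] = per_herb.get(h, 0) + 1
    return ScreenReport(
        retained=tuple(retained),
        rejected=tuple(rejected),
        rejected_reasons=reasons,
        per_herb_counts=per_herb,
        config=cfg,
    )


def per_herb_summary(report: ScreenReport, catalog: HerbCatalog) -> pd.DataFrame:
    """Per-herb input and retained counts, ordered by herb_id.

    Multi-herb compounds are counted once per herb, so the retained column can
    sum to more than the number of distinct retained compounds.
    """
    seen = {r.compound_id for r in report.retained} | {r.compound_id for r in report.rejected}
    retained_ids = {r.compound_id for r in report.retained}
    rows = []
    for hid in catalog.herb_ids():
        cids = catalog.compounds_of(hid)
        missing = [c for c in cids if c not in seen]
        if missing:
            raise ConsistencyError(f"herb {hid!r}: compounds {missing} absent from screen input")
        rows.append({
            "herb_id": hid,
            "n_input": len(cids),
            "n_retained": sum(c in retained_ids for c in cids),
        })
    return pd.DataFrame(rows, columns=["herb_id", "n_input", "n_retained"])
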