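"""Drug-likeness scoring with the continuous Tanimoto index.

A compound's drug-likeness (DL) is the Tanimoto similarity

    f(A, B) = A.B / (|A|^2 + |B|^2 - A.B)

between its molecular-descriptor vector A and the mean descriptor vector B of
a reference library of known drugs. Raw descriptors live on wildly different
scales (molecular weight vs. logP vs. H-bond counts), so each descriptor is
min-max scaled to [0, 1] using the reference library's range before either
the mean vector or a query is formed; queries are clipped into [0, 1]. Under
this convention f is bounded in [0, 1] and a fixed threshold (0.18, the mean
DL of the DrugBank collection) is meaningful across descriptor sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InputError, SchemaError
from .io import CompoundTable

__all__ = ["ReferenceProfile", "DLScore", "build_reference_profile", "dl_index", "score_compounds"]


@dataclass(frozen=True)
class ReferenceProfile:
    """Mean (min-max scaled) descriptor vector of a reference drug library."""

    descriptor_names: tuple[str, ...]
    mean_vector: tuple[float, ...]
    scaling: tuple[tuple[float, float], ...]  # per-descriptor (min, max) of the library
    library_size: int
    constant_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        k = len(self.descriptor_names)
        if len(self.mean_vector) != k or len(self.scaling) != k:
            raise InputError("profile vectors and descriptor names have mismatched lengths")
        if self.library_size < 1:
            raise InputError("library_size must be >= 1")
        mv = np.asarray(self.mean_vector)
        if not np.all(np.isfinite(mv)) or mv.min() < 0 or mv.max() > 1:
            raise InputError("scaled mean_vector entries must be finite and in [0, 1]")

    def rescale(self, raw: np.ndarray) -> np.ndarray:
        """Min-max scale raw descriptor rows with the library's ranges, clipped to [0, 1]."""
        lo = np.array([s[0] for s in self.scaling])
        hi = np.array([s[1] for s in self.scaling])
        span = hi - lo
        safe = np.where(span > 0, span, 1.0)
        scaled = (np.atleast_2d(raw) - lo) / safe
        scaled[:, span == 0] = 0.0
        return np.clip(scaled, 0.0, 1.0)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "descriptor_names": list(self.descriptor_names),
            "mean_vector": list(self.mean_vector),
            "scaling": [list(s) for s in self.scaling],
            "library_size": self.library_size,
            "constant_columns": list(self.constant_columns),
        }, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceProfile":
        d = json.loads(Path(path).read_text())
        return cls(
            descriptor_names=tuple(d["descriptor_names"]),
            mean_vector=tuple(d["mean_vector"]),
            scaling=tuple(tuple(s) for s in d["scaling"]),
            library_size=int(d["library_size"]),
            constant_columns=tuple(d.get("constant_columns", ())),
        )


@dataclass(frozen=True)
class DLScore:
    compound_id: str
    dl: float


def build_reference_profile(library: pd.DataFrame) -> ReferenceProfile:
    """Build the reference profile (symbol B) from a descriptor matrix.

    Per-column (min, max) of the library defines the scaling; the mean vector
    is the column mean after scaling. Constant columns scale to zero and are
    flagged in ``constant_columns``.
    """
    if library is None or len(library) == 0 or library.shape[1] == 0:
        raise InputError("reference library is empty")
    names = tuple(str(c) for c in library.columns)
    values = library.to_numpy(dtype=float)
    for j, name in enumerate(names):
        if not np.all(np.isfinite(values[:, j])):
            raise InputError(f"reference library column {name!r} contains non-finite values")
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    constant = span == 0
    safe = np.where(constant, 1.0, span)
    scaled = (values - lo) / safe
    scaled[:, constant] = 0.0
    mean = scaled.mean(axis=0)
    return ReferenceProfile(
        descriptor_names=names,
        mean_vector=tuple(float(m) for m in mean),
        scaling=tuple((float(a), float(b)) for a, b in zip(lo, hi)),
        library_size=len(library),
        constant_columns=tuple(n for n, c in zip(names, constant) if c),
    )


def dl_index(a: Sequence[float], b: Sequence[float]) -> float:
    """Continuous Tanimoto coefficient f(A,B) = A.B / (|A|^2 + |B|^2 - A.B).

    Symmetric; equals 1 when a == b != 0 and 0 when the vectors are
    orthogonal. Undefined (0/0) when both vectors are zero.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.ndim != 1 or bv.ndim != 1 or av.shape != bv.shape:
        raise InputError(f"descriptor vectors have mismatched lengths {av.shape} vs {bv.shape}")
    if not (np.all(np.isfinite(av)) and np.all(np.isfinite(bv))):
        raise InputError("descriptor vectors must be finite")
    dot = float(av @ bv)
    denom = float(av @ av) + float(bv @ bv) - dot
    if denom == 0.0:
        if dot == 0.0:
            raise DomainError("Tanimoto undefined for two zero vectors (0/0)")
        return 1.0
    return dot / denom


def score_compounds(
    table: CompoundTable, ref: ReferenceProfile, *, on_missing: str = "error"
) -> list[DLScore]:
    """Score every compound in the table against the reference profile.

    Descriptor columns are matched to the profile by name (order-insensitive),
    rescaled with the library's min-max ranges, clipped to [0, 1], and scored
    with :func:`dl_index` against the scaled mean vector. Output is aligned
    1:1 with the input records.

    ``on_missing`` controls compounds whose descriptor vector is entirely
    zero after scaling (a degenerate query, 0/0 against a zero profile):
    ``"error"`` raises, ``"skip"`` assigns ``nan``.
    """
    if on_missing not in ("error", "skip"):
        raise InputError("on_missing must be 'error' or 'skip'")
    table_names = set(table.descriptor_names)
    ref_names = set(ref.descriptor_names)
    if table_names != ref_names:
        diff = sorted(table_names ^ ref_names)
        raise SchemaError(f"descriptor names differ between table and profile: {diff}")
    order = [table.descriptor_names.index(n) for n in ref.descriptor_names]
    raw = np.array([[r.descriptors[j] for j in order] for r in table.records], dtype=float)
    if raw.size == 0:
        return []
    scaled = ref.rescale(raw)
    mean = np.asarray(ref.mean_vector)
    out: list[DLScore] = []
    for rec, row in zip(table.records, scaled):
        if not row.any():
            if on_missing == "error":
                raise DomainError(f"compound {rec.compound_id!r}: zero descriptor vector")
            out.append(DLScore(rec.compound_id, float("nan")))
            continue
        out.append(DLScore(rec.compound_id, dl_index(row, mean)))
    return out
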