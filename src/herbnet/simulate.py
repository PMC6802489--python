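"""Synthetic multi-herb studies with known ground truth.

The generator emits every input the pipeline consumes — herb/compound tables
with descriptors and OB values, a reference descriptor library, scored
target predictions with decoys, curated edges, disease annotations, and a
pathway GMT with planted enriched terms — plus a truth record stating which
compounds are active, which are hubs, and which pathways were planted.

Default shapes mirror the six-herb weight-loss formula study: 541 compounds
split 225/48/85/87/80/16 across herbs, 51 actives, 111 targets, an expected
676 compound-target edges with one hub compound of degree 70, eight disease
classes, and 24 pathways over a 500-target annotation universe.

Planting is done with wide margins so truth is recoverable by construction:
actives draw OB above 41 and descriptors tight around the reference centroid
(drug-likeness near 1); inactives fail OB (OB < 38), drug-likeness (scaled
descriptors near the library minimum), or both. True prediction edges score
above both classifier cutoffs, decoys below both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    AnnotationSet,
    CompoundRecord,
    CompoundTable,
    HerbCatalog,
    InteractionRecord,
    catalog_from_table,
    write_compound_table,
    write_edge_list,
)
from .targets import DEFAULT_DISEASE_VOCAB, DiseaseAnnotation, TargetPrediction

__all__ = ["StudyConfig", "SyntheticStudy", "generate_study"]

# per-disease annotation rates: distinct-target counts of the study's
# target-disease network divided by its 111 targets
DEFAULT_DISEASE_RATES: dict[str, float] = {
    "obesity": 28 / 111,
    "cardiovascular disease": 17 / 111,
    "diabetes": 20 / 111,
    "fatty liver": 14 / 111,
    "gastrointestinal disease": 4 / 111,
    "osteoarthritis": 6 / 111,
    "inflammation": 15 / 111,
    "cancer": 11 / 111,
}


@dataclass(frozen=True)
class StudyConfig:
    """Shapes and effect sizes of a generated study (defaults: study scale)."""

    n_herbs: int = 6
    compounds_per_herb: tuple[int, ...] = (225, 48, 85, 87, 80, 16)
    cross_herb_overlap_rate: float = 0.0
    reference_library_size: int = 6511
    n_descriptors: int = 8
    active_fraction: float = 51 / 541
    n_targets: int = 111
    # non-hub actives average this many targets; with one hub of degree 70
    # the expected edge count is 50 * 12.12 + 70 = 676
    mean_targets_per_active: float = 12.12
    hub_compound_count: int = 1
    hub_degree: int = 70
    disease_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_RATES)
    )
    n_pathways: int = 24
    pathway_size_range: tuple[int, int] = (10, 30)
    planted_enriched_pathways: int = 2
    planted_overlap_strength: float = 0.75
    pathway_universe_size: int = 500
    n_decoy_predictions: int = 200
    curated_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_herbs < 1:
            problems.append("n_herbs must be >= 1")
        if len(self.compounds_per_herb) != self.n_herbs:
            problems.append("compounds_per_herb length must equal n_herbs")
        if any(c < 1 for c in self.compounds_per_herb):
            problems.append("compounds_per_herb entries must be >= 1")
        for name in ("cross_herb_overlap_rate", "active_fraction",
                     "planted_overlap_strength", "curated_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must be in [0, 1]")
        if self.reference_library_size < 2:
            problems.append("reference_library_size must be >= 2")
        if self.n_descriptors < 1:
            problems.append("n_descriptors must be >= 1")
        if self.n_targets < 1:
            problems.append("n_targets must be >= 1")
        if self.hub_degree > self.n_targets:
            problems.append("hub_degree cannot exceed n_targets")
        if self.mean_targets_per_active < 1:
            problems.append("mean_targets_per_active must be >= 1")
        if self.planted_enriched_pathways > self.n_pathways:
            problems.append("planted_enriched_pathways cannot exceed n_pathways")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            problems.append("pathway_size_range must satisfy 1 <= lo <= hi")
        if self.pathway_universe_size < self.n_targets + hi:
            problems.append("pathway_universe_size too small for targets plus one pathway")
        if any(not (0.0 <= r <= 1.0) for r in self.disease_rates.values()):
            problems.append("disease rates must be in [0, 1]")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete generated study plus its ground-truth record."""

    config: StudyConfig
    compounds: CompoundTable
    catalog: HerbCatalog
    reference_library: pd.DataFrame
    predictions: tuple[TargetPrediction, ...]
    curated: tuple[InteractionRecord, ...]
    disease_annotations: tuple[DiseaseAnnotation, ...]
    pathways: AnnotationSet
    truth: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every pipeline input file (formats the readers accept) plus truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["compounds"] = write_compound_table(self.compounds, out / "compounds.tsv")
        lib = out / "reference_library.tsv"
        self.reference_library.to_csv(lib, sep="\t", index=False)
        paths["reference_library"] = lib
        pred = out / "predictions.tsv"
        pd.DataFrame([
            {"left_id": p.compound_id, "right_id": p.target_id,
             "svm": repr(p.svm_score), "rf": repr(p.rf_score), "source": p.source}
            for p in self.predictions
        ]).to_csv(pred, sep="\t", index=False)
        paths["predictions"] = pred
        paths["curated"] = write_edge_list(self.curated, out / "curated.tsv")
        dis = out / "disease_annotations.tsv"
        pd.DataFrame([
            {"left_id": a.target_id, "right_id": a.disease_id, "evidence": a.evidence}
            for a in self.disease_annotations
        ]).to_csv(dis, sep="\t", index=False)
        paths["disease_annotations"] = dis
        gmt = out / "pathways.gmt"
        with open(gmt, "w", encoding="utf-8") as fh:
            for tid in sorted(self.pathways.terms):
                name, members = self.pathways.terms[tid]
                fh.write("\t".join([tid, name, *sorted(members)]) + "\n")
        paths["pathways"] = gmt
        tr = out / "truth.json"
        tr.write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        paths["truth"] = tr
        return paths


def _herb_assignment(cfg: StudyConfig, rng: np.random.Generator) -> dict[str, set[str]]:
    """compound_id -> herb ids; overlap rate reuses existing compounds in later herbs."""
    herbs = [f"herb{h + 1}" for h in range(cfg.n_herbs)]
    membership: dict[str, set[str]] = {}
    counter = 0
    pool: list[str] = []
    for h, n_comp in zip(herbs, cfg.compounds_per_herb):
        chosen: set[str] = set()
        for _ in range(n_comp):
            reuse = (
                pool
                and cfg.cross_herb_overlap_rate > 0
                and rng.random() < cfg.cross_herb_overlap_rate
            )
            candidates = [c for c in pool if c not in chosen] if reuse else []
            if candidates:
                cid = candidates[int(rng.integers(len(candidates)))]
            else:
                counter += 1
                cid = f"c{counter:04d}"
                pool.append(cid)
            chosen.add(cid)
            membership.setdefault(cid, set()).add(h)
    return membership


def generate_study(cfg: StudyConfig | None = None) -> SyntheticStudy:
    """Generate a fully reproducible synthetic study from a config and its seed."""
    cfg = cfg or StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    desc_names = tuple(f"desc_{j + 1}" for j in range(cfg.n_descriptors))

    # reference drug library: independent normal descriptors on assorted scales
    mu = rng.uniform(20.0, 300.0, cfg.n_descriptors)
    sigma = 0.1 * np.abs(mu) + 1.0
    lib = rng.normal(mu, sigma, size=(cfg.reference_library_size, cfg.n_descriptors))
    library = pd.DataFrame(lib, columns=list(desc_names))
    lib_lo = lib.min(axis=0)
    lib_hi = lib.max(axis=0)

    membership = _herb_assignment(cfg, rng)
    compound_ids = sorted(membership)
    n_compounds = len(compound_ids)
    n_active = int(round(cfg.active_fraction * n_compounds))
    active_ids = sorted(rng.choice(compound_ids, size=n_active, replace=False).tolist())
    active_set = set(active_ids)

    records = []
    for cid in compound_ids:
        if cid in active_set:
            ob = min(41.0 + rng.exponential(18.0), 110.0)
            descs = rng.normal(mu, 0.2 * sigma)
        else:
            flavor = rng.choice(["ob", "dl", "both"])
            if flavor in ("ob", "both"):
                ob = rng.uniform(5.0, 38.0)
            else:
                ob = rng.uniform(45.0, 90.0)
            if flavor in ("dl", "both"):
                u = rng.uniform(0.005, 0.05, cfg.n_descriptors)
                descs = lib_lo + u * (lib_hi - lib_lo)
            else:
                descs = rng.normal(mu, 0.2 * sigma)
        records.append(CompoundRecord(
            compound_id=cid,
            display_name=cid.upper(),
            herb_ids=frozenset(membership[cid]),
            descriptors=tuple(float(x) for x in descs),
            ob=float(ob),
            source="synthetic",
        ))
    compounds = CompoundTable(records=tuple(records), descriptor_names=desc_names)
    catalog = catalog_from_table(compounds)

    # compound-target truth: hubs get exactly hub_degree targets, the rest
    # a shifted-Poisson count capped below the hub degree
    target_ids = [f"t{j + 1:03d}" for j in range(cfg.n_targets)]
    hubs = active_ids[: cfg.hub_compound_count]
    true_edges: dict[str, list[str]] = {}
    for cid in active_ids:
        if cid in hubs:
            n_t = cfg.hub_degree
        else:
            lam = max(cfg.mean_targets_per_active - 1.0, 0.0)
            n_t = 1 + int(rng.poisson(lam))
            n_t = min(n_t, cfg.n_targets, max(cfg.hub_degree - 1, 1))
        chosen = rng.choice(target_ids, size=n_t, replace=False)
        true_edges[cid] = sorted(chosen.tolist())
    edge_pairs = [(c, t) for c in active_ids for t in true_edges[c]]

    predictions = [
        TargetPrediction(
            compound_id=c, target_id=t,
            svm_score=float(rng.uniform(0.82, 0.99)),
            rf_score=float(rng.uniform(0.72, 0.99)),
            source="dual-classifier",
        )
        for c, t in edge_pairs
    ]
    true_pair_set = set(edge_pairs)
    n_decoys = 0
    while n_decoys < cfg.n_decoy_predictions:
        c = compound_ids[int(rng.integers(n_compounds))]
        t = target_ids[int(rng.integers(cfg.n_targets))]
        if (c, t) in true_pair_set:
            continue
        predictions.append(TargetPrediction(
            compound_id=c, target_id=t,
            svm_score=float(rng.uniform(0.05, 0.795)),
            rf_score=float(rng.uniform(0.05, 0.695)),
            source="dual-classifier",
        ))
        n_decoys += 1

    n_curated = int(round(cfg.curated_fraction * len(edge_pairs)))
    curated_idx = sorted(rng.choice(len(edge_pairs), size=n_curated, replace=False).tolist())
    curated = tuple(
        InteractionRecord(
            left_id=edge_pairs[i][0], right_id=edge_pairs[i][1],
            kind="compound-target", evidence=frozenset({"curated_db"}),
        )
        for i in curated_idx
    )

    annotations = []
    diseases = sorted(cfg.disease_rates)
    for t in target_ids:
        for d in diseases:
            if rng.random() < cfg.disease_rates[d]:
                annotations.append(DiseaseAnnotation(target_id=t, disease_id=d, evidence="synthetic_db"))

    # pathway annotations over a universe larger than the study's target set
    hit_targets = sorted({t for _, t in edge_pairs})
    background = [f"b{j + 1:03d}" for j in range(cfg.pathway_universe_size - cfg.n_targets)]
    universe = frozenset(target_ids) | frozenset(background)
    not_hit = sorted(universe - set(hit_targets))
    lo, hi = cfg.pathway_size_range
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted = [f"p{j + 1:03d}" for j in range(cfg.planted_enriched_pathways)]
    for j in range(cfg.n_pathways):
        tid = f"p{j + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        if tid in planted:
            k_in = max(1, int(round(cfg.planted_overlap_strength * size)))
            k_in = min(k_in, len(hit_targets), size)
            members = set(rng.choice(hit_targets, size=k_in, replace=False).tolist())
            rest = rng.choice(not_hit, size=size - k_in, replace=False)
            members.update(rest.tolist())
        else:
            members = set(rng.choice(sorted(universe), size=size, replace=False).tolist())
        terms[tid] = (f"pathway {j + 1}", frozenset(members))
    pathways = AnnotationSet(terms=terms, universe=universe)

    truth = {
        "seed": cfg.seed,
        "active_ids": active_ids,
        "hub_ids": hubs,
        "hub_degree": cfg.hub_degree,
        "true_edges": sorted([list(p) for p in edge_pairs]),
        "n_true_edges": len(edge_pairs),
        "planted_pathways": planted,
        "n_targets_hit": len(hit_targets),
    }
    return SyntheticStudy(
        config=cfg,
        compounds=compounds,
        catalog=catalog,
        reference_library=library,
        predictions=tuple(predictions),
        curated=curated,
        disease_annotations=tuple(annotations),
        pathways=pathways,
        truth=truth,
    )
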