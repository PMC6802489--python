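"""End-to-end orchestration: ingest -> DL score -> screen -> target fishing ->
networks -> enrichment, with a validated config and a checksummed run manifest.

Each stage writes its tabular outputs into the run directory; the manifest
records the config, the seed, per-stage row counts, and a SHA-256 checksum of
every file so that re-runs on identical inputs are verifiably byte-identical.
If a compound table already carries DL values the scoring stage passes them
through; otherwise a reference descriptor library is required.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .druglikeness import build_reference_profile, score_compounds
from .enrichment import enrich, kappa_group_terms, results_to_frame
from .errors import ConfigError, HerbnetError, InputError
from .io import (
    CompoundRecord,
    CompoundTable,
    InteractionRecord,
    catalog_from_table,
    read_compound_table,
    read_edge_list,
    read_annotation_gmt,
    write_network,
)
from .networks import build_bipartite, network_summary, per_herb_disease_counts
from .screen import ScreenConfig, per_herb_summary, screen_compounds
from .targets import (
    DEFAULT_DISEASE_VOCAB,
    DiseaseAnnotation,
    TargetPrediction,
    filter_predictions,
    map_targets_to_diseases,
    merge_target_sources,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineStageError", "analyze"]


class PipelineStageError(HerbnetError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


class ScreenSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ob_min: float = Field(40.0, ge=0)
    dl_min: float = Field(0.18, ge=0, le=1)


class FishingSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    svm_min: float = Field(0.8, ge=0, le=1)
    rf_min: float = Field(0.7, ge=0, le=1)
    strict: bool = True


class EnrichmentSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = Field(0.05, gt=0, le=1)
    adjust: Literal["none", "bh"] = "none"
    kappa_min: float = Field(0.4, ge=-1, le=1)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    compounds: Path
    reference_library: Optional[Path] = None
    predictions: Optional[Path] = None
    curated: list[Path] = Field(default_factory=list)
    disease_annotations: Optional[Path] = None
    pathways_gmt: Optional[Path] = None
    disease_vocabulary: list[str] = Field(default_factory=lambda: list(DEFAULT_DISEASE_VOCAB))
    screen: ScreenSettings = Field(default_factory=ScreenSettings)
    fishing: FishingSettings = Field(default_factory=FishingSettings)
    enrichment: EnrichmentSettings = Field(default_factory=EnrichmentSettings)
    export_formats: list[Literal["sif", "graphml", "tsv"]] = Field(default_factory=lambda: ["tsv"])
    out_dir: Path = Path("herbnet_run")
    seed: int = 0

    def check_paths(self) -> None:
        missing = []
        for label, p in [("compounds", self.compounds),
                         ("reference_library", self.reference_library),
                         ("predictions", self.predictions),
                         ("disease_annotations", self.disease_annotations),
                         ("pathways_gmt", self.pathways_gmt),
                         *[(f"curated[{i}]", c) for i, c in enumerate(self.curated)]]:
            if p is not None and not Path(p).exists():
                missing.append(f"{label}: {p}")
        if missing:
            raise ConfigError("missing input files: " + "; ".join(missing))


class _DuplicateKeyLoader(yaml.SafeLoader):
    pass


def _no_dup_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise ConfigError(f"duplicate key {key!r} in config")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_DuplicateKeyLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_dup_mapping
)


def _dup_hook(pairs):
    d = {}
    for k, v in pairs:
        if k in d:
            raise ConfigError(f"duplicate key {k!r} in config")
        d[k] = v
    return d


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML or JSON config; reports all problems at once."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text, object_pairs_hook=_dup_hook)
    else:
        data = yaml.load(text, Loader=_DuplicateKeyLoader)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    try:
        cfg = PipelineConfig(**data)
    except ValidationError as e:
        problems = "; ".join(
            f"{'.'.join(str(x) for x in err['loc'])}: {err['msg']}" for err in e.errors()
        )
        raise ConfigError(f"invalid config: {problems}") from None
    # resolve relative paths against the config file's directory
    base = path.parent
    def _resolve(p):
        return p if p is None or Path(p).is_absolute() else base / p
    cfg = cfg.model_copy(update={
        "compounds": _resolve(cfg.compounds),
        "reference_library": _resolve(cfg.reference_library),
        "predictions": _resolve(cfg.predictions),
        "disease_annotations": _resolve(cfg.disease_annotations),
        "pathways_gmt": _resolve(cfg.pathways_gmt),
        "curated": [_resolve(c) for c in cfg.curated],
        "out_dir": _resolve(cfg.out_dir),
    })
    cfg.check_paths()
    return cfg


def _with_dl(table: CompoundTable, reference_library: pd.DataFrame | None) -> CompoundTable:
    """Attach DL values: pass-through when present, otherwise score against the library."""
    if all(r.dl is not None for r in table.records):
        return table
    if reference_library is None:
        raise InputError(
            "compound table lacks DL values and no reference library was supplied"
        )
    profile = build_reference_profile(reference_library[list(table.descriptor_names)])
    scores = score_compounds(table, profile)
    records = tuple(
        CompoundRecord(
            compound_id=r.compound_id, display_name=r.display_name, herb_ids=r.herb_ids,
            descriptors=r.descriptors, ob=r.ob, dl=s.dl, source=r.source,
        )
        for r, s in zip(table.records, scores)
    )
    return CompoundTable(records=records, descriptor_names=table.descriptor_names)


def analyze(
    compounds: CompoundTable,
    *,
    reference_library: pd.DataFrame | None = None,
    predictions: list[TargetPrediction] | None = None,
    curated: list[list[InteractionRecord]] | None = None,
    disease_annotations: list[DiseaseAnnotation] | None = None,
    annotations=None,
    disease_vocabulary=DEFAULT_DISEASE_VOCAB,
    screen_cfg: ScreenConfig | None = None,
    svm_min: float = 0.8,
    rf_min: float = 0.7,
    strict: bool = True,
    alpha: float = 0.05,
    filter_on: str = "raw",
) -> dict:
    """Run the full analysis on in-memory objects; returns every stage product.

    This is the library-level core used by the file-based pipeline, the tests
    and the acceptance script.
    """
    scored = _with_dl(compounds, reference_library)
    report = screen_compounds(scored, screen_cfg)
    retained_ids = {r.compound_id for r in report.retained}
    out: dict = {"scored": scored, "screen_report": report}

    if predictions is None:
        return out
    kept = filter_predictions(predictions, svm_min, rf_min, strict=strict)
    merged = merge_target_sources(kept, curated or [])
    ct_edges = [e for e in merged if e.left_id in retained_ids]
    herb_attrs = {
        r.compound_id: {"herb_ids": sorted(r.herb_ids)} for r in report.retained
    }
    ct_net = build_bipartite(ct_edges, "compound", "target", node_attrs=herb_attrs)
    out.update({
        "merged_edges": merged,
        "ct_edges": ct_edges,
        "ct_network": ct_net,
        "ct_summary": network_summary(ct_net),
    })

    if disease_annotations is not None:
        td_edges = map_targets_to_diseases(ct_net.right, disease_annotations,
                                           disease_vocabulary)
        td_net = build_bipartite(td_edges, "target", "disease")
        out.update({
            "td_edges": td_edges,
            "td_network": td_net,
            "td_summary": network_summary(td_net),
            "herb_disease_counts": per_herb_disease_counts(ct_net, td_edges),
        })

    if annotations is not None:
        results = enrich(ct_net.right, annotations, alpha=alpha, filter_on=filter_on)
        tp_edges = [
            InteractionRecord(left_id=t, right_id=r.term_id, kind="target-pathway")
            for r in results if r.retained for t in sorted(r.members_hit)
        ]
        tp_net = build_bipartite(tp_edges, "target", "pathway") if tp_edges else None
        out.update({
            "enrichment": results,
            "tp_network": tp_net,
            "tp_summary": network_summary(tp_net) if tp_net else None,
        })
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute every configured stage, writing outputs and a manifest.

    Any stage error aborts with the stage name; the manifest of a failed run
    is written with ``"complete": false``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "herbnet",
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
        "stages": {},
        "files": {},
        "complete": False,
    }
    written: list[Path] = []

    def _emit(name: str, writer) -> Path:
        p = out / name
        writer(p)
        written.append(p)
        return p

    stage = "ingest"
    try:
        table = read_compound_table(cfg.compounds)
        catalog = catalog_from_table(table)
        manifest["stages"]["ingest"] = {"n_compounds": len(table)}

        stage = "score"
        lib = None
        if cfg.reference_library is not None:
            lib = pd.read_csv(cfg.reference_library, sep=None, engine="python", comment="#")
        scored = _with_dl(table, lib)
        _emit("dl_scores.tsv", lambda p: pd.DataFrame(
            [{"compound_id": r.compound_id, "ob": r.ob, "dl": r.dl} for r in scored.records]
        ).to_csv(p, sep="\t", index=False))
        manifest["stages"]["score"] = {"n_scored": len(scored)}

        stage = "screen"
        report = screen_compounds(scored, ScreenConfig(cfg.screen.ob_min, cfg.screen.dl_min))
        _emit("retained.tsv", lambda p: pd.DataFrame(
            [{"compound_id": r.compound_id, "ob": r.ob, "dl": r.dl,
              "herbs": "|".join(sorted(r.herb_ids))} for r in report.retained]
        ).to_csv(p, sep="\t", index=False))
        _emit("rejected.tsv", lambda p: pd.DataFrame(
            [{"compound_id": r.compound_id, "ob": r.ob, "dl": r.dl,
              "reasons": "; ".join(report.rejected_reasons[r.compound_id])}
             for r in report.rejected]
        ).to_csv(p, sep="\t", index=False))
        _emit("screen_summary.json", lambda p: p.write_text(
            json.dumps(report.summary(), indent=1, sort_keys=True)))
        _emit("per_herb_summary.tsv", lambda p: per_herb_summary(report, catalog)
              .to_csv(p, sep="\t", index=False))
        manifest["stages"]["screen"] = report.summary()
        retained_ids = {r.compound_id for r in report.retained}

        results: dict = {"screen_report": report}
        if cfg.predictions is not None:
            stage = "fish"
            pred_records = read_edge_list(cfg.predictions, "compound-target")
            preds = []
            for rec in pred_records:
                scores = rec.scores or {}
                if "svm" not in scores or "rf" not in scores:
                    raise InputError(
                        f"prediction edge ({rec.left_id}, {rec.right_id}) lacks svm/rf scores"
                    )
                preds.append(TargetPrediction(
                    compound_id=rec.left_id, target_id=rec.right_id,
                    svm_score=scores["svm"], rf_score=scores["rf"],
                    source=next(iter(rec.evidence), "prediction"),
                ))
            curated = [read_edge_list(c, "compound-target") for c in cfg.curated]
            kept = filter_predictions(preds, cfg.fishing.svm_min, cfg.fishing.rf_min,
                                      strict=cfg.fishing.strict)
            merged = merge_target_sources(kept, curated)
            ct_edges = [e for e in merged if e.left_id in retained_ids]
            manifest["stages"]["fish"] = {
                "n_predictions": len(preds), "n_kept": len(kept),
                "n_merged": len(merged), "n_active_edges": len(ct_edges),
            }

            stage = "network"
            herb_attrs = {r.compound_id: {"herb_ids": sorted(r.herb_ids)}
                          for r in report.retained}
            ct_net = build_bipartite(ct_edges, "compound", "target", node_attrs=herb_attrs)
            summ = network_summary(ct_net)
            for fmt in cfg.export_formats:
                ext = {"sif": "sif", "graphml": "graphml", "tsv": "edges.tsv"}[fmt]
                _emit(f"ct_network.{ext}", lambda p, f=fmt: write_network(ct_net, p, f))
            _emit("ct_degrees.tsv", lambda p: summ.to_frame().to_csv(p, sep="\t", index=False))
            manifest["stages"]["network"] = {
                "ct": {"n_left": summ.n_left, "n_right": summ.n_right,
                       "n_nodes": summ.n_nodes, "n_edges": summ.n_edges}
            }
            results["ct_network"] = ct_net

            if cfg.disease_annotations is not None:
                td_raw = read_edge_list(cfg.disease_annotations, "target-disease")
                anns = [DiseaseAnnotation(target_id=e.left_id, disease_id=e.right_id,
                                          evidence=next(iter(e.evidence), ""))
                        for e in td_raw]
                td_edges = map_targets_to_diseases(ct_net.right, anns,
                                                   cfg.disease_vocabulary)
                td_net = build_bipartite(td_edges, "target", "disease")
                td_summ = network_summary(td_net)
                for fmt in cfg.export_formats:
                    ext = {"sif": "sif", "graphml": "graphml", "tsv": "edges.tsv"}[fmt]
                    _emit(f"td_network.{ext}", lambda p, f=fmt: write_network(td_net, p, f))
                _emit("herb_disease_counts.tsv", lambda p: per_herb_disease_counts(
                    ct_net, td_edges).to_csv(p, sep="\t", index=False))
                manifest["stages"]["network"]["td"] = {
                    "n_left": td_summ.n_left, "n_right": td_summ.n_right,
                    "n_nodes": td_summ.n_nodes, "n_edges": td_summ.n_edges,
                }

            if cfg.pathways_gmt is not None:
                stage = "enrich"
                annotations = read_annotation_gmt(cfg.pathways_gmt)
                enr = enrich(ct_net.right, annotations, alpha=cfg.enrichment.alpha,
                             filter_on="adjusted" if cfg.enrichment.adjust == "bh" else "raw")
                _emit("enrichment.tsv", lambda p: results_to_frame(enr)
                      .to_csv(p, sep="\t", index=False))
                retained_terms = [r for r in enr if r.retained]
                groups = kappa_group_terms(retained_terms, cfg.enrichment.kappa_min)
                _emit("term_groups.json", lambda p: p.write_text(
                    json.dumps(groups, indent=1)))
                tp_edges = [InteractionRecord(left_id=t, right_id=r.term_id,
                                              kind="target-pathway")
                            for r in retained_terms for t in sorted(r.members_hit)]
                if tp_edges:
                    tp_net = build_bipartite(tp_edges, "target", "pathway")
                    tp_summ = network_summary(tp_net)
                    for fmt in cfg.export_formats:
                        ext = {"sif": "sif", "graphml": "graphml", "tsv": "edges.tsv"}[fmt]
                        _emit(f"tp_network.{ext}", lambda p, f=fmt: write_network(tp_net, p, f))
                    manifest["stages"]["network"]["tp"] = {
                        "n_left": tp_summ.n_left, "n_right": tp_summ.n_right,
                        "n_nodes": tp_summ.n_nodes, "n_edges": tp_summ.n_edges,
                    }
                manifest["stages"]["enrich"] = {
                    "n_terms_tested": len(enr),
                    "n_retained": len(retained_terms),
                    "n_groups": len(groups),
                }
        manifest["complete"] = True
    except HerbnetError as e:
        err = e if isinstance(e, PipelineStageError) else PipelineStageError(stage, e)
        manifest["error"] = str(err)
        for p in written:
            manifest["files"][p.name] = _sha256(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise err from e

    for p in written:
        manifest["files"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
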