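"""End-to-end orchestration of the hybrid phenotype-mining cascade.

Stages, in order: tag drug labels with the CRF (training it first if no
model archive is supplied) -> deduplicate ADR terms per drug -> read and
filter BLAST hits -> map accessions to gene symbols -> one-hop PPI
expansion -> HPO phenotype lookup -> ADR/HPO cross-matching -> GO immune
screen -> candidate triples.  Every run writes the triples TSV, the
matches TSV, a JSON stage report and the resolved config, and is fully
deterministic given config + seed (timestamps are isolated to a single
report field).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import corpus_io, go_screen, phenotype_map, tagger, target_screen, term_match

log = logging.getLogger("phenomine.pipeline")


class PipelineError(RuntimeError):
    """A stage's input could not be processed; names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # paths
    labels_dir: str = ""
    model_path: str = ""       # trained CRF archive; empty -> train
    train_dir: str = ""        # annotated XML corpus for training
    lexicon: str = ""
    blast_tsv: str = ""
    mapping_tsv: str = ""
    string_tsv: str = ""
    obo: str = ""
    gene2pheno_tsv: str = ""
    gaf: str = ""
    go_names_tsv: str = ""
    output_dir: str = "phenomine_out"
    # thresholds
    min_identity: float = 30.0
    max_evalue: float = 1e-4
    min_confidence: float = 0.7
    max_nodes: int = 500
    match_threshold: float = 0.85
    split_ratio: float = 0.7
    # screening keywords + misc
    keywords: list[str] = field(
        default_factory=lambda: list(go_screen.DEFAULT_KEYWORDS))
    restrict_sections: list[str] = field(default_factory=list)
    max_iter: int = 150
    l2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity out of range")
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be non-negative")
        if not 0 <= self.min_confidence <= 1:
            raise ValueError("min_confidence out of range")
        if not 0 <= self.match_threshold <= 1:
            raise ValueError("match_threshold out of range")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False
    return _Ctx()


def _ensure_model(config: PipelineConfig, lexicon: set[str]) -> tagger.CRFModel:
    if config.model_path and Path(config.model_path).exists():
        return tagger.CRFModel.load(config.model_path)
    if not config.train_dir:
        raise ValueError("neither a model archive nor a training dir supplied")
    docs = [corpus_io.parse_annotated_xml(p)
            for p in sorted(Path(config.train_dir).glob("*.xml"))]
    train, dev = corpus_io.split_corpus(docs, config.split_ratio, config.seed)
    model = tagger.train_crf(train, dev, lexicon, l2=config.l2,
                             max_iter=config.max_iter, seed=config.seed)
    if config.model_path:
        model.save(config.model_path)
    return model


def extract_adr_terms(model: tagger.CRFModel, doc: corpus_io.AnnotatedDocument,
                      lexicon: set[str],
                      restrict_sections: list[str] | None = None) -> list[str]:
    """Predicted AdverseReaction surface terms of one label document."""
    mentions = tagger.predict(model, doc, lexicon)
    if restrict_sections:
        wanted = {s.lower() for s in restrict_sections}
        spans = [sp for name, sp in doc.sections if name.lower() in wanted]
        mentions = [m for m in mentions
                    if any(sp.start <= m.span.start and m.span.end <= sp.end
                           for sp in spans)]
    return [m.span.text for m in mentions if m.type == "AdverseReaction"]


def run_pipeline(config: PipelineConfig):
    """Execute the full cascade; returns (triples, report dict)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config),
                    "per_drug": {}, "overall": {}}
    overall = report["overall"]

    # -- drug-centric: tag labels, collect ADR terms per drug
    with _stage("tagging"):
        lexicon = (corpus_io.load_lexicon(config.lexicon)
                   if config.lexicon else set())
        model = _ensure_model(config, lexicon)
        label_paths = sorted(Path(config.labels_dir).glob("*.xml"))
        adr_by_drug: dict[str, list[term_match.NormalizedTerm]] = {}
        for path in label_paths:
            doc = corpus_io.parse_drug_label_xml(path)
            raw = extract_adr_terms(model, doc, lexicon,
                                    config.restrict_sections)
            deduped = term_match.dedup_terms(raw)
            adr_by_drug[doc.drug] = deduped
            report["per_drug"][doc.drug] = {
                "n_adr_terms_raw": len(raw),
                "n_adr_terms_dedup": len(deduped),
            }
    overall["n_adr_terms_raw"] = sum(
        d["n_adr_terms_raw"] for d in report["per_drug"].values())
    overall["n_adr_terms_dedup"] = sum(
        d["n_adr_terms_dedup"] for d in report["per_drug"].values())

    # -- target-centric: BLAST filter, gene mapping, PPI expansion
    with _stage("blast_filter"):
        hits = target_screen.read_blast_tabular(config.blast_tsv)
        kept = target_screen.filter_hits(hits, config.min_identity,
                                         config.max_evalue)
        for drug in report["per_drug"]:
            report["per_drug"][drug]["n_blast_hits_pre"] = sum(
                1 for h in hits if h.query_id == drug)
            report["per_drug"][drug]["n_blast_hits_post"] = sum(
                1 for h in kept if h.query_id == drug)
    overall["n_blast_hits_pre"] = len(hits)
    overall["n_blast_hits_post"] = len(kept)
    overall["accessions_post_filter"] = sorted({h.subject_accession
                                                for h in kept})

    with _stage("gene_mapping"):
        mapping = target_screen.read_gene_mapping(config.mapping_tsv)
        seed_genes = target_screen.hits_to_genes(kept, mapping)
    overall["genes_post_blast"] = sorted(seed_genes)
    overall["n_genes"] = len(seed_genes)

    with _stage("ppi_expansion"):
        edges = target_screen.read_string_edges(config.string_tsv)
        genes = target_screen.expand_ppi(seed_genes, edges,
                                         config.min_confidence,
                                         config.max_nodes)
    overall["genes_post_ppi"] = sorted(genes)
    overall["n_genes_after_ppi"] = len(genes)

    # -- phenotype lookup
    with _stage("phenotype_lookup"):
        onto = phenotype_map.parse_obo(config.obo)
        links = phenotype_map.load_gene_phenotype(config.gene2pheno_tsv, onto)
        pheno_by_gene = phenotype_map.phenotypes_for_genes(genes, links, onto)
    with_repeats = sum(len(v) for v in pheno_by_gene.values())
    distinct = len({t.hpo_id for v in pheno_by_gene.values() for t in v})
    overall["n_hpo_terms"] = {"distinct": distinct,
                              "with_repeats": with_repeats}

    # -- cross-matching
    with _stage("cross_match"):
        matches = term_match.cross_match(adr_by_drug, pheno_by_gene,
                                         threshold=config.match_threshold)
        term_match.write_matches(out_dir / "matches.tsv", matches)
    overall["n_matches"] = len(matches)
    overall["matched_genes"] = sorted({m.gene for m in matches})
    for drug in report["per_drug"]:
        report["per_drug"][drug]["n_matches"] = sum(
            1 for m in matches if m.drug == drug)

    # -- GO screen and triples
    with _stage("go_screen"):
        go_names = go_screen.read_go_names(config.go_names_tsv)
        annotations = go_screen.load_gaf(config.gaf, go_names)
        screen_cfg = go_screen.ScreenConfig(keywords=tuple(config.keywords))
        retained = go_screen.immune_filter({m.gene for m in matches},
                                           annotations, screen_cfg)
        triples = go_screen.screen(matches, retained)
        go_screen.write_triples(out_dir / "triples.tsv", triples)
    overall["retained_genes"] = sorted(retained)
    overall["n_retained_genes"] = len(retained)
    overall["n_triples"] = len(triples)
    for drug in report["per_drug"]:
        report["per_drug"][drug]["n_triples"] = sum(
            1 for t in triples if t.drug == drug)

    # the cascade ends at the screened triple list; the final
    # literature-evidence confirmation is a manual step outside the tool
    overall["note"] = ("candidate triples require manual literature "
                       "confirmation; not performed here")
    report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")

    config.to_yaml(out_dir / "resolved_config.yml")
    payload = dict(report)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline finished: %d triples from %d matches",
             len(triples), len(matches))
    return triples, report
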