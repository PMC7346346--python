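"""GO-based immune screening and candidate-triple emission.

The final cascade stage: genes surviving the phenotype cross-match are
kept only if they carry Gene Ontology biological-process annotations
whose names mention immune-related concepts (T cell proliferation or
activation, immune regulation, B cell activation), and the surviving
matches are collapsed into (drug, side effect, gene) candidate triples
with their GO evidence.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .term_match import MatchResult, normalize

log = logging.getLogger("phenomine.go_screen")

_GO_ID_RE = re.compile(r"^GO:\d{7}$")

DEFAULT_KEYWORDS = (
    "t cell proliferation",
    "t cell activation",
    "immune",
    "b cell activation",
)


@dataclass(frozen=True)
class GoAnnotation:
    gene_symbol: str
    go_id: str
    go_name: str
    aspect: str  # P (process), F (function), C (component)

    def __post_init__(self) -> None:
        if not _GO_ID_RE.match(self.go_id):
            raise ValueError(f"malformed GO id {self.go_id!r}")


@dataclass
class ScreenConfig:
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    go_allowlist: frozenset[str] = frozenset()
    aspects: tuple[str, ...] = ("P",)

    def __post_init__(self) -> None:
        if not self.keywords and not self.go_allowlist:
            raise ValueError("need at least one keyword or allowlisted GO id")
        self.keywords = tuple(k.lower() for k in self.keywords)


@dataclass(frozen=True)
class CandidateTriple:
    drug: str
    side_effect: str
    gene: str
    hpo_id: str
    match_score: float
    evidence_go: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.evidence_go:
            raise ValueError("candidate triple requires GO evidence")


def read_go_names(path) -> dict[str, str]:
    """GO id -> name table: two tab-separated columns, '#' comments."""
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                names[parts[0]] = parts[1]
    return names


def load_gaf(path, go_names: dict[str, str]) -> list[GoAnnotation]:
    """Parse GAF 2.x annotation lines ('!' comments skipped).

    Columns 3 (symbol), 5 (GO id) and 9 (aspect), 1-based; the term name
    is joined from ``go_names`` and empty when absent (such annotations
    remain matchable only via an explicit allowlist).
    """
    anns: list[GoAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(
                    f"{path}:{lineno}: GAF line has {len(cols)} columns, need >= 9")
            anns.append(GoAnnotation(cols[2], cols[4],
                                     go_names.get(cols[4], ""), cols[8]))
    return anns


def immune_filter(genes, annotations: list[GoAnnotation],
                  config: ScreenConfig | None = None) -> dict[str, list[str]]:
    """Retain genes with >= 1 annotation passing the aspect restriction
    whose name contains a keyword (case-insensitive substring) or whose
    id is allowlisted; values are the sorted passing GO ids."""
    config = config or ScreenConfig()
    genes = set(genes)
    evidence: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.gene_symbol not in genes or ann.aspect not in config.aspects:
            continue
        name = ann.go_name.lower()
        if ann.go_id in config.go_allowlist or \
                any(k in name for k in config.keywords):
            evidence.setdefault(ann.gene_symbol, set()).add(ann.go_id)
    return {g: sorted(ids) for g, ids in evidence.items()}


def screen(matches: list[MatchResult],
           retained: dict[str, list[str]]) -> list[CandidateTriple]:
    """Candidate triples from matches whose gene passed the GO screen.

    One triple per (drug, normalized side effect, gene), keeping the max
    match score; sorted by (drug, side_effect, gene).
    """
    best: dict[tuple[str, str, str], MatchResult] = {}
    for m in matches:
        if m.gene not in retained:
            continue
        key = (m.drug, m.adr_term.normalized, m.gene)
        if key not in best or m.score > best[key].score:
            best[key] = m
    triples = [
        CandidateTriple(m.drug, m.adr_term.raw, m.gene, m.hpo_term.hpo_id,
                        m.score, tuple(retained[m.gene]))
        for m in best.values()
    ]
    triples.sort(key=lambda t: (t.drug, normalize(t.side_effect).normalized, t.gene))
    return triples


def write_triples(path, triples: list[CandidateTriple]) -> None:
    """Deterministic TSV: drug, side_effect, gene, hpo_id, score, evidence_go."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\tside_effect\tgene\thpo_id\tscore\tevidence_go\n")
        for t in triples:
            fh.write(f"{t.drug}\t{t.side_effect}\t{t.gene}\t{t.hpo_id}\t"
                     f"{t.match_score:.4f}\t{';'.join(t.evidence_go)}\n")


def read_triples(path) -> list[CandidateTriple]:
    """Round-trip reader for :func:`write_triples` output."""
    triples: list[CandidateTriple] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("drug\t"):
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            drug, se, gene, hpo_id, score, ev = line.split("\t")
            triples.append(CandidateTriple(drug, se, gene, hpo_id,
                                           float(score), tuple(ev.split(";"))))
    return triples
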