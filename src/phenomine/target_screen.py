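"""Homology-hit filtering and PPI-network gene-set expansion.

Implements the target-centric half of the cascade: BLAST tabular
(outfmt 6) hits are filtered at identity > 30% and E-value < 1e-4,
mapped to gene symbols, then expanded one hop through a STRING-style
interaction network at combined score >= 700 (confidence 0.7) with a
500-neighbor display cap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

log = logging.getLogger("phenomine.target_screen")


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_accession: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_identity <= 100:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")


@dataclass(frozen=True)
class InteractionEdge:
    protein_a: str
    protein_b: str
    combined_score: int

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-edge on {self.protein_a}")
        if not 0 <= self.combined_score <= 1000:
            raise ValueError(f"combined_score out of range: {self.combined_score}")


def read_blast_tabular(path) -> list[BlastHit]:
    """Parse a 12-column BLAST outfmt-6 file.

    Columns 1 (query), 2 (subject accession), 3 (% identity),
    4 (alignment length), 11 (E-value) and 12 (bit score) are consumed;
    the rest are ignored.
    """
    hits: list[BlastHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}")
            hits.append(BlastHit(cols[0], cols[1], float(cols[2]),
                                 int(cols[3]), float(cols[10]), float(cols[11])))
    return hits


def filter_hits(hits: list[BlastHit], min_identity: float = 30.0,
                max_evalue: float = 1e-4) -> list[BlastHit]:
    """Keep hits with identity strictly above and E-value strictly below
    the thresholds; input order preserved."""
    return [h for h in hits
            if h.pct_identity > min_identity and h.evalue < max_evalue]


def read_gene_mapping(path) -> dict[str, str]:
    """accession<TAB>gene_symbol, one per line; '#' comments skipped."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected accession<TAB>gene")
            mapping[parts[0]] = parts[1]
    return mapping


def hits_to_genes(hits: list[BlastHit], mapping: dict[str, str]) -> list[str]:
    """Map hit accessions to gene symbols; unmapped dropped (counted),
    duplicates collapsed keeping first-seen order."""
    genes: list[str] = []
    seen: set[str] = set()
    unmapped = 0
    for h in hits:
        sym = mapping.get(h.subject_accession)
        if sym is None:
            unmapped += 1
            continue
        if sym not in seen:
            seen.add(sym)
            genes.append(sym)
    if unmapped:
        log.info("hits_to_genes: %d hits with unmapped accessions dropped", unmapped)
    return genes


def read_string_edges(path) -> list[InteractionEdge]:
    """STRING-style TSV: protein1<TAB>protein2<TAB>combined_score.

    An optional header line (non-numeric third column) is skipped.
    Duplicate / reversed pairs are collapsed keeping the max score.
    """
    best: dict[tuple[str, str], int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            try:
                score = int(parts[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ValueError(f"{path}:{lineno}: non-integer score {parts[2]!r}")
            a, b = parts[0], parts[1]
            key = (a, b) if a <= b else (b, a)
            best[key] = max(best.get(key, -1), score)
    return [InteractionEdge(a, b, s) for (a, b), s in sorted(best.items())]


def expand_ppi(seed_genes, edges: list[InteractionEdge],
               min_confidence: float = 0.7, max_nodes: int = 500) -> set[str]:
    """Seeds plus direct neighbors with combined score >= round(1000 * conf).

    If qualifying neighbors exceed ``max_nodes``, the highest-scoring
    ``max_nodes`` are kept (ties broken lexicographically by symbol).
    Seeds are always retained and do not count against the cap.
    """
    if not 0 <= min_confidence <= 1:
        raise ValueError("min_confidence must be in [0, 1]")
    cutoff = round(1000 * min_confidence)
    seeds = set(seed_genes)
    neighbor_score: dict[str, int] = {}
    for e in edges:
        if e.combined_score < cutoff:
            continue
        for s, n in ((e.protein_a, e.protein_b), (e.protein_b, e.protein_a)):
            if s in seeds and n not in seeds:
                neighbor_score[n] = max(neighbor_score.get(n, -1), e.combined_score)
    ranked = sorted(neighbor_score.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = {g for g, _ in ranked[:max_nodes]}
    if len(ranked) > max_nodes:
        log.info("expand_ppi: %d qualifying neighbors capped to %d",
                 len(ranked), max_nodes)
    return seeds | kept
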