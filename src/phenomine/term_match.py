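"""Phenotype term normalization and drug-ADR vs HPO cross-matching.

Drug-centric ADR surface terms and target-centric HPO term names (plus
synonyms) are compared after normalization; the default similarity
backend is a padded character-trigram cosine, with a hook for an
external word-vector table.  Matches at or above the threshold become
(drug, ADR term, gene, HPO term) candidate records.
"""
from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Callable

from .phenotype_map import PhenotypeTerm

_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class NormalizedTerm:
    raw: str
    normalized: str


@dataclass(frozen=True)
class MatchResult:
    drug: str
    adr_term: NormalizedTerm
    hpo_term: PhenotypeTerm
    gene: str
    score: float


def normalize(term: str) -> NormalizedTerm:
    """Lowercase; punctuation to spaces; whitespace collapsed and trimmed."""
    norm = _WS_RE.sub(" ", _PUNCT_RE.sub(" ", term.lower())).strip()
    return NormalizedTerm(term, norm)


def _trigrams(s: str) -> Counter:
    padded = f"#{s}#"
    if len(padded) < 3:
        return Counter()
    return Counter(padded[i: i + 3] for i in range(len(padded) - 2))


def trigram_cosine(a: NormalizedTerm | str, b: NormalizedTerm | str) -> float:
    """Cosine similarity of padded character-trigram count vectors.

    Both strings empty -> 1.0; exactly one empty -> 0.0.
    """
    sa = a.normalized if isinstance(a, NormalizedTerm) else a
    sb = b.normalized if isinstance(b, NormalizedTerm) else b
    if not sa and not sb:
        return 1.0
    if not sa or not sb:
        return 0.0
    ca, cb = _trigrams(sa), _trigrams(sb)
    dot = sum(v * cb[k] for k, v in ca.items())
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    if na == 0 or nb == 0:
        return 1.0 if ca == cb else 0.0
    return dot / (na * nb)


def load_word_vectors(path) -> dict[str, list[float]]:
    """Text embedding table: token then whitespace-separated floats per line."""
    table: dict[str, list[float]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if len(parts) > 1:
                table[parts[0]] = [float(x) for x in parts[1:]]
    return table


def word_vector_backend(table: dict[str, list[float]]) -> Callable:
    """Mean-of-token-vector cosine similarity over a user-supplied table.

    Terms with no in-vocabulary token share no comparable units and
    score 0 against anything non-identical.
    """
    def embed(norm: str):
        vecs = [table[t] for t in norm.split() if t in table]
        if not vecs:
            return None
        dim = len(vecs[0])
        return [sum(v[i] for v in vecs) / len(vecs) for i in range(dim)]

    def sim(a: NormalizedTerm | str, b: NormalizedTerm | str) -> float:
        sa = a.normalized if isinstance(a, NormalizedTerm) else a
        sb = b.normalized if isinstance(b, NormalizedTerm) else b
        if sa == sb:
            return 1.0
        va, vb = embed(sa), embed(sb)
        if va is None or vb is None:
            return 0.0
        dot = sum(x * y for x, y in zip(va, vb))
        na = math.sqrt(sum(x * x for x in va))
        nb = math.sqrt(sum(x * x for x in vb))
        if na == 0 or nb == 0:
            return 0.0
        return max(0.0, min(1.0, dot / (na * nb)))

    return sim


def dedup_terms(terms: list[str]) -> list[NormalizedTerm]:
    """Normalize and collapse exact normalized duplicates, first-seen order."""
    out: list[NormalizedTerm] = []
    seen: set[str] = set()
    for t in terms:
        nt = normalize(t)
        if nt.normalized not in seen:
            seen.add(nt.normalized)
            out.append(nt)
    return out


def cross_match(adr_by_drug: dict[str, list[NormalizedTerm]],
                pheno_by_gene: dict[str, set[PhenotypeTerm]],
                backend: Callable = trigram_cosine,
                threshold: float = 0.85) -> list[MatchResult]:
    """Score every (drug, ADR) x (gene, HPO term) pair; keep score >= threshold.

    The score against a term is the max over its name and synonyms;
    exact normalized equality with any of them short-circuits to 1.0.
    Output sorted by (drug, gene, -score).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    results: list[MatchResult] = []
    for drug in sorted(adr_by_drug):
        for adr in adr_by_drug[drug]:
            for gene in sorted(pheno_by_gene):
                for term in pheno_by_gene[gene]:
                    names = [term.name, *term.synonyms]
                    score = 0.0
                    for name in names:
                        if normalize(name).normalized == adr.normalized:
                            score = 1.0
                            break
                        score = max(score, backend(adr, normalize(name)))
                    if score >= threshold:
                        results.append(MatchResult(drug, adr, term, gene, score))
    results.sort(key=lambda m: (m.drug, m.gene, -m.score,
                                m.adr_term.normalized, m.hpo_term.hpo_id))
    return results


def write_matches(path, matches: list[MatchResult]) -> None:
    """TSV: drug, adr_term, gene, hpo_id, hpo_name, score."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\tadr_term\tgene\thpo_id\thpo_name\tscore\n")
        for m in matches:
            fh.write(f"{m.drug}\t{m.adr_term.raw}\t{m.gene}\t"
                     f"{m.hpo_term.hpo_id}\t{m.hpo_term.name}\t{m.score:.4f}\n")
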