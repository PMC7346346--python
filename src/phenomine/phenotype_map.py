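"""Minimal HPO ontology loading and gene-to-phenotype mapping.

Reads the subset of OBO 1.2 tags the cascade needs (id, name, synonym,
alt_id, is_obsolete, is_a) and a genes-to-phenotype TSV, producing the
set of phenotype terms linked to each candidate gene.  Only direct
gene->term links are used; no propagation up the is_a hierarchy.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

log = logging.getLogger("phenomine.phenotype_map")

_HPO_ID_RE = re.compile(r"^HP:\d{7}$")
_SYNONYM_RE = re.compile(r'^"(.*)"')


@dataclass(frozen=True)
class PhenotypeTerm:
    hpo_id: str
    name: str
    synonyms: tuple[str, ...] = ()
    obsolete: bool = False
    is_a: tuple[str, ...] = ()  # parsed but unused (reserved)

    def __post_init__(self) -> None:
        if not _HPO_ID_RE.match(self.hpo_id):
            raise ValueError(f"malformed HPO id {self.hpo_id!r}")
        if not self.obsolete and not self.name:
            raise ValueError(f"{self.hpo_id}: non-obsolete term without a name")


@dataclass(frozen=True)
class GenePhenotypeLink:
    gene_symbol: str
    hpo_id: str


@dataclass
class Ontology:
    terms: dict[str, PhenotypeTerm] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def resolve(self, hpo_id: str) -> PhenotypeTerm | None:
        """Look up a term by primary or alternate id."""
        hpo_id = self.alt_ids.get(hpo_id, hpo_id)
        return self.terms.get(hpo_id)


def parse_obo(path) -> Ontology:
    """Parse [Term] stanzas of an OBO 1.2 flat file.

    Consumes id, name, synonym (the quoted string), alt_id and
    is_obsolete; every other tag is ignored.  Duplicate primary ids are
    an error.
    """
    onto = Ontology()
    current: dict | None = None

    def flush() -> None:
        if current is None or "id" not in current:
            return
        tid = current["id"]
        if tid in onto.terms:
            raise ValueError(f"{path}: duplicate term id {tid}")
        onto.terms[tid] = PhenotypeTerm(
            tid, current.get("name", ""),
            tuple(current.get("synonyms", [])),
            current.get("obsolete", False),
            tuple(current.get("is_a", [])))
        for alt in current.get("alt_ids", []):
            onto.alt_ids[alt] = tid

    in_term = False
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                current = {} if in_term else None
                continue
            if not in_term or current is None or not line:
                continue
            tag, _, value = line.partition(":")
            value = value.strip()
            if tag == "id":
                current["id"] = value
            elif tag == "name":
                current["name"] = value
            elif tag == "alt_id":
                current.setdefault("alt_ids", []).append(value)
            elif tag == "is_a":
                current.setdefault("is_a", []).append(value.split("!")[0].strip())
            elif tag == "is_obsolete":
                current["obsolete"] = value.lower().startswith("true")
            elif tag == "synonym":
                m = _SYNONYM_RE.match(value)
                if m:
                    current.setdefault("synonyms", []).append(m.group(1))
    flush()
    return onto


def load_gene_phenotype(path, ontology: Ontology) -> list[GenePhenotypeLink]:
    """Read a genes-to-phenotype TSV (header: gene_symbol, hpo_id, ...).

    Links whose id does not resolve in the ontology (after alt_id
    redirection) are dropped and counted.
    """
    links: list[GenePhenotypeLink] = []
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            gi, hi = header.index("gene_symbol"), header.index("hpo_id")
        except ValueError:
            raise ValueError(
                f"{path}: header must contain gene_symbol and hpo_id columns")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            gene, hid = cols[gi].strip(), cols[hi].strip()
            term = ontology.resolve(hid)
            if term is None:
                dropped += 1
                continue
            links.append(GenePhenotypeLink(gene, term.hpo_id))
    if dropped:
        log.info("load_gene_phenotype: %d links with unresolvable ids dropped",
                 dropped)
    return links


def phenotypes_for_genes(genes, links: list[GenePhenotypeLink],
                         ontology: Ontology) -> dict[str, set[PhenotypeTerm]]:
    """Non-obsolete phenotype terms linked to each input gene.

    Genes with no links map to the empty set (retained in the result).
    """
    by_gene: dict[str, set[PhenotypeTerm]] = {g: set() for g in genes}
    for link in links:
        if link.gene_symbol in by_gene:
            term = ontology.resolve(link.hpo_id)
            if term is not None and not term.obsolete:
                by_gene[link.gene_symbol].add(term)
    return by_gene
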