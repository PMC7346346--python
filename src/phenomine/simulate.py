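"""Deterministic synthetic-fixture generators for every pipeline input.

Two generators cover the whole system:

* :func:`gen_label_corpus` emits an annotated drug-label corpus (TAC-style
  XML) with entities planted at known offsets inside template carrier
  sentences, plus the matching disorder lexicon — enough to train and
  score the CRF tagger against a known ground truth.

* :func:`gen_screen_world` emits a complete input world for the
  off-target cascade — drug labels, a CRF training corpus, BLAST
  tabular hits, an accession-to-gene mapping, a STRING-style interaction
  file, an HPO-subset OBO, gene-to-phenotype links, GAF annotations and
  a GO name table — constructed so that the planted (drug, side effect,
  gene) triples pass every stage while one decoy gene per stage fails
  exactly that stage.

All randomness flows from a single ``random.Random(seed)``; file write
order is fixed, so equal seeds give byte-identical worlds.  The
generators model the statistical shape of the real resources, not
realistic protein sequences or clinical language.
"""
from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

from .corpus_io import ENTITY_TYPES
from .term_match import trigram_cosine

# Per-type syllable alphabets give each entity type a distinct surface
# distribution, mimicking how disorder sub-vocabularies differ.
_TYPE_SYLLABLES = (
    ("ra", "to", "ne", "si", "lo", "da"),
    ("mu", "ko", "ba", "pe", "vi", "za"),
    ("fe", "nu", "gi", "so", "li", "ta"),
    ("ce", "du", "mi", "po", "sa", "ve"),
    ("be", "fo", "ga", "ni", "ru", "te"),
    ("co", "de", "ma", "pi", "su", "vo"),
)
_FILLER_SYLLABLES = ("an", "el", "im", "or", "ul", "en", "ir", "os")

_ENTITY_TEMPLATES = (
    ("Patients", "reported", None, "."),
    ("Severe", None, "was", "observed", "in", "patients", "."),
    ("Clinicians", "noted", None, "after", "treatment", "."),
    ("Patients", "reported", None, "and", None, "."),
)
_DISTRACTOR_TEMPLATE = ("The", "glossary", "lists", None, "among", "examples", ".")


def _word(rng: random.Random, syllables, n_syl: int) -> str:
    return "".join(rng.choice(syllables) for _ in range(n_syl))


def _distinct_words(rng: random.Random, syllables, count: int,
                    n_syl=(2, 3), taken: set[str] | None = None) -> list[str]:
    taken = taken if taken is not None else set()
    out: list[str] = []
    while len(out) < count:
        w = _word(rng, syllables, rng.randint(*n_syl))
        if w not in taken:
            taken.add(w)
            out.append(w)
    return out


def _make_terms(rng: random.Random, syllables, count: int,
                taken: set[str], max_tokens: int = 3) -> list[str]:
    """Multi-token disorder-like terms with globally unique tokens."""
    terms = []
    for _ in range(count):
        n_tok = rng.randint(1, max_tokens)
        terms.append(" ".join(_distinct_words(rng, syllables, n_tok, taken=taken)))
    return terms


# ---------------------------------------------------------------------------
# Annotated label corpus
# ---------------------------------------------------------------------------

@dataclass
class SentencePlan:
    tokens: list[str]
    mentions: list[tuple[int, int, str]]  # token-index run [i, j] + type


def _fill_template(template, terms_by_slot) -> SentencePlan:
    tokens: list[str] = []
    mentions: list[tuple[int, int, str]] = []
    slot = 0
    for part in template:
        if part is None:
            term, etype = terms_by_slot[slot]
            slot += 1
            start = len(tokens)
            tokens.extend(term.split())
            if etype is not None:
                mentions.append((start, len(tokens) - 1, etype))
        else:
            tokens.append(part)
    return SentencePlan(tokens, mentions)


def _render_doc(doc_id: str, plans: list[SentencePlan]):
    """Join sentence token lists with single spaces; compute char offsets."""
    words: list[str] = []
    mention_rows = []  # (start, length, surface, type)
    offset = 0
    offsets: list[int] = []
    for plan in plans:
        for tok in plan.tokens:
            if words:
                offset += 1
            offsets.append(offset)
            words.append(tok)
            offset += len(tok)
        base = len(words) - len(plan.tokens)
        for i, j, etype in plan.mentions:
            start = offsets[base + i]
            end = offsets[base + j] + len(plan.tokens[j])
            surface = " ".join(plan.tokens[i: j + 1])
            mention_rows.append((start, end - start, surface, etype))
    return " ".join(words), mention_rows


def _write_annotated_xml(path: Path, doc_id: str, text: str, mention_rows) -> None:
    lines = [f'<Label drug="{escape(doc_id)}">', "<Text>",
             f'<Section name="adverse reactions">{escape(text)}</Section>',
             "</Text>", "<Mentions>"]
    for k, (start, length, surface, etype) in enumerate(mention_rows):
        lines.append(
            f'<Mention id="M{k}" str="{escape(surface, {chr(34): "&quot;"})}" '
            f'type="{etype}" start="{start}" len="{length}" '
            f'section="adverse reactions"/>')
    lines += ["</Mentions>", "</Label>", ""]
    path.write_text("\n".join(lines), encoding="utf-8")


def _write_label_xml(path: Path, drug: str, text: str) -> None:
    path.write_text(
        f'<Label drug="{escape(drug)}">\n'
        f'<Section name="adverse reactions">{escape(text)}</Section>\n'
        f"</Label>\n", encoding="utf-8")


def _corpus_plans(rng, n_docs, typed_terms, distractor_terms, fillers,
                  sentences_per_doc=(3, 6)):
    """Sentence plans per document, cycling entity terms for even coverage."""
    term_cycle: list[tuple[str, str]] = []
    docs = []
    for d in range(n_docs):
        plans: list[SentencePlan] = []
        for _ in range(rng.randint(*sentences_per_doc)):
            u = rng.random()
            if u < 0.55 and typed_terms:
                template = rng.choice(_ENTITY_TEMPLATES)
                n_slots = sum(1 for p in template if p is None)
                slots = []
                for _ in range(n_slots):
                    if not term_cycle:
                        term_cycle = list(typed_terms)
                        rng.shuffle(term_cycle)
                    slots.append(term_cycle.pop())
                plans.append(_fill_template(template, slots))
            elif u < 0.75 and distractor_terms:
                term = rng.choice(distractor_terms)
                plans.append(_fill_template(_DISTRACTOR_TEMPLATE, [(term, None)]))
            else:
                n = rng.randint(4, 7)
                toks = [rng.choice(fillers) for _ in range(n)]
                toks[0] = toks[0].capitalize()
                plans.append(SentencePlan(toks + ["."], []))
        docs.append(plans)
    return docs


def gen_label_corpus(out_dir, n_docs: int, n_entity_types: int = 3,
                     vocab_size: int = 50, lexicon_size: int = 30,
                     seed: int = 0):
    """Write an annotated corpus plus its disorder lexicon.

    Returns (list of XML paths, lexicon path).  Entities are lexicon
    terms (1-3 tokens, per-type surface distributions) embedded in
    carrier templates at known offsets; about 30% of lexicon terms also
    appear as non-entity distractors in a distinct carrier context.
    """
    if n_entity_types < 1 or n_entity_types > len(ENTITY_TYPES):
        raise ValueError("n_entity_types must be in 1..6")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    taken: set[str] = set()
    fillers = _distinct_words(rng, _FILLER_SYLLABLES, vocab_size, taken=taken)

    types = ENTITY_TYPES[:n_entity_types]
    per_type = max(1, lexicon_size // n_entity_types)
    typed_terms: list[tuple[str, str]] = []
    for k, etype in enumerate(types):
        for term in _make_terms(rng, _TYPE_SYLLABLES[k], per_type, taken):
            typed_terms.append((term, etype))

    n_distract = max(1, int(0.3 * len(typed_terms)))
    distractors = [t for t, _ in rng.sample(typed_terms, n_distract)]

    paths = []
    for d, plans in enumerate(_corpus_plans(rng, n_docs, typed_terms,
                                            distractors, fillers)):
        doc_id = f"synthdoc{d:04d}"
        text, rows = _render_doc(doc_id, plans)
        path = out_dir / f"{doc_id}.xml"
        _write_annotated_xml(path, doc_id, text, rows)
        paths.append(path)

    lexicon_path = out_dir / "lexicon.txt"
    lexicon_path.write_text(
        "".join(f"{t}\n" for t, _ in typed_terms), encoding="utf-8")
    return paths, lexicon_path


# ---------------------------------------------------------------------------
# Screen world
# ---------------------------------------------------------------------------

_DRUG_NAMES = ("Abrelimab", "Betrolimab", "Cevolumab", "Durvelimab", "Epratumab")

#: decoy class name -> cascade stage at which it must die
DECOY_STAGES = {
    "low_identity": "blast_filter",
    "high_evalue": "blast_filter",
    "unmapped_accession": "gene_mapping",
    "weak_ppi": "ppi_expansion",
    "phenotype_mismatch": "cross_match",
    "no_immune_go": "go_screen",
}

_IMMUNE_GO = (
    ("GO:0042098", "T cell proliferation"),
    ("GO:0042110", "T cell activation"),
    ("GO:0050776", "regulation of immune response"),
    ("GO:0042113", "B cell activation"),
)
_NEUTRAL_GO = (
    ("GO:0042254", "ribosome biogenesis"),
    ("GO:0006412", "translation"),
    ("GO:0007049", "cell cycle"),
)


@dataclass
class SynthWorld:
    """Paths of every generated input plus the planted ground truth."""

    root: Path
    labels_dir: Path
    train_dir: Path
    lexicon: Path
    blast_tsv: Path
    mapping_tsv: Path
    string_tsv: Path
    obo: Path
    gene2pheno_tsv: Path
    gaf: Path
    go_names_tsv: Path
    seed: int
    planted_triples: list[dict] = field(default_factory=list)
    decoys: dict[str, dict] = field(default_factory=dict)  # class -> info

    def ground_truth(self) -> dict:
        return {"seed": self.seed,
                "planted_triples": self.planted_triples,
                "decoys": self.decoys}


def _near_variant(rng: random.Random, term: str, threshold: float) -> str:
    """Single-character-edit variant guaranteed above the match threshold.

    Deletes one interior character; regenerates the edit position until
    the trigram cosine clears the threshold with margin.
    """
    for _ in range(50):
        pos = rng.randrange(1, len(term) - 1)
        if term[pos] == " ":
            continue
        variant = term[:pos] + term[pos + 1:]
        if trigram_cosine(term, variant) >= threshold + 0.01:
            return variant
    raise ValueError(f"no near-variant of {term!r} clears threshold {threshold}")


def gen_screen_world(out_dir, n_drugs: int = 5, n_genes: int = 12,
                     n_planted_triples: int = 3, seed: int = 0,
                     match_threshold: float = 0.85) -> SynthWorld:
    """Generate a complete cascade input world with planted ground truth.

    Every planted triple's gene survives all five screening stages; six
    decoy genes each fail exactly one stage (BLAST identity, BLAST
    E-value, accession mapping, PPI confidence, phenotype match, GO
    screen).  One planted gene enters the gene set only through a
    high-confidence PPI edge, and one planted phenotype name is a
    near-variant of its ADR term (similarity < 1 but above threshold).
    """
    if n_planted_triples < 1:
        raise ValueError("need at least one planted triple")
    if n_drugs < 1 or n_drugs > len(_DRUG_NAMES):
        raise ValueError(f"n_drugs must be in 1..{len(_DRUG_NAMES)}")
    n_decoys = len(DECOY_STAGES)
    if n_genes < n_planted_triples + n_decoys:
        raise ValueError(
            f"n_genes={n_genes} cannot host {n_planted_triples} planted genes "
            f"plus {n_decoys} decoys")

    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    drugs = list(_DRUG_NAMES[:n_drugs])

    # --- vocabulary: ADR terms must be pairwise dissimilar so that no
    # accidental cross-drug match survives the threshold
    taken: set[str] = set()
    planted_terms = []
    for k in range(n_planted_triples):
        n_tok = 3 if k == n_planted_triples - 1 else rng.randint(1, 2)
        n_syl = (3, 4) if n_tok == 3 else (2, 3)
        while True:
            words = _distinct_words(rng, _TYPE_SYLLABLES[0], n_tok,
                                    n_syl=n_syl, taken=taken)
            term = " ".join(words)
            if all(trigram_cosine(term, t) < 0.6 for t in planted_terms):
                planted_terms.append(term)
                break
    filler_terms = _make_terms(rng, _TYPE_SYLLABLES[1], 2 * n_drugs, taken,
                               max_tokens=2)
    mismatch_term = " ".join(_distinct_words(rng, _TYPE_SYLLABLES[2], 2,
                                             taken=taken))

    # --- gene symbols and accessions
    def gene_symbol(i: int) -> str:
        return f"GEN{i + 1:02d}"

    planted_genes = [gene_symbol(i) for i in range(n_planted_triples)]
    decoy_classes = list(DECOY_STAGES)
    decoy_genes = {cls: gene_symbol(n_planted_triples + i)
                   for i, cls in enumerate(decoy_classes)}
    extra_genes = [gene_symbol(i)
                   for i in range(n_planted_triples + n_decoys, n_genes)]
    accession = {g: f"Q{10000 + i}" for i, g in enumerate(
        planted_genes + list(decoy_genes.values()) + extra_genes)}

    # --- planted triples: drug round-robin; last gene enters via PPI only
    ppi_gene = planted_genes[-1]
    triples = []
    for k, gene in enumerate(planted_genes):
        drug = drugs[k % len(drugs)]
        term = planted_terms[k]
        triples.append({"drug": drug, "side_effect": term, "gene": gene,
                        "via_ppi": gene == ppi_gene and len(planted_genes) > 1})

    # --- HPO terms
    hpo_rows = []  # (hpo_id, name, synonyms, obsolete)
    next_hp = [1]

    def new_hp(name, synonyms=(), obsolete=False):
        hid = f"HP:{next_hp[0]:07d}"
        next_hp[0] += 1
        hpo_rows.append((hid, name, tuple(synonyms), obsolete))
        return hid

    gene_term_ids: dict[str, str] = {}
    for k, t in enumerate(triples):
        term = t["side_effect"]
        if k == len(triples) - 1 and len(term) > 12:
            name = _near_variant(rng, term, match_threshold).capitalize()
        else:
            name = term.capitalize()
        gene_term_ids[t["gene"]] = new_hp(name)
        t["hpo_name"] = name
    gene_term_ids[decoy_genes["phenotype_mismatch"]] = new_hp(
        mismatch_term.capitalize())
    # the GO decoy's phenotype matches a planted ADR term exactly, so it
    # survives cross-matching and must die at the GO screen
    go_decoy_drug = triples[0]["drug"]
    gene_term_ids[decoy_genes["no_immune_go"]] = new_hp(
        planted_terms[0].capitalize() + " variant",
        synonyms=(planted_terms[0].capitalize(),))
    for g in extra_genes:
        gene_term_ids[g] = new_hp(
            " ".join(_distinct_words(rng, _TYPE_SYLLABLES[3], 2,
                                     taken=taken)).capitalize())
    obsolete_id = new_hp("Obsolete finding", obsolete=True)
    new_hp("Unlinked finding")

    # --- drug labels: each drug gets its planted terms + two fillers
    labels_dir = root / "labels"
    labels_dir.mkdir(exist_ok=True)
    adr_by_drug = {d: [] for d in drugs}
    for t in triples:
        adr_by_drug[t["drug"]].append(t["side_effect"])
    for i, d in enumerate(drugs):
        adr_by_drug[d].extend(filler_terms[2 * i: 2 * i + 2])
    for d in drugs:
        plans = []
        for term in adr_by_drug[d]:
            template = rng.choice(_ENTITY_TEMPLATES[:3])
            plans.append(_fill_template(
                template, [(term, "AdverseReaction")]))
        text, _ = _render_doc(d, plans)
        _write_label_xml(labels_dir / f"{d}.xml", d, text)

    # --- CRF training corpus over the same term pool
    train_dir = root / "train"
    all_terms = planted_terms + filler_terms
    extra_lexicon = _make_terms(rng, _TYPE_SYLLABLES[0], 6, taken, max_tokens=2)
    typed_terms = [(t, "AdverseReaction") for t in all_terms + extra_lexicon]
    fillers = _distinct_words(rng, _FILLER_SYLLABLES, 40, taken=taken)
    distractors = [t for t, _ in typed_terms[:max(1, len(typed_terms) // 3)]]
    train_dir.mkdir(exist_ok=True)
    for d, plans in enumerate(_corpus_plans(rng, 30, typed_terms, distractors,
                                            fillers, sentences_per_doc=(4, 7))):
        doc_id = f"train{d:03d}"
        text, rows = _render_doc(doc_id, plans)
        _write_annotated_xml(train_dir / f"{doc_id}.xml", doc_id, text, rows)
    lexicon = root / "lexicon.txt"
    lexicon.write_text("".join(f"{t}\n" for t, _ in typed_terms),
                       encoding="utf-8")

    # --- BLAST hits: planted (except the PPI-only gene) + decoys + extras
    blast_rows = []

    def blast_row(drug, acc, identity, evalue):
        blast_rows.append(
            f"{drug}\t{acc}\t{identity:.1f}\t{rng.randint(80, 240)}\t0\t0\t1\t"
            f"200\t1\t200\t{evalue:g}\t{rng.randint(100, 400)}")

    for t in triples:
        if not t["via_ppi"]:
            blast_row(t["drug"], accession[t["gene"]],
                      rng.uniform(40, 90), 10.0 ** -rng.randint(10, 40))
    blast_row(drugs[0], accession[decoy_genes["low_identity"]],
              25.0, 1e-20)
    blast_row(drugs[0], accession[decoy_genes["high_evalue"]],
              rng.uniform(40, 90), 1e-2)
    blast_row(drugs[0], accession[decoy_genes["unmapped_accession"]],
              rng.uniform(40, 90), 1e-20)
    blast_row(go_decoy_drug, accession[decoy_genes["phenotype_mismatch"]],
              rng.uniform(40, 90), 1e-20)
    blast_row(go_decoy_drug, accession[decoy_genes["no_immune_go"]],
              rng.uniform(40, 90), 1e-20)
    for g in extra_genes:  # harmless seeds whose phenotypes match nothing
        blast_row(rng.choice(drugs), accession[g], rng.uniform(40, 90), 1e-15)
    blast_tsv = root / "blast_hits.tsv"
    blast_tsv.write_text("".join(r + "\n" for r in blast_rows), encoding="utf-8")

    # --- accession -> gene mapping (the unmapped decoy's accession is absent)
    mapping_tsv = root / "accession_to_gene.tsv"
    rows = ["# accession\tgene_symbol"]
    for g, acc in sorted(accession.items(), key=lambda kv: kv[1]):
        if g != decoy_genes["unmapped_accession"]:
            rows.append(f"{acc}\t{g}")
    mapping_tsv.write_text("".join(r + "\n" for r in rows), encoding="utf-8")

    # --- STRING edges
    anchor = next(t["gene"] for t in triples if not t["via_ppi"])
    string_rows = ["protein1\tprotein2\tcombined_score"]
    if any(t["via_ppi"] for t in triples):
        string_rows.append(f"{anchor}\t{ppi_gene}\t{rng.randint(800, 990)}")
    string_rows.append(
        f"{anchor}\t{decoy_genes['weak_ppi']}\t{rng.randint(400, 699)}")
    string_rows.append(  # noise edge between two non-seed symbols
        f"OFFX1\tOFFX2\t{rng.randint(700, 990)}")
    string_tsv = root / "string_edges.tsv"
    string_tsv.write_text("".join(r + "\n" for r in string_rows),
                          encoding="utf-8")

    # --- OBO ontology
    obo_lines = ["format-version: 1.2", ""]
    for hid, name, synonyms, obsolete in hpo_rows:
        obo_lines += ["[Term]", f"id: {hid}", f"name: {name}"]
        for s in synonyms:
            obo_lines.append(f'synonym: "{s}" EXACT []')
        if obsolete:
            obo_lines.append("is_obsolete: true")
        obo_lines.append("")
    obo = root / "hpo_subset.obo"
    obo.write_text("\n".join(obo_lines), encoding="utf-8")

    # --- gene -> phenotype links
    g2p_rows = ["gene_symbol\thpo_id\thpo_name"]
    names_by_id = {hid: name for hid, name, _, _ in hpo_rows}
    for g in sorted(gene_term_ids):
        hid = gene_term_ids[g]
        g2p_rows.append(f"{g}\t{hid}\t{names_by_id[hid]}")
    g2p_rows.append(f"{sorted(gene_term_ids)[0]}\t{obsolete_id}\t(obsolete)")
    gene2pheno_tsv = root / "genes_to_phenotype.tsv"
    gene2pheno_tsv.write_text("".join(r + "\n" for r in g2p_rows),
                              encoding="utf-8")

    # --- GO annotations; the no_immune_go decoy gets only neutral terms,
    # plus one immune-named annotation outside the P aspect
    go_used: dict[str, str] = {}
    gaf_rows = ["!gaf-version: 2.2"]

    def gaf_row(gene, go_id, go_name, aspect="P"):
        go_used[go_id] = go_name
        gaf_rows.append(
            f"SYNTHDB\t{accession[gene]}\t{gene}\t\t{go_id}\tSYNTH:0001\tIEA\t\t"
            f"{aspect}\t{gene} protein\t\tprotein\ttaxon:9606\t20260101\tSYNTHDB")

    immune_pool = list(_IMMUNE_GO)
    for k, t in enumerate(triples):
        gid, gname = immune_pool[k % len(immune_pool)]
        gaf_row(t["gene"], gid, gname)
        gaf_row(t["gene"], *_NEUTRAL_GO[k % len(_NEUTRAL_GO)])
    gaf_row(decoy_genes["phenotype_mismatch"], *_IMMUNE_GO[2])
    for gid, gname in _NEUTRAL_GO[:2]:
        gaf_row(decoy_genes["no_immune_go"], gid, gname)
    gaf_row(decoy_genes["no_immune_go"], _IMMUNE_GO[0][0], _IMMUNE_GO[0][1],
            aspect="C")
    for g in extra_genes:
        gaf_row(g, *_NEUTRAL_GO[2])
    gaf = root / "annotations.gaf"
    gaf.write_text("".join(r + "\n" for r in gaf_rows), encoding="utf-8")

    go_names_tsv = root / "go_names.tsv"
    go_names_tsv.write_text(
        "".join(f"{gid}\t{name}\n" for gid, name in sorted(go_used.items())),
        encoding="utf-8")

    world = SynthWorld(
        root=root, labels_dir=labels_dir, train_dir=train_dir, lexicon=lexicon,
        blast_tsv=blast_tsv, mapping_tsv=mapping_tsv, string_tsv=string_tsv,
        obo=obo, gene2pheno_tsv=gene2pheno_tsv, gaf=gaf,
        go_names_tsv=go_names_tsv, seed=seed,
        planted_triples=[{k: v for k, v in t.items()} for t in triples],
        decoys={cls: {"gene": g, "accession": accession[g],
                      "stage": DECOY_STAGES[cls]}
                for cls, g in decoy_genes.items()},
    )
    (root / "ground_truth.json").write_text(
        json.dumps(world.ground_truth(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return world
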