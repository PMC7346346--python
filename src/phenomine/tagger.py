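"""Linear-chain CRF sequence tagger for adverse-reaction mention detection.

The model is a standard log-linear chain CRF: per-position state
potentials (sparse binary features x tag weights) plus a first-order
transition matrix.  Entities are encoded in the BIEO scheme — a
single-token entity is ``B-type`` alone, a two-token entity
``B-type E-type``, longer runs ``B (I)* E``.  Sentences are the sequence
unit; labels never cross sentence boundaries.

Training is full-batch L-BFGS on the L2-regularized negative
log-likelihood, with exact gradients from forward-backward marginals.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .corpus_io import AnnotatedDocument, EntityMention, TextSpan, Token

log = logging.getLogger("phenomine.tagger")

MODEL_FORMAT_VERSION = "phenomine-crf-1"


# ---------------------------------------------------------------------------
# Label scheme and BIEO codec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelScheme:
    """BIEO tag inventory over an ordered list of entity types.

    Tag 0 is always ``O``; each entity type contributes ``B-``, ``I-``
    and ``E-`` tags in order.
    """

    entity_types: tuple[str, ...]

    @property
    def tags(self) -> list[str]:
        out = ["O"]
        for t in self.entity_types:
            out += [f"B-{t}", f"I-{t}", f"E-{t}"]
        return out

    @property
    def tag_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tags)}

    @property
    def n_tags(self) -> int:
        return 1 + 3 * len(self.entity_types)


def encode_bieo(tokens: list[Token], mentions: list[EntityMention],
                scheme: LabelScheme) -> list[str]:
    """Tag each token: B/I/E inside a mention's token run, O elsewhere.

    Mentions must align to contiguous, non-overlapping token runs.
    """
    tags = ["O"] * len(tokens)
    starts = {t.span.start: i for i, t in enumerate(tokens)}
    ends = {t.span.end: i for i, t in enumerate(tokens)}
    claimed: dict[int, EntityMention] = {}
    for m in sorted(mentions, key=lambda m: m.span.start):
        if m.type not in scheme.entity_types:
            raise ValueError(f"mention type {m.type!r} not in scheme")
        if m.span.start not in starts or m.span.end not in ends:
            raise ValueError(
                f"mention [{m.span.start},{m.span.end}) not token-aligned")
        i, j = starts[m.span.start], ends[m.span.end]
        for k in range(i, j + 1):
            if k in claimed:
                raise ValueError(f"overlapping mentions: {claimed[k]} and {m}")
            claimed[k] = m
        if i == j:
            tags[i] = f"B-{m.type}"
        else:
            tags[i] = f"B-{m.type}"
            tags[j] = f"E-{m.type}"
            for k in range(i + 1, j):
                tags[k] = f"I-{m.type}"
    return tags


def decode_bieo(tags: list[str], tokens: list[Token]) -> list[EntityMention]:
    """Inverse of :func:`encode_bieo`, with repair of ill-formed runs.

    Repair policy: an orphan ``I-`` or ``E-`` opens (or extends) an
    entity; an entity closes at ``E``, at a tag/type change, or at the
    end of the sequence.  A lone ``B`` is a complete single-token
    entity.
    """
    if len(tags) != len(tokens):
        raise ValueError("tags and tokens length mismatch")
    mentions: list[EntityMention] = []
    open_type: str | None = None
    open_start = 0
    repaired = 0

    def close(upto: int) -> None:
        nonlocal open_type
        if open_type is not None:
            start_tok, end_tok = tokens[open_start], tokens[upto]
            doc_id = start_tok.span.doc_id
            mentions.append(EntityMention(
                TextSpan(doc_id, start_tok.span.start, end_tok.span.end,
                         _run_text(tokens[open_start: upto + 1])),
                open_type))
            open_type = None

    for i, tag in enumerate(tags):
        if tag == "O":
            close(i - 1)
            continue
        if "-" not in tag or tag[0] not in "BIE":
            raise ValueError(f"unknown tag {tag!r}")
        role, etype = tag.split("-", 1)
        if role == "B":
            close(i - 1)
            open_type, open_start = etype, i
        elif role in ("I", "E"):
            if open_type != etype:  # orphan I/E opens a fresh entity
                close(i - 1)
                repaired += 1
                open_type, open_start = etype, i
        if role == "E" and open_type == etype:
            close(i)
    close(len(tags) - 1)
    if repaired:
        log.debug("decode_bieo repaired %d ill-formed runs", repaired)
    return mentions


def _run_text(run: list[Token]) -> str:
    """Surface text of a token run, reconstructed with single spaces."""
    return " ".join(t.text for t in run)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureTemplateConfig:
    """Which feature templates fire at each position.

    window: context half-width for token-identity features.
    affix_max_len: longest prefix/suffix emitted.
    """

    window: int = 2
    use_lexicon: bool = True
    affix_max_len: int = 3
    use_shape: bool = True

    def __post_init__(self) -> None:
        if self.window < 0 or self.affix_max_len < 0:
            raise ValueError("window and affix_max_len must be >= 0")


def _shape(tok: str) -> str:
    out = []
    for ch in tok:
        if ch.isupper():
            c = "A"
        elif ch.islower():
            c = "a"
        elif ch.isdigit():
            c = "9"
        else:
            c = "-"
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


def _lexicon_roles(lower_tokens: list[str], lexicon: set[str],
                   max_len: int = 8) -> list[str | None]:
    """Greedy longest-match, left to right, over normalized tokens.

    Returns per-position role B/I/E/U for positions inside a match.
    """
    roles: list[str | None] = [None] * len(lower_tokens)
    i = 0
    while i < len(lower_tokens):
        best = 0
        for n in range(min(max_len, len(lower_tokens) - i), 0, -1):
            if " ".join(lower_tokens[i: i + n]) in lexicon:
                best = n
                break
        if best == 0:
            i += 1
        elif best == 1:
            roles[i] = "U"
            i += 1
        else:
            roles[i] = "B"
            for k in range(i + 1, i + best - 1):
                roles[k] = "I"
            roles[i + best - 1] = "E"
            i += best
    return roles


def extract_features(sentence: list[Token], lexicon: set[str],
                     template: FeatureTemplateConfig) -> list[list[str]]:
    """Per-position sparse feature-string lists for one sentence."""
    lowers = [t.text.lower() for t in sentence]
    lex_roles = (_lexicon_roles(lowers, lexicon)
                 if template.use_lexicon and lexicon else [None] * len(sentence))
    feats: list[list[str]] = []
    n = len(sentence)
    for i in range(n):
        f = ["bias"]
        for d in range(-template.window, template.window + 1):
            j = i + d
            word = lowers[j] if 0 <= j < n else "<pad>"
            f.append(f"w[{d}]={word}")
        if template.use_shape:
            f.append(f"shape={_shape(sentence[i].text)}")
        w = lowers[i]
        for k in range(1, min(template.affix_max_len, len(w)) + 1):
            f.append(f"pre{k}={w[:k]}")
            f.append(f"suf{k}={w[-k:]}")
        if lex_roles[i] is not None:
            f.append(f"LEX-{lex_roles[i]}")
        feats.append(f)
    return feats


def doc_feature_sequences(doc: AnnotatedDocument, lexicon: set[str],
                          template: FeatureTemplateConfig):
    """(sentence tokens, per-position features) pairs for a document."""
    return [(sent, extract_features(sent, lexicon, template))
            for sent in doc.sentences()]


# ---------------------------------------------------------------------------
# Model and lattice
# ---------------------------------------------------------------------------

@dataclass
class CRFModel:
    scheme: LabelScheme
    feature_index: dict[str, int]
    state_weights: np.ndarray       # [n_features, n_tags]
    transition_weights: np.ndarray  # [n_tags, n_tags]
    template: FeatureTemplateConfig = field(default_factory=FeatureTemplateConfig)
    l2: float = 1.0
    metadata: dict = field(default_factory=dict)

    @classmethod
    def zeros(cls, scheme: LabelScheme, feature_index: dict[str, int],
              template: FeatureTemplateConfig | None = None,
              l2: float = 1.0) -> "CRFModel":
        k = scheme.n_tags
        return cls(scheme, feature_index,
                   np.zeros((len(feature_index), k)), np.zeros((k, k)),
                   template or FeatureTemplateConfig(), l2)

    def feature_ids(self, feats: list[list[str]]) -> list[list[int]]:
        """Map feature strings to ids; unknown features dropped."""
        idx = self.feature_index
        return [[idx[f] for f in pos if f in idx] for pos in feats]

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "format": MODEL_FORMAT_VERSION,
            "entity_types": list(self.scheme.entity_types),
            "template": vars(self.template).copy(),
            "l2": self.l2,
            "feature_index": self.feature_index,
            "state_weights": self.state_weights.tolist(),
            "transition_weights": self.transition_weights.tolist(),
            "metadata": self.metadata,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "CRFModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {payload.get('format')!r}")
        return cls(
            LabelScheme(tuple(payload["entity_types"])),
            payload["feature_index"],
            np.asarray(payload["state_weights"], dtype=float),
            np.asarray(payload["transition_weights"], dtype=float),
            FeatureTemplateConfig(**payload["template"]),
            payload["l2"],
            payload.get("metadata", {}),
        )


@dataclass
class ScoreLattice:
    """Log-potentials of one sequence: [T, K] state + [K, K] transition."""

    state_scores: np.ndarray
    transition_scores: np.ndarray

    @property
    def T(self) -> int:
        return self.state_scores.shape[0]

    @property
    def K(self) -> int:
        return self.state_scores.shape[1]


def build_lattice(model: CRFModel, feat_ids: list[list[int]]) -> ScoreLattice:
    """Sum active feature weight rows into per-position state scores."""
    k = model.scheme.n_tags
    state = np.zeros((len(feat_ids), k))
    for t, ids in enumerate(feat_ids):
        if ids:
            state[t] = model.state_weights[ids].sum(axis=0)
    return ScoreLattice(state, model.transition_weights)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def log_partition(lattice: ScoreLattice) -> float:
    """log sum over all tag paths of exp(path score), via the forward pass."""
    if lattice.T == 0:
        raise ValueError("empty lattice")
    alpha = lattice.state_scores[0].copy()
    for t in range(1, lattice.T):
        alpha = logsumexp(alpha[:, None] + lattice.transition_scores, axis=0) \
            + lattice.state_scores[t]
    return float(logsumexp(alpha))


def forward_backward(lattice: ScoreLattice):
    """Position marginals [T, K] and pairwise marginals [T-1, K, K]."""
    T, K = lattice.T, lattice.K
    trans = lattice.transition_scores
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    alpha[0] = lattice.state_scores[0]
    for t in range(1, T):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + trans, axis=0) \
            + lattice.state_scores[t]
    beta[T - 1] = 0.0
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(
            trans + (lattice.state_scores[t + 1] + beta[t + 1])[None, :], axis=1)
    logz = logsumexp(alpha[T - 1])
    node = np.exp(alpha + beta - logz)
    pair = np.empty((max(T - 1, 0), K, K))
    for t in range(T - 1):
        m = (alpha[t][:, None] + trans
             + (lattice.state_scores[t + 1] + beta[t + 1])[None, :]) - logz
        pair[t] = np.exp(m)
    return node, pair, logz


def viterbi(lattice: ScoreLattice) -> tuple[list[int], float]:
    """Maximum-scoring tag path; ties break toward the lower tag index."""
    if lattice.T == 0:
        raise ValueError("empty lattice")
    T, K = lattice.T, lattice.K
    delta = lattice.state_scores[0].copy()
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + lattice.transition_scores
        back[t] = np.argmax(scores, axis=0)  # argmax picks lowest index on ties
        delta = scores[back[t], np.arange(K)] + lattice.state_scores[t]
    last = int(np.argmax(delta))
    best = float(delta[last])
    path = [last]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, best


# ---------------------------------------------------------------------------
# Training objective
# ---------------------------------------------------------------------------

def sequence_nll_grad(model: CRFModel, feat_ids: list[list[int]],
                      gold: list[int], grad_state: np.ndarray,
                      grad_trans: np.ndarray) -> float:
    """Add one sequence's NLL gradient contributions in place; return NLL."""
    lattice = build_lattice(model, feat_ids)
    node, pair, logz = forward_backward(lattice)
    gold_score = lattice.state_scores[np.arange(lattice.T), gold].sum()
    if lattice.T > 1:
        gold_score += lattice.transition_scores[gold[:-1], gold[1:]].sum()
    # expected minus empirical feature counts
    for t, ids in enumerate(feat_ids):
        if not ids:
            continue
        diff = node[t].copy()
        diff[gold[t]] -= 1.0
        grad_state[ids] += diff
    if lattice.T > 1:
        grad_trans += pair.sum(axis=0)
        np.add.at(grad_trans, (gold[:-1], gold[1:]), -1.0)
    return float(logz - gold_score)


def nll_and_gradient(model: CRFModel,
                     batch: list[tuple[list[list[int]], list[int]]]):
    """L2-regularized NLL and its gradient over a batch of sequences.

    ``batch`` holds (per-position feature-id lists, gold tag indices)
    pairs.  Returns (value, (state gradient, transition gradient)).
    """
    grad_state = np.zeros_like(model.state_weights)
    grad_trans = np.zeros_like(model.transition_weights)
    value = 0.0
    for feat_ids, gold in batch:
        if feat_ids:
            value += sequence_nll_grad(model, feat_ids, gold, grad_state, grad_trans)
    value += 0.5 * model.l2 * (
        float(np.sum(model.state_weights ** 2))
        + float(np.sum(model.transition_weights ** 2)))
    grad_state += model.l2 * model.state_weights
    grad_trans += model.l2 * model.transition_weights
    return value, (grad_state, grad_trans)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _index_features(docs, lexicon, template) -> dict[str, int]:
    idx: dict[str, int] = {}
    for doc in docs:
        for sent in doc.sentences():
            for pos in extract_features(sent, lexicon, template):
                for f in pos:
                    if f not in idx:
                        idx[f] = len(idx)
    return idx


def _doc_batch(doc: AnnotatedDocument, model: CRFModel, lexicon, template):
    """Per-sentence (feature ids, gold tag indices) for a training doc."""
    tag_idx = model.scheme.tag_index
    out = []
    for sent in doc.sentences():
        span_lo, span_hi = sent[0].span.start, sent[-1].span.end
        local = [m for m in doc.mentions
                 if m.span.start >= span_lo and m.span.end <= span_hi]
        tags = encode_bieo(sent, local, model.scheme)
        feats = extract_features(sent, lexicon, template)
        out.append((model.feature_ids(feats), [tag_idx[t] for t in tags]))
    return out


def train_crf(train: list[AnnotatedDocument], dev: list[AnnotatedDocument],
              lexicon: set[str], template: FeatureTemplateConfig | None = None,
              l2: float = 1.0, max_iter: int = 200, tol: float = 1e-6,
              seed: int = 0,
              entity_types: tuple[str, ...] | None = None) -> CRFModel:
    """Fit a CRF by full-batch L-BFGS on the regularized NLL.

    Records dev entity-level micro-F after every optimizer iteration and
    returns the weights with the best dev micro-F (train micro-F when
    ``dev`` is empty).  Deterministic given the inputs and seed.
    """
    if not train:
        raise ValueError("empty training set")
    template = template or FeatureTemplateConfig()
    if entity_types is None:
        seen = {m.type for d in train for m in d.mentions}
        entity_types = tuple(t for t in
                             ("AdverseReaction", "Severity", "Factor",
                              "DrugClass", "Negation", "Animal") if t in seen)
        if not entity_types:
            entity_types = ("AdverseReaction",)
    scheme = LabelScheme(entity_types)
    feature_index = _index_features(train, lexicon, template)
    model = CRFModel.zeros(scheme, feature_index, template, l2)
    model.metadata = {"seed": seed, "n_train": len(train), "n_dev": len(dev),
                      "dev_f_trace": []}
    if max_iter == 0:
        return model

    batch = []
    for doc in train:
        batch.extend(_doc_batch(doc, model, lexicon, template))
    nf, k = len(feature_index), scheme.n_tags

    def unpack(x):
        model.state_weights = x[: nf * k].reshape(nf, k)
        model.transition_weights = x[nf * k:].reshape(k, k)

    def fun(x):
        unpack(x)
        value, (gs, gt) = nll_and_gradient(model, batch)
        return value, np.concatenate([gs.ravel(), gt.ravel()])

    eval_docs = dev if dev else train
    best = {"f": -1.0, "x": np.zeros(nf * k + k * k)}

    def callback(xk):
        unpack(xk)
        gold = {d.doc_id: d.mentions for d in eval_docs}
        pred = {d.doc_id: predict(model, d, lexicon) for d in eval_docs}
        f = evaluate(gold, pred).micro.f_score
        model.metadata["dev_f_trace"].append(f)
        if f > best["f"]:
            best["f"], best["x"] = f, xk.copy()

    x0 = np.zeros(nf * k + k * k)
    res = minimize(fun, x0, jac=True, method="L-BFGS-B", callback=callback,
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8})
    callback(res.x)
    unpack(best["x"])
    model.metadata["best_dev_f"] = best["f"]
    model.metadata["n_iter"] = int(res.nit)
    return model


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(model: CRFModel, doc: AnnotatedDocument,
            lexicon: set[str] | None = None) -> list[EntityMention]:
    """Tag a document sentence by sentence: features -> Viterbi -> decode."""
    lexicon = lexicon or set()
    mentions: list[EntityMention] = []
    tags_list = model.scheme.tags
    for sent in doc.sentences():
        feats = extract_features(sent, lexicon, model.template)
        lattice = build_lattice(model, model.feature_ids(feats))
        path, _ = viterbi(lattice)
        mentions.extend(decode_bieo([tags_list[i] for i in path], sent))
    return mentions


# ---------------------------------------------------------------------------
# Entity-level evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeMetrics:
    precision: float  # percent
    recall: float
    f_score: float
    gold_count: int
    pred_count: int
    correct_count: int


@dataclass
class EvalReport:
    per_type: dict[str, TypeMetrics]
    micro: TypeMetrics

    def as_dict(self) -> dict:
        rows = {t: vars(m) for t, m in self.per_type.items()}
        rows["micro"] = vars(self.micro)
        return rows


def f_from(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percent scale); 0 when both 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _metrics(gold: int, pred: int, correct: int) -> TypeMetrics:
    p = 100.0 * correct / pred if pred else 0.0
    r = 100.0 * correct / gold if gold else 0.0
    return TypeMetrics(p, r, f_from(p, r), gold, pred, correct)


def evaluate(gold: dict[str, list[EntityMention]],
             pred: dict[str, list[EntityMention]]) -> EvalReport:
    """Exact-match entity-level P/R/F (percent), per type and micro-averaged.

    A prediction is correct iff its (type, start, end) matches an
    unconsumed gold mention of the same document.
    """
    if set(gold) != set(pred):
        raise ValueError("gold and pred must cover the same doc ids")
    counts: dict[str, list[int]] = {}  # type -> [gold, pred, correct]
    for doc_id in gold:
        gold_keys: dict[tuple, int] = {}
        for m in gold[doc_id]:
            key = (m.type, m.span.start, m.span.end)
            gold_keys[key] = gold_keys.get(key, 0) + 1
            counts.setdefault(m.type, [0, 0, 0])[0] += 1
        for m in pred[doc_id]:
            key = (m.type, m.span.start, m.span.end)
            c = counts.setdefault(m.type, [0, 0, 0])
            c[1] += 1
            if gold_keys.get(key, 0) > 0:
                gold_keys[key] -= 1
                c[2] += 1
    per_type = {t: _metrics(*c) for t, c in sorted(counts.items())}
    totals = [sum(c[i] for c in counts.values()) for i in range(3)]
    return EvalReport(per_type, _metrics(*totals))
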