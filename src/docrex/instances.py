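"""Document-level relation instance construction.

A document annotated at concept-pair level (e.g. the CDR corpus) is turned
into one classification instance per (chemical concept, disease concept)
combination.  The instance text is the contiguous block of sentences from
the first to the last sentence containing a mention of either target
concept — all evidence for the pair, nothing labeled per sentence.  The
module also provides the heuristic intra/inter splitter used by prior work
as a comparison baseline.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from .corpus import (
    CHEMICAL,
    DISEASE,
    Document,
    Mention,
    SentenceSegmentation,
    split_sentences,
)

logger = logging.getLogger(__name__)

NEGATIVE_LABEL = "negative"


class InstanceConstructionError(ValueError):
    """A target concept has no mention in the document."""


@dataclass(frozen=True, order=True)
class EntityPair:
    chemical_id: str
    disease_id: str


@dataclass
class Instance:
    """One candidate entity pair plus the sentence span covering its mentions.

    Offsets in ``target_mentions`` / ``other_mentions`` are re-based to
    ``text`` (the covered sentences joined by single spaces) and always
    slice it to the original surface strings.
    """

    doc_id: str
    pair: EntityPair
    sentence_range: tuple[int, int]
    text: str
    target_mentions: list[Mention] = field(default_factory=list)
    other_mentions: list[Mention] = field(default_factory=list)
    label: str = NEGATIVE_LABEL

    @property
    def n_sentences(self) -> int:
        return self.sentence_range[1] - self.sentence_range[0] + 1

    @property
    def n_tokens(self) -> int:
        """Whitespace token count of the instance text."""
        return len(self.text.split())


def enumerate_entity_pairs(doc: Document) -> list[EntityPair]:
    """All (chemical concept, disease concept) combinations of a document.

    One pair per distinct ID combination, ordered lexicographically by
    chemical then disease ID.  A document with C chemical and D disease
    concepts yields C×D pairs.
    """
    chems = sorted({m.concept_id for m in doc.mentions if m.entity_type == CHEMICAL})
    diseases = sorted({m.concept_id for m in doc.mentions if m.entity_type == DISEASE})
    return [EntityPair(c, d) for c in chems for d in diseases]


def dedupe_relations(doc: Document) -> list:
    """Gold relations deduplicated by (type, id1, id2)."""
    seen = set()
    out = []
    for r in doc.relations:
        key = (r.relation_type, r.concept_id_1, r.concept_id_2)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def unmatched_relations(doc: Document) -> list:
    """Relations whose chemical or disease concept never appears as a mention."""
    ids = {m.concept_id for m in doc.mentions}
    return [
        r
        for r in dedupe_relations(doc)
        if r.concept_id_1 not in ids or r.concept_id_2 not in ids
    ]


def _pair_label(doc: Document, pair: EntityPair) -> str:
    for r in dedupe_relations(doc):
        if {r.concept_id_1, r.concept_id_2} == {pair.chemical_id, pair.disease_id}:
            return r.relation_type
    return NEGATIVE_LABEL


def build_instance(
    doc: Document, seg: SentenceSegmentation, pair: EntityPair
) -> Instance:
    """Build the contiguous-span instance for one target pair.

    The sentence range is the min/max hull over the sentence indices of ALL
    mentions of either target concept; the covered sentences are joined by a
    single space and every mention inside the range is carried over with
    re-based offsets.  The label is the gold relation type for the pair, or
    ``negative`` when the document asserts none.
    """
    target_idx = [
        i
        for i, m in enumerate(doc.mentions)
        if (m.concept_id == pair.chemical_id and m.entity_type == CHEMICAL)
        or (m.concept_id == pair.disease_id and m.entity_type == DISEASE)
    ]
    if not any(
        doc.mentions[i].concept_id == pair.chemical_id for i in target_idx
    ) or not any(doc.mentions[i].concept_id == pair.disease_id for i in target_idx):
        raise InstanceConstructionError(
            f"document {doc.doc_id}: pair {pair} has a concept with no mention"
        )
    sent_ids = [seg.mention_sentence[i] for i in target_idx]
    lo, hi = min(sent_ids), max(sent_ids)

    covered = seg.spans[lo : hi + 1]
    parts = [doc.text[s:e] for s, e in covered]
    text = " ".join(parts)
    # new start offset of each covered sentence inside the joined text
    new_starts: dict[int, int] = {}
    cursor = 0
    for offset, (s, e) in enumerate(covered):
        new_starts[lo + offset] = cursor
        cursor += (e - s) + 1

    target_set = set(target_idx)
    targets: list[Mention] = []
    others: list[Mention] = []
    for i, m in enumerate(doc.mentions):
        s_idx = seg.mention_sentence[i]
        if not (lo <= s_idx <= hi):
            continue
        span_start = seg.spans[s_idx][0]
        rebased = Mention(
            start=new_starts[s_idx] + (m.start - span_start),
            end=new_starts[s_idx] + (m.end - span_start),
            text=m.text,
            entity_type=m.entity_type,
            concept_id=m.concept_id,
            source_type=m.source_type,
        )
        (targets if i in target_set else others).append(rebased)
    return Instance(
        doc_id=doc.doc_id,
        pair=pair,
        sentence_range=(lo, hi),
        text=text,
        target_mentions=targets,
        other_mentions=others,
        label=_pair_label(doc, pair),
    )


def build_document_instances(
    doc: Document, seg: SentenceSegmentation | None = None
) -> list[Instance]:
    """All instances of one document (one per chemical×disease combination)."""
    if seg is None:
        seg = split_sentences(doc)
    dropped = unmatched_relations(doc)
    if dropped:
        logger.warning(
            "document %s: %d relation(s) reference concepts with no mention "
            "and cannot label any instance", doc.doc_id, len(dropped)
        )
    return [build_instance(doc, seg, p) for p in enumerate_entity_pairs(doc)]


def build_corpus_instances(docs: Iterable[Document]) -> list[Instance]:
    out: list[Instance] = []
    for doc in docs:
        out.extend(build_document_instances(doc))
    return out


# token distance -------------------------------------------------------------

_TOKEN_RE = re.compile(r"\S+")


def token_distance(sentence_text: str, mention_a: Mention, mention_b: Mention) -> int:
    """Whitespace-token index difference between two mentions' edge tokens.

    The sentence is split on whitespace with punctuation left attached to
    its word; the distance is the index of the first token overlapping the
    later mention minus the index of the last token overlapping the earlier
    mention.  Symmetric in argument order; adjacent tokens are at distance 1.
    """
    spans = [m.span() for m in _TOKEN_RE.finditer(sentence_text)]
    first, second = sorted((mention_a, mention_b), key=lambda m: (m.start, m.end))

    def overlapping(m: Mention) -> list[int]:
        idx = [i for i, (s, e) in enumerate(spans) if s < m.end and m.start < e]
        if not idx or not (0 <= m.start < m.end <= len(sentence_text)):
            raise ValueError(
                f"mention {m.text!r} [{m.start},{m.end}) lies outside the sentence"
            )
        return idx

    last_of_first = overlapping(first)[-1]
    first_of_second = overlapping(second)[0]
    return max(first_of_second - last_of_first, 0)


# heuristic intra/inter baseline --------------------------------------------


def heuristic_split(
    doc: Document,
    seg: SentenceSegmentation | None = None,
    threshold: int = 10,
) -> tuple[list[Instance], list[Instance]]:
    """Prior-work baseline: split pairs into intra- and inter-sentence instances.

    An intra-sentence instance is a single sentence containing a mention of
    each target concept whose token distance is below ``threshold``.  A pair
    with at least one intra instance contributes nothing at the inter level;
    every remaining pair yields one contiguous-span (inter) instance.
    """
    if seg is None:
        seg = split_sentences(doc)
    intra: list[Instance] = []
    inter: list[Instance] = []
    for pair in enumerate_entity_pairs(doc):
        label = _pair_label(doc, pair)
        pair_intra: list[Instance] = []
        for s_idx, (s, e) in enumerate(seg.spans):
            sent_text = doc.text[s:e]
            chems = [
                _rebase(m, s)
                for i, m in enumerate(doc.mentions)
                if seg.mention_sentence[i] == s_idx
                and m.entity_type == CHEMICAL
                and m.concept_id == pair.chemical_id
            ]
            dis = [
                _rebase(m, s)
                for i, m in enumerate(doc.mentions)
                if seg.mention_sentence[i] == s_idx
                and m.entity_type == DISEASE
                and m.concept_id == pair.disease_id
            ]
            hits = [
                (mc, md)
                for mc in chems
                for md in dis
                if token_distance(sent_text, mc, md) < threshold
            ]
            if hits:
                pair_intra.append(
                    Instance(
                        doc_id=doc.doc_id,
                        pair=pair,
                        sentence_range=(s_idx, s_idx),
                        text=sent_text,
                        target_mentions=chems + dis,
                        other_mentions=[],
                        label=label,
                    )
                )
        if pair_intra:
            intra.extend(pair_intra)
        else:
            inter.append(build_instance(doc, seg, pair))
    return intra, inter


def _rebase(m: Mention, sentence_start: int) -> Mention:
    return Mention(
        start=m.start - sentence_start,
        end=m.end - sentence_start,
        text=m.text,
        entity_type=m.entity_type,
        concept_id=m.concept_id,
        source_type=m.source_type,
    )


# JSONL serialization --------------------------------------------------------


def _mention_to_dict(m: Mention) -> dict:
    return {
        "start": m.start,
        "end": m.end,
        "text": m.text,
        "entity_type": m.entity_type,
        "concept_id": m.concept_id,
    }


def _mention_from_dict(d: dict) -> Mention:
    return Mention(
        start=d["start"],
        end=d["end"],
        text=d["text"],
        entity_type=d["entity_type"],
        concept_id=d["concept_id"],
    )


def instance_to_dict(inst: Instance) -> dict:
    return {
        "doc_id": inst.doc_id,
        "pair": {"chemical_id": inst.pair.chemical_id, "disease_id": inst.pair.disease_id},
        "sentence_range": list(inst.sentence_range),
        "text": inst.text,
        "target_mentions": [_mention_to_dict(m) for m in inst.target_mentions],
        "other_mentions": [_mention_to_dict(m) for m in inst.other_mentions],
        "label": inst.label,
    }


def instance_from_dict(d: dict) -> Instance:
    return Instance(
        doc_id=d["doc_id"],
        pair=EntityPair(d["pair"]["chemical_id"], d["pair"]["disease_id"]),
        sentence_range=tuple(d["sentence_range"]),
        text=d["text"],
        target_mentions=[_mention_from_dict(m) for m in d["target_mentions"]],
        other_mentions=[_mention_from_dict(m) for m in d["other_mentions"]],
        label=d["label"],
    )


def write_instances_jsonl(instances: Sequence[Instance], sink: IO[str]) -> None:
    for inst in instances:
        sink.write(json.dumps(instance_to_dict(inst)) + "\n")


def read_instances_jsonl(stream: IO[str] | Iterable[str]) -> list[Instance]:
    return [instance_from_dict(json.loads(line)) for line in stream if line.strip()]


def corpus_statistics(instances: Sequence[Instance], bin_width: int = 50) -> dict:
    """Instance-set statistics: counts, label balance, mean span sizes, and a
    token-length histogram with the given bin width."""
    n = len(instances)
    positives = sum(1 for i in instances if i.label != NEGATIVE_LABEL)
    lengths = [i.n_tokens for i in instances]
    hist: dict[str, int] = {}
    for L in lengths:
        b = min((max(L, 1) - 1) // bin_width, 8)
        key = f">{8 * bin_width}" if b == 8 else f"{b * bin_width + 1}-{(b + 1) * bin_width}"
        hist[key] = hist.get(key, 0) + 1
    return {
        "instances": n,
        "positive": positives,
        "negative": n - positives,
        "sentences_per_instance": (
            sum(i.n_sentences for i in instances) / n if n else 0.0
        ),
        "tokens_per_instance": (sum(lengths) / n if n else 0.0),
        "length_histogram": hist,
    }
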