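"""Synthetic PubTator corpora with planted, learnable relation structure.

The generator emulates the structure of document-level annotated corpora
such as CDR: multi-sentence abstracts with typed chemical/disease mentions
at exact character offsets, concept identifiers, and gold relations given
per concept pair.  Positive documents carry lexical relation cues
("induced", "caused", …) near or between the target mentions — optionally
in a different sentence than the chemical — while negative documents use
distractor verbs, so the planted signal is learnable by construction.  Text
is templated English-like filler; only the statistical and structural
properties matter.

Relations are drawn at document level (all of a document's chemical–disease
pairs are related, or none): because an instance spans the hull of all
target-concept mentions, a per-pair cue sentence would leak into the hull
of every other pair sharing its chemical, making per-pair labels
inconsistent with cue presence.  Document-level positivity keeps cue
presence and label in exact correspondence at cue strength 1.0.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .corpus import CHEMICAL, DISEASE, Document, Mention, Relation
from .instances import EntityPair, Instance

CHEMICAL_LEXICON = (
    "aspirin", "lithium", "haloperidol", "warfarin", "cisplatin", "morphine",
    "ketamine", "amiodarone", "clozapine", "gentamicin", "phenytoin", "metformin",
)
DISEASE_LEXICON = (
    "nausea", "seizures", "hypotension", "bradycardia", "nephrotoxicity",
    "headache", "tremor", "hepatitis", "rash", "delirium", "anemia", "fever",
)
FILLER_SENTENCES = (
    "The clinical course was otherwise unremarkable.",
    "Routine laboratory values stayed within normal limits.",
    "The patient was discharged in stable condition.",
    "Follow-up visits were scheduled at regular intervals.",
    "No further interventions were required.",
    "Vital signs were checked every four hours.",
)

_SYLLABLES = ("vor", "zal", "mek", "tar", "lun", "pex", "rin", "quo", "bas", "fim")


class SyntheticConfigError(ValueError):
    """The requested corpus shape is infeasible."""


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic corpus generator.

    ``positive_pair_rate`` is the probability that a document asserts
    relations (see module docstring); ``cross_sentence_fraction`` the
    probability that a positive pair's cue evidence spans two sentences;
    ``cue_strength`` the probability a positive pair emits its cue at all.
    ``nonce_entities`` replaces the small realistic surface-form lexicons
    with randomized nonce words, so no lexical prior links surface form and
    label.
    """

    n_docs: int = 200
    sentences_per_doc: tuple[int, int] = (3, 6)
    chemicals_per_doc: tuple[int, int] = (1, 1)
    diseases_per_doc: tuple[int, int] = (1, 2)
    mentions_per_concept: tuple[int, int] = (1, 2)
    positive_pair_rate: float = 0.3
    cross_sentence_fraction: float = 0.5
    cue_lexicon: tuple[str, ...] = ("induced", "caused", "triggered", "provoked")
    distractor_lexicon: tuple[str, ...] = ("measured", "recorded", "monitored", "assessed")
    cue_strength: float = 1.0
    nonce_entities: bool = False
    relation_type: str = "CID"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.positive_pair_rate, self.cross_sentence_fraction, self.cue_strength):
            if not 0.0 <= p <= 1.0:
                raise SyntheticConfigError(f"probability {p} outside [0, 1]")
        for r in (self.sentences_per_doc, self.chemicals_per_doc,
                  self.diseases_per_doc, self.mentions_per_concept):
            if r[0] > r[1] or r[0] < (0 if r is self.mentions_per_concept else 1):
                raise SyntheticConfigError(f"empty or invalid range {r}")
        if self.chemicals_per_doc[1] * self.diseases_per_doc[1] > self.sentences_per_doc[1] * 2:
            raise SyntheticConfigError(
                "more concept pairs than the sentence budget can host"
            )


_Part = str | tuple[str, str, str]  # literal text | (surface, type, concept_id)


class _DocBuilder:
    """Accumulates sentences built from literal/mention parts, tracking offsets."""

    def __init__(self, doc_id: str, title: str) -> None:
        self.doc = Document(doc_id=doc_id, title=title, abstract="")
        self._cursor = len(title)  # next sentence starts at cursor + 1

    def add_sentence(self, parts: Sequence[_Part]) -> None:
        start = self._cursor + 1  # single joining space
        text = ""
        for part in parts:
            if isinstance(part, str):
                text += part
            else:
                surface, etype, cid = part
                self.doc.mentions.append(
                    Mention(
                        start=start + len(text),
                        end=start + len(text) + len(surface),
                        text=surface,
                        entity_type=etype,
                        concept_id=cid,
                    )
                )
                text += surface
        self.doc.abstract += (" " if self.doc.abstract else "") + text
        self._cursor = start + len(text)

    def finish(self) -> Document:
        self.doc.mentions.sort(key=lambda m: (m.start, m.end))
        self.doc.validate()
        return self.doc


def _nonce_word(rng: random.Random, suffix: str) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(3)) + suffix


def _pick_surfaces(rng: random.Random, n: int, lexicon: Sequence[str],
                   nonce: bool, suffix: str) -> list[str]:
    if not nonce:
        return rng.sample(list(lexicon), n)
    out: set[str] = set()
    while len(out) < n:
        out.add(_nonce_word(rng, suffix))
    return sorted(out)


def generate_corpus(cfg: SyntheticConfig) -> list[Document]:
    """Generate a deterministic synthetic corpus (same config+seed → same docs)."""
    rng = random.Random(cfg.seed)
    docs: list[Document] = []
    for d in range(cfg.n_docs):
        docs.append(_generate_document(cfg, rng, d))
    return docs


def _generate_document(cfg: SyntheticConfig, rng: random.Random, index: int) -> Document:
    n_chem = rng.randint(*cfg.chemicals_per_doc)
    n_dis = rng.randint(*cfg.diseases_per_doc)
    chem_ids = [f"C{index:04d}{j}" for j in range(n_chem)]
    dis_ids = [f"D{index:04d}{j}" for j in range(n_dis)]
    chem_surface = dict(zip(chem_ids, _pick_surfaces(
        rng, n_chem, CHEMICAL_LEXICON, cfg.nonce_entities, "ine")))
    dis_surface = dict(zip(dis_ids, _pick_surfaces(
        rng, n_dis, DISEASE_LEXICON, cfg.nonce_entities, "osis")))
    positive = rng.random() < cfg.positive_pair_rate

    builder = _DocBuilder(str(10_000_000 + index), "A pharmacovigilance case report.")
    mention_count: dict[str, int] = {cid: 0 for cid in chem_ids + dis_ids}

    def chem(cid: str) -> _Part:
        mention_count[cid] += 1
        return (chem_surface[cid], CHEMICAL, cid)

    def dis(cid: str) -> _Part:
        mention_count[cid] += 1
        return (dis_surface[cid], DISEASE, cid)

    for c in chem_ids:
        for di in dis_ids:
            if positive and rng.random() < cfg.cue_strength:
                cue = rng.choice(cfg.cue_lexicon)
                if rng.random() < cfg.cross_sentence_fraction:
                    builder.add_sentence(
                        ["The patient received ", chem(c), " for several days."]
                    )
                    builder.add_sentence(
                        ["Severe ", dis(di), f" was {cue} by the regimen soon afterwards."]
                    )
                else:
                    builder.add_sentence(
                        ["Treatment with ", chem(c), f" {cue} acute ", dis(di),
                         " in this patient."]
                    )
            elif positive:
                builder.add_sentence(
                    ["Both ", chem(c), " and ", dis(di), " were documented during admission."]
                )
            else:
                verb = rng.choice(cfg.distractor_lexicon)
                builder.add_sentence(
                    [chem(c), " exposure and ", dis(di), f" symptoms were {verb} during follow-up."]
                )

    for cid in chem_ids + dis_ids:
        want = rng.randint(*cfg.mentions_per_concept)
        while mention_count[cid] < want:
            if cid in chem_surface:
                builder.add_sentence(["The ", chem(cid), " dose remained stable."])
            else:
                builder.add_sentence(["No worsening of ", dis(cid), " was recorded."])

    n_sentences = builder.doc.abstract.count(". ") + 2  # title + abstract sentences
    min_sentences = rng.randint(*cfg.sentences_per_doc)
    fillers = list(FILLER_SENTENCES)
    rng.shuffle(fillers)
    while n_sentences < min_sentences and fillers:
        builder.add_sentence([fillers.pop()])
        n_sentences += 1

    doc = builder.finish()
    if positive:
        doc.relations = [Relation(cfg.relation_type, c, di)
                         for c in chem_ids for di in dis_ids]
    return doc


# in-text worked-example fixtures -------------------------------------------


def figure1_fixture() -> Document:
    """A document with the entity/relation structure of the worked example:
    2 chemical concepts (C1, C2), 4 disease concepts (D1–D4), gold relations
    (C1, D2) and (C1, D4), laid out over four sentences a)–d) so that the
    (C1, D2) instance covers a)–d) and the (C1, D4) instance covers a)–c).

    The sentences are paraphrased; only the structure is reproduced.
    """
    b = _DocBuilder(
        "fixture-figure1",
        "Two cases of amisulpride overdose: a cause for prolonged QT syndrome.",
    )
    # the title is sentence a); mentions in it are recorded directly
    title = b.doc.title
    b.doc.mentions.extend([
        Mention(title.index("amisulpride"), title.index("amisulpride") + len("amisulpride"),
                "amisulpride", CHEMICAL, "C1"),
        Mention(title.index("overdose"), title.index("overdose") + len("overdose"),
                "overdose", DISEASE, "D1"),
        Mention(title.index("prolonged QT syndrome"),
                title.index("prolonged QT syndrome") + len("prolonged QT syndrome"),
                "prolonged QT syndrome", DISEASE, "D2"),
    ])
    b.add_sentence([  # b)
        "A young woman ingested a large amount of ",
        ("amisulpride", CHEMICAL, "C1"),
        " and was admitted with acute ",
        ("poisoning", DISEASE, "D3"),
        ".",
    ])
    b.add_sentence([  # c)
        "She developed ",
        ("hypocalcemia", DISEASE, "D4"),
        ", and intravenous ",
        ("calcium gluconate", CHEMICAL, "C2"),
        " corrected the deficit that followed the ",
        ("amisulpride", CHEMICAL, "C1"),
        " exposure.",
    ])
    b.add_sentence([  # d)
        "On the second day, ",
        ("QT prolongation", DISEASE, "D2"),
        " was documented and later resolved.",
    ])
    doc = b.finish()
    doc.relations = [Relation("CID", "C1", "D2"), Relation("CID", "C1", "D4")]
    return doc


def figure2_instance() -> Instance:
    """The single-sentence instance of the pretreatment worked example.

    Target pair: (amisulpride, prolonged QT syndrome); the disease mention
    "overdose" belongs to a different concept and is therefore a non-target
    entity.
    """
    text = "Two cases of amisulpride overdose: a cause for prolonged QT syndrome"

    def m(surface: str, etype: str, cid: str) -> Mention:
        start = text.index(surface)
        return Mention(start, start + len(surface), surface, etype, cid)

    return Instance(
        doc_id="fixture-figure2",
        pair=EntityPair("C1", "D2"),
        sentence_range=(0, 0),
        text=text,
        target_mentions=[m("amisulpride", CHEMICAL, "C1"),
                         m("prolonged QT syndrome", DISEASE, "D2")],
        other_mentions=[m("overdose", DISEASE, "D1")],
        label="CID",
    )


def distance_fixture() -> tuple[str, dict[str, Mention]]:
    """The heuristic-rule sentence with its five entity mentions.

    Under whitespace tokenization the token distance between
    "blurred vision" and "amitriptyline" is 12, above the threshold of 10
    that the heuristic intra-sentence rule applies.
    """
    text = (
        "The overall incidence of side effects and the frequency and severity "
        "of blurred vision, dry mouth, and drowsiness were significantly less "
        "with dothiepin than with amitriptyline."
    )

    def m(surface: str, etype: str, cid: str) -> Mention:
        start = text.index(surface)
        return Mention(start, start + len(surface), surface, etype, cid)

    mentions = {
        "blurred vision": m("blurred vision", DISEASE, "D014786"),
        "dry mouth": m("dry mouth", DISEASE, "D014987"),
        "drowsiness": m("drowsiness", DISEASE, "D006970"),
        "dothiepin": m("dothiepin", CHEMICAL, "D004308"),
        "amitriptyline": m("amitriptyline", CHEMICAL, "D000639"),
    }
    return text, mentions
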