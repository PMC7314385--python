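"""Entity pretreatment and WordPiece tokenization.

Two pretreatments make instances of the same document distinguishable by
their target pair and focus the classifier on the pair's context:

* **replacement** — every target chemical mention becomes the word
  ``chemical``, every target disease mention ``disease``, and every
  non-target entity mention ``entity``;
* **addition** — target mentions keep their surface form but are wrapped in
  boundary markers, ``[[ … ]]`` for chemicals and ``<< … >>`` for diseases,
  while non-target mentions are left untouched.

The tokenizer is uncased greedy longest-match-first WordPiece over
whitespace-split words, with ``##``-prefixed continuation pieces and the
usual ``[CLS]``/``[SEP]``/``[PAD]``/``[UNK]`` specials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np

from .corpus import CHEMICAL, DISEASE, Mention
from .instances import Instance

logger = logging.getLogger(__name__)

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"


@dataclass(frozen=True)
class PretreatmentConfig:
    mode: str = "replacement"  # "replacement" | "addition"
    chemical_word: str = "chemical"
    disease_word: str = "disease"
    entity_word: str = "entity"
    chemical_left: str = "[["
    chemical_right: str = "]]"
    disease_left: str = "<<"
    disease_right: str = ">>"

    def __post_init__(self) -> None:
        markers = {self.chemical_left, self.chemical_right,
                   self.disease_left, self.disease_right}
        if len(markers) != 4 or any(not m for m in markers):
            raise ValueError("boundary markers must be non-empty and distinct")


DEFAULT_PRETREATMENT = PretreatmentConfig()


def _select_rewrites(inst: Instance) -> list[tuple[Mention, bool]]:
    """Mentions to rewrite, longest-first on overlap, in ascending order.

    Returns (mention, is_target) with overlapping mentions resolved by
    keeping the longest; duplicate spans (composite-concept expansions)
    collapse to one rewrite.
    """
    candidates = [(m, True) for m in inst.target_mentions] + [
        (m, False) for m in inst.other_mentions
    ]
    # targets first, then longer spans, so a target beats an equal "other" span
    candidates.sort(key=lambda t: (-(t[0].end - t[0].start), not t[1], t[0].start))
    chosen: list[tuple[Mention, bool]] = []
    for m, is_target in candidates:
        clash = next(
            (c for c, _ in chosen if c.overlaps(m.start, m.end)), None
        )
        if clash is not None:
            if (clash.start, clash.end) != (m.start, m.end):
                logger.warning(
                    "document %s: mention %r [%d,%d) overlaps %r; keeping the longer",
                    inst.doc_id, m.text, m.start, m.end, clash.text,
                )
            continue
        chosen.append((m, is_target))
    chosen.sort(key=lambda t: t[0].start)
    return chosen


def apply_replacement(
    inst: Instance, config: PretreatmentConfig = DEFAULT_PRETREATMENT
) -> Instance:
    """Rewrite target mentions to uniform words and non-targets to ``entity``.

    Idempotent: the rewritten words are themselves valid mention surfaces,
    so a second application reproduces the same text.
    """
    pieces: list[str] = []
    cursor = 0
    new_targets: list[Mention] = []
    new_others: list[Mention] = []
    out_len = 0
    for m, is_target in _select_rewrites(inst):
        if is_target:
            word = (
                config.chemical_word
                if m.entity_type == CHEMICAL
                else config.disease_word
            )
        else:
            word = config.entity_word
        pieces.append(inst.text[cursor : m.start])
        out_len += m.start - cursor
        new = Mention(
            start=out_len,
            end=out_len + len(word),
            text=word,
            entity_type=m.entity_type,
            concept_id=m.concept_id,
            source_type=m.source_type,
        )
        (new_targets if is_target else new_others).append(new)
        pieces.append(word)
        out_len += len(word)
        cursor = m.end
    pieces.append(inst.text[cursor:])
    return replace(
        inst,
        text="".join(pieces),
        target_mentions=new_targets,
        other_mentions=new_others,
    )


def apply_addition(
    inst: Instance, config: PretreatmentConfig = DEFAULT_PRETREATMENT
) -> Instance:
    """Wrap target mentions in type-specific boundary markers.

    Chemical mentions become ``[[ text ]]`` and disease mentions
    ``<< text >>``; non-target mentions and all other text are unchanged.
    Re-based offsets keep pointing at the unwrapped surface form.
    """
    pieces: list[str] = []
    cursor = 0
    new_targets: list[Mention] = []
    new_others: list[Mention] = []
    out_len = 0
    for m, is_target in _select_rewrites(inst):
        pieces.append(inst.text[cursor : m.start])
        out_len += m.start - cursor
        if is_target:
            left, right = (
                (config.chemical_left, config.chemical_right)
                if m.entity_type == CHEMICAL
                else (config.disease_left, config.disease_right)
            )
            pieces.append(left + " ")
            out_len += len(left) + 1
            new_targets.append(replace(m, start=out_len, end=out_len + len(m.text)))
            pieces.append(m.text)
            out_len += len(m.text)
            pieces.append(" " + right)
            out_len += len(right) + 1
        else:
            new_others.append(replace(m, start=out_len, end=out_len + len(m.text)))
            pieces.append(m.text)
            out_len += len(m.text)
        cursor = m.end
    pieces.append(inst.text[cursor:])
    return replace(
        inst,
        text="".join(pieces),
        target_mentions=new_targets,
        other_mentions=new_others,
    )


def strip_markers(text: str, config: PretreatmentConfig = DEFAULT_PRETREATMENT) -> str:
    """Inverse of the addition pretreatment on the text level."""
    for marker in (config.chemical_left, config.disease_left):
        text = text.replace(marker + " ", "")
    for marker in (config.chemical_right, config.disease_right):
        text = text.replace(" " + marker, "")
    return text


def apply_pretreatment(
    inst: Instance, config: PretreatmentConfig = DEFAULT_PRETREATMENT
) -> Instance:
    """Dispatch to the pretreatment selected by ``config.mode``."""
    if config.mode == "replacement":
        return apply_replacement(inst, config)
    if config.mode == "addition":
        return apply_addition(inst, config)
    raise ValueError(f"unknown pretreatment mode {config.mode!r}")


# WordPiece ------------------------------------------------------------------


@dataclass
class TokenSequence:
    """A model-ready token sequence: ``[CLS] … [SEP]`` plus padding.

    ``mask`` is 1 on real tokens (including the specials) and 0 on padding;
    ``segment_ids`` is a single constant because instances are
    single-sequence inputs.
    """

    tokens: list[str]
    ids: np.ndarray
    positions: np.ndarray
    segment_ids: np.ndarray
    mask: np.ndarray

    @property
    def n(self) -> int:
        return len(self.tokens)

    @property
    def length(self) -> int:
        """Number of non-pad tokens."""
        return int(self.mask.sum())


class WordPieceTokenizer:
    """Uncased greedy longest-match-first WordPiece tokenizer.

    Any vocabulary file with one token per line is accepted; it must contain
    the four special tokens.  Continuation pieces carry the ``##`` prefix.
    """

    def __init__(self, vocab: Sequence[str], lowercase: bool = True,
                 max_word_chars: int = 100) -> None:
        self.vocab = list(vocab)
        self.lowercase = lowercase
        self.max_word_chars = max_word_chars
        self.token_to_id = {t: i for i, t in enumerate(self.vocab)}
        for special in (PAD, UNK, CLS, SEP):
            if special not in self.token_to_id:
                raise ValueError(f"vocabulary lacks required token {special!r}")
        self.pad_id = self.token_to_id[PAD]
        self.unk_id = self.token_to_id[UNK]

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "WordPieceTokenizer":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls([ln.rstrip("\n") for ln in lines if ln.strip()], **kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.vocab) + "\n", encoding="utf-8")

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    def tokenize_word(self, word: str) -> list[str]:
        """Greedy longest-match decomposition of one whitespace token."""
        if self.lowercase:
            word = word.lower()
        if not word or len(word) > self.max_word_chars:
            return [UNK] if word else []
        pieces: list[str] = []
        start = 0
        while start < len(word):
            end = len(word)
            piece = None
            while end > start:
                sub = word[start:end]
                if start > 0:
                    sub = "##" + sub
                if sub in self.token_to_id:
                    piece = sub
                    break
                end -= 1
            if piece is None:
                return [UNK]
            pieces.append(piece)
            start = end
        return pieces

    def tokenize(self, text: str) -> list[str]:
        out: list[str] = []
        for word in text.split():
            out.extend(self.tokenize_word(word))
        return out

    def encode(self, text: str, max_len: int) -> TokenSequence:
        """Tokenize and frame a text as ``[CLS] pieces [SEP]`` of width max_len.

        Sequences longer than ``max_len`` keep the head: the first
        ``max_len - 2`` content pieces survive truncation.
        """
        if max_len < 2:
            raise ValueError("max_len must allow [CLS] and [SEP]")
        pieces = self.tokenize(text)[: max_len - 2]
        tokens = [CLS] + pieces + [SEP]
        n_real = len(tokens)
        tokens = tokens + [PAD] * (max_len - n_real)
        ids = np.array([self.token_to_id.get(t, self.unk_id) for t in tokens],
                       dtype=np.int64)
        mask = np.zeros(max_len, dtype=np.int64)
        mask[:n_real] = 1
        return TokenSequence(
            tokens=tokens,
            ids=ids,
            positions=np.arange(max_len, dtype=np.int64),
            segment_ids=np.zeros(max_len, dtype=np.int64),
            mask=mask,
        )


def build_vocab(
    texts: Iterable[str],
    lowercase: bool = True,
    char_fallback: bool = True,
) -> list[str]:
    """Build a WordPiece vocabulary from a text corpus.

    Whole lowercased words become single pieces; with ``char_fallback`` every
    seen character is added both bare and as a ``##`` continuation so unseen
    inflections decompose instead of mapping to ``[UNK]``.
    """
    words: set[str] = set()
    chars: set[str] = set()
    for text in texts:
        for w in text.split():
            if lowercase:
                w = w.lower()
            words.add(w)
            chars.update(w)
    vocab = [PAD, UNK, CLS, SEP]
    vocab.extend(sorted(words))
    if char_fallback:
        vocab.extend(sorted(chars - words))
        vocab.extend("##" + c for c in sorted(chars))
    return vocab
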