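"""Uncased WordPiece vocabulary training and fixed-length encoding.

The trainer follows the WordPiece recipe: start from the single-character
alphabet (continuations prefixed "##"), then repeatedly merge the adjacent
symbol pair maximizing count(ab) / (count(a) * count(b)) over the word-
frequency-weighted corpus, until the vocabulary reaches the requested size
or no pairs remain. Encoding uses greedy longest-match-first decomposition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIAL_TOKENS = [PAD, UNK, CLS, SEP, MASK]

# Longest word (in characters) attempted before bailing out to [UNK].
MAX_WORD_CHARS = 100

_PRETOKEN = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def pretokenize(text: str) -> list[str]:
    """Lowercase and split into words and single punctuation marks."""
    return _PRETOKEN.findall(text.lower())


@dataclass
class Vocab:
    """Ordered WordPiece vocabulary; specials occupy ids 0..4."""

    tokens: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.tokens[: len(SPECIAL_TOKENS)] != SPECIAL_TOKENS:
            raise ValueError("specials must occupy the first 5 ids")
        self._index = {t: i for i, t in enumerate(self.tokens)}
        if len(self._index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def id(self, token: str) -> int:
        return self._index.get(token, self._index[UNK])

    def token(self, idx: int) -> str:
        return self.tokens[idx]

    @property
    def pad_id(self) -> int:
        return self._index[PAD]

    @property
    def unk_id(self) -> int:
        return self._index[UNK]

    @property
    def cls_id(self) -> int:
        return self._index[CLS]

    @property
    def sep_id(self) -> int:
        return self._index[SEP]

    @property
    def mask_id(self) -> int:
        return self._index[MASK]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(range(len(SPECIAL_TOKENS)))

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocab":
        tokens = Path(path).read_text(encoding="utf-8").splitlines()
        return cls([t for t in tokens if t])


@dataclass
class TokenSequence:
    """Fixed-length encoded sequence: ids plus aligned attention mask."""

    ids: list[int]
    attention_mask: list[int]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.attention_mask):
            raise ValueError("ids and attention mask must align")

    def __len__(self) -> int:
        return len(self.ids)


def _word_symbols(word: str) -> tuple[str, ...]:
    return tuple([word[0]] + ["##" + c for c in word[1:]])


def train_wordpiece(
    corpus: Iterable[str], vocab_size: int, seed: int = 0
) -> Vocab:
    """Train an uncased WordPiece vocabulary.

    Deterministic given (corpus, vocab_size); the seed parameter is accepted
    for interface uniformity with the other training entry points (the merge
    loop itself involves no randomness — ties break lexicographically).

    Raises ValueError if vocab_size cannot hold the specials plus the
    character alphabet of the corpus.
    """
    word_freq: dict[str, int] = {}
    for text in corpus:
        for w in pretokenize(text):
            word_freq[w] = word_freq.get(w, 0) + 1
    if not word_freq:
        raise ValueError("corpus is empty")

    # alphabet: leading characters plus "##"-prefixed continuations
    alphabet = sorted({s for w in word_freq for s in _word_symbols(w)})
    min_size = len(SPECIAL_TOKENS) + len(alphabet)
    if vocab_size < min_size:
        raise ValueError(
            f"vocab_size {vocab_size} < specials + alphabet = {min_size}"
        )

    vocab_tokens = list(SPECIAL_TOKENS) + alphabet
    vocab_set = set(vocab_tokens)

    # current decomposition of each distinct word
    words: dict[str, list[str]] = {w: list(_word_symbols(w)) for w in word_freq}

    def merged_form(a: str, b: str) -> str:
        return a + (b[2:] if b.startswith("##") else b)

    while len(vocab_tokens) < vocab_size:
        pair_count: dict[tuple[str, str], int] = {}
        sym_count: dict[str, int] = {}
        for w, syms in words.items():
            f = word_freq[w]
            for s in syms:
                sym_count[s] = sym_count.get(s, 0) + f
            for a, b in zip(syms, syms[1:]):
                pair_count[(a, b)] = pair_count.get((a, b), 0) + f
        if not pair_count:
            break
        # WordPiece score: pair frequency over product of part frequencies
        best_pair, _ = max(
            pair_count.items(),
            key=lambda kv: (
                kv[1] / (sym_count[kv[0][0]] * sym_count[kv[0][1]]),
                # deterministic tie-break: lexicographically smallest pair wins
                tuple(-ord(c) for c in kv[0][0] + "\x00" + kv[0][1]),
            ),
        )
        new_tok = merged_form(*best_pair)
        if new_tok in vocab_set:
            # already present (possible when distinct pairs merge to the same
            # string); still apply the merge to the decompositions
            pass
        else:
            vocab_tokens.append(new_tok)
            vocab_set.add(new_tok)
        a, b = best_pair
        for w, syms in words.items():
            i = 0
            while i < len(syms) - 1:
                if syms[i] == a and syms[i + 1] == b:
                    syms[i : i + 2] = [merged_form(a, b)]
                else:
                    i += 1

    return Vocab(vocab_tokens)


def tokenize_word(word: str, vocab: Vocab) -> list[str]:
    """Greedy longest-match-first decomposition of one lowercased word."""
    if len(word) > MAX_WORD_CHARS:
        return [UNK]
    pieces: list[str] = []
    start = 0
    while start < len(word):
        end = len(word)
        cur: Optional[str] = None
        while start < end:
            sub = word[start:end]
            if start > 0:
                sub = "##" + sub
            if sub in vocab:
                cur = sub
                break
            end -= 1
        if cur is None:
            return [UNK]
        pieces.append(cur)
        start = end
    return pieces


def tokenize(text: str, vocab: Vocab) -> list[str]:
    """Uncased WordPiece tokenization of free text."""
    out: list[str] = []
    for w in pretokenize(text):
        out.extend(tokenize_word(w, vocab))
    return out


def encode(text: str, vocab: Vocab, max_seq_len: int) -> TokenSequence:
    """Encode to [CLS] + pieces + [SEP], head-truncated and PAD-padded.

    When the text overflows, the head of the sequence is kept (the leading
    max_seq_len - 1 pieces after [CLS]) and [SEP] is dropped: in these
    reports the answer tends to sit near the beginning of the section of
    interest, so the head carries the signal.
    """
    if max_seq_len < 2:
        raise ValueError("max_seq_len must be >= 2")
    ids = [vocab.cls_id] + [vocab.id(t) for t in tokenize(text, vocab)]
    if len(ids) >= max_seq_len:
        ids = ids[:max_seq_len]
    else:
        ids = ids + [vocab.sep_id]
    mask = [1] * len(ids)
    pad = max_seq_len - len(ids)
    return TokenSequence(ids + [vocab.pad_id] * pad, mask + [0] * pad)


def decode(ids: Iterable[int], vocab: Vocab) -> list[str]:
    """Ids back to tokens, dropping pad positions."""
    return [vocab.token(i) for i in ids if i != vocab.pad_id]


def detokenize(tokens: Iterable[str]) -> str:
    """Concatenate word pieces, stripping "##" continuations."""
    out = []
    for t in tokens:
        if t in (CLS, SEP, PAD, MASK):
            continue
        if t.startswith("##") and out:
            out[-1] += t[2:]
        else:
            out.append(t)
    return " ".join(out)
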