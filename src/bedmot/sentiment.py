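"""Hybrid lexicon- and rule-based polarity scoring.

The scorer follows the Sentida family of Danish polarity algorithms:
word valences in [-5, 5] looked up in a lexicon, adjusted by three rules
(intensity modifiers, non-interrogative negation, exclamation boosting),
then pooled over the document.  Three pooling operators are provided:
``sum``, arithmetic ``mean``, and ``gmean`` — a partitioned signed
geometric mean that is defined for any mix of positive, zero and
negative valences (see :func:`pool_gmean`).

Rule semantics
--------------
1. *modifier*: a modifier token multiplies the adjusted valence of the
   next valence-bearing token in the same sentence by its factor.
2. *negation*: a negator token multiplies the adjusted valences of
   valence-bearing tokens among the following ``negation_window`` tokens
   of the same sentence by -1 — unless the sentence is a question
   (negation in interrogatives does not commit the writer to the negated
   sentiment, so it is suppressed).
3. *exclamation*: each '!' terminating a sentence (up to 3) multiplies
   every adjusted valence in that sentence by ``exclamation_factor``.

Rules are applied in that order; stacked negators cancel pairwise.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .lexicon import MAX_EXCLAMATIONS, Lexicon

POOLING_METHODS = ("sum", "mean", "gmean")

# word = run of letters (unicode-aware, æøå included); digits and '_' excluded,
# so hyphenated words split and numbers carry no valence
_WORD_RE = re.compile(r"[^\W\d_]+", re.UNICODE)
# a sentence is text up to a run of terminal punctuation
_SENTENCE_RE = re.compile(r"([^.!?]+)([.!?]*)")


class PoolingError(ValueError):
    """Unknown pooling method name."""


@dataclass
class TokenScore:
    """One token with its (possibly rule-adjusted) valence."""

    token: str
    position: int
    sentence_index: int
    raw_valence: float | None = None
    adjusted_valence: float | None = None
    rules_applied: set[str] = field(default_factory=set)


@dataclass
class SentenceInfo:
    index: int
    interrogative: bool
    n_exclamations: int


@dataclass(frozen=True)
class PolarityResult:
    """Pooled document polarity under a named pooling method."""

    method: str
    value: float
    n_scored: int
    n_tokens: int


def tokenize(text: str) -> tuple[list[TokenScore], list[SentenceInfo]]:
    """Split ``text`` into lower-cased word tokens with sentence metadata.

    A sentence is flagged interrogative iff its terminal punctuation run
    contains ``?``; the number of ``!`` in the run is recorded.
    """
    tokens: list[TokenScore] = []
    sentences: list[SentenceInfo] = []
    position = 0
    for match in _SENTENCE_RE.finditer(text):
        body, punct = match.group(1), match.group(2)
        words = _WORD_RE.findall(body.lower())
        if not words:
            continue
        s_index = len(sentences)
        sentences.append(
            SentenceInfo(
                index=s_index,
                interrogative="?" in punct,
                n_exclamations=punct.count("!"),
            )
        )
        for word in words:
            tokens.append(TokenScore(token=word, position=position, sentence_index=s_index))
            position += 1
    return tokens, sentences


def apply_rules(
    tokens: Sequence[TokenScore],
    sentences: Sequence[SentenceInfo],
    lexicon: Lexicon,
) -> list[TokenScore]:
    """Assign lexicon valences and apply modifier, negation and exclamation rules."""
    out: list[TokenScore] = []
    for tok in tokens:
        val = lexicon.valences.get(tok.token)
        out.append(
            TokenScore(
                token=tok.token,
                position=tok.position,
                sentence_index=tok.sentence_index,
                raw_valence=val,
                adjusted_valence=val,
            )
        )

    # modifier: boost the next valence-bearing token in the same sentence
    for i, tok in enumerate(out):
        factor = lexicon.modifiers.get(tok.token)
        if factor is None:
            continue
        for nxt in out[i + 1:]:
            if nxt.sentence_index != tok.sentence_index:
                break
            if nxt.adjusted_valence is not None:
                nxt.adjusted_valence *= factor
                nxt.rules_applied.add("modifier")
                break

    # negation: flip valences in the following window, unless interrogative
    for i, tok in enumerate(out):
        if tok.token not in lexicon.negators:
            continue
        if sentences[tok.sentence_index].interrogative:
            continue
        for nxt in out[i + 1: i + 1 + lexicon.negation_window]:
            if nxt.sentence_index != tok.sentence_index:
                break
            if nxt.adjusted_valence is not None:
                nxt.adjusted_valence *= -1.0
                nxt.rules_applied.add("negation")

    # exclamation: amplify the whole sentence, at most MAX_EXCLAMATIONS counted
    boost: dict[int, float] = {}
    for sent in sentences:
        n = min(sent.n_exclamations, MAX_EXCLAMATIONS)
        if n:
            boost[sent.index] = lexicon.exclamation_factor ** n
    if boost:
        for tok in out:
            f = boost.get(tok.sentence_index)
            if f is not None and tok.adjusted_valence is not None:
                tok.adjusted_valence *= f
                tok.rules_applied.add("exclamation")

    return out


def pool_sum(scores: Iterable[float]) -> float:
    """Sum pooling; empty input is neutral (0)."""
    return float(sum(scores))


def pool_mean(scores: Iterable[float]) -> float:
    """Arithmetic mean pooling; empty input is neutral (0)."""
    scores = list(scores)
    return float(sum(scores) / len(scores)) if scores else 0.0


def pool_gmean(scores: Iterable[float]) -> float:
    """Partitioned signed geometric mean.

    Ordinary geometric averaging is undefined for zeros and negatives, so
    the values are partitioned by sign: with P the positives, N the
    negatives and n the total count (zeros included),

        g+ = geometric mean of P            (0 if P is empty)
        g- = geometric mean of |N|          (0 if N is empty)
        result = (|P| * g+  -  |N| * g-) / n

    The operator reduces to the ordinary geometric mean on all-positive
    input, is sign-symmetric, and treats zeros as neutral mass in the
    denominator.  Empty input is neutral (0).
    """
    pos: list[float] = []
    neg: list[float] = []
    n = 0
    for s in scores:
        n += 1
        if s > 0:
            pos.append(s)
        elif s < 0:
            neg.append(-s)
    if n == 0:
        return 0.0
    g_pos = math.exp(sum(math.log(v) for v in pos) / len(pos)) if pos else 0.0
    g_neg = math.exp(sum(math.log(v) for v in neg) / len(neg)) if neg else 0.0
    return (len(pos) * g_pos - len(neg) * g_neg) / n


_POOLERS = {"sum": pool_sum, "mean": pool_mean, "gmean": pool_gmean}


def score_document(text: str, lexicon: Lexicon, method: str = "gmean") -> PolarityResult:
    """Score one document: tokenize, apply rules, pool adjusted valences.

    Pooling is applied once over the whole document (one patient answer),
    not per sentence.  Documents with no lexicon hits score exactly 0.
    """
    if method not in _POOLERS:
        raise PoolingError(f"unknown pooling method {method!r}; expected one of {POOLING_METHODS}")
    tokens, sentences = tokenize(text)
    scored = apply_rules(tokens, sentences, lexicon)
    valences = [t.adjusted_valence for t in scored if t.adjusted_valence is not None]
    return PolarityResult(
        method=method,
        value=_POOLERS[method](valences),
        n_scored=len(valences),
        n_tokens=len(scored),
    )
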