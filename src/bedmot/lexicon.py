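"""Sentiment lexicon container and TSV I/O.

A lexicon maps lower-cased word tokens to valences on the [-5, 5] scale,
plus two auxiliary word classes: *modifiers* (multiplicative intensity
factors such as "meget" = 1.5) and *negators* ("ikke", "aldrig", ...).
The same token may appear in more than one class.

File dialect (all UTF-8, ``#`` starts a comment line):

* valences: ``token<TAB>valence`` — valence a real in [-5, 5]
* modifiers: ``token<TAB>factor`` — factor a positive real
* negators: one token per line
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

VALENCE_MIN = -5.0
VALENCE_MAX = 5.0

#: default multiplicative boost per sentence-terminating '!'
DEFAULT_EXCLAMATION_FACTOR = 1.5
#: default number of following tokens a negator can flip
DEFAULT_NEGATION_WINDOW = 3
#: '!' beyond this count in one sentence carry no extra weight
MAX_EXCLAMATIONS = 3


class LexiconError(ValueError):
    """Raised for malformed or out-of-range lexicon input."""


@dataclass
class Lexicon:
    """Token valences plus rule word classes for polarity scoring."""

    valences: dict[str, float] = field(default_factory=dict)
    modifiers: dict[str, float] = field(default_factory=dict)
    negators: set[str] = field(default_factory=set)
    exclamation_factor: float = DEFAULT_EXCLAMATION_FACTOR
    negation_window: int = DEFAULT_NEGATION_WINDOW

    def __post_init__(self) -> None:
        for token, val in self.valences.items():
            if not VALENCE_MIN <= val <= VALENCE_MAX:
                raise LexiconError(
                    f"valence for {token!r} is {val}, outside [{VALENCE_MIN}, {VALENCE_MAX}]"
                )
        for token, factor in self.modifiers.items():
            if factor <= 0:
                raise LexiconError(f"modifier factor for {token!r} must be > 0, got {factor}")
        if self.exclamation_factor <= 1:
            raise LexiconError("exclamation_factor must be > 1")
        if self.negation_window < 1:
            raise LexiconError("negation_window must be a positive integer")

    def __len__(self) -> int:
        return len(self.valences)


def _parse_two_column(path: Path, what: str) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LexiconError(
                    f"{path}:{lineno}: expected 'token<TAB>number' in {what} file, got {line!r}"
                )
            token = parts[0].strip().lower()
            try:
                value = float(parts[1])
            except ValueError as exc:
                raise LexiconError(f"{path}:{lineno}: non-numeric value {parts[1]!r}") from exc
            if token in out:
                logger.warning("%s:%d: duplicate token %r, last value wins", path, lineno, token)
            out[token] = value
    return out


def load_lexicon(
    valence_path: str | Path,
    modifier_path: str | Path | None = None,
    negator_path: str | Path | None = None,
    **kwargs,
) -> Lexicon:
    """Load a :class:`Lexicon` from TSV files.

    Duplicate tokens keep the last value (a warning is logged).  Valences
    outside [-5, 5] raise :class:`LexiconError`.
    """
    valences = _parse_two_column(Path(valence_path), "valence")
    modifiers = _parse_two_column(Path(modifier_path), "modifier") if modifier_path else {}
    negators: set[str] = set()
    if negator_path:
        with open(negator_path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    negators.add(line.lower())
    return Lexicon(valences=valences, modifiers=modifiers, negators=negators, **kwargs)


def save_lexicon(lexicon: Lexicon, directory: str | Path) -> dict[str, Path]:
    """Write a lexicon to ``directory`` in the TSV dialect; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "valences": directory / "valences.tsv",
        "modifiers": directory / "modifiers.tsv",
        "negators": directory / "negators.txt",
    }
    with open(paths["valences"], "w", encoding="utf-8") as fh:
        for token in sorted(lexicon.valences):
            fh.write(f"{token}\t{lexicon.valences[token]:g}\n")
    with open(paths["modifiers"], "w", encoding="utf-8") as fh:
        for token in sorted(lexicon.modifiers):
            fh.write(f"{token}\t{lexicon.modifiers[token]:g}\n")
    with open(paths["negators"], "w", encoding="utf-8") as fh:
        for token in sorted(lexicon.negators):
            fh.write(token + "\n")
    return paths


def load_lexicon_dir(directory: str | Path, **kwargs) -> Lexicon:
    """Load the three-file layout written by :func:`save_lexicon`."""
    directory = Path(directory)
    return load_lexicon(
        directory / "valences.tsv",
        directory / "modifiers.tsv",
        directory / "negators.txt",
        **kwargs,
    )
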