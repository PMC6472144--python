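"""Word-category lexicons and dictionary-based text scoring.

The measurement unit of the whole pipeline is the *lexical indicator*: the
fraction of a text's tokens that belong to a word category (positive affect,
social processes, shared values, ...).  Categories are defined by lexicons in
the LIWC tradition: a named set of entries, each either a literal token or a
stem pattern written with a trailing ``*`` that matches any token starting
with the stem.

Three on-disk formats are supported: the classic ``%``-delimited ``.dic``
dialect, a plain JSON mapping ``{category: [words...]}``, and a two-column
CSV (``category,word``).  A small synthetic demo pack (:func:`demo_lexicons`)
ships with the package for tests and simulations; licensed dictionaries such
as the French LIWC adaptation are never bundled and must be supplied by the
user.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._demo_lexicons import DEMO_CATEGORY_WORDS, FILLER_WORDS

__all__ = [
    "Lexicon",
    "LexiconParseError",
    "tokenize",
    "matches",
    "indicator_fraction",
    "validate_percent_increase",
    "load_liwc_dic",
    "write_liwc_dic",
    "load_lexicon_json",
    "save_lexicon_json",
    "load_lexicon_csv",
    "demo_lexicons",
    "union_lexicon",
]


class LexiconParseError(ValueError):
    """Raised for malformed lexicon files; message names the offending line."""


@dataclass(frozen=True)
class Lexicon:
    """A named word category with literal and stem (prefix) entries.

    Parameters
    ----------
    name:
        Category label, e.g. ``"posemo"``.
    literals:
        Exact-match entries (lowercase).
    stems:
        Prefix entries *without* the trailing ``*`` (lowercase).
    source:
        Free-text provenance note.
    """

    name: str
    literals: frozenset[str]
    stems: tuple[str, ...]
    source: str = ""
    # sorted stems tuple reused by the hot matching path
    _stem_tuple: tuple[str, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.literals and not self.stems:
            raise ValueError(f"lexicon {self.name!r} has no entries")
        for w in list(self.literals) + list(self.stems):
            if not w or w != w.lower():
                raise ValueError(
                    f"lexicon {self.name!r}: entry {w!r} must be non-empty lowercase"
                )
            if "*" in w:
                raise ValueError(
                    f"lexicon {self.name!r}: entry {w!r} contains '*'; stems are "
                    "stored without the wildcard"
                )
        overlap = self.literals.intersection(self.stems)
        if overlap:
            raise ValueError(
                f"lexicon {self.name!r}: entries both literal and stem: {sorted(overlap)}"
            )
        object.__setattr__(self, "stems", tuple(sorted(set(self.stems))))
        object.__setattr__(self, "_stem_tuple", tuple(self.stems))

    @classmethod
    def from_entries(cls, name: str, entries: Iterable[str], source: str = "") -> "Lexicon":
        """Build from mixed entries where a trailing ``*`` marks a stem."""
        lits, stems = set(), set()
        for e in entries:
            e = e.strip().lower()
            if not e:
                continue
            if e.endswith("*"):
                stems.add(e[:-1])
            else:
                lits.add(e)
        return cls(name=name, literals=frozenset(lits), stems=tuple(sorted(stems)), source=source)

    @property
    def entries(self) -> list[str]:
        """All entries in writable form (stems carry the trailing ``*``)."""
        return sorted(self.literals) + [s + "*" for s in self.stems]

    def matches_token(self, token: str) -> bool:
        if token in self.literals:
            return True
        return bool(self._stem_tuple) and token.startswith(self._stem_tuple)

    def fraction(self, tokens: Sequence[str]) -> float | None:
        """Indicator fraction of a tokenized text; ``None`` on empty input."""
        n = len(tokens)
        if n == 0:
            return None
        lits = self.literals
        st = self._stem_tuple
        if st:
            hits = sum(1 for t in tokens if t in lits or t.startswith(st))
        else:
            hits = sum(1 for t in tokens if t in lits)
        return hits / n


# --- tokenization -----------------------------------------------------------

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION_RE = re.compile(r"@\w+")
# Unicode letters (accents included), optionally glued by internal apostrophes
_TOKEN_RE = re.compile(r"[^\W\d_]+(?:['’][^\W\d_]+)*")


def tokenize(text: str) -> list[str]:
    """Split raw tweet text into lowercase word tokens.

    URLs and @-mentions are removed entirely; ``#`` is stripped so the
    hashtag word survives as an ordinary token; digit-only runs never form
    tokens; internal apostrophes (``aujourd'hui``, ``j'ai``) stay inside a
    single token.  Apostrophes are normalized (``’`` → ``'``).
    """
    if not text:
        return []
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    text = text.lower().replace("#", " ").replace("’", "'")
    return _TOKEN_RE.findall(text)


def matches(entry: str, token: str) -> bool:
    """LIWC matching convention for a single entry against a lowercase token."""
    if entry.endswith("*"):
        return token.startswith(entry[:-1])
    return token == entry


def indicator_fraction(tokens: Sequence[str], lex: Lexicon) -> float | None:
    """Fraction of tokens matching any entry of ``lex``; ``None`` if no tokens.

    A token matching several entries of the same category counts once.
    """
    return lex.fraction(tokens)


def validate_percent_increase(
    corpus_a: Iterable[str], corpus_b: Iterable[str], lex: Lexicon
) -> float:
    """Percent difference of mean indicator fractions, ``100*(mean_a/mean_b - 1)``.

    This is the dictionary-validation statistic: e.g. a labelled positive
    corpus containing 110% more positive-affect terms than a control corpus.
    Texts with no tokens are excluded from the means.
    """

    def corpus_mean(texts: Iterable[str], which: str) -> float:
        vals = [f for t in texts if (f := lex.fraction(tokenize(t))) is not None]
        if not vals:
            raise ValueError(f"corpus_{which} has no scorable (non-empty) texts")
        return sum(vals) / len(vals)

    mean_a = corpus_mean(corpus_a, "a")
    mean_b = corpus_mean(corpus_b, "b")
    if mean_b == 0:
        raise ValueError(
            f"corpus_b contains no {lex.name!r} words: percent increase undefined"
        )
    return 100.0 * (mean_a / mean_b - 1.0)


# --- file formats -----------------------------------------------------------

def load_liwc_dic(path) -> list[Lexicon]:
    """Parse a ``%``-header ``.dic`` file into one :class:`Lexicon` per category.

    The dialect: a header delimited by two lines containing ``%``, holding
    ``id<whitespace>name`` pairs; then word lines ``word id [id ...]``.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    try:
        first = lines.index("%")
        second = lines.index("%", first + 1)
    except ValueError:
        raise LexiconParseError(f"{path}: missing '%' header delimiters") from None

    id_to_name: dict[str, str] = {}
    for i in range(first + 1, second):
        line = lines[i].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2 or not parts[0].isdigit():
            raise LexiconParseError(f"{path}: malformed header at line {i + 1}: {line!r}")
        id_to_name[parts[0]] = parts[1]
    if not id_to_name:
        raise LexiconParseError(f"{path}: header defines no categories")

    words: dict[str, list[str]] = {cid: [] for cid in id_to_name}
    for i in range(second + 1, len(lines)):
        line = lines[i].strip()
        if not line:
            continue
        parts = line.split()
        word, ids = parts[0].lower(), parts[1:]
        if not ids:
            raise LexiconParseError(f"{path}: word with no category at line {i + 1}: {line!r}")
        for cid in ids:
            if cid not in id_to_name:
                raise LexiconParseError(
                    f"{path}: line {i + 1} references unknown category id {cid!r}"
                )
            words[cid].append(word)

    out = []
    for cid, name in id_to_name.items():
        if not words[cid]:
            raise LexiconParseError(f"{path}: category {name!r} (id {cid}) has no words")
        out.append(Lexicon.from_entries(name, words[cid], source=str(path)))
    return out


def write_liwc_dic(lexicons: Sequence[Lexicon], path) -> None:
    """Write lexicons in the ``.dic`` dialect (round-trips with :func:`load_liwc_dic`)."""
    ids = {lex.name: str(i + 1) for i, lex in enumerate(lexicons)}
    word_cats: dict[str, list[str]] = {}
    for lex in lexicons:
        for entry in lex.entries:
            word_cats.setdefault(entry, []).append(ids[lex.name])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("%\n")
        for lex in lexicons:
            fh.write(f"{ids[lex.name]}\t{lex.name}\n")
        fh.write("%\n")
        for word in sorted(word_cats):
            fh.write(word + "\t" + "\t".join(word_cats[word]) + "\n")


def load_lexicon_json(path) -> list[Lexicon]:
    """Load the plain JSON format ``{category: [word, "stem*", ...]}``."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, Mapping):
        raise LexiconParseError(f"{path}: top level must be a mapping category -> word list")
    return [Lexicon.from_entries(name, entries, source=str(path)) for name, entries in data.items()]


def save_lexicon_json(lexicons: Sequence[Lexicon], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({lex.name: lex.entries for lex in lexicons}, fh, ensure_ascii=False, indent=1)


def load_lexicon_csv(path) -> list[Lexicon]:
    """Load a two-column ``category,word`` CSV (header optional)."""
    cats: dict[str, list[str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or (i == 0 and [c.lower() for c in row[:2]] == ["category", "word"]):
                continue
            if len(row) < 2:
                raise LexiconParseError(f"{path}: line {i + 1} needs two columns")
            cats.setdefault(row[0].strip(), []).append(row[1].strip())
    return [Lexicon.from_entries(name, ws, source=str(path)) for name, ws in cats.items()]


def demo_lexicons() -> dict[str, Lexicon]:
    """The synthetic demo lexicon pack, keyed by category name."""
    return {
        name: Lexicon.from_entries(name, ws, source="emosync demo pack (synthetic)")
        for name, ws in DEMO_CATEGORY_WORDS.items()
    }


def union_lexicon(name: str, lexicons: Sequence[Lexicon]) -> Lexicon:
    """Union of several categories (e.g. combined positive+negative affect)."""
    entries: set[str] = set()
    for lex in lexicons:
        entries.update(lex.entries)
    return Lexicon.from_entries(name, entries, source="union:" + "+".join(l.name for l in lexicons))


def demo_filler_words() -> list[str]:
    """Background vocabulary matching no demo category (used by generators)."""
    return list(FILLER_WORDS)
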