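"""Sentiment lexicons: terms with integer valences, boosters, and negators.

A lexicon for one language lives in a directory of three UTF-8,
tab-separated plain-text files using the file names of the classic
dual-polarity sentiment tool, so published dictionary bundles load
unchanged:

``EmotionLookupTable.txt``
    one ``term<TAB>valence`` pair per line; valence is a nonzero integer
    in [-4, 4] (zero is reserved for "not in the lexicon"),
``BoosterWordList.txt``
    one ``term<TAB>delta`` pair per line; delta is a nonzero integer added
    to the magnitude of a following sentiment word (negative delta =
    diminisher),
``NegatingWordList.txt``
    one bare term per line; a negator reverses the sign of a following
    sentiment word.

Lines starting with ``#`` and blank lines are ignored.  A sentiment term
may end in ``*``, which matches any token sharing the prefix
(longest-match wins); this mirrors the stem-with-wildcard convention of
published dictionaries and can be disabled per lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import FormatError, InputError

SENTIMENT_FILE = "EmotionLookupTable.txt"
BOOSTER_FILE = "BoosterWordList.txt"
NEGATOR_FILE = "NegatingWordList.txt"

VALID_VALENCES = frozenset(range(-4, 0)) | frozenset(range(1, 5))


@dataclass(frozen=True)
class LexiconEntry:
    """One sentiment term with its signed integer strength."""

    term: str
    valence: int

    def __post_init__(self) -> None:
        if self.valence not in VALID_VALENCES:
            raise FormatError(
                f"valence for {self.term!r} must be a nonzero integer in "
                f"[-4, 4], got {self.valence}"
            )
        if not self.term or any(c.isspace() for c in self.term):
            raise FormatError(f"invalid lexicon term {self.term!r}")


@dataclass(frozen=True)
class BoosterEntry:
    """A word altering the magnitude of the next sentiment word."""

    term: str
    delta: int

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise FormatError(f"booster delta for {self.term!r} must be nonzero")
        if not self.term or any(c.isspace() for c in self.term):
            raise FormatError(f"invalid booster term {self.term!r}")


@dataclass
class SentimentLexicon:
    """Term→valence map plus booster and negator word lists for one language.

    No term may appear in more than one of the three roles; all terms are
    lowercase.  ``use_wildcards`` controls whether trailing-``*`` stems in
    the sentiment table participate in :meth:`lookup`.
    """

    language: str
    entries: dict[str, LexiconEntry] = field(default_factory=dict)
    boosters: dict[str, BoosterEntry] = field(default_factory=dict)
    negators: set[str] = field(default_factory=set)
    use_wildcards: bool = True

    def __post_init__(self) -> None:
        roles = [set(self.entries), set(self.boosters), self.negators]
        for i in range(3):
            for j in range(i + 1, 3):
                clash = roles[i] & roles[j]
                if clash:
                    raise FormatError(
                        f"terms in multiple roles: {sorted(clash)!r}"
                    )
        for term in set().union(*roles):
            if term != term.lower():
                raise FormatError(f"lexicon term not lowercase: {term!r}")
        self._stems = sorted(
            (t[:-1] for t in self.entries if t.endswith("*")),
            key=len,
            reverse=True,
        )

    def lookup(self, token: str) -> int:
        """Return the valence applying to ``token``, or 0 if none.

        Exact matches win over wildcard stems; among stems the longest
        matching prefix wins.
        """
        entry = self.entries.get(token)
        if entry is not None:
            return entry.valence
        if self.use_wildcards:
            for stem in self._stems:
                if token.startswith(stem):
                    return self.entries[stem + "*"].valence
        return 0

    def booster_delta(self, token: str) -> int | None:
        b = self.boosters.get(token)
        return None if b is None else b.delta

    def is_negator(self, token: str) -> bool:
        return token in self.negators

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SentimentLexicon):
            return NotImplemented
        return (
            self.language == other.language
            and self.entries == other.entries
            and self.boosters == other.boosters
            and self.negators == other.negators
        )


def _iter_data_lines(path: Path):
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read lexicon file {path}: {exc}") from exc
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def _parse_int(value: str, path: Path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: {what} must be an integer, got {value!r}"
        ) from None


def load_lexicon(path: str | Path, language: str) -> SentimentLexicon:
    """Load the three lexicon files from directory ``path``.

    Terms are lowercased on load.  Duplicate terms within a file, a zero
    or out-of-range valence, or a non-integer field raise
    :class:`~crisispulse.errors.FormatError` with the offending line
    number; a missing file raises :class:`~crisispulse.errors.InputError`.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise InputError(f"lexicon directory not found: {directory}")

    entries: dict[str, LexiconEntry] = {}
    sfile = directory / SENTIMENT_FILE
    if not sfile.exists():
        raise InputError(f"missing sentiment file: {sfile}")
    for lineno, line in _iter_data_lines(sfile):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{sfile}:{lineno}: expected term<TAB>valence")
        term = parts[0].strip().lower()
        valence = _parse_int(parts[1].strip(), sfile, lineno, "valence")
        if valence not in VALID_VALENCES:
            raise FormatError(
                f"{sfile}:{lineno}: valence must be nonzero in [-4, 4], "
                f"got {valence}"
            )
        if term in entries:
            raise FormatError(f"{sfile}:{lineno}: duplicate term {term!r}")
        entries[term] = LexiconEntry(term, valence)

    boosters: dict[str, BoosterEntry] = {}
    bfile = directory / BOOSTER_FILE
    if not bfile.exists():
        raise InputError(f"missing booster file: {bfile}")
    for lineno, line in _iter_data_lines(bfile):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{bfile}:{lineno}: expected term<TAB>delta")
        term = parts[0].strip().lower()
        delta = _parse_int(parts[1].strip(), bfile, lineno, "delta")
        if delta == 0:
            raise FormatError(f"{bfile}:{lineno}: booster delta must be nonzero")
        if term in boosters:
            raise FormatError(f"{bfile}:{lineno}: duplicate booster {term!r}")
        boosters[term] = BoosterEntry(term, delta)

    negators: set[str] = set()
    nfile = directory / NEGATOR_FILE
    if not nfile.exists():
        raise InputError(f"missing negator file: {nfile}")
    for lineno, line in _iter_data_lines(nfile):
        term = line.split("\t")[0].strip().lower()
        if any(c.isspace() for c in term):
            raise FormatError(f"{nfile}:{lineno}: negator contains whitespace")
        if term in negators:
            raise FormatError(f"{nfile}:{lineno}: duplicate negator {term!r}")
        negators.add(term)

    return SentimentLexicon(
        language=language, entries=entries, boosters=boosters, negators=negators
    )


def write_lexicon(lex: SentimentLexicon, path: str | Path) -> Path:
    """Write ``lex`` to directory ``path`` in the dialect ``load_lexicon`` reads.

    Output is deterministic: one header comment per file, entries sorted
    by term.  Returns the directory path.
    """
    directory = Path(path)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        sfile = directory / SENTIMENT_FILE
        lines = [f"# sentiment terms ({lex.language}): term<TAB>valence"]
        lines += [
            f"{e.term}\t{e.valence}"
            for e in sorted(lex.entries.values(), key=lambda e: e.term)
        ]
        sfile.write_text("\n".join(lines) + "\n", encoding="utf-8")

        bfile = directory / BOOSTER_FILE
        lines = [f"# booster words ({lex.language}): term<TAB>delta"]
        lines += [
            f"{b.term}\t{b.delta}"
            for b in sorted(lex.boosters.values(), key=lambda b: b.term)
        ]
        bfile.write_text("\n".join(lines) + "\n", encoding="utf-8")

        nfile = directory / NEGATOR_FILE
        lines = [f"# negating words ({lex.language}): one term per line"]
        lines += sorted(lex.negators)
        nfile.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot write lexicon to {directory}: {exc}") from exc
    return directory
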