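"""Report section extraction and text normalization.

The classification pipeline does not consume raw report text.  It first pulls
the FINDINGS and IMPRESSION sections out of the sectioned report, then
normalizes them into a token sequence: lowercase, tokenize, mask numbers and
measurement units to sentinels, drop stopwords (keeping "no", "not" and
"under", which carry the negation signal the classifiers rely on), and reduce
every remaining token to its Porter word stem.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib.resources import files
from typing import Iterable, Sequence

__all__ = [
    "PorterStemmer",
    "SectionedReport",
    "NormalizationConfig",
    "extract_sections",
    "normalize",
    "preprocess_report",
]

logger = logging.getLogger(__name__)

#: A normalized document: ordered list of lowercase word-stem tokens.
TokenSequence = list

# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------


class PorterStemmer:
    """The classic Porter suffix-stripping stemmer for English.

    Faithful port of the reference implementation: five rule steps driven by
    the consonant-vowel measure m of the stem, applied to lowercase words.
    Words of length <= 2 are returned unchanged.
    """

    def __init__(self) -> None:
        self.b = ""  # word buffer
        self.k = 0   # index of last letter in current word
        self.j = 0   # index of last letter of the stem before a matched suffix

    # -- low-level predicates over the buffer --------------------------------

    def _cons(self, i: int) -> bool:
        ch = self.b[i]
        if ch in "aeiou":
            return False
        if ch == "y":
            return i == 0 or not self._cons(i - 1)
        return True

    def _m(self) -> int:
        """Number of consonant-vowel sequences in b[0..j]."""
        n = 0
        i = 0
        while True:
            if i > self.j:
                return n
            if not self._cons(i):
                break
            i += 1
        i += 1
        while True:
            while True:
                if i > self.j:
                    return n
                if self._cons(i):
                    break
                i += 1
            i += 1
            n += 1
            while True:
                if i > self.j:
                    return n
                if not self._cons(i):
                    break
                i += 1
            i += 1

    def _vowel_in_stem(self) -> bool:
        return any(not self._cons(i) for i in range(self.j + 1))

    def _double_cons(self, j: int) -> bool:
        return j >= 1 and self.b[j] == self.b[j - 1] and self._cons(j)

    def _cvc(self, i: int) -> bool:
        # consonant-vowel-consonant ending at i, final consonant not w/x/y;
        # signals a short stem like "hop" that takes back a final -e.
        if i < 2 or not self._cons(i) or self._cons(i - 1) or not self._cons(i - 2):
            return False
        return self.b[i] not in "wxy"

    def _ends(self, s: str) -> bool:
        length = len(s)
        if length > self.k + 1:
            return False
        if self.b[self.k - length + 1: self.k + 1] != s:
            return False
        self.j = self.k - length
        return True

    def _set_to(self, s: str) -> None:
        self.b = self.b[: self.j + 1] + s + self.b[self.j + 1 + len(s):]
        self.k = self.j + len(s)

    def _r(self, s: str) -> None:
        if self._m() > 0:
            self._set_to(s)

    # -- the five steps ------------------------------------------------------

    def _step1ab(self) -> None:
        if self.b[self.k] == "s":
            if self._ends("sses"):
                self.k -= 2
            elif self._ends("ies"):
                self._set_to("i")
            elif self.b[self.k - 1] != "s":
                self.k -= 1
        if self._ends("eed"):
            if self._m() > 0:
                self.k -= 1
        elif (self._ends("ed") or self._ends("ing")) and self._vowel_in_stem():
            self.k = self.j
            if self._ends("at"):
                self._set_to("ate")
            elif self._ends("bl"):
                self._set_to("ble")
            elif self._ends("iz"):
                self._set_to("ize")
            elif self._double_cons(self.k):
                if self.b[self.k] not in "lsz":
                    self.k -= 1
            else:
                self.j = self.k
                if self._m() == 1 and self._cvc(self.k):
                    self._set_to("e")

    def _step1c(self) -> None:
        if self._ends("y") and self._vowel_in_stem():
            self.b = self.b[: self.k] + "i" + self.b[self.k + 1:]

    _STEP2 = (
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
        ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
        ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
        ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
    )

    _STEP3 = (
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    )

    _STEP4 = (
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    )

    def _step2(self) -> None:
        for suffix, repl in self._STEP2:
            if self._ends(suffix):
                self._r(repl)
                return

    def _step3(self) -> None:
        for suffix, repl in self._STEP3:
            if self._ends(suffix):
                self._r(repl)
                return

    def _step4(self) -> None:
        for suffix in self._STEP4:
            if self._ends(suffix):
                if suffix == "ion" and self.b[self.j] not in "st":
                    return
                if self._m() > 1:
                    self.k = self.j
                return

    def _step5(self) -> None:
        self.j = self.k
        if self.b[self.k] == "e":
            a = self._m()
            if a > 1 or (a == 1 and not self._cvc(self.k - 1)):
                self.k -= 1
        if self.b[self.k] == "l" and self._double_cons(self.k) and self._m() > 1:
            self.k -= 1

    def stem(self, word: str) -> str:
        word = word.lower()
        if len(word) <= 2:
            return word
        self.b = word
        self.k = len(word) - 1
        self._step1ab()
        self._step1c()
        self._step2()
        self._step3()
        self._step4()
        self._step5()
        return self.b[: self.k + 1]


_STEMMER = PorterStemmer()


# ---------------------------------------------------------------------------
# Section extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionedReport:
    """The FINDINGS and IMPRESSION bodies of a report (either may be empty)."""

    findings: str
    impression: str

    @property
    def combined(self) -> str:
        return (self.findings + "\n" + self.impression).strip()


# A section header is a line starting with an all-caps token (possibly several
# all-caps words) followed by a colon; FINDINGS/IMPRESSION may omit the colon.
_HEADER_COLON_RE = re.compile(r"^\s*([A-Z][A-Z ]*[A-Z]|[A-Z])\s*:\s?(.*)$")
_HEADER_BARE_RE = re.compile(r"^\s*([A-Z][A-Z ]*[A-Z])\s*$")


def _header(line: str) -> tuple[str, str] | None:
    m = _HEADER_COLON_RE.match(line)
    if m:
        return m.group(1), m.group(2)
    m = _HEADER_BARE_RE.match(line)
    if m and m.group(1).split()[0] in ("FINDINGS", "IMPRESSION"):
        return m.group(1), ""
    return None


def extract_sections(text: str) -> SectionedReport:
    """Pull the FINDINGS and IMPRESSION sections out of a sectioned report.

    A section consists of the lines after its header up to the next section
    header (or end of text).  A header line like "FINDINGS AND IMPRESSION:"
    is treated as a FINDINGS header.  Missing sections come back empty; the
    caller decides on a whole-text fallback (see :func:`preprocess_report`).
    """
    sections: dict[str, list[str]] = {"findings": [], "impression": []}
    current: str | None = None
    for line in text.splitlines():
        hdr = _header(line)
        if hdr is not None:
            name, rest = hdr
            first = name.split()[0]
            if first == "FINDINGS":
                current = "findings"
            elif first == "IMPRESSION":
                current = "impression"
            else:
                current = None
            if current is not None and rest.strip():
                sections[current].append(rest.rstrip())
            continue
        if current is not None:
            sections[current].append(line.rstrip())
    findings = "\n".join(sections["findings"]).strip("\n")
    impression = "\n".join(sections["impression"]).strip("\n")
    if not findings and not impression:
        logger.warning("report has neither FINDINGS nor IMPRESSION section")
    return SectionedReport(findings=findings, impression=impression)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _load_wordlist(name: str) -> frozenset[str]:
    data = files("otolabel").joinpath("data").joinpath(name).read_text(encoding="utf-8")
    return frozenset(w.strip() for w in data.splitlines() if w.strip())


@lru_cache(maxsize=None)
def _default_stopwords() -> frozenset[str]:
    return _load_wordlist("stopwords.txt")


@lru_cache(maxsize=None)
def _default_units() -> frozenset[str]:
    return _load_wordlist("units.txt")


#: Stopwords that are kept because they mark negation/position in this task.
RETAINED_WORDS = frozenset({"no", "not", "under"})


@dataclass(frozen=True)
class NormalizationConfig:
    """Settings for :func:`normalize`.

    ``stopwords`` and ``units`` default to the lists shipped with the package;
    ``retained`` words are never removed even if listed as stopwords;
    ``mask_integers`` also maps bare integers (not just decimals) to the
    "number" sentinel, which makes features robust to measurement values.
    """

    stopwords: frozenset[str] = field(default_factory=_default_stopwords)
    units: frozenset[str] = field(default_factory=_default_units)
    retained: frozenset[str] = RETAINED_WORDS
    mask_integers: bool = True


_DEFAULT_CONFIG = NormalizationConfig()
_TOKEN_RE = re.compile(r"\d+\.\d+|[a-z]+|\d+")
_DECIMAL_RE = re.compile(r"\d+\.\d+")
_INTEGER_RE = re.compile(r"\d+")


def normalize(text: str, config: NormalizationConfig | None = None) -> list[str]:
    """Normalize raw text into the token sequence the featurizer consumes.

    Steps, in order: lowercase; tokenize on non-alphanumeric boundaries
    (keeping decimals like ``3.14`` whole); mask decimal (and by default
    integer) numbers to ``number`` and unit words to ``unit``; remove
    stopwords except the retained negation words; Porter-stem the rest.
    """
    cfg = config or _DEFAULT_CONFIG
    out: list[str] = []
    for token in _TOKEN_RE.findall(text.lower()):
        if _DECIMAL_RE.fullmatch(token):
            out.append("number")
            continue
        if _INTEGER_RE.fullmatch(token):
            out.append("number" if cfg.mask_integers else token)
            continue
        if token in cfg.units:
            out.append("unit")
            continue
        if token in cfg.stopwords and token not in cfg.retained:
            continue
        if token in cfg.retained:
            out.append(token)
            continue
        out.append(_STEMMER.stem(token))
    return out


def preprocess_report(text: str,
                      config: NormalizationConfig | None = None) -> list[str]:
    """Full preprocessing of one raw report: sections then normalization.

    Falls back to normalizing the whole report text when neither a FINDINGS
    nor an IMPRESSION section is present, so unsectioned reports are still
    classifiable rather than silently mapped to an empty document.
    """
    sections = extract_sections(text)
    body = sections.combined
    if not body:
        body = text
    return normalize(body, config)
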