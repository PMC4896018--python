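"""Training-free comparison methods: region keyword search and patient
ICD9-code mapping.

Both are deliberately naive.  The keyword search matches region-specific
abnormality phrases as case-insensitive word-boundary substrings of the raw
(un-normalized) report text, so it cannot see negation ("no ossicular
erosion" still matches).  The ICD9 method flags a region abnormal when any
of the patient's diagnosis codes belongs to that region's code set.
"""

from __future__ import annotations

import csv
import re
from functools import lru_cache
from importlib.resources import as_file, files
from pathlib import Path
from typing import Iterable, Mapping

from .corpus import REGIONS, RegionLabelSet

__all__ = [
    "load_keyword_lexicon",
    "load_icd9_map",
    "keyword_classify",
    "icd9_classify",
    "canonicalize_icd9",
]

_ICD9_RE = re.compile(r"^(?:\d{3}|[VE]\d{2,3})(?:\.\d{1,2})?$", re.IGNORECASE)


def _read_region_csv(path) -> dict[str, frozenset[str]]:
    table: dict[str, set[str]] = {r: set() for r in REGIONS}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            region = row["region"].strip()
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r} in {path}")
            value = row[[k for k in row if k != "region"][0]].strip()
            if value:
                table[region].add(value.lower())
    return {r: frozenset(v) for r, v in table.items()}


def _packaged(name: str):
    return files("otolabel").joinpath("data").joinpath(name)


@lru_cache(maxsize=None)
def _default_keywords() -> dict:
    with as_file(_packaged("keywords.csv")) as p:
        return _read_region_csv(p)


def load_keyword_lexicon(path: str | Path | None = None) -> dict:
    """Region -> keyword set; the packaged representative list by default."""
    if path is None:
        return _default_keywords()
    return _read_region_csv(Path(path))


@lru_cache(maxsize=None)
def _default_icd9_map() -> dict:
    with as_file(_packaged("icd9_map.csv")) as p:
        raw = _read_region_csv(p)
    return {r: frozenset(canonicalize_icd9(c) for c in v) for r, v in raw.items()}


def load_icd9_map(path: str | Path | None = None) -> dict:
    """Region -> ICD9 code set (canonicalized); packaged list by default."""
    if path is None:
        return _default_icd9_map()
    raw = _read_region_csv(Path(path))
    return {r: frozenset(canonicalize_icd9(c) for c in v) for r, v in raw.items()}


def keyword_classify(report_text: str, lexicon: Mapping | None = None) -> RegionLabelSet:
    """Label a report abnormal per region iff any region keyword occurs in
    the raw text (case-insensitive, word-boundary substring match)."""
    if lexicon is None:
        lexicon = load_keyword_lexicon()
    text = report_text.lower()
    flags = {}
    for region in REGIONS:
        keywords = lexicon.get(region, ())
        flags[region] = any(
            re.search(rf"\b{re.escape(kw)}\b", text) for kw in keywords)
    return RegionLabelSet(**flags)


def canonicalize_icd9(code: str) -> str:
    """Normalize an ICD9 code to its trailing-zero-free dotted form.

    "389.10" -> "389.1", "383.00" -> "383", "V72.1" -> "V72.1".  Codes not
    matching the ICD9 lexical pattern are returned stripped/uppercased.
    """
    code = code.strip().upper().rstrip(".")
    if not _ICD9_RE.match(code):
        return code
    if "." in code:
        code = code.rstrip("0").rstrip(".")
    return code


def icd9_classify(patient_codes: Iterable[str],
                  icd9_map: Mapping | None = None) -> RegionLabelSet:
    """Label per region abnormal iff the patient's canonicalized codes
    intersect the region's code set."""
    if icd9_map is None:
        icd9_map = load_icd9_map()
    codes = {canonicalize_icd9(c) for c in patient_codes}
    flags = {region: bool(codes & set(icd9_map.get(region, ())))
             for region in REGIONS}
    return RegionLabelSet(**flags)
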