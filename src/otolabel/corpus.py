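"""Corpus data model, JSONL I/O, stratified splitting and agreement statistics.

A corpus is a list of :class:`LabeledReport` — raw radiology report text plus
four independent binary ear-region labels (inner, middle, outer, mastoid) and
optionally the patient's ICD9 diagnosis codes.  A report is "normal" overall
iff all four region labels are false.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "REGIONS",
    "RegionLabelSet",
    "LabeledReport",
    "CorpusSplit",
    "LabelDistribution",
    "read_corpus",
    "write_corpus",
    "stratified_split",
    "label_distribution",
    "cohen_kappa",
]

#: The four ear regions, in canonical order.
REGIONS: tuple[str, ...] = ("inner", "middle", "outer", "mastoid")


@dataclass(frozen=True)
class RegionLabelSet:
    """Binary abnormality flags for the four ear regions (abnormal = True)."""

    inner: bool
    middle: bool
    outer: bool
    mastoid: bool

    def __post_init__(self) -> None:
        for region in REGIONS:
            value = getattr(self, region)
            if not isinstance(value, bool):
                raise TypeError(f"label {region!r} must be bool, got {value!r}")

    @property
    def any_abnormal(self) -> bool:
        """True iff at least one region is abnormal."""
        return self.inner or self.middle or self.outer or self.mastoid

    def __getitem__(self, region: str) -> bool:
        if region not in REGIONS:
            raise KeyError(region)
        return getattr(self, region)

    def as_dict(self) -> dict[str, bool]:
        return {region: getattr(self, region) for region in REGIONS}

    @classmethod
    def from_dict(cls, d: dict) -> "RegionLabelSet":
        missing = [r for r in REGIONS if r not in d]
        if missing:
            raise ValueError(f"labels missing regions: {missing}")
        return cls(**{r: d[r] for r in REGIONS})


@dataclass(frozen=True)
class LabeledReport:
    """One radiology report: id, raw text, optional labels, optional ICD9 codes."""

    report_id: str
    text: str
    labels: RegionLabelSet | None = None
    icd9_codes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"report {self.report_id!r} has empty text")
        object.__setattr__(self, "icd9_codes", frozenset(self.icd9_codes))


@dataclass(frozen=True)
class CorpusSplit:
    """A stratified train/test partition of a labeled corpus."""

    train: tuple[LabeledReport, ...]
    test: tuple[LabeledReport, ...]
    seed: int
    train_fraction: float


@dataclass(frozen=True)
class LabelDistribution:
    """Abnormal counts and percentages per region and for ``any_abnormal``."""

    n: int
    counts: dict[str, int]
    percents: dict[str, float]


def _parse_record(obj: dict, lineno: int, default_id: str) -> LabeledReport:
    if "text" not in obj or not isinstance(obj["text"], str) or not obj["text"]:
        raise ValueError(f"line {lineno}: record missing non-empty 'text' field")
    labels = None
    if obj.get("labels") is not None:
        labels = RegionLabelSet.from_dict(obj["labels"])
    codes = frozenset(str(c) for c in obj.get("icd9_codes") or ())
    report_id = str(obj.get("report_id") or default_id)
    return LabeledReport(report_id=report_id, text=obj["text"], labels=labels,
                         icd9_codes=codes)


def read_corpus(path: str | Path) -> list[LabeledReport]:
    """Read a JSON-lines corpus file (one report object per line).

    Each line holds ``{"report_id", "text", "labels", "icd9_codes"}``;
    ``labels`` and ``icd9_codes`` may be absent, and a missing ``report_id``
    is auto-assigned from the line number.

    Raises
    ------
    ValueError
        On a malformed line (naming the line number) or a duplicate report_id.
    """
    path = Path(path)
    reports: list[LabeledReport] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {lineno}: malformed JSON record: {exc}") from exc
            if not isinstance(obj, dict):
                raise ValueError(f"line {lineno}: record is not a JSON object")
            report = _parse_record(obj, lineno, default_id=f"report-{lineno:05d}")
            if report.report_id in seen:
                raise ValueError(
                    f"line {lineno}: duplicate report_id {report.report_id!r}")
            seen.add(report.report_id)
            reports.append(report)
    return reports


def write_corpus(reports: Iterable[LabeledReport], path: str | Path) -> None:
    """Write reports as JSON lines (the inverse of :func:`read_corpus`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in reports:
            obj: dict = {"report_id": r.report_id, "text": r.text}
            if r.labels is not None:
                obj["labels"] = r.labels.as_dict()
            if r.icd9_codes:
                obj["icd9_codes"] = sorted(r.icd9_codes)
            fh.write(json.dumps(obj) + "\n")


def stratified_split(corpus: Sequence[LabeledReport], train_fraction: float,
                     seed: int) -> CorpusSplit:
    """Randomly split a labeled corpus, stratified on the any-abnormal flag.

    ``|train| = floor(train_fraction * N)`` exactly; within each stratum
    (any-abnormal vs all-normal) the train share deviates from exact
    proportionality by at most one report.  Deterministic for a fixed seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    unlabeled = [r.report_id for r in corpus if r.labels is None]
    if unlabeled:
        raise ValueError(f"unlabeled reports cannot be split: {unlabeled[:5]}")
    n = len(corpus)
    n_train = math.floor(train_fraction * n)

    strata = {
        True: [r for r in corpus if r.labels.any_abnormal],
        False: [r for r in corpus if not r.labels.any_abnormal],
    }
    rng = random.Random(seed)
    # Allocate floor shares per stratum, then hand remaining train slots to the
    # strata with the largest fractional remainder (abnormal first on ties).
    shares = {k: train_fraction * len(v) for k, v in strata.items()}
    alloc = {k: math.floor(s) for k, s in shares.items()}
    remainder = n_train - sum(alloc.values())
    order = sorted(strata, key=lambda k: (shares[k] - alloc[k], k), reverse=True)
    for k in order[:remainder]:
        alloc[k] += 1

    train: list[LabeledReport] = []
    test: list[LabeledReport] = []
    for k in (True, False):
        members = list(strata[k])
        rng.shuffle(members)
        train.extend(members[: alloc[k]])
        test.extend(members[alloc[k]:])
    rng.shuffle(train)
    rng.shuffle(test)
    return CorpusSplit(train=tuple(train), test=tuple(test), seed=seed,
                       train_fraction=train_fraction)


def label_distribution(corpus: Sequence[LabeledReport]) -> LabelDistribution:
    """Per-region and any-abnormal counts with percentages (2 decimals)."""
    if not corpus:
        raise ValueError("cannot summarize an empty corpus")
    if any(r.labels is None for r in corpus):
        raise ValueError("corpus contains unlabeled reports")
    n = len(corpus)
    counts = {region: sum(r.labels[region] for r in corpus) for region in REGIONS}
    counts["any_abnormal"] = sum(r.labels.any_abnormal for r in corpus)
    percents = {k: round(100.0 * v / n, 2) for k, v in counts.items()}
    return LabelDistribution(n=n, counts=counts, percents=percents)


def cohen_kappa(labels_a: Sequence[bool], labels_b: Sequence[bool]) -> float:
    """Cohen's chance-corrected agreement between two binary annotators.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement rate and
    p_e the agreement expected from the marginal rates.  When both annotators
    are constant and identical (p_e = p_o = 1) kappa is defined as 1.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("annotator label vectors differ in length")
    if not labels_a:
        raise ValueError("annotator label vectors are empty")
    n = len(labels_a)
    a = [bool(x) for x in labels_a]
    b = [bool(x) for x in labels_b]
    p_o = sum(x == y for x, y in zip(a, b)) / n
    pa = sum(a) / n
    pb = sum(b) / n
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)
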