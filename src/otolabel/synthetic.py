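"""Synthetic temporal-bone report corpus generator.

Generates labeled reports with the statistical structure the pipeline
assumes: sectioned text (HISTORY / FINDINGS / IMPRESSION), region-specific
abnormality sentences drawn from a template grammar over ear anatomy
vocabulary, heavy negation around normal structures ("no ossicular
erosion"), decimal measurements with units, optional typo noise, optional
label noise, and patient ICD9 codes correlated with the true labels.  Region
labels are sampled independently with configurable marginal prevalences
(defaults mirror the abnormality rates of the study corpus: inner 26.72 %,
middle 37.59 %, outer 13.79 %, mastoid 30.86 %).
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from functools import lru_cache
from importlib.resources import files
from typing import Mapping, Sequence

import yaml

from .baselines import load_icd9_map
from .corpus import REGIONS, LabeledReport, RegionLabelSet

__all__ = [
    "SyntheticConfig",
    "PAPER_PREVALENCES",
    "load_templates",
    "generate_corpus",
    "make_paper_scale_corpus",
]

#: Marginal abnormality prevalences of the study's 580-report training set.
PAPER_PREVALENCES: dict[str, float] = {
    "inner": 0.2672, "middle": 0.3759, "outer": 0.1379, "mastoid": 0.3086,
}


@lru_cache(maxsize=None)
def load_templates() -> dict:
    """The packaged sentence-template grammar (templates.yaml)."""
    text = files("otolabel").joinpath("data").joinpath(
        "templates.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; all rates are probabilities in [0, 1].

    negation_rate: chance a normal region is mentioned inside a negated
    sentence rather than omitted/benignly described; measurement_rate:
    chance an eligible sentence carries a "measuring <value> <unit>" phrase;
    vocabulary_noise: per-word chance of a single-character typo;
    label_noise: per-region chance of flipping the recorded label after the
    text is written (annotation error).
    """

    n_reports: int = 726
    prevalence: Mapping = field(
        default_factory=lambda: dict(PAPER_PREVALENCES))
    negation_rate: float = 0.5
    measurement_rate: float = 0.3
    vocabulary_noise: float = 0.02
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        rates = {"negation_rate": self.negation_rate,
                 "measurement_rate": self.measurement_rate,
                 "vocabulary_noise": self.vocabulary_noise,
                 "label_noise": self.label_noise,
                 **{f"prevalence[{r}]": self.prevalence[r] for r in REGIONS}}
        for name, value in rates.items():
            if not 0.0 <= float(value) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _typo(word: str, rng: random.Random) -> str:
    if len(word) < 4:
        return word
    i = rng.randrange(len(word))
    op = rng.choice(("sub", "del", "ins"))
    if op == "sub":
        return word[:i] + rng.choice(string.ascii_lowercase) + word[i + 1:]
    if op == "del":
        return word[:i] + word[i + 1:]
    return word[:i] + rng.choice(string.ascii_lowercase) + word[i:]


def _apply_noise(sentence: str, rate: float, rng: random.Random) -> str:
    if rate <= 0:
        return sentence
    words = sentence.split(" ")
    out = [(_typo(w, rng) if rng.random() < rate else w) for w in words]
    return " ".join(out)


def _fill_measurement(template: str, rate: float, rng: random.Random) -> str:
    if "{meas}" not in template:
        return template
    if rng.random() < rate:
        if rng.random() < 0.5:
            value = f"{rng.uniform(1.5, 9.9):.1f}"
        else:
            value = str(rng.randrange(2, 15))
        unit = rng.choice(("mm", "cm"))
        return template.replace("{meas}", f" measuring {value} {unit}")
    return template.replace("{meas}", "")


def _sample_codes(labels: RegionLabelSet, rng: random.Random,
                  icd9_map: Mapping) -> frozenset:
    codes: set[str] = set()
    for region in REGIONS:
        region_codes = sorted(icd9_map[region])
        if labels[region]:
            if rng.random() < 0.7:
                codes.add(rng.choice(region_codes))
        elif rng.random() < 0.05:
            codes.add(rng.choice(region_codes))
    if rng.random() < 0.3:
        codes.add("389.9")  # unspecified hearing loss; maps to no region
    return frozenset(codes)


def generate_corpus(config: SyntheticConfig) -> list[LabeledReport]:
    """Generate a labeled synthetic corpus, reproducibly for a fixed seed.

    Per report and region, the label is Bernoulli(prevalence); abnormal
    regions contribute abnormality sentences, normal regions a negated
    mention at ``negation_rate`` or (half the remaining time) a benign
    mention.  The recorded label is then flipped at ``label_noise``.
    """
    rng = random.Random(config.seed)
    templates = load_templates()
    icd9_map = load_icd9_map()
    reports: list[LabeledReport] = []
    for i in range(config.n_reports):
        true = {r: rng.random() < float(config.prevalence[r]) for r in REGIONS}
        findings: list[str] = []
        for region in REGIONS:
            grammar = templates["regions"][region]
            if true[region]:
                n_sent = 1 + (rng.random() < 0.3)
                picks = rng.sample(grammar["abnormal"],
                                   min(n_sent, len(grammar["abnormal"])))
                for tpl in picks:
                    findings.append(_fill_measurement(
                        tpl, config.measurement_rate, rng))
            else:
                u = rng.random()
                if u < config.negation_rate:
                    findings.append(rng.choice(grammar["negated"]))
                elif u < config.negation_rate + (1 - config.negation_rate) / 2:
                    findings.append(rng.choice(grammar["benign"]))
        rng.shuffle(findings)

        abnormal_regions = [r for r in REGIONS if true[r]]
        if abnormal_regions:
            phrases = [templates["impression_abnormal"][r]
                       for r in abnormal_regions if rng.random() < 0.8]
            if phrases:
                impression = "Abnormal examination with " + ", ".join(phrases) + "."
            else:
                impression = "Abnormal examination of the temporal bones."
        else:
            impression = rng.choice(templates["impression_normal"])

        text = "\n".join([
            "EXAM: CT temporal bones without contrast.",
            "HISTORY: " + rng.choice(templates["history"]),
            "FINDINGS:",
            _apply_noise(" ".join(findings) if findings
                         else "The visualized structures are unremarkable.",
                         config.vocabulary_noise, rng),
            "IMPRESSION:",
            _apply_noise(impression, config.vocabulary_noise, rng),
        ])

        recorded = {r: (not true[r] if rng.random() < config.label_noise
                        else true[r]) for r in REGIONS}
        labels = RegionLabelSet(**recorded)
        reports.append(LabeledReport(
            report_id=f"synth-{i:05d}", text=text, labels=labels,
            icd9_codes=_sample_codes(labels, rng, icd9_map)))
    return reports


def make_paper_scale_corpus(seed: int = 0,
                            label_noise: float = 0.02) -> list[LabeledReport]:
    """Convenience preset at the scale of the study corpus: 726 reports with
    its training-set prevalences, negation rate 0.5, 2 % label noise."""
    config = SyntheticConfig(n_reports=726, prevalence=dict(PAPER_PREVALENCES),
                             negation_rate=0.5, label_noise=label_noise,
                             seed=seed)
    return generate_corpus(config)
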