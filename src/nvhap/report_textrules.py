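"""Rule-based negation classifier for chest radiology reports.

A radiology procedure is dropped from nvHAP preselection when its report
*explicitly rules out* pneumonia.  The rule is deliberately simple text
analysis, not NLP: a report excludes pneumonia iff at least one sentence
contains a negation term (e.g. "no") and an infiltrate term (e.g.
"infiltrate") while containing no *restricting* term (e.g. "but", "left")
— a restricting term signals that the negation is qualified ("no
infiltrate, but ...") or lateralized, in which case the image must still go
to manual review.

Matching is whole-word, case-insensitive and Unicode-diacritics-folded; no
stemming — inflections are handled by enumerating them in the
:class:`TermSet`.  Any ambiguity yields NOT_EXCLUDING: a false "excluded"
loses a case, a false "not excluded" only costs review time.

Term lists are configuration, not code.  The bundled German-style and
French-style sets are reconstructions of unpublished hospital lists and
should be replaced by locally curated lists in production.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml
from pydantic import BaseModel, field_validator, model_validator

_WORD = re.compile(r"\w+", re.UNICODE)
_SENTENCE_BOUNDARY = re.compile(r"[.!?;\n]")


def fold(text: str) -> str:
    """Lowercase and strip combining diacritics (é → e, ü → u)."""
    decomposed = unicodedata.normalize("NFKD", text.lower())
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


class TermSet(BaseModel):
    """Language-specific term lists driving the exclusion rule.

    All terms are stored lowercase; matching additionally folds diacritics
    on both sides.  The three lists must be non-empty and pairwise disjoint
    (after folding) — a term that both negates and restricts would make the
    rule ill-defined.
    """

    model_config = {"frozen": True}

    language_tag: str
    negation_terms: tuple[str, ...]
    infiltrate_terms: tuple[str, ...]
    restricting_terms: tuple[str, ...]

    @field_validator("negation_terms", "infiltrate_terms", "restricting_terms", mode="before")
    @classmethod
    def _non_empty_lowercase(cls, v):
        terms = tuple(v)
        if not terms:
            raise ValueError("term list must be non-empty")
        for t in terms:
            if t != t.lower() or not t.strip():
                raise ValueError(f"terms must be non-blank lowercase: {t!r}")
        return terms

    @model_validator(mode="after")
    def _disjoint(self):
        folded = [
            {fold(t) for t in lst}
            for lst in (self.negation_terms, self.infiltrate_terms, self.restricting_terms)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                clash = folded[i] & folded[j]
                if clash:
                    raise ValueError(f"term(s) {sorted(clash)} appear in two lists")
        return self


class Verdict(str, enum.Enum):
    EXCLUDES_PNEUMONIA = "EXCLUDES_PNEUMONIA"
    NOT_EXCLUDING = "NOT_EXCLUDING"


@dataclass(frozen=True)
class ReportVerdict:
    verdict: Verdict
    matched_sentence: str | None = None
    matched_terms: tuple[str, ...] = field(default_factory=tuple)

    def __bool__(self) -> bool:  # truthy iff the report excludes pneumonia
        return self.verdict is Verdict.EXCLUDES_PNEUMONIA


def segment_sentences(report_text: str) -> list[str]:
    """Split a report into sentences on '.', '!', '?', ';' and newlines.

    Delimiters stay attached to their sentence; surrounding whitespace is
    stripped and empty fragments dropped.  Abbreviations are not
    special-cased: mis-splits only make the exclusion rule more
    conservative (toward manual review).
    """
    sentences: list[str] = []
    start = 0
    for match in _SENTENCE_BOUNDARY.finditer(report_text):
        fragment = report_text[start : match.end()].strip()
        if fragment:
            sentences.append(fragment)
        start = match.end()
    tail = report_text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def _tokens(sentence: str) -> set[str]:
    return set(_WORD.findall(fold(sentence)))


def classify_report(report_text: str, terms: TermSet) -> ReportVerdict:
    """Decide whether a report explicitly rules out pneumonia.

    EXCLUDES_PNEUMONIA iff some sentence contains at least one negation
    term and at least one infiltrate term and no restricting term;
    otherwise NOT_EXCLUDING (including for empty reports).
    """
    negation = {fold(t) for t in terms.negation_terms}
    infiltrate = {fold(t) for t in terms.infiltrate_terms}
    restricting = {fold(t) for t in terms.restricting_terms}
    for sentence in segment_sentences(report_text):
        tokens = _tokens(sentence)
        neg_hits = tokens & negation
        inf_hits = tokens & infiltrate
        if neg_hits and inf_hits and not (tokens & restricting):
            return ReportVerdict(
                Verdict.EXCLUDES_PNEUMONIA,
                matched_sentence=sentence,
                matched_terms=tuple(sorted(neg_hits | inf_hits)),
            )
    return ReportVerdict(Verdict.NOT_EXCLUDING)


def _bundled_termsets() -> dict[str, dict]:
    text = resources.files("nvhap").joinpath("termsets.yaml").read_text(encoding="utf-8")
    return yaml.safe_load(text)


def load_termset(
    source: Mapping | str | Path | None = None,
    language_tag: str | None = None,
) -> TermSet:
    """Build a validated :class:`TermSet`.

    ``source`` may be a mapping (a parsed config section), a path to a YAML
    file with the three lists, or None to select a bundled default by
    ``language_tag`` ("de" or "fr").  The bundled sets are documented
    reconstructions, not the original hospital lists.
    """
    if source is None:
        bundled = _bundled_termsets()
        tag = language_tag or "de"
        if tag not in bundled:
            raise ValueError(f"no bundled term set for language {tag!r}; available: {sorted(bundled)}")
        data = dict(bundled[tag])
    elif isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
        if not isinstance(data, Mapping):
            raise ValueError(f"term-set file {source} must contain a mapping")
        data = dict(data)
    else:
        data = dict(source)
    if language_tag is not None:
        data["language_tag"] = language_tag
    missing = {"language_tag", "negation_terms", "infiltrate_terms", "restricting_terms"} - set(data)
    if missing:
        raise ValueError(f"term-set source missing field(s): {sorted(missing)}")
    return TermSet(**data)
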