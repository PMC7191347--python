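"""Classify raw record strings into ventilation modalities.

Tele-ICU exports mix structured menu selections ("Intubated/oral ETT",
hierarchical treatment paths) with free text (nurse-chart oxygen-device
detail). Two primitives cover both:

* :func:`classify_record_term` — lexicon lookup with partial-term
  (substring) matching and a fixed modality precedence,
  INVASIVE > NIPPV > HFNI > LOW_FLOW, so that a specific device name
  appended to a broader therapy path resolves to the most specific
  therapy and an invasive token inside a longer string is never read
  as noninvasive support.
* :func:`normalize_hfni_variant` — free-text high-flow detection tolerant
  of the many observed spellings ("HFNC", "highflow n/c", "optiflow", ...)
  plus a flow-rate heuristic: a nasal-cannula entry with an explicit flow
  of at least 15 L/min is high-flow, below 15 L/min is conventional
  low-flow oxygen.

The default lexicon ships as YAML package data and can be replaced by any
file with the same schema via :func:`lexicon_from_config`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .ehr_model import Modality, Source

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "MODALITY_PRECEDENCE",
    "HFNI_FLOW_THRESHOLD_LPM",
    "classify_record_term",
    "normalize_hfni_variant",
    "lexicon_from_config",
    "default_lexicon",
    "default_drug_lexicon",
    "drug_lexicon_from_config",
]

#: Tie-break order when one string matches entries of several modalities.
MODALITY_PRECEDENCE: tuple[Modality, ...] = (
    Modality.INVASIVE,
    Modality.NIPPV,
    Modality.HFNI,
    Modality.LOW_FLOW,
)

#: Flow boundary between conventional low-flow oxygen and high-flow
#: nasal insufflation, in litres per minute.
HFNI_FLOW_THRESHOLD_LPM = 15.0

#: Token patterns (matched on normalized text) that identify high-flow
#: nasal insufflation in free-text device fields.
DEFAULT_HFNI_VARIANT_TOKENS: tuple[str, ...] = (
    "hfnc",
    "hfni",
    "high flow",
    "highflow",
    "hi flow",
    "hiflow",
    "optiflow",
    "airvo",
    "vapotherm",
    "nasal insufflation",
)

_FLOW_RE = re.compile(r"(\d+(?:\.\d+)?)\s*l(?:pm|(?:\s*/\s*|\s+)?min)?\b", re.IGNORECASE)
_CANNULA_RE = re.compile(r"cannula|\bnc\b|\bn\s*/\s*c\b|\bn c\b")
_NORMALIZE_RE = re.compile(r"[^a-z0-9]+")


class LexiconError(ValueError):
    """Invalid lexicon definition (empty pattern or contradictory entries)."""


@dataclass(frozen=True)
class LexiconEntry:
    pattern: str
    match_mode: str  # "SUBSTRING" | "EXACT"
    modality: Modality
    sources: frozenset[Source] | None = None  # None = applies to every source

    def applies_to(self, source: Source) -> bool:
        return self.sources is None or source in self.sources

    def matches(self, term: str, case_sensitive: bool) -> bool:
        pattern, text = self.pattern, term
        if not case_sensitive:
            pattern, text = pattern.lower(), text.lower()
        if self.match_mode == "EXACT":
            return text.strip() == pattern.strip()
        return pattern in text


@dataclass(frozen=True)
class Lexicon:
    entries: tuple[LexiconEntry, ...]
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: dict[tuple[str, str], list[LexiconEntry]] = {}
        for entry in self.entries:
            if not entry.pattern:
                raise LexiconError("lexicon pattern must be non-empty")
            if entry.match_mode not in {"SUBSTRING", "EXACT"}:
                raise LexiconError(f"unknown match_mode {entry.match_mode!r}")
            key = (
                entry.pattern if self.case_sensitive else entry.pattern.lower(),
                entry.match_mode,
            )
            for other in seen.setdefault(key, []):
                scopes_overlap = (
                    entry.sources is None
                    or other.sources is None
                    or bool(entry.sources & other.sources)
                )
                if scopes_overlap and other.modality is not entry.modality:
                    raise LexiconError(
                        f"pattern {entry.pattern!r} maps to both "
                        f"{other.modality.value} and {entry.modality.value} "
                        "within the same source scope"
                    )
            seen[key].append(entry)

    def matching_modalities(self, raw_term: str, source: Source) -> set[Modality]:
        return {
            e.modality
            for e in self.entries
            if e.applies_to(source) and e.matches(raw_term, self.case_sensitive)
        }


def _normalize_text(text: str) -> str:
    """Lowercase, strip punctuation to spaces, collapse whitespace."""
    return _NORMALIZE_RE.sub(" ", text.lower()).strip()


def extract_flow_lpm(text: str) -> float | None:
    """Extract an explicit oxygen flow in L/min ('2L', '40 lpm', '30 L/min')."""
    m = _FLOW_RE.search(_normalize_text(text))
    return float(m.group(1)) if m else None


def _mentions_cannula(text: str) -> bool:
    return bool(_CANNULA_RE.search(_normalize_text(text)))


def classify_record_term(
    raw_term: str, source: Source, lexicon: Lexicon | None = None
) -> Modality:
    """Map one raw record string to a ventilation modality.

    Total on text: unmatched or empty strings yield ``Modality.NONE``.
    A nasal-cannula string carrying an explicit flow >= 15 L/min is
    upgraded from LOW_FLOW/NONE to HFNI (flow-rate heuristic).
    """
    if lexicon is None:
        lexicon = default_lexicon()
    matched = lexicon.matching_modalities(raw_term, source) if raw_term else set()
    result = Modality.NONE
    for modality in MODALITY_PRECEDENCE:
        if modality in matched:
            result = modality
            break
    if result in (Modality.LOW_FLOW, Modality.NONE) and _mentions_cannula(raw_term):
        flow = extract_flow_lpm(raw_term)
        if flow is not None and flow >= HFNI_FLOW_THRESHOLD_LPM:
            result = Modality.HFNI
    return result


def normalize_hfni_variant(
    free_text: str, variant_tokens: tuple[str, ...] = DEFAULT_HFNI_VARIANT_TOKENS
) -> bool:
    """True iff a free-text oxygen-device entry denotes high-flow nasal
    insufflation.

    Deterministic for a fixed token list; invariant to case, surrounding
    whitespace and punctuation. A plain nasal-cannula entry qualifies only
    when it states a flow of at least 15 L/min.
    """
    normalized = _normalize_text(free_text)
    if not normalized:
        return False
    if any(token in normalized for token in variant_tokens):
        return True
    if _mentions_cannula(free_text):
        flow = extract_flow_lpm(free_text)
        return flow is not None and flow >= HFNI_FLOW_THRESHOLD_LPM
    return False


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------


def _parse_sources(value) -> frozenset[Source] | None:
    if value in (None, "", "ALL", "all"):
        return None
    if isinstance(value, str):
        names = [v for v in re.split(r"[|,;]", value) if v.strip()]
    else:
        names = list(value)
    return frozenset(Source(name.strip().upper()) for name in names)


def _entry_from_mapping(raw: dict) -> LexiconEntry:
    return LexiconEntry(
        pattern=str(raw["pattern"]),
        match_mode=str(raw.get("match_mode", "SUBSTRING")).upper(),
        modality=Modality(str(raw["modality"]).upper()),
        sources=_parse_sources(raw.get("sources")),
    )


def lexicon_from_config(config_path: str | Path) -> Lexicon:
    """Load a lexicon from YAML (``entries:`` list) or CSV
    (``pattern,match_mode,modality,sources`` columns).

    Raises :class:`LexiconError` for contradictory duplicate patterns,
    citing both entries.
    """
    path = Path(config_path)
    if path.suffix.lower() == ".csv":
        with path.open(newline="", encoding="utf-8") as fh:
            raw_entries = list(csv.DictReader(fh))
        case_sensitive = False
    else:
        config = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        raw_entries = config.get("entries", [])
        case_sensitive = bool(config.get("case_sensitive", False))
    entries = tuple(_entry_from_mapping(e) for e in raw_entries)
    return Lexicon(entries=entries, case_sensitive=case_sensitive)


_default_lexicon_cache: Lexicon | None = None


def default_lexicon() -> Lexicon:
    """The packaged default lexicon covering the standard tele-ICU terms."""
    global _default_lexicon_cache
    if _default_lexicon_cache is None:
        with resources.as_file(
            resources.files("arfpheno.data") / "default_lexicon.yaml"
        ) as path:
            _default_lexicon_cache = lexicon_from_config(path)
    return _default_lexicon_cache


def drug_lexicon_from_config(config_path: str | Path) -> tuple[str, ...]:
    """Load a peri-intubation drug lexicon (YAML ``drugs:`` list of
    lowercase substrings)."""
    config = yaml.safe_load(Path(config_path).read_text(encoding="utf-8")) or {}
    drugs = tuple(str(d).lower() for d in config.get("drugs", []))
    if any(not d for d in drugs):
        raise LexiconError("drug patterns must be non-empty")
    return drugs


_default_drugs_cache: tuple[str, ...] | None = None


def default_drug_lexicon() -> tuple[str, ...]:
    global _default_drugs_cache
    if _default_drugs_cache is None:
        with resources.as_file(
            resources.files("arfpheno.data") / "default_drugs.yaml"
        ) as path:
            _default_drugs_cache = drug_lexicon_from_config(path)
    return _default_drugs_cache
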