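"""Rule-based extraction from sectioned Chinese clinical notes.

The pipeline is: section preprocessing -> per-concept pattern matching
(keyword + quantity + unit; keyword + qualitative token; calendar dates) ->
date/value pairing inside sentence items for concepts followed over time ->
a four-step postprocessor (malformed numerics, date-like values, plausibility
ranges, duplicates).

Spans are always reported in the coordinate system of the *original* document
text: the raw text is never rewritten, sections and items are carved out as
offset windows.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Optional, Sequence

from .concepts import (
    CATEGORICAL,
    DATE,
    MENSTRUAL_CYCLE,
    QUANTITY,
    ConceptSpec,
    default_specs,
)
from .documents import (
    MACHINE_RE,
    MANUAL_RE,
    EMRDocument,
    Extraction,
    PatientRecord,
    TimedValue,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# sections

PRESENT_ILLNESS = "present_illness"
MENSTRUAL_HISTORY = "menstrual_history"
WHOLE_DOCUMENT = "document"

_SECTION_HEADERS = {PRESENT_ILLNESS: "现病史", MENSTRUAL_HISTORY: "月经史"}
# headers that merely terminate a section of interest
_OTHER_HEADERS = ("主诉", "既往史", "婚育史", "家族史", "体格检查", "辅助检查", "诊断")


@dataclass(frozen=True)
class Section:
    name: str
    start: int
    end: int
    text: str

    def lines(self) -> list[str]:
        """Section content with blank lines removed."""
        return [ln for ln in self.text.splitlines() if ln.strip()]


def preprocess(text: str) -> dict[str, Section]:
    """Locate the history-of-present-illness and menstrual-history sections.

    Returns a map of section name -> :class:`Section` (offset windows into
    *text*).  If neither header is present the whole cleaned text is returned
    as a single pseudo-section under ``"document"``, with a warning.
    """
    if not text:
        raise ValueError("text must be non-empty")
    boundaries: list[tuple[int, Optional[str]]] = []
    for name, header in _SECTION_HEADERS.items():
        for m in re.finditer(re.escape(header) + r"[：:]?", text):
            boundaries.append((m.start(), name))
    for header in _OTHER_HEADERS:
        for m in re.finditer(re.escape(header) + r"[：:]", text):
            boundaries.append((m.start(), None))
    boundaries.sort()

    sections: dict[str, Section] = {}
    for i, (pos, name) in enumerate(boundaries):
        if name is None or name in sections:
            continue
        end = boundaries[i + 1][0] if i + 1 < len(boundaries) else len(text)
        sections[name] = Section(name, pos, end, text[pos:end])
    if not sections:
        logger.warning("no section headers found; falling back to whole-document extraction")
        if text.strip():
            sections[WHOLE_DOCUMENT] = Section(WHOLE_DOCUMENT, 0, len(text), text)
        else:
            logger.warning("document contains only blank lines")
    return sections


# ---------------------------------------------------------------------------
# pattern compilation

_SEP = r"[：:＝=]?\s*"
_VALUE = r"(?P<value>\d+(?:\.\d*)*)"  # deliberately loose: captures 5..32 for postprocessing
_LOOSE_GAP = r"[^0-9，。；,;\n]{0,8}?"

_DATE_RE = re.compile(
    r"(?P<y>\d{4})年(?P<m>\d{1,2})月(?P<d>\d{1,2})日"
    r"|(?P<y2>\d{4})-(?P<m2>\d{1,2})-(?P<d2>\d{1,2})"
    r"|(?P<y3>\d{4})\.(?P<m3>\d{1,2})\.(?P<d3>\d{1,2})"
)

_CYCLE_SLASH_RE = re.compile(
    r"(?<![0-9./-])(?P<menses>\d{1,2}(?:-\d{1,2})?)/(?P<value>\d{1,3}(?:-\d{1,3})?)天"
)


def _keyword_pattern(kw: str) -> str:
    """Escape one keyword, guarding Latin aliases against in-word matches."""
    esc = re.escape(kw)
    if not re.fullmatch(r"[A-Za-z][A-Za-z0-9]*", kw):
        return esc
    pat = rf"(?<![A-Za-z]){esc}"
    pat += r"(?![0-9A-Za-z])" if kw[-1].isdigit() else r"(?![A-Za-z])"
    if len(kw) == 1:
        # single-letter aliases (E, P, T) must immediately head a value
        pat += rf"(?={_SEP}\d)"
    return pat


def _keyword_alternation(keywords: Sequence[str]) -> str:
    ordered = sorted(keywords, key=len, reverse=True)
    return "(?:" + "|".join(_keyword_pattern(k) for k in ordered) + ")"


def _unit_alternation(units: Sequence[str]) -> str:
    if not units:
        return ""
    ordered = sorted(set(units), key=len, reverse=True)
    return r"\s*(?P<unit>" + "|".join(re.escape(u) for u in ordered) + ")?"


@dataclass(frozen=True)
class CompiledRule:
    spec: ConceptSpec
    patterns: tuple[re.Pattern, ...]


@dataclass(frozen=True)
class RuleSet:
    rules: dict[str, CompiledRule]
    date_pattern: re.Pattern = _DATE_RE

    def __getitem__(self, concept: str) -> CompiledRule:
        return self.rules[concept]

    def __contains__(self, concept: str) -> bool:
        return concept in self.rules


def compile_manual_ruleset(specs: Optional[dict[str, ConceptSpec]] = None) -> RuleSet:
    """Compile one pattern (occasionally two) per concept from its spec."""
    specs = specs if specs is not None else default_specs()
    rules: dict[str, CompiledRule] = {}
    for spec in specs.values():
        if spec.rule == DATE:
            rules[spec.name] = CompiledRule(spec, (_DATE_RE,))
            continue
        if spec.rule == QUANTITY:
            kws = [k for k in spec.keywords if k != "/"]
            pats = []
            if kws:
                gap = _LOOSE_GAP if spec.gap == "loose" else _SEP + r"(?:约)?"
                value = r"(?P<value>\d{1,3}(?:-\d{1,3})?)" if spec.name == MENSTRUAL_CYCLE else _VALUE
                pats.append(
                    re.compile(_keyword_alternation(kws) + gap + value + _unit_alternation(spec.units))
                )
            if spec.name == MENSTRUAL_CYCLE:
                # the "/" shorthand: menses-days / cycle-days 天
                pats.append(_CYCLE_SLASH_RE)
            rules[spec.name] = CompiledRule(spec, tuple(pats))
        elif spec.rule == CATEGORICAL:
            toks = sorted(spec.categories, key=len, reverse=True)
            pat = re.compile(
                _keyword_alternation(spec.keywords) + _SEP + "(?P<value>" + "|".join(map(re.escape, toks)) + ")"
            )
            rules[spec.name] = CompiledRule(spec, (pat,))
        else:  # pragma: no cover - guarded by ConceptSpec validation
            raise ValueError(f"unknown rule tag {spec.rule!r}")
    return RuleSet(rules)


# ---------------------------------------------------------------------------
# item segmentation and date/value pairing

# a half-width period is a boundary only when not acting as a decimal point
# (runs of dots inside a malformed number stay inside the item)
_ITEM_BOUNDARY = re.compile(r"[。；;\n]|\.(?![0-9.])")


def segment_items(section_text: str, offset: int = 0) -> list[tuple[str, int]]:
    """Split a section into sentence items bounded by full stops/semicolons.

    Returns ``(item_text, absolute_start)`` pairs; commas are kept inside an
    item so that a leading date governs the comma-joined measurements that
    follow it.
    """
    items: list[tuple[str, int]] = []
    pos = 0
    for m in _ITEM_BOUNDARY.finditer(section_text):
        chunk = section_text[pos:m.start()]
        if chunk.strip():
            items.append((chunk, offset + pos))
        pos = m.end()
    tail = section_text[pos:]
    if tail.strip():
        items.append((tail, offset + pos))
    return items


def _parse_date(m: re.Match) -> Optional[Date]:
    for suffix in ("", "2", "3"):
        y = m.group("y" + suffix) if "y" + suffix in m.groupdict() else None
        if y:
            try:
                return Date(int(y), int(m.group("m" + suffix)), int(m.group("d" + suffix)))
            except ValueError:
                return None
    return None


def _parse_number(raw: str):
    """Parse a captured quantity; malformed tokens are kept as raw strings."""
    try:
        if re.fullmatch(r"\d+", raw):
            return int(raw)
        return float(raw)
    except ValueError:
        return raw


def _cycle_value(m: re.Match):
    raw = m.group("value")
    if "-" in raw:
        lo, hi = raw.split("-", 1)
        return (int(lo), int(hi))
    return int(raw)


def _match_to_extraction(
    m: re.Match, spec: ConceptSpec, offset: int, date: Optional[Date], provenance: str
) -> Extraction:
    raw = m.group("value")
    span = (offset + m.start("value"), offset + m.end("value"))
    unit = m.groupdict().get("unit")
    if provenance == MACHINE_RE and (spec.rule != QUANTITY or not re.fullmatch(r"[\d.]+", raw)):
        # machine patterns report whole matches; narrow to the value token
        value = parse_machine_match(raw, spec)
        if isinstance(value, (int, float)):
            vm = re.search(r"\d+(?:\.\d*)*", raw)
            span = (offset + m.start("value") + vm.start(), offset + m.start("value") + vm.end())
            raw = vm.group()
        return Extraction(concept=spec.name, value=value, unit=unit, date=date,
                          span=span, provenance=provenance, raw=raw)
    if spec.name == MENSTRUAL_CYCLE:
        value = _cycle_value(m)
    elif spec.rule == QUANTITY:
        value = _parse_number(raw)
    else:
        value = raw
    return Extraction(
        concept=spec.name, value=value, unit=unit, date=date, span=span,
        provenance=provenance, raw=raw,
    )


def extract_timed(
    section_text: str,
    spec: ConceptSpec,
    ruleset: RuleSet,
    offset: int = 0,
    provenance: str = MANUAL_RE,
) -> list[Extraction]:
    """Find all (date, value) occurrences of a timed concept in a section.

    Within each sentence item, every value is paired with the nearest
    preceding date of the same item; values with no preceding date get a
    null date.  Output is ordered by date (undated last), then position.
    """
    out: list[Extraction] = []
    rule = ruleset[spec.name]
    for item_text, item_start in segment_items(section_text, offset):
        dates = [
            (m.end(), _parse_date(m))
            for m in ruleset.date_pattern.finditer(item_text)
            if _parse_date(m) is not None
        ]
        for pat in rule.patterns:
            for m in pat.finditer(item_text):
                date = None
                for end, d in dates:
                    if end <= m.start():
                        date = d
                    else:
                        break
                out.append(_match_to_extraction(m, spec, item_start, date, provenance))
    out.sort(key=lambda e: (e.date is None, e.date or Date.min, e.span))
    return out


def extract_single(
    section_text: str,
    spec: ConceptSpec,
    ruleset: RuleSet,
    offset: int = 0,
    provenance: str = MANUAL_RE,
) -> Optional[Extraction]:
    """First occurrence of a non-timed concept in reading order, or None."""
    rule = ruleset[spec.name]
    best: Optional[re.Match] = None
    for pat in rule.patterns:
        m = pat.search(section_text)
        if m and (best is None or m.start() < best.start()):
            best = m
    if best is None:
        return None
    return _match_to_extraction(best, spec, offset, None, provenance)


# ---------------------------------------------------------------------------
# postprocessing

REASON_MALFORMED = "malformed_numeric"
REASON_DATE_LIKE = "date_like_value"
REASON_OUT_OF_RANGE = "out_of_range"
REASON_DUPLICATE = "duplicate"


@dataclass(frozen=True)
class Rejection:
    extraction: Extraction
    reason: str


def _is_date_like(value) -> bool:
    return isinstance(value, int) and 1900 <= value <= 2100


# plausibility windows are stated in each concept's canonical unit; values
# reported in an alternate unit are converted for the check only
_RANGE_CONVERSIONS = {("amh", "pmol/L"): 1 / 7.14}


def _range_scale(concept: str, unit: Optional[str]) -> float:
    if unit is None:
        return 1.0
    return _RANGE_CONVERSIONS.get((concept, unit), 1.0)


def postprocess(
    extractions: Sequence[Extraction],
    specs: Optional[dict[str, ConceptSpec]] = None,
) -> tuple[list[Extraction], list[Rejection]]:
    """Drop malformed, date-like, out-of-range and duplicate values.

    Every drop is logged with a reason code.  The operation is idempotent.
    """
    specs = specs if specs is not None else default_specs()
    kept: list[Extraction] = []
    rejected: list[Rejection] = []
    seen: set = set()
    for ext in extractions:
        spec = specs[ext.concept]
        if spec.rule == QUANTITY:
            if isinstance(ext.value, str):
                rejected.append(Rejection(ext, REASON_MALFORMED))
                continue
            if ext.raw is not None and ext.raw.count(".") > 1:
                rejected.append(Rejection(ext, REASON_MALFORMED))
                continue
            if spec.name != MENSTRUAL_CYCLE and _is_date_like(ext.value):
                rejected.append(Rejection(ext, REASON_DATE_LIKE))
                continue
            if spec.plausible_range is not None:
                lo, hi = spec.plausible_range
                scale = _range_scale(ext.concept, ext.unit)
                vals = ext.value if isinstance(ext.value, tuple) else (ext.value,)
                if any(not lo <= v * scale <= hi for v in vals):
                    rejected.append(Rejection(ext, REASON_OUT_OF_RANGE))
                    continue
        key = (ext.concept, ext.date, ext.value)
        if key in seen:
            rejected.append(Rejection(ext, REASON_DUPLICATE))
            continue
        seen.add(key)
        kept.append(ext)
    return kept, rejected


# ---------------------------------------------------------------------------
# whole-document extraction

def _ordered_sections(sections: dict[str, Section]) -> list[Section]:
    return sorted(sections.values(), key=lambda s: s.start)


def extract_document(
    doc: EMRDocument,
    specs: Optional[dict[str, ConceptSpec]] = None,
    ruleset: Optional[RuleSet] = None,
    provenance: str = MANUAL_RE,
) -> tuple[PatientRecord, list[Rejection]]:
    """Run the full pipeline on one document, yielding its structured record."""
    specs = specs if specs is not None else default_specs()
    if ruleset is None:
        ruleset = compile_manual_ruleset(specs)
    sections = _ordered_sections(preprocess(doc.text))

    raw: list[Extraction] = []
    for spec in specs.values():
        if spec.rule == DATE or spec.name not in ruleset:
            continue
        if spec.timed:
            for sec in sections:
                raw.extend(extract_timed(sec.text, spec, ruleset, sec.start, provenance))
        else:
            for sec in sections:
                ext = extract_single(sec.text, spec, ruleset, sec.start, provenance)
                if ext is not None:
                    raw.append(ext)
                    break
    kept, rejections = postprocess(raw, specs)

    record = PatientRecord(doc_id=doc.doc_id, age=doc.age)
    for ext in kept:
        spec = specs[ext.concept]
        if spec.timed:
            record.series.setdefault(ext.concept, []).append(
                TimedValue(value=ext.value, date=ext.date, unit=ext.unit, span=ext.span)
            )
        else:
            record.singles.setdefault(ext.concept, ext.value)
    for vals in record.series.values():
        vals.sort(key=lambda tv: (tv.date is None, tv.date or Date.min, tv.span or (0, 0)))
    return record, rejections


def extract_corpus(
    docs: Sequence[EMRDocument],
    specs: Optional[dict[str, ConceptSpec]] = None,
    ruleset: Optional[RuleSet] = None,
    provenance: str = MANUAL_RE,
) -> tuple[list[PatientRecord], list[tuple[str, Rejection]]]:
    specs = specs if specs is not None else default_specs()
    if ruleset is None:
        ruleset = compile_manual_ruleset(specs)
    records, log = [], []
    for doc in docs:
        rec, rej = extract_document(doc, specs, ruleset, provenance)
        records.append(rec)
        log.extend((doc.doc_id, r) for r in rej)
    return records, log


# ---------------------------------------------------------------------------
# machine-learned rulesets (regex strings produced by the GP synthesiser)


def build_machine_ruleset(
    regexes: dict[str, str], specs: Optional[dict[str, ConceptSpec]] = None
) -> RuleSet:
    """Wrap concept -> regex-string mappings as an extraction ruleset.

    Machine patterns capture whole matches; when a pattern has no ``value``
    group the first numeric token (or categorical token) inside the match is
    taken as the value.
    """
    specs = specs if specs is not None else default_specs()
    rules: dict[str, CompiledRule] = {}
    for concept, rx in regexes.items():
        spec = specs[concept]
        pat = re.compile(rx)
        if "value" not in pat.groupindex:
            pat = re.compile(_wrap_value_group(rx, spec))
        rules[concept] = CompiledRule(spec, (pat,))
    return RuleSet(rules)


def _wrap_value_group(rx: str, spec: ConceptSpec) -> str:
    # run the machine pattern as-is, then locate the value inside the match
    # text via a second pass in _machine_value; here we just name the whole
    # match so downstream code has a value span to report.
    return rf"(?P<value>{rx})"


def parse_machine_match(text: str, spec: ConceptSpec):
    """Pull the normalised value out of a machine-regex match text."""
    if spec.rule == CATEGORICAL:
        for tok in sorted(spec.categories, key=len, reverse=True):
            if tok in text:
                return tok
        return text
    m = re.search(r"\d+(?:\.\d*)*", text)
    return _parse_number(m.group()) if m else text


def save_machine_ruleset(regexes: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for concept, rx in sorted(regexes.items()):
            fh.write(f"{concept}\t{rx}\n")


def load_machine_ruleset(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                concept, rx = line.rstrip("\n").split("\t", 1)
                out[concept] = rx
    return out
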