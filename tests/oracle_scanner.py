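"""Brute-force character-scanning parser used as an independent oracle.

Re-implements the extraction semantics (sectioning, sentence items, keyword
guards, gap/value/unit parsing, date pairing, plausibility filtering) with
plain string operations — no regular expressions anywhere — so that
agreement with the compiled ruleset is a meaningful cross-check.
"""

from __future__ import annotations

from datetime import date as Date
from typing import Optional

from reprotext import concepts as C
from reprotext.concepts import CATEGORICAL, DATE, QUANTITY, default_specs
from reprotext.documents import EMRDocument, PatientRecord, TimedValue

_TARGET_HEADERS = {"present_illness": "现病史", "menstrual_history": "月经史"}
_OTHER_HEADERS = ("主诉", "既往史", "婚育史", "家族史", "体格检查", "辅助检查", "诊断")
_SEP_CHARS = "：:＝="
_ITEM_STOPS = "。；;\n"
_LOOSE_FORBIDDEN = "0123456789，。；,;\n"
_DATE_RANGE = (1900, 2100)
_AMH_PMOL_SCALE = 1 / 7.14


def _find_all(text: str, needle: str) -> list[int]:
    out, i = [], text.find(needle)
    while i >= 0:
        out.append(i)
        i = text.find(needle, i + 1)
    return out


def split_sections(text: str) -> list[tuple[str, int, str]]:
    """(name, start, section_text) in reading order; whole-doc fallback."""
    marks: list[tuple[int, Optional[str]]] = []
    for name, header in _TARGET_HEADERS.items():
        for i in _find_all(text, header):
            marks.append((i, name))
    for header in _OTHER_HEADERS:
        for i in _find_all(text, header):
            if i + len(header) < len(text) and text[i + len(header)] in "：:":
                marks.append((i, None))
    marks.sort()
    sections, taken = [], set()
    for j, (pos, name) in enumerate(marks):
        if name is None or name in taken:
            continue
        taken.add(name)
        end = marks[j + 1][0] if j + 1 < len(marks) else len(text)
        sections.append((name, pos, text[pos:end]))
    if not sections and text.strip():
        sections.append(("document", 0, text))
    sections.sort(key=lambda s: s[1])
    return sections


def split_items(section: str, offset: int) -> list[tuple[str, int]]:
    items, start, i = [], 0, 0
    n = len(section)
    while i < n:
        ch = section[i]
        boundary = ch in _ITEM_STOPS or (
            ch == "." and (i + 1 >= n or section[i + 1] not in "0123456789.")
        )
        if boundary:
            chunk = section[start:i]
            if chunk.strip():
                items.append((chunk, offset + start))
            start = i + 1
        i += 1
    tail = section[start:]
    if tail.strip():
        items.append((tail, offset + start))
    return items


def _is_latin(ch: str) -> bool:
    return "a" <= ch <= "z" or "A" <= ch <= "Z"


def _digits(s: str, i: int, lo: int, hi: int) -> Optional[tuple[int, int]]:
    """Greedy run of between lo and hi digits starting at i -> (value_end, count)."""
    j = i
    while j < len(s) and s[j].isdigit() and j - i < hi:
        j += 1
    if j - i < lo:
        return None
    return (j, j - i)


def _try_date_at(s: str, i: int) -> Optional[tuple[int, Optional[Date]]]:
    """Date starting at i (年月日 / dash / dot dialects) -> (end, parsed)."""
    d4 = _digits(s, i, 4, 4)
    if d4 is None or (d4[0] < len(s) and s[d4[0]].isdigit()):
        return None
    year = int(s[i:d4[0]])
    for sep1, sep2, terminal in (("年", "月", "日"), ("-", "-", ""), (".", ".", "")):
        j = d4[0]
        if j >= len(s) or not s.startswith(sep1, j):
            continue
        j += len(sep1)
        dm = _digits(s, j, 1, 2)
        if dm is None:
            continue
        month_end = dm[0]
        if month_end >= len(s) or not s.startswith(sep2, month_end):
            if dm[1] == 2:  # backtrack to a one-digit month
                dm = (j + 1, 1)
                month_end = dm[0]
                if month_end >= len(s) or not s.startswith(sep2, month_end):
                    continue
            else:
                continue
        month = int(s[j:month_end])
        j2 = month_end + len(sep2)
        dd = _digits(s, j2, 1, 2)
        if dd is None:
            continue
        day_end = dd[0]
        day = int(s[j2:day_end])
        if terminal:
            if not s.startswith(terminal, day_end):
                if dd[1] == 2 and s.startswith(terminal, j2 + 1):
                    day_end, day = j2 + 1, int(s[j2:j2 + 1])
                else:
                    continue
            day_end += len(terminal)
        try:
            return (day_end, Date(year, month, day))
        except ValueError:
            return (day_end, None)
    return None


def scan_dates(item: str) -> list[tuple[int, Optional[Date]]]:
    out, i = [], 0
    while i < len(item):
        hit = _try_date_at(item, i)
        if hit is not None:
            out.append(hit)
            i = hit[0]
        else:
            i += 1
    return out


def _number_end(s: str, i: int) -> int:
    """End of a loose numeric token: digits, then dot-groups (digits optional)."""
    j = i
    while j < len(s) and s[j].isdigit():
        j += 1
    while j < len(s) and s[j] == ".":
        j += 1
        while j < len(s) and s[j].isdigit():
            j += 1
    return j


def _kw_guard_ok(s: str, i: int, kw: str) -> bool:
    if kw[0].isascii() and kw[0].isalpha():
        if i > 0 and _is_latin(s[i - 1]):
            return False
        end = i + len(kw)
        if end < len(s):
            nxt = s[end]
            if kw[-1].isdigit():
                if _is_latin(nxt) or nxt.isdigit():
                    return False
            elif _is_latin(nxt):
                return False
        if len(kw) == 1:  # must immediately head a value
            j = end
            if j < len(s) and s[j] in _SEP_CHARS:
                j += 1
            while j < len(s) and s[j].isspace():
                j += 1
            if j >= len(s) or not s[j].isdigit():
                return False
    return True


def _skip_gap(s: str, kw_end: int, gap: str) -> Optional[int]:
    """Position of the first value digit after the keyword, or None."""
    if gap == "loose":
        for g in range(0, 9):
            j = kw_end + g
            if j >= len(s):
                return None
            if s[j].isdigit():
                return j
            if s[j] in _LOOSE_FORBIDDEN:
                return None
        return None
    j = kw_end
    if j < len(s) and s[j] in _SEP_CHARS:
        j += 1
    while j < len(s) and s[j].isspace():
        j += 1
    if s.startswith("约", j):
        j += 1
    return j if j < len(s) and s[j].isdigit() else None


def _match_unit(s: str, i: int, units: tuple[str, ...]) -> tuple[Optional[str], int]:
    """(unit or None, end of the whole match) starting after the value."""
    j = i
    while j < len(s) and s[j].isspace():
        j += 1
    for u in sorted(set(units), key=len, reverse=True):
        if s.startswith(u, j):
            return (u, j + len(u))
    return (None, j)


def _parse_value(raw: str):
    if raw.isdigit():
        return int(raw)
    try:
        return float(raw)
    except ValueError:
        return raw


def _cycle_number(s: str, i: int, max_digits: int) -> Optional[tuple[int, str]]:
    d = _digits(s, i, 1, max_digits)
    if d is None:
        return None
    end = d[0]
    if end < len(s) and s[end] == "-":
        d2 = _digits(s, end + 1, 1, max_digits)
        if d2 is not None:
            return (d2[0], s[i:d2[0]])
    return (end, s[i:end])


def _cycle_value(raw: str):
    if "-" in raw:
        lo, hi = raw.split("-", 1)
        return (int(lo), int(hi))
    return int(raw)


class Hit:
    __slots__ = ("concept", "value", "unit", "start", "end", "raw", "kw_start", "advance")

    def __init__(self, concept, value, unit, start, end, raw, kw_start, advance):
        self.concept, self.value, self.unit = concept, value, unit
        self.start, self.end, self.raw = start, end, raw
        self.kw_start, self.advance = kw_start, advance


def _scan_quantity(item: str, spec, keywords) -> list[Hit]:
    hits, i = [], 0
    while i < len(item):
        matched = None
        for kw in keywords:
            if item.startswith(kw, i) and _kw_guard_ok(item, i, kw):
                vstart = _skip_gap(item, i + len(kw), spec.gap)
                if vstart is None:
                    continue  # regex alternation would try the next keyword
                if spec.name == C.MENSTRUAL_CYCLE:
                    num = _cycle_number(item, vstart, 3)
                    if num is None:
                        continue
                    vend, raw = num
                    unit, adv = _match_unit(item, vend, spec.units)
                    matched = Hit(spec.name, _cycle_value(raw), unit, vstart, vend, raw, i, adv)
                else:
                    vend = _number_end(item, vstart)
                    raw = item[vstart:vend]
                    unit, adv = _match_unit(item, vend, spec.units)
                    matched = Hit(spec.name, _parse_value(raw), unit, vstart, vend, raw, i, adv)
                break
        if matched is not None:
            hits.append(matched)
            i = max(matched.advance, i + 1)
        else:
            i += 1
    return hits


def _scan_cycle_slash(item: str) -> list[Hit]:
    hits, i = [], 0
    while i < len(item):
        if item[i].isdigit() and (i == 0 or item[i - 1] not in "0123456789./-"):
            men = _cycle_number(item, i, 2)
            if men is not None and men[0] < len(item) and item[men[0]] == "/":
                val = _cycle_number(item, men[0] + 1, 3)
                if val is not None and item.startswith("天", val[0]):
                    vstart, vend = men[0] + 1, val[0]
                    hits.append(Hit(C.MENSTRUAL_CYCLE, _cycle_value(val[1]), "天",
                                    vstart, vend, val[1], i, vend + 1))
                    i = vend + 1
                    continue
        i += 1
    return hits


def _scan_categorical(item: str, spec) -> list[Hit]:
    hits, i = [], 0
    toks = sorted(spec.categories, key=len, reverse=True)
    keywords = sorted(spec.keywords, key=len, reverse=True)
    while i < len(item):
        matched = None
        for kw in keywords:
            if item.startswith(kw, i) and _kw_guard_ok(item, i, kw):
                j = i + len(kw)
                if j < len(item) and item[j] in _SEP_CHARS:
                    j += 1
                while j < len(item) and item[j].isspace():
                    j += 1
                for tok in toks:
                    if item.startswith(tok, j):
                        matched = Hit(spec.name, tok, None, j, j + len(tok), tok, i, j + len(tok))
                        break
                if matched:
                    break
        if matched is not None:
            hits.append(matched)
            i = matched.end
        else:
            i += 1
    return hits


def _plausible(spec, value, unit) -> bool:
    if spec.plausible_range is None:
        return True
    lo, hi = spec.plausible_range
    scale = _AMH_PMOL_SCALE if (spec.name == C.AMH and unit == "pmol/L") else 1.0
    vals = value if isinstance(value, tuple) else (value,)
    return all(lo <= v * scale <= hi for v in vals)


def scan_document(doc: EMRDocument) -> PatientRecord:
    """Full independent parse of one document into a PatientRecord."""
    specs = default_specs()
    sections = split_sections(doc.text)
    record = PatientRecord(doc_id=doc.doc_id, age=doc.age)
    raw_series: dict[str, list[tuple[Optional[Date], Hit]]] = {}

    for spec in specs.values():
        if spec.rule == DATE:
            continue
        keywords = sorted((k for k in spec.keywords if k != "/"), key=len, reverse=True)
        if spec.timed:
            for _, sec_start, sec_text in sections:
                for item, item_start in split_items(sec_text, sec_start):
                    dates = [(e, d) for e, d in scan_dates(item) if d is not None]
                    for hit in _scan_quantity(item, spec, keywords):
                        date = None
                        for end, d in dates:
                            if end <= hit.kw_start:
                                date = d
                            else:
                                break
                        raw_series.setdefault(spec.name, []).append(
                            (date, Hit(spec.name, hit.value, hit.unit,
                                       item_start + hit.start, item_start + hit.end,
                                       hit.raw, hit.kw_start, hit.advance)))
        else:
            found = None
            for _, sec_start, sec_text in sections:
                candidates = []
                if spec.rule == CATEGORICAL:
                    for item, item_start in split_items(sec_text, sec_start):
                        for h in _scan_categorical(item, spec):
                            candidates.append((item_start + h.kw_start, h))
                else:
                    for item, item_start in split_items(sec_text, sec_start):
                        for h in _scan_quantity(item, spec, keywords):
                            candidates.append((item_start + h.kw_start, h))
                        if spec.name == C.MENSTRUAL_CYCLE:
                            for h in _scan_cycle_slash(item):
                                candidates.append((item_start + h.kw_start, h))
                if candidates:
                    candidates.sort(key=lambda t: t[0])
                    found = candidates[0][1]
                    break
            if found is not None and _acceptable(specs[spec.name], found):
                record.singles[spec.name] = found.value

    for concept, entries in raw_series.items():
        spec = specs[concept]
        kept, seen = [], set()
        for date, hit in entries:
            if isinstance(hit.value, str) or hit.raw.count(".") > 1:
                continue
            if isinstance(hit.value, int) and _DATE_RANGE[0] <= hit.value <= _DATE_RANGE[1]:
                continue
            if not _plausible(spec, hit.value, hit.unit):
                continue
            key = (date, hit.value)
            if key in seen:
                continue
            seen.add(key)
            kept.append((date, hit))
        kept.sort(key=lambda t: (t[0] is None, t[0] or Date.min, (t[1].start, t[1].end)))
        if kept:
            record.series[concept] = [
                TimedValue(value=h.value, date=d, unit=h.unit, span=(h.start, h.end))
                for d, h in kept
            ]
    return record


def _acceptable(spec, hit: Hit) -> bool:
    if spec.rule != QUANTITY:
        return True
    if isinstance(hit.value, str) or hit.raw.count(".") > 1:
        return False
    if spec.name != C.MENSTRUAL_CYCLE and isinstance(hit.value, int) \
            and _DATE_RANGE[0] <= hit.value <= _DATE_RANGE[1]:
        return False
    return _plausible(spec, hit.value, hit.unit)
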