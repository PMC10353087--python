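"""Synthetic Chinese reproductive-EMR generator with gold stand-off spans.

Each document is drawn from a latent patient profile (disease state, age,
hormone/ultrasound/menstrual values with measurement dates) and rendered as
a sectioned outpatient note (主诉 / 现病史 / 月经史 / 既往史) with keyworded
lab panels, per-ovary follicle counts and menstrual shorthand.  Every
rendered value carries a gold annotation whose span indexes the final text.

Noise corruptions (typos, duplicated panels, out-of-range values, dates in
value slots) are injected per configurable rates and logged out-of-band in a
sidecar list: gold always describes the intended correct values, so a
perfect extractor + postprocessor reproduces gold exactly.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, replace
from datetime import date as Date, timedelta
from typing import Optional, Sequence

from . import concepts as C
from .concepts import ConceptSpec, UnknownConceptError, default_specs
from .documents import EMRDocument, GoldAnnotation
from .extract import preprocess, segment_items

HEALTHY, DOR, POI, POF = "healthy", "dor", "poi", "pof"
STATES = (HEALTHY, DOR, POI, POF)


class InvalidConfigError(ValueError):
    pass


# conservative clinical defaults; disease bands straddle the diagnostic
# thresholds FSH 10/25/40 IU/L, AMH 1 ng/mL, AFC 5, cycle 24-35 d
_DEFAULT_STATE_MIX = {HEALTHY: 0.55, DOR: 0.2, POI: 0.15, POF: 0.1}

_DEFAULT_MISSING = {
    C.FSH: 0.02, C.LH: 0.05, C.E2: 0.1, C.P: 0.15, C.PRL: 0.15, C.T: 0.15,
    C.AMH: 0.25, C.ENDOMETRIUM: 0.1, C.AFC_LEFT: 0.12, C.AFC_RIGHT: 0.12,
    C.MENARCHE_AGE: 0.1, C.MENSTRUAL_CYCLE: 0.08, C.MENSTRUATION_AMOUNT: 0.2,
    C.UTERINE_POSITION: 0.2,
}

_DEFAULT_NOISE = {"typo": 0.03, "duplicate": 0.04, "out_of_range": 0.03, "date_in_value": 0.03}

# strict-paper mode: only the 年月日 date form; extra dialects are opt-in
_DEFAULT_DIALECTS = {
    "date_iso": 0.0, "date_dot": 0.0,       # 2018-10-03 / 2018.10.3
    "halfwidth_punct": 0.1,                  # , . instead of ，。
    "cycle_keyword_form": 0.3,               # 月经周期30天 instead of 5/30天
    "cycle_range": 0.25,                     # 28-30 style ranges
    "unit_iu_l": 0.35,                       # IU/L instead of mIU/ml for FSH/LH
    "amh_pmol": 0.1,                         # AMH reported in pmol/L
    "amh_chinese_kw": 0.08,                  # 抗苗勒管激素
    "e_single_kw": 0.1,                      # E for E2
    "en_keyword": 0.1,                       # En for 内膜
    "afc_side_ce": 0.3,                      # 左侧卵巢 vs 左卵巢
}

AMH_PMOL_PER_NG = 7.14


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults define the standard study conditions."""

    n_docs: int = 100
    seed: int = 0
    state_mix: dict = field(default_factory=lambda: dict(_DEFAULT_STATE_MIX))
    missing_rates: dict = field(default_factory=lambda: dict(_DEFAULT_MISSING))
    noise_rates: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    dialect_rates: dict = field(default_factory=lambda: dict(_DEFAULT_DIALECTS))

    def __post_init__(self) -> None:
        if self.n_docs <= 0:
            raise InvalidConfigError(f"n_docs must be positive, got {self.n_docs}")
        total = sum(self.state_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"state_mix must sum to 1, got {total}")
        for name, table in (("missing_rates", self.missing_rates),
                            ("noise_rates", self.noise_rates),
                            ("dialect_rates", self.dialect_rates)):
            for k, v in table.items():
                if not 0 <= v <= 1:
                    raise InvalidConfigError(f"{name}[{k}] = {v} outside [0, 1]")

    def noiseless(self) -> "SynthConfig":
        """Copy with all noise and missingness switched off."""
        return replace(
            self,
            missing_rates={k: 0.0 for k in self.missing_rates},
            noise_rates={k: 0.0 for k in self.noise_rates},
        )


@dataclass(frozen=True)
class Panel:
    date: Date
    hormones: dict  # concept -> float


@dataclass(frozen=True)
class UltrasoundExam:
    date: Optional[Date]
    endometrium: Optional[float]
    afc_left: Optional[int]
    afc_right: Optional[int]
    uterine: Optional[str]


@dataclass(frozen=True)
class PatientProfile:
    """Latent truth for one synthetic patient."""

    state: str
    age: float
    menarche: int
    cycle: object  # int or (lo, hi)
    menses_days: int
    amount: str
    uterine: str
    panels: tuple[Panel, ...]
    amh: Optional[float]
    amh_date: Optional[Date]
    ultrasound: tuple[UltrasoundExam, ...]


def _round2(x: float) -> float:
    return round(x, 2)


def _fsh_band(state: str) -> tuple[float, float]:
    return {HEALTHY: (4.0, 9.0), DOR: (10.5, 24.0), POI: (25.5, 39.0), POF: (41.0, 120.0)}[state]


def sample_patient_profile(config: SynthConfig, rng: random.Random) -> PatientProfile:
    """Draw one latent profile consistent with its disease state.

    A healthy profile violates every diagnostic criterion (FSH <= 10 IU/L,
    AMH > 1 ng/mL, total AFC > 5, cycle within 24-35 d); disease profiles
    satisfy their defining FSH band on every dated occasion.
    """
    states = sorted(config.state_mix)
    weights = [config.state_mix[s] for s in states]
    state = rng.choices(states, weights=weights, k=1)[0]

    if state == HEALTHY:
        age = round(rng.uniform(22, 38), 1)
    elif state == DOR:
        age = round(rng.uniform(25, 42), 1)
    else:
        age = round(rng.uniform(22, 39.4), 1)

    menarche = rng.randint(11, 16)
    menses_days = rng.randint(3, 7)
    if state in (HEALTHY, DOR):
        lo = rng.randint(25, 31)
        cycle = (lo, lo + rng.randint(1, 3)) if rng.random() < config.dialect_rates.get("cycle_range", 0) else lo
    else:
        if rng.random() < 0.5:
            lo = rng.randint(37, 90)
        else:
            lo = rng.randint(15, 22)
        cycle = (lo, lo + rng.randint(2, 10)) if (lo > 35 and rng.random() < config.dialect_rates.get("cycle_range", 0)) else lo
    amount = rng.choice(["少", "中", "多"]) if state == HEALTHY else rng.choice(["少", "少", "中"])
    uterine = rng.choice(["前位", "后位", "中位"])

    n_panels = rng.randint(1, 3)
    d = Date(rng.randint(2017, 2021), rng.randint(1, 12), rng.randint(1, 28))
    flo, fhi = _fsh_band(state)
    panels = []
    for _ in range(n_panels):
        hormones = {
            C.FSH: _round2(rng.uniform(flo, fhi)),
            C.LH: _round2(rng.uniform(20, 60) if state == POF else rng.uniform(2, 10)),
            C.E2: _round2(rng.uniform(5, 20) if state in (POI, POF) else rng.uniform(20, 60)),
            C.P: _round2(rng.uniform(0.2, 1.5)),
            C.PRL: _round2(rng.uniform(5, 25)),
            C.T: _round2(rng.uniform(0.1, 0.8)),
        }
        panels.append(Panel(date=d, hormones=hormones))
        d = d + timedelta(days=rng.randint(10, 60))

    amh_bands = {HEALTHY: (1.5, 6.0), DOR: (0.1, 1.0), POI: (0.05, 0.8), POF: (0.01, 0.3)}
    amh = _round2(rng.uniform(*amh_bands[state]))
    amh_date = panels[0].date if rng.random() < 0.7 else None

    if state == HEALTHY:
        endo = round(rng.uniform(6, 12), 1)
        lafc, rafc = rng.randint(4, 9), rng.randint(4, 9)
    else:
        endo = round(rng.uniform(3, 8), 1)
        lafc = rng.randint(0, 3)
        rafc = rng.randint(0, max(0, 5 - lafc))
    us = UltrasoundExam(
        date=panels[0].date + timedelta(days=rng.randint(0, 5)) if rng.random() < 0.8 else None,
        endometrium=endo, afc_left=lafc, afc_right=rafc, uterine=uterine,
    )
    return PatientProfile(
        state=state, age=age, menarche=menarche, cycle=cycle, menses_days=menses_days,
        amount=amount, uterine=uterine, panels=tuple(panels), amh=amh, amh_date=amh_date,
        ultrasound=(us,),
    )


# ---------------------------------------------------------------------------
# rendering


class _Builder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.gold: list[GoldAnnotation] = []

    def add(self, s: str) -> tuple[int, int]:
        start = self.length
        self.parts.append(s)
        self.length += len(s)
        return (start, self.length)

    def add_value(self, surface: str, concept: str, value, date=None, unit=None) -> None:
        span = self.add(surface)
        self.gold.append(GoldAnnotation(concept=concept, span=span, value=value, date=date, unit=unit))

    def text(self) -> str:
        return "".join(self.parts)


def _fmt_date(d: Date, config: SynthConfig, rng: random.Random) -> str:
    r = rng.random()
    iso = config.dialect_rates.get("date_iso", 0.0)
    dot = config.dialect_rates.get("date_dot", 0.0)
    if r < iso:
        return f"{d.year}-{d.month:02d}-{d.day:02d}"
    if r < iso + dot:
        return f"{d.year}.{d.month}.{d.day}"
    return f"{d.year}年{d.month}月{d.day}日"


def _fmt_num(x) -> str:
    if isinstance(x, int):
        return str(x)
    s = f"{x:g}"
    return s


def _cycle_surface(cycle) -> str:
    if isinstance(cycle, tuple):
        return f"{cycle[0]}-{cycle[1]}"
    return str(cycle)


@dataclass
class NoiseEvent:
    doc_id: str
    kind: str
    concept: Optional[str] = None
    detail: Optional[str] = None


def render_document(
    profile: PatientProfile,
    config: SynthConfig,
    rng: random.Random,
    doc_id: str = "synth-0000",
) -> tuple[EMRDocument, list[NoiseEvent]]:
    """Render one profile as a sectioned note with gold spans and a noise log."""
    missing = {k: rng.random() < v for k, v in config.missing_rates.items()}
    dia = config.dialect_rates
    halfwidth = rng.random() < dia.get("halfwidth_punct", 0.0)
    COMMA = "," if halfwidth else "，"
    STOP = "." if halfwidth else "。"
    noise: list[NoiseEvent] = []
    b = _Builder()

    # plan the typo corruption: corrupt the first decimal-valued quantity
    typo_target: Optional[str] = None
    if rng.random() < config.noise_rates.get("typo", 0.0):
        candidates = [c for c in (C.FSH, C.LH, C.E2, C.AMH, C.ENDOMETRIUM) if not missing.get(c)]
        if candidates:
            typo_target = rng.choice(candidates)
    typo_done = False

    b.add("主诉" + "：" + rng.choice(["月经不规律1年", "月经稀发半年", "婚后未避孕未孕2年", "体检发现激素异常"]) + STOP + "\n")

    # -- history of present illness ------------------------------------
    b.add("现病史：")
    b.add(rng.choice(["患者平素月经尚规律", "患者因月经改变就诊", "患者为求进一步诊治来院"]) + STOP)

    fsh_lh_unit = "IU/L" if rng.random() < dia.get("unit_iu_l", 0.0) else "mIU/ml"
    first_panel_snippets: list[tuple[str, str, str, object, Date, str]] = []
    for pi, panel in enumerate(profile.panels):
        rendered = []
        for concept in (C.FSH, C.LH, C.E2, C.P, C.PRL, C.T):
            if missing.get(concept):
                continue
            value = panel.hormones[concept]
            kw = {C.FSH: "FSH", C.LH: "LH", C.E2: "E2", C.P: "P", C.PRL: "PRL", C.T: "T"}[concept]
            if concept == C.E2 and rng.random() < dia.get("e_single_kw", 0.0):
                kw = "E"
            unit = {
                C.FSH: fsh_lh_unit, C.LH: fsh_lh_unit, C.E2: "pg/ml",
                C.P: "ng/ml", C.PRL: "ng/ml", C.T: "ng/ml",
            }[concept]
            rendered.append((concept, kw, unit, value))
        if not rendered:
            continue
        date_str = _fmt_date(panel.date, config, rng)
        b.add(date_str + rng.choice(["查性激素：", "复查：", "查："]) if pi else date_str + "查性激素：")
        for j, (concept, kw, unit, value) in enumerate(rendered):
            if j:
                b.add(COMMA)
            b.add(kw + " ")
            surface = _fmt_num(value)
            if typo_target == concept and not typo_done and "." in surface:
                corrupted = surface.replace(".", "..", 1)
                b.add(corrupted + " " + unit)
                noise.append(NoiseEvent(doc_id, "typo", concept, f"intended {surface}, wrote {corrupted}"))
                typo_done = True
            else:
                b.add_value(surface, concept, value, date=panel.date, unit=unit)
                b.add(" " + unit)
                if pi == 0:
                    first_panel_snippets.append((concept, date_str, kw, unit, value, panel.date, surface))
        b.add(STOP)

    # duplicate corruption: restate one already-reported measurement verbatim
    if first_panel_snippets and rng.random() < config.noise_rates.get("duplicate", 0.0):
        concept, date_str, kw, unit, value, pdate, surface = rng.choice(first_panel_snippets)
        b.add(date_str + "复查" + kw + " " + surface + " " + unit + STOP)
        noise.append(NoiseEvent(doc_id, "duplicate", concept, f"restated {surface} on {pdate.isoformat()}"))

    if profile.amh is not None and not missing.get(C.AMH):
        kw = "抗苗勒管激素" if rng.random() < dia.get("amh_chinese_kw", 0.0) else "AMH"
        if rng.random() < dia.get("amh_pmol", 0.0):
            unit, value = "pmol/L", _round2(profile.amh * AMH_PMOL_PER_NG)
        else:
            unit, value = "ng/ml", profile.amh
        if profile.amh_date is not None:
            b.add(_fmt_date(profile.amh_date, config, rng) + "查")
        b.add(kw + " ")
        b.add_value(_fmt_num(value), C.AMH, value, date=profile.amh_date, unit=unit)
        b.add(" " + unit + STOP)

    for us in profile.ultrasound:
        chunks_present = [
            c for c, v in ((C.ENDOMETRIUM, us.endometrium), (C.AFC_LEFT, us.afc_left),
                           (C.AFC_RIGHT, us.afc_right), (C.UTERINE_POSITION, us.uterine))
            if v is not None and not missing.get(c)
        ]
        if not chunks_present:
            continue
        if us.date is not None:
            b.add(_fmt_date(us.date, config, rng))
        b.add("B超：")
        first = True
        if C.UTERINE_POSITION in chunks_present:
            b.add("子宫")
            b.add_value(us.uterine, C.UTERINE_POSITION, us.uterine)
            first = False
        if C.ENDOMETRIUM in chunks_present:
            if not first:
                b.add(COMMA)
            kw = "En " if rng.random() < dia.get("en_keyword", 0.0) else "内膜"
            b.add(kw)
            b.add_value(_fmt_num(us.endometrium), C.ENDOMETRIUM, us.endometrium, date=us.date, unit="mm")
            b.add("mm")
            first = False
        side_ce = rng.random() < dia.get("afc_side_ce", 0.0)
        for concept, count, zh in ((C.AFC_LEFT, us.afc_left, "左"), (C.AFC_RIGHT, us.afc_right, "右")):
            if concept not in chunks_present:
                continue
            if not first:
                b.add(COMMA)
            b.add(zh + ("侧卵巢" if side_ce else "卵巢") + "卵泡")
            b.add_value(str(count), concept, count, date=us.date, unit="个")
            b.add("个")
            first = False
        b.add(STOP)

    # out-of-range corruption: an implausible undated assay value
    if rng.random() < config.noise_rates.get("out_of_range", 0.0):
        b.add("FSH 5000 IU/L" + STOP)
        noise.append(NoiseEvent(doc_id, "out_of_range", C.FSH, "injected FSH 5000"))
    # date-in-value-slot corruption: a bare year where a measure belongs
    if rng.random() < config.noise_rates.get("date_in_value", 0.0):
        b.add("内膜 2018" + STOP)
        noise.append(NoiseEvent(doc_id, "date_in_value", C.ENDOMETRIUM, "injected 内膜 2018"))
    b.add("\n")

    # -- menstrual history ---------------------------------------------
    b.add("月经史：")
    pieces_added = False
    if not missing.get(C.MENARCHE_AGE):
        b.add("初潮")
        b.add_value(str(profile.menarche), C.MENARCHE_AGE, profile.menarche, unit="岁")
        b.add("岁")
        pieces_added = True
    if not missing.get(C.MENSTRUAL_CYCLE):
        if pieces_added:
            b.add(COMMA)
        surface = _cycle_surface(profile.cycle)
        if rng.random() < dia.get("cycle_keyword_form", 0.0):
            b.add("月经周期")
            b.add_value(surface, C.MENSTRUAL_CYCLE, profile.cycle, unit="天")
            b.add("天")
        else:
            b.add(f"{profile.menses_days}/")
            b.add_value(surface, C.MENSTRUAL_CYCLE, profile.cycle, unit="天")
            b.add("天")
        pieces_added = True
    if not missing.get(C.MENSTRUATION_AMOUNT):
        if pieces_added:
            b.add(COMMA)
        b.add("量")
        b.add_value(profile.amount, C.MENSTRUATION_AMOUNT, profile.amount)
        pieces_added = True
    if not pieces_added:
        b.add("无特殊")
    b.add(STOP + "\n")

    b.add("既往史：无特殊" + STOP + "\n")

    doc = EMRDocument(doc_id=doc_id, text=b.text(), age=profile.age, gold=tuple(b.gold))
    return doc, noise


# ---------------------------------------------------------------------------
# corpus generation and IO


def generate_corpus(
    config: SynthConfig, return_noise_log: bool = False
) -> list[EMRDocument] | tuple[list[EMRDocument], list[NoiseEvent]]:
    """Generate ``config.n_docs`` documents; byte-reproducible under the seed."""
    rng = random.Random(config.seed)
    docs: list[EMRDocument] = []
    log: list[NoiseEvent] = []
    for i in range(config.n_docs):
        profile = sample_patient_profile(config, rng)
        doc, noise = render_document(profile, config, rng, doc_id=f"synth-{config.seed}-{i:04d}")
        docs.append(doc)
        log.extend(noise)
    if return_noise_log:
        return docs, log
    return docs


def generate_profiles(config: SynthConfig) -> list[PatientProfile]:
    """The latent profiles the same seed would render (for truth-recovery tests)."""
    rng = random.Random(config.seed)
    out = []
    for i in range(config.n_docs):
        profile = sample_patient_profile(config, rng)
        render_document(profile, config, rng, doc_id=f"synth-{config.seed}-{i:04d}")
        out.append(profile)
    return out


def write_noise_log(log: Sequence[NoiseEvent], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ev in log:
            fh.write(json.dumps(ev.__dict__, ensure_ascii=False) + "\n")


def read_noise_log(path) -> list[NoiseEvent]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(NoiseEvent(**json.loads(line)))
    return out


# ---------------------------------------------------------------------------
# learning examples for the regex synthesiser


def make_examples(
    corpus: Sequence[EMRDocument],
    concept: str,
    annotate_keywords: bool = True,
    specs: Optional[dict[str, ConceptSpec]] = None,
):
    """Turn gold-annotated documents into (snippet, desired-spans) examples.

    With ``annotate_keywords`` the desired span covers keyword + value + unit
    (e.g. ``FSH 12.53 IU/L``); without it, only the value + unit substring.
    Sentence items carrying any gold mention become snippets; a document
    lacking the concept contributes snippets with empty desired-span lists.
    """
    from .gp import Example  # local import: gp does not import synth

    specs = specs if specs is not None else default_specs()
    try:
        spec = specs[concept]
    except KeyError:
        raise UnknownConceptError(concept) from None

    examples: list[Example] = []
    for doc in corpus:
        if doc.gold is None:
            continue
        sections = sorted(preprocess(doc.text).values(), key=lambda s: s.start)
        for sec in sections:
            for item_text, item_start in segment_items(sec.text, sec.start):
                item_end = item_start + len(item_text)
                anns = [g for g in doc.gold if item_start <= g.span[0] and g.span[1] <= item_end]
                if not anns:
                    continue
                desired = []
                for g in anns:
                    if g.concept != concept:
                        continue
                    rel = (g.span[0] - item_start, g.span[1] - item_start)
                    rel = _extend_unit(item_text, rel, spec)
                    if annotate_keywords:
                        rel = (_find_keyword_start(item_text, rel[0], spec), rel[1])
                    desired.append(rel)
                desired.sort()
                examples.append(Example(snippet=item_text, desired=tuple(desired)))
    return examples


def _extend_unit(item: str, rel: tuple[int, int], spec: ConceptSpec) -> tuple[int, int]:
    import re as _re

    if not spec.units:
        return rel
    tail = item[rel[1]:]
    alts = "|".join(map(_re.escape, sorted(spec.units, key=len, reverse=True)))
    m = _re.match(r"\s?(?:" + alts + ")", tail)
    if m:
        return (rel[0], rel[1] + m.end())
    return rel


def make_cycle_shorthand_task(n_examples: int, seed: int) -> list:
    """A high-variability menstrual-history extraction task.

    Snippets mix four shorthand dialects for the cycle length (``X/C天``,
    ``月经周期C天``, ``平素月经周期约C天`` and ranged ``X-Y/C1-C2天``) with
    distractor numbers (age, menarche); the desired span is the cycle value.
    Small training fractions tend to miss the rarer dialects, which is what
    makes held-out performance grow with the training share.
    """
    from .gp import Example

    rng = random.Random(seed)
    out = []
    for _ in range(n_examples):
        age = rng.randint(21, 39)
        m = rng.randint(11, 16)
        x = rng.randint(3, 7)
        dialect = rng.choices([1, 2, 3, 4], [0.4, 0.3, 0.2, 0.1])[0]
        c = rng.randint(24, 35)
        if dialect == 1:
            pre, val, post = f"{age}岁，初潮{m}岁，{x}/", str(c), "天，量中"
        elif dialect == 2:
            pre, val, post = f"{age}岁，月经周期", str(c), "天，量少"
        elif dialect == 3:
            pre, val, post = f"{age}岁，平素月经周期约", str(c), "天"
        else:
            pre, val, post = f"{age}岁，{x}-{x + 2}/", f"{c}-{c + rng.randint(1, 3)}", "天，量多"
        out.append(Example(pre + val + post, ((len(pre), len(pre) + len(val)),)))
    return out


def make_panel_task(n_examples: int, seed: int, annotate_keywords: bool) -> list:
    """A multi-hormone panel task targeting the FSH level.

    Every snippet reports three assays in an identical numeric format, so the
    keyword is the only reliable cue; with ``annotate_keywords`` the desired
    span is ``FSH <value>``, otherwise the bare value.
    """
    from .gp import Example

    rng = random.Random(seed)
    out = []
    for _ in range(n_examples):
        v1 = f"{rng.uniform(4, 15):.2f}"
        v2 = f"{rng.uniform(2, 12):.2f}"
        v3 = f"{rng.uniform(5, 60):.2f}"
        s = f"2019年3月1日查TSH {v3}，FSH {v1}，LH {v2}"
        i = s.find("FSH ")
        span = (i, i + 4 + len(v1)) if annotate_keywords else (i + 4, i + 4 + len(v1))
        out.append(Example(s, (span,)))
    return out


def _find_keyword_start(item: str, value_start: int, spec: ConceptSpec) -> int:
    head = item[:value_start]
    best = value_start
    for kw in sorted((k for k in spec.keywords if k != "/"), key=len, reverse=True):
        idx = head.rfind(kw)
        if idx < 0:
            continue
        gap = head[idx + len(kw):]
        if len(gap) <= 8 and not any(ch.isdigit() for ch in gap):
            best = min(best, idx) if best != value_start else idx
            break
    return best
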