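"""Tree-based genetic programming that learns extraction regexes from examples.

An individual is a regular expression encoded as an ordered syntax tree over
a small construct set (character classes, literals, possessive quantifiers,
concatenation, disjunction) plus "building blocks" — character sequences
occurring in more than ~90% of the desired extractions (e.g. ``FSH``).  The
initial population is partly random (ramped half-and-half) and partly seeded:
for every example four regexes are built that extract exactly its desired
portions.  Evolution is elitist and generational: each step creates as many
new individuals as the population holds — 10% random, 10% by subtree
mutation, 80% by subtree crossover, parents chosen by size-7 tournaments —
then keeps the best half of the combined pool.  Fitness is bi-objective,
compared lexicographically: character-level extraction F-score (maximised)
first, then serialised regex length (minimised).

A separate-and-conquer wrapper joins '|' branches: a branch is retained only
when it reaches perfect precision on the residual examples, which are then
reduced to the examples it does not yet solve.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# examples


@dataclass(frozen=True)
class Example:
    """One learning snippet with its desired extraction spans."""

    snippet: str
    desired: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        last = 0
        for s, e in sorted(self.desired):
            if not (0 <= s < e <= len(self.snippet)):
                raise ValueError(f"span ({s}, {e}) outside snippet of length {len(self.snippet)}")
            if s < last:
                raise ValueError("desired spans must not overlap")
            last = e

    def desired_texts(self) -> list[str]:
        return [self.snippet[s:e] for s, e in self.desired]


# ---------------------------------------------------------------------------
# regex syntax trees


class Node:
    children: tuple["Node", ...] = ()

    def to_regex(self) -> str:  # pragma: no cover - abstract
        raise NotImplementedError

    def with_children(self, children: tuple["Node", ...]) -> "Node":
        raise NotImplementedError


@dataclass(frozen=True)
class Tok(Node):
    """A predefined construct: \\d, \\w, [a-z], [A-Z], [0-9]."""

    label: str

    def to_regex(self) -> str:
        return self.label

    def with_children(self, children):
        return self


_META_CHARS = set(".^$*+?{}[]()|\\")


def _escape_literal(s: str) -> str:
    """Escape regex metacharacters only (spaces and CJK stay verbatim)."""
    return "".join("\\" + ch if ch in _META_CHARS else ch for ch in s)


@dataclass(frozen=True)
class Lit(Node):
    """A literal string: one observed character or a mined building block."""

    text: str

    def to_regex(self) -> str:
        return _escape_literal(self.text)

    def with_children(self, children):
        return self


@dataclass(frozen=True)
class NeverMatch(Node):
    """Matches nothing anywhere; the seed for an empty-extraction example."""

    def to_regex(self) -> str:
        return r"(?!x)x"

    def with_children(self, children):
        return self


def _group(rx: str) -> str:
    if len(rx) == 1 or re.fullmatch(r"\\.|\[[^\]]*\]", rx):
        return rx
    return f"(?:{rx})"


@dataclass(frozen=True)
class Rep(Node):
    """Possessive quantifier over a subtree: ``++``, ``*+`` or ``?+``."""

    child: Node
    quant: str  # "++" | "*+" | "?+"

    @property
    def children(self):
        return (self.child,)

    def to_regex(self) -> str:
        return _group(self.child.to_regex()) + self.quant

    def with_children(self, children):
        return Rep(children[0], self.quant)


@dataclass(frozen=True)
class Cat(Node):
    """Concatenation of subtrees."""

    parts: tuple[Node, ...]

    @property
    def children(self):
        return self.parts

    def to_regex(self) -> str:
        return "".join(
            _group(c.to_regex()) if isinstance(c, Alt) else c.to_regex() for c in self.parts
        )

    def with_children(self, children):
        return Cat(tuple(children))


@dataclass(frozen=True)
class Alt(Node):
    """Disjunction of subtrees."""

    parts: tuple[Node, ...]

    @property
    def children(self):
        return self.parts

    def to_regex(self) -> str:
        return "(?:" + "|".join(c.to_regex() for c in self.parts) + ")"

    def with_children(self, children):
        return Alt(tuple(children))


@dataclass(frozen=True)
class Look(Node):
    """Fixed-width lookbehind context anchoring a subtree."""

    context: str
    child: Node

    @property
    def children(self):
        return (self.child,)

    def to_regex(self) -> str:
        return f"(?<={_escape_literal(self.context)})" + self.child.to_regex()

    def with_children(self, children):
        return Look(self.context, children[0])


TOKENS = (r"\d", r"\w", "[a-z]", "[A-Z]", "[0-9]")
QUANTS = ("++", "*+", "?+")


def iter_paths(tree: Node, path: tuple[int, ...] = ()) -> list[tuple[tuple[int, ...], Node]]:
    out = [(path, tree)]
    for i, child in enumerate(tree.children):
        out.extend(iter_paths(child, path + (i,)))
    return out


def subtree_at(tree: Node, path: tuple[int, ...]) -> Node:
    for i in path:
        tree = tree.children[i]
    return tree


def replace_at(tree: Node, path: tuple[int, ...], sub: Node) -> Node:
    if not path:
        return sub
    i = path[0]
    children = list(tree.children)
    children[i] = replace_at(children[i], path[1:], sub)
    return tree.with_children(tuple(children))


def tree_depth(tree: Node) -> int:
    if not tree.children:
        return 1
    return 1 + max(tree_depth(c) for c in tree.children)


# ---------------------------------------------------------------------------
# building blocks


def mine_building_blocks(examples: Sequence[Example], threshold: float = 0.9,
                         max_len: int = 10) -> list[str]:
    """Maximal substrings occurring in more than *threshold* of the desired
    extractions, sorted longest first."""
    if not examples:
        raise ValueError("cannot mine building blocks from an empty example set")
    texts = [t for ex in examples for t in ex.desired_texts()]
    if not texts:
        return []
    candidates: set[str] = set()
    for t in texts:
        for i in range(len(t)):
            for j in range(i + 1, min(len(t), i + max_len) + 1):
                candidates.add(t[i:j])
    n = len(texts)
    frequent = [s for s in candidates if sum(1 for t in texts if s in t) > threshold * n]
    frequent.sort(key=lambda s: (-len(s), s))
    maximal: list[str] = []
    for s in frequent:
        if not any(s in m for m in maximal):
            maximal.append(s)
    return maximal


# ---------------------------------------------------------------------------
# fitness


@dataclass(frozen=True)
class Individual:
    tree: Node
    performance: float
    length: int

    @property
    def fitness(self) -> tuple[float, int]:
        return (self.performance, self.length)

    def sort_key(self):
        return (-self.performance, self.length, self.tree.to_regex())


def _match_spans(pattern: re.Pattern, text: str) -> list[tuple[int, int]]:
    return [m.span() for m in pattern.finditer(text) if m.start() < m.end()]


def _char_counts(pattern: re.Pattern, examples: Sequence[Example]) -> tuple[int, int, int]:
    tp = fp = fn = 0
    for ex in examples:
        desired: set[int] = set()
        for s, e in ex.desired:
            desired.update(range(s, e))
        predicted: set[int] = set()
        for s, e in _match_spans(pattern, ex.snippet):
            predicted.update(range(s, e))
        tp += len(predicted & desired)
        fp += len(predicted - desired)
        fn += len(desired - predicted)
    return tp, fp, fn


def char_fscore(pattern: re.Pattern, examples: Sequence[Example]) -> float:
    """Character-level F over all examples; 1.0 when there is nothing to
    find and nothing is found (true-negative convention)."""
    tp, fp, fn = _char_counts(pattern, examples)
    if tp + fp + fn == 0:
        return 1.0
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def char_precision_recall(pattern: re.Pattern, examples: Sequence[Example]) -> tuple[float, float]:
    tp, fp, fn = _char_counts(pattern, examples)
    p = tp / (tp + fp) if tp + fp else 1.0
    r = tp / (tp + fn) if tp + fn else 1.0
    return p, r


def fitness(tree: Node, examples: Sequence[Example],
            max_regex_length: int = 300) -> tuple[float, int]:
    """(performance to maximise, regex length to minimise).

    Uncompilable or over-budget patterns get performance 0.
    """
    rx = tree.to_regex()
    length = len(rx)
    if length > max_regex_length:
        return (0.0, length)
    try:
        pattern = re.compile(rx)
    except re.error:
        return (0.0, length)
    return (char_fscore(pattern, examples), length)


# ---------------------------------------------------------------------------
# seeding


def _classify_char(ch: str) -> Node:
    if ch.isdigit():
        return Tok(r"\d")
    if ch.isascii() and ch.isalpha():
        return Tok(r"\w")
    return Lit(ch)


def _compress(parts: Sequence[Node]) -> list[Node]:
    out: list[Node] = []
    for p in parts:
        if out and isinstance(p, Tok) and out[-1] == p:
            continue_run = True
        elif out and isinstance(out[-1], Rep) and out[-1].child == p:
            continue_run = True
        else:
            continue_run = False
        if continue_run:
            if isinstance(out[-1], Tok):
                out[-1] = Rep(out[-1], "++")
        else:
            out.append(p)
    return out


def _cat(parts: Sequence[Node]) -> Node:
    parts = list(parts)
    return parts[0] if len(parts) == 1 else Cat(tuple(parts))


def _span_variants(text: str, blocks: Sequence[str]) -> list[Node]:
    literal = Lit(text)
    classified = _cat([_classify_char(ch) for ch in text])
    compressed = _cat(_compress([_classify_char(ch) for ch in text]))
    with_blocks = _cat(_compress(_block_split(text, blocks)))
    return [literal, classified, compressed, with_blocks]


def _block_split(text: str, blocks: Sequence[str]) -> list[Node]:
    for b in blocks:
        idx = text.find(b)
        if idx >= 0 and len(b) > 1:
            return (
                _block_split(text[:idx], blocks) + [Lit(b)] + _block_split(text[idx + len(b):], blocks)
            )
    return [_classify_char(ch) for ch in text]


def _exact_on_example(tree: Node, ex: Example) -> bool:
    try:
        pattern = re.compile(tree.to_regex())
    except re.error:
        return False
    return _match_spans(pattern, ex.snippet) == sorted(ex.desired)


def _anchor(tree: Node, ex: Example, span: tuple[int, int]) -> Node:
    """Add the shortest lookbehind context that makes the seed exact."""
    start = span[0]
    for width in range(1, min(10, start) + 1):
        anchored = Look(ex.snippet[start - width:start], tree)
        if _exact_on_example(anchored, ex):
            return anchored
    return Look(ex.snippet[:start], Lit(ex.snippet[span[0]:span[1]]))


def seed_individuals(example: Example, blocks: Sequence[str] = ()) -> list[Node]:
    """Four seed trees that extract exactly the example's desired portions."""
    if not example.desired:
        return [NeverMatch()] * 4
    texts = example.desired_texts()
    seeds: list[Node] = []
    for variant in range(4):
        distinct: list[str] = []
        for t in texts:
            if t not in distinct:
                distinct.append(t)
        parts = [_span_variants(t, blocks)[variant] for t in distinct]
        tree = parts[0] if len(parts) == 1 else Alt(tuple(parts))
        if not _exact_on_example(tree, example):
            if len(example.desired) == 1:
                tree = _anchor(tree, example, example.desired[0])
            else:
                anchored = [
                    _anchor(_span_variants(example.snippet[s:e], blocks)[variant], example, (s, e))
                    if not _exact_on_example(_span_variants(example.snippet[s:e], blocks)[variant], example)
                    else _span_variants(example.snippet[s:e], blocks)[variant]
                    for s, e in example.desired
                ]
                tree = Alt(tuple(anchored)) if len(anchored) > 1 else anchored[0]
        if not _exact_on_example(tree, example):
            # last resort: anchor every span by its full prefix
            tree = Alt(tuple(
                Look(example.snippet[:s], Lit(example.snippet[s:e])) for s, e in example.desired
            )) if len(example.desired) > 1 else Look(
                example.snippet[:example.desired[0][0]],
                Lit(example.snippet[example.desired[0][0]:example.desired[0][1]]),
            )
        seeds.append(tree)
    return seeds


# ---------------------------------------------------------------------------
# random trees and variation operators


def _random_terminal(rng: random.Random, alphabet: Sequence[str], blocks: Sequence[str]) -> Node:
    r = rng.random()
    if r < 0.4:
        return Tok(rng.choice(TOKENS))
    if r < 0.55 and blocks:
        return Lit(rng.choice(list(blocks)))
    return Lit(rng.choice(list(alphabet)) if alphabet else "x")


def random_tree(rng: random.Random, alphabet: Sequence[str], blocks: Sequence[str],
                max_depth: int = 4, full: Optional[bool] = None) -> Node:
    """Ramped half-and-half generation over the construct set."""
    if full is None:
        full = rng.random() < 0.5
    depth = rng.randint(2, max_depth)
    return _grow(rng, alphabet, blocks, depth, full)


def _grow(rng, alphabet, blocks, depth, full) -> Node:
    if depth <= 1 or (not full and rng.random() < 0.3):
        return _random_terminal(rng, alphabet, blocks)
    r = rng.random()
    if r < 0.55:
        n = rng.randint(2, 3)
        return Cat(tuple(_grow(rng, alphabet, blocks, depth - 1, full) for _ in range(n)))
    if r < 0.85:
        child = _grow(rng, alphabet, blocks, depth - 1, full)
        if isinstance(child, Rep):  # avoid stacked quantifiers
            child = child.child
        return Rep(child, rng.choice(QUANTS))
    return Alt(tuple(_grow(rng, alphabet, blocks, depth - 1, full) for _ in range(2)))


def mutate(tree: Node, rng: random.Random, alphabet, blocks, max_depth: int = 4) -> Node:
    paths = iter_paths(tree)
    path, _ = paths[rng.randrange(len(paths))]
    return replace_at(tree, path, random_tree(rng, alphabet, blocks, max_depth))


def crossover(a: Node, b: Node, rng: random.Random) -> Node:
    paths_a = iter_paths(a)
    paths_b = iter_paths(b)
    path_a, _ = paths_a[rng.randrange(len(paths_a))]
    _, sub_b = paths_b[rng.randrange(len(paths_b))]
    return replace_at(a, path_a, sub_b)


# ---------------------------------------------------------------------------
# evolution


@dataclass(frozen=True)
class GPConfig:
    """Evolution settings (population sizes, termination, operator mix)."""

    population_size: int = 100
    n_generations: int = 60
    n_stop: int = 10
    tournament_size: int = 7
    p_random: float = 0.10
    p_mutation: float = 0.10
    p_crossover: float = 0.80
    building_block_threshold: float = 0.90
    max_random_depth: int = 4
    max_regex_length: int = 300
    branch_cap: int = 4
    max_examples: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.population_size, self.tournament_size) <= 0:
            raise ValueError("population and tournament sizes must be positive")
        if self.n_generations < 0 or self.n_stop <= 0:
            raise ValueError("generation counts must be positive")
        mix = self.p_random + self.p_mutation + self.p_crossover
        if abs(mix - 1.0) > 1e-9:
            raise ValueError(f"operator mix must sum to 1, got {mix}")


@dataclass
class EvolutionResult:
    regex: str
    performance: float
    length: int
    trace: list[tuple[int, float, int]] = field(default_factory=list)  # (gen, best perf, best length)
    population: list[str] = field(default_factory=list)  # final population, best first
    branch_log: list[dict] = field(default_factory=list)  # per accepted '|' branch


def _evaluate(tree: Node, examples, config, cache: dict) -> Individual:
    rx = tree.to_regex()
    if rx not in cache:
        cache[rx] = fitness(tree, examples, config.max_regex_length)
    perf, length = cache[rx]
    return Individual(tree, perf, length)


def _tournament(pop: list[Individual], rng: random.Random, k: int) -> Individual:
    contenders = [pop[rng.randrange(len(pop))] for _ in range(min(k, len(pop)))]
    return min(contenders, key=Individual.sort_key)


def evolve(examples: Sequence[Example], config: GPConfig = GPConfig(),
           rng: Optional[random.Random] = None,
           blocks: Optional[Sequence[str]] = None) -> EvolutionResult:
    """Elitist generational GP loop; returns the best regex and its trace."""
    if not examples:
        raise ValueError("evolve requires a non-empty example set")
    if rng is None:
        rng = random.Random(config.seed)
    if blocks is None:
        blocks = mine_building_blocks(examples, config.building_block_threshold)
    alphabet = sorted({ch for ex in examples for ch in ex.snippet})

    cache: dict[str, tuple[float, int]] = {}
    seen: set[str] = set()
    population: list[Individual] = []
    example_order = list(examples)
    if len(example_order) * 4 > config.population_size:
        example_order = rng.sample(example_order, max(1, config.population_size // 4))
    for ex in example_order:
        for tree in seed_individuals(ex, blocks):
            rx = tree.to_regex()
            if rx not in seen:
                seen.add(rx)
                population.append(_evaluate(tree, examples, config, cache))
    while len(population) < config.population_size:
        tree = random_tree(rng, alphabet, blocks, config.max_random_depth)
        population.append(_evaluate(tree, examples, config, cache))
    population.sort(key=Individual.sort_key)
    population = population[: config.population_size]

    if all(ind.performance == 0.0 for ind in population):
        logger.warning("all initial individuals have zero performance; returning best seed")

    best = population[0]
    trace = [(0, best.performance, best.length)]
    stall = 0
    n_p = len(population)
    n_rand = max(1, round(config.p_random * n_p))
    n_mut = max(1, round(config.p_mutation * n_p))
    for gen in range(1, config.n_generations + 1):
        offspring: list[Individual] = []
        for _ in range(n_rand):
            offspring.append(_evaluate(
                random_tree(rng, alphabet, blocks, config.max_random_depth),
                examples, config, cache))
        for _ in range(n_mut):
            parent = _tournament(population, rng, config.tournament_size)
            offspring.append(_evaluate(
                mutate(parent.tree, rng, alphabet, blocks, config.max_random_depth),
                examples, config, cache))
        while len(offspring) < n_p:
            pa = _tournament(population, rng, config.tournament_size)
            pb = _tournament(population, rng, config.tournament_size)
            offspring.append(_evaluate(crossover(pa.tree, pb.tree, rng), examples, config, cache))
        merged = population + offspring
        merged.sort(key=Individual.sort_key)
        # survivors are the best *distinct* expressions: truncation over the
        # merged pool with duplicates removed, so seeds stay in the gene pool
        unique: list[Individual] = []
        seen_rx: set[str] = set()
        for ind in merged:
            rx = ind.tree.to_regex()
            if rx not in seen_rx:
                seen_rx.add(rx)
                unique.append(ind)
        population = (unique + [ind for ind in merged if len(unique) < n_p])[:n_p] \
            if len(unique) < n_p else unique[:n_p]
        new_best = population[0]
        if new_best.fitness == best.fitness:
            stall += 1
        else:
            stall = 0
        best = new_best
        trace.append((gen, best.performance, best.length))
        if stall >= config.n_stop:
            break
    return EvolutionResult(best.tree.to_regex(), best.performance, best.length, trace,
                           [ind.tree.to_regex() for ind in population])


# ---------------------------------------------------------------------------
# separate and conquer


def _solved(pattern: re.Pattern, ex: Example) -> bool:
    return bool(ex.desired) and _match_spans(pattern, ex.snippet) == sorted(ex.desired)


def _best_precise(candidates: Sequence[str], residual: Sequence[Example]):
    """The perfectly precise candidate with the highest recall (then shortest)."""
    best: Optional[tuple[float, int, str, re.Pattern]] = None
    for rx in candidates:
        try:
            pattern = re.compile(rx)
        except re.error:
            continue
        precision, recall = char_precision_recall(pattern, residual)
        if precision < 1.0 or recall <= 0.0:
            continue
        key = (-recall, len(rx), rx)
        if best is None or key < (-best[0], best[1], best[2]):
            best = (recall, len(rx), rx, pattern)
    return best


def separate_and_conquer(examples: Sequence[Example], config: GPConfig = GPConfig(),
                         rng: Optional[random.Random] = None) -> EvolutionResult:
    """Iteratively evolve '|' branches, each retained only at perfect
    precision on its residual example set.

    The branch taken from each evolution is the most-recalling individual of
    the final population that is perfectly precise on the residual; when no
    such individual exists the loop stops (the plain best-by-F regex is
    returned if no branch was ever retained).
    """
    if rng is None:
        rng = random.Random(config.seed)
    residual = list(examples)
    branches: list[str] = []
    branch_log: list[dict] = []
    traces: list[tuple[int, float, int]] = []
    last: Optional[EvolutionResult] = None
    for _ in range(config.branch_cap):
        res = evolve(residual, config, rng)
        last = res
        traces.extend(res.trace)
        # candidate branches: the final population plus the residual's own
        # seed individuals (members of the initial population that aggregate
        # F-ranking may have displaced, but that stay precise by design)
        blocks = mine_building_blocks(residual, config.building_block_threshold)
        seed_rx = [t.to_regex() for ex in residual for t in seed_individuals(ex, blocks)]
        chosen = _best_precise([res.regex] + res.population + seed_rx, residual)
        if chosen is None:
            break
        recall, _, regex, pattern = chosen
        branches.append(regex)
        branch_log.append({"regex": regex, "n_residual": len(residual),
                           "precision": 1.0, "recall": recall,
                           "residual": tuple(residual)})
        if recall >= 1.0:
            break
        remaining = [ex for ex in residual if not _solved(pattern, ex)]
        if len(remaining) == len(residual):
            break  # no progress; avoid looping on the same residual
        residual = remaining
    if not branches:
        return last if last is not None else EvolutionResult("(?!x)x", 0.0, 6, [])
    joined = "|".join(branches)
    pattern = re.compile(joined)
    perf = char_fscore(pattern, list(examples))
    return EvolutionResult(joined, perf, len(joined), traces, branch_log=branch_log)


def heldout_fscore(examples: Sequence[Example], training_fraction: float,
                   config: GPConfig = GPConfig(), seed: int = 0) -> tuple[float, str]:
    """Train on a shuffled fraction of *examples*, score char-F on the rest."""
    if not 0 < training_fraction < 1:
        raise ValueError("training_fraction must be in (0, 1) for a held-out split")
    rng = random.Random(seed)
    pool = list(examples)
    rng.shuffle(pool)
    k = max(1, round(training_fraction * len(pool)))
    train, test = pool[:k], pool[k:]
    result = separate_and_conquer(train, config, rng)
    return char_fscore(re.compile(result.regex), test), result.regex


# ---------------------------------------------------------------------------
# experiments: training-set size and annotation portion


def run_experiment(corpus, concept: str, training_fraction: float,
                   annotate_keywords: bool, config: GPConfig = GPConfig()) -> dict:
    """Train a machine regex on a corpus fraction and score it on the rest.

    The deterministic split, example capping and evolution all derive from
    ``config.seed``.  Metrics are span-level precision/recall/F on held-out
    snippets, under the same annotation convention used for training.
    """
    from .evaluate import ConfusionCounts, metrics as _metrics
    from .synth import make_examples

    if training_fraction <= 0 or training_fraction > 1:
        raise ValueError(f"training_fraction must be in (0, 1], got {training_fraction}")
    rng = random.Random(config.seed)
    docs = list(corpus)
    rng.shuffle(docs)
    n_train = max(1, round(training_fraction * len(docs)))
    if training_fraction == 1.0:
        logger.warning("training_fraction=1: evaluating on the training documents")
        train_docs, test_docs = docs, docs
    else:
        train_docs, test_docs = docs[:n_train], docs[n_train:]

    train_examples = make_examples(train_docs, concept, annotate_keywords)
    if len(train_examples) > config.max_examples:
        train_examples = rng.sample(train_examples, config.max_examples)
    result = separate_and_conquer(train_examples, config, rng)
    pattern = re.compile(result.regex)

    test_examples = make_examples(test_docs, concept, annotate_keywords)
    counts = ConfusionCounts()
    for ex in test_examples:
        pred = set(_match_spans(pattern, ex.snippet))
        ref = set(ex.desired)
        tp, fp, fn = len(pred & ref), len(pred - ref), len(ref - pred)
        if tp == fp == fn == 0:
            counts = counts + ConfusionCounts(tn=1)
        else:
            counts = counts + ConfusionCounts(tp=tp, fp=fp, fn=fn)
    m = _metrics(counts)
    return {
        "concept": concept,
        "training_fraction": training_fraction,
        "annotate_keywords": annotate_keywords,
        "regex": result.regex,
        "precision": m.precision,
        "recall": m.recall,
        "fscore": m.fscore,
        "n_train_examples": len(train_examples),
        "n_test_examples": len(test_examples),
    }
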