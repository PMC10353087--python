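"""GP regex synthesis: trees, building blocks, seeding, evolution."""

import random
import re

import pytest

from reprotext.gp import (
    Cat,
    Example,
    GPConfig,
    Lit,
    Rep,
    Tok,
    char_fscore,
    crossover,
    evolve,
    fitness,
    heldout_fscore,
    mine_building_blocks,
    mutate,
    random_tree,
    run_experiment,
    seed_individuals,
    separate_and_conquer,
    tree_depth,
)


class TestExampleValidation:
    def test_spans_must_lie_inside_snippet(self):
        with pytest.raises(ValueError):
            Example("abc", ((0, 9),))

    def test_spans_must_not_overlap(self):
        with pytest.raises(ValueError):
            Example("abcdef", ((0, 3), (2, 5)))


class TestTrees:
    def test_postorder_serialisation_of_known_tree(self):
        tree = Cat((Lit("FSH "), Rep(Tok(r"\d"), "++"), Lit("."),
                    Rep(Tok(r"\d"), "++")))
        assert tree.to_regex() == r"FSH \d++\.\d++"
        assert len(tree.to_regex()) == 14

    def test_serialised_trees_compile(self):
        rng = random.Random(0)
        for _ in range(300):
            tree = random_tree(rng, alphabet="abc，。123", blocks=["FSH"])
            re.compile(tree.to_regex())

    def test_variation_operators_preserve_compilability(self):
        rng = random.Random(1)
        a = random_tree(rng, "ab1", [])
        b = random_tree(rng, "ab1", [])
        for _ in range(100):
            a = mutate(a, rng, "ab1", [])
            child = crossover(a, b, rng)
            re.compile(child.to_regex())
        assert tree_depth(a) >= 1


class TestBuildingBlocks:
    def test_common_keyword_is_mined(self):
        examples = [Example(f"FSH {v} IU/L", ((0, 8),)) for v in ("5.32", "6.10", "9.87")]
        blocks = mine_building_blocks(examples, 0.9)
        assert any("FSH" in b for b in blocks)

    def test_all_distinct_extractions_yield_nothing(self):
        examples = [Example("abc", ((0, 1),)), Example("def", ((0, 1),)),
                    Example("ghi", ((0, 1),))]
        assert mine_building_blocks(examples, 0.9) == []

    def test_threshold_zero_supersets_shared_characters(self):
        # brute-force oracle: characters present in every desired extraction
        examples = [Example("FSH 5.3", ((0, 7),)), Example("FSH 6.9", ((0, 7),))]
        texts = [t for ex in examples for t in ex.desired_texts()]
        shared = {ch for ch in texts[0] if all(ch in t for t in texts)}
        blocks = mine_building_blocks(examples, 0.0)
        assert all(any(ch in b for b in blocks) for ch in shared)

    def test_blocks_are_maximal_and_longest_first(self):
        examples = [Example(f"FSH {v}", ((0, 3),)) for v in "123"]
        blocks = mine_building_blocks(examples, 0.9)
        assert blocks == sorted(blocks, key=lambda s: (-len(s), s))
        for i, b in enumerate(blocks):
            assert not any(b in other for other in blocks[:i] + blocks[i + 1:])

    def test_empty_example_set_is_an_error(self):
        with pytest.raises(ValueError):
            mine_building_blocks([], 0.9)


class TestSeeding:
    def test_seeds_extract_exactly_the_desired_portions(self):
        ex = Example("FSH 5.32 mIU/ml", ((4, 8),))
        for tree in seed_individuals(ex):
            pattern = re.compile(tree.to_regex())
            assert [m.span() for m in pattern.finditer(ex.snippet)] == [(4, 8)]

    def test_numeric_span_produces_generalised_seed(self):
        ex = Example("FSH 5.32 mIU/ml", ((4, 8),))
        serialisations = [t.to_regex() for t in seed_individuals(ex)]
        assert any(r"\d" in s and "+" in s for s in serialisations)

    def test_empty_span_example_seeds_match_nothing(self):
        ex = Example("FSH 5.32 mIU/ml", ())
        for tree in seed_individuals(ex):
            assert re.compile(tree.to_regex()).search(ex.snippet) is None

    def test_ambiguous_value_seed_gets_anchored(self):
        # the bare value pattern would also match the LH level
        ex = Example("FSH 5.32，LH 3.10", ((4, 8),))
        for tree in seed_individuals(ex):
            pattern = re.compile(tree.to_regex())
            assert [m.span() for m in pattern.finditer(ex.snippet)] == [(4, 8)]


class TestFitness:
    def test_perfect_match_scores_one(self):
        examples = [Example("FSH 5.32", ((4, 8),))]
        assert fitness(Lit("5.32"), examples)[0] == 1.0

    def test_true_negative_convention(self):
        examples = [Example("no values here", ())]
        perf, _ = fitness(Lit("zzz"), examples)
        assert perf == 1.0
        # and adding empty examples never lowers a perfect score
        full = [Example("FSH 5.32", ((4, 8),)), Example("nothing", ())]
        assert fitness(Lit("5.32"), full)[0] == 1.0

    def test_uncompilable_tree_scores_zero(self):
        perf, length = fitness(Lit("x").with_children(()), [Example("x", ((0, 1),))],
                               max_regex_length=0)
        assert perf == 0.0 and length >= 1

    def test_length_is_serialisation_character_count(self):
        tree = Cat((Lit("FSH "), Rep(Tok(r"\d"), "++"), Lit("."), Rep(Tok(r"\d"), "++")))
        assert fitness(tree, [Example("FSH 12", ((0, 6),))])[1] == 14


class TestEvolve:
    def _examples(self, n=20, seed=0):
        rng = random.Random(seed)
        out = []
        for _ in range(n):
            v = f"{rng.uniform(3, 20):.2f}"
            s = f"FSH {v} IU/L"
            out.append(Example(s, ((4, 4 + len(v)),)))
        return out

    def test_single_pattern_family_reaches_perfect_heldout(self):
        train = self._examples(20, seed=0)
        held = self._examples(10, seed=99)
        cfg = GPConfig(population_size=50, n_generations=15, n_stop=5, seed=1)
        res = evolve(train, cfg)
        assert res.performance == 1.0
        assert char_fscore(re.compile(res.regex), held) == 1.0

    def test_zero_generations_returns_best_of_initial_population(self):
        cfg = GPConfig(population_size=30, n_generations=0, seed=2)
        res = evolve(self._examples(5), cfg)
        assert len(res.trace) == 1 and res.performance == 1.0  # a seed is perfect

    def test_identical_seeds_give_identical_traces(self):
        cfg = GPConfig(population_size=40, n_generations=10, n_stop=4, seed=5)
        a = evolve(self._examples(10), cfg)
        b = evolve(self._examples(10), cfg)
        assert a.trace == b.trace and a.regex == b.regex

    def test_elitist_best_fitness_is_monotone_along_trace(self):
        cfg = GPConfig(population_size=40, n_generations=12, n_stop=12, seed=3)
        res = evolve(self._examples(15), cfg)
        for (g1, p1, l1), (g2, p2, l2) in zip(res.trace, res.trace[1:]):
            assert p2 >= p1
            if p2 == p1:
                assert l2 <= l1

    def test_empty_example_set_is_an_error(self):
        with pytest.raises(ValueError):
            evolve([], GPConfig())

    def test_operator_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GPConfig(p_random=0.5, p_mutation=0.5, p_crossover=0.5)


class TestSeparateAndConquer:
    def _bimodal(self, n=16):
        rng = random.Random(7)
        out = []
        for i in range(n):
            v = f"{rng.uniform(3, 20):.2f}"
            if i % 2:
                s = f"FSH：{v}，正常"
            else:
                s = f"FSH {v}，正常"
            start = s.find(v)
            out.append(Example(s, ((start, start + len(v)),)))
        return out

    def test_mixed_dialects_get_or_branches_with_full_training_recall(self):
        cfg = GPConfig(population_size=50, n_generations=12, n_stop=5, seed=4)
        res = separate_and_conquer(self._bimodal(), cfg)
        assert res.performance == 1.0
        assert res.branch_log, "at least one branch should be retained"

    def test_retained_branches_are_perfectly_precise_on_their_residual(self):
        cfg = GPConfig(population_size=50, n_generations=12, n_stop=5, seed=4)
        res = separate_and_conquer(self._bimodal(), cfg)
        for entry in res.branch_log:
            pattern = re.compile(entry["regex"])
            from reprotext.gp import char_precision_recall

            precision, recall = char_precision_recall(pattern, entry["residual"])
            assert precision == 1.0 and recall == pytest.approx(entry["recall"])

    def test_single_pattern_set_needs_no_disjunction(self):
        rng = random.Random(1)
        examples = [Example(f"FSH {v:.2f}", ((4, 8),)) for v in
                    (rng.uniform(3, 9.9) for _ in range(10))]
        cfg = GPConfig(population_size=40, n_generations=10, n_stop=4, seed=6)
        res = separate_and_conquer(examples, cfg)
        assert len(res.branch_log) == 1

    def test_branch_cap_one_returns_a_single_branch(self):
        cfg = GPConfig(population_size=50, n_generations=12, n_stop=5, branch_cap=1, seed=4)
        res = separate_and_conquer(self._bimodal(), cfg)
        assert len(res.branch_log) <= 1


class TestExperiments:
    def test_invalid_fraction_is_rejected(self, clean_corpus):
        docs, _ = clean_corpus
        with pytest.raises(ValueError):
            run_experiment(docs[:10], "fsh", 0.0, True, GPConfig())

    def test_train_equals_test_warns(self, clean_corpus, caplog):
        docs, _ = clean_corpus
        cfg = GPConfig(population_size=30, n_generations=5, n_stop=3,
                       max_examples=10, seed=0)
        import logging

        with caplog.at_level(logging.WARNING, logger="reprotext.gp"):
            out = run_experiment(docs[:8], "fsh", 1.0, True, cfg)
        assert "training" in caplog.text
        assert 0.0 <= out["fscore"] <= 1.0

    def test_experiment_row_has_metrics_and_regex(self, clean_corpus):
        docs, _ = clean_corpus
        cfg = GPConfig(population_size=40, n_generations=8, n_stop=4,
                       max_examples=15, seed=1)
        out = run_experiment(docs[:30], "fsh", 0.5, True, cfg)
        assert set(out) >= {"precision", "recall", "fscore", "regex"}
        assert out["fscore"] > 0.5

    def test_heldout_requires_proper_fraction(self):
        with pytest.raises(ValueError):
            heldout_fscore([Example("x1", ((1, 2),))], 1.0)
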