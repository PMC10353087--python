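"""scikit-learn style estimators wrapping the functional pipeline.

These thin classes make the extractor, the GP regex synthesiser and the
diagnostic model composable with sklearn tooling (``clone``, pipelines,
grid search); all real work is delegated to the functional modules.
"""

from __future__ import annotations

import random
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import gp
from .concepts import load_concept_specs
from .documents import EMRDocument, PatientRecord
from .extract import compile_manual_ruleset, extract_document
from .gp import Example, GPConfig
from .scoring import THRESHOLDS, score_record
from .stratify import LABELS, diagnose


class RuleBasedExtractor(BaseEstimator, TransformerMixin):
    """Transform EMR documents into structured patient records.

    Parameters
    ----------
    concept_config : str, optional
        Path to an alternative concept-table YAML; the packaged default
        reproduces the standard 15-concept inventory.
    """

    def __init__(self, concept_config: Optional[str] = None):
        self.concept_config = concept_config

    def fit(self, X=None, y=None):
        self.specs_ = load_concept_specs(self.concept_config)
        self.ruleset_ = compile_manual_ruleset(self.specs_)
        return self

    def transform(self, X: Sequence[EMRDocument]) -> list[PatientRecord]:
        check_is_fitted(self, "ruleset_")
        return [extract_document(doc, self.specs_, self.ruleset_)[0] for doc in X]


class RegexSynthesizer(BaseEstimator):
    """Learn an extraction regex from annotated example snippets by GP."""

    def __init__(self, population_size: int = 100, n_generations: int = 60,
                 n_stop: int = 10, tournament_size: int = 7,
                 building_block_threshold: float = 0.9, branch_cap: int = 4,
                 max_examples: int = 40, random_state: int = 0):
        self.population_size = population_size
        self.n_generations = n_generations
        self.n_stop = n_stop
        self.tournament_size = tournament_size
        self.building_block_threshold = building_block_threshold
        self.branch_cap = branch_cap
        self.max_examples = max_examples
        self.random_state = random_state

    def _config(self) -> GPConfig:
        return GPConfig(
            population_size=self.population_size,
            n_generations=self.n_generations,
            n_stop=self.n_stop,
            tournament_size=self.tournament_size,
            building_block_threshold=self.building_block_threshold,
            branch_cap=self.branch_cap,
            max_examples=self.max_examples,
            seed=self.random_state,
        )

    def fit(self, X: Sequence[Example], y=None):
        rng = random.Random(self.random_state)
        result = gp.separate_and_conquer(list(X), self._config(), rng)
        self.regex_ = result.regex
        self.performance_ = result.performance
        self.trace_ = result.trace
        return self

    def predict(self, X: Sequence[str]) -> list[list[tuple[int, int]]]:
        """Extraction spans per snippet."""
        check_is_fitted(self, "regex_")
        import re

        pattern = re.compile(self.regex_)
        return [gp._match_spans(pattern, snippet) for snippet in X]

    def score(self, X: Sequence[Example], y=None) -> float:
        """Character-level extraction F-score on a held-out example set."""
        check_is_fitted(self, "regex_")
        import re

        return gp.char_fscore(re.compile(self.regex_), list(X))


class OvarianReserveClassifier(BaseEstimator):
    """Score records with the DOR/POI/POF model and stratify risk."""

    def __init__(self, require_irregular_menses: bool = False):
        self.require_irregular_menses = require_irregular_menses

    def fit(self, X=None, y=None):
        self.classes_ = np.array(LABELS)
        self.thresholds_ = dict(THRESHOLDS)
        return self

    def predict(self, X: Sequence[PatientRecord]) -> np.ndarray:
        check_is_fitted(self, "classes_")
        labels = []
        for record in X:
            card = score_record(record, th=self.thresholds_)
            labels.append(diagnose(card, record.age, self.require_irregular_menses,
                                   self.thresholds_).label)
        return np.array(labels)

    def score_cards(self, X: Sequence[PatientRecord]):
        check_is_fitted(self, "classes_")
        return [score_record(record, th=self.thresholds_) for record in X]
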