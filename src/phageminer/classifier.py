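"""Random-forest phage-contig classifier and a rule-based baseline.

The model is a random forest (1500 trees, 7 candidate features per split)
over the 10 per-contig predictors.  Because confident non-phage contigs
vastly outnumber phage contigs in real assemblies, the training set is
rebalanced: all phage contigs, all ambiguous contigs, and a seeded random
sample of 3000 confident non-phage contigs drawn from those whose relative
abundance is at or above the median of non-phage abundances.  Ambiguous
contigs enter training as negatives, mirroring their treatment at
evaluation time; a flag excludes them instead.

Cross-validation is leave-one-subject-out: all samples of one individual
form the test fold, preventing within-subject leakage, with the negative
subsample redrawn per fold.

``rule_based_viral`` implements the published homology-profile decision
rules of Paez-Espino et al. as a baseline: a contig is viral when it has at
least 5 viral-protein-family hits with <20% KO, <=40% Pfam and >10%
viral-family gene fractions; or at least as many viral-family hits as Pfam
hits; or >=60% of genes in viral protein families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .evaluation import PerformanceReport, aggregate, evaluate
from .features import FEATURE_NAMES
from .ground_truth import Label


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 1500
    candidate_features_per_split: int = 7
    probability_threshold: float = 0.5
    n_nonphage_sample: int = 3000
    nonphage_abundance_percentile: float = 0.50
    ambiguous_as_negative: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.candidate_features_per_split <= len(FEATURE_NAMES):
            raise ValueError("candidate_features_per_split out of range")
        if not 0 < self.probability_threshold < 1:
            raise ValueError("probability_threshold must be in (0, 1)")


@dataclass(frozen=True)
class Prediction:
    contig_id: str
    phage_probability: float
    call: str  # "phage" | "non_phage"


@dataclass
class TrainingSet:
    """Feature matrix + binary labels for one fold's training data."""

    features: pd.DataFrame  # indexed by contig_id, FEATURE_NAMES columns
    y: np.ndarray  # 1 = phage, 0 = non-phage
    n_phage: int = 0
    n_ambiguous: int = 0
    n_nonphage_sampled: int = 0


def build_training_set(
    features: pd.DataFrame,
    labels: Mapping[str, Label],
    abundances: Mapping[str, float],
    config: ClassifierConfig,
    rng: np.random.Generator | None = None,
) -> TrainingSet:
    """Assemble the rebalanced training set for one fold.

    Positives: every phage contig.  Negatives: every ambiguous contig (when
    ``ambiguous_as_negative``) plus ``n_nonphage_sample`` confident
    non-phage contigs sampled uniformly (seeded) from those whose relative
    abundance is >= the configured percentile of non-phage abundances; when
    fewer are eligible, all are taken with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    ids = list(features.index)
    phage = [c for c in ids if labels[c] is Label.PHAGE]
    ambiguous = [c for c in ids if labels[c] is Label.AMBIGUOUS]
    nonphage = [c for c in ids if labels[c] is Label.NON_PHAGE]
    if not phage:
        raise ValueError("no phage contigs in the training pool; untrainable")
    if nonphage:
        cutoff = float(
            np.quantile(
                [abundances[c] for c in nonphage],
                config.nonphage_abundance_percentile,
            )
        )
        eligible = sorted(c for c in nonphage if abundances[c] >= cutoff)
    else:
        eligible = []
    k = min(config.n_nonphage_sample, len(eligible))
    if k < config.n_nonphage_sample:
        warnings.warn(
            f"only {len(eligible)} eligible non-phage contigs "
            f"(< {config.n_nonphage_sample}); taking all of them"
        )
    sampled = sorted(rng.choice(eligible, size=k, replace=False)) if k else []
    negatives = (ambiguous if config.ambiguous_as_negative else []) + list(sampled)
    chosen = phage + negatives
    y = np.array([1] * len(phage) + [0] * len(negatives), dtype=int)
    return TrainingSet(
        features=features.loc[chosen],
        y=y,
        n_phage=len(phage),
        n_ambiguous=len(ambiguous) if config.ambiguous_as_negative else 0,
        n_nonphage_sampled=len(sampled),
    )


@dataclass
class PhageClassifier:
    """A fitted forest plus the configuration that produced it."""

    config: ClassifierConfig
    forest: RandomForestClassifier

    @classmethod
    def train(
        cls, training: TrainingSet, config: ClassifierConfig
    ) -> "PhageClassifier":
        if len(np.unique(training.y)) < 2:
            raise ValueError("training set must contain both classes")
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.candidate_features_per_split,
            bootstrap=True,
            random_state=config.rng_seed,
            n_jobs=1,
        )
        forest.fit(training.features[list(FEATURE_NAMES)].to_numpy(), training.y)
        return cls(config=config, forest=forest)

    def predict(self, features: pd.DataFrame) -> list[Prediction]:
        """Per-contig phage probability and threshold call (phage iff
        probability >= threshold)."""
        X = features[list(FEATURE_NAMES)].to_numpy()
        phage_col = list(self.forest.classes_).index(1)
        probs = self.forest.predict_proba(X)[:, phage_col]
        return [
            Prediction(
                contig_id=cid,
                phage_probability=float(p),
                call="phage" if p >= self.config.probability_threshold else "non_phage",
            )
            for cid, p in zip(features.index, probs)
        ]

    def save(self, path) -> None:
        joblib.dump({"config": self.config, "forest": self.forest}, path)

    @classmethod
    def load(cls, path) -> "PhageClassifier":
        blob = joblib.load(path)
        return cls(config=blob["config"], forest=blob["forest"])


@dataclass
class CrossValidationResult:
    per_subject: dict[str, dict[str, PerformanceReport]]  # subject -> weighting -> report
    aggregate: dict[str, dict[str, dict[str, float]]]  # weighting -> metric -> stats
    predictions: dict[str, Prediction]


def cross_validate_by_subject(
    features: pd.DataFrame,
    labels: Mapping[str, Label],
    abundances: Mapping[str, float],
    subjects: Mapping[str, str],
    config: ClassifierConfig,
) -> CrossValidationResult:
    """Leave-one-subject-out cross-validation.

    For each subject, a model is trained on the pooled remaining subjects
    (training set rebuilt and the negative sample redrawn per fold, all
    seeded) and evaluated on the held-out subject under both weighting
    schemes.  Ambiguous contigs count as non-phage at evaluation.
    """
    subject_ids = sorted(set(subjects.values()))
    if len(subject_ids) < 2:
        raise ValueError("leave-one-subject-out requires >= 2 subjects")
    rng = np.random.default_rng(config.rng_seed)
    per_subject: dict[str, dict[str, PerformanceReport]] = {}
    all_predictions: dict[str, Prediction] = {}
    for subject in subject_ids:
        test_ids = [c for c in features.index if subjects[c] == subject]
        train_ids = [c for c in features.index if subjects[c] != subject]
        if not test_ids:
            warnings.warn(f"subject {subject!r} has no contigs; skipped")
            continue
        training = build_training_set(
            features.loc[train_ids], labels, abundances, config, rng=rng
        )
        model = PhageClassifier.train(training, config)
        preds = model.predict(features.loc[test_ids])
        all_predictions.update({p.contig_id: p for p in preds})
        pred_map = {p.contig_id: p.call == "phage" for p in preds}
        truth = {c: labels[c] is Label.PHAGE for c in test_ids}
        weights = {c: abundances[c] for c in test_ids}
        per_subject[subject] = {
            "count": evaluate(pred_map, truth, weighting="count"),
            "abundance": evaluate(pred_map, truth, weights, weighting="abundance"),
        }
    agg = {
        w: aggregate([r[w] for r in per_subject.values()])
        for w in ("count", "abundance")
    }
    return CrossValidationResult(
        per_subject=per_subject, aggregate=agg, predictions=all_predictions
    )


def rule_based_viral(
    n_viral_family: int,
    n_pfam: int,
    pct_ko: float,
    pct_pfam: float,
    pct_viral_family: float,
) -> tuple[bool, int]:
    """Homology-profile baseline; returns (is_viral, condition_fired).

    Fractions are in [0, 1].  ``condition_fired`` is the lowest-numbered
    condition (1-3) that held, or 0.
    """
    if (
        n_viral_family >= 5
        and pct_ko < 0.20
        and pct_pfam <= 0.40
        and pct_viral_family > 0.10
    ):
        return True, 1
    if n_viral_family >= n_pfam:
        return True, 2
    if pct_viral_family >= 0.60:
        return True, 3
    return False, 0
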