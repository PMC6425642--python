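"""Classifier: training-set construction, forest determinism, label-swap
symmetry, and the rule-based baseline's truth-table agreement."""

import numpy as np
import pandas as pd
import pytest

from phageminer.classifier import (
    ClassifierConfig,
    PhageClassifier,
    build_training_set,
    cross_validate_by_subject,
    rule_based_viral,
)
from phageminer.evaluation import evaluate
from phageminer.features import FEATURE_NAMES
from phageminer.ground_truth import Label


def _features(ids, phage_like):
    """Separable synthetic vectors: phage-like rows have high viral-family
    counts (f4 ~ 8), others near zero."""
    rng = np.random.default_rng(42)
    rows = []
    for cid, is_phage in zip(ids, phage_like):
        f4 = rng.normal(8, 1) if is_phage else abs(rng.normal(0, 1))
        base = rng.normal(0, 0.2, len(FEATURE_NAMES))
        row = dict(zip(FEATURE_NAMES, np.abs(base)))
        row["f4_n_viral_family"] = max(f4, 0)
        row["f2_n_genes"] = 10
        rows.append(row)
    return pd.DataFrame(rows, index=ids)


def _small_config(**kw):
    defaults = dict(n_trees=100, rng_seed=42)
    defaults.update(kw)
    return ClassifierConfig(**defaults)


class TestBuildTrainingSet:
    def _pool(self, n_phage=50, n_ambig=20, n_non=200):
        ids = (
            [f"p{i}" for i in range(n_phage)]
            + [f"a{i}" for i in range(n_ambig)]
            + [f"n{i}" for i in range(n_non)]
        )
        labels = {}
        labels.update({f"p{i}": Label.PHAGE for i in range(n_phage)})
        labels.update({f"a{i}": Label.AMBIGUOUS for i in range(n_ambig)})
        labels.update({f"n{i}": Label.NON_PHAGE for i in range(n_non)})
        # non-phage abundances 1..200 so the top half is exactly 100 contigs
        abundances = {cid: 1.0 for cid in ids}
        abundances.update({f"n{i}": float(i + 1) for i in range(n_non)})
        feats = _features(ids, [l is Label.PHAGE for l in labels.values()])
        return feats, labels, abundances

    def test_composition_with_percentile_and_sample_size(self):
        feats, labels, ab = self._pool()
        cfg = _small_config(n_nonphage_sample=30)
        ts = build_training_set(feats, labels, ab, cfg)
        assert ts.n_phage == 50
        assert ts.n_ambiguous == 20
        assert ts.n_nonphage_sampled == 30
        assert len(ts.y) == 100
        # sampled negatives all come from the top-half abundance pool
        sampled = [c for c in ts.features.index if c.startswith("n")]
        assert all(ab[c] >= 101 for c in sampled)

    def test_clamps_when_fewer_eligible(self):
        feats, labels, ab = self._pool(n_non=160)
        cfg = _small_config(n_nonphage_sample=3000)
        with pytest.warns(UserWarning, match="eligible"):
            ts = build_training_set(feats, labels, ab, cfg)
        assert ts.n_nonphage_sampled == 80  # top half of 160

    def test_same_seed_same_sample(self):
        feats, labels, ab = self._pool()
        cfg = _small_config(n_nonphage_sample=30)
        a = build_training_set(feats, labels, ab, cfg)
        b = build_training_set(feats, labels, ab, cfg)
        assert list(a.features.index) == list(b.features.index)

    def test_no_phage_is_untrainable(self):
        feats, labels, ab = self._pool(n_phage=0)
        with pytest.raises(ValueError, match="untrainable"):
            build_training_set(feats, labels, ab, _small_config())

    def test_ambiguous_exclusion_flag(self):
        feats, labels, ab = self._pool()
        cfg = _small_config(n_nonphage_sample=30, ambiguous_as_negative=False)
        ts = build_training_set(feats, labels, ab, cfg)
        assert ts.n_ambiguous == 0
        assert len(ts.y) == 80


class TestTrainPredict:
    def test_separable_data_refit_accuracy(self):
        ids = [f"c{i}" for i in range(100)]
        phage_like = [i < 30 for i in range(100)]
        feats = _features(ids, phage_like)
        labels = {c: Label.PHAGE if p else Label.NON_PHAGE for c, p in zip(ids, phage_like)}
        ab = {c: 1.0 for c in ids}
        cfg = _small_config(n_nonphage_sample=70)
        ts = build_training_set(feats, labels, ab, cfg)
        model = PhageClassifier.train(ts, cfg)
        preds = model.predict(ts.features)
        calls = {p.contig_id: p.call == "phage" for p in preds}
        assert all(calls[c] == (labels[c] is Label.PHAGE) for c in ts.features.index)

    def test_conflicting_labels_give_intermediate_probability(self):
        feats = pd.DataFrame(
            [dict(zip(FEATURE_NAMES, [1.0] * 10))] * 10,
            index=[f"c{i}" for i in range(10)],
        )
        from phageminer.classifier import TrainingSet

        ts = TrainingSet(features=feats, y=np.array([1, 0] * 5))
        model = PhageClassifier.train(ts, _small_config())
        probs = [p.phage_probability for p in model.predict(feats)]
        assert all(0 < p < 1 for p in probs)

    def test_single_class_rejected(self):
        from phageminer.classifier import TrainingSet

        feats = _features(["a", "b"], [True, True])
        with pytest.raises(ValueError):
            PhageClassifier.train(
                TrainingSet(features=feats, y=np.array([1, 1])), _small_config()
            )

    def test_refit_is_deterministic(self):
        ids = [f"c{i}" for i in range(60)]
        phage_like = [i < 20 for i in range(60)]
        feats = _features(ids, phage_like)
        labels = {c: Label.PHAGE if p else Label.NON_PHAGE for c, p in zip(ids, phage_like)}
        ab = {c: 1.0 for c in ids}
        cfg = _small_config(n_nonphage_sample=40)
        p1 = PhageClassifier.train(build_training_set(feats, labels, ab, cfg), cfg).predict(feats)
        p2 = PhageClassifier.train(build_training_set(feats, labels, ab, cfg), cfg).predict(feats)
        assert p1 == p2

    def test_model_round_trip(self, tmp_path):
        ids = [f"c{i}" for i in range(40)]
        phage_like = [i < 15 for i in range(40)]
        feats = _features(ids, phage_like)
        labels = {c: Label.PHAGE if p else Label.NON_PHAGE for c, p in zip(ids, phage_like)}
        cfg = _small_config(n_nonphage_sample=25)
        model = PhageClassifier.train(
            build_training_set(feats, labels, {c: 1.0 for c in ids}, cfg), cfg
        )
        model.save(tmp_path / "model.bin")
        loaded = PhageClassifier.load(tmp_path / "model.bin")
        assert loaded.predict(feats) == model.predict(feats)


class TestCrossValidation:
    def _toy_study(self, n_subjects=4, per_subject=60):
        rng = np.random.default_rng(7)
        ids, phage_like, subjects = [], [], {}
        for s in range(n_subjects):
            for i in range(per_subject):
                cid = f"s{s}c{i}"
                ids.append(cid)
                phage_like.append(i < 10)
                subjects[cid] = f"s{s}"
        feats = _features(ids, phage_like)
        labels = {c: Label.PHAGE if p else Label.NON_PHAGE for c, p in zip(ids, phage_like)}
        ab = {c: float(rng.uniform(0.001, 0.01)) for c in ids}
        return feats, labels, ab, subjects

    def test_one_report_per_subject_and_mean(self):
        feats, labels, ab, subjects = self._toy_study()
        cfg = _small_config(n_nonphage_sample=50)
        cv = cross_validate_by_subject(feats, labels, ab, subjects, cfg)
        assert len(cv.per_subject) == 4
        sens = [r["count"].sensitivity for r in cv.per_subject.values()]
        assert cv.aggregate["count"]["sensitivity"]["mean"] == pytest.approx(
            np.mean(sens)
        )

    def test_single_subject_rejected(self):
        feats, labels, ab, subjects = self._toy_study(n_subjects=1)
        with pytest.raises(ValueError):
            cross_validate_by_subject(feats, labels, ab, subjects, _small_config())

    def test_label_swap_swaps_sensitivity_and_specificity(self):
        """Swapping classes in predictions and labels mirrors the report."""
        rng = np.random.default_rng(3)
        preds = {f"c{i}": bool(rng.integers(0, 2)) for i in range(100)}
        labels = {f"c{i}": bool(rng.integers(0, 2)) for i in range(100)}
        fwd = evaluate(preds, labels, weighting="count")
        swapped = evaluate(
            {k: not v for k, v in preds.items()},
            {k: not v for k, v in labels.items()},
            weighting="count",
        )
        assert fwd.sensitivity == pytest.approx(swapped.specificity)
        assert fwd.specificity == pytest.approx(swapped.sensitivity)


def independent_rule_eval(n_vf, n_pfam, pct_ko, pct_pfam, pct_vf):
    """Truth-table re-coding of the three published conditions."""
    c1 = n_vf >= 5 and pct_ko < 0.20 and pct_pfam <= 0.40 and pct_vf > 0.10
    c2 = n_vf >= n_pfam
    c3 = pct_vf >= 0.60
    return c1 or c2 or c3


class TestRuleBasedViral:
    @pytest.mark.parametrize(
        "kw,expected,cond",
        [
            # 20 genes, 6 viral-family (30%), 15% KO, 40% Pfam -> condition 1
            (dict(n_viral_family=6, n_pfam=8, pct_ko=0.15, pct_pfam=0.40,
                  pct_viral_family=0.30), True, 1),
            # viral-family count 5 >= Pfam count 4 -> condition 2
            (dict(n_viral_family=5, n_pfam=4, pct_ko=0.5, pct_pfam=0.2,
                  pct_viral_family=0.25), True, 2),
            # 12% viral genes, 4 viral hits, 25% KO, more Pfams -> non-viral
            (dict(n_viral_family=4, n_pfam=9, pct_ko=0.25, pct_pfam=0.45,
                  pct_viral_family=0.12), False, 0),
        ],
    )
    def test_published_examples(self, kw, expected, cond):
        viral, fired = rule_based_viral(**kw)
        assert viral is expected
        assert fired == cond

    def test_agrees_with_truth_table_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(10_000):
            n_genes = int(rng.integers(1, 40))
            n_vf = int(rng.integers(0, n_genes + 1))
            n_pfam = int(rng.integers(0, n_genes + 1))
            n_ko = int(rng.integers(0, n_genes + 1))
            kw = dict(
                n_viral_family=n_vf,
                n_pfam=n_pfam,
                pct_ko=n_ko / n_genes,
                pct_pfam=n_pfam / n_genes,
                pct_viral_family=n_vf / n_genes,
            )
            assert rule_based_viral(**kw)[0] == independent_rule_eval(
                n_vf, n_pfam, kw["pct_ko"], kw["pct_pfam"], kw["pct_viral_family"]
            )
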