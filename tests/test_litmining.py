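"""Query building, tokenization, naive Bayes triage and coverage mapping."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdome.expression import CDMolecule, CellType, Registry
from cdome.litmining import (
    AbstractRecord,
    Band,
    HitCountMatrix,
    Label,
    bin_hits,
    build_queries,
    classify,
    coverage_fraction,
    evaluate,
    mid_shade,
    rank_cells,
    read_corpus,
    tokenize,
    train_nb,
    write_corpus,
)


def rec(text, label=None, id="r"):
    return AbstractRecord(id=id, text=text, label=label)


class TestTokenize:
    def test_alphanumeric_runs_lowercased(self):
        assert tokenize("CD8+ T cells") == ["cd8", "t", "cells"]

    def test_empty_text(self):
        assert tokenize("") == []

    @given(st.text(max_size=80))
    def test_idempotent_on_joined_output(self, text):
        once = tokenize(text)
        assert tokenize(" ".join(once)) == once


class TestBuildQueries:
    def test_alias_expansion_counts(self):
        cells = Registry([CellType("NK cell")])
        mols = Registry([CDMolecule("CD52", aliases=frozenset({"CAMPATH-1"}))])
        queries = build_queries(cells, mols)
        assert queries == ["NK cell AND CD52", "NK cell AND CAMPATH-1"]

    def test_cartesian_product_arithmetic(self):
        cells = Registry([CellType(f"cell{i}") for i in range(9)])
        mols = Registry([CDMolecule(f"CD{j}") for j in range(13)])
        assert len(build_queries(cells, mols)) == 9 * 13

    def test_empty_molecule_registry(self):
        cells = Registry([CellType("NK cell")])
        assert build_queries(cells, Registry([])) == []


class TestTrainNB:
    def test_balanced_corpus_has_equal_log_priors(self):
        corpus = [rec("a b", Label.POSITIVE), rec("c d", Label.NEGATIVE)]
        model = train_nb(corpus)
        assert model.log_prior[Label.POSITIVE] == model.log_prior[Label.NEGATIVE]

    def test_laplace_arithmetic_by_hand(self):
        """pos = {"a a"}, neg = {"b"}, alpha = 1 over vocab {a, b}: P(a|pos) = 3/4."""
        model = train_nb([rec("a a", Label.POSITIVE), rec("b", Label.NEGATIVE)], alpha=1.0)
        assert math.isclose(math.exp(model.log_prob[Label.POSITIVE][model.vocab["a"]]), 3 / 4)
        assert math.isclose(math.exp(model.log_prob[Label.NEGATIVE][model.vocab["a"]]), 1 / 3)

    def test_smoothing_keeps_unseen_tokens_positive(self):
        model = train_nb([rec("a", Label.POSITIVE), rec("b", Label.NEGATIVE)])
        assert model.log_prob[Label.POSITIVE][model.vocab["b"]] > -math.inf

    def test_token_distributions_normalise(self):
        model = train_nb([rec("a a b", Label.POSITIVE), rec("b c", Label.NEGATIVE)], alpha=0.5)
        for label in Label:
            assert math.isclose(np.exp(model.log_prob[label]).sum(), 1.0)

    def test_single_class_corpus_rejected(self):
        with pytest.raises(ValueError, match="each class"):
            train_nb([rec("a", Label.POSITIVE)])

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            train_nb([rec("a", Label.POSITIVE), rec("b", Label.NEGATIVE)], alpha=0)


class TestClassify:
    def test_hand_bayes_arithmetic(self):
        """Record "a": posterior = (3/4) / (3/4 + 1/3) = 9/13 with equal priors."""
        model = train_nb([rec("a a", Label.POSITIVE), rec("b", Label.NEGATIVE)])
        label, posterior = classify(model, rec("a"))
        assert label is Label.POSITIVE
        assert math.isclose(posterior, 9 / 13)

    def test_out_of_vocabulary_record_decided_by_prior(self):
        model = train_nb(
            [rec("a", Label.POSITIVE)] * 3 + [rec("b", Label.NEGATIVE)], alpha=1.0
        )
        label, posterior = classify(model, rec("zzz qqq"))
        assert label is Label.POSITIVE
        assert math.isclose(posterior, 3 / 4)  # prior alone

    def test_symmetric_tie_goes_positive(self):
        model = train_nb([rec("a", Label.POSITIVE), rec("b", Label.NEGATIVE)])
        label, posterior = classify(model, rec("a b"))
        assert math.isclose(posterior, 0.5)
        assert label is Label.POSITIVE

    def test_consistent_duplication_invariance(self):
        """Doubling every document while scaling the smoothing constant alike
        leaves the fitted token distributions, hence posteriors, unchanged."""
        base = [rec("a a c", Label.POSITIVE), rec("b c", Label.NEGATIVE)]
        doubled = [rec(" ".join(tokenize(r.text) * 2), r.label) for r in base]
        m1, m2 = train_nb(base, alpha=1.0), train_nb(doubled, alpha=2.0)
        for text in ("a", "b c", "a b c c"):
            assert math.isclose(classify(m1, rec(text))[1], classify(m2, rec(text))[1])

    def test_agrees_with_sklearn_multinomial_nb(self):
        """Independent cross-check against the reference multinomial NB."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.feature_extraction.text import CountVectorizer
        from sklearn.naive_bayes import MultinomialNB

        rng = np.random.default_rng(5)
        vocab = ["alpha", "beta", "gamma", "delta"]
        docs, labels = [], []
        for i in range(40):
            k = rng.integers(0, 2)
            probs = [0.4, 0.3, 0.2, 0.1] if k else [0.1, 0.2, 0.3, 0.4]
            docs.append(" ".join(rng.choice(vocab, size=8, p=probs)))
            labels.append(k)
        corpus = [
            rec(d, Label.POSITIVE if k else Label.NEGATIVE, id=str(i))
            for i, (d, k) in enumerate(zip(docs, labels))
        ]
        model = train_nb(corpus, alpha=1.0)

        vec = CountVectorizer(vocabulary=sorted(model.vocab))
        X = vec.transform(docs)
        ref = MultinomialNB(alpha=1.0).fit(X, labels)
        test_docs = [" ".join(rng.choice(vocab, size=6)) for _ in range(20)]
        ours = np.array([classify(model, rec(t))[1] for t in test_docs])
        theirs = ref.predict_proba(vec.transform(test_docs))[:, list(ref.classes_).index(1)]
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_matches_brute_force_joint_likelihood_on_tiny_inputs(self):
        """Exhaustive oracle: all token sequences of length <= 4 over a 3-word vocab."""
        corpus = [
            rec("x x y", Label.POSITIVE),
            rec("y z", Label.POSITIVE),
            rec("z z z", Label.NEGATIVE),
        ]
        model = train_nb(corpus, alpha=1.0)

        counts = {Label.POSITIVE: {"x": 2, "y": 2, "z": 1}, Label.NEGATIVE: {"x": 0, "y": 0, "z": 3}}
        priors = {Label.POSITIVE: 2 / 3, Label.NEGATIVE: 1 / 3}
        totals = {lab: sum(c.values()) for lab, c in counts.items()}

        def oracle(tokens):
            joint = {}
            for lab in Label:
                p = priors[lab]
                for t in tokens:
                    p *= (counts[lab][t] + 1) / (totals[lab] + 3)
                joint[lab] = p
            post = joint[Label.POSITIVE] / (joint[Label.POSITIVE] + joint[Label.NEGATIVE])
            lab = Label.POSITIVE if post >= 0.5 else Label.NEGATIVE
            return lab, post

        for length in range(5):
            for tokens in itertools.product("xyz", repeat=length):
                got_label, got_post = classify(model, rec(" ".join(tokens)))
                exp_label, exp_post = oracle(tokens)
                assert got_label is exp_label
                assert math.isclose(got_post, exp_post, rel_tol=1e-12)


class TestEvaluate:
    def test_perfect_predictions(self):
        corpus = [rec("a a a", Label.POSITIVE), rec("b b b", Label.NEGATIVE)]
        metrics = evaluate(train_nb(corpus), corpus)
        assert metrics.accuracy == metrics.sensitivity == metrics.specificity == 1.0

    def test_hand_confusion_counts(self):
        model = train_nb([rec("a", Label.POSITIVE), rec("b", Label.NEGATIVE)])
        records = [
            rec("a", Label.POSITIVE),  # TP
            rec("a", Label.POSITIVE),  # TP
            rec("b", Label.POSITIVE),  # FN
            rec("b", Label.NEGATIVE),  # TN
        ]
        m = evaluate(model, records)
        assert (m.tp, m.fn, m.tn, m.fp) == (2, 1, 1, 0)
        assert math.isclose(m.sensitivity, 2 / 3)
        assert m.specificity == 1.0
        assert math.isclose(m.accuracy, 3 / 4)

    def test_invariant_under_reordering(self):
        model = train_nb([rec("a", Label.POSITIVE), rec("b", Label.NEGATIVE)])
        records = [rec(t, lab) for t, lab in
                   [("a", Label.POSITIVE), ("b", Label.NEGATIVE), ("a b", Label.NEGATIVE)]]
        assert evaluate(model, records) == evaluate(model, records[::-1])

    def test_empty_or_unlabeled_rejected(self):
        model = train_nb([rec("a", Label.POSITIVE), rec("b", Label.NEGATIVE)])
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, [])
        with pytest.raises(ValueError, match="labeled"):
            evaluate(model, [rec("a")])


class TestCoverage:
    def test_all_zero_matrix(self):
        hits = HitCountMatrix(pd.DataFrame(np.zeros((3, 4), dtype=int),
                                           index=list("abc"), columns=list("wxyz")))
        assert coverage_fraction(hits).fraction == 0.0

    def test_planted_seventeen_percent(self):
        grid = np.zeros((10, 10), dtype=int)
        grid.flat[:17] = 5
        hits = HitCountMatrix(pd.DataFrame(grid, index=[f"c{i}" for i in range(10)],
                                           columns=[f"m{j}" for j in range(10)]))
        cov = coverage_fraction(hits)
        assert (cov.numerator, cov.denominator) == (17, 100)
        assert cov.fraction == 0.17

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            grid = rng.integers(0, 4, size=(50, 50))
            hits = HitCountMatrix(pd.DataFrame(grid, index=[f"c{i}" for i in range(50)],
                                               columns=[f"m{j}" for j in range(50)]))
            for threshold in (1, 2):
                expected = sum(
                    1 for i in range(50) for j in range(50) if grid[i, j] >= threshold
                )
                assert coverage_fraction(hits, threshold).numerator == expected

    def test_empty_matrix_rejected(self):
        hits = HitCountMatrix(pd.DataFrame(index=[], columns=[]))
        with pytest.raises(ValueError, match="empty"):
            coverage_fraction(hits)


class TestRankCells:
    def test_row_sums_single_cell(self):
        hits = HitCountMatrix(pd.DataFrame([[5, 0, 2]], index=["cellA"], columns=list("xyz")))
        row = rank_cells(hits).iloc[0]
        assert (row["total_hits"], row["n_molecules_hit"]) == (7, 2)

    def test_all_zero_matrix_ties_broken_by_name(self):
        hits = HitCountMatrix(pd.DataFrame(np.zeros((3, 2), dtype=int),
                                           index=["b", "a", "c"], columns=["x", "y"]))
        table = rank_cells(hits)
        assert list(table["cell"]) == ["a", "b", "c"]
        assert (table["total_hits"] == 0).all()

    def test_matches_brute_force_sort(self, rng):
        for _ in range(10):
            grid = rng.integers(0, 3, size=(20, 15))
            hits = HitCountMatrix(pd.DataFrame(grid, index=[f"c{i:02d}" for i in range(20)],
                                               columns=[f"m{j}" for j in range(15)]))
            table = rank_cells(hits)
            oracle = sorted(
                ((f"c{i:02d}", int(grid[i].sum()), int((grid[i] >= 1).sum())) for i in range(20)),
                key=lambda t: (-t[2], -t[1], t[0]),
            )
            got = list(table.itertuples(index=False, name=None))
            assert got == oracle


class TestBinHits:
    @pytest.mark.parametrize(
        "count, band",
        [
            (0, Band.NONE),
            (1, Band.LOW), (9, Band.LOW),
            (10, Band.MID), (50, Band.MID), (100, Band.MID),
            (101, Band.HIGH), (999, Band.HIGH),
            (1000, Band.TOP), (1500, Band.TOP),
        ],
    )
    def test_band_boundaries(self, count, band):
        assert bin_hits(count) is band

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            bin_hits(-1)

    def test_mid_shade_spans_light_to_dark(self):
        assert mid_shade(10) == 0.0
        assert mid_shade(100) == 1.0
        with pytest.raises(ValueError):
            mid_shade(5)


class TestCorpusIO:
    def test_round_trip_including_unlabeled(self, tmp_path):
        records = [
            AbstractRecord("r1", "CD8+ T cells express CD3", Label.POSITIVE),
            AbstractRecord("r2", "unrelated abstract", Label.NEGATIVE),
            AbstractRecord("r3", "to be triaged", None),
        ]
        write_corpus(records, tmp_path / "corpus.tsv")
        assert read_corpus(tmp_path / "corpus.tsv") == records

    def test_malformed_line_reports_position(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("r1\tpositive\n")
        with pytest.raises(ValueError, match="bad.tsv:1"):
            read_corpus(tmp_path / "bad.tsv")
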