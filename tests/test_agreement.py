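"""Micro-F1 agreement: matching semantics, symmetry, relaxation orderings."""

import itertools

import numpy as np
import pytest

from chqakit import MatchSpec, agreement_matrix, match_mentions, pairwise_f1, rank_annotators
from chqakit.agreement import FRAME_VARIANTS, PairScore, _doc_counts
from chqakit.model import AnnotatedCorpus, EntityAnn, FrameAnn, Mention, QuestionDoc, TriggerAnn

TEXT = "x" * 200


def ent(eid, category, *spans, is_topic=False):
    return EntityAnn(eid, category, Mention.from_text(TEXT, spans), is_topic)


def trig(tid, qtype, *spans):
    return TriggerAnn(tid, qtype, Mention.from_text(TEXT, spans))


def doc(doc_id, entities=(), triggers=(), frames=()):
    return QuestionDoc(doc_id, TEXT, list(entities), list(triggers), list(frames))


def brute_force_max_pairs(a, b, compatible):
    """Oracle: exhaustive enumeration of all one-to-one pairings."""
    best = 0
    idx_b = range(len(b))
    for r in range(min(len(a), len(b)), -1, -1):
        for subset_a in itertools.combinations(range(len(a)), r):
            for perm_b in itertools.permutations(idx_b, r):
                if all(compatible(i, j) for i, j in zip(subset_a, perm_b)):
                    return r
    return best


class TestMatchMentions:
    def test_identical_pairs(self):
        a = [ent("T1", "PROBLEM", (0, 5))]
        b = [ent("T1", "PROBLEM", (0, 5))]
        assert match_mentions(a, b, "exact") == [(0, 0)]

    def test_overlap_only_pairs_in_approximate(self):
        a = [ent("T1", "PROBLEM", (0, 5))]
        b = [ent("T1", "PROBLEM", (2, 7))]
        assert match_mentions(a, b, "exact") == []
        assert match_mentions(a, b, "approximate") == [(0, 0)]

    def test_label_mismatch_never_pairs(self):
        a = [ent("T1", "PROBLEM", (0, 5))]
        b = [ent("T1", "SUBSTANCE", (0, 5))]
        assert match_mentions(a, b, "approximate") == []

    def test_two_overlapping_one_target_single_pair(self):
        a = [ent("T1", "PROBLEM", (0, 5)), ent("T2", "PROBLEM", (3, 8))]
        b = [ent("T1", "PROBLEM", (2, 6))]
        pairs = match_mentions(a, b, "approximate")
        assert len(pairs) == 1

    def test_discontinuous_exact_needs_identical_fragments(self):
        a = [ent("T1", "PROBLEM", (0, 4), (10, 14))]
        b_same = [ent("T1", "PROBLEM", (0, 4), (10, 14))]
        b_diff = [ent("T1", "PROBLEM", (0, 4), (11, 14))]
        assert match_mentions(a, b_same, "exact") == [(0, 0)]
        assert match_mentions(a, b_diff, "exact") == []
        assert match_mentions(a, b_diff, "approximate") == [(0, 0)]


class TestPairwiseF1:
    def test_identical_sets_perfect(self):
        d = doc("d1", [ent("T1", "PROBLEM", (0, 5))])
        score = pairwise_f1({"d1": d}, {"d1": d}, MatchSpec("entity"))
        assert score.f1 == 1.0

    def test_disjoint_sets_zero(self):
        a = doc("d1", [ent("T1", "PROBLEM", (0, 5))])
        b = doc("d1", [ent("T1", "PROBLEM", (50, 55))])
        assert pairwise_f1({"d1": a}, {"d1": b}, MatchSpec("entity")).f1 == 0.0

    def test_two_of_three_reproduced_plus_one_extra(self):
        gold = doc("d1", [ent("T1", "PROBLEM", (0, 5)), ent("T2", "PROBLEM", (10, 15)),
                          ent("T3", "SUBSTANCE", (20, 25))])
        pred = doc("d1", [ent("T1", "PROBLEM", (0, 5)), ent("T2", "PROBLEM", (10, 15)),
                          ent("T4", "FOOD", (30, 35))])
        score = pairwise_f1({"d1": gold}, {"d1": pred}, MatchSpec("entity"))
        assert (score.tp, score.fp, score.fn) == (2, 1, 1)
        assert score.f1 == pytest.approx(2 / 3)

    def test_empty_doc_sets_error(self):
        with pytest.raises(ValueError):
            pairwise_f1({}, {}, MatchSpec("entity"))

    def test_zero_annotations_scores_zero_not_nan(self):
        a = doc("d1", [ent("T1", "PROBLEM", (0, 5))])
        b = doc("d1")
        score = pairwise_f1({"d1": a}, {"d1": b}, MatchSpec("entity"))
        assert (score.precision, score.recall, score.f1) == (0.0, 0.0, 0.0)

    def test_topic_layer_requires_topic_flag_on_both(self):
        a = doc("d1", [ent("T1", "PROBLEM", (0, 5), is_topic=True)])
        b = doc("d1", [ent("T1", "PROBLEM", (0, 5))])
        assert pairwise_f1({"d1": a}, {"d1": b}, MatchSpec("topic")).tp == 0

    def test_qtype_layer_ignores_mentions(self):
        a = doc("d1", triggers=[trig("T1", "TREATMENT", (0, 4))])
        b = doc("d1", triggers=[trig("T1", "TREATMENT", (50, 60))])
        assert pairwise_f1({"d1": a}, {"d1": b}, MatchSpec("qtype")).f1 == 1.0
        assert pairwise_f1({"d1": a}, {"d1": b}, MatchSpec("trigger")).f1 == 0.0


def frame_doc(doc_id, trigger_span, theme_span, keyword_span=None, qtype="TREATMENT"):
    entities = [ent("T1", "PROBLEM", theme_span)]
    args = [("THEME", "T1")]
    if keyword_span is not None:
        entities.append(ent("T2", "SUBSTANCE", keyword_span))
        args.append(("KEYWORD", "T2"))
    triggers = [trig("Q1", qtype, trigger_span)]
    frames = [FrameAnn("E1", "Q1", tuple(args))]
    return doc(doc_id, entities, triggers, frames)


class TestFrameVariants:
    def test_keyword_difference_breaks_full_not_core(self):
        a = {"d1": frame_doc("d1", (0, 4), (10, 15), keyword_span=(20, 25))}
        b = {"d1": frame_doc("d1", (0, 4), (10, 15), keyword_span=(30, 35))}
        core = pairwise_f1(a, b, MatchSpec("frame", frame_variant="core_trigger"))
        full = pairwise_f1(a, b, MatchSpec("frame", frame_variant="full_trigger"))
        assert core.f1 == 1.0 and full.f1 == 0.0

    def test_trigger_span_difference_breaks_trigger_not_type(self):
        a = {"d1": frame_doc("d1", (0, 4), (10, 15))}
        b = {"d1": frame_doc("d1", (5, 9), (10, 15))}
        by_trigger = pairwise_f1(a, b, MatchSpec("frame", frame_variant="core_trigger"))
        by_type = pairwise_f1(a, b, MatchSpec("frame", frame_variant="core_type"))
        assert by_trigger.f1 == 0.0 and by_type.f1 == 1.0

    def test_theme_mismatch_breaks_all_variants(self):
        a = {"d1": frame_doc("d1", (0, 4), (10, 15))}
        b = {"d1": frame_doc("d1", (0, 4), (50, 55))}
        for variant in FRAME_VARIANTS:
            assert pairwise_f1(a, b, MatchSpec("frame", frame_variant=variant)).f1 == 0.0

    def test_duplicate_frames_matched_one_to_one(self):
        base = frame_doc("d1", (0, 4), (10, 15))
        dup = base.frames[0]
        a = doc("d1", base.entities, base.triggers, [dup, FrameAnn("E2", "Q1", dup.args)])
        score = pairwise_f1(
            {"d1": a}, {"d1": base}, MatchSpec("frame", frame_variant="core_trigger")
        )
        assert (score.tp, score.fp, score.fn) == (1, 0, 1)


class TestInvariants:
    """Symmetry, relaxation monotonicity, hierarchy, oracle equivalence."""

    def _rand_docs(self, rng, n_items=5):
        cats = ["PROBLEM", "SUBSTANCE"]
        def one(did):
            entities = []
            for i in range(rng.integers(1, n_items + 1)):
                s = int(rng.integers(0, 50))
                entities.append(ent(f"T{i}", cats[rng.integers(2)], (s, s + int(rng.integers(2, 8)))))
            return doc(did, entities)
        return one

    def test_symmetry_under_annotator_swap(self):
        rng = np.random.default_rng(5)
        make = self._rand_docs(rng)
        a, b = {"d": make("d")}, {"d": make("d")}
        for mode in ("exact", "approximate"):
            s_ab = pairwise_f1(a, b, MatchSpec("entity", mode=mode))
            s_ba = pairwise_f1(b, a, MatchSpec("entity", mode=mode))
            assert s_ab.f1 == pytest.approx(s_ba.f1)
            assert s_ab.precision == pytest.approx(s_ba.recall)

    def test_approximate_at_least_exact(self):
        rng = np.random.default_rng(6)
        make = self._rand_docs(rng)
        for _ in range(30):
            a, b = {"d": make("d")}, {"d": make("d")}
            f_exact = pairwise_f1(a, b, MatchSpec("entity", mode="exact")).f1
            f_approx = pairwise_f1(a, b, MatchSpec("entity", mode="approximate")).f1
            assert f_approx >= f_exact

    def test_frame_variant_hierarchy(self, noisy_pair):
        docs_a = {d: noisy_pair.docs[(d, "ann1")] for d in noisy_pair.doc_ids}
        docs_b = {d: noisy_pair.docs[(d, "ann2")] for d in noisy_pair.doc_ids}
        f1 = {
            v: pairwise_f1(docs_a, docs_b, MatchSpec("frame", frame_variant=v)).f1
            for v in FRAME_VARIANTS
        }
        assert f1["core_trigger"] >= f1["full_trigger"]
        assert f1["core_type"] >= f1["full_type"]
        assert f1["full_type"] >= f1["full_trigger"]
        assert f1["core_type"] >= f1["core_trigger"]

    @pytest.mark.parametrize("mode", ["exact", "approximate"])
    def test_tp_equals_exhaustive_enumeration(self, mode):
        rng = np.random.default_rng(7)
        make = self._rand_docs(rng, n_items=6)
        for _ in range(60):
            a, b = make("d"), make("d")
            tp, _, _ = _doc_counts(a, b, MatchSpec("entity", mode=mode))
            from chqakit.agreement import _item_compatible
            oracle = brute_force_max_pairs(
                a.entities, b.entities,
                lambda i, j: _item_compatible(a.entities[i], b.entities[j], mode),
            )
            assert tp == oracle


class TestReportAndRanking:
    def test_two_annotators_one_pair(self, noisy_pair):
        report = agreement_matrix(noisy_pair, [MatchSpec("entity")])
        assert len(report.pair_scores) == 1
        avg, lo, hi = report.summary(MatchSpec("entity"))
        assert lo <= avg <= hi

    def test_pair_only_counted_with_shared_docs(self, gold_corpus):
        from chqakit.corpus_tools import AnnotatorProfile, corrupt_annotations
        corpus = AnnotatedCorpus(scheme="chqa-email")
        doc_ids = gold_corpus.doc_ids
        # a/b share the first half, c/d share the second: 2 pairs, not 6
        halves = {"a": doc_ids[:4], "b": doc_ids[:4], "c": doc_ids[4:], "d": doc_ids[4:]}
        for name, ids in halves.items():
            noisy = corrupt_annotations(gold_corpus, AnnotatorProfile(name, seed=ord(name)))
            for did in ids:
                corpus.add(name, noisy[did])
        report = agreement_matrix(corpus, [MatchSpec("entity")])
        assert len(report.pair_scores) == 2

    def test_rank_means_and_ties(self):
        spec = MatchSpec("entity")
        report_scores = {
            ("A", "B"): (3, 1, 1),   # f1 = 0.75... compute via counts
            ("A", "C"): (4, 0, 0),   # f1 = 1.0
            ("B", "C"): (1, 3, 3),   # f1 = 0.25
        }
        from chqakit.agreement import AgreementReport
        report = AgreementReport()
        for (x, y), (tp, fp, fn) in report_scores.items():
            report.pair_scores[(x, y, spec)] = PairScore(x, y, spec, tp, fp, fn)
        ranked = rank_annotators(report, spec)
        assert ranked[0] == "A"
        assert ranked == sorted(ranked, key=lambda a: (-np.mean(
            [s.f1 for (x, y, _), s in report.pair_scores.items() if a in (x, y)]), a))

    def test_lexicographic_tie_break(self):
        spec = MatchSpec("entity")
        from chqakit.agreement import AgreementReport
        report = AgreementReport()
        report.pair_scores[("B", "A", spec)] = PairScore("B", "A", spec, 1, 1, 1)
        assert rank_annotators(report, spec) == ["A", "B"]

    def test_per_type_breakdown_shape(self, noisy_pair):
        report = agreement_matrix(
            noisy_pair, [MatchSpec("trigger")], per_type_breakdown=True
        )
        table = report.per_type_frame()
        assert set(table.columns) == {"question_type", "trigger", "type"}
        assert len(table) > 0
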