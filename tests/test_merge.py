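"""Merging policies, consistency enforcement, and gold evaluation."""

import pytest

from chqakit import (
    CandidateItem,
    ConfidenceModelConfig,
    GenConfig,
    build_candidates,
    class_mean_thresholds,
    evaluate_against_gold,
    fit_item_response,
    generate_gold,
    merge_agree,
    merge_confidence,
    merge_rank,
)
from chqakit.agreement import MatchSpec, agreement_matrix, rank_annotators
from chqakit.corpus_tools import AnnotatorProfile, build_noisy_corpus
from chqakit.merge import MergePolicy, merged_to_doc
from chqakit.schema import load_scheme


def item(iid, responses, cls="entity", key=None, deps=()):
    return CandidateItem(
        item_id=iid, doc_id="d1", semantic_class=cls,
        identity_key=key or ("entity", iid, ((0, 1),)),
        responses=responses, depends_on=deps,
    )


UNANIMOUS = {"a": True, "b": True}
DISPUTED = {"a": True, "b": False}


class TestPolicyConfig:
    def test_rank_spec_required_for_iaa_rank(self):
        with pytest.raises(ValueError):
            MergePolicy(method="iaa_rank")
        MergePolicy(method="iaa_rank", rank_spec=MatchSpec("entity"))

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            MergePolicy(method="majority")


class TestMergeAgree:
    def test_identical_sets_kept(self):
        items = [item("i1", UNANIMOUS), item("i2", UNANIMOUS)]
        merged = merge_agree(items)
        assert merged.all_keys() == {it.identity_key for it in items}

    def test_disjoint_sets_empty(self):
        items = [item("i1", DISPUTED), item("i2", {"a": False, "b": True})]
        assert merge_agree(items).all_keys() == set()

    def test_unanimous_frame_over_disputed_entity_dropped(self):
        ekey = ("entity", "PROBLEM", ((0, 5),))
        tkey = ("trigger", "TREATMENT", ((6, 9),))
        fkey = ("frame", "TREATMENT", ((6, 9),), (("THEME", ("PROBLEM", ((0, 5),))),))
        items = [
            item("d1/entity/0", DISPUTED, "entity", ekey),
            item("d1/trigger/0", UNANIMOUS, "trigger", tkey),
            item("d1/frame/0", UNANIMOUS, "frame", fkey, deps=(tkey, ekey)),
        ]
        merged = merge_agree(items)
        assert fkey not in merged.all_keys()
        assert tkey in merged.all_keys()


class TestMergeRank:
    def test_prefers_higher_ranked_annotator(self, noisy_pair):
        doc_id = noisy_pair.doc_ids[0]
        docs = {a: noisy_pair.docs[(doc_id, a)] for a in ("ann1", "ann2")}
        merged = merge_rank(docs, ["ann1", "ann2"])
        from chqakit.confidence import doc_item_keys
        expected = {k for kk in doc_item_keys(docs["ann1"]).values() for k in kk}
        assert merged.all_keys() == expected

    def test_empty_preferred_set_is_wholesale(self, noisy_pair):
        doc_id = noisy_pair.doc_ids[0]
        base = noisy_pair.docs[(doc_id, "ann2")]
        empty = base.with_annotations(entities=[], triggers=[], frames=[])
        merged = merge_rank({"ann1": empty, "ann2": base}, ["ann1", "ann2"])
        assert merged.all_keys() == set()

    def test_missing_from_ranking_errors(self, noisy_pair):
        doc_id = noisy_pair.doc_ids[0]
        docs = {a: noisy_pair.docs[(doc_id, a)] for a in ("ann1", "ann2")}
        with pytest.raises(ValueError):
            merge_rank(docs, ["ann1"])


class TestClassMeanThresholds:
    def test_arithmetic_mean(self):
        items = [item("i1", UNANIMOUS), item("i2", DISPUTED)]
        thresholds = class_mean_thresholds(items, {"i1": 0.2, "i2": 0.8})
        assert thresholds == {"entity": pytest.approx(0.5)}

    def test_empty_class_omitted(self):
        items = [item("i1", UNANIMOUS)]
        assert "frame" not in class_mean_thresholds(items, {"i1": 0.9})

    def test_equal_confidences_block_all_disputed(self):
        items = [item(f"i{k}", DISPUTED) for k in range(4)]
        confs = {it.item_id: 0.4 for it in items}
        thresholds = class_mean_thresholds(items, confs)
        merged = merge_confidence(items, confs, thresholds)
        assert merged.all_keys() == set()

    def test_disagreed_only_population(self):
        items = [item("i1", UNANIMOUS), item("i2", DISPUTED)]
        t = class_mean_thresholds(items, {"i1": 0.9, "i2": 0.3}, population="disagreed")
        assert t == {"entity": pytest.approx(0.3)}


class TestMergeConfidence:
    def test_unanimous_accepted_despite_low_confidence(self):
        items = [item("i1", UNANIMOUS)]
        merged = merge_confidence(items, {"i1": 0.05}, {"entity": 0.5})
        assert merged.all_keys() == {items[0].identity_key}
        assert merged.provenance[items[0].identity_key] == "agreed"

    def test_disputed_above_mean_accepted(self):
        items = [item("i1", DISPUTED), item("i2", DISPUTED)]
        confs = {"i1": 0.9, "i2": 0.1}
        merged = merge_confidence(items, confs, class_mean_thresholds(items, confs))
        assert merged.all_keys() == {items[0].identity_key}
        assert merged.provenance[items[0].identity_key] == "above-threshold"

    def test_frame_with_rejected_theme_rejected(self):
        ekey = ("entity", "PROBLEM", ((0, 5),))
        tkey = ("trigger", "TREATMENT", ((6, 9),))
        fkey = ("frame", "TREATMENT", ((6, 9),), (("THEME", ("PROBLEM", ((0, 5),))),))
        items = [
            item("d1/entity/0", DISPUTED, "entity", ekey),
            item("d1/trigger/0", UNANIMOUS, "trigger", tkey),
            item("d1/frame/0", DISPUTED, "frame", fkey, deps=(tkey, ekey)),
        ]
        confs = {"d1/entity/0": 0.1, "d1/frame/0": 0.95}
        merged = merge_confidence(items, confs, {"entity": 0.5, "frame": 0.5})
        assert fkey not in merged.all_keys()

    def test_unscored_disputed_item_errors(self):
        items = [item("i1", DISPUTED)]
        with pytest.raises(KeyError):
            merge_confidence(items, {}, {"entity": 0.5})

    def test_agree_subset_of_confidence_output(self, noisy_pair):
        items = build_candidates(noisy_pair)
        table = fit_item_response(items, ConfidenceModelConfig(seed=13))
        thresholds = class_mean_thresholds(items, table.confidences)
        by_doc = {}
        for it in items:
            by_doc.setdefault(it.doc_id, []).append(it)
        for doc_id, doc_items in by_doc.items():
            agree_keys = merge_agree(doc_items, doc_id=doc_id).all_keys()
            conf_keys = merge_confidence(
                doc_items, table.confidences, thresholds, doc_id=doc_id
            ).all_keys()
            assert agree_keys <= conf_keys


class TestStructuralInvariant:
    def test_all_policies_produce_valid_documents(self, noisy_pair):
        """Merged outputs re-validate cleanly at the structural level."""
        scheme = load_scheme("chqa-email")
        items = build_candidates(noisy_pair)
        table = fit_item_response(items, ConfidenceModelConfig(seed=13))
        thresholds = class_mean_thresholds(items, table.confidences)
        report = agreement_matrix(noisy_pair, [MatchSpec("entity")])
        ranking = rank_annotators(report, MatchSpec("entity"))
        by_doc = {}
        for it in items:
            by_doc.setdefault(it.doc_id, []).append(it)
        for doc_id, doc_items in by_doc.items():
            docs = {a: noisy_pair.docs[(doc_id, a)] for a in ("ann1", "ann2")}
            outputs = [
                merge_agree(doc_items, doc_id=doc_id),
                merge_rank(docs, ranking),
                merge_confidence(doc_items, table.confidences, thresholds, doc_id=doc_id),
            ]
            for merged in outputs:
                merged.check_consistency()
                doc = merged_to_doc(merged, list(docs.values()))
                # structural codes only: semantic codes can reflect simulated
                # label confusion, dangling structure must never appear
                doc._check_refs()


class TestEvaluateAgainstGold:
    def test_perfect_merge_scores_one(self, gold_corpus):
        from chqakit.model import AnnotatedCorpus
        duplicated = AnnotatedCorpus(scheme=gold_corpus.scheme)
        for (doc_id, _), doc in gold_corpus:
            duplicated.add("a1", doc)
            duplicated.add("a2", doc)
        items = build_candidates(duplicated)
        by_doc = {}
        for it in items:
            by_doc.setdefault(it.doc_id, []).append(it)
        merged = {d: merge_agree(v, doc_id=d) for d, v in by_doc.items()}
        report = evaluate_against_gold(merged, gold_corpus.docs_of("gold"))
        assert (report.precision, report.recall, report.f1) == (1.0, 1.0, 1.0)

    def test_missing_one_of_four_items(self):
        corpus = generate_gold(GenConfig(n_questions=1, seed=7))
        gold_doc = corpus.docs_of("gold")[corpus.doc_ids[0]]
        from chqakit.confidence import doc_item_keys
        from chqakit.merge import MergedQuestion
        keys = doc_item_keys(gold_doc)
        merged = MergedQuestion(doc_id=gold_doc.doc_id)
        dropped = False
        for cls in ("entity", "trigger", "topic", "frame"):
            for key, deps in keys[cls].items():
                if not dropped and cls == "frame":
                    dropped = True  # omit one frame (a leaf: nothing depends on it)
                    continue
                merged.accepted[cls].add(key)
                merged.dependencies[key] = deps
        n_total = sum(len(k) for k in keys.values())
        report = evaluate_against_gold({gold_doc.doc_id: merged},
                                       {gold_doc.doc_id: gold_doc})
        assert report.precision == 1.0
        assert report.recall == pytest.approx((n_total - 1) / n_total)

    def test_empty_merged_zero_recall(self, gold_corpus):
        from chqakit.merge import MergedQuestion
        merged = {d: MergedQuestion(doc_id=d) for d in gold_corpus.doc_ids}
        report = evaluate_against_gold(merged, gold_corpus.docs_of("gold"))
        assert report.recall == 0.0

    def test_no_overlap_errors(self, gold_corpus):
        with pytest.raises(ValueError):
            evaluate_against_gold({}, gold_corpus.docs_of("gold"))

    def test_agree_precision_perfect_against_containing_gold(self, noisy_pair, gold_corpus):
        """AGREE only asserts unanimous items; gold containing them gives P=1."""
        items = build_candidates(noisy_pair)
        by_doc = {}
        for it in items:
            by_doc.setdefault(it.doc_id, []).append(it)
        # build a gold that contains every unanimous item: union of gold corpus
        # and unanimous keys is exactly what merge_agree accepts plus the rest
        merged = {d: merge_agree(v, doc_id=d) for d, v in by_doc.items()}
        from chqakit.confidence import doc_item_keys
        from chqakit.model import QuestionDoc
        gold_docs = {}
        for doc_id, mq in merged.items():
            sources = [noisy_pair.docs[(doc_id, a)] for a in ("ann1", "ann2")]
            gold_docs[doc_id] = merged_to_doc(mq, sources)  # gold := exactly the unanimous set
        report = evaluate_against_gold(merged, gold_docs)
        assert report.precision == 1.0


class TestRankVersusAgreeRecovery:
    def test_rank_recovers_recall_with_one_clean_annotator(self):
        """A correct ranking restores the clean annotator's full set."""
        wins = 0
        for seed in range(20):
            gold = generate_gold(GenConfig(n_questions=6, seed=900 + seed))
            corpus = build_noisy_corpus(
                gold,
                [
                    AnnotatorProfile("clean", competence=1.0, spurious_rate=0.0,
                                     span_jitter=0, seed=seed),
                    AnnotatorProfile("noisy", competence=0.6, spurious_rate=1.0,
                                     span_jitter=1, type_confusion=0.1, seed=500 + seed),
                ],
            )
            items = build_candidates(corpus)
            by_doc = {}
            for it in items:
                by_doc.setdefault(it.doc_id, []).append(it)
            gold_docs = gold.docs_of("gold")
            agree_merged = {d: merge_agree(v, doc_id=d) for d, v in by_doc.items()}
            rank_merged = {
                d: merge_rank(
                    {a: corpus.docs[(d, a)] for a in ("clean", "noisy")},
                    ["clean", "noisy"],
                )
                for d in corpus.doc_ids
            }
            f_agree = evaluate_against_gold(agree_merged, gold_docs).f1
            f_rank = evaluate_against_gold(rank_merged, gold_docs).f1
            wins += f_rank >= f_agree
        assert wins == 20
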