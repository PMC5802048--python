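# Methods

This note documents the models, procedures and numerical choices behind
`chqakit`, and what the synthetic-data experiments do and do not show.

## The question-frame representation

A consumer health question is decomposed into sub-questions, each
represented as a *frame*: a trigger mention carrying a normalized
question type, one or more THEME arguments (named entities), and optional
role-labelled arguments. The topic of a question — its central disease,
drug or other entity — is an attribute on the relevant entity in the
email scheme; in the web scheme it is omitted because short queries'
topics coincide with the frame THEME almost always.

Scheme inventories ship as YAML data files
(`src/chqakit/schemes/*.yaml`) rather than code so the category and type
tables are auditable; the test suite pins their cardinalities (17/33 for
the email scheme, 18/26 for the web scheme). Validation returns
`Violation` records instead of raising so a corpus audit sees every
problem at once; only structural corruption (an argument referencing a
nonexistent annotation) raises. Questions carrying an exclusion label
(NOT_QUESTION, NOT_ANSWERABLE, DUPLICATE) are exempt from semantic
validation — they are excluded from corpus counts, so the checks would be
vacuous. The THEME restriction for each email question type is enforced
exactly as tabulated, including COMPLICATION's
{problem, procedure_device, lifestyle, food}; no relaxations are applied
to the email scheme because none are defined for it.

## brat standoff conventions

Offsets are 0-based, end-exclusive Unicode code points; text is UTF-8
with no newline normalization (offsets must match the source file).
Whether a T-line label is an entity or a trigger is decided by scheme
membership, so files from a different scheme fail loudly rather than
parse into nonsense. The topic attribute is accepted as `Topic` or
`Focus` on read and written as `Topic`. brat has no document-level
attributes, so question-level labels are carried on a sentinel term with
the reserved label `QUESTION` spanning the document; this is a
convention of this package, chosen so labelled corpora round-trip.
Normalization (N) and relation (R) lines are out of scope — the
representation uses terms, events and attributes only.

## Agreement

Agreement between two annotators is the micro-averaged F1 when one side
is treated as gold: per-document true positives are the cardinality of a
maximum one-to-one pairing between the two annotation sets, pooled over
documents before computing precision/recall. Maximum-cardinality
bipartite matching (Hopcroft–Karp via networkx) rather than greedy
pairing makes counts order-independent and guarantees the relaxation
property (approximate-match F1 ≥ exact-match F1: every exact pairing is a
legal approximate pairing, and a maximum matching cannot shrink when
edges are added). The test suite checks the pooled counts against
exhaustive enumeration of all one-to-one pairings on small documents.

Layer semantics: *entity* and *trigger* compare label + mention; *topic*
compares entities that carry the topic flag on both sides; *qtype*
compares normalized types only, aligned one-to-one per document by count
(whether the original protocol aligned per document or pooled
corpus-wide is not determinable; per-document alignment is used and
noted here). Discontinuous mentions match exactly only with identical
fragment lists; approximately if any fragments overlap. Frame variants:
`core_*` requires the trigger criterion plus an equal-size perfectly
matched THEME set; `full_*` additionally requires equal role sets with
perfectly matched arguments per role; `*_type` ignores the trigger
mention entirely (identifying the exact words expressing a question is
rarely needed downstream), `*_trigger` compares it under the active
span criterion. Frame attributes participate in no variant. Repeated
identical frames stay separate items: one-to-one matching forces
duplicates to be matched by duplicates.

Annotator ranking (for the IAA_RANK merge policy) sorts annotators by
the mean of their pairwise F1s for a chosen spec, ties broken
lexicographically by id.

## Confidence model

Every distinct annotation proposition in a multiply-annotated document —
deduplicated by canonical content key — becomes a binary item: each
annotator of that document responded *present* (asserted it) or *absent*.
The item-response model in the MACE family is:

    T_i ~ Bernoulli(π)                    latent truth of item i
    y_ij = T_i                with prob c_j   (annotator j copies)
    y_ij ~ Bernoulli(s_j)     with prob 1−c_j (annotator j "spams")

fitted by EM with symmetric pseudo-count smoothing (default 0.5) on π,
each competence c_j, and each spamming distribution s_j; unsmoothed EM on
two-annotator data collapses to 0/1 competences. The monitored objective
is the penalized log-likelihood (likelihood plus conjugate log-priors),
which MAP-EM makes non-decreasing; it is asserted every iteration with a
relative tolerance of 1e-8. Defaults: 50 iterations, 10 random restarts
(competence initialized Uniform(0.3, 0.9), spamming and prior at 0.5),
best final objective retained, bit-deterministic given the seed. A
label-switching guard requires the selected restart to give unanimous-
present items mean confidence above 0.5; if no restart qualifies, the
complementary confidences (1 − posterior) of the best restart are
reported. Items are scored independently of one another — frames are not
coupled to their argument items at this stage; structural coupling is
deferred to merging.

The candidate space is the union of asserted annotations: the model can
down-weight what somebody asserted but cannot hypothesize annotations
nobody produced.

### What parameter recovery can and cannot show

`simulate_item_responses` draws items directly from the generative model
for recovery studies. Its default truth prior is 0.7 — in a
double-annotation regime where the unanimous subset has near-perfect
precision at recall ≈ 0.66 and a single annotator's set has precision
≈ 0.78 at recall ≈ 0.80, roughly 70 % of pooled candidate propositions
are correct — and its spam distribution is neutral (0.5), since the two
spam event types (junk assertions vs omissions) balance closely under
the same arithmetic.

Under these conditions, with three annotators of competences
(0.95, 0.85, 0.35) and 300 items, the fitted competences separate the
near-chance annotator from the competent pair essentially always, but
the 0.95-vs-0.85 distinction is only weakly identified: it rests on the
small asymmetry between (present, absent) and (absent, present)
disagreement patterns, whose expected count difference at n = 300 is of
the same order as its sampling noise. EM initialized at the true
parameters converges to the same optimum as the restart-selected fit, so
this is a property of the likelihood, not of the optimizer; the full
ordering is recovered in roughly two thirds of seeded replicates, while
the rank correlation between true and estimated competences averages
above 0.8. Consumers of the model should treat competence estimates as
reliable for separating good from poor annotators and the per-item
confidences — not the competences — as the primary output.

A second corpus-level caveat: when candidate items are built from unions
of full annotation sets, a *better* annotator contributes more correct
singleton assertions (items their partners missed), which the model —
lacking any external truth — cannot distinguish from spurious ones.
Competence estimates from exactly-two-annotator corpora are therefore
biased against high-recall annotators, one reason pairwise agreement
ranking is a strong baseline in this regime.

## Merging

All policies emit per-question sets of accepted identity keys with
provenance, and all enforce the structural invariant that an accepted
topic's entity and an accepted frame's trigger and arguments are
themselves accepted (re-checked on construction).

* **AGREE** — unanimous items only, consistency-filtered. Against any
  gold standard containing the unanimous items its precision is 1 by
  construction; recall is whatever double agreement reaches.
* **IAA_RANK** — wholesale: the complete set of the higher-ranked of the
  two annotators of the question.
* **Confidence** — unanimous items are accepted regardless of their
  score (agreement overrides the threshold); disputed items are visited
  class by class in dependency order (entities, triggers, topics,
  frames) and within a class by descending confidence, accepted iff
  their confidence strictly exceeds their class threshold and their
  dependencies were accepted. The class threshold is the arithmetic mean
  confidence of the class; whether the mean should be over all items or
  disputed items only is genuinely ambiguous, so both populations are
  implemented (`population="all"` is the default). Strict `>` comparison
  means that when all confidences in a class are equal, no disputed item
  passes. Visiting by descending confidence prevents a high-confidence
  frame from being blocked merely because its arguments had not been
  visited yet.

Evaluation against an adjudicated gold compares canonical identity keys
(exact content), pooled over all layers for the headline
precision/recall/F1 and also reported per layer.

## Synthetic corpora

The generator emulates the *structure* of the corpus — short and long
template-built question texts, entity mentions drawn from small
category-tagged lexicons, triggers from a per-type lexicon, frames with
THEME (respecting each scheme's category restrictions and cardinalities,
e.g. two themes for COMPARISON/INTERACTION), optional KEYWORD/RESTRICTOR
arguments, topics in the email scheme — not natural language. Downstream
computations consume only offsets and labels, so template text exercises
them fully; nothing about linguistic realism is claimed, and passing
tests say nothing about how hard real questions are to annotate.
Sampling weights default to the corpus's frequency rank order (PROBLEM
the dominant entity category; TREATMENT and INFORMATION the dominant
question types). Tokenization for corpus statistics splits whitespace
after separating punctuation; token statistics are computed over unique
questions while annotation counts include every annotator's copy (the
convention when no adjudicated set exists).

Annotator noise per profile: each gold annotation is independently kept
with probability `competence`; kept mentions suffer boundary jitter of at
most `span_jitter` characters with probability `boundary_noise`
(default 0.25 — annotators disagree on some boundaries, they do not
re-draw every one) and label confusion with probability `type_confusion`;
spurious annotations arrive at Poisson rate `spurious_rate`; frames
whose trigger or arguments were dropped are dropped (structural closure,
so corrupted documents are always structurally valid).

Question harvesting: a query counts as a natural-language question if it
contains a wh-word token (*how, what, when, where, which, who, why* —
matched anywhere by default, start-anchored optionally), ends with a
question mark, or starts with one of the auxiliaries *is it, can, could,
do, does*; matching is case-insensitive and token-boundary aware.

## Problem sizes and determinism

The shipped experiments use deliberately small corpora — 8–25 questions
per corpus, 200–350 candidate items per EM fit, 20 seeds for recovery
studies, 3 noise levels × 10 seeds for the end-to-end merge study —
sizes at which every property they test is already exercised and the
whole suite plus the acceptance script completes in well under a minute
each. Every stochastic component takes an explicit integer seed
(generation, corruption, EM restarts), and identical inputs plus seed
reproduce outputs bit-for-bit.

## Known limitations

* Exactly-two-annotator corpora leave the item-response model weakly
  identified; see the recovery discussion above.
* Approximate-overlap matching is not available for evaluating merged
  sets against gold (identity keys are exact content).
* The brat reader supports the T/E/A subset only.
* Question texts are templates; statistics that depend on real language
  (token standard deviation, trigger lexical diversity) are only
  meaningful on real corpora.
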