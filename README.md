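# chqakit

A toolkit for **semantic question-frame annotation of consumer health
questions**: the data model and scheme validation, brat standoff I/O,
pairwise inter-annotator agreement, unsupervised annotation-confidence
estimation, and consistency-constrained merging of double annotations.

Consumer health questions — long customer-service emails or short search
queries — typically bundle several information needs around a central
topic. The representation implemented here decomposes each question into
**question frames**: a typed *trigger* expression (e.g. *cure* →
TREATMENT) plus role-labelled named-entity arguments, with a mandatory
THEME and optional roles such as KEYWORD or RESTRICTOR. Two annotation
schemes are shipped:

| scheme       | entity categories | question types | topic layer | nested entities |
|--------------|-------------------|----------------|-------------|-----------------|
| `chqa-email` | 17                | 33             | required    | allowed         |
| `chqa-web`   | 18                | 26             | none        | forbidden       |

The web scheme consolidates rare email types (e.g. DOSAGE, TAPERING,
STORAGE_DISPOSAL → USAGE), renames EFFECT to ASSOCIATION, adds
DIAGNOSE_ME and TIME, and lifts THEME category restrictions while keeping
cardinality constraints (COMPARISON and INTERACTION still need ≥ 2 themes).

The toolkit is aimed at corpus builders who double-annotate questions and
need to (a) quantify agreement, (b) estimate which annotations to trust
without full expert adjudication, and (c) publish a single merged set.

## Core methods

**Agreement** is micro-averaged F1 with one annotator taken as gold:
true/false positives are pooled over shared documents, with
maximum-cardinality bipartite matching resolving overlap ambiguity.
Mentions compare under an *exact* (identical fragments) or *approximate*
(any overlap) criterion; frames under four variants crossing
{full, core} × {trigger, type}, where *core* compares only trigger/type +
THEME and *_type* ignores the trigger mention entirely.

**Confidence estimation** treats every distinct annotation proposition as
an item with present/absent responses per annotator and fits a MACE-style
item-response model by EM: item *i* has latent truth `T_i ~ Bernoulli(π)`;
annotator *j* copies `T_i` with competence `c_j`, else emits a label from
their own spamming distribution `s_j`. The posterior `P(T_i = present | Y)`
is the item's confidence.

**Merging** policies: `AGREE` (unanimous items only), `IAA_RANK` (the
full set of whichever annotator agrees better with others), and
confidence thresholding (accept unanimous items, then disputed items whose
confidence exceeds their semantic class's mean, in dependency order so no
frame is kept without its trigger and arguments).

## Worked example

```python
from chqakit import load_scheme, parse_standoff, validate_question

scheme = load_scheme("chqa-email")
text = (
    "pls guide us . recently we found she has ACTIVE LUNG TB . "
    "so what we have to do for her ? is this contages ? "
    "who is the pople staying with her need to do test ?"
)
ann = """T1\tPROBLEM 41 55\tACTIVE LUNG TB
T2\tTREATMENT 77 79\tdo
T3\tSUSCEPTIBILITY 98 106\tcontages
T4\tDIAGNOSIS 154 158\ttest
E1\tTREATMENT:T2 THEME:T1
E2\tSUSCEPTIBILITY:T3 THEME:T1
E3\tDIAGNOSIS:T4 THEME:T1
A1\tTopic T1"""

doc = parse_standoff(text, ann, scheme, doc_id="tb")
print(len(doc.frames), sorted(doc.frame_qtype(f) for f in doc.frames))
print(len(validate_question(doc, scheme)))
```

prints

```
3 ['DIAGNOSIS', 'SUSCEPTIBILITY', 'TREATMENT']
0
```

— the question decomposes into three frames (what to *do* about the
disease, whether it is contagious, who should be tested), all sharing the
PROBLEM entity *ACTIVE LUNG TB* as THEME and topic, and the document is
valid under the email scheme (zero violations).

The same pipeline scales to corpora from the command line:

```bash
chqakit simulate --scheme chqa-email --n-questions 50 --seed 7 \
    --annotator a1:0.95:0.2:1:0.02 --annotator a2:0.8:0.6:1:0.08 --out work/
chqakit agree work/ --annotators a1,a2 --layer frame --variant core_type --out work/reports
chqakit merge work/ --annotators a1,a2 --method confidence --seed 13 --out work/merged
```

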