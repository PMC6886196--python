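# Methods

## Problem and scope

Pelvic ultrasound reports describe the uterus, both ovaries, and adjacent
structures in dictated prose. The package determines, per report, whether
polycystic ovary morphology (PCOM) is *present*, *absent*, or
*unidentifiable from the text*, following the volume arm of the 2003
Rotterdam Consensus Criteria: an ovary is polycystic-appearing if its
volume exceeds 10 ml without a confounding structure, or if the radiologist
describes the classical appearance outright. Follicle counting — the other
Rotterdam arm — is out of scope: antral follicle counts are rarely dictated
as numbers, and this package never sees the images.

## Text preprocessing

Cleaning lowercases, maps unicode spaces and `×` to ASCII, strips irregular
characters and all punctuation except what measurements and sentence
boundaries need (`.`, `-`, `/`, `x` between digits, and `.!?;`), and
collapses whitespace. Cleaning is idempotent. Sentences are split on
`. ! ? ;` followed by whitespace or end-of-string, so a decimal point never
ends a sentence; dictated radiology prose is terse enough that a trained
segmenter would add nondeterminism without accuracy.

Tokens are whitespace-delimited; stopwords are removed *before* stemming,
using a Snowball-style English list shipped with the package. The list
deliberately excludes `left`, `right`, `no`, `not`, `nor`, and `both` —
laterality and negation are meaningful here — and the loader enforces those
exclusions on user-supplied lists too. Numerals are preserved: volume
extraction depends on them.

Stemming uses the Snowball (Porter2) English algorithm, implemented in
`pcomtext._snowball` directly from the published algorithm definition
(regions R1/R2, steps 0–5, exceptional forms) and verified against
hand-derived vectors. One domain merge is applied after stemming:
`ovarian → ovari`. The genuine algorithm maps `ovary` and `ovaries` to
`ovari` but leaves `ovarian` intact (it carries no removable suffix), and
ovary detection must treat the noun and its adjective as one term. The raw
stemmer stays faithful; the merge lives in `textprep.stem_token`.

Two parallel representations flow downstream: the cleaned, *unstemmed*
sentence text (measurement extraction would be destroyed by stemming) and
the stemmed, stopword-free token sentences (term counting; n-grams never
cross sentence boundaries).

## Contextualization

Only sentences whose tokens contain the ovary stem, plus each immediately
following sentence, survive; uterus and kidney descriptions are discarded.
Laterality: a sentence with exactly one of `left`/`right` joins that side's
document; both cues, plural `ovaries`/`both`, or no cue duplicate the
sentence into both documents. A follower sentence without its own cue
inherits the side(s) of the ovary sentence it follows (follower sentences
elaborate the same organ); a follower that itself names the other side
starts its own context. `adnexa`/`adnexal` is not treated as an ovary
mention. Every report yields exactly two ovary documents, possibly with
`mention_found=False` and empty text, so downstream labeling can emit
*unidentifiable*.

## Volume extraction

A measurement is 1–3 positive decimals joined by `x` (optional spaces) with
an optional trailing unit (`cm`, `mm`, `cc`, `ml`). Bare numbers without a
unit are not measurements; `cc`/`ml` matches are stated volumes, not
diameters, and are skipped rather than re-derived. Explicit `mm` divides by
10; with no unit, any dimension ≥ 8 is read as mm (an ovary 8 cm along any
axis is implausible as a routine cm entry; threshold configurable).
Three diameters give V = d₁·d₂·d₃·π/6 ml. When several 3-D tuples occur in
one ovary document, the first tuple inside an ovary-mentioning sentence
wins, else the first tuple anywhere: radiologists state the organ
measurement before internal structures, and taking the maximum would
conflate cyst size with ovarian size. 1-/2-D-only measurements yield no
volume. Rounding to 2 decimals happens only at the reporting boundary; the
10 ml comparison uses the unrounded value. A garbled measurement (`3.x4x5`)
matches nothing and yields no volume — the intended degradation for
dictation typos.

## Term mining and the curated lists

The per-ovary documents form a corpus; a sparse document-term matrix over
stemmed n-grams is its frequency table. Candidate *volume confounders* are
2-/3-grams whose binary occurrence correlates (Pearson, on indicators) with
the large-volume indicator (> 10 ml) across documents with volumes;
candidate *PCOM descriptors* are n-grams correlating with seed phrases
("numerous peripheral follicles", "polycystic ovarian", "string of pearls",
"ovarian syndrome"). Unigrams are excluded from confounder mining to reduce
variance. Score threshold 0.1 and minimum document frequency 5 are
defaults, not dogma; constant columns score 0. Mining writes a review file
— curation is a human step — and the package ships a small curated default
list containing the canonical confounders (dominant follicle, corpus
luteum, dermoid, hemorrhagic/simple/complex cyst) and PCOM phrases, all
stemmed. Term hits are contiguous stemmed token runs within a sentence.

## Rule engine

Per ovary, first match wins:

| # | condition | label | reason code |
|---|-----------|-------|-------------|
| 1 | PCOM phrase in document | present | `PHRASE` |
| 2 | no ovary mention / no volume | unidentifiable | `NO_MENTION` / `NO_VOLUME` |
| 3 | V > 10 ml and confounder | unidentifiable | `CONFOUNDED` |
| 4 | V > 10 ml | present | `VOL_GT_CUTOFF_NO_CONFOUNDER` |
| 5 | V ≤ 10 ml | absent | `VOL_LE_CUTOFF` |

The phrase rule outranks the confounder rule: an explicit statement of
classical PCOM appearance is sufficient on its own. The cutoff is strict
(`> 10` present, `≤ 10` absent). Confounders are searched in the whole
ovary document, not just the measured sentence, because follower sentences
carry the cyst descriptions. Report label: present > unidentifiable >
absent; *(absent, unidentifiable)* aggregates to unidentifiable because
PCOM in an unassessed ovary cannot be excluded. This rule table is a
reconstruction from the criteria's prose definition, made explicit here;
an exhaustive truth-table oracle in the tests pins it down.

## Boosted trees

The GBT path deliberately skips contextualization: each whole report is one
document, and all 1-/2-/3-grams (minimum document frequency 2) become count
features without human selection — testing whether bilaterality and
phrasing can be *learned*. The two extracted volumes join as numeric
features `eval_left`/`eval_right`; missing volumes are passed as missing
(XGBoost's native handling), never imputed to 0, which would be a concrete
(impossible) volume. Hyperparameters are pinned rather than left to
library defaults that drift across versions: `eta` 0.3, `max_depth` 6,
softmax multiclass objective, `hist` tree method, one thread. Only the
round count is selected, by stratified seeded 5-fold CV minimizing
multiclass error rate (the error metric is config-exposed), ties broken
toward fewer rounds; ceiling 400 rounds.

## Evaluation statistics

Confusion matrices have rows = truth (or rater A) and columns = prediction.
Accuracy CIs are exact Clopper–Pearson (beta-quantile) intervals — the
method that reproduces published bounds of this kind where Wilson does not.
One-vs-rest collapse gives sensitivity, specificity, PPV and NPV per class;
zero-denominator ratios are reported as NaN, never silently 0. Cohen's
kappa is computed from the cross-tab definition ((Po − Pe)/(1 − Pe)) and
cross-checked against scikit-learn in the tests. Marginal percentages round
half-up to 1 decimal, kappa is reported to 4.

## Synthetic corpus generator

No public corpus of pelvic ultrasound reports exists, so experiments run on
generated ones. Each report draws an overall class from the mixture
(default 0.44 / 0.32 / 0.24 absent / unidentifiable / present, the marginal
prevalences reported for a large urban safety-net hospital population),
assigns compatible per-ovary targets, and renders: a uterus lead sentence
(sometimes with its own 3-D measurement, as a distractor), right then left
ovary sentences, and a kidney/free-fluid tail. Measured ovaries get
1-decimal diameters rejection-sampled so the ellipsoid volume lands on the
correct side of the 10 ml cutoff with margin; normal and enlarged diameter
ranges overlap substantially (1.8–4.0 vs 2.4–5.2 cm) so that single
diameters — and hence single number tokens — do not separate the classes;
only the product does. 20% of measurements are dictated in integer mm, 10%
without a unit (values chosen so the mm-inference rule resolves them
correctly). Present ovaries split between phrase descriptions and
large-volume measurements (50/50); unidentifiable ovaries among
confounded-large (0.3), unmentioned-or-not-visualized (0.3), 2-D-only
(0.2) and garbled-measurement (0.2) arms.

Truth is fixed by construction *before* text noise: every record carries a
generation trace (dims, flags, mention), and re-running the rule engine on
the trace must reproduce the truth — a tested invariant. The global
`p_typo` (default 0.03) then corrupts the measurement text of an otherwise
measured ovary without changing its truth, emulating dictation
transcription noise; this is the knob that degrades classifier accuracy
monotonically. At the defaults, rule-based accuracy sits in the mid-90s,
matching the regime the method reports on real text; on the noiseless
configuration it is exactly 100%, which validates the pipeline, not the
method's real-world accuracy.

What the generator does **not** emulate: temporal language ("previously
seen cyst"), negated findings, coreference beyond the follower-sentence
pattern, spelling errors outside measurements, impressions/billing
boilerplate, and institution-specific template drift. Passing tests on
synthetic text therefore demonstrate internal consistency and noise
robustness of the documented kinds, not performance on any particular
hospital's reports.

## Problem sizes and numerical choices

The shipped experiments use 1,000-report evaluation corpora and a
2,000-train / 1,000-test split for the boosted trees, with a 60-round CV
ceiling — sizes at which every quantity in `scripts/acceptance.py` is
stable to well under a percentage point across seeds. All randomness flows
from a single integer seed through `numpy`'s `default_rng`; classification
itself is fully deterministic. Sub-seeds derived for each stage stay below
2³¹.

## Known limitations

- The stemmer's domain merge (`ovarian → ovari`) is a deliberate deviation
  from pure Porter2, required for ovary detection.
- Sentence spans index the *cleaned* text, not the raw input.
- The unit-inference threshold (8) misreads a genuinely 8+ cm unitless
  measurement as mm; such entries are vanishingly rare and usually
  pathological masses, not ovaries.
- The rule engine has no notion of time or negation: "no longer seen" and
  "previously noted" confound it exactly as they do in the underlying
  method.
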