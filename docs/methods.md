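# Methods

This note records the models, the synthetic-data design, the numerical
conventions, and the open design choices made while building `vcase`.

## Segmentation model

Sentences are sequences of atomic symbols from a finite alphabet; a word
is a short symbol sequence. This abstraction targets scripts without word
delimiters (the motivating setting is Chinese clinical narrative); the
test and fixture alphabets are lowercase letters, which exercise exactly
the same code paths.

The segmentation probability model is a unigram language model: a
segmentation `w_1..w_k` scores `Σ log(f(w_i)/N)` where `f` is lexicon
frequency and `N` the lexicon total. The word graph contains an edge
`(i, j)` whenever `sentence[i:j]` is a lexicon word, plus the always-legal
single-symbol edge, so a full path always exists. The DP runs
right-to-left; `best[i]` combines the edge score with `best[j]`.
Numerical conventions:

* **OOV floor.** A single symbol outside the lexicon scores
  `log(floor/N)` with `floor = 1e-3`, so any dictionary word
  (frequency ≥ 1) strictly beats an OOV symbol. The floor is a parameter
  of `max_prob_segment`/`segment`.
* **Tie-breaks.** On equal score, fewer tokens win; on equal token count,
  the lexicographically smallest boundary tuple wins. Segmentation is
  therefore a deterministic function of (sentence, lexicon).
* **Rule spans.** Anchored regexes for durations, dates, measurements,
  ranges and bare numbers are matched first and frozen as single tokens;
  overlaps resolve to the earliest start, then the longest match, then
  rule-file order.

## Unknown-word HMM

The BMES tagging HMM is supervised: maximum-likelihood counts from a
tagged corpus with additive smoothing (default 1.0). Transition smoothing
is applied only over each state's legal successors (B→{M,E}, M→{M,E},
E→{B,S}, S→{B,S}); illegal transitions and illegal initial states (M, E)
stay at −∞, so every decoded sequence parses into complete words.
Emissions are smoothed over the observed alphabet plus one unseen-symbol
bucket per state, keeping each distribution normalised to 1 (checked to
1e−9 in tests). Viterbi constrains the terminal state to {E, S} and
breaks ties by the fixed state order B < M < E < S.

Within the full pipeline, dictionary matches are frozen first and only
maximal runs of single-symbol OOV fallback tokens are re-decoded by the
HMM (the jieba-style convention). The alternative — a global joint decode
over dictionary and character model — is noted as unimplemented.
Misspellings are deliberately not corrected; they surface as OOV tokens
for a human reviewer.

## Synonym vectors

The word-vector model is a count-based embedding: a symmetric windowed
co-occurrence matrix, positive pointwise mutual information, truncated
SVD, vectors `U·√S`. The matching contract only requires that words with
shared contexts be cosine-close and that lookup of the cosine-nearest
standard term behave correctly; the count-based route satisfies it
deterministically (SVD signs are fixed by forcing each component's
largest-magnitude loading positive; a 1e−9 seeded jitter removes exact
zero vectors). A token is replaced by its nearest standard term only when
cosine similarity ≥ 0.7 (configurable); out-of-vocabulary tokens pass
through unchanged.

## Question routing

Distance is token-level Levenshtein with unit costs — token-level because
synonym conversion operates on whole tokens and symbol-level distance
would undo it. The routing partition is total: `d = 0` exact, `0 < d < 5`
candidates (all questions under the cutoff, sorted by distance then
question id), `d ≥ 5` deviation. The source description of the middle
band excludes `d = 1` and `d = 5`; closing the gaps this way is a
deliberate choice so every input has exactly one outcome. The candidate
set includes *all* questions under the cutoff rather than a top-k, and
negation annotation is carried as metadata rather than entering the
distance. The deviation message string is part of the contract.

## Matching rate and case building

"Matching rate" is defined as the fraction of standard questions for
which some narrative clause (split on clause punctuation) normalises to
within the routing cutoff of the question's canonical tokens. It is the
quantity compared against the 90% review gate, and is computed against
the disease-template-specific question library. De-identification
replaces each configured field value by a `*` run of equal length and
scrubs every occurrence of the value from all text in the record; no
mapping is retained. Release is a one-way state machine
(draft → under_review → released) and is refused while a leak scan still
finds any original PII value. Difficulty levels: L2 injects
`ceil(0.30 · n_questions)` distractors sampled (seeded) from a cross-case
pool and marks them not-indicated with zero weight; L3 converts items at
or above the 75th weight percentile to free entry; L4 converts every
scoring item. The simple/moderate/complex case class is teacher-assigned
metadata, not computed.

## Sessions and scoring

Sessions are event-sourced: the log is the source of truth and replaying
it through the same case and pipeline reconstructs the state exactly
(property-tested across competence levels). Selections use set semantics,
so repeated asks or selections are idempotent. Auxiliary-examination
questions are scored with the physical examinations: the rubric's five
categories are inquiries, physical examinations, diagnoses, diagnosis
bases and treatments, and auxiliary items belong with the examinations.

Indicator conventions:

* The logic formula's first terms are read as *correct* inquiries/
  examinations selected; with misses subtracted the numerator can go
  negative, so it is clamped at 0 (and the result capped at 100). Without
  the clamp the score would leave [0, 100] whenever misses outnumber
  hits. The narrative reading of "logic" as order compliance has no term
  in the formula; an order-violation penalty is left unimplemented.
* A category with no correct items scores 100 (vacuously complete) and
  logs the fact; absent categories thus never penalise.
* Total = unweighted mean of the five indicators.
* Times are seconds; the recommended completion time is case metadata.

## Synthetic-data design

The generators define the test conditions:

* **Lexicons** — distinct words of length 1–4, Zipf frequencies
  (`max(1, round(1000/r^s))`, exponent 1.0 by default).
* **Tagged corpora** — 3–8 word tokens per sentence drawn by frequency,
  OOV words injected at a configurable rate with ground-truth flags.
* **Reference HMMs** — transitions from seeded Dirichlet draws over the
  legal successors; each state emits ~95% of its mass from its own
  quarter of the alphabet. The structured emissions mirror the real
  phenomenon that word-initial and word-final characters distribute
  differently, and make the states identifiable — the regime in which
  training on samples from the model recovers its transition matrix
  (L∞ well under 0.05 at 10k sentences) and held-out boundary F1 sits
  around 0.96–0.99.
* **Question libraries** — canonical sequences of 5–8 fixed-length
  (3-symbol) words. Two structural guarantees are enforced at generation
  time: display texts round-trip through segmentation (all words the same
  length makes alternative full-dictionary parses impossible), and
  questions are redrawn until pairwise distances reach the routing
  cutoff, so an answer clause can never match a different question —
  mirroring a curated library of distinct standard questions.
* **Source records** — `ceil(coverage · |library|)` answer clauses spread
  over narrative sections, plus populated PII fields whose values are
  additionally embedded in the narrative so the leak scan is tested on
  free text. Two built-in disease templates (inguinal hernia, upper
  gastrointestinal hemorrhage) supply diagnoses with ICD codes, weighted
  bases and treatments, and recommended times.
* **Simulated students** — each correct item selected independently with
  probability = competence; each not-indicated item with probability
  `0.3·(1 − competence)` (zero for a perfect student); completion time
  `T_rec · (2 − competence)` with lognormal noise (σ = 0.1; σ = 0 gives
  the exact scaled time).

What the generators do *not* emulate: realistic clinical prose,
inter-item correlations in student behaviour, spelling errors, or corpus
statistics of any real record collection. Passing tests therefore
demonstrate the correctness of the algorithms and contracts on
well-specified synthetic conditions, not performance on real clinical
text.

## Problem sizes

The default test and acceptance runs use: 500-sentence oracle sweeps for
the segmentation DP (length ≤ 12) and Viterbi (length ≤ 6, against full
enumeration), 10k training sentences for HMM recovery, 200 records for
the leak scan, 20-question libraries for the gate checks (the smallest
size at which coverages 0.90 and 0.85 fall on opposite sides of the
gate), 1000 fuzzed sessions for indicator bounds, and 30-student cohorts
for the direction-of-effect comparison. These sizes were chosen to give
stable statistics while keeping a full run in seconds.

## Known limitations

* Only the HMM unknown-word model is implemented; CRF/MEM comparisons
  would need new models (boundary precision/recall/F1 utilities are
  provided so such a comparison could reuse the evaluation).
* Dictionary-first reconciliation between the DP path and the HMM is a
  convention, not an optimum.
* Diagnosis and free-entry grading match normalised labels/ICD codes
  exactly; fuzzy diagnosis matching is not implemented.
* The CLI plays sessions in scripted (simulated-trace) mode only;
  interactive play is done programmatically through the session API
  (`ask`, `confirm_candidate`, `submit_diagnosis`, …), not via a shell
  REPL.
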