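# Methods

This note documents the models and procedures implemented in `adrmine`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data results do and do not show.

## Text representation and matching

All matching is case- and diacritics-insensitive. The folding function is
length-preserving (each character maps to exactly one character:
`ë → e`, `A → a`), so offsets found in folded text address the original
text directly. Character offsets are 0-based half-open everywhere.

Segmentation is deliberately simple and lossless: paragraphs split on
blank lines, sentences on `.!?` followed by whitespace, with separators
attached to the preceding segment so that segments partition the text and
concatenation reconstructs it exactly. Clinical notes are telegraphic;
nothing downstream depends on linguistically perfect sentence boundaries,
only on stable, reproducible proximity units.

Dictionary lookup is longest-match: surface forms are matched with
token-boundary checks, longer alternatives tried first, non-overlapping
per mention kind (drug / reaction term / trigger). Multi-word surfaces
tolerate flexible internal whitespace.

## Candidate assembly

Five independently switchable strategies fire per paragraph (S1 drug +
reaction term in the same sentence; S2 causal trigger with drug and term
in the proximity window; S3 term + causal trigger, drug from the nearest
preceding drug mention in the paragraph; S4 allergy label adjacent to a
drug, with an unspecified-hypersensitivity code when no reaction term is
nearby; S5 discontinuation trigger + drug + term in one paragraph). The
strategy inventory is this package's concrete rendering of a rule family
described only by citation in the source literature, so each strategy is
a toggle and ablation is testable. When several fire for one pair, the
lowest-numbered one is recorded.

Parameters, with defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| `proximity_window` | 250 chars | association is paragraph-bounded in practice; 250 chars ≈ 2–3 clinical sentences |
| `allergy_adjacency` | 30 chars | allergy labels are written tight against the drug ("Allergie: penicilline") |
| `re_adr_gap_days` | 30 days | occurrences ≤ 30 days apart are one episode; beyond that, a recurrence is suspected |
| `hypersensitivity_code` | `T_HYPERSENS` | code assigned to bare allergy labels |

Counting rules mirror manual-review conventions: a reaction phrase that
resolves to *k* distinct term codes (conjunction/comma-joined symptoms)
yields *k* candidates; a combination-drug construction
("metoprolol/ hydrochloorthiazide") stays one candidate carrying all
ingredient ids.

No general negation or speculation detection is implemented; the
validated configuration of this pipeline family has none, and its
moderate precision reflects that. The only precision mechanisms are three
named false-positive filters, all **off** by default: refusal (a refusal
trigger in the candidate's context), switch (a configurable
drug-substitution pattern list), and indication (the reaction term is a
listed indication of the drug). Enabling a filter can only remove
candidates, so the unique-pADR count is monotone non-increasing in the
filter flags.

## Unique ADRs, duplicates and recurrences

The deduplication key is (patient, normalized ingredient set, term code);
the earliest date is kept and an audit trail links every unique ADR to
its contributing candidates. A recurrence (reADR) is a later episode of
the same key — occurrence dates clustered with a chained 30-day gap —
with an intervening drug mention (re-prescription signal) between the
episodes. The unique record keeps its first episode; each later episode
is reported as a separate recurrence event and excluded from the counts,
matching review-flow arithmetic in which total records = unique +
duplicates + recurrence records. The same episode logic reduces manual
annotation ledgers; planted flags on annotation records are informative
only and are always recomputed from dates.

## Causality and seriousness

Naranjo weights are bundled as an editable ten-item table (score range
−4 … 13) rather than hard-coded; the score is the weighted sum of ternary
answers, bands are definite ≥ 9 / probable 5–8 / possible 1–4 / doubtful
≤ 0, and inclusion requires score ≥ 1 (equivalently, any category other
than doubtful — the literature uses "certain" and "definite"
interchangeably for the top band). Seriousness is a pure membership test
of the term code against the loaded important-medical-events list, and is
stored on the reaction term at load time so the two views cannot diverge.

## Evaluation

Matching granularity is the unique-ADR key, not the text span: the unit
under study is "did both methods find this patient–drug–reaction", not
mention offsets. Drug attributions are compatible when their expanded
ingredient sets intersect, where a group id expands to itself plus its
member ingredients.

Matching is solved as an optimal assignment per (patient, term-code)
block rather than a single greedy pass. A greedy pass is not maximal
precisely in the case this domain produces — a group-level attribution
("opiates") compatible with several specific-drug records can absorb the
one record a specific-drug entry needed — and a maximal matching is the
natural reading of "concordance". Preferences among maximum matchings are
encoded as secondary weights: exact ingredient agreement first, then the
earliest predicted date, then input order; this keeps results
deterministic and agrees with exhaustive search on small instances (a
property test verifies this up to 8×8 blocks).

Proportions are computed unrounded and rounded only at presentation,
half-up (`percent(286/534) = 54`); the F-score is the harmonic mean of
the unrounded sensitivity and PPV, reported to two decimals. Empty
denominators are explicit errors (or `None` in reports), never silent
zeros; the degenerate s = p = 0 case defines F = 0 with a warning flag.
The portability threshold is strict: F > 0.6.

Cohen's κ is the standard chance-corrected agreement over a square
assessor table; degenerate marginals (chance agreement 1) are an explicit
undefined result. What counts as a shared negative universe for two
assessors is study-specific, so κ is offered as a general operation, not
wired to any particular pipeline stage. The group comparison is the
unpaired equal-variance t-test on per-patient F-scores scaled ×100;
patients with no gold and no predicted ADRs have no defined F and must be
excluded by the caller; the 95% CI of the mean difference is always
two-sided, while `tails=1` halves the p-value in the hypothesized
direction mean(a) > mean(b).

## Synthetic corpora

The generator's defaults are the study conditions, not tuning knobs:
62 patients (15/15/15/17 over CZE/JBZ × geriatric/orthopedic),
per-patient note counts log-normal with department medians 480
(geriatric) and 248 (orthopedic) truncated to the reported ranges
(99–1,720 and 70–670), words per note derived from the reported
per-patient word medians (21,626 and 6,861.5), a right-skewed unique-ADR
count per patient (hospital medians 6 and 3, capped at 30), a
duplicate-to-unique ratio of 234/455, a recurrence rate of 58/455 and a
serious fraction of 69/359. Only medians and ranges are calibrated; the
log-normal shape and the log-sd values (0.45 notes, 0.55 words, 0.8
ADRs) are the package's own choice to reproduce the skew. Confounder
rates default to 0.6 expected plants per patient and type, enough to make
filter efficacy measurable without dominating the corpus.

Filler text is drawn from a closed neutral vocabulary that is checked at
generation time against every lexicon surface form (a surface could only
arise in filler if all of its tokens were filler words, which is
rejected). Planted fragments are template instantiations placed as their
own paragraphs, which — because all strategies are paragraph-bounded —
guarantees plants cannot interfere with each other. The ledger is
therefore exhaustive: on an undegraded corpus, mined unique ADRs are a
subset of planted ADRs plus planted confounders, and plant recall is 1.0.

The optional degradation pass adds character-substitution misspellings
(edit distance 1, re-checked against the lexicon), abbreviation
substitution and paragraph shuffling, with the ledger annotating every
degraded plant and all spans updated.

**What passing synthetic tests shows — and does not.** The corpus
emulates data *volume*, planted-mention structure and the documented
false-positive patterns. It does not emulate real clinical language:
misspellings beyond edit distance 1, paraphrase, negation, temporal
reasoning, copy-forward text or list-formatted medication tables. Perfect
recall on clean synthetic text is a correctness statement about the
implementation (every planted surface is found and reduced to the right
key), not a performance claim about real EHRs, where this pipeline family
is known to trade precision for recall.

## Problem sizes

The default test suite generates corpora of 3–8 patients for unit-level
checks and one full 62-patient corpus (~23,000–25,000 notes, ~0.75 M
words) for the end-to-end property test; the full chain (generate, mine,
evaluate) completes in a few seconds on one core.

## Known limitations

- Dictionary matching cannot find reactions phrased outside the term
  dictionary; the bundled toy vocabularies are illustrative only.
- Drug attribution for trigger-only associations (S3) is a nearest-
  preceding heuristic and will mis-attribute in dense polypharmacy
  paragraphs.
- The recurrence rule needs an intervening drug mention; recurrences
  documented without one are merged as duplicates.
- Specialty is free text; no controlled specialty vocabulary is imposed.
- No negation/experiencer/temporality handling by design (see above).
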