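# adrmine

Rule-based mining of **potential adverse drug reactions (pADRs)** from
free-text electronic health record (EHR) notes, with Naranjo causality
scoring, an evaluation harness for portability studies, and a seeded
synthetic-corpus generator with a known gold standard.

Most ADRs in hospital EHRs live in free text (consultations, nursing
reports, medical history) rather than in the structured ADR module, which
defeats automated re-prescription alerts. `adrmine` implements a
dictionary-and-trigger pipeline of the kind used in Dutch hospital
pharmacovigilance: drug surface forms (generic, trade, group names and
synonyms), a coded reaction-term dictionary with synonyms, and trigger
words (causal links, allergy labels, discontinuation, refusal) are matched
in note text; proximity strategies assemble candidate drug–reaction pairs;
counting rules and deduplication reduce them to **unique ADRs** — the
(patient, drug ingredient(s), coded reaction term) triples that every
metric counts. It is aimed at clinical pharmacists and researchers who
want to study such pipelines, their failure modes and their portability
without access to patient data.

## The statistics at the core

A predicted set *P* is compared with a reference set *G* (typically manual
chart review) by one-to-one matching on the unique-ADR key; synonyms
("hives" vs "urticaria") collapse to one term code at dictionary-lookup
time, and group-level drug attributions ("opiates") are compatible with
their member ingredients. With TP matched pairs, FP = |P| − TP and
FN = |G| − TP:

    sensitivity = TP / (TP + FN)
    PPV         = TP / (TP + FP)
    F           = 2·s·p / (s + p)

with portability judged acceptable when F > 0.6. The harness also provides
stratified reports with Venn triples (concordant, algorithm-only,
manual-only), Cohen's κ for inter-annotator agreement, and the unpaired
two-sample t-test (one- or two-tailed) for comparing per-patient F-scores
between hospitals or departments. Causality per ADR is scored with the
ten-item Naranjo questionnaire (weights bundled as an editable table):
doubtful ≤ 0, possible 1–4, probable 5–8, definite ≥ 9; only ADRs scoring
≥ 1 are included.

## Worked example

Generate a synthetic two-hospital corpus (62 patients at realistic EHR
volume, with planted ADRs, duplicates, recurrences and the three classic
false-positive patterns), mine it, and evaluate against the generator's
gold ledger:

```sh
adrmine simulate --out-dir sim --seed 5
adrmine mine --corpus sim/corpus.jsonl --out-dir mined
adrmine evaluate --gold sim/gold_unique.jsonl \
                 --pred mined/unique_padrs.jsonl \
                 --out-dir eval --strata strata.json
```

which prints (strata.json maps each patient to their hospital):

```
wrote 23304 notes, 301 planted ADRs, 125 confounders to sim
...
unique: 426
re_adr_events: 28
        Total           CZE             JBZ
F-score 0.83            0.84            0.82
Sensitivity (%) 301/301 (100)   166/166 (100)   135/135 (100)
PPV (%) 301/426 (71)    166/230 (72)    135/196 (69)
```

Every planted ADR is recovered (sensitivity 100% on clean synthetic text —
the plants use exact lexicon surface forms), and all 125 false positives
are the planted confounders. Re-running `mine` with the three proposed
false-positive filters enabled (`--filter-refusal --filter-switch
--filter-indication`) rejects exactly those 125 candidates and drives PPV
to 100% on this corpus; on real text the filters would also cost recall,
which is why they default to off. The 28 `re_adr_events` are recurrences
of an already-recorded ADR after an intervening re-prescription signal;
they are reported separately and never counted twice.

The same components are available as a library:

```python
from adrmine import lexicons, miner, evaluation

lex = lexicons.load_bundled()
result = miner.mine_corpus(notes, lex)              # unique pADRs + audit trail
matching = evaluation.match(gold, result.unique, lex.drugs)
print(evaluation.report(matching).to_dict())
```

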