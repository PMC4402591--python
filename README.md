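# kdse — knowledge-driven drug–side-effect extraction

`kdse` extracts drug–side-effect (drug-SE) pairs from a sentence-segmented
biomedical corpus using *known* drug-SE associations as prior knowledge, and
compares this knowledge-driven (KD) strategy against a supervised SVM
sentence classifier.  It is aimed at pharmacovigilance and drug-repositioning
researchers who want to mine adverse-event co-mentions from literature-scale
text without hand-annotating training data.

## The method

Two empirical observations drive the design:

1. a drug's side effects tend to be reported several at a time in one
   sentence or abstract;
2. a sentence that contains one *known* drug-SE pair is very likely to be
   reporting side effects.

Given a drug lexicon, an SE lexicon and a knowledge base of known pairs
K ⊂ D × S, extraction proceeds in three steps over an inverted corpus index:

- **gate** — a text unit u (sentence or abstract) is SE-related iff it
  contains some (d, s) ∈ K, with the restriction that matched drug and SE
  strings are noun phrases;
- **enumerate** — within each SE-related unit, every co-occurring
  combination of matched drug ids × SE ids is a candidate pair, with
  per-unit support counts;
- **report** — candidates not already in K are the novel extractions.

No classifier is trained: the knowledge base *is* the classifier, so an
updated knowledge base propagates to extraction immediately.  The SVM
baseline instead trains a polynomial-kernel SVM on TF-IDF bag-of-words
features (stopword removal, Porter stemming) over distantly labeled
sentences — positives contain a known pair, negatives are an equal-size
random sample — then extracts co-occurrences from positively classified
sentences.

Evaluation is per drug: each evaluated drug's known pairs are split in half,
the train half serves as prior knowledge (and distant labels), and precision
/ recall / F1 are computed against the held-out half, with unweighted column
means and the per-drug relative F1 increase

    ΔF1% = 100 · (F1_KD − F1_SVM) / F1_SVM.

A correlation module relates drug-drug *shared-SE* counts to shared gene
targets, metabolism genes, disease indications, and pairwise chemical
scores: for drug pairs sharing at least k SEs it reports the mean attribute
overlap |A(d1) ∩ A(d2)| or mean pairwise score as a function of the cutoff
k.

A synthetic-corpus generator produces corpora with the structure the method
assumes — multi-SE reporting sentences, confounding sentences in which a
drug co-occurs with SE-lexicon terms that are not its side effects, latent
drug classes that tie SE sharing to attribute sharing — so every component
is testable without any external download.

## Worked example

The packaged fixture corpus contains four single-sentence abstracts,
including one listing six toxicities of irinotecan and one in which an
erroneous knowledge-base pair ("ondansetron–pain", actually a treatment
relation) gates a sentence:

```python
from kdse import build_index, extract
from kdse.synthetic_corpus import paper_fixtures

bundle = paper_fixtures()
index = build_index(bundle.corpus, bundle.drugs, bundle.ses)
result = extract(index, bundle.prior, level="sentence")
for c in result.novel:
    print(f"{c.drug_id}\t{c.se_id}\t{c.count}")
```

prints

```
fentanyl	pain	1
irinotecan	anorexia	1
irinotecan	fatigue	1
irinotecan	nausea	1
irinotecan	neutropenia	1
irinotecan	thrombosis/embolism	1
lidocaine	pain	1
tramadol	pain	1
```

The five irinotecan pairs are correct novel extractions gated by the single
known pair irinotecan–diarrhea; the three `*–pain` pairs show how an error
in the knowledge base propagates into the output.  A title mentioning three
drugs but no known pair contributes nothing, and a 3-drugs × 3-SEs sentence
enumerates 9 candidates (resolving which 3 are real is out of scope).

The same pipeline runs from the shell:

```sh
kdse simulate --seed 7 --out demo/
kdse index --corpus demo/corpus.jsonl --drugs demo/drugs.tsv --ses demo/ses.tsv --out demo/index.bin
kdse extract --index demo/index.bin --prior demo/prior_pairs.tsv --level sentence --out demo/pairs.tsv
```

which reports `indexed 200 abstracts / 1800 sentences` and
`kd/sentence: 357 candidates, 177 novel -> demo/pairs.tsv`.

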