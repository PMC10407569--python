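# mirlit

Text mining of the miRNA literature, built for desk-scale reanalysis of how
microRNAs are studied in a disease area (the motivating case is diabetes
mellitus). Starting from already-downloaded literature exports, the package

- reads **MEDLINE flat files** and **PubTator annotation files** into a
  common corpus model and filters records by publication type,
- recognizes **miRNA mentions** with a nomenclature-aware regular expression
  and normalizes every surface variant (`miR-155`, `microRNA-155`, `miR155`,
  `hsa-miR-155-5p`, …) to a core name (`miR-155`), counting each core at
  most once per document,
- fits **LDA topic models** on abstracts and derives topic-by-year and
  miRNA-by-topic association matrices,
- classifies documents as case vs. control from **binary miRNA-presence
  features** with four model families (Bernoulli naive Bayes, decision tree,
  random forest, and an SVM with C=10, gamma="scale", kernel="sigmoid"),
  reporting accuracy, recall, precision, MCC, F-score, ROC/AUC and
  **permutation feature importance**,
- builds **gene co-mention matrices** for a chosen miRNA, intersects them
  with a predicted-target list (TargetScan-style TSV), and runs local
  **hypergeometric over-representation analysis** against GMT gene sets with
  Benjamini–Hochberg adjustment,
- and ships a **synthetic corpus generator** with planted topics,
  class-conditional miRNA frequencies, realistic surface-form variation and
  full ground truth, so the entire pipeline is testable without downloads.

## The statistics at the core

Classification metrics follow the usual confusion-matrix definitions:
accuracy = (TP+TN)/N, recall = TP/(TP+FN), precision = TP/(TP+FP),
F = 2PR/(P+R), MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), and
AUC equals the probability that a random positive outscores a random
negative (Mann–Whitney U / n₊n₋). Permutation importance of feature *f* is
the mean drop in held-out accuracy after shuffling column *f*. Pathway
enrichment uses the upper-tail hypergeometric probability
P(X ≥ k) with population |universe|, successes |set ∩ universe| and draws
|query|.

## Worked example

```python
import mirlit

# synthetic corpus: 1,000 case + 1,000 control documents, five miRNAs
# mentioned in 60% of cases vs 10% of controls
config = mirlit.SynthConfig(seed=1)
corpus, truth = mirlit.generate_corpus(config)
pos, neg = mirlit.split_by_label(corpus, truth)

matrix = mirlit.build_feature_matrix(mirlit.tag_corpus(pos), mirlit.tag_corpus(neg))
train, test = mirlit.holdout_split(matrix, mirlit.SplitConfig(test_fraction=0.3, seed=1))
model, predicted, scores = mirlit.fit_predict(
    mirlit.ClassifierConfig(model="SVM", seed=1), train, test
)
print("accuracy", round(float((predicted == test.labels).mean()), 4))
print(mirlit.permutation_importance(model, test, n_repeats=20, seed=1).head(5))
```

prints

```
accuracy 0.88
miR-903    0.064000
miR-905    0.062083
miR-901    0.054500
miR-902    0.046750
miR-904    0.043250
dtype: float64
```

The held-out accuracy is 0.88 on 600 test documents, and the five planted
signal miRNAs (`miR-901` … `miR-905`) head the permutation-importance
ranking — the pipeline recovers exactly the features that carry the
class signal. The same stages run from the shell via the `mirlit` command
(`mirlit simulate`, `mirlit tag`, `mirlit topics`, `mirlit classify`,
`mirlit network`; see `mirlit --help`).

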