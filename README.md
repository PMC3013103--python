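# psmvalid

Machine-learning validation of Sequest peptide–spectrum matches (PSMs),
with an interpretable boosted classifier and protein-level presence
probabilities.

## The problem

A tandem-MS database search (Sequest-style) returns, for every spectrum, a
ranked list of tentative peptide matches with correlation scores (XCorr,
deltaCn, Sp, …) that have no direct statistical interpretation. Filtering
them with fixed score cut-offs is either too conservative or too
permissive, so the standard practice is to *learn* which matches are
correct. `psmvalid` implements such a protocol for people who analyze
Sequest-style search results and want (a) validated PSMs, (b) a model they
can actually read, and (c) per-protein presence probabilities:

* **Features.** Each ranked candidate (all ten ranks per spectrum, since
  roughly a third of correct matches are not ranked first) becomes a
  25-dimensional instance: the Sequest scores; sequence/spectrum
  descriptors (tryptic termini NTT, peptide length, C-terminal residue
  code, mobile-proton class, mass-window peptide count, …); and
  dataset-global protein evidence. The **protein hit count**
  `PHC = −log10 P(X ≥ k)` with `X ~ Poisson(P·n/D)` asks how surprising it
  is to see `k` PSMs for a parent protein with `n` observable tryptic
  peptides, in a search of `P` instances against a database with `D`
  observable peptides; the **potential coverage ratio** (PCR) is the
  fraction of a protein's observable residues covered by matches; the
  **PTM percentage** flags matches that needed implausibly many
  modifications. `n` and `D` come from an in-silico tryptic digest of the
  FASTA database restricted to the instrument's mass window.
* **Classifier.** An alternating decision tree (ADTree): boosted additive
  rules whose margin is the sum of all prediction nodes an instance
  reaches; margin > 0 means "correct match". Nine boosting iterations give
  at most 19 prediction nodes — small enough to print and read.
* **Calibration.** A logistic (Platt-family) sigmoid fitted on held-out
  margins turns scores into probabilities `p(+|D_ij)`.
* **Protein inference.** A protein's presence probability is the
  conservative noisy-OR over its distinct peptides,
  `P = 1 − Π_i (1 − max_j p(+|D_ij))`, taking the maximum over repeated
  identifications of the same peptide (they are not independent).

A fully synthetic simulator generates labeled Sequest-like datasets
(database, spectra, ranked candidates with a ~4.7% positive fraction and
true hits clustered on a small "present" protein subset) so the entire
pipeline is testable without any external data.

## Worked example

Everything below runs from scratch in under a minute:

```sh
psmvalid simulate --out-dir data --seed 42 --n-proteins 300 --present-fraction 0.1
psmvalid split    --psms data/psms.tsv --train-out train.tsv --test-out test.tsv --seed 42
psmvalid features --fasta data/database.fasta --mgf data/spectra.mgf \
                  --psms train.tsv --out train_features.tsv
psmvalid features --fasta data/database.fasta --mgf data/spectra.mgf \
                  --psms test.tsv --out test_features.tsv
psmvalid train    --features train_features.tsv --out model.json --seed 42
psmvalid predict  --features test_features.tsv --model model.json --out predictions.tsv
psmvalid evaluate --predictions predictions.tsv --out metrics.tsv
psmvalid proteins --predictions predictions.tsv --psms test.tsv --out proteins.tsv
```

The evaluate step prints the held-out metrics:

```
accuracy = 0.97938
sensitivity = 0.74419
specificity = 0.99181
net_prediction = 0.86800
precision = 0.82759
auc = 0.98225
```

Accuracy and specificity are dominated by the ~95% negative instances;
sensitivity says that 74% of the planted correct matches were recovered at
the margin > 0 operating point, and the AUC summarizes ranking quality
over all thresholds. The trained model is a readable rule list
(`python -c "import psmvalid; m,_ = psmvalid.load_model('model.json'); print(psmvalid.export_tree(m))"`):

```
root: -1.5471
  [ion_fraction (1)] <= 0.265686
    yes: -0.6758
      ...
  [phc (7)] <= 0.338979
    yes: -0.6067
      ...
    no:  +0.2404
```

The parenthesized numbers are the discovery order of each base rule — an
indication of relative importance. Note that the protein hit count enters
the model on its own: a protein with more hits than chance predicts lends
positive evidence to *all* of its matches. The protein report
(`proteins.tsv`) lists each accession with its noisy-OR presence
probability, peptide counts, and its best-supported peptide:

```
accession   probability            n_distinct_peptides  n_psms  top_peptide    top_probability
SIM00128    0.9999999999890038     11                   19      AKFCMFESTQEPR  0.984320874100736
```

## Layout

| module | contents |
| --- | --- |
| `psmvalid.io_formats` | FASTA / MGF / PSM-TSV / pepXML readers and writers |
| `psmvalid.digest` | tryptic digestion, peptide masses, observable-peptide index |
| `psmvalid.features` | the 25-feature vector incl. PHC, PCR, PTM percentage |
| `psmvalid.adtree` | ADTree training, margins, JSON/DOT/text export |
| `psmvalid.calibrate` | logistic calibration of margins |
| `psmvalid.proteins` | noisy-OR protein presence probabilities |
| `psmvalid.evaluate` | confusion metrics, net prediction, ROC/AUC, PRC |
| `psmvalid.simulate` | synthetic search-result generator and benchmark |
| `psmvalid.cli` | the `psmvalid` command |

See `docs/methods.md` for the model details, defaults and limitations.
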