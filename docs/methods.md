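# Methods

## Instances and scope

The unit of classification is one peptide–spectrum match (PSM): one ranked
candidate peptide for one spectrum, carrying the Sequest scores, an
optional 0/1 label, and a link to exactly one parent protein. All ten
top-ranked candidates of each spectrum are kept as instances — a
substantial minority of correct matches are not ranked first, and
discarding them both loses signal and hides the hard cases. The package
validates existing search results; it is not a search engine, and it does
not re-implement comparison classifiers (boosted C4.5 variants, random
forests) — a generic margin-producing learner can be evaluated with the
same harness if desired.

## Digestion and the observable-peptide index

Trypsin cleaves C-terminal of K or R unless the next residue is P;
protein termini always count as valid boundaries. The digest enumerates
fully tryptic peptides with up to `max_missed_cleavages` internal missed
sites (default 2, a common search setting). A peptide is **observable** if
its monoisotopic mass — in the unmodified state or in some admissible
combination of the searched PTMs (at most 3 simultaneous modifications
are enumerated) — falls inside the instrument window, default
[600, 4000] Da (a typical MALDI-TOF/TOF acquisition range; both bounds
are configurable). Peptides containing the unknown residue X have no
defined mass and are excluded from the index.

Uniqueness is per protein by literal sequence: the same peptide in two
proteins contributes to both proteins' `n` and twice to the database
count `D`. This matches the sampling story behind PHC — every Sequest hit
is attributable to one specific parent protein. I/L ambiguity is ignored
(sequences compared literally).

NTT (tryptic-terminus count) uses the conventional encoding: 2 = fully
tryptic, 0 = neither terminus tryptic. Missed cleavages are a separate
concept and are never conflated with NTT.

Masses: residue monoisotopic masses from pyteomics; water 18.0105647 Da;
the MH+ convention adds a proton of 1.00728 Da. deltaMH is computed on
the MH+ scale. A missing MGF CHARGE defaults to 1+ (MALDI precursors are
predominantly singly charged).

## Features

25 features in a fixed, documented order (`features.FEATURE_NAMES`).

**Sequest group** — pass-throughs (xcorr, deltaCn, Sp, SpRank), the
matched-ion fraction, and deltaMH against the (modified) candidate mass.
Expert cut-offs (e.g. XCorr > 2.2) are never applied; they are what the
classifier learns.

**Published group** — NTT, peptide length, summed peak intensity, the
C-terminal residue code (Arg = 1, Lys = 2, other = 3), counts of database
peptides within ±3.0 Da of the candidate mass (the window is an artifact
default; configurable), and proline/arginine tallies. The mobile-proton
factor is the standard three-class convention (1 mobile if charge exceeds
the R+K+H count, 3 non-mobile if charge ≤ the R count, else 2 partially
mobile); treated, like the C-terminal code, as an ordered numeric feature
— a documented caveat of threshold-based splitting.

**Novel group** — spectral-quality statistics (intensity mean, population
standard deviation, peak count, and the five-bin histogram of intensities
normalized by the per-spectrum maximum — bins always sum to 1), plus the
three dataset-global evidence features:

* **PHC.** With `D` observable peptides database-wide, `n` from the
  parent protein, and `P` instances in the search result, the number of
  hits for the protein under random sampling is `X ~ Binomial(P, n/D)`,
  approximated by `Poisson(λ = P·n/D)` and reported in negative log10
  space. The default is the **upper tail** `−log10 P(X ≥ k)` — large PHC
  means more hits than chance predicts, which is the direction the
  learned trees use as positive evidence; a `lower` mode computes the
  literal k-or-fewer probability for comparison. Base 10 is a
  documented choice (it affects threshold readability, not ranking). The
  tail includes the boundary term at `k`. `k = 0` gives PHC = 0 in upper
  mode; `n = 0` with hits present is an error. `k` counts the protein's
  PSM instances over all ranks of the dataset being featurized (a
  rank-1-only mode exists but is not default), and `P` counts instances,
  not spectra. Because `n/D` and `P` normalize the calculation, models
  transfer across databases and search sizes — but PHC/PCR are
  *dataset-global*, so feature matrices must be computed per dataset
  (training and prediction sets separately), which the split utilities
  enforce at spectrum level.
* **PCR.** Residue-union coverage: the fraction of a protein's
  observable residues (union of all observable peptide spans on protein
  coordinates, so overlaps are not double-counted) covered by matched
  peptides. Matched peptides outside the observable set (semi-tryptic or
  out-of-window) are excluded with a logged warning.
* **PTM percentage.** 100 × modified residues / modifiable residues of
  the peptide (targets of any searched PTM); 0 when no residue is
  modifiable. A match that needs many of its possible modifications to
  explain the spectrum is suspect.

Instances with missing numeric Sequest fields are rejected, never
imputed.

## ADTree

Labels {0,1} map to {−1,+1}; instance weights start at 1. The root
prediction value is the smoothed prior log-odds
`0.5·ln((W⁺+ε)/(W⁻+ε))` and weights are immediately re-weighted by it.
Each boosting iteration searches every (prediction node, feature,
threshold-midpoint) triple and selects the minimizer of

    Z = 2·[√(W⁺(c∧s)·W⁻(c∧s)) + √(W⁺(c∧¬s)·W⁻(c∧¬s))] + W(¬c)

over the instances reaching the precondition `c`; the two new prediction
values are smoothed log-odds with ε (default 1.0, the classical
unnormalized-weights setting), and weights are multiplied by
`exp(−y·r(x))` for the new rule's contribution. Candidate thresholds are
midpoints between consecutive distinct feature values under the
precondition; ties in Z break toward the lowest node id, then feature
index, then threshold, so training is fully deterministic (the recorded
seed is provenance only). Preconditions range over *all* existing
prediction nodes (full ADTree search, not root-only stumps). The default
9 iterations yield at most 19 prediction nodes. An optional
class-balanced initialization (equal total weight per class) exists but
is off by default. Zero iterations produce the root-only prior
classifier; single-class input is an error whenever rules are to be
learned.

The margin of an instance is the root value plus the branch values of
every rule whose precondition node the instance reaches; `margin > 0`
(strictly) classifies as correct. Margins are exactly additive —
verified against an independent path-enumeration oracle. Models
serialize to JSON (lossless round-trip) and render as indented text or
Graphviz DOT with each splitter labelled "feature (discovery order)".

## Calibration

`p(+|m) = sigmoid(A·m + B)` fitted by maximum likelihood (L-BFGS-B with
analytic gradients; gradient tolerance 1e−10, cap 10⁴ iterations). The
fit should use margins from data not used to train the tree — the `train`
command holds out half of the spectra (configurable) for exactly this.
Plain {0,1} targets are the default; Platt's smoothed targets
((N⁺+1)/(N⁺+2), 1/(N⁻+2)) are available for small or separable samples.
On separated data the slope simply stops growing at the optimizer cap; no
divergence. The map is strictly monotone, so AUC is invariant under
calibration, and the MLE score equation makes the mean fitted probability
equal the positive fraction on the fitting set.

## Protein probabilities

`P(present) = 1 − Π_i (1 − max_j p_ij)` over distinct peptides `i` and
identifications `j`, computed in log1p space. The distinct-peptide key is
the bare sequence by default (modified and unmodified forms of one
sequence are repeated observations of the same molecule and take the
max); a sequence+modifications key is available. A peptide shared by two
accessions contributes to both proteins. No parsimony or minimal-set EM
step is applied, and charge state does not distinguish peptides (the
reference setting is MALDI, predominantly 1+).

## Evaluation

Confusion-based metrics use the strict `margin > 0` call (or probability
> 0.5 in calibrated mode): accuracy, sensitivity, specificity, precision,
and net prediction = (sensitivity + specificity)/2, the class-balance-
insensitive summary. Zero-denominator metrics are reported as NaN with an
explicit flag, never as 0 or 1. The ROC is the (1−specificity,
sensitivity) curve over all distinct-score thresholds with tied scores
grouped into one step; its trapezoidal area equals the pairwise rank-sum
statistic exactly. The PRC reports (recall, precision) over the same
sweep.

## The simulator

The generator reproduces the *structure* of the reference search at about
quarter scale, not MALDI physics:

* 1500 random proteins of 150–450 residues with K/R frequencies tuned so
  tryptic segments average ~9 residues (the reference database is far
  larger; what matters for PHC is that `D ≫` the per-protein hit counts,
  which this preserves: `D ≈ 10⁵` against ~10⁴ instances).
* ~60 "present" proteins (4%) receive Poisson-distributed true spectra,
  mean 8 — matching the reference ratio of ~2000 true PSMs over ~250
  sample proteins. Decoy-only spectra are added until positive instances
  are ~4.7% of the total (~1000 spectra × 10 candidates).
* True-candidate scores are a 0.66/0.34 mixture of a strong component
  (XCorr ~ N(3.0, 0.7), ion fraction ~ Beta(9, 11)) and a degraded one
  (XCorr ~ N(1.7, 0.5), ion fraction ~ Beta(4.5, 15.5)); decoys draw
  XCorr ~ N(1.5, 0.5), ion fraction ~ Beta(3, 17). Ranks follow the
  simulated XCorr ordering and deltaCn is computed from the XCorr gaps,
  so the true match lands at rank 1 about two thirds of the time —
  mirroring the reference observation that a third of true matches are
  not ranked first — without ever breaking rank/score consistency. The
  degraded component is deliberately hard on *all* match-quality scores:
  those are the instances only protein-level evidence can rescue, which
  is precisely the mechanism being tested.
* Decoy candidates are database peptides mass-matched to the precursor
  within ±1.5 Da (window doubled up to 4 times if empty, nearest-mass
  fallback); decoys carry a searched modification 35% of the time versus
  5% for true matches, giving the PTM-percentage feature its signal.
  True-spectrum precursors are the true peptide's MH+ ± 0.02 Da.
* Peak lists are Poisson-count peaks with lognormal intensities — they
  exist only to exercise the spectral-quality features, which are not
  expected to carry real signal here.
* `cluster_hits=False` spreads true spectra uniformly over all proteins,
  removing the PHC/PCR signal while leaving everything else unchanged;
  `null_features=True` routes *every* candidate through the decoy
  generator and labels a random one, a zero-signal null under which the
  pipeline must recover nothing (held-out AUC ≈ 0.5).

What passing the synthetic benchmark does and does not show: it
demonstrates that the implementation recovers a planted signal of
realistic shape and that the protein-evidence features add discriminatory
power exactly when true hits cluster on a small protein subset. It does
not certify performance numbers on real MALDI data — score distributions
there are not Gaussian/Beta, homologous proteins share peptides
non-randomly, and spectral quality varies in ways the peak-list model
ignores.

## Numerical choices and degenerate inputs

* PHC is computed via log-space Poisson survival functions throughout;
  no underflow for any realistic k.
* The Poisson approximation to the exact binomial tail is validated in
  the regime the protocol actually operates in (searches of thousands of
  instances, per-peptide sampling probability ≤ 0.01): agreement is
  within 0.01 log10 units there. For tiny searches (tens of instances)
  the approximation degrades; PHC is still well-defined but its absolute
  scale should not be compared across such regimes.
* Protein probabilities use log1p/expm1; a peptide with p = 1 short-
  circuits to probability 1.
* A protein with no cleavage sites digests to itself; an empty peptide
  or unknown residue is an error in mass computation.
* Feature matrices are sorted by (spectrum id, rank) before assembly, so
  construction is bit-exactly permutation-invariant.
* TSV round-trips use shortest-repr float formatting and are bit-exact.

## Problem sizes used by the test suite

The default test run trains on half of a ~1000-spectrum simulation
(~5000 instances, 25 features, 9 boosting iterations) and repeats this
over 10 seeds for the benchmark plus 6-seed ablation arms; the whole
suite completes in well under two minutes on one core. These sizes were
chosen as the smallest at which the PHC regime (`D ≫ k`) and the positive
fraction of the reference data are faithfully represented.

## Known limitations

* The ADTree treats ordered categorical codes (C-terminal residue,
  mobile-proton factor) as numeric thresholds.
* The observable index is fully tryptic; semi-tryptic matches are
  handled by NTT at the PSM level but do not enter `n`, `D` or PCR
  denominators.
* Calibration assumes a monotone margin–probability relationship; no
  isotonic fallback is provided.
* pepXML reading is a tolerant convenience, not a validator; pepXML and
  protXML writing, Mascot/X!Tandem dialects, and RAW/mzML input are out
  of scope.
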