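# Methods

## Potency scale and curation rules

All activities are carried internally in molar. IC50 measurements are
converted to inhibition constants by the standard half rule
Ki = IC50/2 and mapped to a free-energy-scale binding affinity
BA = 1.3633·log10(Ki) kcal/mol. Molar is the only unit convention
under which Ki = 0.1 μM lands on the −9.54 kcal/mol screening
threshold, so the parser owns unit normalisation (accepted unit
strings: nM, uM/μM/µM, M) and everything downstream is unit-free.

Replicate measurements of one molecule against one target are merged
by the geometric mean of their Ki-equivalents — the natural average
for log-scaled potencies; mixed IC50/Ki replicates are converted to
Ki before averaging. Records are ordered by canonical SMILES then
compound id before any split, so curation, fold assignment and
tie-breaking are deterministic. Dataset acceptance requires the
configured organism (default *Homo sapiens*), single-protein targets,
and at least `min_size` surviving compounds; the default of 250 is
inclusive (n ≥ 250), reading the minimum-data-size rule as a floor
rather than a strict bound, and is configurable through
`CurationCriteria`.

## Tokenization, masking and fingerprints

The SMILES tokenizer uses a fixed 51-symbol vocabulary: five special
markers (begin, end, pad, mask, unknown), six two-character symbols
(Cl, Br, Si, Se, Na, se), atoms and aromatic atoms, ring digits and
punctuation. Bracket atoms (`[...]`) are single units; units outside
the vocabulary map to the unknown token. Sequences are padded to a
fixed frame (default 256); over-length input raises rather than
truncating so features stay deterministic.

Masked-sequence corruption selects round(0.15 × eligible) positions
(round half up) among the valid non-special symbols and applies
mask/keep/replace with probabilities 0.8/0.1/0.1; replacements are
uniform over the non-special vocabulary (and may coincide with the
original symbol, as in standard masked-language-model practice).
Everything is driven by one `numpy` generator per call, so a seed
fully determines the corruption.

Fingerprints come from *providers*. Pretrained encoder networks
(transformer or sequence-to-sequence autoencoder embeddings) are
external artifacts consumed through `TableProvider` as CSV files of
precomputed vectors. The shipped `BaselineNgramProvider`
canonicalises the SMILES (RDKit), tokenizes it, and hashes token
n-grams (n = 1..3) into a signed, L2-normalised count vector (feature
hashing keyed by a seed; blake2b, so the map is stable across
processes). The default dimension is 512, matching the embedding
length the provider contract anticipates from external encoders; the
contract exposes the dimension, so 256-dimensional or other providers
coexist freely.

## Consensus models and cross-validation

Per target, one regressor is fitted per (provider × seed) pair with
seeds `base_seed + 0..n_seeds−1` (defaults: 2 providers × 10 seeds).
The consensus prediction averages members within a provider, then
across providers; it therefore always lies between the member
extremes. The default algorithm is an RBF support-vector regressor
with C = 10, ε = 0.1 and γ = 1/n_features; gradient-boosted trees and
random forests are available via `RegressorSpec`. Features are
standardised (zero mean, unit variance per coordinate) inside each
member: on raw L2-normalised fingerprints the fixed γ = 1/d kernel
width degenerates (all pairwise kernel values ≈ 1), while after
standardisation it is the classic "auto" width. Support-vector
regression is deterministic in the seed, so identical member slots
share one fitted estimator; predictions are bit-identical to fitting
each slot separately, only cheaper.

Model quality is summarised by k-fold cross-validation (default
k = 10, shuffled split with a recorded seed). Out-of-fold predictions
are pooled over the whole dataset and a single Pearson *R* and RMSD
are computed on the pooled vectors — pooled rather than per-fold
averaged, so the statistic is well defined for every fold size. The
pooled vectors are retained in the report so the correlation can be
re-derived independently.

## Cross-target matrix and screening semantics

Off-diagonal cell (i, j) of the cross-target matrix is the prediction
of model j over the compounds of dataset i with maximum absolute
value (ties broken by the dataset's deterministic compound order);
diagonal cells store each model's CV *R*. Side-effect classification
flags off-diagonal cells strictly below the −9.54 kcal/mol threshold;
the reported counts partition the *full* grid, diagonal included, so
that a 136×136 study partitions as 18,496 cells = flagged + remainder
— this matches how full-grid totals are conventionally quoted, while
the diagonal itself is never flagged (it is a correlation, not an
affinity). hERG is one more target dataset with its own stricter
threshold (−8.18 kcal/mol). All comparisons are strict; equality is
the safe side and is excluded from potency.

Repurposing candidates must be weak on their origin target by
*experimental* BA, predicted potent on the therapeutic target,
predicted clean on every other modeled target, and hERG-safe. Lead
reports conjoin five flags (potency, hERG, off-target, ADMET range,
SAS); the verdict is exactly the conjunction and every failed rule is
listed. Correlation between two models' predictions over one
compound set is reported as a binding-site-similarity *hypothesis*
only.

## ADMET/SAS screening

Property profiles are consumed, never predicted: the package screens
externally computed values (toxicity score, half-life,
bioavailability, logP, logS, logD, Caco-2 permeability, plus SAS)
against closed optimal-range intervals. Only the lipophilicity
windows logP [0, 3] and logD [1, 3] ship as defaults; other intervals
come from user configuration, and unconfigured properties are skipped
with a warning instead of silently passing. Boundaries are inclusive,
matching "0–3"-style printed ranges. Attrition is attributed to the
first failing rule in a fixed property order (SAS last), with full
per-property flags retained. The SAS cutoff defaults to 6 on the
1 (easy) to 10 (hard) scale — a deliberately loose filter.

## Networks

STRING-style edge lists are undirected and deduplicated keeping the
highest confidence; 0–1000 integer scores are auto-detected and
normalised to [0, 1]. Capping to 201 proteins proceeds greedily from
the seed gene: the node with the highest-confidence edge into the
retained set joins next, ties broken lexicographically. The true
selection rule of the upstream database export is not published;
greedy max-confidence expansion is this package's documented
stand-in. Merging reports the total node count with multiplicity and
the deduplicated union; curated datasets then attach as a bipartite
drug–target network with experimental BA on the links, exactly one
therapeutic target flagged, and hERG admitted from outside the PPI
pool.

## Synthetic worlds

The generator emulates the statistical structure the analysis
assumes. Targets are grouped into families; the therapeutic target
and hERG each form singleton families so that potency on one does not
force potency on the other. Each family is anchored by a prototype
molecule — a random hetero-atom chain over {C, N, O, S}, which is
always valid SMILES — and a dataset's compounds are token-level
mutants of their family prototype (0–14 substitutions/insertions/
deletions), so chemical similarity, and with it affinity, decays with
mutation count.

Compound latent vectors are tied to the SMILES string: a reference
sample of chains and mutants fixes a PCA-whitening map from baseline
n-gram fingerprints to a latent space (default dimension 64), and
ba_true(c, t) = ba0 − s·max(0, cos(u_c, t_vec)) with baseline
ba0 = −6 kcal/mol and span s = 6 kcal/mol, covering the −12…−6
kcal/mol range typical of inhibitor panels. Whitening makes the
latent cloud nearly isotropic, and family base directions are
orthogonalised, so unrelated compound–target alignments concentrate
near zero (spread ~1/√64): unrelated dataset/target pairs sit well
clear of the −9.54 threshold while same-family pairs are deeply
potent. Without these two steps the latent cloud is anisotropic and
stray mutants generate many margin-free borderline pairs, which makes
planted structure meaningless rather than merely hard. Target vectors
add a small jitter (0.25) to their family base, giving within-family
cosines ≈ 0.94 and a family-block side-effect structure.

Observed activities are ba_true plus Gaussian noise (default
sd 0.3 kcal/mol) and are written as alternating IC50 (nM) and Ki (μM)
rows — IC50 as exactly twice the Ki-equivalent — so ingestion
exercises the unit and conversion pipeline and reproduces the labels
to 1e-9. Planted truth (side-effect pairs, repurposable compounds,
clean leads) is derived by thresholding ba_true, never the noisy
observations. Repurposable compounds are planted as low-mutation
variants of the therapeutic prototype slipped into one cross-family
dataset; ADMET profile stubs give planted leads in-range
lipophilicity and easy SAS while other compounds draw from wide
distributions. A single seeded generator drives everything; the same
parameters and seed reproduce the world bit for bit.

What the generator does *not* emulate: realistic medicinal chemistry
(compounds are hetero-atom chains, not drug-like scaffolds), ChEMBL's
empirical affinity distribution beyond range and noise level, assay
heterogeneity, and activity cliffs sharper than the smooth latent
cosine surface. Passing recovery tests therefore demonstrates that
the pipeline's statistics and rule logic are correct and that the
models can learn a signal genuinely present in the fingerprints — not
that real screening data are this benign.

## Problem sizes and numerical choices

The standard study conditions used by the tests and the acceptance
script are 12 targets × 300 compounds at noise 0.3 kcal/mol — large
enough that 10-fold CV, the 144-cell cross matrix and the planted
flag structure are all non-trivial, small enough to run on a laptop
CPU in well under a minute. Under these conditions mean CV *R* is
≈ 0.95 (qualitatively mirroring the ≈ 0.79 reported for the
heterogeneous real datasets the workflow targets, which are far
noisier than the generator) and side-effect recovery is ≈ 1.0
sensitivity / ≥ 0.97 specificity. Noise-free recoverability is
benchmarked with labels *linear* in the fingerprint features at
n = 500, where pooled-CV *R* ≥ 0.99; the nonlinear hinge-cosine world
surface is deliberately not fully recoverable (CV *R* ≈ 0.95–0.97
noise-free).

Other numerical conventions: correlation is the plain product-moment
formula with a zero-variance error rather than a NaN; Pearson values
are clipped to [−1, 1] against rounding; max-|BA| ties take the first
occurrence; curation rejections name the failed rule; degenerate
masking inputs (no eligible symbols) select nothing rather than
erroring. Known limitations: no assay-confidence weighting, no
stereochemistry handling beyond canonicalisation, no hyperparameter
search, and no uncertainty quantification on predictions.
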