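# Methods

`digepipe` implements a within-patient differential analysis for
two-dimensional difference gel electrophoresis (2D-DIGE) studies in which
each gel co-resolves a pooled internal standard (Cy2) and one patient's two
biological samples (Cy3/Cy5), each patient contributes two dye-swap
technical-replicate gels per subcellular fraction, and three fractions
(P1 nuclear pellet, P2 membrane, cytosol) are analyzed as independent
datasets. The motivating application compares high- versus low-spiking
neocortical tissue blocks resected from six patients with refractory
epilepsy, but every stage is generic over the design.

## Normalization

**Ratiometric.** Commercial gel software exports "ratiometrically
normalized" volumes without publishing the formula. We define the scheme by
the two properties downstream analysis relies on: abundances are comparable
across gels through the common pooled standard, and they are invariant to
per-image gain. Concretely, each sample channel is divided spot-wise by the
same gel's standard channel and the ratios are then divided by their
per-image median. Whether the original software centres by the median or by
total intensity is unknown; the median is robust to the handful of truly
differential spots and is documented here as our stand-in. Gain invariance
is exact (floating-point identical), not approximate.

**Total volume.** Each image's volumes are rescaled to sum to 1e6, i.e.
parts-per-million of total fluorescence. Unlike ratios to a spot-specific
standard level, these values can be added across spots (isoform roll-up)
and compared across fractions, so the cross-fraction united matrix and all
protein totals are restricted to this mode (enforced by a mode check).

**Replicate averaging** is the arithmetic mean of the normalized abundances
over a patient's dye-swap gels, on the abundance scale (not the log scale):
the averaged quantity is "the normalized volume", so its mean is taken
directly.

## Differential testing

Each gel yields one technical ln fold change ln(H/L) per spot, because the
high and low samples sit on the same gel. Technical replicates are nested
within patient; the test of mean ln FC = 0 is the random-intercept-per-
patient model. For the balanced dye-swap design its REML analysis reduces
exactly to a one-sample two-sided t-test on the per-patient replicate-mean
ln FCs with df = n_patients − 1, which is what we compute (and verify in
the tests against a general `statsmodels` MixedLM REML fit to ≤1e-6 in p;
the identity holds off the boundary where the between-patient variance
estimate is positive). Zero variance across patient means leaves p
undefined and is flagged degenerate rather than reported as 0 or 1.

Fold changes use the signed gel-proteomics convention +H/L (H ≥ L) / −L/H
(H < L), so |FC| ≥ 1 and the sign is the direction. Threshold comparisons
use ≥, so a tie at exactly the 1.25 cutoff passes. A spot is *significant*
when p < 0.05 and |geometric-mean FC| ≥ 1.25. No multiple-testing
correction is applied by default — recurrence across patients and isoform
trains provides the replication argument — but Benjamini–Hochberg
adjustment is available behind a flag.

The *variable spot* rule flags spots whose per-patient screen passes in at
least half of the patients (⌈n/2⌉, 3 of 6). The default screen is
fold-change-only (|signed FC of replicate means| ≥ 1.25); an optional ANOVA
gate additionally requires a one-way ANOVA on the log replicate abundances
(equivalently the squared two-sample t) at p < 0.05, falling back with a
warning when a condition has fewer than two replicates. Spots of interest
(SOIs) are the union of significant and variable spots, kept distinct per
fraction.

## Expression-pattern clustering

SOIs are clustered by their pattern over the 12 biological samples using
Gower's dissimilarity (mean over samples of |Δ|/range; on all-numeric
profiles a range-normalized Manhattan distance, scale-invariant per column)
and Ward's minimum-variance linkage. Since Gower dissimilarities are not
Euclidean, Ward is applied through the Lance–Williams recurrence; the
default squares the dissimilarities first (the "D2" convention, identical
to scipy's `ward` on a distance matrix) with the unsquared "D1" form
selectable. Merge ties break on the lowest index pair, making the tree
deterministic and order-invariant.

Profiles are row-centred log10 abundances of the total-volume united
matrix: subtracting a spot's across-sample mean expresses each sample as
its level and direction of variation relative to the pooled standard
(which is, by construction, the mean of all samples). The tree is cut to a
fixed K (default 37). Cluster reproducibility is estimated by leaving out
one sample column at a time, re-clustering at the same K, and averaging the
fraction of each cluster's spot pairs that stay co-assigned; leaving out
*samples* rather than spots reflects that spots are the objects being
clustered and the samples are their features. Clusters containing at least
two distinct genes of a marker panel (erythrocyte HBA1/HBB/CAT/CA1/BLVRB,
fibrinogen FGB/FGG, smooth-muscle TPM1/TPM2/TAGLN, plasma ALB/APOA1/APOD)
are labelled with the panel; a cluster's per-patient score is the median
(mean selectable) of its member spots' H/L ratios, which can be correlated
(Pearson, t-transform p) against an external per-patient measure such as a
stained blood-vessel length ratio. Patients missing the external measure
are dropped.

## Protein roll-up

A protein's isoform spot train is quantified by summing its member spots'
total-volume abundances per sample, optionally restricted to a molecular
weight class (e.g. the six ~50 kDa GFAP isoforms versus the five 38–40 kDa
fragments). The paired test on totals is a two-sided paired t-test on ln
totals across patients (the log scale matches the multiplicative error
model; reported fold changes are geometric means of the per-patient
ratios). The cytosol-to-nuclear total ratio serves as a solubility /
gliosis proxy, with qualitative bands (normal < 1/3, pronounced ≥ 3/4).

The spike-frequency relation correlates per-patient fold change (low/high)
with Δspike = spike_high − spike_low using Pearson's r with the t-transform
p (t = r√(n−2)/√(1−r²), df = n−2; |r| = 1 reported as the limit p = 0 with
a warning), a least-squares line fitted as Δspike = slope·FC + intercept
(this orientation is the only one whose coefficients have magnitudes of
order hundreds for spike frequencies in the hundreds and fold changes near
1–2.5), and Kendall's tau with an *exact* two-sided permutation p for
tie-free samples of n ≤ 10. The exact null distribution of the discordant-
pair count is computed from the inversion-number generating polynomial
∏ᵢ(1+x+⋯+x^{i−1}) — algebraically identical to enumerating all n!
permutations (perfect concordance at n = 6 gives p = 2/720 ≈ 0.003). Ties
fall back, explicitly, to the tie-corrected normal approximation.

## Gene-set recurrence

Per patient, the genes behind SOIs with |FC| ≥ 1.3 are tested against each
gene set by the one-sided Fisher exact test (hypergeometric upper tail)
over a configurable universe, defaulting to all annotated genes in the
dataset. Genes whose every SOI lies in an erythrocyte-labelled cluster are
excluded (they proxy vascularity, not a pathway), unless also expressed
outside that cluster. A set is *recurrent* when −log10 p ≥ 1.3 (p ≤ 0.05)
in at least 3 patients; recurrent sets are ranked by the summed −log10 p
with per-patient contributions retained. −log is base 10 so that the 1.3
threshold corresponds to p = 0.05. No multiple-testing correction is
applied by default, matching the recurrence-based filtering philosophy.

## Synthetic studies and what they do (not) show

Because no raw spot-volume data are publicly deposited for the motivating
study, the generator in `digepipe.simulate` produces datasets with the
statistical structure the analysis assumes, plus a ground-truth record:

- **Design**: 6 patients × 2 conditions × 2 dye-swap gels × 3 channels ×
  3 fractions; 12 gels / 36 analytical images per fraction; 1500 spots per
  fraction by default.
- **Abundance model**: log10 baselines N(4.0, 0.5); per-(spot, sample)
  biological variation with sd 0.05 log10 (chosen as a realistic ~12%
  biological CV; not a published value), shared within isoform trains at
  correlation 0.8 (trains of up to 11 spots); the pooled standard is the
  arithmetic mean of the 12 samples' true abundances per spot.
- **Measurement**: per-image gain uniform in [0.5, 2] and multiplicative
  log-normal technical noise at CV 0.10 (a free parameter — the original
  replicate CV is unpublished).
- **Planted signal**: 40 differential spots per fraction at |ln FC| =
  ln 1.6 with random sign, consistent across patients; marker panels driven
  by independent latent per-sample factors with loading = SNR ×
  biological sd (SNR 5), the erythrocyte factor playing the role of
  vascularity with a patient-specific high−low offset N(0.75, 0.75);
  a GFAP-like nuclear protein (6 abundant ~50 kDa spots + 5 fainter LMW
  fragments that co-vary with the blood factor) whose per-patient fold
  change FC(L/H) = (Δspike + 251)/200 using the six-patient cohort's
  Δspike values — strictly increasing in Δspike by construction, with
  biological jitter off by default so the planted monotonicity survives
  measurement noise; and a cytosolic GFAP pool scaled so the
  cytosol/nuclear ratio equals a per-patient gliosis level anchored at
  0.22 (normal) to 1.0 (pronounced).
- **Gene sets**: one set per marker panel, one set of the planted
  differential genes, and random decoys, over the universe of all
  annotated genes.

Passing tests on these data show that the pipeline recovers exactly the
structures the generator plants under a log-normal noise model with
independent images. They do not show robustness to what real gels add:
spot-detection and matching errors, spatially correlated background,
saturation, missing spots, or dye-specific biases beyond a scalar gain
(the dye swap would absorb those, but none are simulated).

For the type-I-error calibration check a dedicated null configuration is
used (no planted effects, singleton trains, no marker loadings, one
fraction, 2000 spots) so that spots are independent, as the binomial
confidence interval around the empirical rejection rate presumes.

## Numerical and design choices

- Problem sizes in the tests and the acceptance script are the defaults
  above (3 × 1500 spots end-to-end; 2000 null spots; 25 mixed-model oracle
  fits), which keep a full run under a minute of compute.
- Ward and Gower are implemented in-package (the variant and tie-break are
  part of the contract); scipy's `ward` and a naive O(n³) agglomerator are
  used as independent oracles in the tests only. Tree cutting delegates to
  scipy's `fcluster`.
- `fcluster(..., "maxclust")` equals cutting the K−1 tallest surviving
  merges because Ward heights are monotone.
- Degenerate inputs: zero-variance patient means → degenerate flag, not a
  p-value; all-identical clustering profiles → zero dissimilarity matrix;
  zero-range sample columns are dropped from the Gower mean with a
  warning; a zero nuclear total or a constant correlation input raises.
- Determinism: one root seed; fractions draw from named substreams
  (`SeedSequence.spawn`), so adding a fraction does not change another
  fraction's data; re-running the pipeline with the same seed is
  byte-identical.

## Known limitations

- The ratiometric centring statistic (median) is a documented guess at
  unpublished proprietary behaviour; results that depend on per-image
  centring to better than a few percent should not be over-interpreted.
- The exact Kendall p requires tie-free data and n ≤ 10; larger or tied
  inputs use the normal approximation.
- LOOCV stability leaves out samples, one of several defensible
  cross-validation schemes for clustering; absolute stability values are
  only comparable within one scheme.
- The per-patient enrichment universe is the annotated dataset, not a
  curated nervous-system background; enrichment output is comparable in
  structure, not content, to knowledge-base tools.
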