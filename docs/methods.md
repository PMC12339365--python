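# Methods

This note documents the models, estimators and numerical choices behind
`escapeseq`, in the order the pipeline runs them.

## The measurement being modelled

A single-chain trimer (SCT) fuses an 8-12-residue peptide, beta-2
microglobulin (B2M) and an HLA class I heavy chain into one polypeptide.
Only stably folded peptide-HLA complexes traffic to the cell surface, so
surface staining intensity is a proxy for presentation strength.  In a
pooled screen, cells each carry one construct, are sorted into four
fluorescence bins laid out evenly on a log scale, and each bin is sequenced.
The analysis problem is to turn four read counts per construct into a
presentation score, calibrate it across alleles, and benchmark it.

## Library design (`libdesign`)

Coordinates are 1-based inclusive residue indices throughout.  Tiling uses a
1-residue step (a 3-bp in-frame shift at the DNA level); the step is
configurable.  For a window length k:

* a protein of length L yields L-k+1 tiles;
* an interior mutated residue is covered by exactly k windows (9 nine-mers
  per point mutation);
* a fusion junction is covered, in the default *strict-spanning* convention,
  by the k-1 windows containing at least one residue from each side.
  Summed over k = 8..12 this gives 45 windows per junction, matching the
  ~45-peptides-per-target pool arithmetic; a *position* convention (treat
  the first right-side residue as a mutated position, k windows) is
  available because both conventions appear in practice.  The emitted
  records carry provenance tags so either convention can be audited.

Oligos are reverse-translated with the most-used human codon per residue, a
deterministic choice so a given library always encodes identically; if the
greedy encoding contains an Esp3I/BsmBI site (the cloning enzyme), codons
are swapped one at a time for synonymous alternatives, and an unavoidable
site is an error.  Allele barcodes re-encode the invariant 12-residue B2M
C-terminal tail (`SQPKIVKWDRDM`, synonymous space 55,296 encodings) by
greedy acceptance over a seeded random ordering, subject to a pairwise
Hamming floor (default 2) so single sequencing errors cannot convert one
panel barcode into another.

## Demultiplexing (`readproc`)

Extraction requires an exact, unique match of every 6-10 bp anchor; the
peptide insert must be a codon multiple within 24-36 nt; inserts and
barcodes are matched to the design by exact identity.  Every failure is a
categorized discard (`no_anchor`, `multiple_anchor`, `bad_insert_length`,
`unknown_peptide`, `unknown_barcode`), so assigned + discarded equals input
per file — the invariant the QC report asserts.  Reads with duplicated
anchors are discarded rather than resolved, since ambiguity cannot be
settled without the vector map.  Quality strings are ignored: the method
uses sequence identity only, and with exact matching a base-call error is
equivalent to a discard.

### Chimera (recombination) rate

Spike-in pools pair known peptide sets with disjoint allele sets.  A
spike-in peptide observed with an out-of-pool allele evidences a barcode
swap.  The raw cross-pool fraction underestimates the swap rate because a
swap landing on an allele of the *same* pool is invisible; assuming swaps
land uniformly on the other n-1 panel alleles, the detectable fraction is
(n_panel - n_own_pool)/(n_panel - 1) per pool.  The estimator reports both
the raw fraction and the corrected rate (raw / detectable fraction, combined
across pools by read weight); the corrected rate is the unbiased estimate
and is what the recovery tests check against injected rates.

## E-scores (`escore`)

Normalization is two-step: (1) each (bin, replicate) file's counts are
divided by that file's mean count across trimers — a sequencing-depth
correction, deliberately without a log transform; (2) each trimer's
four-vector is divided by its sum, giving bin fractions.  The E-score is
the weighted sum with weights (0, 2, 4, 8) for (bg, low, med, high), placed
on the same log scale as the sort gates, and is therefore bounded in
[0, 8].  Two consequences worth noting:

* "dividing by the average" is implemented as the per-bin mean across
  trimers: this makes the score invariant to rescaling any one bin's file
  depth, which is the point of the step;
* the sum-to-one step makes the 0-8 range and the fixed binder cutoffs
  coherent across screens of different depth.

Trimers with zero reads in all four bins are reported as missing (NaN),
never as 0 — a zero would assert confident non-presentation.

### Per-allele mode alignment

In combinatorial screens each allele's E-score distribution is bimodal with
a dominant negative peak whose location varies with the allele's intrinsic
surface efficiency.  The negative-peak mode is estimated by Gaussian KDE
(Silverman bandwidth) on scores below a valley threshold (default 4.0),
argmax on a 512-point grid; each allele's scores are then shifted
*additively* so all modes meet the panel median mode.  Additive shifting
was chosen over rescaling because the negative peak is a location artifact,
not a gain artifact; alignment of an already-aligned table is the identity
to grid resolution.  Alleles with fewer than 50 scored trimers (default) or
no resolvable lower peak are left unshifted with a warning.  Alignment runs
per replicate; replicate scores are averaged afterwards (mean), and binder
calls are made on the mean.

### Calls and summaries

Binder calls use strict inequality: score > 3.2 in single-allele mode,
> 3.8 in combinatorial mode (the higher cutoff absorbs the extra noise of
multi-allele pooling); overrides outside the 3.5-4.0 guidance band warn.
Replicate QC requires pairwise Pearson r > 0.9.  Downstream summaries —
position-frequency motifs, capture percentage against an MS hit list,
mutant/wild-type quadrant classification (WT-Mut-, WT+Mut+, WT+only,
Mut+only), and allele-sharing profiles — are straight tallies over the call
table and are each tested against brute-force oracles.

## Benchmarking (`benchmark`)

IC50 values are mapped to t = 1 - log(ic50)/log(50000) (log base cancels;
implemented with log10 and pinned at the 500 nM -> 0.426 checkpoint).
Binders are IC50 strictly below 500 nM, with elution flags passing through
where IC50 is absent.  ROC-AUC is the Mann-Whitney concordance probability
with half-credit ties; PR-AUC uses step-wise interpolation (average
precision), not trapezoids, to avoid optimistic bias.  Metrics are computed
separately per allele, with a pooled row reported alongside.  Confidence
intervals are nonparametric percentile bootstrap with B = 1000 resamples;
degenerate resamples (e.g. single-class draws) are skipped and counted.
External predictor tables are harmonized with the conventional 0.5% /
2% percentile-rank cutoffs for strong/weak binders; missing predictions
stay missing rather than counting as negatives.

## Allele similarity (`allelesim`)

Pseudo-sequences are the 34 cleft-lining residues supplied as input (their
derivation from structures is out of scope).  The BLOSUM62 comparison is
shipped in two forms: the product-denominator form
1 - S12/(S11 * S22) as documented in the field (`as_printed`; note its
self-distance is nonzero because the denominator is a product, not a
root-product), and a cosine-style root-product normalization
(`sqrt_normalized`, default) whose self-distance is zero.  Functional
similarity is 1 - cosine similarity between allele E-score profiles over a
shared peptide pool.  Both constructions are symmetric with zero diagonal;
the triangle inequality is *not* asserted (cosine distance violates it).
Embedding uses UMAP on the precomputed distance matrix with n_neighbors=5,
min_dist=0.01, random_state=42; heatmap preparation filters peptides with
no above-threshold score, clips to [2, 5] for display only, and clusters on
cosine distance (average linkage).

## Population coverage (`popcov`)

Coverage of a mutation is the probability that a random diploid individual
(two alleles at each of HLA-A, -B, -C) carries at least one allele
presenting at least one of its peptides.  Under Hardy-Weinberg independence
within and between loci: coverage = 1 - prod_locus (1 - p_locus)^2 with
p_locus the summed presenting-allele frequency.  A seeded genotype sampler
provides the same quantity by simulation; sampler and closed form agree
within 3 Monte-Carlo standard errors by construction and by test.
Frequency mass not in the panel is treated as never presenting
(conservative).  Known limitation: real HLA haplotypes show linkage
disequilibrium within the extended MHC; the independence assumption will
misstate coverage where strong A-B-C haplotype structure exists.

## The synthetic screen (`simdata`)

The generator's defaults are the study conditions.  Bin centres sit at
100 / 400 / 1,600 / 6,400 a.u. with gates at their geometric midpoints
(200, 800, 3,200) — four even bins on a log scale.  Each construct's latent
presentation strength theta in [0, 1] sets its mean log10-fluorescence by
linear interpolation between the background and top centres (a logistic
link is available, reflecting the saturating intensity-affinity
relationship seen at high affinity).  Cell-level noise is normal in log10
space with sigma = 0.12 decades, chosen so that a non-presenting construct
keeps >= 99% of its cells below the first gate — the tight negative peak a
sorted screen requires.  Defaults: 1,500 cells per construct (the
recommended >1,500x library representation), 10% binder fraction with
theta drawn Uniform(0.55, 1) for binders and Uniform(0, 0.35) otherwise,
sequencing depth of 100 reads per construct per bin, two replicates.
Chimeras swap only the barcode, to a uniformly drawn other allele,
mirroring template switching between the highly homologous HLA sequences
during pooled PCR.

What the simulator does *not* capture: base-call errors beyond optional
anchor corruption, PCR amplification jackpots, cell-to-cell expression
heterogeneity beyond the single log-normal term, per-experiment gate drift,
peptide-processing biology (proteasome/TAP), and real allele-specific
binding motifs (synthetic peptides are random sequences).  Passing
recovery tests therefore demonstrates that the *computational* chain is
correct and well-calibrated under the stated noise model — not that the
assay itself has any particular sensitivity on real libraries.

## Problem sizes used in the checks

The bundled checks run a 200-peptide x 10-allele screen (2,000 constructs,
two replicates, 100 reads/construct/bin) for parameter recovery, 50-peptide
two-pool spike-in screens for chimera-rate recovery at 2/5/10% injected
rates, 100 random configurations for the sampler-vs-closed-form coverage
comparison, and 500 repeats of B = 1000 bootstrap intervals for coverage
calibration.  These sizes were chosen as the smallest at which the
Monte-Carlo tolerances (3 SE) are meaningfully tight.

## Known limitations

* Exact-match demultiplexing discards any read with a sequencing error in
  an anchor, peptide or barcode; a Hamming-1 rescue exists but is off by
  default to mirror the reference behaviour.
* Mode alignment needs a populated negative peak; screens composed almost
  entirely of binders (or nearly empty alleles) are left unshifted.
* The fixed-depth-per-bin sequencing model makes scores of a screen in
  which *every* construct saturates degenerate (empty lower bins still
  receive reads); real screens always contain a dominant negative
  population, which the default mixture reproduces.
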