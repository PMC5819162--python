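# Methods

`chromasig` implements a chromatin-state analysis pipeline for panels of
cell lines profiled with histone-mark ChIP-seq: binarization of binned
coverage against a Poisson background, a multivariate Bernoulli hidden
Markov model trained jointly across cell lines, biological annotation of
the learned states, and differential ("signature") calling of chromatin
states between cancer subtypes, together with variability and expression
associations. A synthetic-cohort generator with planted ground truth makes
every stage testable end to end.

## Coordinate model

Everything lives on one `BinGrid`: each chromosome is tiled by fixed-width
half-open bins (default 200 bp). The final partial bin at a chromosome end
is kept (truncated) so bins always partition the chromosome; all per-bin
statistics treat it as one bin. Coordinates are 0-based half-open
throughout, matching BED. bedGraph rows spanning several bins assign their
value to every overlapped bin (step-function coverage semantics); values
are never apportioned. The TSS of an unstranded gene defaults to its start
coordinate.

## Binarization

A mark is present in a bin when its pooled count reaches the smallest
c* >= 1 with P(X >= c* | Poisson(lambda)) <= p. Defaults: p = 1e-4 and
lambda equal to the track's global mean over all bins, zeros included; no
input-control track is used. Per-chromosome and user-supplied backgrounds
are available as options. Replicates are pooled by element-wise summation
before binarization. An all-zero track yields all-zero calls with a
warning. Note that the global-mean background is only meaningful when the
mark occupies a minority of the genome; at high prevalence the background
estimate is contaminated and sensitivity drops (this is inherent to the
method, not an implementation artifact).

## The chromatin-state HMM

States emit the M binarized marks as independent Bernoullis
(`E[k, m]` = probability mark m is present in state k); transitions are a
K x K row-stochastic matrix. Sequences — one per cell line per chromosome —
are independent: the initial distribution applies at every sequence start
and no transition crosses a boundary. Since observations are binary
M-vectors, each bin is encoded as one of 2^M symbols and the scaled
forward/backward, Viterbi and Baum-Welch recursions (numba-compiled) work
from a K x 2^M symbol-likelihood table. Emission parameters are clipped to
[1e-6, 1 - 1e-6] to avoid log(0); Viterbi ties break to the lowest state
index for determinism.

Training protocol. Random-restart EM on this model class lands in
state-merging local optima often enough to matter, so two complementary
protocols are provided and tested:

- `BernoulliChromatinHMM` (sklearn-style estimator): emissions initialized
  as mark-frequency-perturbed random draws, transitions near-uniform with a
  0.5 self-transition boost; `n_init` independent restarts (default 3) run
  to convergence and the best final log-likelihood wins. Stopping rule:
  per-observation log-likelihood gain below `tol` (default 1e-6) or
  `max_iter` (default 300).
- Split-EM ladder (`select_model`): fit a small K, then repeatedly grow
  the model one state at a time and re-run EM to convergence. The state to
  split is chosen by an overdispersion diagnostic computed from one
  E-step: a true Bernoulli-product state has diagonal within-state mark
  covariance mu(1-mu), so excess covariance flags a state covering two
  real mark combinations; the split displaces the two copies along the top
  excess-covariance eigenvector. This approaches the target K through
  warm starts and targets exactly the states that are hiding structure.

Model selection trains one model per K (default 10..20 via the ladder) and
reports log-likelihood, BIC (parameter count K·M + K(K−1) + K−1), and an
emission-redundancy score — the minimum pairwise Euclidean distance between
emission rows. When K exceeds the number of distinguishable mark
combinations the newly added state duplicates an existing one and the
redundancy score collapses; the default choice is minimum BIC, with the
full diagnostics table persisted so a user can force any K.

## State annotation

The 13-label vocabulary (PrAct, PrFlk, EhAct, EhGen, TxAct, TxFlk, RepPC,
WkRep, PrBiv, EhBiv, RpZNF, Htchr, QsLow) is encoded as archetypal emission
vectors with high = 0.8, mid = 0.4, low = 0.1 (configurable). A learned
state takes the label of the nearest archetype (Euclidean distance on the
emission row); when the two nearest archetypes are within 0.1 of each
other, genomic fold enrichment breaks the tie (TSS-enriched states prefer
promoter labels, gene-body-enriched states prefer transcription labels).
Duplicate labels are suffixed and warned about. This labeler is a
deterministic operationalization of what is usually done by inspection; it
claims nothing beyond its distance rule.

Fold enrichment of state s in category c is
[n(s∩c)/n(s)] / [n(c)/N] with n counting bins; on categories that
partition the genome the enrichment of any state, averaged with category
weights n(c)/N, is exactly 1 — used as a numerical invariant.

Model robustness is assessed by pooling the emission rows of a jointly
trained reference model with independently trained per-line models,
clustering them (average linkage, Euclidean), cutting the tree at
K_reference clusters, and scoring the fraction of reference states whose
cluster contains at least one state from every per-line model.

## Signature calling

Per-bin, per-subtype consensus: a subtype holds a state at a bin only if
all of its cell lines agree; otherwise the bin is discordant for that
subtype. Candidate bins require every subtype concordant and at least two
distinct subtype states. At a candidate bin a focal subtype is
uniquely-present when its state occurs in no other subtype, and
uniquely-absent when additionally all other subtypes share a single state.
The absent condition implies the present one, so calls are reported
present-dominant with an `uniquely_absent` flag — both facts are kept.
Group contrasts compare partitions of the design: pan-cancer
(normal-like vs all cancer subtypes) and TNBC (basal/claudin-low vs
luminal/HER2); both sides must be internally uniform and mutually
distinct, and the global candidate filter applies. Contiguous bins with an
identical call and consensus pattern merge into regions; runs shorter than
`min_bins` (default 2, i.e. 400 bp) are dropped to suppress single-bin
decoding noise.

Signature regions are characterized by representative histone-mark
signals: the maximum peak height of H3K36me3 over gene bodies for
TxAct/TxFlk calls, H3K27me3 over gene bodies for RepPC/WkRep, H3K4me3
within 1 kb of the TSS for promoter states, H3K4me1 within 1 kb of the
region for enhancer states (or of supplied enhancer intervals), and
H3K9me3 over gene bodies for Htchr. Gene lists attach genes overlapping a
call by gene body (TSS window for promoter states).

## Variability and expression

State variability counts, for each state, how many of the N samples carry
it at each bin where it occurs at all; the cumulative fraction F(n) of
occupied bins covered by <= n samples has AUC = (1/N)·Σ F(n), bounded by
1/N (fully shared) and 1 (fully private). Variability is computed per bin,
not per merged region. Variable-region clustering ranks rows of an
intensity matrix by variance (optionally after seeded random subsampling
of rows, mirroring two-stage peak sampling), standardizes the selected
rows to mean 0 and sd 1 (sample sd, ddof = 1), and clusters with average
linkage on Euclidean distance. Replicate QC is the Pearson correlation of
peak intensities. FPKM = count / (total reads / 1e6) / (gene length / 1e3).
Genes are associated to chromatin states by the majority state over their
gene-body bins (ties to the lowest state index); per-state expression
distributions are compared by one-sided rank-sum tests. The mark-expression
association uses Spearman rank correlation with midrank ties; the pipeline
correlates mean H3K36me3 gene-body occupancy with FPKM (the maximum
statistic is reserved for representative signature signals, where a single
saturated bin is the object of interest).

## Synthetic cohort generator

The generator emulates a 13-line breast-cancer panel (two
normal-immortalized lines; luminal A/B, HER2, TNBC-basal and
TNBC-claudin-low subtypes) profiled for the five core marks H3K4me1,
H3K4me3, H3K9me3, H3K27me3 and H3K36me3 at 200 bp bins:

- Generating model: the 13 archetype patterns with sharper levels
  (high 0.9, mid 0.45, low 0.05 — deliberately different constants from the
  annotation archetypes so generator and labeler stay independent), sticky
  transitions (0.9 self, uniform otherwise), uniform initial distribution.
- A backbone segmentation is drawn once from the model's Markov chain and
  shared by all lines. Differential biology is planted as disjoint regions
  (default 10 bins = 2 kb, long enough to survive posterior smoothing):
  target lines carry a replacement state, all others the replaced state.
  Four classes are planted: subtype-present, subtype-absent (bookkeeping
  distinction of the same bin-level pattern), pan-cancer (all cancer lines
  differ from normals) and TNBC (basal/claudin-low differ from
  luminal/HER2, normals kept with the luminal side).
- Per-line noise resamples each non-planted bin to a uniformly random
  state with probability `noise_rate`; noise perturbs states (marks are
  then emitted from the perturbed state) so noisy bins remain
  model-consistent.
- Marks are Bernoulli draws from the emissions; counts are
  Poisson(lambda_on = 20) at present bins and Poisson(lambda_off = 0.5)
  elsewhere (20 vs 0.5 reads per 200 bp bin is typical for a
  20M-read ChIP at a marked vs background locus).
- Expression: each gene's count is Poisson(rate[dominant body state] ×
  length_kb). Rates follow elongation biology — gene bodies dominated by
  H3K36me3-positive states are the productively transcribed ones
  (TxAct 100, TxFlk 50, RpZNF 40, EhGen 30 per kb; promoter-only bodies
  modest; repressed/quiescent near 1).
- Backbone modes: ``shared`` (all lines share one backbone path — the
  cohort structure that differential calling assumes) and ``independent``
  (each line draws its own chain from the model; no planting). Recovery
  and model-selection experiments use independent chains, since their
  premise is data i.i.d. from the HMM; a shared path makes the effective
  hidden-path sample 13-fold smaller and is the wrong testbed for that
  question.
- One master seed spawns per-line and per-line-per-mark substreams
  (`numpy` SeedSequence), so all outputs are bit-reproducible and stages
  can be rerun without cross-contamination.

What the generator does not emulate: read-level noise and mappability,
copy-number effects, replicate structure, gene-coherent chromatin domains
(the backbone is a bin-level Markov mosaic, so a "silent" gene body can
contain stray marked bins), and non-uniform state frequencies of real
genomes. Tests passing on this cohort therefore demonstrate correctness of
the algorithms under the stated model, not performance on real data.

## Problem sizes and numerical choices

The validation suite runs the recovery, selection and per-line
reproducibility experiments at 13 lines × 50k bins; the acceptance script
runs the same experiments at 13 lines × 20k bins (the package's demo
scale). The reproducibility score depends on per-line sequencing depth —
with only 20k bins per line an occasional per-line model misses one state
of the vocabulary, so the script's score can sit slightly below the
50k-bin value. The packaged end-to-end demo uses 3 subtypes × 2 lines,
20k bins and a 6-state generating model. Degenerate inputs are
handled explicitly: all-zero tracks binarize to all-zero with a warning,
constant vectors yield missing correlations, constant matrix rows are
excluded from variance ranking, empty consensus sides raise errors, and
EM on identical observations converges with a warning. 0/0 fold
enrichments are reported as 0.

## Known limitations

- The uniquely-absent condition is a strict subset of uniquely-present
  under the consensus definitions; a "pure absent" call cannot exist.
- The global-mean Poisson background assumes minority mark prevalence.
- EM is a local optimizer; even with restarts and the split ladder,
  pathological seeds can fit poorly. All training entry points expose
  seeds, restart counts and tolerances, and model-selection diagnostics are
  persisted for audit.
- The signature caller treats subtypes symmetrically and requires full
  concordance within a subtype; a single noisy line can veto a bin (by
  design, matching the strict consensus definition).
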