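# Methods

`crossqtl` implements, at desk scale and with known ground truth, the full
statistical path of a developmental-QTL study on an interspecies F2 fish
cross: simulate the cross and its shallow sequencing, call recombination
blocks from binned allele frequencies with a Gaussian HMM, phenotype
oscillatory reporter traces by wavelet ridge analysis, normalise traits
across imaging batches, and map 5-kb pseudo-SNPs with a
leave-one-chromosome-out (LOCO) linear mixed model under a permutation
genome-wide significance threshold.

## Cross and sequencing simulator

Two fully inbred parental strains ("Cab-type" and "Kaga-type") differ at a
panel of biallelic, homozygous-divergent SNPs, so every F1 is heterozygous
at every panel site.  F2 individuals are unions of two independent F1
gametes.  Meiosis places Poisson-distributed crossovers (default mean 0.8
per chromosome per meiosis, matching the empirical "under one per
chromosome" regime for fish) at uniform positions with no interference —
the baseline model when only a mean rate is known — and picks the starting
strand fairly.  True genotype states per 5-kb bin (0 = hom-Cab, 1 = het,
2 = hom-Kaga) are evaluated at bin midpoints; a crossover inside a bin
therefore assigns the bin to the side holding its midpoint.

Sequencing is modelled at the allele-count level (the upstream alignment
and read-counting steps are outside scope): reads per panel SNP are
Poisson (default mean 1.0), each read samples one of the two haplotypes —
so a heterozygous site reports either allele with probability 1/2 — and
flips allele with probability 0.002 (small but non-zero, to exercise the
caller's noise tolerance).

The default genome is 5 chromosomes x 5 Mb with 5-kb bins (5,000 bins) and
SNP density 1/250 bp, i.e. ~20 informative sites per bin.  This preserves
the per-bin information content of a real ~2.2M-SNP / ~140k-bin dataset at
roughly 1/30 the size, which is what makes the replicate-level experiments
tractable on one CPU.

Quantitative phenotypes are `y = Σ β_q·dosage_q + g + batch + ε`, where
the polygenic term `g` is a weighted sum of genome-wide standardised bin
dosages with i.i.d. normal weights, rescaled to the requested variance
(consistent with the additive-GRM assumption of the mixed model), `batch`
is an additive per-microscope shift (two batches by default), and
`ε ~ N(0, σ²)`.  `effect_for_pve` converts a target variance fraction to
an additive effect using the F2 dosage variance of 1/2.

The simulator does not model segregation distortion (a real cross between
strains near speciation can skew away from 0.25/0.5/0.25), indels,
multi-allelic sites, crossover interference, or read-level artefacts
beyond the symmetric flip error.  Passing tests therefore validate the
statistical machinery under clean Mendelian segregation, not robustness to
hybrid-incompatibility skew.

## Genotype calling

Per sample, reads supporting the Kaga-type allele are summed within
non-overlapping 5-kb bins and divided by total reads in the bin; bins with
zero reads are set to exactly 0.5.  Each chromosome's bin series is
decoded by a 3-state HMM with Gaussian emissions (means 0, 0.5, 1; shared
variance 0.8), off-diagonal transition probability 1e-8 (rows
renormalised) and Mendelian initial probabilities (0.25, 0.5, 0.25).  The
decoder is the most-probable path (Viterbi), vectorised across samples in
log space; a test cross-checks it against both exhaustive path
enumeration (short sequences) and hmmlearn's decoder (long sequences).

Two numerical points are worth stating plainly:

* The emission variance 0.8 far exceeds the spread of a [0,1]-valued
  frequency.  Discrimination between states then comes almost entirely
  from run lengths: a state switch costs ~log(1e-8) ≈ −18.4 while one
  misfit het emission costs only 0.5²/(2·0.8) ≈ 0.156, so a switch pays
  off only after ~118 consecutive consistent bins (~590 kb).  This is the
  designed behaviour — it is what forces long recombination blocks — and
  it means block boundaries are localised to a few bins while blocks much
  shorter than ~0.5 Mb can be absorbed into their neighbours.
* "Missing" bins are bins containing no panel SNPs; they are excluded
  from decoding entirely.  Bins with SNPs but no reads are decoded at
  f = 0.5.  After decoding, missing bins copy the previous called bin's
  state (or, at a chromosome start, the next one) and are flagged filled.

Sample QC excludes samples whose genome-wide fraction of bins with at
least one read falls below 0.5 (the study excluded "poor coverage" samples
without a printed numeric rule; 0.5 is this package's default and is
configurable).  Filled per-bin states double as pseudo-SNP dosages
(count of Kaga-type alleles, 0/1/2); monomorphic columns can optionally be
dropped and are always flagged.

At the default settings the caller recovers ≥95% of bins correctly, calls
state fractions within Monte-Carlo error of 0.25/0.5/0.25, and its 90th
percentile of state changes per chromosome is ≤3.

## Period extraction

Traces are reporter intensities sampled every 10 min.  The pipeline is:

1. **Detrend** — subtract a windowed-sinc low-pass (cut-off period
   100 min).  The kernel is `scipy.signal.firwin` with Hamming window and
   ~4 cut-off periods of support, applied over reflect padding; this keeps
   a 55-min oscillation >99% intact while removing a 300-min component to
   <10%.
2. **Envelope normalisation** — divide by √2 x sliding RMS over a 150-min
   window (reflect boundary), i.e. the amplitude a sinusoid of that RMS
   would have, so bleaching or reporter decay does not weight the
   transform.
3. **Morlet CWT** — base frequency ω₀ = 6 (the standard
   admissibility-respecting choice), 200 linearly spaced periods in
   [40, 100] min, computed by the FFT method with zero padding to the next
   power of two ≥ 2N so the circular convolution cannot wrap one trace
   edge into the other.
4. **Ridge** — per timepoint, the scanned period of maximal power; phase
   and amplitude are read off the complex transform along the ridge.  The
   cone of influence uses the wavelet's e-folding time √2·s; samples whose
   ridge scale's e-folding time reaches past the nearest edge are flagged
   unreliable.
5. **Summaries** — over the first 300 min of edge-free samples (the
   window anchors at the first such sample): the arithmetic **mean
   period**, and the **intercept period** = y-intercept of an ordinary
   least-squares line on (time since window start, period).  OLS rather
   than a robust fit is the simplest reading of a fitted-line intercept.

With 10-min sampling and a 40–100-min scan range the period grid step is
~0.3 min; recovery error under 20% noise, linear drift and exponential
decay is well inside ±1.5 min.  The reference tool's exact sinc kernel and
period-grid convention are not published; recovered periods may differ
from it in the second decimal.

## Trait normalisation

Within each imaging batch j of size N_j, the rank-based inverse normal
transform is `z = Φ⁻¹(rank/(N_j + 0.5))` with 1-based ascending average
ranks on the raw values (tie rule and rank base are this package's
declared choices); missing values propagate.  The alternative correction
shifts every non-reference batch additively so its mean equals the
reference batch's mean — it preserves within-batch variances and rank
orders exactly.  The two are alternatives selected by configuration; the
mapping stage defaults to inverse normalisation with no batch covariate.
Egg volume treats the egg as an oblate spheroid, V = (4/3)πb²c.

## Mixed-model association

The GRM is GCTA-style: `G_jk = (1/M) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) /
(2p_i(1−p_i))` over polymorphic markers, with allele frequencies estimated
from the analysed sample (the only option without external data).
Constant columns — including all-het columns, whose allele frequency is
0.5 but whose dosage variance is zero — are excluded and counted.  For a
marker on chromosome c the random-effect covariance uses the LOCO GRM
built from all other chromosomes, avoiding proximal contamination.

Variance components are estimated once per LOCO GRM (not per marker) by
profile REML on the eigendecomposition of G: the single free parameter is
λ = σ²_g/σ²_e, optimised on a log grid refined by bounded scalar
minimisation, with σ²_e profiled out in closed form; the λ→0 boundary is
always evaluated so a zero-heritability fit is reachable.  Each marker
then gets a 1-df Wald chi-square with λ fixed at the null estimate and the
residual scale re-estimated per marker (RSS/(n−p−1)); this is standard
practice in eigendecomposition-based mixed-model scans, and it makes the
model collapse exactly onto ordinary least squares (z-based p-values) when
the genetic variance is zero.  Monomorphic markers get p = 1 and a flag
rather than an error.

Significance: the phenotype (jointly with covariates, when present) is
permuted across samples with 10 distinct seeds, a full LOCO scan is run
per permutation, and the genome-wide threshold is the single smallest
p-value observed anywhere — the literal min-over-permutations rule, not a
quantile of per-permutation minima.  Bonferroni 0.05/M over the M
pseudo-SNPs in the model is kept as a secondary threshold (always derived
from the data at hand, never hard-coded).  Contiguous significant bins
merge into loci; each locus reports its peak bin.

Under these conditions a PVE-0.15 QTL at n = 600 over a polygenic
background (h² = 0.2) is detected and localised within 500 kb in ≥90% of
replicates, and pure-noise phenotypes clear the permutation threshold in
roughly the 1/(n_perm+1) fraction of runs that the min-p construction
implies.

## Pipeline and reproducibility

`run_pipeline` executes simulate → genotype → phenotype → map from one
YAML config; the resolved config is written verbatim into the output
directory before any stage runs.  A single global seed spawns per-stage
seeds through `numpy.random.SeedSequence`, so identical configs produce
byte-identical numerical outputs.  The run report (text + JSON) records
per-stage row counts, QC exclusions, thresholds, significant loci and the
seed chain; `compare_to_truth` scores any simulated run for genotype
accuracy, crossover-breakpoint localisation and QTL hits.

Problem sizes used by the validation experiments — 150 F2s for the
genotyping calibration, 20 replicates of n = 600 for QTL recovery, 50
null replicates at n = 300 (using true genotype states directly, since
read noise is irrelevant under the null), and 50 traces per true period —
are this package's desk-scale choices; they keep every experiment
single-CPU friendly while leaving Monte-Carlo error well below the margins
being tested.

## Known limitations

* Ties in the Viterbi path (possible at exactly symmetric inputs such as
  an all-0.5 chromosome) resolve by lowest state index; real frequency
  data makes exact ties measure-zero.
* The permutation threshold with 10 permutations is itself a random
  variable with substantial spread; the package reports per-permutation
  minima so users can judge its stability.
* The polygenic simulator draws one weight per bin, so its effective
  number of independent background loci is bounded by the recombination
  block count, not the bin count — at desk scale a background draw can
  occasionally concentrate enough variance near the QTL to shift the peak
  by a few hundred kb.
* REML assumes a dense, well-conditioned GRM; cohorts of near-clonal
  samples will push eigenvalues toward zero and the fit toward the λ
  boundary.
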