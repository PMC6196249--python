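# Methods

## Signal model and normalization

Each probe contributes a two-channel pair (IP, input). The analysis works on
r_i = log2(max(IP_i, floor) / max(input_i, floor)) with floor = 1.0 intensity
unit, which only guards against zero intensities and is otherwise inert.

Tracks are centered by subtracting the Tukey bi-weight mean: starting from
the median with the scale fixed at S = MAD + ε, points get weights
w_i = (1 − u_i²)² for |u_i| < 1 (u_i = (r_i − T)/(c·S), zero outside), and
the weighted mean is iterated until the step falls below ε·S or 10
iterations. Defaults c = 5, ε = 1e-4 follow the common microarray convention
for this estimator; the iteration is deterministic, so re-centering an
already centered track is a no-op to machine precision, which the tests
exploit. If every weight vanishes (degenerate spread) the median is
returned. Scaling is per array (all chromosomes pooled); a per-chromosome
variant can be had by slicing profiles per chromosome before scaling.

Dye-swap merging is the probe-wise arithmetic mean of the two scaled
replicate tracks. Any dye bias that is additive on the log2 scale and equal
in magnitude between the orientations cancels exactly; the generator plants
such a bias (±0.2 log2 units on the Cy5 channel) to keep this property under
test. The combination rule (mean after per-array scaling) is a design choice;
weighted schemes would need per-probe variance estimates the design does not
provide.

## Peak calling

The cutoff grid is 90%, 85%, …, 15% of the hypothetical maximum
H = mean + 6·SD (sample SD, n−1) of the scaled merged track. At each cutoff,
maximal runs of above-cutoff probes are formed, joining consecutive
above-cutoff probes at most 300 bp apart and keeping runs of ≥ 2 probes.
With 100 bp probe spacing this tolerates one dropped-out probe inside a
site; both parameters are config-exposed because no canonical values exist
for this vendor workflow.

FDR estimation shuffles the track values uniformly across the fixed probe
layout (genome-wide; a within-chromosome option exists) 20 times. For each
cutoff c, FDR(c) = min(1, mean_j F_j(c) / max(O(c), 1)) where F_j and O are
the shuffled and observed run counts. Candidate peaks are the runs at the
lowest cutoff of the sweep; each candidate's `detect_cutoff` is the highest
cutoff at which it still contains a qualifying run, and its `fdr_score` is
the minimum FDR over all cutoffs at which it is detected — equivalent to a
cumulative-min across the sweep, which keeps the score monotone in detection
stringency even when the 20-shuffle estimate is noisy. Shuffle streams are
seeded `(seed, j)`, so results are independent of iteration order and
bit-reproducible.

The peak score is S = −log10 Pr[X ≥ k] with X ~ Poisson(ρ·m): k above-cutoff
probes (at the peak's detection cutoff by default) inside a 600 bp window
centered on the summit, m probes in the window, ρ the genome-wide
above-cutoff fraction. The upper tail comes from `scipy.stats.poisson.sf`;
the tests pin it against direct series summation to 1e-10. k = 0 scores 0;
an empty window scores 0 with a warning; a probability underflowing double
precision is clamped to the smallest positive double rather than producing
infinity. The same statistic evaluated on an input-only reference track
(log2 input, bi-weight-centered) gives `score_input` and the ratio
`score_ip / score_input`; when `score_input` = 0 the ratio is reported as
NaN rather than a division. Filtering applies FDR ≤ 0.05 and score ≥ 1.3
(relaxed: ≥ 1.0) to `score_ip` by default; applying it to the ratio instead
is a config switch, since either reading of "peak score" is defensible.

## Target mapping and expression classes

Promoter windows are [tss − 1200, tss + 300) on the plus strand, mirrored on
the minus strand, clipped to the chromosome. Assignment is any ≥ 1 bp
overlap between a filtered peak and a window (half-open intervals; abutment
is not overlap); a peak spanning two windows is assigned to both genes —
with dense promoter designs exclusivity would be arbitrary. REL values are
log2 throughout; linear fold-change tables must be declared as such and are
log2-transformed on input rather than guessed. Classification: up_in_HE iff
REL_HE ≥ 1, down_in_HE iff REL_HE ≤ −1, dependent iff REL_HE ≥ 1 and
REL_M ≤ −1, all thresholds inclusive.

## Motif context

Promoters for motif analysis are the 2,000 bp ending at the A of the start
codon (the ATG anchor, not the TSS). Motif counting is overlapping exact
forward-strand matching; CATG is reverse-complement palindromic so strand
choice cannot affect it, and CACG is deliberately counted on the promoter
strand only (a both-strands option exists but is off by default, the more
conservative reading). The TATA-box is the 3′-most match of the IUPAC
pattern TATAWAW — a minimal consensus model, replaceable via config; no
position-weight-matrix scan is attempted. The reported distance is the
minimum |motif start − TATA start| over occurrences ("nearest"); the 3′-most
occurrence is available as an alternative rule.

## Synthetic data

The generator emulates the study conditions end to end, from one seed with
named substreams (placement, sites, sequence, motifs, each array replicate,
expression):

- **Design**: 2,600 genes on 5 chromosomes of 2.5 Mb, alternating strands,
  evenly slotted with jitter; 15 probes of 50 bp at 100 bp spacing per
  promoter window → 39,000 probes, matching the ≈38,500-probe scale of real
  promoter chips of this type.
- **Intensities**: input ~ log-normal(location 7.0, scale 0.8 natural-log
  units; median ≈ 1,100 a.u.); IP = input × fold^kernel × 2^N(0, 0.3), with
  a triangular kernel over 5 probes peaking at 1 at the site center
  (20 planted sites, 6-fold enrichment ⇒ max log2 ratio ≈ 2.58 against
  probe noise sd 0.3). Replicate 2 swaps dye labels; the Cy5 channel is
  multiplied by 2^0.2 in both replicates, giving equal-and-opposite ratio
  biases.
- **Promoters**: iid uniform background nucleotides; each promoter gets a
  planted TATAAAT box ~30 bp upstream of the TSS, Poisson(3) extra CATG
  placed at exponential distance (scale 50 bp) from the TATA-box and
  Poisson(2) CACG placed uniformly (the ≥ 2× planted separation). Note that
  iid uniform sequence already contains (2000−3)/4⁴ ≈ 7.8 chance occurrences
  of any 4-mer per promoter, which both raises the mean counts above the
  planted rates and compresses nearest-distances; the planted CATG-near-TATA
  signal survives this background clearly (≈ 28 vs ≈ 96 bp in the worked
  example).
- **Expression**: bound genes REL_HE ~ N(3, 0.3), REL_M ~ N(−3, 0.3);
  unbound genes N(0, 0.3). With these effects the dependent classification
  is essentially deterministic, so end-to-end recovery measures the peak
  caller and mapper, not expression noise.

What the generator does *not* model: sequence-driven binding energetics,
cross-hybridization, probe GC effects, spatial array artifacts, and
correlated noise between neighboring probes. Passing recovery tests
therefore demonstrate correctness of the pipeline's inference under its own
stated noise model, not performance on real chips, where probe effects are
heavier-tailed and replicate noise is correlated.

## Validation sizes and observed behavior

The test suite and acceptance script size the Monte-Carlo checks as: 1,000
random samples for bi-weight/oracle equivalence; a 40 × 21 (λ, k) grid for
Poisson-tail exactness; 200 site-free ~5,000-probe arrays for FDR
calibration (mean realized false-discovery proportion at FDR ≤ 0.05 stays
below 0.10; n_perm = 20 makes the estimate itself noisy, which is why the
bound is looser than 0.05); 100 planted-site arrays for recall/precision and
summit accuracy; and 50 independent end-to-end datasets for dependent-gene
recovery. These sizes keep the whole suite within a routine CI run while
leaving the Monte-Carlo standard errors well below the tested margins.

## Known limitations

- The raw-file dialect is a documented TSV stand-in for the vendor's binary
  "pair" exports; only the column semantics, not the container, are modeled.
- FDR scores at a cutoff are shared by all peaks detected there; the method
  cannot rank two peaks detected at the same cutoff by FDR (the Poisson
  score does that).
- With n_perm = 20 the FDR estimate at any single cutoff has coarse
  resolution (multiples of 1/(20·O)); the cumulative-min rule mitigates but
  does not remove this.
- The β-galactosidase and ΔΔCt conversions assume fixed amplification
  efficiency 2.0 and no multi-reference normalization.
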