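# Methods

`hmmscreen` builds a profile hidden Markov model (HMM) of a protein
family from a multiple sequence alignment, calibrates a score-to-E-value
map, and screens six-frame-translated nucleotide assemblies for family
members. It was written with subclass I lantibiotic (lanthipeptide)
modification enzymes in mind — the LanB lanthionine dehydratase family
that marks subclass I biosynthetic gene clusters in microbiome
assemblies — but nothing in the implementation is specific to that
family.

## Model architecture

The profile is the classic left-to-right match/insert/delete
architecture. An alignment column whose weighted non-gap occupancy is at
least the occupancy threshold (default 0.5, boundary inclusive) becomes
a match state; the model has `M` match states, insert states `I_0..I_M`
(one before the first match position and one after each) and one delete
state per position. Transition probabilities are stored per position
`k = 0..M` as the seven core moves (M→M, M→I, M→D, I→M, I→I, D→M, D→D),
with the three source-state groups each summing to one. Row 0 carries
the begin-state transitions, row `M` the transitions into the implicit
end state.

### Parameter estimation

* **Sequence weights.** Henikoff position-based weights: within a
  column, each distinct residue type shares a unit of weight equally
  among the sequences carrying it, divided by the number of types; a
  sequence's weight is its sum over columns, normalized so the weights
  sum to the number of sequences. Weights are computed only over
  columns with ≥ 50% non-gap occupancy. Rarely occupied insert columns
  are excluded on purpose: a column occupied by a single sequence would
  otherwise hand that sequence an entire column's weight (we measured
  weight ratios above 100× on profile-sampled alignments), which
  visibly flattens the estimated emissions.
* **Match emissions.** Weighted residue counts per match column plus
  background-proportional pseudocounts with total mass `alpha`
  (default 1.0): `p(a) = (c_a + alpha·bg_a) / (C + alpha)`. X residues
  and gaps carry no count.
* **Insert emissions.** Fixed to the background distribution — the
  standard choice; inserts then score zero bits and only transition
  costs discourage them.
* **Transitions.** Each aligned sequence induces a unique path through
  the match/insert/delete skeleton; weighted transition counts get a
  flat `alpha/7` pseudocount per move before per-group normalization,
  so every transition is strictly positive.
* **Background.** Flat 1/20 by default; `background="empirical"` uses
  weighted training-set frequencies. The flat default keeps scores
  comparable across models built from compositionally biased families.

A note on weighting and parameter recovery: Henikoff weighting corrects
phylogenetic redundancy, which i.i.d. samples from a known profile do
not have. On such data the weighting systematically flattens skewed
emission columns (total-variation error plateaus near 0.07 regardless of
sample size, versus 0.027 and shrinking for uniform weights at n =
2,000). The parameter-recovery benchmarks therefore rebuild with uniform
weights (`reweight=False`); screening pipelines use Henikoff weights, as
real family alignments are redundant.

## Local alignment scoring

Both scores are log-odds in bits against an i.i.d. background null,
computed in log space with explicit −∞ for forbidden moves:

* **forward** — log₂ of the sum over all local alignments of the path
  odds (the default search score);
* **Viterbi** — the best single alignment, with traceback; ties break by
  state preference M > D > I, then smaller position.

Local alignment is itself probabilistic. An alignment may start at any
residue position `i` and any match state `j`, with entry mass
`1/(M·L)`; it leaves from match state `k` with exit probability
`1/(M−k+1)`, which makes the exit position uniform over the match states
at or after the entry point. Flanking residues are emitted by the
background in both model and null and cancel exactly, as do unknown
residues (X) anywhere. Because the entry, transition and exit masses
never exceed one, the summed path mass of a background-identical peptide
is at most one — an all-X peptide can never score above zero bits, and
a likelihood-ratio (Markov) bound caps the null tail at
`P(score > s) ≤ 2^(−s)`.

The dynamic programming is vectorized across target batches (arrays of
shape `n_targets × M` per residue step), which is what makes the
10,000-peptide calibration experiments below run in seconds rather than
hours.

## E-values

Scores are mapped to E-values through a Gumbel law,
`E = Z · (1 − exp(−exp(−λ(s − μ))))`, with `Z` the number of searched
segments (per-sample by default; a global `Z` can be set for
cross-sample comparability). Calibration scores `n_random` background
peptides (lengths gamma-distributed around a configurable mean) and fits
the parameters by one of:

* `tail` (default) — exponential fit to the exceedances over the upper
  `tail_fraction` quantile: `λ = 1/mean(excess)`, `μ` from the observed
  exceedance rate. Measured on a 300,000-peptide null sample, the score
  tail is exponential with a slope drifting only mildly (≈ 0.88 to
  ≈ 0.68 per bit between p = 10⁻³ and 10⁻⁵), so tail extrapolation from
  the 0.5% quantile stays within ~15% of the true tail probability at
  p = 10⁻⁵.
* `gumbel_ml` — full maximum-likelihood Gumbel fit. Accurate in the
  distribution body (useful for the E-value uniformity diagnostic) but
  body-dominated, and off by ~5× deep in the tail.
* `tail_ln2` — `λ` pinned to ln 2, the asymptotic likelihood-ratio
  slope, with `μ` fitted alone. Conservative: the finite-length tail is
  steeper than ln 2, so pinning overestimates E-values.

Thresholding is inclusive (`E ≤ cutoff`), with 10⁻⁵ as the default
cutoff throughout.

## Screening pipeline

Each sample's contigs are six-frame translated with the standard genetic
code; stop codons split frames into maximal stop-free segments, segments
shorter than 20 aa are dropped (configurable), and every segment keeps
1-based inclusive forward-strand coordinates. Each segment is scored
once (its best local alignment); retained hits on the same contig whose
nucleotide intervals overlap by ≥ 1 bp are collapsed to the lowest
E-value, so a gene found in two frames counts once. Sample summaries
report hits per assembled megabase, with the denominator the total
assembled nucleotides of the sample.

Cross-method comparison treats two hits as the same locus when their
intervals on the same (sample, contig) overlap by at least 50% of the
shorter interval; loci are partitioned into Venn-style regions by the
subset of methods that found them. Group comparisons use the two-sided
Wilcoxon rank-sum test (exact enumeration when the combined size is
≤ 10 and tie-free, normal approximation with midranks and continuity
correction otherwise) or Welch's t-test; both delegate to scipy. Raw
p-values are reported without multiple-testing correction, matching the
typical presentation of per-site screens; a Holm correction can be
applied downstream.

Validation against labelled producer/non-producer controls is
sequence-set-level: a control is detected if any of its translated
segments reaches the cutoff. The report carries the confusion matrix,
sensitivity and specificity, and per-control best E-values so the
cutoff can be swept without re-searching.

## Synthetic data

The generator produces every input class with known ground truth:

* `random_profile` — a ground-truth model with one dominant residue per
  match state (conservation 0.8 by default) and a match-backbone
  transition of 0.96, mimicking a well-conserved enzyme family profile.
* `sample_from_profile` / `sample_msa_from_profile` — i.i.d. generative
  samples, optionally arranged on their true state-path alignment.
* `make_family` — a random ancestor (default 250 aa, the length scale
  of a dehydratase-like enzyme domain) and homologs at a controlled
  expected divergence (default 20%).
* `diverge` — per-site point mutation at a given rate, for positives at
  recognisable distance and far-diverged negatives (rate 0.9 leaves
  ~13% identity, beyond recognition).
* `reverse_translate` — GC-biased codon choice with an appended stop;
  translating frame +1 regenerates the protein exactly.
* `make_metagenome` — background contigs with i.i.d. nucleotides at a
  target GC (default 0.45, gamma-distributed lengths around 5 kb) and
  implanted coding sequences on either strand, with a truth table of
  implant intervals.

What the generator does **not** model: repeat structure, assembly
artefacts, chimeric contigs, coverage variation, and real codon-usage
tables. Passing benchmarks therefore demonstrate the correctness of the
machinery (translation, scoring, calibration, thresholding, bookkeeping)
and detection power under idealized homology, not performance on real
assemblies, where fragmentation and compositional bias matter.

## Benchmark problem sizes

The standing benchmarks use: 100 random small models (M ≤ 3, peptides
≤ 4 residues) against exhaustive path enumeration at 10⁻⁹ tolerance;
parameter recovery from 2,000 sampled sequences of a 10-state model
(every emission row within total variation 0.05); calibration accuracy
as the mean count of background hits at E ≤ t for t ∈ {0.1, 1, 10} over
20 seeds × 10,000 peptides (within a factor of three of t); a 20-contig
screen with five implanted homologs at 20% divergence (all five found at
E ≤ 10⁻⁵, zero false positives); and a 9-positive / 7-negative control
mirror (sensitivity and specificity 1.0). These sizes were chosen so the
whole battery completes in a few minutes on one CPU while leaving each
check statistically meaningful.

## Known limitations

* E-values assume the calibration length distribution resembles the
  searched segments; strongly different length profiles shift `μ` by
  roughly `log₂` of the length ratio.
* One hit per target segment: tandem copies inside a single stop-free
  segment are reported once.
* The profile serialization is an HMMER3-*style* ASCII dialect, not
  byte-compatible with HMMER's `.hmm` files.
* No heuristic pre-filters: scoring cost is `O(L·M)` per segment, fine
  for desk-scale screens, slow for multi-gigabase databases.
* Exact numeric parity with hit counts produced by other tool stacks is
  not promised: match-column choice, pseudocounts, weighting and
  calibration all differ at the level of unstated defaults.
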