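# Methods

## Signal model

Strand-specific sequencing of Okazaki fragments yields, per genomic bin,
a Watson-strand count W and a Crick-strand count C. Because lagging-strand
synthesis runs opposite to fork movement, C counts fragments laid down by
rightward-moving forks and W by leftward-moving forks, and

RFD = (C − W) / (C + W)

is the net fork polarity of the bin: +1 all rightward, −1 all leftward,
0 balanced. Normalizing by the local total makes the profile robust to
depth variation (copy number, mappability). RFD is undefined (missing)
where C + W = 0; missingness is propagated, never imputed.

### Counting conventions

Fragments are assigned to exactly one bin by the 5′-most aligned
coordinate of the fragment (read 1 for paired data) — the biological
start of the Okazaki fragment. Forward-strand alignments count to Watson,
reverse to Crick; `flip_strands` inverts the mapping for protocols whose
chemistry reverses the strand ↔ fork-direction correspondence (the
correct orientation per protocol is an empirical question; the flag is the
escape hatch). Secondary and supplementary alignments are always dropped;
duplicates are dropped unless requested; the default MAPQ floor is 10.
For paired data one of three retention modes applies: all unique read-1
records, read-1 with mapped mate, or proper pairs only. Bins are 0-based
half-open; the default binning keeps autosomes (chrN/N naming) and falls
back to all contigs for other naming schemes, since sex-chromosome
hemizygosity distorts RFD in unknown ways.

### Smoothing

The smoothed track at span k (default 15 bins, i.e. 15 kb at 1 kb bins)
is the RFD of counts *summed* over k bins centred on each bin, stepped by
one bin — a ratio of sums, not a mean of ratios — so deep windows carry
more weight and the downstream read-count mask applies to the same
aggregated totals. Chromosome-edge windows are truncated to the available
bins rather than dropped, preserving subtelomeric signal. The 15 kb
default trades spatial resolution against the reproducibility of
ascending-segment detection between replicates; 2.5 kb (51 × 50 bp bins
rounded to odd) is more appropriate for yeast.

## HMM segmentation

The observed quantity is the step signal ΔRFDₙ = (RFDₙ₊₁ − RFDₙ)/2
between adjacent sliding windows, which for an initiation zone integrates
to the zone's firing efficiency. Windows whose aggregated two-strand
total is below 30 reads are masked (a per-strand variant is available),
as is any window where ΔRFD is undefined. Unmasked ΔRFD values are pooled
genome-wide and cut at the empirical 1/5 … 4/5 quantiles; a value maps to
symbol 1 + #{boundaries strictly below it}, ties falling to the lower
symbol. Genome-wide (rather than per-chromosome) quantiles keep the
symbol alphabet comparable across chromosomes. The boundaries are written
into the output metadata.

The 4-state chain — Up (initiation), Down (termination), Flat1, Flat2 —
uses fixed, documented probabilities rather than trained ones, because
the segmentation targets a known signal shape rather than an unknown
mixture. Defaults: uniform initial distribution; self-transition 0.99
with the remaining 0.01 split evenly (state persistence on the 10-window
scale, matching real zone sizes); emissions Up = (0.02, 0.03, 0.10, 0.35,
0.50) over ascending quantile symbols, Down the exact reverse, both Flats
(0.10, 0.20, 0.40, 0.20, 0.10). The mirror symmetry (Up reversed = Down,
Flat1 = Flat2, symmetric transitions) guarantees that swapping Watson and
Crick maps Up segments onto Down segments exactly. Parameters load from a
JSON file for other designs.

Decoding is Viterbi in log space — a single globally consistent path,
with ties broken to the lowest state index in (Up, Down, Flat1, Flat2)
order for determinism — and forward–backward (scaled) supplies per-window
posteriors used only as confidence. Masked windows stay *inside* the
chain with emission likelihood 1 for every state, so short masked gaps
(repeats, low-mappability patches) do not fragment segments; runs
consisting entirely of masked windows are dropped afterwards.
Chromosomes are decoded independently from the initial distribution.
Both recursions are checked in the test suite against brute-force path
enumeration and the analytic chain marginals.

### Segments, efficiency, confidence

Maximal same-state runs become segments spanning the centre bins of their
first and last windows. Efficiency is ΔRFD_segment =
(RFD_end − RFD_start)/2 with each flank RFD computed from raw counts in a
5 kb window centred on the segment extremity (missing if a flank has no
reads). Confidence is the mean posterior of the assigned state over
member windows.

Up/Down calls additionally pass a noise floor: |ΔRFD_segment| ≥ 0.1 by
default. The flank RFD of a genuine zone is bounded below by its firing
efficiency, while counting noise alone produces |ΔRFD_segment| of order
1/√(flank reads) (≈ 0.07 at 40 reads/kb with 5 kb flanks); the floor is
about twice that and is scale-free, which we prefer over a minimum
segment length (the natural zone length differs 20-fold between yeast and
human). `min_abs_efficiency=0` disables it.

Flat runs whose mean |RFD| exceeds 0.5 are exported separately as
high-polarity regions — candidate domains replicated by long-travelling
unidirectional forks, where head-on transcription–replication conflicts
concentrate.

Replicate reproducibility keeps segments of a reference replicate having
≥ 1 bp same-state overlap in the other replicate (or centre distance
below a threshold); distances from zone centres to annotated features
(e.g. known origins) use centre-to-centre distance with a 2 kb default
overlap call.

## Origin efficiency metric

At bin boundary i with quadrant width L bins,
OEM_i = W_L/(W_L+C_L) − W_R/(W_R+C_R) over the windows [i−L, i) and
[i, i+L). OEM peaks at origins (the Watson fraction falls across an
initiation site) and dips in termination regions, and the positive peak
amplitude estimates firing efficiency on the same 0–1 scale. Quadrant
sums come from integer prefix sums — exact and O(n) per scale — with
boundaries missing where either quadrant is empty or within L of a
chromosome end (0/0 is never coerced to 0). Values are exported on the
bin-width interval ending at the boundary. A scale ladder (default 1, 10,
20, 50, 100, 1000 kb for human data; 50 bp – 25 kb appropriate for
yeast) shows transitions at the size of the zones that produce them.

## Metagene matrices

Rows are regions, columns run 5′→3′ relative to each region
(minus-strand rows are reversed). `reference_point` samples the exported
track at bin-size offsets from the anchor (centre/start/end, strand
aware); `scale_regions` resamples the body to a fixed number of slots by
averaging covered bins and keeps flanks at native resolution. Values are
sampled from track windows rather than recomputed from counts, matching
the usual compute-matrix workflow over exported browser tracks. Mean
profiles report per-column mean, standard error and non-missing n; a
single observation yields a missing SE rather than 0. Matrices are
written as TSV with a JSON header (mode, anchor, bounds) so any plotting
layer can reproduce the heatmap; plotting itself is out of scope.

## Simulator

A replication program is a set of origins (position, firing efficiency
e ∈ (0,1], transition half-width h) placed by order statistics on the
free length after reserving a 4h minimum spacing and 2h end margins —
deterministic under a seed. Two truth models:

- **piecewise_linear** (default): RFD ramps linearly from −e to +e across
  [o−h, o+h] and relaxes linearly to the inter-origin midpoint, where the
  value is (eᵢ − eᵢ₊₁)/2; constant −e₁ / +e_last outside the terminal
  origins. Exact, fast, and analytic — the reference for unit tests.
- **cell_simulation**: per simulated cell each origin fires independently
  with probability e, and a position is replicated rightward iff its
  nearest fired origin lies to the left; RFD is the average over
  informative cells. This model produces plateaus between origins with a
  step at the midpoint rather than a linear relaxation, and saturated
  polarity outside the terminal origins. The two models agree exactly on
  the defining 2e RFD rise across every zone and correlate strongly
  genome-wide, but differ by up to O(e) inside termination regions —
  tests therefore assert the shared rise property, not pointwise
  equality.

Counts are sampled per bin as Poisson(depth) totals split
Binomial(total, (1+RFD)/2) onto the Crick strand. The synthetic BAM
writer emits each counted fragment as a record whose 5′ end lies inside
its bin (read length clipped to the bin), sorted and indexed, optionally
as proper pairs; counting it back through the default filters reproduces
the planted counts exactly.

The standard simulated study conditions used by the acceptance script and
the heavier tests are a 10 Mb single-chromosome genome, 1 kb bins, 20
origins with 30 kb transitions and efficiencies uniform in [0.5, 1], and
mean depth 40 reads per bin — deep, well-separated zones representative
of a good mammalian OK-seq library at desk scale. The simulator does not
model fragment-length or GC bias, mappability holes, replication timing,
or inter-origin interference, so passing tests demonstrate correctness of
the computation and calibration under the stated noise model, not
robustness to every artifact of real libraries.

## Numerical notes and limitations

- All probability work is in log space (Viterbi) or scaled linear space
  (forward–backward); zero emissions are legal and become −inf log
  contributions; a sequence impossible under the model raises an error
  naming the first impossible position.
- Quantile ties map to the lower symbol; constant ΔRFD is rejected as
  degenerate rather than silently producing one quantile.
- RFD/OEM strand-swap antisymmetry is exact in real arithmetic; the OEM
  evaluation rounds differently in the last ulp, so tests compare at
  1e-15.
- Efficiency estimates assume the 5 kb flank windows sit in the flat
  shoulders of a zone; for zones narrower than the flank (sharp yeast
  origins at coarse bins) the estimate biases low.
- The HMM parameters are fixed by design; datasets with very different
  noise structure may need a custom parameter file rather than
  re-estimation, which is deliberately unsupported.
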