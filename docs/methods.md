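# Methods

## Event-space signal model

A pore model maps each k-mer (default k = 5) to the mean ionic current
μ(k-mer) in pA observed while that k-mer occupies the pore. A DNA sequence
of length L is converted to event space by emitting, for each of its
L − k + 1 successive k-mer windows, the model level repeated S times. S
("sampling rate", default 10 for simulation-scale work, 50 suggested for
real squiggles) is the expansion factor that couples the event sequence to
the fixed FFT window below: with window 128 and S = 10 one spectrogram
frame spans 12.8 events. k-mers containing N take the model-wide mean level
and are counted in a warning; coordinates are 0-based and k-mer i covers
bases [i, i+k).

Synthetic pore models draw all 4^k levels uniformly from [50, 110) pA and
spreads from [0.5, 3.0) pA. These bounds bracket the working range of real
pore chemistries; uniform, independent levels are a simplification (real
k-mer levels are strongly structured by base composition), which makes
synthetic signals somewhat *more* distinguishable per event than real ones.

## Landmark fingerprinting

Database construction, per reference and per strand (forward and reverse
complement are both indexed):

1. **Spectrogram.** Short-time FFT with window 128 samples, overlap 64
   (hop 64), rectangular taper; columns are linear magnitudes of the real
   FFT, bins 0..64. A tapered (Hann) variant was evaluated and performed
   slightly worse end-to-end, so the rectangular default stands.
2. **Peaks.** Strict local maxima over a (2·2+1)² neighborhood with
   amplitude ≥ 5 (≥ 20 in the high-specificity profile). On these signals
   the threshold is permissive and peak density is set mainly by the strict
   local-max rule (~1 peak per 25 cells).
3. **Pairing.** Each anchor peak is paired with up to 10 later peaks within
   100 frames (300 in the high-specificity profile). The 10 are spread
   evenly across the candidate range rather than taken nearest-first:
   with ~2 peaks per frame, nearest-first pairing concentrates Δt in 2–12,
   collapsing the effective hash space and flooding posting lists with
   chance collisions; spreading Δt over the full window multiplies key
   entropy ~10× at identical database size. A hash packs (f₁, f₂, Δt) into
   one integer (10 bits per field) and is stored with its anchor frame t₁
   in an inverted index (sorted parallel arrays; persisted as a single
   `.npz` with a JSON parameter header).
4. **Pruning.** `keep_all_pruned` (default) stores every instance and then
   removes any hash occurring more than 50 times within a single reference;
   `keep_last` instead keeps only the final instance per (hash, strand) of
   each reference — cheaper and less sensitive, intended for the
   high-specificity profile.

Classification:

* **Phase scanning.** A read's signal starts at an arbitrary sample offset
  relative to the reference frame grid (a fragment starting at base p is
  misaligned by p·S mod 64 samples), which destroys most exact spectral
  matches if the query is framed only once. The query is therefore
  fingerprinted at `query_phases` = 8 evenly spaced sub-hop sample offsets
  and the per-(reference, strand) offset histograms are merged by maximum
  count per offset — the near-aligned phase dominates and merging never
  double-counts an offset. Scanning more phases gave marginal gains for
  double the cost.
* **Offset voting.** A match of one query hash to a posting contributes to
  offset t₁(reference) − t₁(query); the template score of a placement is
  the number of matches sharing one exact integer offset.
* **Two-strand agreement.** With a complement signal, complement offsets
  are mapped to forward coordinates, o′ = frames(ref) − o_c − frames(read),
  and a reference is callable only where a template offset has complement
  support within ±2 frames (`strand_tolerance`; offsets quantize to ±1
  frame per strand). The joint score is the template count plus the best
  such complement count. Scoring the joint placement — rather than checking
  agreement between each strand's separately-chosen best offset — matters
  at high error rates, where each strand's individual argmax falls to
  chance while the shared true offset still carries the most combined
  support.
* **Calls and ties.** The call is the top-scoring reference; t-way ties
  each receive fractional weight 1/t, so aggregate per-reference counts sum
  to the number of classified reads. Reads too short to frame, or with no
  offset-consistent two-strand support, are reported unclassified with a
  reason.

## Error-induction benchmark

Reads are simulated as uniform random 2,500-base forward-strand fragments
joined to their reverse complements (2D reads). Errors are induced on the
base sequence before conversion to currents: per base one draw from
{match, mismatch, delete} with probabilities (1 − m − d, m, d), a
mismatched base replaced by a uniformly random different base, and an
independent uniform insertion after each base with probability i. The
corrupted read is split at its midpoint into template and complement
halves, converted to signals, and classified. `fraction_correct` counts
each read's fractional weight on the true source. Stay/skip artifacts can
additionally be injected at the signal level (per event block: duplicate
with probability `stay_rate`, delete with probability `skip_rate`).

Observed behavior on 12 random 200-kb genomes: perfect reads ≈ 100%
correct; 10% mismatches retain most of it; 5% deletions or insertions
collapse accuracy — substitutions only corrupt the windows they touch,
while indels shift the signal in time and break both Δt-pairing and offset
consistency.

## Entropy mapping

For a window of m = 20 samples, C(r) is the fraction of the m(m−1)/2 pairs
closer than r; H = −ln(max(C(r), ε)) with ε = 2/(m(m−1)) keeping H finite
(and equal to the one-pair-equivalent cap when no pair is within r). The
radius is r = 0.2 × s.d. of the whole input signal, floored at 1e-6 pA for
constant signals; tying r to the signal's own spread makes H invariant to
shifting and scaling the currents. Windows slide by step = window − overlap
= 1. Traces are compared at zero lag: both are mean-smoothed (window 20),
the reference trace is linearly resampled to the read's length, and
Pearson's r is reported with the two-sided p-value of the exact null for
independent Gaussian sequences (t-transform, n − 2 df). Zero-variance
traces yield an undefined (NaN) correlation, never 0. No elastic alignment
(DTW) is attempted; consequently reads stretched by stays lose the zero-lag
correspondence, and reads at ≥ 0.1 stays per base called are excluded by
the gate (strict inequality at the boundary).

## Event QC

From a tab-delimited event table (columns mean, stdv, length, model_state,
move): bases called = Σ move (the number of new k-mers; a supplied
basecalled length can replace it via a flag, since real basecaller outputs
need not equal Σ move); stays/base = #(move = 0)/Σ move; skips/base =
Σ max(move − 1, 0)/Σ move; median current = median of event means; noise =
median of event stdv (an approximation to the device's per-read noise
metric). The per-k-mer table reports observed mean ± s.d. against the model
level, ordered by model level ascending; the global shift is the unweighted
mean over k-mers of (observed − model).

## Synthetic data: what it does and does not emulate

The generator produces uniform-random genomes, uniform-level pore models,
and event tables with: geometric stay runs (continuation probability p ⇒
p/(1−p) expected stays per base emitted; a skipped k-mer emits no stay
opportunity, so with skip probability q the expectation is
(1−q)·p/(1−p)), Bernoulli skips (probability q per k-mer, accumulated into
the next event's move), Gaussian current noise around model levels, and
exponential dwell times. Not emulated: genome repeat structure and
composition bias, current drift within a run, correlated noise,
dwell/current dependence, and basecaller miscalls in `model_state`. Tests
passing on these data show the algorithms are implemented correctly and
behave as designed under their stated error models; they do not certify
accuracy on real squiggles, where repeats and level structure make
references mutually more confusable.

## Numerical and design choices

* Spectrogram amplitude thresholds (5 / 20) apply to linear FFT magnitude;
  scale and taper are configurable.
* Hash packing is bijective for f ≤ 1023 and Δt ≤ 1023, so windows up to
  2046 samples and pairing limits to 1023 frames are supported.
* Degenerate inputs: sequences shorter than k, signals shorter than the FFT
  window or the entropy window, empty event tables, and all-zero move
  columns raise explicit errors; references too short to frame are skipped
  with a warning when building a database.
* Tie-breaks: equal-count offsets resolve to the smallest offset; tied
  references are reported in lexicographic order with fractional weights.
* Determinism: every simulation takes an explicit seed; one top-level seed
  is fanned out to stage seeds via `numpy.random.SeedSequence.spawn`.

## Problem sizes

The test suite and `scripts/acceptance.py` run the classification
experiments at 12 × 200-kb genomes with 100–200 reads per condition and the
entropy experiments at 100 trials of 2,000-base reads — sizes chosen so the
full suite completes in minutes while keeping binomial standard errors a
few percent. The benchmark design scales to the 1,000-read conditions via
`SimulationParams(n_fragments=1000)` unchanged.

## Known limitations

* Landmark matching requires near-exact timing; indels and stays defeat it
  by design (no query-by-humming-style elastic search is implemented).
* Entropy mapping scores supplied candidate regions only; there is no
  genome-wide entropy index.
* The event-table dialect is TSV; FAST5/HDF5 containers are out of scope.
* Real pore models and real squiggles were not used anywhere; see the
  synthetic-data section for what that implies.
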