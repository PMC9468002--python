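# Methods

## The problem

DNA data storage writes a file into a pool of short synthetic oligos and
reads it back by sequencing. The channel between writing and reading is
hostile in a way ordinary storage media are not: besides per-base
substitutions and indels, stored molecules *break* (hydrolysis during
storage, accelerated by heat) and *rearrange* (breakage–rejoining into
chimeras during unspecific PCR amplification). Classical inner decoders
first cluster reads by strand and then reconstruct each strand by multiple
alignment (CL-MA); both steps assume full-length reads, so fragmentation and
chimerism defeat them. The saving grace of the medium is that every designed
strand exists in many noisy copies.

This package implements a de novo assembly route that exploits that
multi-copy redundancy directly: all reads — mixed, unclustered, fragmented,
chimeric — are decomposed into k-mers, noise k-mers are excluded by
coverage, and each designed strand is reassembled independently by a greedy
path walk through the implicit de Bruijn graph, with an embedded CRC
selecting the unique correct path.

## Strand layout (inner code)

Each designed strand is 200 nt:

    primer5 (18) | index (16) | payload (140) | CRC-16 (8) | primer3 (18)

* 2 bits/base, A=00 C=01 G=10 T=11, most-significant pair first.
* The index is the strand number `m` (also the fountain seed) in big-endian
  base 4; it both identifies the droplet and seeds the decoder's path walk.
* The CRC is CRC-16/CCITT-FALSE (poly 0x1021, init 0xFFFF) over the 39-byte
  image of index+payload, stored as 8 bases. The published layout names the
  field sizes but not the polynomial or the bit mapping; these choices are
  this package's conventions and are fixed so outputs are bit-exact.
* Optional block-checking: one mod-4 parity base after every B payload bases
  (B in 3..10), giving the path search a mid-strand pruning signal for very
  high error channels. Off by default; the payload region stays 140 nt.

A 16-bit CRC passes a random wrong candidate with probability 2^-16, and the
suite verifies exhaustively that every single substitution, insertion or
deletion in a core is detected.

## Outer code

Files are split into 35-byte chunks (= one 140-base payload). Chunks are
combined into Luby-transform droplets: degree from a robust soliton
distribution (defaults c=0.025, delta=0.001, common practice in DNA storage
fountain codes), chunk subset drawn without replacement from a PRNG keyed by
the droplet seed. The seed *is* the strand index, so the decoder regenerates
every droplet definition from the index alone; a small JSON manifest carries
the file length, chunk count, k, probe count and rejected seeds.

Two departures from the most naive construction, both forced by the decoder:

* **Probe order.** Seeds are probed along a fixed full-period LCG over the
  32-bit index space rather than 0,1,2,…  Consecutive small integers give
  near-all-A indexes whose windows crowd a code space of only ~n values, and
  the entanglement filter (below) then rejects a flat 25–35% of candidates
  at every scale; LCG-spread indexes bring rejections down to the birthday
  level (≲2%).
* **Padding.** The tail of the last chunk is padded with a fixed
  pseudo-random byte stream, not zeros: a zero tail is an all-A homopolymer
  whose repeated (k−1)-mers the filter rejects outright. The decoder
  truncates to the true byte length, so pad content never reaches the user.

**Entangled-strand filter.** The decoder's graph walk requires each (k−1)-mer
to occur in at most one designed strand; a repeat is a fork between strands.
Candidate strands are therefore rejected at design time if any (k−1)-mer of
their core, in either orientation, already occurs in an accepted core (or
twice within their own core). Rejected seeds are skipped and recorded.
A consequence worth knowing: highly repetitive *input data* produces
repetitive payloads that the filter cannot place — compress before encoding
(the published demonstrations store zipped archives for the same reason).

**Outer decoding** is classic peeling plus a Gaussian-elimination
inactivation step over GF(2) on the post-peeling residual, the standard
trick from the fountain-code literature. Peeling alone needs a few percent
droplet excess; with inactivation any droplet set that spans the chunks
decodes, which matters at desk scales where the *absolute* excess is tens of
droplets, not thousands.

## The decoder

**Stage 1 — counting and filtering.** The de Bruijn graph is just a k-mer
count table; edges are implicit in (k−1)-base overlaps. Every window of
every read *and of its reverse complement* is counted (directed k-mers, both
orientations stored separately, because the walk is directional and
sequencers emit molecules in either orientation). Primer landing sites are
trimmed when found intact (≤2 mismatches) at a read end. Noise k-mers are
excluded by a coverage cutoff: a specific error is individually rare, so
erroneous k-mers sit near coverage 1 while correct ones sit near the copy
number. The cutoff can be fixed (2 throughout the desk-scale drills) or
chosen automatically as the valley of the log-smoothed coverage histogram,
bounded to [2, copies/2].

**Stage 2 — per-index path search.** For each designed index m: encode m to
bases; seed with the table k-mer(s) whose leading 16 bases equal the index
(for k>16 this is a contiguous range scan of the sorted code array); extend
every live path by each base whose k-mer survives the filter; paths that
reach the 164 nt core length are candidates; the CRC (and block parity, if
enabled) must pass for *exactly one* candidate — zero passers is a failure,
two is ambiguity, and ties are never arbitrated by coverage. The frontier is
capped (default 10^5 live paths); on overflow the strand is retried once
with the cutoff raised by one, then recorded as ambiguous. Indexes are
processed independently, so results are invariant to read order and index
order (tested by permutation).

**k selection.** Smallest odd k in [17, 33] such that the expected number of
colliding (k−1)-mers across the pool — a birthday bound,
n_total(n_total−1) / (2·4^(k−1)) with n_total = n_strands·(core_len−k+2) —
stays below 1% of the strand count. Odd k avoids palindromic
self-reverse-complement k-mers. One k=17 graph indexes roughly a megabyte-
scale pool; the bound, not memory, is what grows k.

## S_m: the reconstruction ceiling

A strand can be assembled only if its entire k-mer path survives the
coverage filter. `estimate_sm` measures this by Monte Carlo: corrupt
`copies` copies of a random core, count k-mers, apply the cutoff, and score
the fraction of repetitions in which every true k-mer keeps coverage ≥
cutoff. Common random numbers (a fixed seed) make sweeps over rates or
copies smooth. The estimator takes k explicitly and the package evaluates it
at the decoder's k, so that S_r ≤ S_m stays a meaningful invariant (and is
tested as one).

Representative values at k=17, cutoff 2 (400 repetitions): S_m ≈ 0.95 at
10 copies / 3% mixed point errors; ≈ 0.42 at 10 copies / 5%; ≈ 1.0 at
20 copies / 5%. The 5%/10-copy point is a genuine cliff: a k-mer window is
error-free with probability ~0.95^17 ≈ 0.42 per copy, and demanding every
one of 148 windows twice among 10 copies is already improbable. Only k ≤ 9
would push this point above 0.9, and such small k cannot index a pool (or
even keep a single 164 nt core self-collision-free at the 1% bound), so the
package does not claim high S_m at 5% with 10 copies; at 20 copies, or at
3%, the ceiling is high and the decoder operates near it.

**Operating-point rule.** The outer redundancy must budget for the ceiling:
redundancy > (1+ε)/S_m − 1, with ε the outer decoder's small overhead need.
The published 7.8% figure assumes ≥95% of strands received (deep sequencing
of a wet pool); at the 10-copy, 3% desk operating point S_m ≈ 0.94, so the
desk-scale drills default to 15%.

## Channel model

Per molecule, corruption follows the physical order: breaks (Poisson count,
uniform positions; optionally forced ≥1 for guaranteed-fragmentation stress
runs), then rearrangements (a chosen fraction of the per-copy fragment pool
joined pairwise into chimeras, cross-parent when possible, base count
conserved), then point errors (independent per position; substitutions
uniform over the three alternatives; insertions add a uniform base after the
position), then random read orientation. Mixed-error budgets follow the
1:1:2:1:1 (breaks : rearrangements : sub : ins : del) convention:
sub/ins/del weights become per-base rates, break/rearrangement weights
become per-molecule expected event counts from the same budget of
rate × strand-length events. Everything is deterministic given the seed.
Qualities are a constant Q40 placeholder (the decoder ignores them); PCR
bias and machine-specific error profiles are out of scope.

## The CL-MA baseline

A minimal, faithful stand-in for the traditional route, not a reproduction
of any specific pipeline: orient each read by its 5' primer (edit distance
≤5, either strand), require both landing sites (full-length products only,
as standard read preprocessing does), trim them, discard cores deviating
>10% from 164 nt, cluster by the exact 16-base index prefix, and per cluster
(minimum 3 reads — a majority needs voters) take a column-wise majority
consensus over a center-star alignment against the medoid, accepting the
consensus only if its CRC passes. It recovers substitution-laden pools well
and collapses on fragmented or chimeric ones — which is the comparison the
sweeps quantify.

## Desk-scale study conditions

Simulations in tests and in `scripts/acceptance.py` use 200-strand pools,
20 copies, 3 replicates with distinct seeds for sweeps; 1 MB files at
10 copies for round trips; 200–400 Monte Carlo repetitions for S_m. These
sizes are this package's desk-scale choices; the published experiments run
the same pipeline at 6.8 MB / 210,000 strands and GB-scale simulation.
Copy-number sweeps reuse one read set at the maximum copy number and take
nested prefixes (common random numbers), so the reported copies-trend is not
dominated by sampling noise.

What the generator does not emulate: coverage skew across strands (copies
are exact, not sampled from an amplification distribution), sequencing
quality structure, synthesis-batch effects, and GC-/homopolymer-dependent
error rates. Passing tests therefore demonstrate algorithmic robustness
under the stated error processes, not wet-lab performance.

## Numerical and degenerate-input notes

* k-mers are packed two bits per base into uint64 (k ≤ 32 in packed form;
  the admissible decode range is 17–33, and 33 would need a wider type —
  `choose_k` only reaches 33 beyond ~10^13 strands, far outside desk scale).
* Reads shorter than k contribute nothing; fragments are still emitted.
* `check_strand` is strict about length: wrong-length candidates are layout
  errors, never truncated.
* Consensus tie-breaks in the baseline are deterministic (medoid base,
  then alphabetic); path candidates are deduplicated before CRC selection.
* Empty inputs, out-of-range indexes, and rate/parameter violations raise
  typed errors rather than propagating garbage.

## Known limitations

* Uncompressed, highly repetitive inputs can exhaust the entanglement
  filter (CapacityError): compress first.
* At copy numbers below ~6 with 3% errors the cutoff-2 ceiling is low and
  the CL-MA baseline is genuinely better — consistent with the published
  copy-number comparison; the de novo route is the right tool from ~7
  copies up.
* The MA baseline is intentionally minimal; a published clustering algorithm
  with edit-distance clustering would recover more reads at high
  substitution rates (it would still fail on breaks and chimeras).
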