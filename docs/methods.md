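# Methods

`chemsteg` implements a complete chemical-steganography pipeline: a secret
key is converted into acoustic-liquid-handler instructions that permute an
object's pre-existing surface chemistry, and recovered later from mass
spectra of that surface. Because no real instrument is attached, the
package ships a statistical simulator of the whole physical channel —
substrate, extract library, droplet deposition, FT-ICR-style acquisition —
so that every digital component can be exercised end to end. This note
records the models, the defaults and the reasoning behind the open design
choices.

## The digital chain

### Payload framing

A key (UUID/hex or raw bytes) is binarized MSB-first, turbo encoded at
rate 1/3, repeated `R` times, zero-padded to fill the `M x N` transfer
frame, interleaved, and cut into `log2(L)`-bit symbols (MSB-first; symbol
0 = dispense nothing, symbols 1..L-1 = log-spaced dilutions, symbol L-1 =
undiluted). All permutations are regenerable from a single shared integer:
a Fisher-Yates shuffle driven by a fixed 64-bit linear congruential
generator (a = 6364136223846793005, c = 1442695040888963407, mod 2^64;
swap index from the top 32 bits of the state), evaluated in exact integer
arithmetic so writer and reader agree across platforms.

Repetition inversion is soft where it can be: for binary symbols the
continuous regression outputs are averaged across the R copies of each
coded bit before thresholding at 1/2 (exact ties fall to 0); for L > 2 the
symbols are quantized to the nearest level first (ties round down).

### The turbo code

The error-correcting code is a parallel concatenation of two identical
recursive systematic convolutional encoders. The binding external
constraint is that a 128-bit key must yield **exactly 384 coded bits** —
no transmitted termination. Within that constraint the constituent
design is free, and we chose it for frame-error performance at this very
short block length:

| choice | value | why |
|---|---|---|
| constituents | memory-4 RSC, feedback 23 (octal), feedforward 33 | measurably lower frame-error rate at n=128 than the classic memory-2 (7,5) pair |
| trellis ends | tail-biting (circular) | uniform two-sided protection for every bit with zero transmitted tail bits; the encoder starts each trellis in its circulation state, computed over GF(2) (falls back to a plain unterminated run when `I + A^n` is singular, i.e. n a multiple of the feedback period) |
| decoder | iterative BCJR, exact log-MAP metric, 16 iterations, early stop when the two constituent hard decisions agree | max-log-MAP costs ~0.5 point of threshold at this length |
| tail-biting decoding | boundary metrics estimated by wrap-around warm-up passes (8 x memory trellis steps) | standard circular-BCJR approximation |
| internal interleaver | quadratic permutation polynomial pi(k) = (15k + 32k^2) mod n when bijective, else the seeded LCG/Fisher-Yates shuffle | QPP spread suppresses the short-block error floor (measured ~4x fewer frame errors at a 12% flip fraction than a random permutation) |

LLR convention: positive favours bit 0; hard-decision inputs use
`(1-2y) ln((1-p)/p)`. Ties in the final hard decision resolve to 0.

Measured with this stack: flipping exactly 12% of the 384 codeword bits,
the frame-error rate is about 0.1-0.4%, and a 1%-step sweep over raw
error rates reports 12-13% as the largest rate at which 100/100 random
keys decode perfectly. A finite-blocklength aside explains why the sweep
is over *realized* flip fractions: at BSC crossover 0.12 the normal
approximation (channel dispersion) bounds the frame-error rate of *any*
rate-1/3, n=384 code at ~0.2%, because noise realizations with far more
than 12% flips are common; the threshold claim is therefore a statement
about the raw error rate a message actually suffered, which is also what
an experimenter measures per message.

## The synthetic channel

### Substrate

The untreated cover is modelled on a worn banknote imaged by
laser-desorption FT-ICR:

- a fixed compound catalog (seeded separately from the realization, since
  the object's chemistry does not change between measurements): 50 dye
  peaks decaying log-linearly over 2 decades from 1e9 a.u., the strongest
  pinned at the phthalocyanine lock mass m/z 575.0788, plus 4000 trace
  compounds continuing the tail over 4 more decades (1e7 -> 1e3);
- a two-class dye/no-dye spatial pattern (checker blocks; dye intensities
  x0.3 in the dye-free class), standing in for the two chemical classes
  visible on a real bill;
- sporadic compounds: a fraction 0.0013 of the catalog is confined to one
  (realization-specific) surface location — the "masses seen at exactly
  one spot" census;
- per-location lognormal intensity jitter (sigma = 0.25 natural log).

Spectra are centroided peak lists with true compound masses; all
measurement distortions live in acquisition.

### Extracts

Each extract is a solvent pull of the cover's own chemistry: its shared
profile is the catalog's ubiquitous compounds, proportional to their
substrate intensities, scaled to 1e5 a.u. at the strongest compound —
so a full-strength deposit perturbs every mass by a relative epsilon
(~1e-4 of the dye background, matching the identifying-signal-to-
background ratio the readout has to live with). Mild per-extract
lognormal enrichment (sigma = 0.5) differentiates extracts along the
shared profile. Each extract additionally carries 4 unique identifying
masses (intensities 1e5, 5e4, 2.5e4, 1.25e4; extract 0 gets the
conventional 184.07 and 478.33 first), pairwise disjoint across extracts
and kept > 0.02 Da away from the catalog. With 4 unique among ~4054
compounds the shared fraction is 99.9% (the real-bill figure is 99.99%;
a desk-scale catalog cannot reach it with at least one unique mass).

Because the identifying compounds are natural trace products of the
cover, they also occur sporadically in the untreated background: at each
location, each unique mass appears with probability 0.25 at a lognormal
trace intensity (median 1e3, sigma = 1 natural log). This ambient
interference is what makes presence/absence readout genuinely noisy.

### Writing and reading

Deposition is additive: each picklist row adds `signature x dilution x
volume/2.5 nL`, matched into the location's peak list within +-0.005 Da
(nearest peak, ties to lower m/z). Dispense noise: lognormal efficiency
sigma = 0.05 (acoustic dispensers are precise; surface spreading adds a
few percent) and a 2% chance a transfer largely fails (1% of material
arrives). With both at zero, deposit is exactly invertible by
subtraction.

Acquisition averages `k` reads: per read, mean-preserving lognormal
intensity scatter (sigma = 0.25, a ~25% shot-to-shot CV) plus
sqrt-intensity shot noise; the averaged noise standard error shrinks as
1/sqrt(k). The location drifts by a common calibration shift (sigma =
0.002 Da) removed later by lock-mass alignment, per-peak m/z jitter is
5e-4/sqrt(k) Da, and averaged peaks below 1 a.u. are dropped
(centroiding threshold). Dilutions default to 32 log steps spanning 2
decades.

## Readout

The reader aligns every spectrum on the lock mass (strongest peak within
+-0.05 Da; unreadable locations are flagged), converts intensities to
SNR = (I - mu)/sigma, and filters features by grid-mean SNR. The
background population for (mu, sigma) is the lowest quartile of each
spectrum's intensities: centroided lists contain only real peaks, so the
weak tail plays the role that sub-noise-floor samples play in a profile
spectrum (a higher percentile would sweep mid-tail trace compounds into
"background" and compress the SNR of trace-scale deposits toward zero).

Concentration regression is one random forest per extract (200 trees,
fixed seeds) predicting the continuous level index from feature SNRs,
trained on pilot spots — a block of locations written with known levels
generated from the shared interleaver seed, so the reader regenerates its
own training labels from the key material it already holds. Before
fitting, the 8 features most correlated with the training labels are
selected per extract; with few pilot spots this screening matters more
than any forest hyperparameter. For characterization we keep the
literal 10% train / 90% test split; for deployment decoding the reader
trains on 80% of its pilots (holding out 90% of data you own buys
nothing at read time).

Quantization maps continuous predictions to the nearest integer level
(log-domain grid; exact midpoints round down), soft repetition averaging
happens before thresholding as described above, and the turbo decoder
consumes hard-decision LLRs at a nominal 10% crossover (uniform LLR
scaling is almost immaterial to the iterative decoder).

## Detectability

The steganalysis metrics are exactly the computations an analyst without
the key could run: the sorted mean-peak intensity curve, the census of
masses confined to one location above an intensity cutoff (thresholding
the single occurrence keeps the count monotone in the cutoff), the
shared-compound fraction of a library, and total-vs-identifying signal
profiles along a grid row. "Concealment" is operationalized as two-sample
Kolmogorov-Smirnov tests between encoded and untreated grids on (a) the
log mean-peak intensity distribution, (b) the per-location total signal,
and (c) the unique-mass census curve; at default extract scale all three
stay statistically indistinguishable (p > 0.05) across seeds.

## Problem sizes used in the tests

The shipped tests run the complete pipeline at desk scale, chosen so the
whole suite stays in the minutes range on one CPU: the end-to-end key
demonstration uses a 12x12 grid (3 extracts, 4 levels, 64 data + 48 pilot
spots); the repetition/averaging sweep a 24x24 grid (6 extracts, binary,
R = 1..6, k in {4, 32}, 3 replicates, pooled over the 384-bit codeword);
the 32-level write/read characterization a full 32x32 grid of pilot spots
(2 extracts, 1024 readings each, 10/90 split, 32x read averaging — the
heavy-averaging acquisition setting); concealment 20 seeds at the
demonstration scale; and the turbo threshold sweep 100 keys per 1% step.
Physical-model defaults are never changed between tests; only grid sizes,
extract counts and replicate counts vary.

## What the simulator does and does not capture

It captures: a heavy-tailed shared chemical background with spatial
structure, near-identical extracts with trace-level identifying masses,
ambient interference at exactly those masses, multiplicative write/read
noise with 1/sqrt(k) averaging, calibration drift with lock-mass
correction, dilution-series encoding, and the full digital chain. It
does not capture: ionization suppression and matrix effects, isotope
envelopes and adducts (each compound is one peak), spatial bleed between
neighbouring spots, surface degradation under repeated laser reads,
profile-mode peak shapes, or instrument-specific mass-accuracy drift
beyond a constant per-location shift. Passing tests therefore show that
the algorithms are correct and that the workflow is robust in a channel
with realistic *statistical* structure — not that a particular physical
banknote will reach the same error rates.

## Known limitations

- The regression readout needs on the order of 1e2-1e3 labelled pilot
  spots per extract for dense level grids (L = 32); at the 10/90 split
  with only ~40 training spots, exact-level accuracy drops to ~0.2.
- Levels near the bottom of the dilution range sit at the ambient
  interference scale and are systematically harder — error mass
  concentrates there and between adjacent levels, as in the write/read
  scatter.
- The codec's measured zero-failure threshold (12-13% raw error over 100
  keys) is seed-dependent at the 1-point level, because the frame-error
  rate near threshold is a fraction of a percent.
- `unframe` treats levels in excess of the frame's capacity check as a
  hard error rather than attempting partial recovery.
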