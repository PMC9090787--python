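# Methods

## Barcode design

Identities are payloads of k = 3 symbols over GF(16); the field uses the
conventional primitive polynomial x⁴+x+1 (0x13, configurable). The
parity-check matrix H (3×6) is drawn at random with column weight 2 and
row weight 4, nonzero entries uniform over {1..15}, and resampled until
the parity-column submatrix is invertible over the field, so systematic
(parity-first) encoding exists. At n = 6 this construction is about
graph regularity and rank, not girth optimization — the code is far too
short for density-evolution arguments to matter, and belief propagation
is checked against exhaustive MAP instead (below).

The dictionary ε is found by seeded greedy search: 16 distinct 6-mers
with pairwise Hamming distance ≥ 3 and 2–4 G/C per word (a mild
synthesizability bound; no homopolymer or secondary-structure screening
is attempted). The watermark is a seeded pseudo-random 36-mer.
Nucleotides are identified with GF(4) as A=00, C=01, G=10, T=11, making
⊕ a bitwise XOR; any consistent labeling is isomorphic, and A=0 keeps
"no watermark" equivalent to an all-A watermark. H, ε and w are design
choices of this package: decoded *identities* are only meaningful
relative to a given spec YAML, which reproduces a design bit-exactly.

Of the 4096 barcodes, 3840 are marked synthesized (split 1920/1920 into
pools A and B at random) and 256 are negative controls: designed,
decodable, but never placed on any molecule, so every decode to one is a
detected error.

## The simulated experiment

The simulator emulates a two-species "barnyard" run. Constructs are

    BPF – bc5 – pad – CS – A – insert – rc(A) – rc(CS) – rc(pad) – rc(bc3) – rc(BPF)

with pool-specific 20-nt consensus sequences (CS) and species primers
taken from the real protocol, pads CGC/GCG, and seeded-random 20-nt BPF
sites and insert interiors (synthetic stand-ins; the real BPF sequences
and amplicon interiors are not published as text). Insert lengths 400
and 538 nt give 560/698-bp constructs. Reads draw a pool at molar ratio
1:2 (A:B), a barcode pair from the pool's 1920 synthesized barcodes,
and a uniform strand.

Per-barcode abundances are log-normal with σ = 0.7 by default: across
1920 draws the expected extreme-value spread of a standard normal is
about ±3.26σ, so exp(0.7 · 6.5) ≈ 100 — the two-orders-of-magnitude
concentration spread reported for amplified oligo pools. σ = 0 gives
equimolar pools (used for estimator-consistency checks, which assume
uniformity).

The channel applies, per template base, deletion with probability P_d
then substitution with P_s (uniform over the three alternatives), and
inserts a geometric run of uniform bases before every position and at
the end (continuation probability P_i). Default rates are 0.03 each —
a stand-in for a mid-quality single-pass long-read error profile; real
runs vary, which is why the demultiplexer re-estimates rates from the
data. Quality strings are constant: the decoder never reads them.

What the simulator does **not** model: signal-level artifacts, adapter
sequence and imperfect trimming (the real read-length peaks sit ~30 bp
above nominal), quality decay over the run, homopolymer-context errors,
and chimeric molecules. Tests passing on this generator validate the
decoding machinery under the stated channel, not performance on any
particular flow cell; the real-run headline numbers (86.4% recovery at
0.17% crosstalk) depend on an error profile this generator does not
claim to reproduce.

## Demultiplexing pipeline

Coordinates are 0-based half-open; reverse complementation happens only
at subread extraction.

1. **Length filter.** Keep reads with 531 ≤ length ≤ 814 bp (inclusive),
   the ±10% window around the 590/740-bp peak centers; both bounds are
   configurable and derivable via `bounds_from_peaks`.
2. **Anchor search.** The four pad–CS–A–primer strings and their
   reverse complements are aligned semi-globally (edlib HW — free gaps
   at read ends); hits with edit distance ≤ 12 are kept. A pool's FP and
   RP anchors share their 24-nt pad–CS–A prefix, so each also hits the
   *other* end's site 10–11 edits away even on a clean read — inside the
   cutoff. Overlapping same-sense hits (starts within 20 nt) are
   therefore collapsed to the minimum edit distance, which the primer
   region does discriminate; without this, end labels swap and estimated
   substitution rates inflate. Distinct surviving sites of one sense
   then compete by decoding confidence (highest L wins).
3. **Rate estimation.** P_s, P_i, P_d are the mismatch, read-insertion
   and template-deletion counts from the anchor-alignment CIGARs divided
   by template-consuming columns (matches + mismatches + deletions),
   aggregated over all kept hits. Alignment-derived estimates are biased
   slightly low for indels (boundary indels absorb into the free end
   gaps; adjacent insertion+deletion pairs collapse into substitutions):
   about −0.004 on P_i at 3% rates, growing with the rate. A config
   override is available when rates are known.
4. **Subread extraction.** Forward hits: window [start−61, start+56);
   reverse hits: [end−56, end+61) then reverse complemented. Either way
   the decoder sees a forward-oriented subread with the anchor starting
   56 nt before its end and the 36-nt barcode immediately upstream,
   leaving 25 nt of slack. Windows clipped by a read boundary are
   truncated and flagged; offsets are kept relative to the subread end,
   which survives slack-side truncation.

## The decoder

**Drift lattice.** The subread and templates are reversed, and a
forward pass runs a banded HMM whose state is the drift d = (received −
transmitted position), |d| ≤ 15 — more than 3σ of the indel random walk
over a 117-nt window at the default rates, and matching the 25-nt
extraction slack. Per template step the lattice allows ≤ 2 insertions
(geometric weights P_iʲ(1−P_i)(1/4)ʲ), deletion (P_d), or transmission
with emission 1−P_s on match and P_s/3 on mismatch — the simulator's
exact generative model. Rates are floored at 10⁻⁴ so nominally
noiseless channels keep a connected lattice. The pass starts with a
uniform drift prior at the anchor's far end and traverses the anchor
first ("walking upstream"), concentrating the drift posterior at the
barcode boundary before any barcode base is scored. Unknown barcode
positions during synchronization use the position-wise mixture emission
over a uniform symbol prior; the watermark is removed *inside* the
emission model by ⊕-shifting dictionary entries per position, so the
lattice is watermark-agnostic. A backward pass (all-ones at the far
template end: read bases beyond the template are unmodeled) meets the
forward pass at every block boundary, and each 6-nt block is scored for
all 16 candidate symbols simultaneously, yielding the n×q likelihood
matrix. Messages are renormalized per step (a single shared scale across
the 16 symbol hypotheses, preserving their ratios); rows are normalized
to sum to one and the scale constants kept in log₁₀.

**Belief propagation.** Sum-product on H with a flooding schedule, no
damping, at most 50 iterations; check-node convolutions are computed
directly over GF(16) via the XOR index table (O(q²) per edge — trivial
at n = 6). Decoding succeeds only when the hard decision satisfies every
check; ties in hard decisions break toward the lower symbol. The
exhaustive MAP decoder scores all 4096 codewords on the same likelihood
matrix and is used as an oracle: BP agrees with it on ≥ 99% of
non-failed decodes at 3% channel rates (measured ~99.8%).

**Confidence.** L = ∏ᵢ L(dᵢ) over the row-normalized likelihoods of the
decoded symbols, stored as log₁₀ L ∈ (−∞, 0]. Normalization makes L
scale-free and window-length-independent; thresholds are data-driven
(the sweep uses every observed value), so only the ordering matters.

## Metrics and the negative-control estimator

A "considered subread" is one per (read, sense) with at least one
qualifying anchor hit. At a threshold t, each considered subread is
exactly one of: decoder-failed, below threshold, decoded to a negative
control, or recovered — conservation is exact by construction. Recovery
= recovered/considered; crosstalk = misassigned/recovered (undefined,
not zero, when nothing is recovered).

Without ground truth, crosstalk is estimated as the negative-control
fraction among confident decodes times 3840/256 = 15, exact under the
uniformity assumption that any barcode is equally likely to be mistaken
for any other. The `corrected` mode replaces the flat factor by one
weighting each potential error target by source abundance and an
edit-distance kernel exp(−λ·Levenshtein) (λ = 1 per edit by default,
source subsampling for tractability). This is a documented
approximation for non-uniform pools — a plausibility-weighted
reallocation, not an exact bias correction.

Consistency of the uniform estimator is validated on a 2500-read
equimolar simulation at 5% rates (5% rather than 3% so enough decode
errors occur for the comparison to be informative). The check compares
the estimate with ground-truth crosstalk at 95% confidence *including
both sampling variances*: the estimator multiplies a small count by 15,
so its standard error is √15 ≈ 3.9× the ground truth's at any sample
size, and a one-sided interval around truth alone could never reach
nominal coverage.

## Problem sizes and numerical choices

Exhaustive checks (field axioms over all 16³ triples, syndromes and the
noiseless decode round trip over all 4096 barcodes) run in full. The
stochastic validations use 1000 subreads for BP/MAP agreement, ~10⁴
anchor hits for rate recovery, and 2500 reads (≈5000 subreads) for the
estimator and threshold-sweep checks — sizes at which the relevant
standard errors are several times smaller than the tolerances being
asserted. The lattice band (±15) and insertion-run cap (2 per step)
discard negligible probability mass at the default rates; decode of one
subread takes a few milliseconds in pure numpy.

## Known limitations

- Decoded identities match a given spec YAML, not any externally
  synthesized barcode set; H, ε and w are seeded reconstructions.
- The anchor-overlap collapse assumes the two primers of a pool differ
  by clearly more than the channel noise over the anchor length; nearly
  identical primer pairs would need longer anchors or pool-specific CS
  at both ends.
- Windows truncated on the anchor side (hits within 56 nt of a read
  boundary on the anchor's side) lose the offset convention and
  typically fail decoding; they are flagged rather than rescued.
- The corrected negative-control estimator is heuristic; its λ is not
  fitted to data.
- Edlib reports only best-scoring locations per anchor, so a weaker
  second occurrence of the same anchor (e.g., in a chimera) ≤ 12 edits
  away can be missed; chimeras are expected to be removed by the length
  filter.
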