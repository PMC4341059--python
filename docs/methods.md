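# Methods

`fluorosim` models single-molecule peptide sequencing by Edman degradation
("fluorosequencing"): peptides carrying residue-specific fluorescent labels are
anchored to a surface and repeatedly stripped of their N-terminal residue, and
the cycle at which each fluorescent channel loses intensity is recorded. The
observed read — the *fluorosequence* — is the ordered set of (channel, cycle)
luminosity drops. This note describes the model, its parameters, the synthetic
data, and the numerical and design choices.

## The sequencing model

**Digestion and anchoring.** A proteome is digested completely (no missed
cleavages) by a protease that cuts C-terminal to a recognition set: GluC {E},
CNBr {M}, trypsin {K, R}, or `none` (intact proteins). Peptides attach to the
surface either through a cysteine thioether (only Cys-containing peptides are
retained; the anchor is the first Cys) or through their C-terminus (all
peptides retained). Edman chemistry cannot remove the anchor residue or
anything C-terminal to it, so drops can only originate from labeled positions
strictly before the anchor — except that fluorophores anywhere, including past
the anchor, can still photobleach and register a drop.

**Ideal encoding.** With perfect chemistry, a labeled position *p* produces a
drop at cycle *p* when `p < anchor_index` and `p ≤ cycle budget`. Multiple
residue types may share one channel (the four-label preset maps both D and E to
channel "E"); a drop is a binary per-channel, per-cycle event, so coincident
losses in one channel collapse to a single drop — the model deliberately does
not assume fluorophore counting.

**Error model.** Three independent stochastic processes corrupt a read, applied
in this order:

1. *Dye failure* (probability `u` per label, default axis 0–0.25): a label
   that never fluoresces; the read loses that drop.
2. *Edman inefficiency* (per-cycle success `p`, default axis 0.90–1.00): an
   inter-label interval of `d` residues takes `d + e` cycles with probability
   `C(d−1+e, e) · p^d · q^e`, the negative-binomial law of `e` failures
   interleaved before the `d`-th success. Extra cycles accumulate down the
   peptide, so all downstream drops shift together.
3. *Photobleaching* (decay constant `b` per cycle; half-life = ln 2 / b):
   each fluorophore survives `k` cycles with probability `e^(−b·k)`. A bleach
   before the label's removal moves its drop to the bleach cycle — an apparent
   upstream residue. Laser exposure is additive, so one exponential draw per
   fluorophore suffices; the continuous bleach time `T` is discretised to
   cycle `⌈T⌉` (the bleach clock starts with the first post-Edman imaging, so
   cycle 0 is impossible), and a tie between bleach and removal yields the one
   drop at that cycle.

The vectorised batch simulator draws dilation over all removable labels rather
than only dye-surviving ones; by negative-binomial additivity (a sum of
NB(dᵢ, p) variables is NB(Σdᵢ, p)) the joint distribution of the surviving
labels' removal cycles is unchanged. The tests verify this against both the
literal per-copy composition and an exhaustive enumeration of the outcome
distribution for a worked peptide.

## Attribution and coverage

Simulated reads are collated into a prefix trie keyed by drop events with
absolute cycle indices, each node tallying per-source-protein counts for the
read ending there. Normalised node counts estimate the posterior
P[protein | read]. A read is **uniquely attributed** when its top protein
yielded it at least `min_count` times *and* all rivals combined hold strictly
less than `rival_fraction` (default 10%) of its observations; a protein is
**covered** when it owns at least one uniquely attributed read. The coverage
denominator is the whole input proteome, including proteins whose peptides all
lack an anchor. Empty reads are tallied (for count conservation) but never
attributable.

`min_count` defaults to 10 per 10,000 simulated copies, scaled proportionally
with depth. At desk-scale depths (~100) the proportional rule floors at 1 and
degenerates: every singleton read becomes "uniquely attributed", so adding
noise *raises* apparent coverage. The threshold is fundamentally an absolute
sampling-error guard, so scaled-down experiments in this package pass
`min_count=10` explicitly; treat coverage from depth < ~1000 with the
proportional default as unreliable.

Ideal-condition coverage needs no sampling and is computed exactly: a protein
is identified at budget *n* iff one of its peptides' ideal reads truncated to
*n* cycles is produced by no other protein.

## Randomness and parallelism

All randomness flows from a master seed through `numpy.random.SeedSequence`
substreams keyed by protein index (and, in sweeps, by grid-combination index).
Sharded execution over protein subsets therefore reproduces the unsharded
result byte-for-byte after trie merge, whatever the shard count.

## Synthetic proteomes

The generator draws residues i.i.d. from a composition table — uniform by
default (assumption-free), or a shipped "human-like" table of approximate
Swiss-Prot average frequencies — with lengths from a lognormal with median 375
residues and σ = 0.6, floored at 30 (roughly the shape and scale of real
protein length distributions). What it deliberately does not emulate: residue
autocorrelation, paralog families and shared domains, signal peptides, or
biased cleavage-site spacing. Green tests on synthetic proteomes therefore
establish the correctness of the machinery and the direction and rough
magnitude of error effects, not real-proteome coverage values, which depend on
sequence redundancy that i.i.d. proteomes lack (notably, i.i.d. proteomes have
almost no indistinguishable paralogs, inflating coverage).

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| cycles | 30 | Edman/imaging cycles per run (200 is sensible for undigested proteins) |
| depth | 10,000 | simulated copies per peptide; desk runs use 100–500, flagged `scaled_down` |
| dye_failure_u | 0 | per-label dark probability; literature suggests 0.15–0.20 |
| edman_success_p | 1 | per-cycle removal success; literature suggests ~0.94 |
| photobleach half-life | ∞ | in cycles; lifetime in minutes × 60 / exposure-seconds converts |
| min_count | 10 per 10⁴ copies | unique-attribution count guard (see caveat above) |
| rival_fraction | 0.10 | maximum combined rival share for unique attribution |

Sweep axes default to six values per axis (216 combinations): dye failure
0–0.25 and Edman efficiency 0.90–1.00, evenly spaced; the photobleach
half-life axis {∞, 5400, 1800, 600, 210, 70} cycles. The two error-rate axes
span well-established ranges, but the interior photobleach values are a
documented guess — the reference ranges are stated only by their endpoints and
inconsistently (90 minutes at 1 s/cycle is 5400 cycles, yet 210 cycles is
discussed as a tested value) — so the axis spans both and remains fully
config-exposed, as does the labeling-scheme choice for each sweep.

## Numerical choices and degenerate inputs

- Medians use the lower of the two central values for even-size samples, so
  length and label-count medians are always attained integers.
- `p = 1` short-circuits the negative-binomial draw (zero dilation); `b = 0`
  encodes "no photobleaching" (infinite half-life) exactly, not approximately.
- A peptide whose anchor is at position 1 (N-terminal Cys) yields an empty
  read; unlabeled peptides likewise. Both are counted, never attributed.
- Nonstandard residues (U, B, Z, J, O) in input FASTA become `X`: unlabelable,
  non-cleavable, never an anchor, with a logged count. Stop characters `*` are
  stripped.
- Tie-break in attribution when two proteins have equal top counts: the
  lexicographically smaller identifier is "top", which is irrelevant in
  practice because equal counts always fail the rival-share test.
- Fluorosequences have one canonical form (sorted by cycle then channel,
  duplicate-free); the trie rejects non-canonical input rather than reordering
  it silently.

## Known limitations

- Fluorophore photophysics beyond exponential bleaching (blinking, quenching,
  FRET, channel bleed-over) is out of scope, as are protease inefficiency,
  missed cleavages, post-translational modifications, and abundance-weighted
  protein priors (simulation assumes a flat prior over proteins).
- C-terminally anchored peptides never produce an ideal drop from their final
  residue (the anchor cannot be Edman-removed); only bleaching can reveal it.
- Real-proteome acceptance numbers (median peptide lengths 8/26/10 for
  GluC/CNBr/trypsin; four-label CNBr coverage ≈98% C-term / ≈80% Cys) require
  the reviewed human proteome FASTA, which is not shipped; the corresponding
  test directs the user to supply it under `data/human_swissprot.fasta`.
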