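# Methods

This note documents the models, conventions and design choices behind
`peptarray`, in the order the pipeline runs.

## Library design

Toxin sequences are consumed as mature chains (pro-peptide and signal
peptide removal is the caller's responsibility). Each sequence of length
L ≥ 12 is tiled into 12-mers at every second residue (starts 1, 3, 5, …,
1-based). When the step-2 grid misses the final window, an extra tile at
start L−11 is appended (`force_terminal=True`, the default) so every
residue, including the C-terminus, is covered by at least one peptide.
This terminal-window convention is a genuine open choice — an array
designer could equally drop the tail — so it is exposed as a flag; the
default guarantees the coverage invariant the profiling stage relies on.
Sequences shorter than 12 produce no tiles (warning, not error) but stay
in the record set.

Deduplication is global across all toxins: homologous toxins share many
12-mers, and each unique peptide keeps the full list of (accession,
start) occurrences that produced it. The redundancy count reported by the
builder is total tiles generated minus unique tiles.

Alanine variants are generated per unique wild-type peptide, one per
non-alanine position (substituting A for A would reproduce the parent and
is skipped), then deduplicated on variant sequence with all
(parent, position) provenance retained. A variant whose sequence
coincides with a wild-type peptide is kept in the variant set by default
— on a physical array the sequence is synthesised once and measured once,
and signal lookup is by sequence — with `drop_wt_collisions=True`
available as the alternative convention.

The layout replicates each wild-type peptide 5 times and each variant
once, then applies one seeded uniform permutation to the pooled spots so
local intensity biases cannot align with peptide identity. The seed is
stored in the library metadata; identical inputs and seed give a
byte-identical layout.

Coordinates are 1-based throughout, spans inclusive.

## Synthetic experiments

The generator emulates the signal structure of a real antivenom
hybridisation, not its chemistry:

- every spot draws `Normal(expected mean, replicate_sd)` clipped at 0
  (fluorescence is non-negative; the small truncation bias is accepted);
- a wild-type peptide's expected mean is `background_mean` unless one of
  its occurrence spans fully contains a planted epitope core, in which
  case the core's `amplitude` is added (overlapping epitopes contribute
  the strongest amplitude, not the sum);
- an alanine variant inherits its parent's expected mean unless the
  substituted position maps onto a key residue of a contained core, in
  which case the amplitude is multiplied by `knockdown`; substitutions at
  non-key epitope residues deliberately leave the signal unchanged (a
  sharp oracle for testing; real epitopes degrade more gradually).

Defaults define the standard study conditions used by the tests and the
acceptance script: background mean 50 AU, background SD 8 AU, replicate
SD 8 AU, 30 toxins of 55–70 random residues, 10 epitopes with cores of
7–9 residues (the typical linear-epitope element size), 2 key residues
per core drawn from the core's non-alanine positions (an alanine key
residue would have no variant to reveal it), amplitude 160 AU = 20
background SD, knockdown 0.25. Under the threshold rule below, the
lower-70% truncation of a normal population estimates an SD of ≈ 0.70 of
the population spread, so the effective cutoff sits ≈ 6.5 population SD
above the truncated mean — far above the noise (false-positive
probability ~1e-10 per peptide) and far below planted peptides at 20 SD.

Planted truth is derived deterministically from the epitope list and the
library: the expected binder set is exactly the wild-type peptides fully
containing a core, and the expected effect at a key residue is
`log2((knockdown*A + bg) / (A + bg))` from the noiseless medians (≈ −1.22
under the defaults; exactly −2.0 when the background is negligible).

What the generator does *not* emulate — spatial artifacts, scanner
saturation, producer-dependent background distributions, antibody
competition, partial-containment attenuation — bounds what passing tests
show about real data: they validate the statistics and bookkeeping, not
robustness to array-specific systematics.

## Binder classification

Replicate intensities collapse to the standard median (mean of the middle
two for even n); replicate SD is the sample SD (n−1 denominator, 0 for a
single replicate). The background model is fitted on wild-type medians
only: the classification concerns the original toxin peptides, while
variant medians feed the substitution analysis. The lower 70-percentile
is implemented as nearest-rank — the `floor(0.7·N)` smallest medians —
because no interpolation scheme is canonical here; an interpolated
variant is available via `method="interpolated"`. The threshold is
`mean + 10·sd` with a strict `>` comparison ("more than 10 SD"). At least
10 wild-type medians are required to fit the model; fewer is an error.
Negative intensities are rejected at validation time: extractions that
background-subtract below zero must be floored by the caller, keeping the
non-negativity invariant explicit in the data contract.

Consensus across the two dilutions of one antivenom is plain set
intersection.

## Residue profiling

Binding profiles place one point per tile occurrence at the tile's
N-terminal residue; a peptide shared by homologs contributes to every
carrier's profile. Residue scores average the medians of all covering
wild-type tiles, binders or not. Alanine effects are computed per
experiment (no cross-dilution averaging), use `log2(variant/wt)` so loss
of binding is negative (configurable orientation), assign 0 to residues
that are already alanine (self-substitution is the identity), and are
null exactly where no binder tile covers the residue. Medians at or below
zero are floored to a configurable epsilon (default 1.0 AU — one unit of
the arbitrary fluorescence scale, negligible against real signals but
large enough to keep ratios finite) before taking the ratio.

Occurrence resolution uses the exact substring provenance recorded at
library build time; nothing is re-matched at analysis time, and repeated
occurrences within one toxin each contribute.

Alignment projection places residue values at their alignment columns;
gap cells carry no value, every row must ungap to its toxin's sequence,
and the round trip (project, then ungap) is lossless by construction.

## Experiment comparison

Venn regions for 2–3 binder sets are exclusive counts over the union, so
the inclusion–exclusion identity holds by construction. The non-shared
fraction is |A∪B| − |A∩B| over |A∪B| (0 when both sets are empty);
dividing by |A|+|B| is available should a different denominator
convention be needed.

## Structure annotation

Per-residue values are written into the B-factor columns (61–66) of
ATOM/HETATM records for one chain, every atom of a residue carrying the
residue's value in fixed-width 6.2 format. The writer edits those six
columns textually and leaves every other byte of the file untouched —
the reason it does not round-trip through a structure object. Values are
min–max scaled into [0, 99.99] by default (raw medians overflow the
field); the scaling parameters go to a sidecar JSON so raw values are
recoverable. Unmapped residues receive a fill value (default 0.00), and
an optional offset reconciles sequence numbering with author residue
numbers in the structure.

## Problem sizes and determinism

The test suite and acceptance script run the synthetic conditions at 30
toxins × 10 epitopes over 20 seeds (~16,000 wild-type peptide decisions
and 400 key-residue effect estimates per run), which keeps a full run in
a few seconds while making the binomial bounds on the null tests
meaningful. All randomness flows through `numpy.random.default_rng`
seeds; derived sub-seeds are drawn below 2^31. Stage outputs are flat TSV
and JSON with a manifest recording the config hash and input checksums,
so reruns with identical inputs are byte-identical.

## Known limitations

- The published library counts on the real 82-toxin set can only be
  verified after a one-time sequence fetch
  (`scripts/fetch_study_sequences.py`); the sequences are not
  redistributed. Until then the terminal-window and variant-collision
  flags rest on the defaults argued above rather than on the printed
  counts.
- Real-data comparison numbers (cross-antivenom Venn sizes on the six
  published experiments) require the corresponding signal tables; the
  comparison path is exercised end-to-end on synthetic six-experiment
  data instead.
- Epitope containment is all-or-nothing; peptides partially overlapping
  a core are treated as background in the generative model.
- No spatial or inter-array normalisation is implemented, matching the
  original analysis, which applied none.
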