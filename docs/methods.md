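# Methods

## Coordinate model and library geometry

A positioned nucleosome is described by a `NucleosomeFrame`: the 0-based
backbone index of the dyad, a core span (147 bp, odd and centered on the
dyad) and 10 bp per superhelical location (SHL). Offsets from the dyad map
to SHL by plain division, signed, so the mapping round-trips exactly for
integer offsets; internally everything is 0-based with half-open intervals,
and SHL is a signed decimal (dyad = 0, edge near ±7.3 for a 147-bp core).

The default backbone is the canonical 147-bp Widom 601 positioning sequence
embedded in fixed flanks for a 230-bp construct; the dyad defaults to the
center of the 601 core (index 114). The flanks are synthetic (arbitrary but
fixed ~50% GC sequence); their outermost 20 bp serve as the amplification
primer sites in the simulator and the CLI examples.

Tiling substitutes a target+PAM motif into the backbone at every position
of a window, one member per position, never changing length. A member's
position is reported as the SHL of its *PAM center base*: the center is
symmetric for a 3-bp PAM and supports the 0.2-SHL granularity that matters
near the edge (6.6 vs 7.0 vs 7.6). Forward motifs carry the PAM 3' of the
20-nt target, reverse motifs 5' of it, and the nontarget uses an 18-nt
target 5' of the PAM; all are stored as the drawn Watson strand — which
strand Cas9 engages is role metadata, not a sequence transformation.
Background fillers are seeded random sequences at backbone GC that share no
17-nt window (either strand) with any configured target, so they behave as
nonspecific carriers for Z-normalization. The default design tiles all
three motifs at every valid position (647 members including one native-601
control and 20 fillers); member counts are config-driven.

## Read processing

Stages run in a fixed order: 3' quality trim → pair merge → primer removal
→ length filter → member assignment. Defaults are the assay's published
settings (q30; ≥20-nt overlap with ≤2 mismatches; keep 174–220 nt;
assignment needs ≥150 aligned columns and ≥98.5% identity, best hit only).

- *Quality trim* uses the BWA running-partial-sum rule: accumulate
  `cutoff − q` from the 3' end, stop when the sum goes negative, cut at the
  maximum. It never lengthens a read and may empty it.
- *Merging* enumerates every relative placement of read 2 (reverse-
  complemented) against read 1 and takes, among placements with ≤ max_diffs
  mismatches and at least the minimum overlap, the one maximizing overlap
  length (ties: fewer mismatches, then leftmost). Consensus at a mismatch
  keeps the higher-quality base; an equal-quality disagreement becomes `N`
  with quality 2 (conservative and deterministic); agreements keep the
  higher quality. Failures are values, not exceptions: a placement set
  whose best-scoring candidate (matches − 2·mismatches) is long but too
  mismatched reports `too_many_diffs`; a convincing but short overlap
  reports `too_short_overlap`. The two reason codes are a diagnosis layered
  on top of the selection rule, since the rule alone cannot distinguish
  them.
- *Primer removal* strips a terminal Hamming match to each primer at up to
  10% mismatches of the primer length; the *length filter* keeps
  174–220 nt inclusive (the published cuts are strict inequalities on the
  removal side).
- *Assignment* aligns the processed read end-free inside each member
  (edlib infix mode; the read aligns in full, member overhangs are free and
  excluded from the column count). Identity is matching columns over
  alignment columns, internal gaps counted as columns. `N` is treated as a
  wildcard by the matcher — a merge-masked disagreement should not be
  charged as a mismatch twice — while the merge step itself counts `N` as a
  difference. Identity 0.985 and 150 columns exactly are accepted (the
  thresholds reject "less than"). Because adjacent tiling members are
  near-duplicates, an exact identity tie between distinct members is
  discarded as ambiguous rather than resolved arbitrarily; the run report
  tallies every terminal status so counts always sum to the input size.

## Protection statistic

For member N against the native-601 control, with digested/undigested
uncleaved counts D/U: `log2((D_N/D_CON) / (U_N/U_CON))`. A pseudocount
(default 1, configurable; 0 honored for exact checks) is added to all four
counts, since real digested pools contain zeros. The statistic is
antisymmetric under swapping the two samples, exactly 0 for the control,
and invariant to per-sample depth scaling — the control normalization is
what removes PCR/sequencing depth effects.

Per replicate, members are Z-scored against the background members using
the population SD (the background set renormalizes to mean 0, SD 1);
replicate values are then averaged with a standard error (SD/√n, 0 for a
single replicate). Replicate agreement is assessed by Pearson correlation
of log2(count+1) per member, since counts span orders of magnitude; a
constant sample yields NaN entries (correlation undefined) rather than a
silent fill.

## MNase footprint

Protection at a base is the fraction of a member's fragments covering that
base: `coverage[bp] / total_reads`, with coverage counting fragments whose
half-open interval contains the base (not fragment ends) and total reads
taken per member, not library-wide. A windowed mean around a chosen SHL is
provided alongside the per-bp track, since plateau summaries can be read
either way. `align_profiles` joins a Cas9 profile and an MNase track on
backbone position through the shared frame, with explicit NaN where only
one measure exists.

## Digestion simulator

The protection-versus-position functional form is a deliberate stand-in: a
two-parameter logistic in the PAM center's distance from the dyad,
`p = base + (max_cleavage·f − base) · σ(steepness·(d − mid))`, with
`mid = edge_offset` (73 bp) for reverse targets and `edge_offset +
orientation_shift` (6 bp) for forward targets — encoding that a forward
target's 20-mer trails the PAM into the octamer, so its cleavage transition
sits further out. `f` is the product of per-position mismatch penalties
(≤1); members the sgRNA does not engage (nontarget, control, background)
cleave at `base = nontarget_cleavage`, default 0 since nonspecific members
show no cleavage. The form is monotone, minimal and recoverable; it is not
a kinetic model of R-loop formation or nucleosome breathing.

Counts: per replicate the undigested sample is a multinomial draw over
members (uniform abundance by default) at `n_reads` depth; the digested
sample is an *independent* multinomial aliquot of the same pool, thinned
per member by Binomial(count, 1−p). Independence of the two aliquots
mirrors a real sample split and gives zero-cleavage members genuine
sampling noise — thinning the same draw would make the background exactly
deterministic and the Z-score undefined. Under this scheme the expected
raw protection of a member is log2(1−p) (control p = 0 cancels), which the
tests verify within binomial error at 10^5 reads/sample.

Reads: R1 is the 5' prefix of the member amplicon, R2 the 5' prefix of its
reverse complement (sequencing orientation); for read length L on a 230-bp
member they overlap by 2L − 230 nt. Substitution errors follow an
Illumina-like positional profile: a low body rate (error_rate/20) with the
remaining error mass concentrated in the final 10% of cycles, and each
base's Phred score encodes its true error probability. A flat quality
string at the Phred of the configured mean rate would be q20 at 1% error —
which the pipeline's own q30 trimmer would delete outright; concentrating
errors in a low-quality tail is both how real Illumina data behave and
what makes quality trimming a meaningful stage. Consequences worth noting:
passing round-trip tests show the pipeline recovers counts when errors are
flagged by quality, as on a well-behaved run; they do not bound performance
under quality-blind error modes (miscalibrated basecallers, chimeras, indel
errors), which the simulator does not model. One top-level seed drives
everything; per-replicate streams derive from it, and identical config plus
seed yields byte-identical FASTQ.

MNase fragments: each simulated molecule is cut independently at every
inter-base boundary with the given probabilities (molecule ends always
cut), and yields its longest resulting piece — the octamer-protected
stretch survives digestion while accessible flanks are chewed away. A zero
cut probability across the core therefore produces an exact full-height
coverage plateau, and raising the cut rate shortens fragments and lowers
flank coverage, emulating a digestion time course.

Edge recovery: `fit_edge_offset` grid-searches the logistic midpoint,
scoring each candidate by least squares between the measured profile and
the model prediction. Two consistency details matter. The prediction can
carry the same pseudocount compression as the measurement (pass the
pseudocount and the expected per-member depth); comparing a
pseudocounted measurement against the ideal log2(1−p) biases the fitted
edge outward by several bp at ~150 reads/member. And a Z profile should be
fitted with the same affine constants used to produce it — the package fits
the Z-score of the replicate-mean profile, passing that profile's
background mean/SD as `loc`/`scale`, which is exactly equivalent to fitting
the raw mean profile. (Averaging per-replicate Z values instead mixes three
noisy background-SD estimates into the profile shape; with only 20
background members that distorts the amplitude enough to shift the fitted
edge.)

## Structure clash module

PDB files are read and written with gemmi into plain coordinate arrays.
Superposition is chain-guided, as in interactive structure tools: the two
nucleic chains' residue sequences are globally aligned (Needleman–Wunsch),
each aligned non-gap column contributes one backbone phosphorus pair
(robust, exactly one per nucleotide; 5'-terminal residues without P are
skipped), and the paired coordinates get a least-squares rigid fit (Kabsch
via SVD; collinear pairings are rejected as underdetermined, since the
rotation about the common axis is free). A clash is an unordered cross
pair with vdW overlap `r_a + r_b − d ≥ 0.6 Å` — the common interactive
default, with no hydrogen-bond allowance since the synthetic fixtures are
hydrogen-free; both values are configurable. Radii come from a packaged
Bondi-style element table with per-atom overrides. Exclusions (the directly
bound duplex, atoms beyond a chosen SHL) are caller-supplied predicates or
masks — the module does not hard-code nucleosome annotations. Candidate
pairs come from a KD-tree; tests verify exact agreement with dense O(n²)
enumeration. Reproducing published clash counts for real Cas9/nucleosome
structures is out of scope: those depend on the exact deposited models,
base mutation, hydrogen addition and energy minimization.

## Problem sizes and numerical choices

Simulation-backed tests use 10^5 reads/sample for count-level checks and a
few thousand read pairs for sequence-level round trips on a 20-member toy
library; brute-force oracle comparisons run on reads ≤80 nt, libraries of
~12–20 members and 2000-atom structures. These sizes give the statistics
room (per-member depth ~150 at 10^5 reads over 647 members) while keeping
the suite fast. Ties are always broken deterministically (documented per
operation); degenerate inputs raise informative errors rather than
returning silent defaults (zero background SD, zero total reads, collinear
superposition pairs, empty libraries).

## Known limitations

- The logistic protection model and the mismatch penalties are stand-ins
  for measured biology; parameter recovery shows the pipeline's statistics
  are faithful, not that the model describes real nucleosomes.
- The simulator emits substitution errors only (no indels, chimeras or
  adapter read-through), so the merger's indel-free overlap model is never
  stressed by construction.
- Identity is computed over the aligned region only; a tool computing it
  over the full merged read would differ slightly for reads with terminal
  overhangs.
- The MNase longest-piece rule ignores sequence bias and sub-nucleosomal
  particles; plateau heights are constructed, not predicted.
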