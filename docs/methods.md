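# Methods

## Cleavage model

The Csm complex is modelled as a set of `n_cuts` scissile phosphates placed
at fixed intervals inside the crRNA-complementary interval (the target
site). Cut *i* sits at `start + cut_offset + i * spacing`. Each cut leaves
a 2′,3′-cyclic phosphate on the upstream fragment and a 5′-hydroxyl on the
downstream fragment; these tags are constants of the nuclease mechanism and
are what make every cut end a ligase substrate. The model deliberately
ignores cleavage kinetics, per-subunit efficiency differences and complex
assembly: it answers "where can the transcript be cut and which religation
products are possible", not "how often is each product formed".

Parameters, defaults and rationale:

| parameter | default | unit | rationale |
|---|---|---|---|
| `spacing` | 6 | nt | Csm3 subunit periodicity; fixes deletion lengths to multiples of 6 |
| `n_cuts` | 5 | — | an observed deletion set {6, 12, 18, 24} implies five cleavable registers |
| `cut_offset` | 4 | nt | centres the 24-nt cut span in a 32-nt protospacer; the register relative to the crRNA ends is not an established constant, so this is an exposed parameter rather than a fact |
| `flank_k` / `anchor_k` | 12 | nt | seam anchor long enough that a chance 24-mer match is ~4⁻²⁴; short enough to fit typical reads |
| `shift_tol` | 3 | nt | absorbs aligner left/right-shifting of deletions at microhomologous seams |

Coordinates are 0-based half-open on the sense strand (DNA alphabet); a cut
position names the first base 3′ of the scissile phosphate so a cis
deletion length is `right_pos − left_pos` with no off-by-one bookkeeping.

## Junction enumeration

Microexcision species are all unordered pairs of cuts within one site
(`n(n−1)/2` species, sorted by deletion length then position); macroexcision
species are the full cross product of cuts between two non-overlapping
sites on one transcript. Only pairwise seam products are enumerated:
whether three or more simultaneous cuts release middle fragments that
religate combinatorially is not modelled. When `spacing` is a multiple of
3, every cis deletion preserves reading frame (`frame_delta = 0`), which is
the design basis for stop-codon excision.

The seam context of a junction is the `2k`-mer formed by `k` nt ending at
the cyclic-phosphate end and `k` nt starting at the hydroxyl end. Two
junctions can share a context when the reference is repetitive or the seam
is microhomologous; such junctions are all retained, flagged ambiguous, and
a read matching the shared context is split equally between them at
quantification — deterministic and conservative.

"Innermost" cut means minimal distance to the site midpoint, ties broken
5′-ward; it ranks stop-excision designs because the single-spacing deletion
between the innermost cuts is the dominant observed religation product.

## Guide and donor design

`place_scissile_at` inverts the cut-position formula
(`site.start = phosphate_pos − cut_offset − rank·spacing`), and its default
rank is the innermost cut (`⌈(n_cuts−1)/2⌉`). `design_stop_excision` scores
every window placement that keeps the stop codon inside the cut span and
returns only placements with at least one frame-safe species deleting the
whole codon, ranked innermost-6-nt-species first, then by the deletion
length needed. Guides are not filtered for GC content, secondary structure
or transcriptome-wide specificity; apply such filters downstream on the
returned designs.

Donor constructs acquire their 5′-OH end by one of four mechanisms
(`csm_site`, `rzb_hammerhead`, `other_ribozyme`, `cas6_hairpin`). The RzB
hammerhead cleaves exactly at its 3′ boundary and leaves 0 extra
nucleotides; the other mechanisms leave construct-specific 5′ leftovers,
configured via a table (defaults 0/0/5/8 nt; the Cas6 default is the
canonical 8-nt repeat tag left on processed crRNAs). When only a count is
configured, the leftover sequence defaults to G-repeats as a placeholder —
supply the real construct sequence for sequence-accurate chimera
prediction. A chimeric ORF is declared in frame iff
`(cut_pos − orf_start) mod 3 == (3 − leftover mod 3) mod 3` with the donor
body in its own frame 0.

## Read classification and normalization

Both classification modes share one index built from the junction library:
the seam `2k`-mer of each junction, each junction's observation window, and
the intact window.

The denominator of every reported fraction is the *target-site-spanning
depth*. A read enters it only by being classified intact or as a junction
species, and both calls require containment of an observation window of
identical length `W = cut span + 2k`: the intact window `[first cut − k,
last cut + k)` of the uncut reference, or the species window of the same
length centred on the junction seam. Equal window lengths matter — the seam
`2k`-mer alone is half the intact window, so seam-only matching lets
junction reads survive partial overlaps and substitution errors roughly
twice as often as intact reads, which measurably inflates the religated
fraction (≈0.16 observed for a true 0.12 under the simulator's default
conditions). With equal-length windows the probability that a read is
countable is the same for every category, and the fraction estimator is
unbiased; this is also the operational reading of "reads spanning the
target site": the site must be covered far enough that any species would
have been observable.

Raw mode scans each read (and its reverse complement) for seam `2k`-mers
and confirms the full species window around the first hit; intact requires
the full intact window. Matching is exact by design — deterministic and
testable — so raw mode degrades with error rate (a 0.5% substitution rate
drops ~21% of spanning reads into `unassigned`, equally across categories);
alignment mode is recommended for noisy long reads. Alignment mode extracts
deletion-type gaps (both D and N operations, since spliced aligners emit N
for long gaps) from records spanning the intact window and matches a gap to
a junction by exact length and start within `shift_tol` (nearest start,
then 5′-most). Unparseable or secondary/supplementary records are skipped
and tallied.

Degenerate inputs: an empty read or a read spanning no window is
`unassigned`; a run with zero spanning reads reports counts with fractions
flagged undefined rather than dividing by zero.

## Synthetic data

The simulator emulates the measurable endpoint of cleavage plus religation:
a pool of full-length species (intact, each junction species, optional
off-target) sampled i.i.d. at specified fractions, read start positions
uniform over each species, i.i.d. substitution errors, fixed read length,
constant base quality. The default composition used throughout the tests —
88% intact and 12% religated, split 7 / 3 / 1.5 / 0.5% across the
6/12/18/24-nt deletion classes — mirrors the species ordering seen in
religation sequencing data, with each class budget divided equally among
its junctions. The default test geometry is a 400-nt amplicon with the site
at its centre and 350-nt reads, i.e. amplicon sequencing in which every
read spans the target site; 20,000 reads put 3 binomial SD on the aggregate
religated fraction at about ±0.008.

Ground truth is carried in read names and a sidecar table, and ground-truth
SAM records (exact placements, M-D-M CIGARs across seams) can be written
for the alignment-mode path; a real aligner (minimap2) is additionally used
as an independent cross-check in the test suite. What the simulator does
*not* model bounds what passing tests show: no platform error profiles
(nanopore homopolymer errors), no indels by default (an indel mode exists
solely to exercise alignment-mode robustness), no coverage bias, no
degradation intermediates, and no species outside the enumerated library.
Real libraries will put more reads in `unassigned` and favour alignment
mode; the normalization logic is unchanged.

## Known limitations

* Cleavage efficiency and product abundance are not predicted; the model
  enumerates possibilities and the quantifier measures them.
* The cleavage register relative to the crRNA (`cut_offset`) is a
  configurable assumption, not a measured constant.
* Exact-match raw mode is unsuitable for high-error long reads.
* Trans-junction quantification assumes the donor's processed 5′ terminus
  is known exactly; heterogeneous donor processing would smear the seam.
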