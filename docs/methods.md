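# Methods

## Scope and model

`fragribo` quantifies two sequencing signatures of endonucleolytic mRNA
cleavage by RNase L, the interferon-inducible endoribonuclease activated by
2'-5'-linked oligoadenylates (2–5A):

1. **3' cleavage fragments in direct RNA nanopore data.** RNase L cuts
   single-stranded RNA after U-N dinucleotides (UN^N), leaving a
   poly(A)-bearing 3' fragment that survives poly(A) selection. Because the
   nanopore cannot sequence the last ~10–15 nt of a molecule's 5' end
   ("RNA left in pore"), the apparent 5' end of a fragment read sits
   downstream of the true cut; the cleavage dinucleotide is therefore read
   off the *reference* sequence a fixed window upstream of the mapped 5'
   end, where it classically peaks at offsets −12/−11.
2. **Short stalled-ribosome footprints in ribosome profiling.** A ribosome
   that reaches a cleaved 3' end protects only 15–18 nt ("16-mer") because
   no mRNA occupies its entry channel, versus 25–34 nt ("28-mer") during
   elongation. The 16-mer's 3' terminus coincides with the cut site, so its
   3'-end dinucleotide and its pile-up at UU motifs read out the same
   cleavage geometry as the nanopore analysis.

A single cut convention ties every analysis together: `cleave_pos` is the
first nucleotide of the 3' fragment, the motif occupies
`cleave_pos − 2 .. cleave_pos − 1`, nanopore fragment reads start at
`cleave_pos + k` with pore truncation `k`, and 16-mer footprints end at
`cleave_pos − 1`.

## Coordinates and conventions

All coordinates are 0-based, half-open, in transcript (sense-strand) space.
The internal alphabet is DNA; U↔T conversion happens at I/O boundaries.
`annotated_len` excludes the poly(A) tail. Transcripts with non-triplet or
out-of-range CDS annotations are skipped with a logged warning, never
repaired. Secondary/supplementary SAM records are skipped; unmapped records
are retained with their sequence for the poly(A)/spike-in analyses.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, with
per-read ground truth, so every stage is testable without external data.

Defaults (units nt unless noted):

| parameter | default | meaning |
|---|---|---|
| `n_transcripts`, `len_range` | 30, (600, 2000) | random transcripts, i.i.d. uniform bases, ATG…stop CDS |
| `utr_fracs` | (0.15, 0.35) | 5'UTR / 3'UTR shares, typical mRNA proportions |
| `cleave_prob` | 0.8 | per-molecule cleavage probability (activated-like) |
| `motif_weights` | UU .4 / UA .3 / UG .2 / UC .1 | relative site propensity by second base, ordered per the known UU^N > UA^N preference |
| `trunc_dist` | {9: .25, 10: .5, 11: .25} | pore truncation, mode 10 so the motif peaks at −12/−11 |
| `bg_frag_frac` | 0.05 | motif-free 3'-anchored background fragments (degradation, pore clogging) |
| `footprint_mix` | long28 .6 / mid21 .1 / short16 .2 / polyA .05 / spike .05 | read-class mixture |
| `frame0_prob` | 0.7 | P-site frame-0 probability for elongating footprints |
| `polyA_run_range` | (8, 18) | terminal A-run of unmappable poly(A)-stall reads |
| `untemplated5_prob` | 0.5 | chance the sacrificial 5' base is untemplated |

Where the source protocols state values (class bounds 15–18/19–24/25–34 nt,
the 12-nt P-site shift, the 8–18 A-run bounds, the six spike-in oligo
sequences), the generator and analyses use them as given. Where no value is
stated (truncation distribution, background share, mixture fractions), the
defaults above were chosen once as field-plausible and are config knobs,
not calibrated quantities.

**Untemplated 5' base.** Library preparation can add one untemplated 5'
base; the processing protocol removes a single 5' base from every read and
reports lengths pre-trim. The generator mirrors this exactly: each footprint
read carries one extra 5' base (untemplated with probability
`untemplated5_prob`, otherwise the genuine upstream transcript base), the
recorded truth alignment is what the *trimmed* read maps to, and the
reported length is the aligned span + 1. This keeps P-site frames and
3'-end positions exact regardless of untemplated prevalence — which is
precisely why the protocol trims.

**altORF targeting.** `simulate_footprints(orf_targets=...)` places
elongating footprints' P sites in arbitrary ORF intervals (default: the
annotated CDSs). Frame-recovery experiments pass one altORF per transcript
(the longest stopped one), because overlapping altORFs in different frames
would dilute the measured frame fractions; the analysis then evaluates the
same ORF set.

**What the generator does not emulate:** base-call errors, signal-level
nanopore behavior, ligation/RT sequence bias, UMI structure, duplicate
reads, 5'→3' exonucleolytic decay kinetics (which fragments survive is
folded into `cleave_prob`/`bg_frag_frac` per sample). Passing tests
therefore demonstrate that the statistics recover the generative structure
they target, not that real libraries are free of these artifacts.

## Analysis definitions and numerical choices

- **Fragment rule** — a mapped read is a 3' fragment iff aligned span
  < annotated_len/3 (strict), `ref_end` within `end_tol` = 30 nt of the
  transcript end (poly(A)-adjacent jitter tolerance; no value is stated
  upstream), and 50 ≤ span ≤ 10 000 nt. Aligned span, not full read length,
  is used for normalized length (the unsequenced poly(A) tail would
  otherwise inflate it).
- **Motif window** — reference bases `[p−15, p)` upstream of the mapped 5'
  end `p`; reads with `p` < 15 are excluded and counted. Information content
  is Shannon `2 + Σ f·log2 f` per position, no small-sample correction;
  dinucleotide spectra are taken at offsets (−12, −11) by default, with the
  {UU, UA, UG, UC} breakdown renormalized among U-first windows.
- **Rank test** — two-sided Mann–Whitney U; exact enumeration when both
  samples are ≤ 20 without cross-ties, tie-corrected normal approximation
  otherwise; two fully degenerate samples give p = 1. No multiple-testing
  correction: one test per comparison.
- **Region ratios** — each read contributes one position (default P site =
  5' + 12); rpm = raw × 10⁶ / mapped reads. Transcripts enter a
  region:CDS ratio only when raw CDS + region reads strictly exceed 5;
  zero-CDS/nonzero-region transcripts are excluded and counted. The pooled
  ratio sums rpm before dividing. Ratios use raw rpm, not length-normalized
  density.
- **Metagenes** — per-transcript count vectors over the window, each divided
  by its own mean over in-bounds offsets, then averaged equally across
  transcripts (≥ 5 reads in window for the stop-codon metagene); offsets
  beyond a transcript's ends contribute nothing and per-offset coverage is
  tracked. The motif-anchored variant anchors at the 3'-most base of each
  motif occurrence, skips occurrences within the window of region edges, and
  sums occurrences per transcript before normalizing.
- **altORFs** — every AUG in the 3'UTR opens an ORF (overlaps kept); the
  first in-frame stop closes it, or it runs to the transcript end (stop
  absent). ORFs with a stop but < 2 codons are discarded. This is a minimal
  AUG-scan definition.
- **poly(A) reads** — a trimmed unmapped read counts when its *maximal*
  terminal A-run length lies in [8, 18]; a 19+ run does not count unless
  `open_ended=True`. Both the 8–18 and 8–17 conventions that appear in the
  protocol sources are expressible; 8–18 is the default.
- **Spike-ins** — exact string match against the six fixed oligos, allowing
  the 1-nt 5'-trim offset; no deduplication. Ratio = Σ(18-mer counts) /
  Σ(30-mer counts).

## Problem sizes

Tests and the acceptance script use 30 transcripts of 600–2000 nt and
5 000–50 000 reads per experiment — sizes at which binomial/multinomial 3σ
bands are a few ×10⁻³ wide, tight enough to detect implementation bias
while keeping any run in seconds.

## Known limitations

- The fragment-rule end tolerance (30 nt) and metagene normalization
  ("divide by own window mean, average transcripts equally") are explicit
  choices where the upstream descriptions are silent; both are parameters.
- Whether normalized length should use aligned span or full read length on
  real data is a genuine sensitivity question; span is the default here.
- Real-data mode ingests transcript-space SAM/BAM produced elsewhere; this
  package never runs an aligner, and mapping policy (e.g. zero-mismatch
  footprint mapping) is the upstream aligner's responsibility.
- Recovered motif fractions on random transcriptomes carry a small
  availability bias (transcripts differ in site-type counts), bounded well
  inside the ±0.03 end-to-end tolerance at the default sizes.
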