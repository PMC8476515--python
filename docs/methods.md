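# Methods

This note documents the models and conventions behind `miser`: what each
stage computes, the parameters that matter, and where a genuinely open
design choice was resolved.

## Coordinate model

Everything is anchored to one coordinate system on the target coding
sequence (N codons, stop codon excluded):

- **Insertion positions** are 1-based, "immediately after codon *i*",
  *i* ∈ 1..N. This yields exactly N sites per enzyme — the convention that
  reproduces one oligo per codon for an N-codon gene. The alternative
  "strictly between codons" reading gives N−1 sites; we include the final
  position (between the last codon and the stop) as the Nth site. Either
  end choice yields N sites; this is the one consistent convention the
  package uses, not a claim about any particular published oligo pool.
- **Deletion variants** are junction pairs (a, b), a ≤ b: codons a+1..b are
  deleted (k = b − a). The space has N(N+1)/2 members and includes the N
  zero-length (a = b) scar-only insertions; the closed form forces their
  inclusion. For N = 1368 this is 936,396.
- Deleted **residue intervals** are reported 1-based inclusive ([a+1, b]);
  BED exports convert to 0-based half-open nucleotide coordinates.

Length arithmetic follows directly: a variant ORF is 3(N − k) + 6 bp (the
6-bp scar), its protein N − k + 2 residues; a stacked construct with m
disjoint deletions is N − Σk + 2m residues, and its retained fraction
(N − Σk)/N excludes scar residues.

## Junction chemistry

NheI (G^CTAGC) and SpeI (A^CTAGT) leave identical 5'-CTAG overhangs, so an
NheI-cut upstream fragment ligates to a SpeI-cut downstream fragment and
vice versa. Cross-ligation yields a hybrid 6-mer neither enzyme recognizes:
GCTAGT (Ala-Ser) for NheI→SpeI, ACTAGC (Thr-Ser) for SpeI→NheI. Same-enzyme
junctions regenerate a cuttable site and are rejected
(`ReligationError`). Products with b < a are duplications: modelled,
classified by the read caller, and excluded from the deletion landscape.
The scar pair is closed under reverse complement — a reverse-strand read of
one scar shows the other — which is why the caller's reverse-complement
mode re-calls the whole read rather than just rescanning for motifs.

## Oligo design

Each oligo is `fwd_prime + upstream_arm + site + downstream_arm +
rev_prime`. Defaults: 35-nt homology arms (enough for uniqueness in
gene-sized, non-repetitive targets while keeping total length ≤ ~116 nt)
and synthetic 20-nt priming ends, each carrying one BsmbI site oriented to
cut outward so digestion releases exactly `arm + site + arm`. The priming
ends are this package's own placeholder sequences. BsmbI digestion is
simulated at the top-strand cut point; the 4-nt overhang detail is
abstracted. Arms at the ORF termini extend into user-supplied vector
context; without context they truncate with a warning rather than fail.

## Read calling

Deletion coordinates are called from single-end reads by exact matching
only — no alignment, no mismatch tolerance:

1. scan for the two scar motifs; no motif → WT; more than one → no call
   (`multiple_motifs`);
2. take `flank_len` (default 15) nt on each side of the motif; incomplete
   flanks → `flank_truncated`;
3. each flank must occur in the reference exactly once (configurable via
   `require_unique_flank`); zero hits → `flank_mismatch`, several →
   `flank_nonunique`;
4. the upstream flank must end at a codon boundary (position 3a) and the
   downstream flank start at one (3b + 1); otherwise `frame_violation`.
   This frame check is an addition over plain flank matching: it rejects
   spurious motif hits at almost no cost in sensitivity;
5. if the gap is exactly 6 nt and the skipped reference 6-mer equals the
   motif, the read is indistinguishable from wild type
   (`ambiguous_natural_motif`).

The trade is deliberate: a substitution in a flank demotes the read to a
no-call but can essentially never reassign it to a different (a, b) — in a
non-repetitive reference a mutated 15-mer almost surely matches nowhere.
Tallies are order-invariant and conserve reads: deletions + duplications +
WT + no-calls = input reads.

## Enrichment scores and slice combination

For the union of variants seen in the naive and sorted pools, one
pseudocount read is added to every variant in **both** pools (a uniform,
conservative superset of adding reads only to singly-detected variants;
the alternative is available as `pseudocount_mode="missing_only"`),
frequencies are renormalized so each pool stays a proper distribution, and
the score is log10(freq_sorted) − log10(freq_naive) — a difference of
logs, so pool swap negates scores bit-exactly and every score is finite.

Multiple slices are combined by (i) reporting Pearson r on shared
variants as the QC statistic, (ii) an affine least-squares map of each
slice onto the first slice's scale (the minimal transform consistent with
"normalize by correlation, then average"; the exact published transform is
not recoverable), (iii) per-variant means, and (iv) a min–max rescale to
[0, 1] **for display only**. Slices sharing fewer than `min_overlap`
(default 50) variants refuse to combine.

## Landscape raster

A variant (a, b) maps to row L = b − a (deletion length) and column
c = a + b (twice the midpoint). Using the doubled-resolution midpoint axis
makes the map a bijection — no lossy pixel binning, every populated cell
traces back to exactly one variant. The plotted value is the [0, 1]
display score.

## Tolerated-region calling

Variants with combined score ≥ `score_threshold` and k ≥ 1 project their
deleted spans onto the residue axis; overlapping-or-abutting spans merge;
merged intervals shorter than `min_len` (default 10 aa) or supported by
fewer than `min_support` (default 5) variants are dropped. The threshold
applies to the **log10** combined score, not the [0, 1] rescale: 0.3
(~2-fold enrichment) means the same thing in every run, whereas a fixed
cut on a data-dependent min–max rescale does not — in a neutral experiment
the rescale stretches pure noise across [0, 1], and any fixed cut on it
would fabricate regions. Region calling by threshold + merge + support is
this package's formalization of what is usually done by inspection.

## The simulator

`miser.simulate` generates the full experiment with one seeded
`numpy.random.Generator`, so (seed, config) reproduces everything
bit-for-bit.

- **Reference**: random stop-free ORF with NheI/SpeI/scar/BsaI/BsmbI
  motifs (both strands) rejection-sampled away, so the chemistry and the
  caller see a clean target.
- **Library**: junction pairs drawn uniformly over the triangle
  {(a, b): a ≤ b} — which induces the triangular length marginal of a real
  ligation pool (N − k variants of length k) — then rejection-sampled
  against the gel-slice window until `n_library_variants` pass.
  `n_library_variants` is the *post-slice* library size, matching how a
  gel slice is transformed at fixed depth. Scar types are assigned AS/TS
  uniformly; the landscape identity collapses scar type (counts summed),
  with the per-scar breakdown retained in outputs.
- **Fitness**: a step landscape — windows of tolerance (height ∈ (0, 1],
  nested windows allowed, smallest containing window wins) over a low
  baseline (default 0.01); k = 0 insertions are fully fit. This is a
  deliberate simplification sufficient for recovery testing; real deletion
  landscapes have sub-domain structure and isolated intolerant elements
  inside otherwise tolerant regions.
- **Pools**: naive pool is a multinomial draw proportional to library
  abundance; the sorted pool weights abundance by fitness (an idealized
  one-gate sort with no gating noise or carry-over).
- **Reads**: 100-nt single-end by default. Variant reads are windows of
  the variant ORF drawn uniformly among windows overlapping the scar by
  ≥ 1 nt; amplicon reads elsewhere are indistinguishable from full-length
  template and are represented by `wt_read_fraction` (default 0.5) reads
  from random reference windows. Errors are i.i.d. substitutions at
  0.001/nt; indels and quality structure are not modelled.

### Default scenario

`default_simulation()` builds the standard full-scale experiment: a
1368-codon synthetic ORF; four planted tolerated windows at residues
180–297, 503–708, 792–897 and 1010–1081 (height 1.0, baseline 0.01); a
stringent gel slice retaining deletions of 1–50 codons (3960–4107 bp);
1500 library variants; 200,000 reads per pool.

The slice width is a design-time derivation, not a tuning knob. With the
unsliced triangle, ~96% of variants sit at baseline fitness, and the rank
correlation between scores and a two-level fitness with tie fraction p is
bounded by √(3p(1−p)) ≈ 0.34 — no read depth can push it past that. The
1–50-codon slice places ~30% of junction pairs inside tolerated windows
(bound ≈ 0.79) while giving every window, including the 72-residue one,
hundreds of contained variants for coverage. At these settings a selective
run recovers all four windows with Jaccard ≥ 0.8 (typically 1.0), scores
rank-correlate ≈ 0.79 with planted fitness over well-sampled variants, and
a neutral run calls zero regions; one full run takes a few seconds on one
CPU.

### What passing simulations do and do not show

The simulator shares the caller's sequence model, so end-to-end tests
validate coordinate bookkeeping, the enrichment algebra, and the recovery
pipeline's statistical behaviour — they do not validate robustness to PCR
chimeras, indel errors, repeat-induced flank ambiguity, or fitness
structure finer than step windows. Those belong to real-data validation.

## Numerical choices and degenerate inputs

- All stochastic draws flow through one `numpy.random.Generator`; variant
  iteration is always in sorted order so multinomials are reproducible.
- Scores are float64 differences of `log10`; the pseudocount guarantees
  finiteness. A degenerate min–max rescale (all scores equal) maps to 0.
- `enumerate_deletions` is lazy (the full-scale space has ~10⁶ members;
  the count is closed-form).
- Empty FASTQ → empty table; empty score table → no regions; a gel window
  excluding every reachable ORF length raises `EmptyLibraryError` before
  any sampling.

## Known limitations

- Single contiguous ORFs only: no introns, no strand-ambiguous references.
- No ligation-efficiency, transformation-bottleneck or PCR side-product
  modelling; no thermodynamic oligo optimization.
- No variance model or FDR for enrichment — scores are relative
  measurements, as ratio-based selection readouts generally are.
- Exact flank matching discards every read with an error in a flank;
  sensitivity is traded for precision by design.
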