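# Methods

## Telomeric homology model

The telomeric repeat is modelled as a primitive 7-mer unit
(`TTTAGGG` on the G-rich strand; its reverse complement `CCCTAAA` on
the C-rich strand). "Telomeric sequence of any rotation" is defined as
any substring of the infinite periodic sequence built from a unit —
equivalently, the cyclic rotations of the unit extended to the query
length. Non-cyclic letter permutations of the unit are *not* matched:
the homology annotation of a read only makes sense as a contiguous
stretch of the periodic repeat. The scanner computes, per strand, the
longest run of positions `i` in a read satisfying
`read[i] == unit[(phase + i) mod 7]` over all 7 phases (O(7·n) per
read), which equals the brute-force maximum over all read substrings
checked against the rotation k-mer sets; the test suite asserts this
equivalence on 1,000 random reads. `N` never matches. A read whose
maximal G- and C-strand homologies tie is labelled `ambiguous`,
retained, and excluded from strand-specific counts; for runs ≥ 7 nt a
tie is impossible (every G-strand window of that length contains G and
no C, and vice versa), so ambiguity only arises below one unit length.

Key parameters: `min_homology` (default 12 nt — the threshold used to
call a read telomeric), the repeat unit (configurable; vertebrate
`TTAGGG` works too), and a `collapse_identical` flag that collapses
identical sequences within a library before counting (default off:
each read record counts once, because public AGO datasets may or may
not be pre-deduplicated and the choice is left explicit).

Mismatches are never tolerated inside a homology run; a fuzzy mode is
deliberately out of scope.

## Subtelomere alignment

Alignment is full-length, exact, on both strands, against a supplied
set of subtelomeric windows (≤ 20 kb each, matching the ~15 kb windows
used for real chromosome arms). The index stores all `min_len`-mers of
the forward references and verifies candidate extensions, which is
exactly equivalent to a naive quadratic scan (asserted in tests on
≤ 2 kb references). The uniqueness filter keeps a read only if it has
exactly one placement across *all* references and strands jointly —
the stricter of the two possible readings of "unique location"; a
read palindromic under reverse complement therefore never survives
(its single locus yields two placements). Coordinates are 0-based
half-open; `distance_to_telomere` is measured from the
telomere-abutting end of the reference (declared per arm as
`telomere_side ∈ {left, right}`) to the nearer edge of the placement.
Uniqueness is evaluated only within the supplied reference set, not
genome-wide — callers who need genome-wide uniqueness must supply
genome-wide references.

## Bisulfite calling

Clones are Sanger reads of a PCR amplicon, so alignment is anchored
and gap-free: the clone (or its reverse complement, whichever scores
better — clones are sequenced in either orientation) is overlaid at
the offset maximizing bisulfite-aware matches, where a reference C
accepts clone C or T and every other reference base must match
exactly. Clones exceeding `max_mismatch` (default 5) mismatches at
non-cytosine positions are rejected into a visible rejects table.
At each reference cytosine: clone C → methylated, T → converted,
anything else or uncovered → missing. Per-position call counts always
sum to the clone count (asserted after every batch).

Context classification follows the standard plant rules: `CG` if the
next base is G, `CHG` if base+2 is G, `CHH` otherwise (H = A/C/T);
cytosines within 2 nt of the region end use explicitly supplied
downstream genomic bases, else the context is `NA` — never guessed.
Repeat phase k (1–3) is the k-th cytosine of the CCC triplet of an
annotated CCCTAAA unit.

Reported frequencies are **raw** methylated fractions of non-missing
cells, without correction for incomplete conversion, because
conversion is checked separately (from annotated control cytosines
known to be unmethylated; failure below `min_rate`, default 0.95, is
flagged). The expected apparent frequency under true methylation
probability p and conversion efficiency e is p + (1−p)(1−e); this
formula is used only to validate the estimator in tests (mean over 200
simulated matrices within 3 SE). The overall rate is reported both
over all amplicon cytosines and restricted to repeat cytosines
(`overall_repeat`); the repeat-restricted figure is the headline
number, since the amplicon flanks are unmethylated primer-anchor
sequence. Genotype comparison is a plain side-by-side difference table
per context/phase — no hypothesis test is attached, as none is part of
the procedure being reproduced.

## Signal normalization

Dot-blot: index = S(TTTAGGG probe)/S(CCCTAAA probe); fold =
index_sample / index_background, where the background is a fully
converted non-methylated telomeric plasmid. Division only — no
background subtraction before ratioing, per the normalization as
described. ChIP: enrichment = antibody/normalizer (H3 or mock);
replicate panels are normalized individually and then averaged (mean ±
SD). Both statistics are scale-invariant by construction and validated
by arithmetic identities and simulator recovery; absolute blot/ChIP
magnitudes from wet-lab membranes are not reproducible quantities.

## Synthetic data: what it emulates and what it does not

One global seed feeds fixed per-stage substreams
(`subtelomere`, `smallrna`, `bisulfite`, `signals`), so any stage can
be regenerated independently and all outputs are byte-identical under
a fixed seed.

* **Subtelomeres** (default 2 arms × 15 kb): random unique sequence
  with a terminal telomeric tract (default 20 units) on the declared
  side and short interstitial tracts inside. Background is
  rejection-cleaned of incidental tracts ≥ 2 units and tract junctions
  get explicit periodicity-breaking bases, so the tract finder at
  `min_units=2` recovers exactly the planted truth intervals.
* **Small-RNA library** (AGO4-like default: G-homologies spanning
  12–25 nt, C-homologies capped at 14 nt, 23–25-nt reads, 50
  background + 10 subtelomeric reads): planted telomeric reads embed a
  repeat substring of exactly the drawn homology at a random phase and
  are re-drawn until the scanner confirms the target (and until they
  do not coincidentally have a unique subtelomeric placement, keeping
  truth labels disjoint); subtelomeric reads are exact,
  reference-unique substrings at recorded positions and strands;
  background reads are rejection-sampled (bounded at 10,000 attempts)
  against the telomeric 12-mer set and against exact subtelomeric
  membership, guaranteeing labelled negatives.
* **Bisulfite clones**: per clone, each reference cytosine is
  methylated independently with its per-position probability;
  unmethylated cytosines convert C→T with probability e (methylated
  cytosines never convert); an optional uniform per-base error follows.
  The `wt-1L0` preset models the 13-unit CCCTAAA amplicon with phase
  probabilities (0.35, 0.35, 0.65) — mean 0.45 over repeat cytosines
  with phase-3 enrichment — between fixed unmethylated flanks whose
  cytosines double as conversion controls; `rdr2-1L0` is flat 0.05.
  The 0.45/0.05 means are this package's defaults, chosen to be
  consistent with the published ">40% methylated" wild-type level and
  its dramatic RdDM-mutant reduction; 30 wild-type and 19 mutant
  clones mirror the published clone counts. Default conversion
  efficiency is 0.99.
* **Signal panels**: multiplicative log-normal noise on planted true
  indices/enrichments (default fold 4.0, SD 0.1, 3 replicates).

Deliberately **not** modelled: sequencing error profiles of real sRNA
libraries, PCR duplicates and amplification bias, chimeric clones or
indels in Sanger reads, degenerate (imperfect) interstitial telomeric
repeats, and realistic blot noise structure. Passing round-trip tests
therefore demonstrates correctness of the algorithms under clean
conditions and calibration of the estimators — not robustness to
artefacts of real libraries.

## Numerical and design notes

* Homology tie-break: on an ambiguous read, the reported offset is the
  earliest maximal run over both strands.
* Tract finding resolves overlapping same-strand candidates (possible
  only for overlaps shorter than one unit) longest-first.
* Degenerate inputs: empty read sets produce empty outputs; an empty
  clone matrix, empty reference set, or non-positive k raise argument
  errors; all-missing matrix positions are NA and excluded from
  overall rates; a zero normalizer in the quantify module raises a
  division error naming the sample.
* Problem sizes in the test suite (2–4 kb reference arms, tens of
  reads, 5–30 clones per matrix) were chosen as the smallest sizes at
  which every planted structure and statistical check is
  well-determined; the acceptance computation uses the full study-scale
  preset (13 units, 30 clones).
* The demo pipeline writes a manifest with SHA-256 hashes of every
  output; a rerun with the same seed reproduces them byte-for-byte.

## Known limitations

* The clone aligner's gap-free overlay mis-handles clones with real
  indels (they inflate the mismatch count and get rejected rather than
  realigned); a gapped mode would require affine alignment against a
  C/T-ambiguous reference.
* Uniqueness of siRNA placements is relative to the supplied
  subtelomeric windows; reads from elsewhere in a real genome can
  masquerade as unique.
* The scanner's "ambiguous" strand label cannot occur at biologically
  relevant thresholds (≥ 7 nt) but is kept for completeness at small
  homology lengths.
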