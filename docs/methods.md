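# Methods

## Conventions

- **Coordinates.** All in-memory intervals are 0-based half-open. GFF3's
  1-based inclusive coordinates are converted at parse time and converted
  back only when writing. Domain-hit coordinates on proteins stay 1-based
  inclusive, as in HMMER and InterProScan output.
- **Phase.** `phase` follows GFF3 CDS semantics: bases to drop from the
  5' end of a segment to reach the first complete codon. Propagation along
  a transcript uses `next_phase(len, phase) = (3 - ((len - phase) mod 3)) mod 3`;
  `validate_phase_chain` checks every junction in translation order (on
  the minus strand, reverse genomic order).
- **Site numbering.** Selection-screen sites are reported 1-based within
  the 23-residue repeat unit (site 1 = first residue encoded by exon
  bases 3–5).

## Canonical exon model (`shuffle_detect`)

A shuffled-LRR exon is a CDS exon with

- length 72 bp (`length_tolerance` 0 by default — the planted geometry is
  exact, and real annotations matching the model do so exactly),
- GFF3 phase 2, and
- a 23-mer translation (bases 3–71 after the 2 phase bases; base 72 is the
  dangling base that re-opens a split codon, so phase 2 propagates) whose
  17-residue consensus window matches `LxxLxxLxxLxLxxNxL`.

The identity `phase + 3 x repeat_length + dangling = exon_length`
(2 + 69 + 1 = 72) ties the parameters together and is validated in
`LrrExonSpec`. The 17-mer is slid over all `23 - 17 + 1 = 7` offsets; at
each offset the score counts hydrophobic anchors (consensus positions
1, 4, 7, 10, 12, 17 in {L, V, I, A}) plus one for Asn at position 15. The
motif passes if some offset has Asn (required by default) and at least 4
of 6 hydrophobic anchors — strict enough to reject random 23-mers, loose
enough to tolerate a few substitutions per unit. An **array** is a maximal
run of consecutive qualifying exons with run length >= `min_run` = 3;
shorter runs are common in non-shuffled LRR genes and are not evidence of
cassette-style expansion.

## Identification cascade (`roco_identify`)

Proteins pass the cascade when they carry >= 1 LRR hit (PF00560) and
>= 1 ROC hit (PF08477), both at i-Evalue <= `e_threshold` = 1e-5 (a
conventional per-domain significance cutoff; the cascade is monotone in
this threshold by construction). COR hits (PF16095) are attached without
gating because the COR profile is weakly detected by general-purpose
scans; gating on it would silently drop true members. Candidates whose
earliest LRR hit does not precede the earliest ROC hit are kept but
labelled `unclassified`. Architecture groups come from accessory
signatures with precedence group3 > group4 > group1_2:

- **group3**: a peptidase fold (IPR009003) C-terminal of the ROC span;
- **group4**: the SM00368 LRR subfamily plus a C-terminal DUF900 domain
  (IPR010297);
- **group1_2**: remaining canonical members (separating groups 1 and 2
  requires a ROC phylogeny, not domain content).

## Repeat profiles and the selection screen (`repeat_profile`)

Repeat units are equal-length 23-mers already aligned by position, so the
"alignment" is a matrix. Column information content is
`log2(20) + sum_a p_a log2 p_a` over the 20 canonical residues
(`X` is counted but carries no information), clipped to [0, log2 20]
against floating-point drift; consensus ties break alphabetically and are
recorded.

### Counting

Per codon, synonymous and nonsynonymous **site** fractions follow
Nei & Gojobori (1986): each of the three positions contributes the
fraction of its non-stop single-base changes that are synonymous.
Pairwise **differences** are pathway-averaged: all orderings of the
differing positions count equally, and pathways through a stop codon are
discarded unless every pathway is. The 61x61 pair tables and 61-long site
vectors are precomputed once; per-column sums over all unit pairs are
quadratic forms in the column's codon-count vector
(`sum_pairs N(c_i, c_j) = 1/2 c^T N c`), evaluated with `einsum`, which is
what makes 999-permutation screens take fractions of a second.

### Statistic

Per site, dN = (nonsynonymous differences over all unit pairs) /
(pair-averaged nonsynonymous sites). The synonymous baseline is a
**pooled dS over all 23 sites jointly**: per-site synonymous counts are
far too sparse (often zero) to be a stable per-site denominator, and
under the generator's model the synonymous process is site-homogeneous,
so pooling is both necessary and unbiased. `omega_hat = dN / pooled dS`;
when no synonymous signal exists at all, omega is set to infinity where
dN > 0 and the screen records a note.

### Permutation null

Sites are treated as exchangeable at the level of **deviations from the
per-site consensus codon**, not raw codons: every site has its own
consensus codon, so permuting raw codon columns would manufacture huge
artificial dN at every site and make the null degenerate. Instead each
unit x site cell is classified as consensus / synonymous variant /
nonsynonymous variant; each replicate permutes every unit's deviation
labels across the 23 sites independently and re-expresses a moved
deviation relative to the destination site's consensus codon (a random
member of its synonymous class, or a random codon of a different amino
acid). This preserves each unit's mutation load — and hence the pairwise
clustering that a single mutated copy induces — while destroying the site
assignment, which is exactly the signal being tested. Per site,
`p = (1 + #{null dN >= observed dN}) / (n_perm + 1)` (the add-one form
keeps p valid); `n_perm` = 999 by default with a floor of 199, below
which the resolution cannot support alpha = 0.05 after correction. The
observed-vs-null comparison uses a 1e-12 slack so ties of identical
floating-point values count as >=.

Rows are lexicographically sorted before drawing permutations, making
p-values invariant to input row order. The 23 p-values are adjusted by
Benjamini–Hochberg (`scipy.stats.false_discovery_control`) — the screen
asks "which sites" rather than "is there any site", so FDR control across
sites is the appropriate correction — and a site is flagged iff its
adjusted p <= alpha **and** omega_hat > 1, so significance alone never
flags a purifying site.

## Splice catalogs (`splice_variants`)

A transcript's LRR combination is the ordered tuple of its qualifying
exons' genomic intervals; isoforms differing only in non-LRR exons
collapse together (a strict mode compares full CDS-exon chains). The
catalog reports distinct combinations, per-exon usage and pairwise
Jaccard similarity of the interval sets. `combination_capacity` gives the
theoretical count of non-empty combinations: `2^n - 1` for arbitrary
subsets, `n(n+1)/2` for contiguous runs.

## Expression (`expression`)

Fold changes are plain `log2(treated / control)` of the provided
normalized values — no shrinkage, no renormalization — matching how the
published microarray fold changes were computed, which is what the
bundled fixture verifies (within ±0.01, the rounding of the printed
table). Non-positive values raise rather than returning ±inf. DEG calls
use strict inequalities `|log2FC| > 1` and `p < 0.05` by default; a
missing p-value yields `not_significant` rather than a guess. Heatmap
matrices cluster genes by average-linkage/Euclidean hierarchical
clustering on label-sorted rows (missing cells filled with 0 for distance
computation only), so the leaf order is deterministic and input-order
invariant.

The sequencing-normalized fixture blocks (RPKM, TPM) are shipped for
completeness but marked non-checkable: their published fold changes are
not log2 ratios of the printed values (upstream per-library
normalization), so no test asserts on them.

## Synthetic generator (`synthetic_data`)

### What it emulates

- The canonical gene layout: leader exon (length ≡ 1 mod 3), N repeat
  exons of exactly 72 bp in phase 2, tail exon; `GT...AG` introns; a fixed
  junction codon (`GAG`) split 1+2 across **every** junction so that any
  spliced subset of repeat exons recombines into the same residue and the
  phase chain stays valid for every variant.
- Repeat divergence: all units descend from one consensus-conforming base
  repeat (`LAGLKELDSLELTTNGLSGSKAE`, consensus window at offset 0, so the
  planted selection sites avoid every anchor) under a per-codon i.i.d.
  model — synonymous substitution with probability `synonymous_rate`,
  nonsynonymous with `nonsynonymous_rate`, the latter multiplied by
  `selection_multiplier` at `selected_sites`.
- Negative gene classes exercising each gate: LRR-only (shuffling arrays
  without a ROC domain), ROC-only, plain multi-exon genes, wrong exon
  length (75 bp), wrong phase (phase-0 whole-codon repeat exons).
- Matching domain tables (HMMER domtblout and InterProScan TSV rows
  mirroring the planted architectures), protein lengths, splice-variant
  transcripts (distinct random repeat subsets; the primary transcript
  always keeps all repeats) and expression tables with planted log2 fold
  changes plus Gaussian noise.
- Minus-strand placement with probability 0.5 via reverse-complement and
  coordinate mapping, so strand handling is always exercised.

### Key defaults and why

| parameter | default | rationale |
|---|---|---|
| `synonymous_rate` | 0.1 | enough synonymous events in ~30 units to anchor pooled dS without saturating codons |
| `nonsynonymous_rate` | 0.075 | below the synonymous rate, so unselected sites come out purifying (measured omega ≈ 0.2 in simulated families) |
| `selection_multiplier` | 8 | per-codon nonsynonymous probability 0.6 at selected sites → omega ≈ 3–4, a genuinely positively selected planted truth |
| `selected_sites` | (14, 16, 18, 19) | solvent-exposed repeat positions away from all consensus anchors, so selection never destroys detectability |
| `repeats_range` | (4, 49) | spans the observed extremes of planted arrays |
| `max_transcripts` | 9 | mirrors the maximal observed isoform count |
| `cor_prob` | 0.16 | COR-positive minority fraction |
| `expression_noise_sd` | 0.1 | planted fold changes remain recoverable within ±0.5 |

The rate pair was chosen by forward calibration — verifying that the
planted condition (omega > 1 at selected sites, omega < 1 elsewhere)
actually holds and that a neutral configuration
(`selection_multiplier=1`) yields flag rates at or below alpha — not by
tuning against any particular test outcome.

### What it does not emulate

- No phylogeny: units are i.i.d. draws from the base repeat, not leaves
  of a tree, so real lineage correlation structure is absent.
- No insertions/deletions, no repeat-length variation within an array, no
  partial or degenerate repeats.
- No sequencing or annotation noise: gene models are exact, domain tables
  are idealized (every planted domain is hit once, with fixed strong
  E-values), and the wrong-length/wrong-phase classes are clean single-
  failure negatives rather than messy real mis-annotations.
- The expression model is a planted fold change plus log-normal noise; it
  does not simulate counts, library sizes or replicate structure.

Conclusions drawn from the generator therefore validate the *machinery*
(detection, counting, permutation calibration, enumeration), not
biological effect sizes.

## Numerical and reproducibility choices

- All stochastic code takes an explicit seed and uses
  `numpy.random.default_rng`; nothing reads global random state.
- The permutation screen is fully vectorized (count matrices + einsum
  quadratic forms), so the default acceptance-scale run (20 seeds x 999
  permutations x 30 units) completes in a few seconds on one CPU.
- All orderings that could depend on dict/file order are made
  deterministic by sorting (gene ids, transcript ids, record keys), and
  the CLI `run` command writes a manifest of SHA-256 artifact hashes so
  end-to-end determinism is checkable.
- Information content is clipped to [0, log2 20]; division-by-zero
  branches (empty columns, zero denominators) return 0 rather than NaN.

## Limitations

- The selection screen is a screen, not an estimator: omega_hat uses a
  pooled synonymous baseline and uncorrected raw proportions (no
  Jukes–Cantor correction), appropriate at the low divergences the
  generator produces but biased downward at high divergence.
- Group 1 vs group 2 of the ROCO family cannot be separated from domain
  content; the merged `group1_2` label is deliberate.
- Published family counts (per-species totals, COR fractions, non-ROCO
  shuffling counts) require the original external genome assemblies and
  are out of scope for the bundled tests, which validate the cascade on
  synthetic cohorts instead.
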