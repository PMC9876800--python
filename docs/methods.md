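# Methods

## Problem and model

Positional-scanning peptide arrays (PSPAs) measure a Ser/Thr kinase's
positional substrate preferences: each array spot fixes one of 22 residues
(the 20 natural amino acids plus phosphothreonine and phosphotyrosine) at one
of nine flank positions (−5..−1, +1..+4) around a central phospho-acceptor,
randomizing the remaining positions over 17 amino acids (20 natural minus
Ser, Thr and Cys; 16 when Tyr is also excluded, as in the customized library
used for PDHK-family kinases). Densitometry of the spots yields a
22-row × 9-column raw matrix per kinase. Everything downstream — site
scoring, percentile ranks, enrichment statistics, motif clustering — derives
from these matrices.

## Matrix normalization

Applied in this order (outcomes differ if reordered, so the order is part of
the contract):

1. **Column normalization.** Each position's column is divided by the sum of
   its *n* randomized residues (n = 17 or 16), making each column a
   probability-like profile over the randomized alphabet.
2. **Cysteine rescaling.** Cys is printed on the array but absent from the
   randomized mixture, so its raw column-share is not comparable; the whole
   Cys row is rescaled by one factor so that its median across positions is
   1/n.
3. **S/T neutralization.** Ser and Thr in the flank cannot be distinguished
   from direct phosphorylation of the neighbouring residue, so the S and T
   rows at each position are overwritten with the median of that position's
   *n* randomized values ("neutral" height). The median is taken over the
   randomized residues only — pThr/pTyr and Cys are excluded because they are
   not statistically comparable mixture rows.
4. The pThr/pTyr rows receive only the column scaling of step 1.

**Acceptor favourability.** `S_S` and `S_T` are the raw S- and T-row sums.
They are divided by configurable composition controls `s_ctrl`/`t_ctrl`
(accounting for the different Ser:Thr content of the central 1:1 position and
the single-acceptor peripheral positions) and normalized by the larger value,
so `max(s0, t0) = 1`. The controls default to 1.0 and are inputs, not
estimated from data.

**Zero handling.** Zero cells are floored to `1e-6 ×` the column maximum
before normalization (and the event is logged). The flooring covers all 22
rows, not just the randomized ones: a zero in the Cys or phospho-residue rows
would equally break the downstream product score and the Cys median factor.
Entire-zero columns are rejected.

Invariants verified by the test suite: randomized column sums equal 1 to
1e−9; Cys row median equals 1/n; the normalized matrix is invariant under
global rescaling of the raw matrix; `max(s0, t0) = 1`.

## Substrate scoring and percentiles

A site is a canonical 10-symbol window (positions −5..+4, acceptor at offset
5). Its raw score under a kinase is

    score = s0_or_t0 × Π_p  m(residue_p, p) × n

with one factor per *scored* flank position. Multiplying each factor by `n`
divides the product by the probability of a random library peptide, so a flat
motif scores exactly 1 and windows with different numbers of scorable
positions stay comparable. Gap (`_`, beyond-terminus) and unknown (`X`)
positions are skipped. Phosphorylated flank residues map to the pThr row
(`s`, `t` — pSer selectivity is taken as equivalent to pThr) or the pTyr row
(`y`). Scores are kept as log2.

**Percentile.** For each kinase, a reference phosphoproteome is scored once
and the sorted log2 scores stored. A site's percentile is
`100 × #(reference ≤ score) / reference size` — the weak inequality
guarantees the maximum reference element maps to 100, and percentiles are
monotone in the score. Percentiles are computed on the log2 scale (a
monotone transform of the raw scale, hence equivalent).

**Annotation.** Kinases are ranked per site by percentile (descending), ties
broken by log2 score (descending) then kinase id (ascending; ties at rank
`k` are resolved by this deterministic ordering, not admitted). The first 15
kinases are the site's *biochemically favoured* set; the *promiscuity index*
is the number of kinases with percentile > 90 ("favourable" = top 10 % of
the phosphoproteome for that kinase); the median percentile over all kinases
is reported alongside.

## Enrichment analysis

Input sites are filtered to singly phosphorylated, non-duplicate windows and
split at the fold-change threshold (default |log2 fc| ≥ 1.5; the boundary
counts as regulated; a 0.5 option exists for low-dynamic-range studies). For
each kinase and each side (up vs unchanged, down vs unchanged) a 2×2 table
counts favoured/not-favoured sites. When any cell is zero the
Haldane–Anscombe correction adds 0.5 to **all four** cells; the corrected
cells feed the frequency factor `log2[(a/(a+b)) / (c/(c+d))]`, while the
one-sided (enrichment) Fisher exact test runs on the raw integer table —
exact tests require integer counts, and the correction exists only to keep
the log-ratio finite. P values are Benjamini–Hochberg–adjusted per side
across all atlas kinases (two families; the volcano-plot-consistent
choice). Kinases significant (adjusted p ≤ 0.1) on both sides, or depleted
(negative frequency factor) on both sides, are excluded; otherwise the side
with the smaller adjusted p is the kinase's dominant side (ties go to the up
side). Depleted kinases remain in the output — they populate the left arms
of volcano plots — unless the both-sides rule fires.

The user-facing surface is `KinaseEnrichment(sites, atlas, ...).fit()`,
returning a results object with `.frame()`, `.dominant()`, `.significant()`,
`.summary()` and `.plot_volcano()`.

## Motif clustering and logos

Each PSSM is flattened to 22 × 9 = 198 features (fixed row/position order;
s0/t0 excluded — clustering compares flank selectivity only) and
agglomerated with Ward minimum-variance linkage on Euclidean distances,
without feature standardization. The dendrogram is exported as an
ultrametric Newick tree with node height = linkage height / 2 (the standard
dendrogram halving convention), branch length = parent height − child
height.

Logo heights: a flank letter's height is its matrix value divided by the
median of that position's randomized values (the same median as in
normalization), so neutral residues have height 1 and heights below 1 mark
disfavoured residues (stored with the height; drawing below the axis is a
rendering concern). The central S and T heights are `s0` and `t0`. Group
logos average the member matrices element-wise (and the s0/t0 values) before
computing heights. Logos are computed natively and rendered with a minimal
matplotlib routine.

## Synthetic data

The generators produce inputs with the statistical structure the pipeline
assumes, so every stage is testable end to end without the published data:

- **Densitometry** (`gen_densitometry`): baseline intensity × planted fold
  factors × multiplicative log-normal noise (σ on the natural-log scale,
  default 0.2); acceptor bias is planted through the S/T row levels and read
  back out by normalization as s0/t0.
- **Background phosphoproteome** (`gen_background_sites`): flank residues
  i.i.d. from a frequency table — by default uniform over the 17 randomized
  residues, matching the library composition, with an empirical
  human-proteome option; acceptors drawn S:T at 0.85:0.15 (the approximate
  pSer:pThr ratio of observed phosphoproteomes); configurable rates of
  phosphorylated flank residues and terminus-truncated windows.
- **Substrates** (`gen_substrates_from_pssm`): flanks sampled position-wise
  proportional to the PSSM columns, acceptor proportional to (s0, t0).
- **Differential studies** (`gen_differential_study`): background sites get
  log2 fc ~ N(0, 0.3); substrates of one planted kinase get
  log2 fc ~ N(effect, 0.3) with default effect +2. All sites are singly
  phosphorylated unless configured otherwise.

What the generators do **not** emulate: real kinase families and their
motif similarities, inter-positional residue coupling, protein abundance and
detectability biases, peptide-level missingness, and shared substrates
between kinases. Passing the planted-recovery and null-calibration tests
therefore shows the statistical machinery is correct under the stated
generative model, not that real studies will reach the same power.

## Problem sizes and numerical choices

- Synthetic atlases use 20 kinases, each with 3 strongly favoured positions
  (fold 15, noise σ = 0.1) — well-separated motifs by construction.
- Planted-recovery experiments: 5,000-site reference phosphoproteome,
  5,000 background + 200 planted study sites, effect +2, noise 0.3,
  threshold 1.5, top-15 rule, 20 seeded replicates (10 in the acceptance
  script).
- Null calibration: same atlas geometry, 2,000-site reference and studies,
  zero effect, 50 replicates (20 in the acceptance script).
- Percentile and scoring paths are vectorized (window → row-index encoding,
  `searchsorted` percentiles), so these runs complete in seconds.
- Degenerate cases: empty regulated classes produce p = 1 rows with a
  warning rather than failure; an empty unchanged class is an error (no
  reference class); duplicate kinase ids are rejected everywhere; Ward
  tie-breaks follow SciPy's deterministic pair ordering.
- Floats are serialized with Python's shortest round-tripping
  representation and parsed with pandas' `round_trip` converter, making
  write → read → write byte-identical.

## Known limitations

- First-order model: position-specific factors multiply independently; no
  interpositional coupling is measured or modelled.
- `s_ctrl`/`t_ctrl` must be supplied by the user when the acceptor
  composition of the library deviates from 1:1; they are not estimated.
- The Fisher test on Haldane-corrected tables uses the raw integer counts;
  a continuous extension of the exact test is deliberately not attempted.
- Image-level processing (densitometry extraction from scans, local
  background subtraction) is out of scope; the pipeline starts at tabular
  densitometry.
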