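# Methods

## Scores

Three quantities characterise a chain of `N` residues as a precursor of
bioactive peptides, all computed against a peptide-activity reference
table (peptide sequence → activity label, with (peptide, activity)
pairs unique):

* **Frequency of occurrence** `A = a/N` per activity, where `a` counts
  every occurrence of every reference peptide carrying that activity as
  a contiguous substring. Overlapping and repeated occurrences all
  count (`AAAA` versus the dipeptide `AA` gives `a = 3`), and a peptide
  listed under two activities contributes once to each — per-activity
  counting is independent. Matching is exact substring identity; there
  is no substitution tolerance. `∑A` is the sum of `A` over all
  activity labels in the reference, and the implementation guarantees
  this additivity exactly by computing in rational arithmetic
  (`fractions.Fraction`), converting to float only at output, where
  scores are rendered with 4 decimals.
* **Theoretical degree of hydrolysis** `DH_t = d/D × 100 %` of an
  exhaustive digest: `d` hydrolysed bonds out of `D = N − 1`. A
  single-residue chain has `D = 0` and `DH_t` is an error, not 0.
* **Frequency of release** `A_E = d/N` per activity, `d` counting
  digest fragments whose full sequence equals a reference peptide of
  that activity (each released fragment occurrence counts once; a
  reference peptide present in the chain but bisected by a cleavage
  site contributes nothing). `∑A_E` sums over activities.

Single-residue reference entries are excluded by default
(`min_fragment_length = 2`): dipeptides are the shortest fragment class
that dominates curated bioactive-peptide collections, and free residues
would swamp both `A` and `A_E`.

## Digestion model

Each protease is a single-position specificity rule: it cleaves the
bond C-terminal to any residue in its P1 set unless the next residue is
in its P1′ exclusion set. This deliberately follows the convention of
database-style proteolysis simulators rather than context-dependent
rule sets (e.g. PeptideCutter): the tools this package mirrors treat
specificity at single-bond resolution. The pinned default table —
pepsin at pH > 2: P1 {F, L}; trypsin: P1 {K, R}; chymotrypsin A:
P1 {F, Y, W}; no exclusions — ships as editable TSV data
(`src/nutpep/data/enzymes.tsv`), so a different specificity dialect is
a data change, not a code change. Multi-enzyme digestion is
simultaneous (the union of all sites), and every susceptible bond is
cut; there is no partial-digestion or missed-cleavage model. Released
fragments are by construction resistant to re-digestion with the same
enzymes (idempotence), a property the test suite checks on random
inputs.

## Epitope mapping and merging

Linear epitopes are placed on their annotated source protein by exact
substring search (all occurrences). Cross-species transfer to
homologous proteins uses Smith–Waterman local alignment with the PAM30
substitution matrix, gap open 9 and gap extension 1 — the standard
parameterisation for short peptide queries, where default scoring
schemes produce false negatives. A full dynamic-programming alignment
at this scale is exact, so it bounds from below the sensitivity of any
word-seeded heuristic at word size 3.

Identity is defined as the number of identically aligned residues
divided by the *epitope* length, not by the number of aligned columns.
This coverage-inclusive convention is deliberate: a short perfect local
sub-alignment must not masquerade as a full-identity hit, and it makes
identity 1.0 exactly equivalent to an exact full-length substring
match. For the default transfer threshold of 1.0 (identical epitopes
only) the implementation therefore uses exact substring search on all
proteins, which additionally finds every occurrence rather than the
single best-scoring placement; the aligner is engaged for thresholds
below 1.0.

Mapped placements on the same protein are merged iteratively when they
overlap by at least one residue or directly abut (gap 0 — one residue
of separation does *not* merge, matching how overlapping peptides are
joined in peptide-scanning epitope mapping; any larger tolerance would
be an unstated assumption). Merging is idempotent, order-invariant and
coverage-preserving; merged regions carry the sorted union of their
member epitope IDs and 1-based inclusive coordinates throughout.

Epitope regions are scored by exactly the same operations as whole
proteins, with `N` the region length and the excised region treated as
a standalone chain. Flanking protein context is ignored during
digestion of a region; in vivo, flanking residues could create or
destroy terminal cleavage sites, so region-level `DH_t`/`A_E` are
properties of the excised sequence, not of the region in situ.

## Domain sets and group statistics

Proteins are classified from their InterPro IDs by a priority rule:
napin domain IPR000617 → set 1; vicilin N-terminal domain IPR006792 →
set 2; cupin 1 (IPR006045) with an 11S seed-storage domain
(IPR006044 or IPR022379) → set 3b; cupin 1 alone → set 3a; otherwise
unclassified. Sets 3a and 3b merge to set 3 (the cupin 1 family). The
17 studied tree-nut allergens and their domain IDs are bundled as
package data and the classifier reproduces each allergen's catalogued set label.

Group summaries report the arithmetic mean and the sample standard
deviation (n − 1 denominator; single-member groups report sd = 0 and
are excluded from testing). Unclassified proteins are excluded from the
labelled groups but included in the whole-set ("all") summary.
Pairwise comparisons use the two-sided Welch t-test — the safe default
when group sizes and variances differ and the test variant is otherwise
unspecified — at p < 0.05 with no multiple-testing correction; the
number of comparisons is reported so users can correct externally.
Between-group "distance" is the absolute difference of scalar group
means (the Euclidean distance in one dimension), exported as a
symmetric zero-diagonal matrix suitable for external heat-map tools.
Epitope `∑A` values are binned into four fixed intervals
(0.1–0.5999, 0.6000–1.0999, 1.1000–1.5999, 1.6000–2.1000), endpoints
inclusive at the printed 4-decimal precision, with values outside
[0.1, 2.1] labelled out-of-range.

## Synthetic data

The generators stand in for database retrievals so every stage is
testable offline, and their defaults mirror realistic conditions:

* `generate_reference` draws peptides with length weights
  {2: 0.70, 3: 0.25, 4: 0.05} — dipeptides dominant, tripeptides
  common, longer fragments exceptional, matching the composition of
  curated bioactive-peptide collections — across four default activity
  labels (ACE, DPP-IV and DPP-III inhibition, antioxidative), the most
  abundant catalogued classes.
* `generate_protein_with_plants` places an exact number of copies of
  each planted peptide at recorded positions, separated by at least one
  background residue, with the background alphabet (default `AGST`)
  disjoint from all planted residues. Any window containing a
  background residue therefore cannot equal a planted peptide, making
  the recorded occurrence counts exact rather than probabilistic.
  `plantable_reference` additionally enforces a substring-free peptide
  set so that no planted peptide hides inside another.
* `generate_cleavage_layout` joins inert fragments with K residues so
  the trypsin cut sites — and hence `DH_t` — are known by construction.
* `generate_epitope_scenario` lays epitopes out in chained, disjoint or
  abutting-pairs profiles with known merged-region truth.

Every generator re-runs the corresponding pipeline operation on its own
output before returning and raises on any mismatch, so a planted truth
can never silently drift from the implementation. All randomness flows
through one seeded `numpy.random.Generator` per call; outputs are
bit-stable for fixed (parameters, seed).

What the synthetic data does not emulate: real allergen homology
families, the actual composition of any bioactive-peptide database
snapshot, or IgE reactivity. Passing the planted-truth suite
demonstrates the correctness of the counting, digestion and merging
machinery, not the reproduction of database-dependent score magnitudes:
`∑A` and `∑A_E` for real proteins depend on the contents of the
reference snapshot used.

## Numerical and design choices

* All frequencies are exact rationals internally; `DH_t` is a float
  ratio of small integers. Output rendering is fixed at 4 decimals.
* Ambiguity codes (B, J, X, Z, U, O) are rejected at parse time by
  default; in permissive mode they are retained but any fragment
  containing them matches no reference peptide, since occurrence
  counting is undefined for ambiguous residues.
* Sequences are taken as given in the input FASTA; whether they are
  full precursors or mature chains is the caller's decision, and scores
  are always relative to the supplied chain length.
* Welch p-values with zero variance in both groups are defined as 1
  when the means coincide and 0 otherwise (the degenerate limit).
* The test suite validates Welch p-values against a studentized
  permutation oracle; the comparison band (0.08) combines three-sigma
  Monte-Carlo error at 2,000 permutations with the expected
  small-sample discrepancy between the permutation null and the
  t-reference distribution at group sizes of 5–9.
* Problem sizes in the test and acceptance batteries (sequences ≤ 300
  residues, references ≤ 50 peptides, 100–1,000 random cases per
  property) were chosen to exercise every code path exhaustively at
  interactive runtimes; all checks are exact, so larger sizes add cost
  without adding discrimination.

## Known limitations

* Exhaustive cleavage overstates real digestion; experimentally, not
  all susceptible bonds are hydrolysed.
* The pinned P1 sets reproduce a single specificity dialect; other
  conventions (e.g. chymotrypsin including L, proline exclusions)
  require editing the enzyme table. Score comparisons across dialects
  are not meaningful.
* Cross-species epitope transfer below identity 1.0 reports the single
  best local alignment per protein, not all co-optimal placements.
* Group statistics assume independent entities; homologous proteins
  within a family violate this assumption.
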