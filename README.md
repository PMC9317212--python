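# nutpep

Quantitative in-silico evaluation of proteins — and of the linear IgE
epitopes mapped onto them — as precursors of bioactive peptides, built
around the workflow used for tree-nut seed-storage allergens (cashew,
pecan, English walnut, pistachio).

Food proteins encrypt short bioactive peptides (ACE inhibitors, DPP-IV
inhibitors, antioxidative fragments, mostly di- and tripeptides) that
can be released during digestion. `nutpep` scores any protein or
epitope region with three standard quantities:

* **Frequency of occurrence** of fragments with a given activity,
  `A = a / N`, where `a` counts every (possibly overlapping) occurrence
  of a reference peptide with that activity in the chain and `N` is the
  chain length; `∑A` sums `A` over all activities.
* **Theoretical degree of hydrolysis** under exhaustive rule-based
  proteolysis, `DH_t = d / D × 100 %`, with `d` the number of
  hydrolysed peptide bonds and `D = N − 1` the total bond count. The
  default enzyme set is the digestive-tract trio pepsin (pH > 2,
  P1 ∈ {F, L}), trypsin (P1 ∈ {K, R}) and chymotrypsin A
  (P1 ∈ {F, Y, W}), acting jointly (union of cleavage sites).
* **Frequency of release**, `A_E = d / N`, where `d` here counts digest
  fragments whose sequence equals a reference peptide of the given
  activity; `∑A_E` sums over activities.

Around these scores the package provides: linear-epitope mapping
(exact, and cross-species via Smith–Waterman with PAM30) with merging
of overlapping/abutting epitopes into non-redundant regions; InterPro
domain-set classification of allergens (napin set 1, cupin 1 + vicilin
N-terminal set 2, cupin 1 sets 3a/3b and their union set 3); group
means/SDs, pairwise Welch t-tests and distance-matrix export; and a
synthetic-data generator that plants fragments, cleavage sites and
epitope layouts with exact, self-validated ground truth.

Intended users: food scientists and bioinformaticians screening
proteins or protein families as candidate precursors of bioactive
peptides, and anyone needing a tested, scriptable replacement for
manual web-tool profiling at small scale.

## Worked example

```python
from nutpep import (ActivityEntry, ActivityReference, activity_frequency,
                    default_enzymes, digest, theoretical_dh,
                    release_frequency, total_frequency)

ref = ActivityReference([ActivityEntry("VW", "ACE inhibitor"),
                         ActivityEntry("YP", "DPP-IV inhibitor")])

print(float(total_frequency("VWYPVW", ref)))          # 0.5
print(float(activity_frequency("VWYPVW", ref, "ACE inhibitor")))  # 0.3333...

trypsin = default_enzymes(["trypsin"])
result = digest("AKVWKG", trypsin)
print([f for f, _, _ in result.fragments])            # ['AK', 'VWK', 'G']
print(theoretical_dh(result))                         # 40.0

ref2 = ActivityReference([ActivityEntry("VWK", "ACE inhibitor")])
print(float(release_frequency("AKVWKG", trypsin, ref2, "ACE inhibitor")))
# 0.1666... (one released VWK in a chain of 6)
```

`VWYPVW` (N = 6) contains the ACE-inhibitor dipeptide `VW` twice and
the DPP-IV-inhibitor dipeptide `YP` once, so A(ACE) = 2/6 ≈ 0.3333 and
∑A = 3/6 = 0.5. Trypsin cuts `AKVWKG` after both K residues (2 of 5
bonds, DH_t = 40 %) and thereby releases the ACE-inhibitor tripeptide
`VWK`, giving A_E = 1/6.

From the shell, the same analyses (plus epitope mapping, group
statistics and the full pipeline) are available as:

```bash
nutpep simulate proteins --seed 3 --out-dir sim/
nutpep scan   --fasta sim/proteins.fasta --activities sim/activities.tsv --out scores.tsv
nutpep digest --fasta sim/proteins.fasta --activities sim/activities.tsv --out digest.tsv
nutpep run    --config run.cfg
```

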