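# Methods

## The distance

Input is a dominant SSR band matrix: accessions × amplified fragments with
cells present/absent/missing. Scoring is per fragment, not per locus, so a
single allele substitution at one microsatellite locus typically contributes
*two* differences (one band lost, one gained); difference counts must be read
with that in mind. The distance between two accessions is the plain mismatch
count over fragments scored in both ("number of differences" with pairwise
deletion). Two normalisations are exposed:

- the default divergence proportion divides by the **fixed total band
  count** of the matrix, so one mismatch always means the same fraction
  (1/493 ≈ 0.2% at the reference band total) regardless of how many bands a
  particular pair had scored;
- an alternative divides by the per-pair compared count; it is available
  (`proportion_matrix(..., denominator="compared")`) but never the default.

Monomorphic bands are retained (they contribute zero mismatches); this keeps
the fixed denominator literal. A pair with *no* mutually scored band has an
undefined distance and is a hard error rather than a silent NA — with ~60
markers per accession such a pair indicates broken input, not missingness.

## Duplicate calling

Accession pairs with at most `threshold` differences (default 5) are linked
and the connected components of that graph with ≥ 2 members are the duplicate
clusters — single-linkage transitive closure. Chaining is accepted
deliberately: it is the only rule that never leaves an accession ambiguously
assigned, and clonal variation is transitive in origin (all members descend
from one clone). Consequently the reported max within-cluster difference may
exceed the threshold. A stricter all-pairs-within-threshold variant
(`linkage="clique"`, maximal cliques assigned greedily largest-first) exists
for sensitivity analysis only.

Census bookkeeping identities, checked on every pipeline run:
`unique_genotypes = singletons + clusters`, and the number of within-cluster
pairs at ≤ threshold equals the histogram mass at 0..threshold (single
linkage puts every such pair inside some cluster). Cluster labels C-1, C-2, …
are assigned by descending size, ties by smallest member id, so reruns are
reproducible.

A helper (`suggest_threshold`) reports the largest difference value below the
first empty histogram band as a data-driven threshold candidate; it is
advisory and never applied automatically.

## Trees and bootstrap support

UPGMA and neighbor joining both run on the raw difference counts, not
proportions. UPGMA places each merge at half the average between-cluster
difference (Lance–Williams average-linkage update), giving an ultrametric
rooted dendrogram; NJ uses the standard Q-criterion with the usual three-point
formulas for the final join. Numerical choices:

- **Tie-breaking**: argmin scans row-major, so ties resolve to the lowest
  current (row, column) pair. Deterministic, but *index-based*, so equality
  of outputs under accession reordering is only guaranteed for tie-free
  distance matrices (integer band distances do tie in practice).
- **Negative NJ branch estimates** (non-additive data) are clamped to zero;
  the total clamped length is reported in the tree's run log.
- Trees are stored as dendropy trees; Newick output carries branch lengths
  and integer bootstrap supports as internal node labels.

Bootstrap support resamples the **individual band columns** with replacement
(the character unit of the matrix; locus-block resampling is not the unit
the fingerprint is scored in), recomputes pairwise-deletion distances, and
rebuilds the tree per replicate. Support of an internal edge of the
point-estimate tree is the percentage of replicates containing the same
clade (rooted UPGMA) or the same unrooted leaf bipartition (NJ) — support is
mapped onto the single point-estimate topology, not a majority-rule
consensus. Replicates in which some pair loses every mutually scored column
are rejected and redrawn, with a counter in the log and a hard cap to
guarantee termination. `collapse_branches` contracts internal edges below a
support threshold (default 75%) into polytomies, leaving surviving supports
untouched.

## The simulator

`generate_collection` emulates a clonal tetraploid collection:

| parameter | default | meaning |
|---|---|---|
| `n_loci` | 62 | SSR markers |
| `alleles_per_locus` | 3–12 | per-locus fragment pool (uniform draw) |
| `bands_per_genotype` | 1–4 | bands a genotype carries per locus (tetraploid, dosage-free) |
| `n_unique_genotypes` | 140 | distinct genotypes in the collection |
| `group_size_distribution` | {2:21, 3:4, 4:3, 5:1, 8:1, 10:1} | planted clonal groups (31 groups, 89 accessions, 198 total) |
| `within_clone_flip_range` | 0–5 | founder→copy band flips |
| `missing_rate` | 0.01 | uniform cell missingness |
| `allele_concentration` | 0.2 | Dirichlet concentration of locus allele frequencies |
| `seed` | 0 | full determinism |

Each unique genotype draws, per locus, 1–4 alleles without replacement,
weighted by locus allele frequencies drawn from a symmetric Dirichlet. The
concentration 0.2 makes one or two alleles per locus common and the rest
rare; independent genotypes then share the common bands, which places
between-genotype distances mostly in the 70–140 band range (mean ≈ 105–112
of ~470 bands) — the regime of a real clonal crop collection, which a
uniform allele model (distances ≈ 200+) does not reproduce. This value was
fixed once from that calibration and is a generator constant, not a fit.

Clone-group members are the founder's fingerprint with an exact number of
band flips (drawn uniformly from `within_clone_flip_range`), modelling
scoring error and somatic mutation directly at the band level where the
pipeline's distance operates. Flips are applied before missingness. Because
every member is within 5 flips of its founder, single linkage at threshold 5
recovers each planted group through the founder even when two members are up
to 10 flips apart. The realised within/between gap is *measured*
(`realized_gap`), never assumed; recovery tests skip-and-count seeds where
the gap fails (none observed across the tested seed ranges).

What the simulator does **not** model, and what passing tests therefore do
not show about real data: allelic (paired-band) mutation structure, pedigree
relatedness between distinct genotypes (simulated genotypes are exchangeable
draws, so there are no "close but distinct" varieties at 10–40 differences),
locus-correlated missingness (failed PCRs drop whole marker columns), and
scoring error on unrelated accessions. The 5–40-difference band that is
nearly empty in simulation can be populated in real collections by parent–
offspring or sport relationships; the census on real data should be read
with the divergence-band report (`divergence_band`) alongside.

## Pipeline and problem sizes

`run_pipeline` chains read/simulate → validate → distances → histogram →
census → bootstrap trees → collapsed trees and writes every artifact
(CSV/PHYLIP/Newick/JSON) into one directory; identical config + seed gives
byte-identical files, and artifacts of a failed run are removed. Stage
failures carry the stage name.

Default analysis sizes: 198 accessions × ~470 bands, 500 bootstrap
replicates. A full UPGMA bootstrap at that size runs in ~20 s on one CPU
(vectorised distance recomputation per replicate; merge bookkeeping in
NumPy); tests use smaller collections (10–30 genotypes, 10–30 loci) except
the end-to-end acceptance checks, which run the study-scale configuration.

## Known limitations

- UPGMA/NJ are O(n³); fine for collection-scale inputs (hundreds of
  accessions), not for thousands.
- Support values are bipartition frequencies on the point topology; they are
  not corrected for the multiplicity of near-equal merges among identical
  fingerprints (duplicate-group-internal branching order is arbitrary and
  its internal edges legitimately get low support).
- The clique-linkage variant assigns overlapping cliques greedily; for
  pathological threshold graphs the assignment, while deterministic, is not
  an optimum of any stated criterion.
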