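# Methods

This note records the models implemented, the parameter defaults and why
they were chosen, the scope of the synthetic generator, numerical
choices, and known limitations. Nothing here makes empirical claims
beyond what the test suite and `scripts/acceptance.py` compute.

## Screening (`magphylo.screen`)

Candidate bins are screened by exact nucleotide k-mer containment
against per-species reference k-mer sets:
`containment = |bin ∩ ref| / |bin k-mers|`, best species wins
(lexicographic tie-break). Defaults `k = 21`,
`min_containment = 0.30`. Containment is normalized by the bin's own
k-mers, so duplicating scaffolds does not change the score. This is a
deterministic, desk-scale replacement for a megablast search with a
high bit-score gate; it has the same qualitative sensitivity profile —
in the synthetic study, bins at ≤ 5% protein divergence from a
reference pass easily, while a bin at 15% divergence falls below the
21-mer containment floor (long exact matches die off roughly as
`(1 − per-codon substitution rate)^7`). The phylogenomic stages are
therefore driven from the protein orthology path, not the screen.

The genus genome-size filter drops a bin only when its total length is
*strictly more than* 1.10 × the genus median genome size; undersized
bins are retained (handled as incompleteness). Marker completeness
counts 0 / 1 / ≥ 2 copies per marker orthogroup as
missing / single-copy / duplicated.

## LCA classification (`magphylo.lca`)

MEGAN-style lowest-common-ancestor rule: discard hits with bit score
< 50 or e-value > 0.001, keep hits within 10% of the best surviving bit
score (boundary inclusive, so exact floating-point ties at the band
edge are kept), and assign the LCA of the kept subject taxa; an empty
survivor set yields `unassigned`. Verified against an
exhaustive-enumeration oracle on random taxonomies.

## Orthology and supermatrix (`magphylo.supermatrix`)

Orthogroups are inferred by reciprocal best hits on shared residue
5-mers, merged by single-linkage union-find. A hit must share at least
`min_shared = 3` 5-mers; without this guard, tie-at-zero chance
collisions between unrelated proteins occasionally become spurious
reciprocal pairs and chain whole proteomes into one group. The pipeline
then applies a single-copy filter (drop any group where some taxon has
≥ 2 copies — contaminant copies are deliberately caught here) and an
occupancy filter keeping groups present in at least
`ceil(min_fraction × n_taxa)` taxa, boundary inclusive so exactly 50%
passes at the default. Surviving equal-length loci are concatenated in
lexicographic locus order with gap (`-`) padding for absent cells, and
per-locus column intervals are recorded as a partition map.

## Distances and trees (`magphylo.treekit`)

Pairwise distances use a 20-state equal-rates (Jukes–Cantor-type
protein) model with pairwise deletion of gapped columns:
`E[p] = (19/20)(1 − exp(−20 d / 19))`, inverted as
`d = −(19/20) ln(1 − 20 p / 19)`. Mismatch fractions at or beyond
19/20 raise a saturation error rather than returning infinity; pairs
with no mutually ungapped column raise an undefined-distance error.

Neighbor joining is implemented by hand because the pipeline fixes two
behaviors library implementations do not guarantee: ties in the
Saitou–Nei Q criterion break to the lowest (row, column) index pair,
and negative branch-length estimates are clamped to zero with the
deficit moved onto the sister branch so patristic distances remain a
valid metric. On any additive matrix, NJ provably recovers the exact
topology and branch lengths; the tests verify this on seeded 12-taxon
trees (Robinson–Foulds distance 0, patristic error ≤ 1e−9).

Bootstrap supports come from nonparametric column resampling: each
replicate resamples supermatrix columns with replacement, and an
internal edge's support is the rounded percentage of replicates whose
NJ tree contains its bipartition. Bipartitions are keyed
rooting-invariantly as the frozenset of their two leaf-label sides, so
rerooting never migrates a support value to a different split. Rooting
places the root at the midpoint of the outgroup's terminal edge.

## Classification cascade (`magphylo.classify`)

After a long-branch filter (reject queries whose terminal branch
exceeds 5 × the median reference terminal branch), each query gets the
smallest clade above it with stem bootstrap support ≥ 95, and evidence
is extracted: nearest reference by minimum patristic distance
(tree-wide, lexicographic tie-break), number of reference species
co-clustered (or in the immediate sister group when the clade holds
only queries), intra-clade distance range among co-clustered queries,
and the clade's stem support. The cascade (first rule wins):

1. support < 95 → `unplaced`;
2. nearest genus flagged non-monophyletic (*Candida* sensu lato) →
   `family_level`;
3. one near reference and d ≤ 0.02 → `conspecific`;
4. one near reference and d ≤ 0.08 → `provisional_species`;
5. several near references and d ≤ 0.08 → `novel_species_in_genus`;
6. otherwise → `family_level`.

The thresholds 0.02 / 0.08 substitutions per site are calibrated so the
bundled survey's printed decisions are all reproduced (0.0070 and 0.016
conspecific; 0.032–0.077 with four equally near references novel;
0.0731 single-reference provisional; 0.1082 family-level); both are
exposed on the CLI. The cascade is total, monotone in distance (larger
d never yields a finer rank), and order-independent — all three are
property-tested.

## Synthetic generator (`magphylo.synthgen`)

Scope: the generator produces *inputs* for every pipeline stage with
known ground truth. It is a benchmark harness, not a sequence-evolution
research tool.

- **Species tree**: Yule (pure-birth) tree, leaves relabeled T01…Tnn,
  branches rescaled so the mean root-to-leaf path is 0.5
  substitutions/site — deep enough to emulate a subphylum-wide panel,
  shallow enough that 5-mer orthology detection still works. Terminal
  branches are floored at 0.05: a curated reference panel holds
  distinct species, never near-identical genomes, and the floor also
  keeps the 5×-median long-branch rule from flagging ordinary divergent
  queries. The ingroup root stem is fixed at 0.1 × depth (an unbounded
  random stem occasionally pushed the outgroup out of orthology range)
  and the outgroup branch at 0.2.
- **Proteins**: root sequences uniform over 20 residues; each branch
  applies Poisson(d·L) substitution events with uniform replacement
  over the other 19 residues — exactly the model the distance estimator
  inverts, so estimator calibration is testable. Per-(locus, taxon)
  occupancy dropout is Bernoulli; the outgroup keeps all loci.
- **Query MAGs**: evolved off a chosen reference at a requested
  divergence; optional incompleteness (random locus deletion),
  contamination (duplicate copies from a donor taxon, caught by the
  single-copy filter), and chimerism (half the loci from each of two
  parents). Nucleotide scaffolds come from a fixed codon per residue
  with lognormal scaffold lengths (median 20 kb).
- **Depth tables**: per-base depth is negative binomial
  (gamma-Poisson, dispersion 10); a minor strain at fraction f differs
  at Bernoulli(strain divergence) sites, where the alternate-allele
  count is Binomial(depth, f). `expected_alt_positions` computes the
  mean and SD of called heterogeneous positions numerically from this
  model for independent verification.
- **Ground truth**: divergence ≤ 0.02 → conspecific, ≤ 0.08 →
  provisional, < 0.3 → family-level; divergence ≥ 0.3 or chimerism →
  rejected. All randomness flows from one root seed through named
  substreams (`numpy.random.default_rng([seed, crc32(name)])`),
  so adding one generator never perturbs another's draws.

## Community metrics (`magphylo.community`)

Positions absent from a depth table count as depth 0 (sparse
convention, 1-based coordinates). A position is heterogeneous when
`alt_count ≥ 2` **and** `alt_count / depth ≥ 0.1` — the two-knob rule
suppresses singleton errors while catching ≥ 10% minor strains; both
knobs are CLI-exposed. Presence matrices exclude rejected MAGs;
co-occurrence percent is rounded to the nearest integer (5/9 → 56); the
abundance scatter keeps scaffolds of length ≥ 4,000 bp, boundary
inclusive, with log2 transforms left to the plotting layer.

## Limitations

- **Balanced chimeras do not produce long branches under distance
  methods.** A query whose loci are drawn half/half from two distant
  parents is placed by NJ near the midpoint of the path between them
  with a *short* terminal branch, because distance averaging absorbs
  the conflict instead of expressing it as excess divergence. The
  long-branch filter therefore catches uniform excess divergence
  (misassembly / error-rich genomes, emulated at divergence ≥ 0.3) but
  not balanced chimeras; those are caught earlier, by the genome-size
  filter and the single-copy/occupancy filters. The `chimera_with`
  generator mechanism exists and its ground truth is `rejected`, but
  the benchmark scenario uses uniform excess divergence for the
  rejected category.
- NJ with Poisson-corrected distances is a deliberate desk-scale
  substitute for maximum-likelihood inference (IQ-TREE); externally
  inferred Newick trees can be imported instead.
- The k-mer screen loses sensitivity beyond ~10% divergence, like the
  exact-match seeding of the search it replaces; distant novelties
  enter the pipeline through the protein orthology path.
- The generator's fixed codon table makes nucleotide scaffolds
  unrealistic at the composition level; they exist only to exercise
  screening and scaffold-length plumbing.
- Bootstrap supports use 50–200 replicates in the scripts and tests
  (not the thousands used in production phylogenomics) to keep runtimes
  in seconds.
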