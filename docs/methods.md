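# Methods

## Model and procedure

`funred` treats functional prediction from 16S amplicon data as a lookup
problem: a reference database associates 16S rRNA gene sequences with the
gene content (KO counts) of the genomes they came from, and a community's
functional profile is the abundance-weighted mixture of the profiles of the
references its OTUs map to. The core assumption is the one all
marker-gene-based predictors share: phylogenetic proximity of the 16S gene
predicts gene content. The redundancy indices add a second layer: given
which community members carry a function, how phylogenetically spread out
are they?

### Reference database construction

1. **Clustering.** All 16S sequences from the genome collection are sorted
   by decreasing length (ties broken lexicographically by sequence id) and
   processed greedily: a sequence joins the *first* existing cluster whose
   centroid it matches at or above the identity threshold, else founds a new
   cluster whose centroid it becomes. This is the classical greedy centroid
   scheme; it is deterministic given the input set. Identical sequences are
   memoized, so intra-genome paralogs (which the simulator generates as
   exact copies) cost one alignment.
2. **Copy-number normalization.** A genome's KO counts are divided by its
   16S copy number. Without this, a 10-copy genome would contribute ten
   times its gene content per observed amplicon.
3. **Cluster averaging.** A cluster's abundance profile is
   `Σ_g copies_g · profile_g / n_genomes`: each member genome's normalized
   profile is first multiplied by the number of its 16S copies that landed
   in the cluster, then the mean over member genomes is taken. An
   alternative `weighted_mean` mode divides by total copies instead; it is
   exposed behind the `averaging` flag of `build_reference_database` because
   the two readings differ only for multi-copy genomes and the scaled mean
   is the default. Alongside, the *presence fraction* — the share of member
   genomes with a nonzero count — is stored per KO; it drives the
   presence/absence step of the redundancy indices.

### Percent identity

Identity is matches / aligned columns under a semi-global alignment:
terminal gaps are free (amplicon fragments are substrings of full-length
references), internal gaps count as non-matching columns. The alignment
path is computed with edlib (Myers bit-vector, ~30 µs per 400-nt pair,
roughly 80× faster than a general affine-gap aligner), in infix mode when
lengths differ and global mode at equal lengths, with terminal indel runs
trimmed from the path. The pair is aligned in a canonical order so the
function is exactly symmetric. The test suite checks it against an
independent overlap-alignment dynamic program.

### Nearest-neighbour search and tiering

Each query is scored against every reference; the best hit maximizes
identity, with ties broken by longer reference and then lexicographic id.
When a user (habitat-specific) database is present, both tiers are
searched; a user-tier hit passing the identity floor wins regardless of the
default tier's score, on the assumption that user genomes were chosen to
represent the habitat. "Significance" of a hit is defined as identity ≥ the
floor (default 97%); an adapter for external BLAST tabular output (e-value
≤ 1e-5 plus the same floor) is provided for users who prefer BLAST, but the
built-in search never requires it.

### Redundancy indices

For detected members `M` (references hit by ≥ 1 passing OTU with nonzero
count in the sample) and function `f` carried by `M_f ⊆ M`:

    raw(f)  = mpd(M_f) · |M_f| / |M|
    rFRI(f) = raw(f) / mpd(M)
    aFRI(f) = raw(f) / mpd(all tree leaves)

`mpd` is the mean pairwise patristic distance; it is defined as 0 for at
most one leaf, which makes a single-carrier function score exactly 0 — this
is the property that fixes "average phylogenetic distance" to the
*pairwise* reading rather than distance-to-centroid. The proportion counts
distinct detected references, consistent with the presence/absence
conversion of the OTU table.

**Presence binarization.** A detected reference carries `f` when
`presence_fraction(f) × k_otus ≥ 0.5`, where `k_otus` is the number of
distinct passing OTUs mapped to that reference: more distinct phylotypes
behind one reference make it likelier that some member genome carries the
function. The boundary is inclusive — with 5 OTUs, a 10% presence fraction
is admitted (5 × 0.10 = 0.50). The comparison uses an exact-or-isclose test
so the canonical 0.10 × 5 case never falls to floating-point rounding.
Setting `presence_threshold=1.0` recovers the strict rule where a function
must be present in every member genome of the cluster.

**Degenerate cases.** A sample with no detected member is skipped (its
coverage log still records FTU = FSU = 1). If all detected members are one
leaf, the denominators vanish and the indices are reported as 0.

## Synthetic data: what it emulates and what it does not

`simulate_world` generates the study conditions used throughout testing and
validation:

- **Tree.** A Yule (pure-birth) tree, lineages splitting at rate 1, with an
  exponential waiting time appended after the last split so every terminal
  branch is strictly positive; branch lengths are rescaled to unit tree
  height. (A birth–death simulator that stops exactly at the n-th
  speciation leaves the last cherry with zero-length tips — i.e. two
  identical genomes — which is why the generator draws the final waiting
  time explicitly.)
- **16S evolution.** Per-site substitution with probability
  `1 − exp(−r·L)` per branch of length `L`, to a uniformly random different
  base (Jukes–Cantor-like, no indels, keeping identities analytic). The
  default `substitution_rate = 0.10` expected substitutions/site over the
  tree height gives within-community identities of roughly 82–97% with
  sister taxa above 99% — a realistic amplicon spread in which clustering
  actually merges some taxa.
- **Gene content.** A `core_fraction` (default 0.2) of the `n_functions`
  (default 300) KOs is present in every genome; the rest start at the root
  with probability 0.5 and flip (gain/loss) along branches with probability
  `1 − exp(−0.3·L)`. Where present, KO counts are uniform on 1–3.
- **Copy number.** Uniform on 1–4 per genome, with identical paralogs.
- **Communities.** Uniform random genome subsets (default size 30); their
  16S copies are clustered at 97% into OTUs, each represented by its
  longest sequence, with OTU counts equal to member 16S copy counts.

Not emulated: sequencing noise and chimeras, 16S paralog divergence within
a genome, amplicon primer truncation, read-depth sampling (OTU counts are
copy counts, not reads), taxonomic bias of reference availability, and
annotation error in the KO tables. Passing validation on this generator
therefore shows that the *pipeline arithmetic* — clustering, normalization,
mapping, binarization, index computation — preserves the genome-level
signal; it does not certify accuracy on real surveys, where reference
coverage of the habitat is the dominant error source.

`run_validation` replays the accuracy experiment at desk scale: it builds
the reference database from the full pool (threshold 0.99), predicts rFRI
for each community through the full 16S pipeline, computes the oracle
indices directly from true presence/absence on the true tree, and reports
per-community Spearman correlations over functions present in ≥ 2 sampled
genomes (communities with < 2 informative functions or degenerate ranks are
excluded and logged). The validation harness hands the database the *true*
tree pruned to centroid genomes (pruning preserves patristic distances)
rather than a re-inferred one, because tree inference is not the component
under test; `build_reference_database` itself defaults to neighbour-joining
on `1 − identity` distances with midpoint rooting when no tree is supplied.
The acceptance script runs 50 communities of 30 genomes from a 200-genome
pool — sizes chosen to exercise clustering collisions while keeping the run
around a minute.

## Numerical and design choices

- Threshold comparisons in clustering and hit filtering subtract 1e-9
  before comparing, so sequences at exactly the threshold identity join.
- Tie-breaks are total and documented: clustering order (length, then id),
  hit selection (identity, reference length, reference id).
- Neighbour-joining can emit slightly negative branch lengths; these are
  clamped to 0 after midpoint rooting.
- TSV outputs serialize numbers with 6 significant digits and are written
  atomically (temp file + rename); reruns with the same seed are
  byte-identical.
- All simulator randomness derives from one integer seed via spawned
  `numpy` seed sequences (separate streams for tree, sequences, gene
  content, counts, copy numbers); community draws mix the seed with the
  community index, so any community can be regenerated independently.
- Merged two-tier databases prefix user reference ids with `user:`. For
  redundancy indices the two tiers must share one tree, so the merged
  handle is flattened and a neighbour-joining tree is rebuilt over the
  union of reference sequences.
- The per-sample FTU denominator is the set of OTUs with nonzero count in
  that sample; a dataset-level FTU over all OTUs is logged alongside, since
  both conventions are in use.

## Known limitations

- The greedy clustering scans centroids linearly; fine for thousands of
  sequences, not for millions (no k-mer prefilter).
- Nearest-neighbour search is exhaustive over references — exact, but
  quadratic in database size.
- Pathway summaries count a KO once per containing pathway; the pathway
  table is interpretable as coverage-weighted pathway mass, not a
  probability distribution.
- aFRI from a merged database is normalized by the rebuilt combined tree,
  whose branch lengths are identity-derived, not time-calibrated; aFRI
  values are therefore comparable across surveys only when computed against
  the same reference tree.
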