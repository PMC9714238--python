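# Methods

`ystrkit` analyzes Y-chromosomal short tandem repeat (Y-STR) haplotype
data of the kind produced by forensic typing kits: male samples from one
or more populations, each typed at the 17 Yfiler allele slots (16 named
loci, with the duplicated locus DYS385 contributing an unordered allele
pair). Because the non-recombining Y is inherited as a single block,
every analysis here treats the multi-locus profile as one haplotype.

## Data model and panels

Alleles are repeat counts in [5, 60]; microvariants (partial repeats
such as 17.2) are legal with fractional parts .1/.2/.3 and are kept as
exact decimal values throughout — they are never rounded to integers,
and they compare equal only to themselves. Missing calls are explicit
nulls, never zero. DYS385's two peaks are stored as an ascending pair
(a single peak becomes a duplicated pair), so "14, 17" and "17, 14"
load to the same haplotype. DYS389II physically contains the DYS389I
stretch; the model enforces DYS389II >= DYS389I at construction.

Four built-in nested panels implement the standard resolution ladder:

* **MH-9** (minimal haplotype): DYS19, DYS385a/b, DYS389I, DYS389II,
  DYS390, DYS391, DYS392, DYS393 — 9 allele slots;
* **SWGDAM-11** = MH-9 + DYS438, DYS439;
* **PPY-12** = SWGDAM-11 + DYS437;
* **Yfiler-17** = PPY-12 + DYS448, DYS456, DYS458, DYS635, Y_GATA_H4.

Restricting a sample to a smaller panel is a pure projection: sample
size is unchanged and distinct haplotypes can only merge, which is the
monotonicity the resolution comparison relies on.

An individual with any null call in the active panel is excluded from
haplotype-level statistics for that panel but still contributes to
locus-level statistics at the loci where it was called. This matches
direct-counting semantics (a partial profile has no haplotype frequency
but its called alleles are real observations).

## Forensic statistics

All frequencies are direct counts: p = count / n over called
individuals. For DYS385 the counting unit is the unordered allele pair
("combination"), so each male contributes one observation per locus.
From haplotype frequencies p_h in a sample of n males:

* random match probability RMP = sum p_h^2;
* haplotype diversity HD = n/(n-1) * (1 - RMP) (Nei's unbiased form);
* TH = number of distinct haplotypes, UH = singletons;
* discrimination capacity DC = TH/n; unique fraction %UH = UH/n.

Gene diversity GD applies the same n/(n-1) * (1 - sum p^2) form to
allele frequencies at one locus. Note the "1 -" term: the estimator is
the complement of the homozygosity sum, bias-corrected by n/(n-1) —
published tables of these quantities are consistent with this form even
where a formula is typeset without the complement. Polymorphic
information content uses the Botstein form
PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2, and discrimination power
the haploid DP = 1 - sum p^2; PIC <= DP always. DC and %UH are divided
by n (not by TH), the convention that makes published worked rows
(102/122 = 0.836, 90/122 = 73.77%) come out.

"Overall" gene diversity — a mean of per-locus GDs — depends on whether
the DYS385 combination key is averaged in; both variants are exposed
(`overall_gene_diversity(include_dys385=...)`) and neither is asserted
against external values, since the averaging scheme is a convention.

## AMOVA distances (Rst / Fst)

Population differentiation uses two-level analysis of molecular
variance on the matrix of squared inter-individual distances d_ij.
With groups g of sizes n_g, N total:

    SSD_total  = (1/N) sum_{i<j} d_ij
    SSD_within = sum_g (1/n_g) sum_{i<j in g} d_ij
    sigma2_w   = SSD_within / (N - k)
    n0         = (N - sum n_g^2 / N) / (k - 1)
    sigma2_a   = (SSD_among/(k-1) - sigma2_w) / n0
    Phi_st     = sigma2_a / (sigma2_a + sigma2_w)

Two haplotype metrics make this Rst or Fst:

* **repeat_ssd (Rst)**: sum over single-copy loci of squared
  repeat-count differences. By default DYS389II enters as the
  difference DYS389II - DYS389I so the two DYS389 slots are independent
  repeat stretches (a mutation in the I stretch would otherwise count
  twice), and DYS385 is excluded because its two alleles have no
  canonical pairing; when explicitly included it contributes the
  minimum squared-difference sum over the two pairings. Both choices
  are configurable on the metric object.
* **identity (Fst)**: 0/1 distance on whole haplotypes (DYS385
  included). With 0/1 distances the pair sums reduce algebraically to
  haplotype counts, which the tests exploit as an independent check.

Slightly negative Phi estimates are legitimate sampling outcomes and
are reported as computed; clipping to zero happens only where a
downstream consumer needs a metric input (MDS, NJ), with a logged
count. Significance comes from permuting individuals across the two
samples with sizes fixed, p = (#{Phi_perm >= Phi_obs} + 1)/(n_perm + 1);
the +1 convention avoids zero p-values and keeps the test valid.

## Ordination and trees

**Classical (Torgerson) MDS**: square the distances, double-center
(B = -1/2 J D^2 J), eigendecompose, embed on the top eigenpairs with
positive eigenvalues. Requested dimensions beyond the positive rank are
padded with zero axes and a warning. Axes are sign-canonicalized (first
nonzero loading positive) so output is bit-reproducible. The `strain`
diagnostic is the fraction of total absolute eigenvalue mass not
captured by the embedding. This deterministic spectral method replaces
the iterative stress-majorization MDS of desktop statistics packages;
for four-to-dozens of populations the visual cluster structure is the
same, but coordinate-level agreement with any particular package is not
claimed.

**Neighbor joining**: Saitou-Nei agglomeration with the standard
Q-criterion. Ties in Q are broken by the lexicographically smallest
label pair and internal nodes are numbered in creation order, making
the output deterministic. Negative branch-length estimates are clipped
to zero with the excess transferred to the sibling edge, so path
lengths through the join are preserved where possible. On additive
matrices the method is exact (topology and branch lengths), which is
the main correctness property the tests assert. Newick serialization
sorts children by smallest descendant leaf, so equal trees give equal
strings.

## Median-joining network

Networks are built over 14-locus integer repeat vectors: the
single-copy loci with DYS389II replaced by DYS389II - DYS389I and
DYS385 excluded. Identical vectors condense to one node carrying a
multiplicity and per-population composition. Construction:

1. **Relaxed minimum spanning network.** A pair (u, v) is linked iff
   d(u, v) <= bottleneck(u, v) + epsilon, where the bottleneck is the
   minimax-path distance (the largest edge on the minimum-spanning-tree
   path between u and v). At epsilon = 0 this is exactly the union of
   all minimum spanning trees; large epsilon tends to the complete
   graph. Default epsilon = 0.
2. **Median augmentation.** For candidate triples (u, v, w) that form a
   two-edge path in the current network, the coordinate-wise median
   vector is computed; it is added as an inferred multiplicity-0 node
   when it is new and the Steiner star through it is cheaper than the
   triple's own spanning edges. The network is rebuilt and the step
   iterates to a fixed point (cap: 50 rounds, then an error reporting
   the current state). Restricting candidates to connected two-edge
   paths rather than all same-component triples keeps each round
   near-linear in the edge count — at cohort scale (hundreds of
   condensed nodes) the all-triples variant is cubic and intractable —
   and is the candidate rule commonly used for ordered-state STR data.
3. **Pruning.** Inferred nodes that end as dead ends (degree <= 1) are
   removed iteratively.

Edge lengths default to the sum of absolute repeat differences — the
number of single-step mutations separating two haplotypes — with a
squared variant available. Per-locus step labels annotate every edge.
Microvariant coordinates participate as exact states: a median
coordinate is the true median only when all three values are integers,
otherwise the majority value, and a three-way tie vetoes the candidate.
Locus weights are uniform; a weight map can be supplied.

## Synthetic cohorts

The simulator emulates the structure of a real multi-population Yfiler
study so every pipeline stage is testable without external data:

* a handful of **founder lineages** (default 6) stand in for the
  haplogroup backbone; founders differ from a modal ancestral profile
  by signed Poisson(0.9) repeat steps per slot;
* each sampled male descends from a founder through an **independent
  line** of g generations (star-genealogy approximation — no shared
  internal coalescences within a lineage);
* per generation each of 17 slots mutates with probability mu_l,
  stepping +-1 repeat (symmetric single-step model, no multi-step
  mutations); so a line's offset has mean 0 and variance mu_l * g,
  the closed-form oracle used for calibration tests;
* default per-slot rates span 5e-4 to 8.2e-3 per generation — inside
  the range reported for Y-STR loci (about 4e-4 to 7e-2), slow for
  DYS392/DYS438, fast for DYS458 — and are validated against
  [1e-5, 1e-1];
* DYS385 is simulated as two independent slots then canonicalized;
  DYS389II is DYS389I plus an independently mutating second stretch, so
  the ordering constraint holds by construction; repeat counts reflect
  at the validity bounds [5, 60];
* `simulate_divergent_pair` lets shared founders drift independently in
  each daughter population for t_split generations before sampling, so
  expected Rst grows with t_split and is centered at zero for
  t_split = 0.

The study-like dataset uses sample sizes 128/122/108/135 (four
populations, 493 males — the shape of the real cohorts this package
targets), Dirichlet(1) founder-mixing weights per population, 40
generations of population-private founder drift and genealogy depth 60,
which lands every population's 17-locus haplotype diversity in
[0.98, 1.0]; the depth check runs at generation time and the cohort is
redrawn with 1.5x depth on the rare miss.

What the generator deliberately does **not** reproduce: coalescent
genealogy within lineages (haplotype frequency spectra are more even
than real data, so DC runs high), linkage between DYS385's two slots,
multi-step or locus-length-dependent mutation, population growth, or
realistic haplogroup founder profiles. Tests passing on synthetic data
therefore validate the estimators and algorithms, not demographic
realism.

## Determinism and numerics

Every random path takes a single integer seed (numpy Generator);
identical seeds give byte-identical outputs, and pipeline artifacts
carry no timestamps so reruns hash identically. Frequency tables are
exact integer counts; sums of frequencies are checked to 1e-12. AMOVA
decomposition consistency (SSD_total = within + among) is asserted to
1e-9 relative. The MDS eigenvalue cutoff for "positive" is
1e-9 relative to the leading eigenvalue. Degenerate inputs: two-taxon
NJ returns the single split edge; one-node networks are legal; an
all-zero distance matrix embeds at the origin.

## Problem sizes

The analysis scripts and acceptance run use the full 493-male synthetic
cohort for statistics, distances, ordination, tree and network (the
network stage dominates at a few seconds). Property tests use 2-13
individuals per group for the AMOVA oracle, 4-8 leaves for tree
recovery, 6-7 points for MDS recovery, 200 replicates for permutation
calibration, and 500 replicate lines for mutation-variance calibration
— sizes at which the independent oracles are exact or their sampling
error is well characterized.
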