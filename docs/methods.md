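# Methods

This note documents the models and procedures otukit implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter when results
are compared across machines or runs.

## Pipeline semantics

**Chunk/merge.** `split_sequences` partitions a record stream into
consecutive chunks (default 20 000 records, the size that balances
per-job overhead against queue throughput on a typical cluster); records
are never reordered or split. `merge_otu_results` concatenates per-chunk
OTU maps per OTU in input order and rejects any sequence ID seen twice —
a read picked in two chunks indicates an upstream bookkeeping error, not
something to repair silently. Because reference-based picking treats each
read independently, split → pick-per-chunk → merge is exactly equivalent
to picking the unsplit input; the test suite asserts this for chunk sizes
1, 7 and 20 000 with a deterministic mock picker.

**Two-primer averaging.** Sequencing the same samples with two
hypervariable-region primer sets reduces single-primer taxon bias, but an
OTU captured by both primers is effectively counted twice. For such an OTU
with member lists of length n_A and n_B, the averaged map keeps
⌈(n_A + n_B)/2⌉ sequence IDs, drawn by alternating between the two lists
(A first) and truncating. Two consequences of this rule are deliberate:
the ceiling means an OTU shared as a singleton by both primers survives
(floor would annihilate it), and the interleave makes the retained member
list — hence every downstream per-sample count — a deterministic function
of the inputs. Averaging a map with itself leaves per-OTU counts unchanged
(⌈2n/2⌉ = n). The retained-member selection is the one genuinely open
design point in this operation; any rule that kept the right *count* would
give the same table totals, and determinism decided the tie.

**Taxonomy assignment and condensing.** OTU IDs produced by
reference-based picking are database IDs, so assignment is a dictionary
lookup; IDs without a database entry get the `Unassigned` sentinel and are
reported, never dropped. Condensing groups OTUs by their *full* 7-rank
taxonomy string, elects the lexicographically smallest member OTU ID as
representative (any member is equally valid biologically; lexicographic
choice makes reruns identical), and concatenates member sequence lists in
ascending-ID order. The number of condensed OTUs always equals the number
of distinct lineages among the input OTUs, and the sequence-ID multiset is
conserved — per-sample column sums of the OTU table are therefore
invariant under condensing.

**Transient filtering.** OTUs are aggregated at a taxonomic rank (genus by
default — fine enough to keep ecologically distinct groups apart, coarse
enough that database over-splitting does not defeat the prevalence count).
Pass 1 removes aggregates present in strictly fewer than 5 % of samples;
pass 2 removes surviving aggregates holding strictly less than 0.01 % of
the table's grand total. Both inequalities are strict: an aggregate at
exactly the threshold stays. The abundance denominator is the *original*
grand total by default (the filter asks "is this organism a meaningful
part of the overall sequence data?"), with `abundance_denominator=
"survivors"` exposed for the alternative reading. Removed aggregates are
reported with their percent abundance and member OTU IDs; member sequence
IDs are included when the caller supplies the OTU map (the table alone
does not carry them).

**Table construction.** Sequence IDs encode their originating sample as
the prefix before the last underscore (`S1_000123` → `S1`), tolerating
underscores inside sample IDs. Unknown or undecodable samples are an
error listing the offending IDs — silently dropping reads would break
every conservation property above.

## Alpha diversity

* **Shannon** H = −Σ_{pᵢ>0} pᵢ ln pᵢ, natural log by default with a
  `base` option (log₂ is a common alternative convention in ecology
  software). Input vectors are renormalized, so raw counts are accepted.
* **Equitability** H / ln S with S the number of nonzero taxa; defined as
  0 when S = 1 (the denominator vanishes and a one-species community has
  no evenness to measure).
* **ACE** with rare threshold 10 (the EstimateS convention): species with
  count ≤ 10 are "rare", coverage C_ACE = 1 − F₁/N_rare, and

      S_ACE = S_abund + S_rare/C_ACE + (F₁/C_ACE)·γ²,
      γ² = max[(S_rare/C_ACE)·Σk(k−1)F_k / (N_rare(N_rare−1)) − 1, 0].

  With no rare species the estimate is S_obs. When every rare species is a
  singleton C_ACE = 0 and the estimator is undefined; the bias-corrected
  Chao1 estimate S_obs + F₁(F₁−1)/(2(F₂+1)) is returned instead and
  flagged in the components so callers can tell the regimes apart.
* **KDE curves** use a Gaussian kernel with Scott bandwidth
  h = σ̂ n^(−1/5), evaluated on 256 points over [min − 3h, max + 3h] so the
  trapezoid integral is ≈ 1 (the tails beyond 3h carry < 0.3 % of mass).
  Constant input has σ̂ = 0 and no meaningful density; the error message
  suggests an explicit bandwidth.
* **Group comparisons** test every unordered pair by two-sided Wilcoxon
  rank-sum: the exact null distribution when both groups have n ≤ 20 and
  the pooled values are tie-free, otherwise the normal approximation with
  tie and continuity corrections. p-values are Benjamini–Hochberg adjusted
  across all pairs (q-values are monotone and ≥ p by construction) and
  flagged at FDR < 0.1 by default.

## Ordination

**PCoA.** Gower centering B = −½ J D² J with J = I − 11ᵀ/n, symmetric
eigendecomposition, axes kept while λ > 10⁻¹⁰·λ_max, coordinates
vₖ√λₖ, explained fractions λₖ/Σλ⁺. Distance matrices that are not
Euclidean-embeddable (unweighted UniFrac often is not) produce negative
eigenvalues; these axes are dropped and their summed magnitude is reported
on the result rather than corrected (Cailliez/Lingoes corrections change
all distances and are better applied deliberately upstream). For a matrix
built from points in R^k the embedding reproduces every pairwise distance
to 10⁻⁸ and yields exactly k positive axes — the test suite checks this
against scikit-bio's independent implementation as well.

**LDA.** Fisher discriminants maximizing between- over within-class
scatter. Compositional OTU tables make S_w rank-deficient twice over
(features can outnumber samples, and proportions sum to 1), so S_w is
regularized as S_w + ε·(tr S_w/p)·I with ε = 10⁻⁴ — small enough not to
perturb well-conditioned problems, large enough to make the generalized
eigenproblem definite. Input must be per-sample proportions; raw counts
are rejected with a pointer to `relative_abundance`. At most
(groups − 1) axes exist. The accompanying effect size
(`group_separation`, |Δmean|/pooled SD on one axis) is a training-set
statistic: it is only meaningful when the within-class scatter has full
rank, i.e. fewer taxa than samples — with p ≥ n a discriminant can
separate arbitrary labelings perfectly. The LDA benchmark community is
sized accordingly (below).

**Axis signs.** Eigenvectors are sign-ambiguous; every axis is flipped so
its largest-magnitude entry is positive, making plots and TSVs identical
run-to-run and machine-to-machine.

**Bubble plots.** Marker area scales linearly with the OTU's relative
abundance, normalized to the most abundant sample (= `max_size`); samples
where the OTU is absent get a small fixed marker so they remain visible.

## iTol export

Leaf display names are "Genus species" when both ranks are named,
otherwise the deepest named rank with its prefix (`f__Lachnospiraceae`),
`Unassigned` for empty lineages; characters outside `[A-Za-z0-9_.-]`
become underscores and duplicates get `_2`, `_3`, … suffixes in leaf
order. Relabeling operates on an independent copy; topology and branch
lengths are untouched and the old→new mapping is returned so data tracks
can follow.

Three track modes: `log10_raw` = log₁₀(1 + total count) — the +1 keeps
zero-count OTUs representable in subset tables; `mra` = mean over samples
of per-sample relative abundance; `nmra` = per-group MRA normalized across
groups per OTU, so each OTU's row sums to 1 and the multi-bar ring shows
*which group* holds each organism. (The alternative reading — normalizing
within a group across OTUs — answers a different question and can be had
by transposing the normalization on the returned per-group MRA values.)
The optional arcsine-square-root stabilization asin(√p) is applied to each
per-sample proportion *before* averaging; the mean of transforms is not
the transform of the mean, and applying it after would undo the variance
stabilization that motivates it. Single-column tracks are written as iTol
`DATASET_SIMPLEBAR`, multi-column NMRA as `DATASET_MULTIBAR`; the writer's
output self-parses back to identical values.

## Synthetic communities

`make_community` draws, per sample, a composition from
Dirichlet(base ⊙ group-effect) and read counts from a multinomial at fixed
depth — the standard overdispersed model for amplicon counts. Each true
species is emitted under `redundancy` distinct reference IDs sharing one
taxonomy string (spreading the species' reads uniformly over them), which
is exactly the database redundancy the condensing workflow exists to
remove; condensing a generated dataset must recover the true species
count. Defaults: 50 species, Dirichlet concentration 0.5 (long-tailed,
few dominant taxa), 20 samples per group, 5 000 reads per sample,
redundancy 3. The reference tree is a random sequential coalescent with
exponential waiting times over the reference IDs — only leaf-label
consistency matters downstream. All outputs are byte-reproducible from the
seed.

`lda_benchmark_spec` is the fixed operating point for supervised-ordination
checks: 8 species, concentration 3.0, 20 samples per group, 5 000 reads,
five species enriched 8-fold in the Treatment group. Eight taxa versus 40
samples keeps the within-class scatter full-rank (see the LDA rank caveat
above), so the recovered separation exceeds 3 pooled SDs while the median
separation over 20 random label permutations stays below 1.

What the generator does **not** emulate: chimeras and sequencing error,
length/GC primer bias within a primer set, realistic sequence content
(reference FASTA records are random nucleotides), sample-to-sample depth
variation, and phylogenetic signal in abundances (the tree is independent
of the compositions). Tests passing on these fixtures therefore certify
the bookkeeping, conservation and statistical algebra of the toolkit —
not the upstream read-processing steps, which belong to the picking
pipeline this package deliberately sits downstream of.

## Numerical conventions and degenerate inputs

* Distance-matrix asymmetry up to 10⁻⁹ (floating-point artifacts in
  upstream UniFrac output) is averaged away; beyond that it is an error.
  Diagonals are forced to zero.
* All-zero samples carry no compositional information: left at zero by
  `relative_abundance` with a warning, never renormalized into NaNs.
* Empty OTU-map entries, duplicate identifiers anywhere, and records that
  would be silently dropped are all hard errors — every parser either
  preserves record counts or raises.
* Problem sizes in the test and acceptance runs (10–50 species, 10–40
  samples, 10³–5·10³ reads per sample) are chosen so every conservation
  and recovery property is exercised end-to-end in seconds; all the
  properties asserted are size-invariant, and the generator scales to
  larger communities unchanged.

## Known limitations

* BIOM support is the 1.0 JSON dialect only (the generation the rest of
  the format ecosystem here targets); HDF5 BIOM 2.x files must be
  converted upstream.
* UniFrac and other phylogenetic beta-diversity distances are consumed as
  precomputed matrices, never computed.
* The Wilcoxon exact path is limited to tie-free groups of ≤ 20; with
  ties the normal approximation is used regardless of size.
* LDA's separation statistic is in-sample; it is a descriptive effect
  size, not a cross-validated classification accuracy.
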