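# Methods

## Repertoire model and statistics

A repertoire is a multiset of clonotypes with template counts. Clonotype
identity is configurable (`nt`, `aa`, `aa+v`); the default is the CDR3
nucleotide sequence, the sequencing platform's native rearrangement-level
unit. All statistics operate on the aggregated table (counts summed per
key). Records with an empty key field (unresolved CDR3) are kept as
distinct singleton clonotypes during aggregation so that count-based
statistics keep their read mass; amino-acid-level analyses skip records
without a usable CDR3 amino-acid string.

**Diversity.** Shannon entropy `H = −Σ p_i ln p_i` over clonotype
frequencies, computed in nats (the natural-log base is an internal
convention recorded in output headers; the normalized index is
base-invariant because the base cancels in `H / log k`). The normalized
index is defined as 0 for `k = 1`: a monoclonal repertoire has minimal
diversity and `H = 0`, so the 0/0 case is resolved downward. Frequencies
are computed over productive records by default, matching the ingest
filter; the filter is configurable.

**Clonal expansion.** A clone is "expanding" when its read frequency is
strictly greater than the threshold (default 0.001, i.e. 0.1 % of total
reads — "more than" means the boundary clone is excluded). The statistic
is the summed frequency of expanding clones. The threshold denominator is
whatever count population was ingested (productive-only by default); both
conventions are computable by toggling the ingest filter.

**Overlap.** Pure set algebra on clonotype keys: each clonotype in the
union is assigned to exactly one exclusive Venn region by its
presence/absence pattern, so regions are disjoint and sum to the union
size regardless of abundances.

**Vβ usage.** Usage ratio of gene `g` in a sample = unique clonotypes
carrying `g` / unique clonotypes with a resolved V call. Gene labels are
uppercased, trimmed, and stripped of allele suffixes (`*01`) before
counting. Read-weighted ratios are available behind a flag but are not
the default, because expansion would otherwise dominate the profile. PCA
is centered but unscaled (covariance PCA): the columns are ratios on a
common scale, so correlation scaling would only inflate rare-gene noise;
this also matches the common default of R's `prcomp`. The SVD sign is
fixed by making the largest-magnitude loading of each component positive,
so outputs are deterministic. A rank-0 matrix (all rows identical)
reports zero scores and zero explained-variance ratios.

## IMGT CDR3 numbering

The platform CDR3 string includes both conserved anchors, mapped to
positions 104 (C) and 118 (F/W); `anchors=False` treats the whole string
as the inner loop for anchor-free inputs. The inner loop of length `l`
splits into a left arm of `ceil(l/2)` residues numbered 105, 106, … and a
right arm of `floor(l/2)` residues numbered …, 116, 117 from the end.
Left-arm residues beyond position 111 receive insertion codes 111.1,
111.2, …; right-arm residues beyond 112 receive 112.1, 112.2, …. This
reproduces the canonical 13-slot layout exactly at `l = 13` and the IMGT
middle-gapping order (111, 112, 110, 113, …) for shorter loops.

The middle-position composition pools every residue assigned an integer
label in {108, …, 112} across all CDR3 lengths of a sample — insertion
codes are excluded because the analysis names exactly five positions —
and each unique clonotype contributes once. Pooled counting (one
frequency per amino acid from the combined residue pool) is the default;
per-position averaging (mean of the five per-position frequency vectors)
is available behind a flag. The two coincide when every CDR3 reaches all
five positions and differ only in how unevenly-occupied positions are
weighted. A sample whose CDR3s are all too short to reach 108–112 yields
an explicitly undefined composition (flagged, not silent zeros).

## Synthetic repertoire generator

The generator emulates the *shape* of a bulk immunoSEQ clonotype table,
not its biology: clone frequencies are drawn first (so ground truth is
depth-independent), then template counts by a single multinomial at the
requested depth, so depth is conserved exactly. Two clone-size models:

- `dirichlet(α)` — symmetric Dirichlet over `k` clones; α is the
  evenness dial (α ≪ 1 gives oligoclonal, α ≫ 1 near-uniform samples).
- `spike(m, f_e)` — `m` expanded clones at frequency `f_e` each, the
  remainder uniform; expected expanded read fraction is `m·f_e` when the
  background clones sit below the threshold.

Each clonotype independently receives a V gene (categorical draw), a CDR3
length (default support 9–20 total residues, bell-shaped around 14, as in
β-chain repertoires), and residues drawn position-wise: anchors fixed to
C/F, integer middle positions 108–112 drawn from the enriched
distribution, all other positions from the background (uniform over the
20 amino acids by default — a deliberate simplification; real CDR3s have
strong positional biases). Enrichment and usage shifts are *exact*
additive deltas: the target's probability becomes `base + δ` and the
remaining entries are rescaled to renormalize, so recovery tests compare
against a sharply defined truth. Nucleotide CDR3s are back-generated by
choosing a random synonymous codon per residue; there is no V(D)J
junction model, so generated sequences are not biologically realistic —
passing tests demonstrate correctness of the statistics, not realism of
the inputs.

Cohorts derive per-sample seeds from `SeedSequence([master_seed,
sample_index])`, giving independent, reproducible streams; all generator
seeds stay below 2³¹.

## Pipeline

`run_pipeline` ingests a manifest (sample_id, group, path, format),
aggregates once per sample, and computes all tables in memory before
writing anything, so a failing stage (reported with its stage and sample
name) leaves no partial output. Every report carries a comment header
with the package version, a config hash (over the analysis parameters,
not the output location), the key mode, the log base and the expansion
threshold. Reruns on identical inputs are byte-identical. Group summaries
are descriptive means and standard deviations only — inferential testing
is out of scope by design, as it belongs to general statistics packages
rather than this pipeline.

## Problem sizes and tolerances

Default test and verification scales were chosen to make sampling error
negligible relative to the effects checked: expansion recovery uses the
spike model (m = 3, f_e = 0.05) at 3000 clonotypes, depth 10⁶, averaged
over 20 seeds (tolerance ±0.01 around 0.15); enrichment recovery uses
δ = 0.08 on a 0.05 background at 20 000 unique clonotypes (≈ 68 000
middle-position observations, checked within 3 binomial standard
errors); usage-shift recovery uses Δ = 0.10 at 5000 clonotypes per
sample, 3 samples per group (3 SE ≈ 0.01); the end-to-end determinism
check runs a 2-group × 3-sample cohort at 20 000 clonotypes and depth
10⁶ per sample. Exact identities (PCA reconstruction, Shannon versus a
naive loop) are held to 10⁻⁹ and 10⁻¹².

## Known limitations

- No raw-read processing or clonotype calling; inputs are called tables.
- No fuzzy CDR3 matching, similarity networks, or generation-probability
  machinery.
- Only Shannon-based diversity; no Simpson/Chao1/Hill estimators.
- The generator's amino-acid background is position-independent apart
  from the configured middle enrichment.
- immunoSEQ column names vary across pipeline versions; non-default
  exports need a custom dialect map. Whether counts are "templates" or
  "reads" is transparent to the statistics — both are supported through
  the same column.
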