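# Methods

`dermengraft` analyses longitudinal topical-probiotic studies of the skin
microbiome: communities are profiled at two taxonomic levels — *Cutibacterium
acnes* strain types from single-locus sequence typing (SLST) and genera from
16S rRNA profiling — and the questions asked are (i) what community types
("dermatotypes") recipients carry, and (ii) how strongly, and for how long,
an applied donor solution engrafts on recipient skin.

## Profiles and diversity

Count tables (samples × taxa, integer reads) are normalised per sample to
relative abundances on a 0–100 scale (each count divided by the sample total
and multiplied by 100). Taxa absent from a sample are kept as explicit
zeros so that all pairwise computations share one aligned taxon universe.
All-zero samples are an error, never silently dropped. No abundance filter
is applied by default; an optional minimum-library-size gate
(`min_total_count`) is exposed and defaults to 0.

Shannon diversity is H = −Σ pᵢ ln pᵢ over taxa with pᵢ > 0. Natural
logarithms are the default; the base is configurable because conventions
differ between fields. Genus co-occurrence is the Pearson correlation of
two taxa's abundance vectors across samples; a taxon with zero variance
yields an explicit "undefined" flag rather than a number.

## Dermatotype calling

The procedure is the enterotype convention:

1. **Distance.** d(p, q) = √JSD(p, q) with logarithms base 2, where
   JSD(p, q) = H(m) − ½[H(p) + H(q)], m = (p+q)/2, and 0·log 0 := 0. This
   form is a metric bounded in [0, 1] (1 at disjoint supports). No
   pseudocounts are needed: mᵢ > 0 wherever either profile has mass. The
   plain (unsquare-rooted) divergence is available via `sqrt=False`.
2. **Clustering.** Partitioning around medoids (PAM) on the distance
   matrix. When the medoid search space is tiny (C(n, k) ≤ 2000 subsets)
   the optimum is found by exhaustive enumeration — at that scale exactness
   is cheaper than cleverness. Otherwise a deterministic BUILD phase
   (greedy medoid addition minimising total cost) is followed by a SWAP
   phase (best single medoid/non-medoid exchange, iterated to a local
   optimum). Every tie breaks toward the lowest sample index, so results
   are reproducible and independent of run-to-run randomness.
3. **Model selection.** The Calinski–Harabasz index,
   CH = [B/(k−1)] / [W/(n−k)], is maximised over k (default 2–10); exact
   ties go to the smaller k. CH is defined for coordinate data, so it is
   evaluated on the full positive-eigenvalue classical-MDS (PCoA) embedding
   of the distance matrix — exact for Euclidean-embeddable distances and an
   explicit, reproducible generalisation otherwise. A clustering with
   W = 0 maps to +∞, ranking above all finite values. Average silhouette
   width (singletons scored 0) is reported for every k as verification.
4. **Ordination.** PCoA by double-centring −½d²; axes with negative
   eigenvalues are dropped and their total magnitude reported; explained
   fractions are relative to the positive-eigenvalue sum.

Cluster ids are renumbered 1..k by decreasing size (ties by lowest medoid
index), since raw cluster numbering is arbitrary. Clustering identical
profiles is refused as degenerate. By default the full pipeline clusters
**pre-application samples** (days ≤ baseline), so dermatotypes describe
recipients before modulation; clustering all samples is a config switch.

## Engraftment

Engraftment of a sample against its applied solution is the Pearson
correlation r between the two abundance vectors over the union of their
taxa (absent taxa zero-filled). Higher r = stronger engraftment; the
distance form is 1 − r. The score is symmetric and invariant to rescaling
either profile; either vector being constant yields an undefined score that
is excluded from tests with a logged count. Note that r over a zero-filled
union depends on the declared taxon universe (a taxon zero in both profiles
still shifts the means); what is guaranteed is that a zero-abundance taxon
contributes identically whichever side declares it.

Defined strain mixes (PA solutions) are scored on SLST profiles and
complete-microbiome preparations (CM solutions) on genus profiles — each
solution's native level. Control (untreated) areas are scored against every
solution by default, providing an untreated contrast arm per solution.

**Significance.** Within each arm (solution × dose, and each control
contrast), scores at each post-application day are compared with the
pre-application baseline day (default day 1, the measurement taken before
the first application; configurable) using a two-sided unpaired
Wilcoxon–Mann–Whitney rank-sum test: exact null distribution when both
groups have < 25 untied observations, normal approximation with tie and
continuity corrections otherwise. Benjamini–Hochberg step-up adjustment is
applied across the whole (arm × day) family jointly by default (per-arm
adjustment is a config option). Comparisons with fewer than 3 observations
on either side are reported as NA with a reason, never silently dropped.

**Contrasts.** Arm-level comparisons (by solution, dose, or dermatotype)
use Tukey's HSD on subject-area mean post-application scores — one
observation per subject-area, so repeated days do not pseudo-replicate.
Groups with fewer than 2 subjects are excluded with a warning.
The diversity association correlates each subject's baseline Shannon
diversity with their mean post-application engraftment (Pearson, with the
usual t-test of zero correlation; ≥ 4 subjects required).

## Synthetic study generator

The generator reproduces the design the analysis assumes, so every stage is
testable end-to-end without external data: 18 subjects × 8 skin areas (area
4 an untreated control), five solutions (PA: H1; H1+A1 with a 90/10 split;
H1+D1+A1 at 45/45/10 — and CM: two complete-microbiome donors) × three
doses (10⁴/10⁶/10⁸ CFU/mL) rotated across the 126 treated subject-areas
(8–9 subject-areas per arm), applications on days 1–3 after sampling,
sampling at days 0, 1, 2, 3, 4, 5, 8, 10, 12, 17, 24, 38, 52, and ~10,000
reads per sample.

*Communities.* Each subject draws one SLST baseline from a Dirichlet around
one of five archetypes (driven by L1; D1; C3+A5; D1+H1; A1) and one genus
baseline around one of three archetypes (Cutibacterium-dominated;
Cutibacterium+Corynebacterium; Leifsonia-enriched), with concentration 50
(distinct but touching clusters). Each sampling day additionally jitters
the subject baseline with a Dirichlet of concentration 400 (~2–3 percentage
points day-to-day s.d. for mid-range taxa): repeat strip samples of the
same site are similar but not identical, so day-level oscillations exist
but stay small relative to the dose response. Days are conditionally
independent given the kinetics (no autocorrelation is modelled).

*Kinetics.* The sampled community is (1−λ)·baseline + λ·solution. Each
application moves λ a fraction g = 0.8 of the remaining way to the dose
ceiling λ_max ∈ {0.2, 0.5, 0.8} for doses {10⁴, 10⁶, 10⁸}; after the last
application λ decays with a 4-day half-life. The gain and ceilings are
free parameters chosen so that the second application day already shows a
clear effect and donor dominance lasts about a week after application —
the qualitative pattern the analysis is designed to detect. Recipients of
the D1+H1 archetype carry a susceptibility multiplier (1.3, λ capped at 1),
modelling communities that accept donor strains more readily; it can be
switched off for null simulations, and `EngraftmentKinetics.null()` gives
λ ≡ 0 for calibration runs. Sequencing is a multinomial draw per sample
and level. Identical seeds give identical output, and the ground truth
(archetype per subject, λ per sample) is returned for recovery tests.

*CM donor compositions.* Complete-microbiome preparations are
culture-expanded, which enriches fast-growing staphylococci relative to the
skin baseline; the two defaults are therefore Staphylococcus-rich, with
donor 2 carrying a 1.8-fold greater Cutibacterium/Staphylococcus ratio
than donor 1. This also keeps donors distinguishable from recipient
baselines, so pre-application engraftment starts low — without it, a donor
that resembles the recipients has nothing measurable to engraft.

*Reads.* For the SLST typing stage, amplicon reads are simulated from a
**synthetic** allele database (400 nt; alleles share a backbone and differ
in disjoint 20-position blocks, so every pair is exactly 40 substitutions
apart — these are not real SLST alleles). Reads are full-length allele
copies drawn multinomially, with iid substitution errors and a constant
Phred score matching the error rate.

What passing tests show — and do not show — about real data: the generator
emulates the design, compositional structure and dose-response kinetics,
but not PCR/chimera artefacts, contamination, subject dropout, true
temporal autocorrelation, or open-universe taxa. Recovery results
establish that the pipeline measures what it claims under the stated noise
model, not that real studies will reach the same effect sizes.

## SLST read typing

Because an SLST database holds tens of short alleles, reads are typed by an
exhaustive best-Hamming-match scan rather than a heuristic mapper: the
shorter sequence slides ungapped along the longer, the overlap is the full
shorter length, N/ambiguity positions count as mismatches, and the read is
assigned to the allele with the uniquely smallest distance at its best
offset if that distance ≤ `max_mismatch` (default 3). Equidistant ties are
reported `ambiguous` and excluded from counts (conservative and
reproducible); no allele in range gives `unassigned`; reads shorter than
`min_overlap` (default 50 nt) are not typed. Upstream, reads failing mean
Phred ≥ 20 or N-fraction ≤ 0.10 (both configurable; thresholds are this
package's policy) are dropped as `low_quality`. Reverse-complement search
is off by default (amplicons are orientation-fixed by primer design) and
available via `both_strands`. Every read lands in exactly one outcome
bucket; this conservation is asserted at run time. At a 0.5% per-base
error rate about 14% of 400-nt reads exceed 3 mismatches and are
unassigned; the loss is allele-unbiased, so recovered proportions remain
accurate.

## Numerical and interface choices

- Distances are clipped to [0, 1] and symmetrised against float round-off;
  PCoA eigenvalues below 10⁻¹⁰ of the largest are treated as zero.
- The exact Mann–Whitney distribution is built by the standard count
  recurrence in float64, exact for group sizes ≤ 25.
- All tabular I/O is UTF-8 TSV with `NA` for missing values and optional
  `#` provenance headers (tool version, config hash, seed); abundances are
  written with 6 decimals. Solutions are long-format
  `solution_id, level, taxon_id, abundance` — a solution may carry
  compositions at both levels, and dose is a property of the treated
  subject-area (metadata), not of the composition.
- The pipeline writes a `manifest.json` whose config hash excludes the
  output path, so re-running into a different directory is byte-identical.
- The CLI exits 0 on clean runs and 3 when significance tests were skipped
  for insufficient observations.

## Problem sizes used in validation

Recovery and calibration properties are established over 100 simulated
studies per property in the test suite (dermatotype recovery additionally
uses 150 SLST / 90 genus samples per replicate), and the acceptance script
recomputes the same quantities over 50 replicates per property, 200 random
instances for the PAM/brute-force and reference-implementation
comparisons, and 1000 random triples for the metric axioms.

## Known limitations

- CH-index selection can resolve finer-than-archetype structure when
  within-subject variation is very small relative to between-subject
  variation (many near-replicate samples per subject act as tight blobs);
  with the default generator settings this occurs in a minority of seeds
  when clustering full studies, and not in the archetype-sampler
  validation.
- The per-arm score-vs-λ Spearman is diluted by late sampling days where λ
  is numerically ordered but practically zero; typical min-arm values are
  0.79–0.94, weakest for the lowest-dose CM arm (λ ≤ 0.2).
- Engraftment for PA solutions compares against compositions supported on
  few strain types; Pearson on short vectors is coarse, which is inherent
  to the correlation definition of the score.
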