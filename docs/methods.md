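# Methods

This note documents the statistical procedures implemented in
`allerprofile`, the synthetic-data model behind its tests, the numerical
conventions, and the design choices made where the underlying methodology
left them open.

## Band-profile similarity and clustering

A band profile is a binary vector over a shared set of annotated bands.
Band identity across species is established at annotation time via a
common `band_label`; the package deliberately does **not** match bands by
molecular-weight windows, because cross-lane band matching is a curation
decision, not an arithmetic one. The similarity index between two species
is `SI = 2Z/(X+Y) × 100` with `Z` the bands present in both and `X`, `Y`
their band counts — the Dice coefficient on a percent scale. It is
undefined when both profiles are empty (`X+Y = 0`); this raises an
explicit error rather than returning a conventional value. The
alternative metric is the Pearson product-moment correlation of the two
binary vectors (equivalently the phi coefficient), computed without
continuity correction; it is undefined for a constant profile and the
offending species is named in the error.

Clustering is agglomerative on the distance `100 − SI` (or `1 − r`), with
UPGMA (average linkage) as the default because it produces ultrametric
trees whose node heights are merge distances — the customary display for
band-profile dendrograms; single and complete linkage are available by
flag. The agglomeration is implemented directly rather than through
`scipy.cluster.hierarchy` for one reason: determinism under ties. Among
equally close cluster pairs, the pair with the lexicographically smallest
cluster keys (a cluster is keyed by its smallest leaf label) is merged.
scipy's average linkage is used in the test suite as an independent
oracle on tie-free random matrices (cophenetic matrices must agree
exactly). Newick export writes branch lengths as height differences, so
the cophenetic distance between two leaves is the height of their lowest
common ancestor.

Percent similarities are rounded to one decimal in all tabular output;
full precision is kept in memory and in JSON reports.

## Consensus and conservation scoring

The consensus of an alignment column is its most frequent symbol (gap
included as a symbol) provided that symbol is the *unique* maximum and
its count reaches the threshold; otherwise the column is ambiguous
(`X`). The default threshold is a strict majority, ⌊n/2⌋+1 — 4 of 6 for a
six-species alignment. Tie columns are always ambiguous, which makes the
consensus deterministic.

Similarity of a sequence to the consensus classifies each column as:

* **excluded** — consensus ambiguous, or both symbols are gaps;
* **identical** — equal symbols;
* **similar** — differing residues with BLOSUM62 score ≥ `similar_cutoff`
  (default 1);
* **dissimilar** — everything else, *including residue-vs-gap columns*.

The percent is `(identical + similar)/(length − excluded) × 100`. Two
conventions here were genuinely open. First, "scored above one" is
ambiguous between `> 1` and `≥ 1`; the cutoff is therefore a parameter
with default 1 (`≥ 1`), and raising it can only lower scores (a tested
monotonicity invariant). Second, gap handling: counting residue-vs-gap as
dissimilar (rather than excluding it) keeps self-similarity at 100 while
not rewarding shared deletions; gap-gap columns carry no information and
are excluded. A fully ambiguous consensus (possible for a short epitope
with a 3/3 split) gives an undefined percent, reported as NaN and
flagged, never silently dropped.

BLOSUM62 comes from biopython's `substitution_matrices`; any NCBI-format
matrix file can be substituted. Whether a species should be held out of
the consensus it is scored against is unstated in standard practice;
the default scores each row against the all-rows consensus.

Epitopes are 1-based inclusive intervals on the *ungapped* reference
sequence, with the peptide string stored redundantly and validated
against the reference — a mismatch is an input error, caught before any
scoring. Mapping walks the gapped reference row, counting residues only,
and returns the spanned alignment columns for every row.

## Serology

The positivity cutoff is `multiplier × mean(negative ODs)` with
multiplier 3. Positivity is **strictly above** the cutoff: a serum at
exactly the cutoff is negative (the conservative reading of a dotted-line
rule). Replicates are averaged before thresholding, with the standard
deviation carried to output. Sensitization rates are
`round(100·k/n, 1)` with counts always reported alongside, because a
rounded percent alone does not identify `k`.

Percent inhibition is `100 × (S_no − S_inh)/S_no` for both ELISA ODs and
immunoblot band intensities (the difference-ratio form; the same formula
serves both assays). Negative values — signal enhancement — are reported
and flagged, not clamped. A dilution series is *dose-dependent* when its
percent-inhibition vector never falls more than 2 percentage points below
its running maximum as concentration increases; the running-max form
penalises slow drifts that consecutive-difference checks miss. With
realistic multiplicative well noise (CV ≈ 5%) this binary flag is itself
noisy for series whose early points sit near zero inhibition — a
limitation of any fixed-tolerance monotonicity rule, worth remembering
when interpreting it on single series. No sigmoid fitting is performed:
the summary statistic is the maximum of the observed percent-inhibition
vector and its concentration, which is upward-biased by noise by a few
points when the plateau is low (see the generator discussion below).

## Expression

`quant.sf` files (columns Name, Length, EffectiveLength, TPM, NumReads)
are merged by transcript; transcripts absent from a sample get TPM 0 with
a warning. Allergen-level TPM is the **sum** of member-isoform TPMs — the
natural choice when isoforms of tropomyosin-like genes are abundant and
the quantity of interest is total gene output. The mapping is
species-aware: an allergen with no mapped transcript for a sample's
species is *missing* (NaN), not zero, because absence of annotation is
not absence of expression.

Heatmap values are `log2(TPM + 1)`. The pseudocount 1 sends TPM 0 to 0
and keeps the display range at 0–20 (a transcript absorbing an entire
sample's million TPM gives log2(1e6) ≈ 19.9). Per-column z-scoring is
available behind a flag but off by default, since unstandardized log2 TPM
is what the 0–20 cell values of such heatmaps correspond to. Group
comparisons use one-way ANOVA followed by Tukey's HSD
(`scipy.stats.f_oneway` / `scipy.stats.tukey_hsd`); samples from mixed
tissue are labelled and excluded from cross-species comparisons by
default. p-values map to codes by the largest strict inequality satisfied
(0: p > 0.05, 1: p < 0.05, 2: p < 0.01, 3: p < 0.001, 4: p < 0.0001), so
a p exactly at a boundary takes the weaker code.

## Synthetic-data model

The generators exist to give every pipeline stage input with the
*structure* its inferences assume, plus ground truth for recovery tests.
They are not biological simulators, and passing recovery tests shows the
estimators work under the generating model — not that real gels or
transcriptomes satisfy that model.

**Species tree.** Ultrametric, topology `((((CF,PP),SP),(CO,ES)),PC)`,
heights 0.5 / 2.5 / 1.0 / 5 / 8 in arbitrary divergence units. The
king-crab leaf sits far outside the in-group, and internal branches are
long relative to terminal ones so that the topology is identifiable from
finite data — the property the recovery tests quantify.

**Band profiles.** Root profile Bernoulli(0.7) per band; along each
branch every band flips independently with probability
`flip_prob × branch_length`, capped at 0.5, the decorrelation limit of a
symmetric two-state flip process (so saturated branches randomize rather
than invert a profile; at the cap, expected SI approaches the
independent-Bernoulli Dice baseline of 50%). Defaults: 150 band
positions, `flip_prob = 0.05`. The 150 positions represent the pooled
annotation grid across gel and blot images; topology recovery from
SI+UPGMA needs on the order of a hundred informative positions, and at
these defaults the generating topology is recovered in ≈98% of seeded
replicates. Molecular weights are log-spaced over 10–250 kDa, the span
of a typical gradient gel.

**Protein families.** Per site and branch, the substitution count is
Poisson with mean `rate × branch_length`, `rate = base_rate` (default
0.03) outside and `base_rate × 0.2` inside epitope intervals;
replacements are uniform over the other 19 amino acids. No indels by
default — columns stay in register — with a gap-injection option purely
to exercise gap handling downstream. The uniform-replacement scheme is
intentionally simple: only the *relative* conservation structure matters
for testing the scoring, not phylogenetic realism. At the defaults the
outgroup attains the minimum consensus similarity in ≈100% of replicates
and similarity values land in the 80–98% range.

**OD plates.** Negative and non-sensitized sera are lognormal with mean
0.02 and CV 0.2; sensitized sera are lognormal around `20 × 0.02` (the
positive fold must exceed the cutoff multiplier 3). The sensitized count
is `⌈fraction × n⌉` (rounded before the ceiling so fractions like
0.14 × 50 stay exact). Defaults mirror a 50-serum plate with three
nonallergic controls and a 14% sensitization fraction; at this
separation the called prevalence is essentially error-free.

**Inhibition series.** True inhibition follows a Hill curve
`Imax·c^h/(IC50^h + c^h)` over a seven-point 1e-4–100 µg/mL dilution;
measured signals (the no-inhibitor well included) carry multiplicative
lognormal noise of CV 5%. Because the summary statistic is a plain
maximum, its error scales with the residual signal `(100 − I) × CV`:
a 93% plateau is recovered within ±3 points in ≈100% of replicates,
whereas low plateaus (≈10%) are overestimated by the max statistic by
more than 3 points about half the time — which is why the recovery
experiment is run at the high-inhibition operating point and low-Imax
series are checked only against a coarse "remains minimal" bound.

**TPM tables.** Lognormal (σ = 0.5) around allergen-specific muscle
means with a dominant tropomyosin-like allergen (mean 2^19 relative
units) and a hemocyanin-like allergen near zero in muscle but high in
mixed-tissue samples (PP, CO), reproducing the migrant-protein pattern;
50 unmapped background transcripts per species fill out the
transcriptome, and every sample is renormalized to 1e6 TPM. Sample
counts per species default to 1/1/4/1/6/3 (CF/PP/SP/CO/ES/PC), matching
a study layout where only SP, ES and PC carry enough replicates for
cross-species tests.

All generators are deterministic given their seed; regenerating a study
with the same configuration yields byte-identical files.

## Numerical conventions and degenerate inputs

* Similarity of two empty band profiles, rates over zero sera, zero
  no-inhibitor signal, empty negative-OD lists, sub-minimum
  concentration counts: explicit errors, never sentinel values.
* Consensus ties and sub-threshold columns: ambiguity character, never
  an arbitrary winner.
* An epitope whose denominator vanishes: NaN, flagged.
* All p-values validated to [0, 1]; NaN passes through aggregation as
  missing.
* Percent outputs rounded to one decimal only at the I/O boundary.

## Problem sizes

Recovery experiments run 100 replicates each (band simulations with 150
bands, protein families of length 300, 50-serum plates, 7-point
inhibition series); the complete test suite and the acceptance script
each finish in well under a minute on a single CPU.

## Known limitations

* Band identity must be curated upstream; no densitometry, MW
  calibration, or bootstrap support is provided.
* The conservation score depends on the consensus convention (threshold,
  tie rule, gap handling); all three knobs are exposed, and results
  should quote them.
* The dose-dependence flag is a fixed-tolerance heuristic, not a test
  with a controlled error rate.
* ANOVA/Tukey on a handful of RNA-seq samples is a descriptive device
  (as in the source study design), not a calibrated differential
  expression analysis; no multiple-testing correction beyond Tukey's is
  applied.
* The substitution model ignores amino-acid exchangeability and rate
  heterogeneity beyond the epitope/background split.
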