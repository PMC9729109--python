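# Methods

`sedadna` re-implements, as a tested library, the computational core of a
sedimentary ancient DNA (sedaDNA) site study: deciding which taxonomic
signals in shotgun metagenomes from ancient sediments are genuinely ancient,
and placing independent geochronological bounds on how old the site — and
its DNA — can be. This note records the models, the defaults and why, what
the synthetic data does and does not emulate, and the design choices made
where the design was genuinely open.

## Taxonomic assignment (taxonomy, lca)

Reads arrive with competitive alignments against a mixed reference panel.
A hit is accepted when its nucleotide identity lies in an **absolute**
similarity window, default [0.95, 1.00], and the read is at least 30 bp.
Each read is assigned to the lowest common ancestor (LCA) of its accepted
hits' taxa; reads with no accepted hit are tallied as unassigned so that
assigned + unassigned equals the number of reads per sample. The window is
applied per hit, not relative to the read's best hit: distant-in-time
communities are expected to sit a few percent away from modern references,
and the absolute window expresses exactly that tolerance. Identity is
1 − mismatches/aligned-length; alignments with indels are rejected with a
warning (SAM input requires NM/MD tags; mismatch positions are stored
1-based from the 5′ end of the read as sequenced, with reverse-strand
alignments complemented into that frame at parse time so damage counting is
strand-uniform).

Profiles count direct assignments per node per sample and, separately,
subtree-aggregated counts (a node plus all its descendants), which is the
level at which damage statistics and abundance filters operate.

## Damage model (damage)

Postmortem cytosine deamination concentrates C→T substitutions at the 5′
terminus and, on the complementary strand, G→A at the 3′ terminus. For each
node we tally, at terminal distances x = 1..K (K = 15 by default; beyond
~15 bp the excess has decayed into the background), the opportunities
(aligned reference C, resp. G) and hits (read T, resp. A). The aligned
reference is reconstructed exactly from the read sequence with the hit's
mismatch substitutions reverted, so opportunities need no reference genome
at tally time. Counts at a node include all subtree reads.

The damage frequency model is

    f(x) = A (1 − q)^(x−1) + c ,

an excess terminal damage A decaying geometrically (rate q per position)
over a constant background mismatch rate c. Both read ends are fit jointly
with shared parameters. The likelihood is beta-binomial with concentration
φ to absorb between-read heterogeneity; the null model is a constant
frequency (the A = 0 submodel) with its own free c and φ. Estimation is
bounded L-BFGS-B from five deterministic starts (A ∈ {data-driven, 0.05,
0.3, 0.6, 1e−3}, φ searched on the log scale in [1, 1e7]); the statistics
reported are

* **D_max = A + c**, the fitted damage frequency at position 1 (the
  alternative convention D_max = A is available by reading the fit's `a`
  field directly), and
* **λ_LR = 2 (ℓ_damage − ℓ_null)**, the raw likelihood-ratio statistic,
  clamped at 0 and not converted to a p-value; the convention is recorded
  in the fit output.

A node is called ancient when D_max ≥ 0.25 and λ_LR ≥ 1.5 (both inclusive,
both configurable).

**Type-I behaviour.** Testing A = 0 puts A on the boundary of its parameter
space with q unidentified under the null, so λ_LR is not χ²-mixture-calibrated
in the textbook way; empirically its null tail at 1.5 is ≈ 0.22 (the χ²₁
tail), i.e. roughly one in five undamaged nodes would pass the λ_LR rule
alone. The joint rule with D_max ≥ 0.25 is what carries the specificity: in
the end-to-end experiments undamaged contaminants are rejected without
exception because their fitted D_max sits near the background rate.

**Window selection bias.** Because damage events count as mismatches, the
most heavily damaged reads fall below the 95% similarity window and are
never tallied; assigned-read damage estimates are therefore biased slightly
*downward* — a conservative direction for authentication. The test suite
checks both the exact agreement of the hit-route and truth-route tallies on
correctly attributed reads and the direction of this bias.

## Filter cascade (filters)

After authentication, four stages run in a fixed order, each with a strict
">" on the median rules and with medians recomputed over the retained set:

1. drop taxa failing (or lacking) the damage fit;
2. drop taxa whose dataset-wide total is ≤ median(taxon totals)/2;
3. drop samples whose total is ≤ median(sample totals)/2;
4. drop taxa detected in fewer than 3 distinct samples ("replicates" =
   distinct biological samples surviving stage 3).

The taxon median is computed across the dataset (not per sample) on the
profile's per-node totals; divisor, replicate minimum and thresholds are
config fields, and one machine-parsable log row records each removal with
its triggering rule. Retained counts are then converted to within-sample
proportions (sums checked to 1 within 1e−12). Note the cascade is
idempotent only when retained taxa stay above the recomputed thresholds;
removing the lowest taxon raises the median, so a hypothetical second pass
could remove more. The cascade, like the study design it follows, applies
each rule exactly once.

## Marine reference validation (marine)

Per reference genome, after collapsing duplicate fragments (identical
coordinates/strand): reads mapped, mean read ANI (%), mean depth d̄, breadth
(fraction of positions covered ≥ 1), expected breadth 1 − e^(−d̄) under
Poisson random placement, breadth ratio = breadth/expected (capped at 1),
and coverage evenness

    E = (1/⌊d̄⌋) Σ_{i=1..⌊d̄⌋} F_i ,   F_i = fraction of positions with depth ≥ i

(E = F₁ when d̄ < 1). E is 1 for perfectly uniform coverage and strictly
decreases when the same mass is concentrated on fewer positions
(property-tested). The exact breadth-ratio and evenness formulas are
implementation-defined choices (standard coverage-QC scores) and are
config-swappable; they are flagged as such in the output. The working ANI
cutoff is chosen at the elbow of the reads-retained-vs-cutoff curve:
both axes normalized to [0, 1], the interior point maximizing perpendicular
distance to the endpoint chord, ties toward the lower cutoff. Retention
requires reads ≥ 500, mean ANI ≥ 93%, breadth ratio ≥ 0.75, evenness ≥ 0.75,
D_max ≥ 0.25 and λ_LR > 1.5 (the "fewer than / less than" wordings of the
source filters make all but the λ_LR rule inclusive at the boundary).

## Proxy-record comparison (records)

Names are harmonized through an editable synonym TSV (cycles rejected,
unknown names passed through and flagged), then every (name, rank) entry in
the union of the DNA, macrofossil and pollen sets receives exactly one
category: 1 — genus seen at genus level by DNA and by a fossil proxy
(genus-level match wins over the family route); 2 — genus seen by DNA whose
family is in a fossil record (the fossil family entry is also counted as
category 2, keeping the overlap symmetric); 3 — DNA only; 4 — fossil only.
Records above family rank go to a residual `unclassifiable` bucket rather
than being forced into 1–4. Category counts partition the union.

## Geochronology (geochron)

**Thermal age.** Reaction rates follow Arrhenius kinetics with activation
energy Ea = 127 kJ mol⁻¹ (DNA depurination-scale chemistry) relative to a
283.15 K (10 °C) reference; the thermal age is ∫ k(T(t))/k(T_ref) dt,
integrated trapezoidally on the *rate* (the rate is exponential in 1/T, so
integrating temperature first would be wrong) over a piecewise temperature
history, refined to ≤ 200-yr steps for linearly interpolated histories and
summed exactly for stepped ones. The whole history is first cooled by the
environmental lapse rate (6.49 °C km⁻¹) times site altitude. At a constant
−17 °C the rate factor is ≈ 295, so a 2.0 Myr deposit carries a thermal age
of ≈ 6.8 kyr at 10 °C; a glacial–interglacial stepped history scaled to the
same present-day MAT only increases the factor (glacials are colder).
Reproducing a specific published thermal age additionally requires the
specific long-term temperature record scaled to local conditions, which is
why the record, its scaling and the altitude are config inputs rather than
constants. Expected surviving fragment length under first-order depurination
at site rate k (per site per thermal year) is 1/(k·τ) bp — 50 bp at
k·τ = 0.02.

**Simple ²⁶Al/¹⁰Be burial dating.** After burial shields quartz from
cosmic-ray nucleons, the ²⁶Al:¹⁰Be concentration ratio decays from its
surface value R₀ at rate λ₂₆ − λ₁₀; decay constants default to
half-lives 0.705 Myr (²⁶Al) and 1.387 Myr (¹⁰Be), the standard values.
The point age is t = ln(R₀_eff/R)/(λ₂₆ − λ₁₀); a measured ratio above
R₀_eff is clamped to age 0 and flagged (post-burial production or
inheritance). Under the steady-erosion scenario
R₀_eff = R₀ (λ₁₀ + ρε/Λ)/(λ₂₆ + ρε/Λ) with ρ = 2.65 g cm⁻³ and
Λ = 160 g cm⁻², so steady-erosion ages are never older than zero-erosion
ages for the same measurement. Measurement uncertainty is propagated by
Monte Carlo (default 100,000 draws, seeded; positive-truncated normals on
both concentrations) onto an age grid of 0–6 Myr at 0.005 Myr. Several
samples sharing one burial event are combined by the **normalized pointwise
product** of their age PDFs — a joint constraint on a common age, not a
sum-convolution — and the scenario summary takes the midpoint and
half-range between the lowest −3σ and highest +3σ limits across the
production-ratio endmembers (6.75, 7.42) and erosion endmembers. Post-burial
muogenic production is neglected (deep burial). The validation experiments
use a maximum-erosion endmember of 500 cm Myr⁻¹ (5 m Myr⁻¹), a typical
magnitude for slowly eroding high-latitude bedrock; at that rate the
erosion term ρε/Λ ≈ 8.3 Myr⁻¹ shifts ages younger by ≈ 0.1 Myr.

## Synthetic data (simulate)

The generator produces every input the pipeline consumes, with the
statistical structure the analysis assumes, and is byte-reproducible given
a seed.

* **Taxonomy and references**: root → family → genus → species; species
  references derive from a genus ancestor by substituting a controlled
  proportion of sites (default sibling divergence 3%, chosen to straddle
  the 95% assignment window the way a Pleistocene community straddles
  modern references), no indels, so all congeneric references share
  coordinates and competitive hits can be recomputed exactly.
* **Reads**: fragment lengths are lognormal (dispersion 0.35) truncated to
  [30, 150] bp with the location parameter solved so the *truncated* mean
  equals the requested mean (default 50 bp, the fragment scale at which
  very old frozen-sediment DNA is expected to survive; 30 bp is the usual
  retention cutoff). Ancient reads get C→T at 5′ distance x with
  probability A(1−q)^(x−1) + c and mirrored G→A from the 3′ end (defaults
  A = 0.40, q = 0.30, c = 0.01, the regime of heavily damaged very old
  material); contaminant reads see only c on both substitution types.
* **Hit tables**: each read is compared against its source species and all
  congeneric siblings at the same coordinates; identity and per-position
  mismatch lists are exact recomputations from the emitted bases. Optional
  Gaussian `identity_noise` perturbs the identity column only, leaving
  mismatch lists faithful to the read bases (default 0).
* **Geochronology inputs**: isotope pairs decayed from a known burial age
  with normally perturbed concentrations (reported 1σ = cv × value), and
  declarative temperature histories (constant, or square-wave
  glacial–interglacial cycles with configurable cooling, period, glacial
  fraction).

Not emulated: platform error profiles and base qualities (FASTQ qualities
are uniform Q40), indel damage, assembly artefacts, reference database
incompleteness, and real alignment ambiguity beyond congeneric competition.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under its own assumptions, not robustness to every
failure mode of real sediment libraries.

Two consequences of the generative model are worth knowing. First, a
deamination event can coincide with a divergence site whose sibling allele
equals the damaged base, in which case the sibling genuinely outscores the
true source and the read is assigned off-lineage (~0.025% of reads at
defaults); the assignment tests assert ancestry for > 99.9% of reads rather
than all. Second, the similarity window's selection against heavily
damaged reads (above) is visible in the synthetic data exactly as it would
be in real data.

## Problem sizes and numerical choices

The validation experiments run at desk scale: damage recovery uses 100
replicates of 5,000 reads (median |D̂_max − 0.41| ≈ 0.006), the type-I
experiment 100 replicates of 2,000 undamaged reads, LCA oracle equivalence
1,000 random trees of ≤ 50 nodes, burial-age calibration 100 repetitions of
a 3-sample trio with 5% measurement noise at 20,000 Monte-Carlo draws, and
the end-to-end experiment 20 cohorts of 8,000 reads across 8 genera and 4
replicates. Optimizer tolerances are scipy L-BFGS-B defaults with the
multi-start scheme above; PDF normalization is trapezoidal with quantiles
from the interpolated CDF; seeds are explicit everywhere and identical
seeds give byte-identical FASTQ, hit tables, isotope tables and summary
outputs.

## Known limitations

* λ_LR alone is an anticonservative authenticator (≈ 22% null pass rate at
  the 1.5 threshold); it should always be paired with the D_max rule, as it
  is in the defaults.
* The filter cascade's stage order (sample-depth filtering after taxon
  filtering) and the dataset-wide scope of the taxon median are choices the
  source description leaves open; both are config-exposed and recorded in
  output metadata.
* The evenness and breadth-ratio formulas are implementation-defined stand-ins
  for an unspecified upstream QC tool's definitions.
* The burial-age scenario machinery assumes a single shared burial event
  per sample trio and neglects post-burial production entirely.
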