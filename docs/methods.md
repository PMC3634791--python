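# Methods

This note documents the models, the numerical choices, and what the
synthetic data does and does not establish.

## Trait model

The thoracic vertebral count is generated from a latent Gaussian:

    latent = mu + a·d + delta·[d = 1] + g + e,    count = round(latent)

with d ∈ {0, 1, 2} the Q-allele dosage, `a` the additive effect in
vertebrae per allele (default 0.5), `delta` a dominance deviation
(default 0), `g` a pedigree-structured polygenic value and
`e ~ N(0, σe²)`. Rounding to the nearest integer (ties to even, the
IEEE default) reproduces integer counts whose summary statistics are
near-normal; it adds ≈ 1/12 to the latent variance. The lumbar count is
an independent integer trait with its own mean and spread and no QTL
effect — pipelines built on these data should find a thoracic signal
and a lumbar null.

Polygenic values drop down the pedigree: founders draw
N(0, σg²), offspring take the parental average plus Mendelian sampling
N(0, σg²/2). `h2_poly` fixes σg² = σe²·h²/(1 − h²), i.e. the polygenic
fraction of the non-QTL variance.

Defaults: `TraitModel` uses σe = 0.6 (a modeling choice; the source
tables' dispersion column is internally inconsistent between SD/SE
readings, so no value can be quoted) and h2_poly = 0. The *study
fixture* instead uses σe = 0.45 and h2_poly = 0.1, calibrated so that
simulated within-haplotype-group SDs (≈ 0.6 in the generated cohorts)
sit at the upper end of the published group dispersions; with larger
residuals the progeny-test Z statistic rarely leaves the undecided band
at realistic family sizes, which contradicts the published call table.

## Gamete dropping and the planted QTL

Meioses use the Haldane map function r = (1 − exp(−2d/100))/2 with no
interference; the genetic map defaults to 1 cM/Mb when only physical
positions exist. The QTL is carried as a hidden pseudo-marker inserted
at its physical position, so its alleles recombine with flanking
markers exactly as a genotyped SNP would; `plant_qtl` reads the
per-animal dosage back and the observable panel simply excludes the
hidden marker.

Founders are drawn in linkage equilibrium. In the study fixture, chip
frequencies are drawn once (shared ascertainment) and perturbed
(SD 0.05) per population, mimicking correlated breed frequencies; every
Q-carrying founder chromosome receives a copy of one ancestral
haplotype over a random window around the causal site (half-width
uniform on 0.6–1.6 Mb per side), and that haplotype is enriched for
minor alleles (85%) — a rare derived haplotype against the cohort
background, which is precisely what gives chip markers on it mapping
information and makes identity-by-state sharing informative about
identity by descent.

What the fixture does **not** emulate: genotyping batch effects, linked
ascertainment bias, crossover interference, sex-specific maps, X-linked
inheritance, or real 60K marker spacing (600 markers per chromosome
over three chromosomes stand in for it). Passing tests show the stages
are correct under the stated generative model, not that real chip data
meet that model.

## Mixed-model scan

Two-stage strategy: one REML fit of y = μ + g + e with
Var(y) = σ²(h²·G + (1 − h²)I), G the VanRaden-standardized genomic
relationship matrix (mean over markers of
(x − 2p)(x − 2p)ᵀ/(2p(1 − p)), missing dosages mean-imputed,
monomorphic markers excluded with a warning); then a per-marker Wald
χ²(1) from GLS in the polygenic eigenbasis at the fitted h². At h² = 0
this is exactly the OLS t² — the unit tests pin that against
statsmodels. The two-stage test is slightly conservative near the
causal site (part of a strong QTL is absorbed into G), which is
acceptable here because localization, not effect estimation, is the
goal. h² is optimized by bounded 1-D search (xatol 1e-8) with an
explicit check of the h² = 0 boundary.

LOD is computed from the χ² log survival function, so it survives
p-value underflow; reported p-values are clipped to the smallest
positive double.

## Support intervals

The LOD-drop interval is the span of **all** markers on the peak
chromosome with LOD ≥ peak − drop (drop = 2). The alternative rule —
extend contiguously from the peak — collapses to a single marker
whenever an uninformative marker sits next to the peak, which happens
routinely in crosses with few founders (markers segregate but carry no
QTL information). Both rules agree on smooth profiles. Intersection of
population intervals is the closed-interval [max start, min end] and
raises naming the first disjoint pair. The pipeline first intersects
the intervals of all populations with a genome-wide-significant signal
on the consensus chromosome; if they are disjoint (possible on a sparse
scaled-down panel), it falls back to the intervals containing the
meta-analysis anchor and records which populations were discordant.

## Progeny-test Z statistics

Two likelihood ratios are provided.

* `zscore_segregation` — the nested form: heterozygote model with two
  free group means versus homozygote model with one, both with
  ML variance. Closed form Z = (N/2)·log₁₀(SS₀/SS₁). It is the
  simplest Gaussian reading of the published description, but since the
  two-mean model always fits at least as well, Z ≥ 0: it can *detect*
  heterozygous sires (Z > 2) but can never produce positive evidence
  for homozygosity.
* `zscore_fixed_effect` — the heterozygote hypothesis fixes the gene
  substitution effect at a prior value δ (default 0.5 vertebrae, the
  effect estimated by the antecedent linkage study):
  Z = (N/2)·log₁₀[(SS₁ + wD²)/(SS₁ + w(|D| − δ)²)], with D the observed
  group-mean difference and w = nL·nR/N. This is informative in both
  directions — strongly negative values are evidence the sire is
  homozygous — and reproduces the sign pattern and magnitudes of
  published call tables. The pipeline uses it for calling; the
  classification rule is Z > 2 → Qq (Q on the higher-mean chromosome),
  Z < −2 → homozygous, otherwise undecided.

Sires are only tested when both transmitted-chromosome groups reach a
minimum size (default 20); smaller families put the threshold rule in
a regime where a single lucky family crosses Z = 2 spuriously.

Homozygote direction (QQ vs qq) is resolved, when possible, by pooled
t-tests of the sire's progeny against the Q- and q-group progeny of the
deduced heterozygous sires *of the same population* (baselines differ
between populations). When direction stays unresolved the animal still
constrains the concordance test as "homozygous, either class" — exactly
the property the published concordance argument uses. Founder
chromosomes are classified by the same reference t-tests
(`founder_call`, α = 0.01 two-sided by default) subject to Mendelian
consistency; a significant call contradicting pedigree transmission is
an error, an undecided one is resolved by it.

## Haplotype sharing

Pedigree phasing is rule-based: homozygous sites are trivially phased;
heterozygous sites resolve when a parent's homozygous genotype forces
the transmitted allele; sites contradicting Mendelian transmission are
blanked and counted. Founders (no genotyped parents) keep their
chromosome labels as given — progeny-based reconstruction of founder
phase, which dedicated haplotyping software would perform, is out of
scope, and the "Left/Right defined arbitrarily per sire" convention of
progeny testing needs only a consistent labeling. Phase-unresolved
heterozygous sites act as wildcards in the sharing scan and are
counted per segment.

The shared region extends marker-by-marker from the anchor while all
Q-bearing haplotypes agree (identity by state as the IBD proxy);
flanking discordant markers are reported, maximality and soundness are
property-tested against an exhaustive-interval oracle, and densifying
the map can only narrow the region. BED gene annotation is converted
to 1-based closed coordinates at the boundary; overlap is ≥ 1 bp on
closed intervals.

## Concordance and constraint

A variant passes iff, under one of the two allele-to-Q orientations,
zero tested animals violate their class constraint (Qq → het,
QQ/qq → the matching homozygote, hom-undirected → either homozygote,
partial "q_" calls → carry ≥ 1 q-linked allele). Evaluating both
orientations makes the result independent of animal order; ties in
mismatch count are broken toward the orientation anchored by the first
informative animal. Missing genotypes are skipped and counted;
monomorphic-across-tested-animals variants fail as uninformative.
The constraint screen retains a candidate iff no non-focal species
carries the derived allele; an all-missing comparison row is retained
but flagged low-evidence. Complete LD between two variants means
identical genotype classes on every co-genotyped animal up to a fixed
relabeling of the homozygote classes.

## Study-fixture scale

Chosen once as the package's study conditions: three chromosomes of
120–135 Mb with 600 chip markers each; F2 intercross with 900
phenotyped offspring (full-scale families — per-sire progeny-test
power collapses below ~40 offspring per transmitted chromosome);
half-sib families 4 × 55 with 400 offspring; a 61-animal second
intercross; 400 outbred animals at Q frequency 0.55; Q frequencies
~0.29/~0.28/~0.09 in the three mapping populations. The whole pipeline
runs in well under a minute.

## Known limitations

* The mixed model is two-stage, not an exact per-marker LMM; strong
  signals are mildly deflated.
* Identity-by-state sharing can be broken by a single miscalled sire;
  the minimum-family-size gate mitigates but does not remove this.
* Cross-family homozygote-direction calls are unreliable when dams
  segregate and polygenic family effects are large; the pipeline then
  deliberately degrades to undirected homozygote constraints.
* The exact HWE mid-p test enumerates the conditional distribution per
  marker; it is exact but O(n) per marker and meant for cohort-scale,
  not biobank-scale, data.
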