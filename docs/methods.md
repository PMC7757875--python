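# Methods

## The game and the elicited phenotype

Four players each hold 20 tokens (250 CLP apiece). Tokens contributed to a
common pot are doubled and split equally, giving the payoff
π_i = (20 − g_i + 0.5 Σ_j g_j) × 250 CLP. The marginal private return of a
contributed token is 0.5 against 1 for a kept token, so contributing
nothing is the dominant action for a selfish maximizer while joint full
contribution maximizes group earnings — a linear social dilemma
(`Endowment` enforces 1/4 < return < 1).

The strategy method elicits, per subject, (a) an *uninformed* contribution
chosen with no information about the group and (b) a *contingent schedule*:
a planned contribution for every possible rounded average contribution
(0..20) of the other three members. Groups are resolved by averaging three
members' uninformed contributions, rounding, and letting the fourth
member's schedule respond; because either decision type can determine
earnings, both are incentive compatible. The schedule is the phenotype:
unlike a single observed action it is purged of beliefs about others and
of learning.

Rounding of the others' average is half-up (8.5 → 9). No rounding rule is
canonical for the original software; half-up matches everyday convention,
only affects exact-.5 averages, and is configurable in `resolve_group`.
Payoffs are held as exact rationals (multiples of half a token value) so
the accounting identity Σπ = 250·(80 + Σg) holds without float drift.

## Strategy classification

Rules are applied in strict order; every schedule receives exactly one of
four labels.

1. **FR** — max(schedule) ≤ round-half-up(fr_fraction × 20) tokens. The
   default fraction 0.20 gives a 4-token ceiling; 0.10 and 0.30 (2 and 6
   tokens) are robustness settings. FR screening precedes the correlation
   tests, so a constant-4 schedule is FR even though its correlation is
   undefined.
2. **HS** — for every split k = 3..18, Spearman correlations of schedule
   against others' average are computed on entries 0..k−1 and k..20. The
   label fires if *any* split has the leading coefficient significantly
   positive and the trailing coefficient significantly negative, both at
   α = 0.01. "Significant" means two-sided p < α together with the
   required sign (a one-sided mode is available as a config switch);
   requiring both segments individually significant is the strictest
   reading of a "positive-to-negative change at the 1% level" and keeps
   sign flips of noise-level coefficients from triggering HS.
3. **CC** — the full 21-entry Spearman is significantly positive at 1%.
   The whole table is used because the precursor protocol defines
   conditional cooperation on the full schedule.
4. **OT** — everything else. Constant schedules (unconditional
   cooperators included) have zero rank variance, hence undefined
   correlations, hence can only land in FR (if low) or OT.

The per-subject trace always contains all 16 split diagnostics plus the
full-schedule test, whether or not the label needed them.

**Spearman p-values.** Ranks are midranks. For segments of n ≤ 8 entries
the p-value is exact: all n! orderings of one side's ranks are enumerated
and the tail of the permutation distribution of rho is taken (ties make
this a permutation test rather than the classical tie-free table). The
null distribution depends only on the two rank multisets, so it is cached
and reused; tie-free segments of equal length share one distribution.
For n > 8 the usual t-approximation t = rho·√((n−2)/(1−rho²)) with n−2 df
is used, with |rho| = 1 mapped to p = 0. A consequence worth knowing: a
3-entry segment's smallest exact two-sided p is 2/6, so the shortest
splits can never be significant at 1% — the min_segment = 3 scan is safe
by construction.

## Genotype coding and Hardy–Weinberg tests

- *MAOA*-uVNTR is X-linked: men carry one allele (4.5 repeats → H,
  3.5 → L); women carry two, and because X inactivation makes a
  heterozygote's expressed copy unknowable, only homozygous women are
  coded (4.5/4.5 → H, 3.5/3.5 → L) and 3.5/4.5 women are excluded.
  The rare 5.5 and 6.5 alleles exclude their carriers in either sex.
- *OXTR* rs53576 genotypes are unordered A/G pairs: GG, GA, AA.
- *AVPR1a* RS3 allele lengths are binned Short (324–341 bp inclusive) and
  Long (342–356 bp inclusive) — a standard low-frequency-allele reduction
  for microsatellites — giving Short/Short, Short/Long, Long/Long.
  Lengths outside 324–356 bp are treated as out of range and exclude the
  carrier rather than being extrapolated into a bin.

HWE is tested with the 1-df Pearson chi-square on the three diploid
genotype classes, expected counts n·(p̂², 2p̂q̂, q̂²) with p̂ estimated from
the same counts, and *no* continuity correction (the corrected statistic
would not reproduce the conventional values on pooled study-scale counts).
A monomorphic sample is reported as degenerate with χ² = 0. MAOA HWE is
only defined in women and is computed on the *pre-exclusion* female
genotype table (L/L, L/H, H/H): a table purged of heterozygotes cannot
meaningfully be tested against p², 2pq, q².

## The association battery

Everything is run separately by sex. Four Bonferroni families, each at
family-wise α = 0.05; per-test thresholds are exact (0.05/m), with the
conventionally printed rounded values (0.008, 0.00125, 0.003) carried
alongside for reporting. Flags always use the exact threshold — the
printed values are slightly anti-conservative.

**Fisher (m = 6).** Strategy × genotype independence per variant. The
two-sided p is the total probability of fixed-margin tables no more
probable than the observed one (R's `fisher.test` definition, including
its 1e-7 relative slack). Tables are enumerated exactly by a vectorized
column-wise expansion, smallest margins first, under a path budget
(default 5·10⁶); beyond the budget a seeded permutation Monte-Carlo
estimate with ≥ 10⁵ draws is returned and flagged as such. At study-scale
4×2 and 4×3 tables the exact route always applies.

**Multinomial AMEs (m = 40).** A multinomial logit of strategy on genotype
with genotype the only regressor is saturated, so its MLE probabilities
are the within-genotype sample proportions and the discrete-change average
marginal effect of level g versus the baseline on strategy s is exactly
P̂(s|g) − P̂(s|baseline). That closed form makes a full nonparametric
bootstrap cheap: subjects are resampled (default 1000 reps, seeded) to
give the reported SE and a percentile interval at the Bonferroni level.
The m = 40 family is 2 sexes × (2 OXTR + 2 RS3 + 1 MAOA non-baseline
levels) × 4 strategies; baselines are OXTR AA, RS3 Long/Long, MAOA L.

The p-value is *not* the Wald ratio effect/SE_boot. The bootstrap SE
conditions on the observed cell proportions, and when a small genotype
group (the baselines have as few as nine subjects) happens to show an
extreme strategy share, p̂(1−p̂) collapses and the Wald tail becomes an
order of magnitude anticonservative — in null simulations at study-scale
group sizes, P(p < 0.00125) ≈ 0.014 and the family-wise false-positive
rate reached ~27%. Instead p comes from the pooled-variance (score-type)
normal approximation for a difference of proportions,
z = AME / √(p̄(1−p̄)(1/n_g + 1/n_base)), which is the classical calibrated
choice at boundaries (measured P(p < 0.00125) ≈ 0.0016). Genotype levels
observed with a single strategy are additionally flagged `separated` —
the regime where coefficient-scale Wald machinery degenerates — and their
percentile intervals remain available.

**Kruskal–Wallis (m = 18 and m = 6).** Per-subject scenario means — low
(others' average 0–6), mid (7–13), high (14–20), each spanning exactly
seven schedule entries — are compared across genotypes per variant ×
scenario (one value per subject preserves independence of observations),
and uninformed contributions across genotypes per variant. H is
tie-corrected; p from χ² with k−1 df. A sample in which every observation
ties is reported as H = 0, p = 1.

A stratum-variant cell with fewer than two genotype levels after
exclusions skips its tests with a logged message; family sizes (and hence
thresholds) are unchanged.

## Synthetic cohorts

The generator draws what the analysis assumes and nothing more:

- **Genotypes** allele-wise under HWE: two independent alleles per
  autosomal locus, one MAOA allele for men, two for women. Defaults match
  a 188-subject study cohort (107 women): OXTR A-allele frequency 0.332;
  RS3 length distribution over 12 alleles in 327–353 bp with a Short
  frequency of 0.56; MAOA allele frequencies {3.5: 0.56, 4.5: 0.42,
  5.5: 0.015, 6.5: 0.005} (the rare alleles exist so the exclusion paths
  are exercised). The MAOA 3.5 frequency follows the male hemizygote
  share, since female heterozygote counts are not identifiable from
  homozygote-only tables.
- **Schedules** from five archetypes at Table-2-like mixture weights
  (CC 0.489, HS 0.117, FR 0.096, unconditional 0.016, miscellaneous
  0.282): CC is a line through the origin with per-subject slope β ~
  U(0.6, 1.0) — the sub-unit slope is the "selfish bias" that puts mean
  CC profiles below the diagonal; HS is a tent with peak position 8–13 and
  height 12–20 (peaks much beyond 14 leave too short a trailing segment
  ever to test significantly negative, so such shapes would land in OT —
  a property of the classifier, not a bug); FR draws entries within a
  ceiling 0–4; UNCOND is constant 20; MISC is uniform noise over the full
  range, populating OT with genuinely unclassifiable plans. Entrywise
  integer jitter (default half-width 1 token) is applied and clipped.
- **Uninformed contributions** are the subject's own schedule evaluated at
  a belief about others drawn Binomial(20, 0.45) — uninformed behavior
  mixes strategy with expectations, which gives the Kruskal–Wallis test on
  uninformed contributions realistic dependence on the schedule.
- An optional **planted effect** tilts archetype weights multiplicatively
  per genotype level, providing ground truth for power and recovery
  simulations; with no effect, genotype and strategy are independent by
  construction.

What the generator does *not* emulate: linkage disequilibrium, population
admixture or stratification, genotyping error, within-subject
inconsistency between uninformed and contingent decisions beyond the
belief draw, and any correlation between sex and behavior. Tests passing
on these cohorts therefore validate the pipeline's statistics under its
own assumptions; they say nothing about confounding structure real
cohorts may carry.

Noise magnitudes and the belief parameter are not estimates of any real
population; they were fixed once for plausibility (±1 token jitter keeps
zero-order archetype recovery essentially perfect, which is what makes
mixture-recovery checks interpretable) and are config-exposed.

## Problem sizes in the test and acceptance runs

Chosen as the package's own defaults: null-battery simulations use 200
seeded replicates at n = 188 in the test suite and 100 in the acceptance
script; archetype-mixture recovery uses one n = 2000 cohort; bootstrap-CI
recovery of a planted effect uses 100 replications at n = 5000 with the
default 1000 bootstrap reps; the HWE null-calibration check uses 10,000
multinomial replicates.

## Numerical and serialization choices

Exact Spearman tails use a 1e-12 comparison tolerance; permutation
matrices and null distributions are cached per segment length and rank
multiset. Fisher probabilities are computed in log space from a cached
log-factorial table. Bootstrap and Monte-Carlo draws chunk their work to
bound memory. Reports never round internally; TSV floats are serialized
at fixed precision (6 decimals) and JSON floats at 6 decimals with sorted
keys, so a rerun with the same config and seed is byte-identical.

## Known limitations

- With four families each holding family-wise error at 5%, the chance
  that a fully null battery shows *no* flag anywhere is about
  0.95⁴ ≈ 0.81–0.87 (measured ≈ 0.85–0.89 across seed blocks, the
  families being positively dependent). A single null study is therefore
  more likely than not to be clean, but "some flag somewhere" is not rare
  under the global null — which is the Bonferroni-per-family design
  working as specified, not a calibration failure.
- The t-approximation for segments of 9+ entries is an approximation;
  only segments of ≤ 8 entries get exact tails. At α = 0.01 and the
  lengths involved the approximation error is immaterial to labels.
- Monte-Carlo Fisher p-values have resolution 1/(draws+1) and are flagged
  so consumers do not over-interpret digits.
- The AME battery tests marginal association only; no gene–gene or
  gene–environment interactions, haplotypes, or covariate adjustment.
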