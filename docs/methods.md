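# Methods

This note records the models implemented by `soilrisk`, the defaults they
ship with, and the design choices made where conventions genuinely diverge.

## Data model and non-detects

A survey panel is a samples × elements concentration matrix (mg·kg⁻¹ dry
soil; no unit-conversion layer) with per-cell censoring flags and detection
limits. Cells below the detection limit are substituted at 5/6 of the limit
before any index, health-risk or PMF computation; the flags are retained so
the PMF uncertainty construction can treat those cells differently.
Substitution is idempotent, and a write/read round trip through the wide
CSV format (censored cells serialized as `<DL`) restores values to full
precision and flags exactly.

The packaged reference set pairs the regional background values of the
survey area's non-agricultural soils with Hakanson's toxicity response
coefficients (Hg 40, Cd 30, As 10, Pb/Cu/Ni 5, Cr 2, Zn 1). The published
background compilation for this region is internally inconsistent for Hg:
the tabulated value (11.48 mg·kg⁻¹) is three orders of magnitude above all
observed Hg concentrations and above any plausible crustal level, while the
accompanying narrative lists a different (and incomplete) set of values.
The tabulated row is kept as the packaged default because the published
per-element risk means are only reproducible with it; backgrounds are
user-overridable through the YAML reference config, and the synthetic
generator's natural source uses a geochemically plausible Hg level instead
(see below).

## Pollution indices

* `I_geo = log2(C/(1.5·C0))`, graded none (≤0), slight (0,1], moderate
  (1,2], severe (2,3], extremely severe (>3). Upper bounds inclusive.
* `E_r = T_r·C/C0`, graded slight (<40), moderate [40,80), strong [80,160),
  very strong [160,320), extremely strong (≥320). Lower bounds inclusive —
  a value exactly on a boundary takes the higher class.
* `RI = Σ E_r`. Grading thresholds are re-scaled to the panel: the classical
  first-level threshold 150 was set for a substance set with ΣT_r = 133, so
  the per-unit-toxicity grading value is 150/133; a panel's first threshold
  is `round_half_up(150/133 · ΣT_r)` — 111 for the default 8-element panel
  (ΣT_r = 98) — and levels 2 and 3 double successively on the rounded value
  (222, 444).
* Summary statistics use the sample (n−1) standard deviation; CV = sd/mean;
  exceedance factor = (mean − C0)/C0.

## Probabilistic health risk

Doses follow the three-pathway USEPA equations given in the README. Unit
bridging: EF (d·y⁻¹) × ED (y) yields total exposure days and divides by AT
in days directly; the receptor AT defaults (2190 d = 6 y child, 9125 d =
25 y adult) pair with the ED ranges uniform(0,10] and uniform(0,50], so no
additional 365 factor is applied. The same AT is used for carcinogenic and
non-carcinogenic risk, exactly as parameterized — deliberately not the
70-year lifetime-AT convention some USEPA guidance uses for carcinogens;
users wanting that convention can override AT in the exposure model.

Distribution families: point, triangular(min, mode, max), uniform(low,
high) open at the lower bound (a drawn hard zero is resampled; zero
exposure duration is measure-zero anyway), lognormal(geometric mean, GSD
with GSD > 1), and truncated-normal(mean, sd, lower bound 0). The default
lognormal parameter pairs (e.g. adult BW 57.03, 1.18) are read as GM/GSD —
spreads of 1.1–1.5 are implausible as arithmetic SDs in kg or cm² and are
the canonical GSD range in exposure-factor compilations. The one exception
is the adult skin-adherence factor (0.49, 0.54): 0.54 < 1 cannot be a GSD,
so it is modelled as arithmetic mean/SD truncated at zero. Any parameter
can be re-specified with either family.

Each iteration draws one whole survey row (empirical concentration mode,
preserving inter-element correlation; a fitted per-element lognormal mode
is selectable) and an independent value of every exposure parameter shared
across elements. HQ/CR sum only over pathways with a published RfD/SF
(e.g. Cd has no dermal SF, Cu and Zn none at all); elements with no RfD at
all are excluded from HI with a warning, elements with no SF contribute 0
to TCR. Summaries report mean and 5th/50th/95th percentiles at a default
of 10,000 iterations; risk bands: CR ≤ 10⁻⁶ negligible, (10⁻⁶, 10⁻⁴]
tolerable, > 10⁻⁴ intolerable; HQ/HI ≤ 1 negligible.

With every distribution degenerate the engine reproduces the deterministic
closed form to machine precision (tested against an independent hand
calculation). The published per-element mean CR/HQ values for the reference
survey are *not* desk-reproducible — they depend on the unpublished
84-sample distribution and on the original analysis's exact lognormal
convention — and are treated as order-of-magnitude anchors only; this
package's defaults land within a factor ≈ 2 of them at the survey means.

## PMF

Objective `Q = ΣΣ ((x − gf)/u)²` over nonnegative g, f, minimized by
alternating weighted multiplicative updates (each half-update is monotone
in Q). Initialisation is uniform-random scaled to the data mean;
convergence when the relative Q change falls below 1e-8 (default) or after
5000 iterations, with non-convergence flagged on the result rather than
raised. Multi-restart (default 20 independent initialisations) keeps the
lowest-Q solution. This is an in-package optimizer equivalent to the EPA
receptor-model formulation at the level of the objective; it does not
reproduce the ME-2 conjugate-gradient engine, rotational tools (Fpeak) or
bootstrap/displacement error estimation.

Uncertainties follow the standard receptor-modelling convention:
`u = sqrt((error_fraction·c)² + (0.5·MDL)²)` for detected cells
(error_fraction default 0.10, configurable) and value = u = 5/6·MDL for
non-detects. The source survey does not publish its uncertainty equation;
this convention is a package assumption, not a reproduced fact.

Robust mode re-weights outliers every 10 iterations: cells with scaled
residual |e/u| > 4 get u inflated by sqrt(|e/u|/4). Both Q_true (original
u) and Q_robust (inflated u) are reported; Q_robust ≤ Q_true always.
Diagnostics report the fraction of scaled residuals within ±3 (threshold
0.955), per-element and overall R² between observed and reconstructed
concentrations (threshold 0.98), and the Q_robust/Q_true ratio.

Shares: for element j, factor k's contribution is mean_i(g_ik)·f_kj over
the element's total mean reconstructed mass, ×100; overall source shares
weight elements by reconstructed mass. Factor identities (asbestos /
natural / coal) are analyst metadata: `label_factors` reports each factor's
top marker elements, nothing more.

Factor matching in tests resolves the permutation ambiguity by Hungarian
assignment on cosine similarity computed after dividing profiles by the
element mean concentrations. The scaling matters: in raw mg·kg⁻¹ the
profile vectors are numerically dominated by Cr and Ni (~10³ mg·kg⁻¹
against ~10⁻² for Hg), so an As- or Hg-defined factor would be compared
almost entirely on its incidental Cr/Ni content.

## Synthetic surveys

The generator emulates the reference survey as a three-source mixture,
`C = (G·F)·exp(ε)`:

* **asbestos** — profile equal to the mean composition of the sampled
  asbestos source materials (Cr 1339.17, Ni 1788.33 mg·kg⁻¹, all else low);
  mean loading set so the expected Ni excess over background is entirely
  asbestos-derived (≈ 0.346).
* **coal combustion** — pure-As profile carrying the As excess left after
  the asbestos contribution (mean loading 1).
* **natural** — the residual profile (survey mean minus the two
  anthropogenic terms). It tracks the regional background vector closely
  for most elements (As and Ni exactly, by construction), with two
  deliberate departures: Hg is set near 0.003–0.02 mg·kg⁻¹ rather than the
  implausible tabulated background, and Cr sits above background because
  the asbestos materials' Cr:Ni ratio (0.75) is lower than the survey's
  excess ratio (0.87), leaving residual Cr mass with the natural term.
  Making the natural profile *strictly* proportional to the tabulated
  backgrounds is incompatible with matching the survey's element means,
  and mean-matching was kept as the binding constraint.

Expected element means of a generated panel therefore equal the survey
means exactly (up to the exp(σ²/2) ≈ 1.005 noise bias); the default-seed
84-sample draw lands within ~8% on every element. Loading heterogeneity is
lognormal with log-scale SDs 0.85 (asbestos), 0.30 (natural) and 1.20
(coal), chosen to echo the survey's observed CV ordering (Ni/Cr ≈ 1, Zn/Cd
lowest, As highest); measurement noise is multiplicative lognormal with
σ = 0.10 — concentrations are positive and right-skewed, so additive
Gaussian noise would be the wrong error model. Detection limits default to
values that censor roughly 5% of Hg and Cd cells (0.0038 and 0.050
mg·kg⁻¹, near those elements' 5th percentiles) and essentially none of the
others, exercising the 5/6-DL path without dominating the panel.

What the generator does **not** emulate: spatial autocorrelation and
zone-specific layouts (samples are i.i.d.), inter-element noise correlation
beyond the shared source loadings, analytical batch effects, and the exact
tail behaviour of the real survey (its printed maxima imply heavier tails
than a lognormal with these σ). Tests passing on synthetic panels
demonstrate correct recovery of a known mixture under realistic noise —
not that three sources is the right model for any particular real site.

## Problem sizes and determinism

Default problem sizes used by the test suite and reports: 84-sample panels
for pipeline checks, 200-sample panels for factor-recovery studies, 10,000
Monte Carlo iterations, 10–20 PMF restarts. Every stochastic stage takes an
integer seed and is bitwise reproducible under it; the consolidated
pipeline report is byte-identical across reruns of the same configuration
(run timestamps live in a separate metadata file).
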