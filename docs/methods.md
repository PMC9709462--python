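# Methods

This note records the modelling and numerical choices behind the toolkit:
what each engine computes, where the shipped defaults come from, what the
synthetic generator does and does not emulate, and the known limitations.

## Scope and data model

One `ExposureRecord` is a single airborne measurement of one chemical at one
job/location: concentration CA (mg/m³, time-weighted), exposure time ET
(h/day), frequency EF (days/year), duration ED (years), worker count.  One
`HazardProfile` carries a chemical's toxicology: RfC (μg/m³), OELs (China
PC-TWA and ACGIH TLV-TWA, mg/m³), IARC carcinogenicity class, oral LD50 /
inhalation LC50, risk phrases, physical form and dustiness/volatility band,
and an optional hazard-rating override.  Only the inhalation route is
modelled; dermal and ingestion exposure, and carcinogenic (unit-risk-based)
assessment, are out of scope — the IUR field is stored but unused.

Units are fixed at the API boundary: concentrations are mg/m³ everywhere
except inside the EPA hazard-quotient arithmetic, which works in μg/m³
because reference concentrations are tabulated in μg/m³.  The conversion is
explicit (×1000 inside `compute_ec`), never implicit.

## Shared quantities

**EC** — `EC = CA·ET·EF·ED / AT` with `AT = ED·365·24` h.  ED cancels, which
the implementation exploits and a property test pins down.  Consequently
`0 ≤ EC ≤ CA` always, with equality at continuous exposure (ET=24, EF=365).

**CR** — `CA / OEL`.  The China PC-TWA is the default denominator (the
shipped dataset emulates a Chinese workforce); `--oel-source acgih`
switches.  CR feeds the Singaporean exposure rating and the derived
probability/likelihood ratings of the ICMM, Australian and Romanian engines,
so those methods respond to measured exposure even though their source
descriptions leave the rating to an evaluator.

When records omit ET/EF/ED they default to a full working shift: 8 h/day,
250 days/year, 25 years.  These are standard full-shift assessment
assumptions; they are deliberately not tuned to reproduce any published
level range, and a few published cells are knowingly not reproducible under
them.

## The engines

**EPA.**  `HQ = EC/RfC`, both μg/m³.  Some descriptions print the formula
with an explicit "×1,000 (μg/mg)" factor; that factor is the mg→μg unit
conversion of an RfC quoted in mg/m³, not an extra multiplier — taking it
literally on top of consistent units would inflate every HQ by 10³ and
contradict all published level tables.  HQ maps to five levels through the
band table `<0.1, 0.1–0.5, 0.5–1, 1–2, ≥2`.

**Banding convention.**  Every band lookup in the package (HQ bands, ER
bands, probability/frequency bands) is left-closed/right-open with the top
band closed above: HQ = 0.5 is level 3, CR = 0.1 is rating 2.  One
convention everywhere, enforced by an interval oracle in the tests.

**Singaporean.**  `Risk = √(HR·ER)`, rounded **up** (conservative; also the
reading consistent with published medians, e.g. HR 4 with ER 2 giving level
3), capped at 5.  HR comes from, in priority order: a per-chemical override
in the registry, the IARC class (1→5, 2A→4, 2B→3, 3→2), else the worse of
the LD50/LC50 acute-toxicity bands.  The override exists because the
published sketch of the HR assignment is incomplete; manganese ships with
HR 4 (expert judgment for a potent neurotoxicant without an IARC class).
ER is the CR band `<0.1, 0.1–0.5, 0.5–1, 1–2, ≥2 → 1..5`.

**COSHH.**  Control banding ignores measured concentration by design.  Risk
phrases map to hazard bands A–E (compound codes like R48/20 are keyed by
their first token; a chemical with no phrases defaults to band A as a
nuisance-level substance).  Exposure potential EP1–EP4 combines the quantity
band (default "medium" for an unattended run) with the solid's dustiness or
liquid's volatility band; gases count as high-volatility.  The band × EP
matrix returns CS1–CS4, which map to common levels 2–5, so only four levels
are attainable.

**ICMM / Australian / Romanian.**  The source methods leave their grids to
the evaluator, so reproducibility requires freezing one evaluator's tables:
they ship as editable YAML (`ohra/data/method_config.yaml`) and every result
file embeds the configuration checksum.  The shipped defaults are
reconstructions in the spirit of each source method, not published tables:

* ICMM: consequence (= hazard rating) × likelihood (CR band), product-banded
  `≤2, ≤5, ≤10, ≤15, >15 → 1..5`; an exposure-time weight (1–3, default 2)
  shifts the likelihood column.
* Australian: a 5×5×5 nomogram over likelihood (CR band), exposure frequency
  (EF band: `<10, 10–50, 50–100, 100–200, ≥200` days/year) and severity
  (= hazard rating), generated as `1 + 4·ln(l·e·s)/ln(125)` — the log-scaled
  Fine–Kinney-style product — and stored to two decimals; fractional levels
  are part of this method's scale.
* Romanian: severity 1–7 (hazard rating stretched via `(1,3,4,6,7)`) ×
  probability 1–6 (CR band with extra `2–5, ≥5` top bands), grid
  `min(7, ⌈s·p/6⌉)`.

Exhaustive brute-force oracles over every grid cell (25, 75, 125 and 42
cells) guard the shipped tables against silent edits.

## Harmonization

`RR = level / max_level`; five-level methods attain exactly
{0.2, 0.4, 0.6, 0.8, 1.0}.  The Romanian denominator defaults to **10**
rather than its seven-level maximum: published level→RR conversions for this
method consistently equal level/10 (4→0.4, 6→0.6, 3→0.3, 1→0.1), which
level/7 cannot produce.  Both modes are supported
(`--romanian-denominator 7|10`); neither is asserted as the original
authors' intent.  RR stays at full precision internally; reports round
half-up to one decimal, the precision published tables print.

## Statistics

All comparisons are rank-based (RR takes at most seven distinct values, so
ties dominate): Kruskal–Wallis with midrank tie correction and chi-square
p-values (H defined as 0 when every observation is identical), Mann–Whitney
with exact permutation enumeration when both samples have ≤ 8 observations
(valid under ties; ≈13k splits at most) and the tie-corrected normal
approximation otherwise, and midrank Spearman correlation with
pairwise-complete deletion — the EPA column is missing wherever no RfC
exists — reporting cells with fewer than three complete pairs as
not-computable rather than zero.  Tests are two-sided; raw p-values at
α = 0.05 are reported, matching common practice in this literature; a Holm
step-down adjustment is available but off by default.

## Verification against inherent risk

Industries carry catalog IR tiers (severe=1, medium=2, low=3; the shipped
mapping: mining and ferrous casting severe, ship and equipment repair
medium, petrol stations low).  Chemicals are ranked by ascending RfC
(smaller RfC = more severe inherent consequence), with two chemicals tied
when their RfCs lie within a factor of 5 **and** their observed CR ranges
overlap (similar exposure probability) — for the four focal toxicants this
yields manganese > benzene ≈ xylene > ethyl acetate.

"Consistent with the IR sequence" is not formally defined in the literature
this reproduces, so the report separates two components and flags both: (a)
weak ordering — every group in a higher-IR tier has a median RR at least
that of every group in a lower tier (ties allowed within a tier); (b)
adjacent-tier separation — at least one significant cross-boundary pairwise
test per adjacent tier pair.  `consistent` requires both;
`distinguishes_all` requires every off-diagonal pairwise p < α (monotone in
α by construction).  Users preferring a stricter or looser reading can apply
their own rule to the reported components.

## Synthetic generator

The generator expands a summary table — per job/location: n, mean, min, max
(mg/m³) — into records, emulating the canonical occupational-hygiene
concentration model, the lognormal:

* **sigma** from the range: the printed min–max is read as the expected
  extreme span of n draws, `sigma = ln(max/min)/(2z)` with z the
  standard-normal quantile at (n−0.5)/n;
* **mu** from the mean: `fit_lognormal` applies the plain moment condition
  `mu = ln(mean) − sigma²/2`; generation then recalibrates mu (Brent root
  find) so the **clipped** distribution's mean equals the printed mean,
  because draws are clipped to [min, max] and the printed mean describes
  data inside that range — for wide ranges (sigma ≈ 2, e.g. the xylene row)
  the unclipped fit is biased low by ~30%;
* **draws** are quantile-stratified: one jittered uniform per probability
  stratum, shuffled, pushed through the lognormal quantile function, then
  clipped.  Stratification pins each generated row to its target mean and
  range even at n ≈ 15, which is the point of emulating a summary table;
  the seed still controls every draw.  Degenerate rows (min = max) are point
  masses; a uniform option exists for sensitivity checks.

Per-row streams are seeded by hashing the global seed with (industry,
location, hazard), so editing one row never perturbs the others' samples.

The shipped spec (`ohra/data/five_industry_specs.csv`) instantiates a five-industry
study structure with 1,519 records.  Row counts follow the published
location counts with three small adjustments, documented in the file header,
so that the per-industry totals match the published record counts — the
published per-row and per-industry counts are not mutually consistent under
any single counting rule.

What this emulation does **not** reproduce: within-location correlation,
per-worker ET/EF/ED variation (all records carry the full-shift defaults),
seasonal or process trends, censoring at analytical detection limits, and
the real dataset's joint distribution across hazards.  Tests that pass on
this fixture therefore validate the pipeline's mechanics and the engines'
logic, not field performance on any real campaign.

## Registry defaults

The shipped registry covers the 13 hazards of the five-industry structure.
RfCs for the four focal toxicants are the published reference values
(manganese 0.05, benzene 30, xylene 100, ethyl acetate 3,500 μg/m³).  OELs,
acute-toxicity data and risk phrases are GBZ 2.1-2019 / ACGIH-style defaults
marked "placeholder" in the `notes` field; the loader logs them as
unconfirmed once per load.  Dusts without toxicological data carry
hazard-rating overrides representing frozen expert judgment.  Confirm all
placeholder values against authoritative sources before any regulatory use.

## Numerical conventions and degenerate inputs

* Rounding: half-up (0.25 → 0.3) at one decimal, only at reporting.
* Empty inputs: an empty registry or record set is a warning, not an error;
  an empty group in a statistical test is an error.
* A hazard missing the datum a method needs produces a skip with a recorded
  reason, never a silent default — e.g. EPA without RfC, the exposure-driven
  engines without the selected OEL, COSHH without a release band.
* Determinism: identical inputs and seed give byte-identical outputs; the
  method-config checksum stamped into results ties every number to the grid
  that produced it.

## Problem sizes

The shipped fixture (1,519 records → ~8,000 assessments) runs the full
simulate→assess→compare→verify pipeline in a few seconds on one CPU; the
test suite adds exhaustive grid oracles (≤ 125 cells each), exact
Mann–Whitney enumerations at n ≤ 8, and one 10,000-draw generator check.
These sizes were chosen as comfortably sufficient for the properties being
tested, since every assertion is either closed-form or far from its
tolerance at this scale.

## Known limitations

* The ICMM/Australian/Romanian grids are one frozen evaluator's judgment;
  different plausible grids change those methods' absolute RRs (though less
  so their orderings).  That sensitivity is inherent to the methods.
* Dataset-dependent statistics (medians, correlation coefficients) depend on
  the undeposited original campaign data; the toolkit reproduces their
  format and the structurally determined cells, not their exact values.
* CR-derived ratings make the qualitative engines exposure-aware; a site
  with evaluator-supplied ratings may score differently.
* Single-route (inhalation), single-chemical records: no mixture rule, no
  additive hazard index across co-exposures at a location.
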