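# Methods

`seafoodrisk` implements a deterministic, point-estimate dietary risk
assessment for contaminants measured in edible fish tissue, together with
composition-based source diagnostics and a synthetic survey generator. This
note records the model, its parameters, the numerical conventions, and the
design decisions taken where the underlying reporting conventions were
ambiguous or internally inconsistent.

## Exposure model

For an analyte with mean tissue concentration C (mg/kg), daily fillet
intake VIRd (g/day) and body weight BW (kg), the estimated daily intake is

* trace metals: `EDI = C · VIRd · (ED·EF) / (BW · AT)`
* organochlorine pesticides (OCPs): `EDI = C · VIRd / BW`

with exposure duration ED (years), exposure frequency EF (days/year) and
averaging time AT (days). The default averaging time is `AT = ED·EF`, which
makes the duration factor exactly 1 and the two formulas numerically
identical; they are kept as separate entry points because the metal formula
responds to non-default averaging times.

Default scenario (a Mexican adult consumer): VIRd = 32.88 g/day,
BW = 74.3 kg, ED = 26 y, EF = 365 d/y, AT = 9490 d.

**Arithmetic modes.** The intake formula is dimensionally incoherent if
VIRd is left in grams while C is in mg/kg: a coherent dose needs the 10⁻³
g→kg factor. Published report tables of this kind are routinely computed
*without* that factor, and the tables this package reproduces are among
them. Two modes are therefore exposed on the scenario:

* `paper_compat` (default): VIRd enters as a bare gram count; the EDI
  column of the reference report reproduces cell for cell at printed
  precision (13 of its 19 OCP rows; see the register below for the other
  six).
* `strict_si`: multiplies by 10⁻³, yielding EDI in mg per kg body weight
  per day. The relation `strict_si = paper_compat × 10⁻³` is exact.

## Risk indices

* **THQ** (metals): `THQ = (EF·ED·VIRd·C) / (RfD·BW·AT) × 10⁻³`. The
  denominator is the *product* RfD·BW·AT — the only dimensionally coherent
  form; the 10⁻³ is the g→kg intake conversion, applied exactly once.
  Concern threshold 1.
* **HI**: exact sum of metal THQs (`math.fsum`), with a contributor
  breakdown; any metal whose RfD is absent makes the aggregate `partial`
  and is listed by id.
* **HQ** (OCPs): `HQ = 100 · EDI / RfD`, concern threshold 100; **ΣHQ** is
  its exact sum.
* **ILCR**: `EDI × CSF`, flagged above 10⁻⁶.
* **CR_lim**: `ARL · BW / Σ(C·CSF)` in kg/day, also expressed in g/day and
  in 32.88-g meals/day. Default ARL = 10⁻⁵. Computed per analyte by
  default (matching per-row report values); pooling over an analyte set is
  an explicit option. `Σ(C·CSF) = 0` returns an infinite-allowance marker,
  never a division error.
* **MRL screening**: exceedance iff mean > upper MRL bound (strict
  inequality; sitting exactly on the bound is not an exceedance), with the
  fold-change. MRLs are compared only on the units/basis they were
  published on — there is no silent unit or dry/wet conversion.

All threshold flags use strict inequalities. Quantities whose toxicity
benchmark is absent return an explicit `NOT_COMPUTABLE` marker — never a
silent zero — and the pipeline logs every such marker.

**Safe-consumption inversion.** THQ, HQ and ILCR are linear in VIRd, so
the intake rate at which an index hits its threshold has the closed form
`VIR* = VIRd · threshold / index(VIRd)`; the forward recomputation at VIR*
returns the threshold to better than 1e-12 relative. Zero concentration
gives an infinite allowance. Consumption-rate sweeps recompute each rate
block independently and internally re-verify the linear scaling (to 1e-12
relative) as a regression guard.

## Source diagnostics

Within each OCP family the composition is the fraction of each member in
the family's summed mean concentration; ND members contribute their
nd-policy value (0 by default). Fractions are scale invariant. This
fraction-of-family-total definition was chosen because it reproduces the
published DDx (0.52/0.48) and chlordane (heptachlor 0.007, epoxide 0.003)
ratios exactly at printed precision.

Classification is a declarative rule per family (all thresholds live in
`ClassificationRules`), and every result carries the text of the rule that
fired:

* **DDx** — parent DDT fraction < 0.10 with DDE+DDD dominant → historical
  (DDT weathered away); DDT > 0.5 → recent.
* **drins** — dieldrin+endrin > aldrin → historical (aldrin oxidises to
  dieldrin); the reverse ordering → recent.
* **HCH** — all four isomers present with γ fraction < 0.5 → historical
  (aged technical HCH / lindane); γ ≥ 0.9 → recent lindane (the commercial
  product is 99 % γ).
* **chlordane** — heptachlor + epoxide share ≤ 0.1 × the γ-chlordane
  share → historical.
* **endosulfan** — sulfate metabolite present and the parent I:II split
  within ±0.20 (absolute, on the I fraction) of the 70:30 technical
  product → recent; sulfate only → historical. The tolerance default is
  0.20 rather than a tighter band because the reference survey's own
  profile (parent split 0.54:0.46, deviation 0.157 from 0.70) is
  classified as recent in the source literature; a ±0.15 band would
  reject the very case the rule was built to capture.

An all-zero family is *indeterminate*; anything else not matching a rule is
*mixed*. Divergence from a technical mixture is the total variation
distance ½Σ|fᵢ−tᵢ| on the common member set (a warning is emitted when the
member sets differ). The HCH technical fingerprint uses the midpoints of
the published manufacturing ranges (α 0.65, β 0.085, γ 0.125, δ 0.08);
these midpoints sum to 0.94 and are deliberately left unnormalised.

## Synthetic surveys

The generator emulates what the analysis assumes about real monitoring
data: per specimen × analyte, detection is Bernoulli(p); detected values
are lognormal(µ, σ); any value below the LOD is censored to the ND token
(internally a sub-LOD magnitude is drawn as lod·U(0,1) but never emitted).
The default layout is five quarterly collections totalling 86 specimens,
the scale of the study the package was built around. Seasonal effects are
multiplicative shifts of µ.

`survey_config_from_summary` inverts a published summary table into
generator parameters: p = frequency/100, σ² = ln(1+(s/m)²),
µ = ln m − σ²/2, and LOD = exp(µ−4σ) — deep enough in the lower tail
(≈3×10⁻⁵ mass) that censoring of genuine detects is negligible and the
observed detection frequency stays within sampling error of p. Records
with no usable SD get σ = 0.5, a typical spread for trace residues.

What the generator does *not* emulate: correlation between analytes,
specimen size/weight–concentration relationships, measurement error or
recovery rates of the analytical chemistry, and any real seasonal
structure (the default has none; multipliers are illustrative). Passing
recovery tests therefore shows the estimators are consistent under the
assumed hurdle-lognormal model — not that field data follows that model.

Summaries are computed two ways, because published tables rarely say which
they use: mean ± SD over detects only (default) or over all specimens with
NDs at their policy value. Parameter recovery is verified at n = 5,000
(frequency within 3 binomial SE of p; detect-mean within 3 SE of
exp(µ+σ²/2)) and the full pipeline runs end-to-end on generated data at
the study scale n = 86. These sizes keep the whole suite and the
acceptance script to a few seconds of runtime.

## Numerical conventions

* **Unit conversion** (mg/kg ↔ µg/kg) is a decimal-point shift computed
  through `Decimal(repr(x))`, not a float multiplication. A plain ×1000
  round trip loses the last ulp on ~2 % of doubles (and a float→float
  ×1000 map cannot be a bijection at all, by a pigeonhole argument across
  binades); the decimal shift restores every value with ≤ ~15 significant
  decimal digits — i.e. anything parsed from a data file — exactly.
* **Dry/wet basis** is metadata, never converted implicitly; conversion
  requires an explicit moisture fraction.
* **ND policy**: `zero` (default), `half_lod`, `lod`; the latter two
  require an LOD and fail loudly without one.
* **Rounding** for report cells is round-half-even at per-column precision,
  with unrounded twins in `*_raw` columns.
* **Aggregates** use `math.fsum`; empty aggregates are 0; a single marker
  contributor marks the aggregate partial rather than poisoning it.
* **Output ordering** is contaminant class then analyte id, making reports
  diffable across platforms and re-runs (the run metadata carries a config
  hash for bit-identical re-execution).

## Register of non-reproducible published values

The reference report's printed tables contain values that do not follow
from its own equations and inputs. They are recorded here and pinned by
tests (which assert the *recomputed* values, so a silent drift toward the
printed numbers fails):

* The metal summary table's EDI column (Cd 2.38, Cu 37.82, Fe 2.88,
  Pb 0.68 …) is not derivable from the metal intake formula under any unit
  convention tried; no intermediate values are given.
* The printed metal THQs sum to 3.46, not the printed HI = 2.84; the text
  attributes THQ 2.16 to Pb while the table lists 2.16 under Zn.
* The 120 g/day THQ triple (Pb 7.89, Cd 2.49, Zn 1.08) is inconsistent
  with the linearity of THQ in the intake rate: scaling the printed
  32.88 g/day column by 120/32.88 = 3.6496 gives different values.
* The OCP table's HQ column does not follow HQ = 100·EDI/RfD (aldrin
  prints 1.257487 where the equation gives 93.3), and its ΣHQ header value
  55.2 is not the sum of the printed column.
* Six OCP EDI cells (aldrin, p,p'-DDD, methoxychlor, γ-chlordane, α-HCH,
  β-HCH) recompute 2–5 % low at BW = 74.3 kg — consistent with BW ≈ 73 kg
  having been used — and are excluded from the reproduction set.
* The printed drin ratios (dieldrin 0.43, endrin 0.47, aldrin 0.1) are not
  derivable from the published concentrations under fraction-of-family
  normalisation (which gives 0.04/0.70/0.25); the α-chlordane ratio prints
  0.0007 where the data give 0.0009.
* Some printed CR_lim cells match ARL = 10⁻⁵, others 10⁻⁶ (aldrin prints
  0.0053 where ARL = 10⁻⁵ gives 0.005523); ARL is therefore configurable
  per run and the stated 10⁻⁵ is the default.
* The OCP concentration basis is labelled wet weight in the summary table
  and dry weight in a seasonal figure; the basis is carried as metadata
  and the discrepancy is not resolved here.
* Ni is described as below MRLs although its printed mean (8.06 mg/kg)
  exceeds its printed MRL upper bound (0.14 mg/kg); the strict
  mean > bound screen flags it, and the flag is intentional.

## Limitations

Point estimates only — no intake or body-weight distributions and no
Monte-Carlo layer. Linear low-dose cancer slopes only. No cooking-loss or
bioaccessibility adjustment. Metal RfD/CSF values are bundled regulatory
defaults (with provenance strings) and are configuration, not constants:
the reference report does not print them, so any metal THQ/ILCR depends on
the user's chosen benchmarks.
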