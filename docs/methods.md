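# Methods

## The model class and its assumptions

`halogem` analyses genome-scale metabolic models (GEMs) under the
steady-state, constraint-based framework. A model supplies a
stoichiometric matrix *S* (rows = metabolites, columns = reactions),
flux bounds *lb ≤ v ≤ ub* in mmol/gDW/h, boolean gene–protein–reaction
(GPR) rules, and a linear objective *c* — normally the biomass
pseudo-reaction, whose flux is the specific growth rate in 1/h. Flux
balance analysis (FBA) solves

```
max c·v   s.t.   S·v = 0,   lb ≤ v ≤ ub
```

All downstream protocols (variability, essentiality, media, envelopes)
are re-parameterisations of this LP. The framework assumes balanced
growth and optimality of the objective; it ignores kinetics and gene
regulation, so predictions are best-case capabilities, not rates the
organism necessarily realises. The package was built around the
analysis battery used for models of halophilic production organisms
(*Chromohalobacter*, *Halomonas*): minimal-medium reduction with a
CO₂-only secretion check, sole-carbon-source screens, anaerobic tests
with candidate electron acceptors, single-gene essentiality, and
growth-versus-production trade-offs for compatible solutes (ectoine,
5-hydroxyectoine) and storage polymers (PHB) probed through demand
reactions.

## Conventions and units

- All fluxes and bounds are mmol/gDW/h; biomass flux is 1/h. No unit
  conversion is ever performed.
- Exchange reactions: negative flux = uptake, positive = secretion. A
  medium maps exchange ids to maximal uptake rates; rate *u* is applied
  as lower bound −*u*, and every exchange not in the medium has uptake
  closed (lower bound 0) while secretion stays open.
- Exchange identification: SBO:0000627 when present, otherwise a
  single-metabolite stoichiometry together with an `EX_` id prefix.
  Demand (`DM_`, SBO:0000628), sink and biomass (SBO:0000629)
  pseudo-reactions are classified analogously and are exempt from mass-
  and charge-balance validation.
- SBML files are read and written through libSBML (Level 3 Version 1,
  fbc v2). Whatever bound encoding a file uses (±1000 or ±infinity) is
  preserved; bounds are defaulted to the conventional BiGG-style
  [−1000, 1000] / [0, 1000] only when a file omits them. BiGG-style
  `M_`/`R_`/`G_` prefixes are stripped on read and restored on write,
  and compartment suffixes (`_c`/`_p`/`_e`) serve only as a fallback
  hint when a species declares no compartment.
- GPR grammar: case-insensitive `and`/`or` with `and` binding tighter,
  the de-facto convention for FBC association strings. Parsing is a
  fixpoint under serialisation.

## Numerical choices

- All LPs are solved with HiGHS via `scipy.optimize.linprog`. The
  feasibility/optimality tolerance and the flux-is-zero threshold are
  both 1e-6, standard for double-precision LP on these problems.
- Growth calls use a zero-growth threshold of 1e-6 1/h: the literature
  convention is that "zero flux" means no growth, and 1e-6 separates
  true zeros from solver noise. Some studies prefer 1–5 % of wildtype;
  the threshold is therefore a parameter everywhere it is used.
- FBA returns one optimizer-chosen vertex. Alternate optima are
  ubiquitous, so every contract in the package is stated on objective
  values and FVA ranges, never on a particular flux vector.
- FVA holds the objective at `fraction · Z*` via one added inequality
  (`c·v ≥ fraction·Z* − 1e-6`; the slack guards against
  tolerance-level infeasibility at fraction exactly 1.0, and the same
  form is applied unchanged when `Z* < 0`). Production envelopes and
  phase planes instead pin the biomass flux exactly (`lb = ub = μ`),
  which keeps the toy envelopes on their closed-form lines to 1e-9.
- Blocked reactions are assessed on the model exactly as bounded (its
  declared exchange bounds, no objective constraint): a reaction is
  blocked iff its flux minimum and maximum are both within 1e-6 of
  zero; for irreversible reactions the minimisation is skipped since
  the maximum already pins the flux. A metabolite is blocked iff every
  reaction touching it is blocked, which includes orphan metabolites.
- Knockouts clamp disabled reactions to (0, 0) rather than removing
  them — equivalent for the optimum, cheaper to apply — and knockouts
  that disable the same reaction set share one LP solve.

## Protocol details that were genuinely open

- **Minimal medium.** Each non-carbon component of the full medium is
  closed alone and growth re-optimised; essential ⇔ growth < threshold;
  the carbon source stays open throughout. A per-component test cannot
  resolve interchangeable nutrients (two substitutable sources each
  test non-essential although one is needed), so a joint check follows:
  if the essential set does not support growth by itself, non-essential
  components are restored greedily in audit order until it does, and
  every restoration is flagged in the audit. Soundness (growth on the
  returned set; closing any essential member abolishes growth) is
  re-verified by the test suite after every run, and the optimum on the
  minimal medium is screened for secretion of carbon compounds other
  than CO₂ — species without a parseable formula are reported as
  `unknown-formula` rather than silently passed.
- **Carbon screen.** Candidates are tested one at a time at a uniform
  uptake of 10 mmol/gDW/h (the conventional benchmark rate) with all
  other candidates closed; candidates absent from the model are
  reported as "not in model" rather than dropped. Inorganic nutrients
  in shipped media are effectively unconstrained (1000 mmol/gDW/h)
  unless a medium says otherwise.
- **Production at "lowest possible growth".** `max_production` with
  `growth_requirement = 0` leaves biomass at its natural lower bound,
  so it reports the production capability with growth unconstrained;
  `run_fva` at `fraction → 0` reaches the same number, while fraction
  1.0 reports production compatible with optimal growth (usually 0).
  Both modes are exposed because published maxima for demand fluxes
  are conventionally quoted at minimal growth.
- **Validation battery.** Every stage runs on an independent copy of
  the model, so bound edits cannot leak between stages and the battery
  is deterministic. Flux-valued expectations compare at 0.01
  mmol/gDW/h, the two-decimal precision such rates are reported at;
  counts compare exactly. A stage crash marks its rows "error" and the
  battery continues — no configured row is ever dropped. Biomass
  composition adjustments for compatible solutes at different
  salinities are accepted only as user-supplied replacement
  coefficients; no formula is assumed for them.

## The synthetic fixtures and what they do (not) show

The generators in `halogem.synth` produce networks whose answers are
known in closed form: a linear chain (optimum = uptake bound; one
essential transporter gene vs. an isozyme pair), the chain with
interchangeable nitrogen sources and a dispensable substrate (minimal
medium and the greedy-repair degeneracy), a production branch whose
envelope is the exact line `product = yield_p · (uptake − μ/yield_b)`,
a two-resource toy obeying `growth = min(u_C, u_N)`, and seeded sparse
random networks (≤ 12 metabolites) with a hand-planted path that
guarantees a growing wildtype without rejection sampling. Random
networks are deterministic per seed down to byte-identical SBML.

These fixtures exercise every code path at desk scale, and the random
ensemble is cross-checked against independently formulated dense LPs
and against an independent COBRA toolchain. What they do not emulate:
genome-scale degeneracy (thousands of alternate optima), realistic
biomass compositions, cofactor/energy coupling, or annotation noise —
so passing the fixture tier demonstrates correctness of the
algorithms, not calibration of any particular organism's model. The
genome-scale tier of the test suite runs the shipped expectation
configuration against the deposited *C. canadensis* 85B model
(BioModels MODEL2204110001), which must be downloaded separately; that
test states its requirement explicitly and fails with instructions
when the file is absent.

## Problem sizes

The test suite and the acceptance script use the fixture scale
throughout: toy networks of 3–12 metabolites, ensembles of 100 random
networks for oracle equivalence, 11-point envelopes and ≤ 6-point
phase planes. These sizes make every quantity exactly checkable
against brute force while keeping the whole battery interactive (a few
seconds end to end).

## Known limitations

- One LP per FVA direction and per knockout; no warm-started batching.
  Genome-scale essentiality (~1200 genes) takes minutes, not seconds.
- No parsimonious FBA, MOMA/ROOM, thermodynamic or regulatory
  constraints, and no double knockouts.
- The SBML writer targets the fbc-v2 subset the analyses need
  (species, bounds, GPRs, objectives, SBO terms); model annotations
  (CV terms, notes) are not preserved.
- Mass/charge validation requires parseable formulas on every
  participant of a reaction; reactions with any unknown formula are
  skipped rather than guessed.
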