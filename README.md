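# halogem

Constraint-based analysis battery for genome-scale metabolic models
(GEMs), built around the simulation protocols used to characterise
halophilic production organisms such as *Chromohalobacter canadensis*:
flux balance analysis (FBA), flux variability analysis (FVA),
blocked-metabolite detection, minimal-medium determination with a
CO₂-only secretion check, sole-carbon-source growth screens, anaerobic
growth tests, single-gene essentiality, demand-reaction insertion for
compatible solutes (ectoine, 5-hydroxyectoine) and storage polymers
(PHB), and production envelopes / two-flux phase planes.

It is aimed at systems-biology practitioners who want these protocols
as a small, fully tested library and CLI rather than as notebook
glue. Models are read and written as SBML Level 3 with the
flux-balance-constraints (fbc) package; all linear programs are solved
with HiGHS through SciPy.

## The core computation

A GEM defines the LP

```
max c·v    subject to    S·v = 0,    lb ≤ v ≤ ub
```

with *S* the stoichiometric matrix, *v* the flux vector (mmol/gDW/h)
and *c* the objective — normally the biomass pseudo-reaction, whose
flux is the growth rate μ (1/h). Everything else in the package is a
re-parameterisation of this program: FVA minimises/maximises each flux
with `c·v ≥ fraction·Z*` added; a gene knockout clamps to zero every
reaction whose boolean GPR rule evaluates false; a medium sets
exchange lower bounds (negative flux = uptake); production envelopes
pin μ on a grid and extremise a target (demand) flux.

## Worked example

```python
from halogem import (
    Medium, build_system, solve_fba, production_envelope,
    single_gene_essentiality, make_production_branch, make_chain,
)

# a toy network: 10 mmol/gDW/h of carbon split between biomass and a
# product demand (both at yield 1)
model = make_production_branch(uptake=10, yield_biomass=1, yield_product=1)
medium = Medium({"EX_A_e": 10})

growth = solve_fba(build_system(model)).objective_value
print(f"wildtype growth: {growth:.2f} 1/h")

env = production_envelope(model, medium, "DM_P_c", n_points=5)
for mu, lo, hi in env.points:
    print(f"biomass {mu:5.2f}  product max {hi:5.2f}")

screen = single_gene_essentiality(make_chain(1, 10), Medium({"EX_A_e": 10}))
print("essential genes:", sorted(screen.essential))
```

prints

```
wildtype growth: 10.00 1/h
biomass  0.00  product max 10.00
biomass  2.50  product max  7.50
biomass  5.00  product max  5.00
biomass  7.50  product max  2.50
biomass 10.00  product max  0.00
essential genes: ['g1']
```

— the envelope is the exact trade-off line `product = uptake − μ`
(every carbon atom goes either to biomass or to product), and the
only essential gene is the sole transporter `g1`; the isozymes
`g2`/`g3` back each other up.

The same operations run from the shell:

```
halogem make-fixture --kind production_branch --out toy.xml
halogem fba toy.xml --medium medium.json
halogem envelope toy.xml --medium medium.json --target DM_P_c
halogem essentiality toy.xml --medium medium.json
halogem validate model.xml --config expectations.json
```

## Analysing the deposited *C. canadensis* 85B model

The genome-scale model iEB1159 is deposited in BioModels under
accession `MODEL2204110001` (also on GitHub at
`Angione-Lab/GEM-Chromohalobacter-canadensis-85B`). It is too large to
redistribute here; download it to `models/MODEL2204110001.xml` and run

```
halogem validate models/MODEL2204110001.xml \
    --config src/halogem/data/iEB1159_expectations.json
```

The shipped configuration encodes the published expectations for that
model — 1159 genes, 37 blocked metabolites, 27 growth-supporting
carbon sources (with lactose and citrate negative), 60 essential
genes, no anaerobic growth with or without nitrate, and production
maxima of 12.35 mmol/gDW/h (PHB) and 7.05 mmol/gDW/h (ectoine) at
minimal growth. The genome-scale tier of the test suite runs this same
battery and reports how to obtain the file when it is absent.

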