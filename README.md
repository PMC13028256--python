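# fruitfba

Constraint-based metabolic analysis of ripening fruit: flux balance
analysis (FBA) with a ripening-quality objective, transcriptome-weighted
parsimonious flux minimization, and detection of **regulatory lever**
reactions — reactions a ripening fruit cannot switch off even when their
genes are transcriptionally down-regulated.

It is written for plant and postharvest systems biologists who want to
interrogate fruit mesocarp metabolism (the worked fixtures model peach
nectarine varieties across cold-storage transitions) without a growth
objective: mature fruit does not grow, it *ripens*.

## The model

A curated reaction network (tab-delimited table: reaction id, equation
with compartment-suffixed metabolites `_c`/`_m`/`_v`, GPR rule,
subsystem) is analyzed at steady state:

```
max / min  c·v     s.t.   S·v = 0,   lb ≤ v ≤ ub
```

Instead of biomass, the objective is a ripening-quality sink (RQS)
pseudo-reaction that couples four ripening traits,

```
chlorogenate_c + cyanidin_c + ethylene_c + galacturonate_c → ∅
```

under a maintenance regime: a non-growth-associated maintenance (NGAM)
ATP demand with a strictly positive floor (1.0 mmol·gDW⁻¹·h⁻¹), reserve
mobilization pools capped at a common upper bound (10.0), and citrate and
chlorogenate mobilization blocked so the network must synthesize de novo.

Differential-expression contrasts enter as *soft* penalties. Genes are
classified up/down/neutral (|log2FC| ≥ 1 plus significance, by default),
classes propagate through GPR rules (complexes = AND → worst subunit;
isoenzymes = OR → best isoform, conflicting evidence → mixed), and each
reaction gets a weight `w` with `w(down) > w(mixed) > w(neutral) > w(up)`.
The transcript-penalized parsimonious problem at fixed ripening output is

```
min  Σᵢ wᵢ·|vᵢ|    s.t.   S·v = 0,  bounds,  v_RQS = 1
```

A reaction is a **lever** in a contrast iff (a) its class is `down` and
(b) flux-variability LPs show its flux cannot reach zero while the RQS is
sustained — so lever status is structural and independent of the weight
scheme; weights only shape the reported flux distribution. Magnitudes are
normalized per unit RQS flux; directions (`-->`/`<--`) come from the
penalized solution.

Because the full published fruit network is not reproducible from text,
the package ships a reduced reference model (65 reactions, 74
metabolites, 9 metabolic processes from glycolysis and the TCA cycle to
the shikimate, phenylpropanoid, flavonoid, ethylene, pectin and
glutathione pathways) plus four seeded synthetic expression contrasts
(`MG/RP × E1vsE2/E3vsE4`) that reproduce the published lever layout.

## Worked example

```python
from fruitfba import CONTRAST_IDS, build_reference_model, run_contrast_analysis
from fruitfba.reference import scenario_contrast

model = build_reference_model()
report = None
for cid in CONTRAST_IDS:
    part = run_contrast_analysis(model, scenario_contrast(cid, seed=42))
    report = part if report is None else report.merge(part)
print(report.to_frame().to_string(index=False))
```

prints

```
reaction_id  contrast class  required  normalized_magnitude    direction
      QDH_c MG_E1vsE2  down      True               2.00000      reverse
    EPSPS_c MG_E1vsE2  down      True               2.00000 irreversible
      HQT_c MG_E1vsE2  down      True               1.00000      forward
      CAS_c MG_E1vsE2  down      True               1.00000 irreversible
      QDH_c MG_E3vsE4  down      True               2.00000      reverse
      HQT_c MG_E3vsE4  down      True               1.00000      forward
      QDH_c RP_E1vsE2  down      True               2.00000      reverse
   PPA_AT_c RP_E1vsE2  down      True               2.00000 irreversible
      HQT_c RP_E1vsE2  down      True               1.00000      forward
      CAS_c RP_E1vsE2  down      True               1.00000 irreversible
      ACO_m RP_E3vsE4  down      True               0.62069      forward
      FUM_m RP_E3vsE4  down      True               0.62069      forward
      HQT_c RP_E3vsE4  down      True               1.00000      forward
      CAS_c RP_E3vsE4  down      True               1.00000 irreversible
       GR_c RP_E3vsE4  down      True               3.00000 irreversible
```

Read: hydroxycinnamoyl-CoA quinate transferase (HQT) must carry one unit
of forward flux per unit of ripening output in **every** contrast — the
fruit keeps routing carbon to p-coumaroylquinate and chlorogenate even as
HQT transcription falls. Quinate dehydrogenase (QDH) must run in reverse
(net quinate → dehydroquinate, two units: one aromatic ring for the
chlorogenate acyl moiety, one for cyanidin) in three contrasts, but is
*not* a lever in RP E3vsE4, where its gene flips to up-regulated after
chilling — the contrast in which chilled fruit accumulates quinate. The
lever union across contrasts is exactly eight reactions.

More narrative scripts live in `examples/` (FBA on the reference model,
expression classification, lever detection, growth rates). A thin CLI
wraps the same calls:

```
fruitfba init-demo --out demo/
fruitfba fba    --model demo/reference_model.tsv --config demo/config.json
fruitfba levers --model demo/reference_model.tsv --contrast demo/MG_E1vsE2.tsv
```

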