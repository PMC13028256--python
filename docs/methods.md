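# Methods

## The model and its assumptions

`fruitfba` treats ripe fruit mesocarp as a non-growing, heterotrophic
sink tissue at metabolic steady state. The network is a set of reactions
over compartment-suffixed metabolites (`_c` cytosol, `_m` mitochondrion,
`_v` vacuole) with signed stoichiometry, flux bounds in mmol·gDW⁻¹·h⁻¹,
and optional boolean gene–protein–reaction (GPR) rules. All analyses are
linear programs over the steady-state polytope `{v : S·v = 0, lb ≤ v ≤ ub}`,
solved with scipy's HiGHS backend (single-threaded and deterministic; the
cross-check in the test suite uses cobrapy/GLPK as an independent
implementation, never as the engine).

Because the tissue does not grow, there is no biomass reaction. Two
pseudo-reactions define the physiological regime instead:

- **NGAM** (`NGAM_c`, ATP + H₂O → ADP + Pi + H⁺) with a strictly positive
  lower bound, default 1.0 mmol·gDW⁻¹·h⁻¹: the cell must pay a
  maintenance cost at all times.
- **RQS** (`RQS`, chlorogenate_c + cyanidin_c + ethylene_c +
  galacturonate_c → ∅): the ripening-quality objective. Unit
  coefficients mean one "unit of ripening" requires one unit of each
  trait simultaneously; maximizing or fixing RQS flux couples the
  phenylpropanoid, flavonoid, ethylene and cell-wall branches.

Stored reserves enter through `POOL_*` mobilization reactions (∅ → met),
all capped at a common `pool_upper_bound`, default 10.0. The default is a
deliberate design value: it must comfortably exceed the per-unit-RQS
draw of every reserve (the largest is hexose at ≈3.8 per RQS unit) so
that pools do not bind at the working point `v_RQS = 1`, while still
making the FBA maximum finite. Citrate and chlorogenate mobilization are
blocked (bounds (0,0)) by default so that neither respiration nor the RQS
can be fed from reserves directly. Environmental boundary exchanges
(`EX_O2`, `EX_CO2`, `EX_H2O`, `EX_H`, the cyanoalanine sink) are *not*
pools: gas and water exchange is diffusion, not reserve mobilization, and
is left wide open.

## Expression integration

Per-gene log2 fold-changes are classified `up` (log2FC ≥ θ), `down`
(≤ −θ) or `neutral`, with θ = 1.0 by default and, by default, only for
genes flagged significant. Classes aggregate through GPR trees:

- AND (complex): the most-penalized subunit wins (`down` > `mixed` >
  `neutral` > `up`) — a complex is only as available as its scarcest part;
- OR (isoenzymes): the least-penalized isoform wins, **except** that
  strictly conflicting children (some up, some down) yield `mixed`;
- empty GPR (pools, transport, NGAM, RQS): always `neutral` — transcripts
  carry no evidence about pseudo-reactions.

One consequence is documented explicitly: the aggregation is monotone
under relieving a down-regulated gene (down → neutral never raises the
penalty) but deliberately *not* under neutral → up, which can surface an
isoenzyme conflict and raise the class from neutral to mixed. That is the
intended conservative treatment of ambiguous evidence, not an accident.

Classes map to weights; only the ordering `w(down) > w(mixed) >
w(neutral) > w(up) > 0` is meaningful. The default scheme
{down 2.0, mixed 1.5, neutral 1.0, up 0.5} is one admissible choice; the
lever set is provably identical under any admissible scheme (see below),
and the test suite checks this with schemes at ratio spreads up to 10×.
Penalties are soft: no reaction is ever forced on or off by transcripts.

## Lever detection

The transcript-penalized parsimonious problem fixes `v_RQS = 1` and
minimizes `Σ wᵢ|vᵢ|`, linearized with auxiliary variables `tᵢ ≥ |vᵢ|`
(equivalent to the usual forward/reverse split for positive weights).
`rqs_target = 1` rather than the FBA maximum makes "flux per unit RQS"
well-defined and independent of where pool bounds happen to bind; the FBA
maximum is still computed first as a feasibility gate and logged in the
report metadata.

A reaction is a **regulatory lever** in a contrast iff

1. its reaction class is `down`, and
2. its minimum attainable |flux| subject to `v_RQS ≥ 1` exceeds
   ε = 1e-6 (after snapping solver noise below 1e-6 to zero).

Condition 2 is evaluated by a flux-variability pair of LPs per candidate
reaction, never by inspecting one optimal vertex: FBA optima are
degenerate, and a single solution's support is solver-dependent.
Requiredness is therefore structural — weights affect which reactions are
*candidates* (via classes) and the reported direction/magnitude (via the
penalized solution), but not whether flux is avoidable. Reported
magnitudes are |v|/v_RQS; directions are `forward`/`reverse` for
reversible reactions (sign of the penalized flux) and `irreversible`
otherwise.

## The reference network

The shipped reference model (65 reactions, 74 metabolites, 40 genes) is a
reduced, fully connected stand-in for a full fruit genome-scale model,
spanning nine processes: glycolysis (lumped to PEP, ATP-neutral, then
pyruvate kinase), an oxidative-pentose-phosphate lump as the NADPH
source, a complete TCA cycle, lumped oxidative phosphorylation (P/O 2.5),
the shikimate pathway, phenylpropanoid/chlorogenate synthesis, the
flavonoid route to cyanidin, ethylene biosynthesis (lumped Yang cycle)
with β-cyanoalanine cyanide detoxification, pectin degradation to
galacturonate, and glutathione redox. Structural devices, each asserted
by test rather than assumed:

- **Chlorogenate** is reachable only through HQT (p-coumaroyl-CoA +
  quinate → p-coumaroylquinate) followed by 3'-hydroxylation, so HQT
  carries exactly 1 forward flux per RQS unit.
- **Dehydroquinate** has a single source: quinate dehydrogenase (QDH)
  run in reverse against its written direction (dhq + H⁺ + NADH ⇌ NAD⁺ +
  quinate). There is no erythrose-4-P/DAHP entry into the shikimate
  pathway; vacuolar quinate reserves feed everything aromatic. Per RQS
  unit the network builds two aromatic rings (chlorogenate's caffeoyl
  moiety and cyanidin), so QDH flux is exactly −2. Total quinate draw is
  3: two through QDH, one as the chlorogenate ester moiety.
- **Cyanide coupling**: the ACC-oxidase lump co-produces HCN with
  ethylene; β-cyanoalanine synthase (CAS) is its only sink, so CAS flux
  equals ethylene flux. The H₂S released by CAS is recycled into
  cysteine synthesis, closing the sulfur loop.
- **Glutathione coupling**: the two phenylpropanoid hydroxylases each
  oxidize 2 GSH → GSSG; glutathione reductase (GR) is the only GSSG
  consumer, so GR flux is pinned at 3 per RQS unit (two C4H events, one
  C3'H event).
- **Forced respiration**: cytosolic NADH is re-oxidized only by a
  non-phosphorylating external dehydrogenase (the alternative-oxidase
  route prominent in climacteric fruit), so substrate-level ATP (≈3
  units via pyruvate kinase at v_RQS = 1) cannot cover the ATP demand of
  maintenance plus biosynthesis (12 units). Mitochondrial NADH arises
  only from a complete TCA turn (oaa regeneration requires
  MDH ← FUM ← SDH ← … ← ACO ← CS), which forces ACO and FUM to carry
  equal flux t satisfying 14.5·t + 3 = 12, i.e. t = 9/14.5 ≈ 0.6207 per
  RQS unit at the default NGAM.
- Every enzymatic reaction carries a synthetic single-gene GPR
  (`G_<reaction id>`); the two focal enzymes use their published gene
  ids (HQT: Prupe.3G101000, QDH: Prupe.6G166100). Transport, pools and
  pseudo-reactions have none.

Known divergences from the reported full-network values: with two
aromatic sinks the reduced model yields EPSPS = PPA_AT = 2 and GR = 3
per RQS unit where the full-network analysis reports 1, and ACO/FUM
carry ≈0.62 versus 0.3 — these magnitudes depend on network
completeness (parallel aromatic entries, full energetics) and are not
claims of this package; the HQT = 1 and QDH = 2 magnitudes are
stoichiometrically pinned and are.

## Synthetic expression scenarios

`scenario_contrast(contrast_id, seed)` emulates the four variety ×
transition comparisons (MG/RP × E1vsE2/E3vsE4). Gene *classes* are fixed
per contrast (seed-independent): each focal gene is `down` exactly in the
contrasts where its reaction behaves as a lever in the published layout,
QDH's gene flips to `up` in RP E3vsE4, all other model genes are
neutral, and 12 decoy genes (unattached to any reaction) cycle through
down/neutral/up to give the classifier off-model content. Log2
fold-changes are drawn per class — down: N(−2.0, 0.3), up: N(+2.0, 0.3),
neutral: N(0, 0.2), with significance flags true only for up/down — so
effect sizes sit >3σ from the ±1 threshold and classes are recovered
from draws in ≥99% of cases. What the generator does *not* emulate:
count-level noise, dispersion estimation, p-value computation,
correlated co-expression, or the genome-wide scale (tens of genes, not
~15k). Passing tests therefore demonstrate the pipeline's logic, not
robustness to realistic RNA-seq error structure.

## Numerical choices

- LP backend HiGHS, presolve on; bounds at ±1000 keep every LP bounded.
- Reported fluxes below 1e-6 are snapped to zero; lever activity uses
  ε = 1e-6 on top of that, two decades above solver tolerance.
- Stoichiometric coefficients compare at 1e-9 so formatting differences
  never break round trips.
- Equations net-sum metabolites appearing on both sides; an equation that
  nets to nothing is an error.
- Infeasible/unbounded solves return a status, never a zero vector.
- `min_required_flux` distance-from-zero is `max(0, v_min, −v_max)` over
  the flux range, which handles forward-required, reverse-required and
  non-required reactions uniformly.

## Problem sizes

All shipped analyses are desk-scale by construction: the reference model
has 65 reactions (66 with RQS), each contrast analysis solves one FBA
gate, one weighted LP (~130 variables) and two LPs per down-classified
reaction; the full four-contrast run completes in a few seconds on one
CPU, and the whole test suite (including property-based cases and the
cobrapy cross-checks) in well under a minute.

## Limitations

- The reference network is a reduced surrogate; census-level claims
  (reaction/metabolite/gene counts of a full reconstruction) are out of
  scope, as are elemental/charge balancing and gap-filling.
- No thermodynamic (loopless) constraints beyond irreversibility; no
  MILP-style discrete expression integration (penalties are soft by
  design); no flux sampling or kinetics.
- Lever magnitudes other than HQT and QDH are surrogate-dependent (see
  divergences above).
- SBML export is an extension point, not implemented; the tab-delimited
  table is the interchange format.
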