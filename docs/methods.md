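# Methods

`meflux` implements the in-silico half of a growth-coupled strain design
for synthetic methylotrophy in *E. coli*: find knockout genotypes for
which a multi-carbon co-substrate can no longer support growth on its own,
while growth is restored when methanol is additionally assimilated through
a heterologous ribulose-monophosphate (RuMP) entry — NAD-dependent
methanol dehydrogenase (Mdh), 3-hexulose-6-phosphate synthase (Hps) and
6-phospho-3-hexuloisomerase (Phi). It also implements the two companion
analyses used to characterize such strains: average ¹³C labeled fractions
from isotopologue distributions, and specific methanol uptake rates from
evaporation-corrected depletion curves.

## Flux balance analysis

Growth is predicted by FBA: maximize the flux through a lumped biomass
reaction subject to steady state `S·v = 0` and flux bounds, solved with
the HiGHS simplex through `scipy.optimize.linprog`. Exchange reactions
follow the usual convention (negative flux = uptake). Only the objective
value is treated as well-defined; flux vectors are generally degenerate
and are never asserted in tests except where uniqueness is forced.
Infeasible LPs are mapped to zero growth with a logged warning so that
knockout screens are total; numerically failed solves raise. Tolerances:
HiGHS primal/dual feasibility 1e-9; a 1e-6 "zero flux" threshold is used
only for printing, never for growth-threshold comparisons.

## The packaged core model

The screen runs on a hand-built reduced *E. coli* network (73 reactions,
62 metabolites, 15 exchanges) rather than a genome-scale model: it is
self-contained, fast enough for exhaustive enumeration cross-checks, and
reproduces the pathway logic that the design rests on. It contains
gluconate entry (GntT/GntK), the Entner–Doudoroff (ED) pathway, the
oxidative PPP (lumped Zwf+Pgl, and Gnd), the full reversible
non-oxidative PPP (Rpi, Rpe, TktA/B ×2, Tal), glycolysis and
gluconeogenesis, pyruvate dehydrogenase, a complete TCA cycle with both
malate dehydrogenase activities (NAD-dependent Maldh and quinone-linked
Mqo) and the glyoxylate shunt, PEP carboxylase/carboxykinase and malic
enzyme, acetate overflow (reversible Pta–AckA and acetate transport),
uptake routes for glucose, glycerol, pyruvate, ribose, xylose, succinate
and acetate, a lumped respiratory chain (P/O = 2 for NADH, 1 for the
flavin-linked steps), a transhydrogenase restricted to the NADPH→NADH
(SthA) direction, and a tetrahydrofolate-linked C1 spur (spontaneous
HCHO–THF condensation, reversible glycine cleavage, serine
hydroxymethyltransferase, serine deaminase).

Deliberate modeling choices, and why:

* **Biomass** draws the branch-point precursors PEP, pyruvate,
  acetyl-CoA, oxaloacetate and 2-oxoglutarate (≈ 29 C-mmol gCDW⁻¹)
  plus NH₄⁺ (10), ATP (40) and NADPH (18 mmol gCDW⁻¹). Keeping
  sugar-phosphate precursors out of the biomass confines the co-substrate
  coupling logic to the pathway branch points the screen is about;
  with hexose/pentose precursors included, a reduced network acquires
  large families of bookkeeping-driven knockout "solutions" that say
  nothing about the underlying design principle.
* **Gnd is reversible.** This lets surplus pentose phosphate drain back
  to 6-phosphogluconate and leave through the ED pathway — precisely the
  escape that the *edd* knockout closes. Without it, deleting Rpi alone
  already blocks gluconate growth (the C5 pool dead-ends), and the
  design would not need the *edd* cut at all.
* **The THF/serine spur** gives formaldehyde a pentose-cycle-independent
  assimilation route (net 2 HCHO + CO₂ + NADH → pyruvate). This reflects
  a capability of genome-scale *E. coli* networks that a canonical
  RuMP-only core lacks: net ribulose-5-phosphate regeneration from
  hexose/triose requires ribose-5-phosphate isomerase, so a ΔrpiAB
  genotype could never retain pure methylotrophic growth without some
  such bypass. With the spur, Δedd ΔrpiAB grows on methanol alone, as
  required of the design.
* **Overflow outlets** (acetate, succinate export) prevent spurious
  lethality from closed redox books — a reduced network without
  fermentative outlets couples NADH balancing to growth much more
  rigidly than a genome-scale model does.
* Carbon accounting tracks substrate-derived skeletons only: carrier
  moieties (CoA, NAD(P), adenosine, THF) count zero carbons. Every
  internal (non-exchange, non-biomass) reaction is carbon-balanced under
  this convention, enforced by tests. Proton/charge balancing is not
  audited. Growth rates are qualitatively sensible (≈ 0.94 h⁻¹ on
  gluconate at 7 mmol gCDW⁻¹ h⁻¹, ≈ 0.23 h⁻¹ on methanol) but not
  calibrated to measured rates; all screening decisions compare rates
  against the 0.01 h⁻¹ threshold or against each other.

## The essentiality screen

A deletion set is classified from three growth rates at 7 mmol gCDW⁻¹
h⁻¹ per carbon source: μ_co (co-substrate only), μ_co+MeOH (co-substrate
plus methanol) and μ_MeOH (methanol only), with the no-growth threshold
ε = 0.01 h⁻¹:

* **methanol-essential** — μ_co ≤ ε, μ_co+MeOH > ε, methanol genuinely
  rescues *co-substrate-dependent* growth (μ_co+MeOH − μ_MeOH > 10⁻⁴
  h⁻¹, a margin far above LP noise and far below any real substrate
  contribution), and methylotrophic potential is retained
  (μ_MeOH > ε);
* **non-rescuable** — no growth even with methanol, or methanol merely
  substitutes for the co-substrate (e.g. a gluconate transporter
  knockout, after which growth with methanol equals growth on methanol
  alone). These are discarded;
* **neutral** — grows on the co-substrate; carries a differential
  fitness score μ_co+MeOH − μ_co used for ranking.

The coupling margin is the package's resolution of an ambiguity: on any
model that grows on methanol alone, "rescued by methanol" must mean more
than μ_co+MeOH > ε, or every co-substrate-entry knockout would count as a
design.

The search is a beam search over reaction-deletion sets: screen all
single deletions, rank neutral candidates by differential fitness
(ties lexicographic), keep the best `beam_width` sets, extend each by one
further deletion, and stop at the first depth at which methanol-essential
genotypes appear (or at `max_depth`). Every reported genotype is
re-verified with fresh FBA calls. The default beam width is 16: deletions
of the ED-entry reactions are *exactly growth-neutral* on gluconate (the
reversible non-oxidative PPP supplies Ru5P carbon-neutrally, so the cut
lowers μ_co and μ_co+MeOH symmetrically), which places them inside the
neutral tie block of the ranking; the default width keeps that whole
block in the frontier, and the test suite verifies that the beam then
returns **exactly** the minimum-cardinality solution sets found by
exhaustive enumeration. A narrower beam (e.g. 5) finds the pentose-side
designs, including the Δedd ΔrpiAB anchor, but misses the
lower-glycolysis alternatives.

Results are reported at reaction level and mapped to genes: for a
reported reaction set, all inclusion-minimal gene sets that deactivate
exactly those reactions (and nothing else) are derived from the GPR
rules; Δ{EDD, RPI} maps to {edd, rpiA, rpiB} since the two isomerase
isozymes must both be removed.

On the packaged model the gluconate screen returns 18 minimum-size
genotypes: {EDD | EDA} × {RPI, RPE, TKT1, TKT2, TAL, GAPD, PGK, PGM,
ENO}. The ED pair members are interchangeable because a KDPG-aldolase cut
silences the dehydratase through its dead-end product; the second member
either blocks the C5 exit of the forced Gnd route or severs lower
glycolysis so that only methanol-derived carbon (via the serine spur) can
reach pyruvate. Acetate is the one co-substrate with single-reaction
solutions (ΔFUM, ΔSUCDH): the glyoxylate shunt's net output is
succinate, which must re-enter C4 metabolism through those two steps.
All other co-substrates require at least two deletions.

## Labeling analytics

For an n-carbon pool with isotopologue abundances A₀..Aₙ the average
labeled fraction is `Σᵢ i·Aᵢ / (n·ΣᵢAᵢ)`. Measured distributions are
first corrected for natural ¹³C (a = 0.0107, configurable) by inverting
the lower-triangular binomial mixing matrix
`M[j,i] = C(n−i, j−i)·a^(j−i)·(1−a)^(n−j)` (observed = M·true). The
correction is carbon-only — H/O/N isotope contributions are not
modeled — and small negative corrected intensities (noise artifacts) are
clipped to zero with a warning, then renormalized to the input total.
Under equimolar co-assimilation of methanol with a C6 substrate each
hexose unit carries one methanol carbon, giving the expected fraction
1/6 (17% at half-up nearest-percent rounding) and, assuming no carbon
loss, a 17% higher maximal biomass than the C6 substrate alone.

## Physiology estimators

Growth rates come from ordinary least squares on ln(OD₆₀₀) vs time; OD
converts to cell dry weight at 0.33 gCDW L⁻¹ per OD unit (the 0.25
factor sometimes used for metabolome normalization is deliberately not
used here). The specific uptake rate over a window [t₁, t₂] divides the
abiotic-corrected substrate decrease (culture minus a non-consuming
evaporation-control culture) by the biomass integral:

    q = (ΔS_culture − ΔS_evap) · μ / (X₀ · (e^{μt₂} − e^{μt₁}))

This is the exact mass-balance form of dividing the interval rate by
X₀·e^{μt}; the literal evaluation at the window midpoint is available as
an option and converges to the integral form as the window shrinks
(verified in tests). If μ ≤ 0 the denominator falls back to the mean
biomass X₀·(t₂−t₁) with a warning. Uncertainty follows the first-order
variance formula over the four concentration readings and the growth-rate
standard error.

## Synthetic data

The culture generator produces exponential OD series with multiplicative
Gaussian noise (CV-parameterized — the measurements it emulates are
reported as mean ± sd without a distributional claim), and methanol
series combining a linear abiotic evaporation term (shared with the
control culture, as in an evaporation-control design) with the biomass-
integral consumption term. Defaults are the methanol-essential strain
conditions: μ = 0.081 h⁻¹, q = 13 mmol gCDW⁻¹ h⁻¹, 500 mM initial
methanol, 0.5 mM h⁻¹ evaporation, 1% CV noise, 8 samples over 36 h from
X₀ = 0.08 gCDW L⁻¹ — an inoculum and duration chosen so the biotic
depletion (≈ 200 mM) is large against the noise floor of the two-point
estimator. The isotopologue generator draws tracer labels binomially over
a chosen number of methanol-derived positions (per-position probability
scaled so the molecule-average fraction is the requested one) and smears
the result with the same natural-abundance matrix the correction inverts,
so the noise-free analysis round trip is exact by construction — passing
round-trip tests validate the algebra, not the mass spectrometer.

What the generators do *not* emulate: stationary-phase plateaus, lag
phases, substrate-dependent noise structure, peak-integration artifacts,
or non-carbon isotope effects. Parameter-recovery results on this
synthetic data therefore demonstrate estimator correctness and noise
propagation, not instrument-level accuracy on real cultures.

## Known limitations

* The core model is a topology instrument: absolute growth rates and
  yields are not calibrated, and knockout phenotypes outside the central
  pathways it contains (e.g. regulatory effects the source strains show
  on pyruvate) are out of scope.
* Thermodynamic (ΔG-constrained) analysis is not implemented; the
  unfavorable standard energy of NAD-dependent methanol oxidation enters
  only as narrative motivation for the low-TCA-activity (Δmaldh) design,
  whose stoichiometric viability `verify_reaction_dispensability`
  confirms.
* Gene-level reporting enumerates minimal gene cut sets only for rules
  of ordinary GPR size; rules with more than 12 genes are not enumerated.
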