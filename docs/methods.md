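# Methods

## Model

The package implements a segment-based solvation model of the COSMO-RS
family. A species is represented solely by its sigma profile `p_X(σ)`:
surface area per bin of screening charge density σ, discretised on a
uniform grid over σ ∈ [−0.025, +0.025] e/Å² with 0.001 spacing (51 bins),
the convention of the open sigma-profile databases. Profiles store areas
(Å² per bin); ensemble probability distributions appear only after mixing,

    P_S(σ) = Σ_i x_i p_i(σ) / Σ_i x_i A_i ,

so mole-fraction weighting and segment counting (area / a_eff) stay
unambiguous.

Surface-segment contacts interact through an electrostatic misfit penalty
and a hydrogen-bond term,

    E_misfit(σ, σ′) = a_eff (α′/2) (σ + σ′)²           ≥ 0
    E_hb(σ, σ′)     = a_eff c_hb min(0, σ_don + σ_hb)
                                max(0, σ_acc − σ_hb)   ≤ 0 ,

with the donor taken as the more negative member of the pair (hydrogen
atoms screen negatively) and the acceptor as the more positive. A
compound-additive van der Waals term `a_eff (τ + τ′)` exists behind
`vdw_mode`; because it cancels identically between the mixture and the
pure-liquid reference it is off by default and no τ values are shipped.

Segment chemical potentials of a solvent ensemble solve the
self-consistency equation

    μ_s(σ) = −RT ln Σ_σ′ P_S(σ′) exp[(μ_s(σ′) − E(σ, σ′)) / RT] .

μ is stored per segment (kcal/mol); dividing by a_eff gives the per-area
sigma-potential curve. Two typographic ambiguities in the source
formulation were resolved on dimensional grounds: the prefactor is
−RT/a_eff on the per-area scale (equivalently −RT on the per-segment scale
used internally, where the equation coincides with the standard
segment-activity-coefficient form ln Γ(σ) = −ln Σ P Γ e^{−E/RT}), and all
σ thresholds (±0.01 region boundaries, the −0.018/+0.012 solute peaks,
σ_hb) are in e/Å², not the "e/nm²" sometimes printed for the same
magnitudes — those values are only meaningful on the Å² scale.

The activity coefficient of solute X in solvent S uses the symmetric
(pure-liquid) reference

    ln γ = [μ_X^S − μ_X^X]/RT + ln γ_comb ,
    μ_X^S = Σ_σ (A_X(σ)/a_eff) μ_S(σ) ,

so γ = 1 for a solute in itself by construction. Infinite dilution is
realised exactly: the solute is evaluated in the unperturbed solvent
ensemble (mole fraction identically zero); no numerical limit is taken.
The screening metric is the capacity C∞ = 1/γ∞, reported with log10 C∞
since screening studies quote either scale.

### Combinatorial term

The Staverman–Guggenheim contribution is included when cavity volumes are
available on both sides (and silently skipped with a logged warning
otherwise): coordination number z = 10, with volume and area parameters
normalised by the standard segment volume 66.69 Å³ and area 79.53 Å². At
infinite dilution the volume-fraction ratio reduces to r_X/r_S and the
area-fraction ratio to q_X/q_S. The term vanishes identically for a solute
in itself, preserving the pure-limit identity.

### Parameters

| symbol | default | units | note |
|---|---|---|---|
| a_eff | 7.5 | Å² | effective segment contact area |
| α′ | 16466.72 / a_eff | kcal Å⁴ mol⁻¹ e⁻² / Å² | misfit constant; a_eff·α′ is the published open value |
| c_hb | 85580 / a_eff | same | hydrogen-bond coefficient |
| σ_hb | 0.0084 | e/Å² | hydrogen-bond threshold |
| R | 1.9872e−3 | kcal mol⁻¹ K⁻¹ | gas constant |
| T | 298.15 | K | screening temperature (25 °C) |

The source study names the symbols but prints no values; the defaults are
the open published segment-model (COSMO-SAC) parametrization, the standard
choice when the proprietary parametrization is unavailable. Consequently
*absolute* capacities produced here are not comparable with numbers from
proprietary implementations — only orderings and trends are meaningful,
and the tests and acceptance checks are structured accordingly.

## Solver numerics

Damped successive substitution from μ = 0:
`μ ← d·rhs(μ) + (1−d)·μ` with damping d = 0.5, tolerance 1e−10 on
max|Δμ|/RT, and a 10 000-iteration cap; non-convergence raises an explicit
error carrying the last residual (screening reports such pairs flagged,
never silently dropped). The log-sum-exp form keeps the update stable at
the ±20 RT energy scales the hydrogen-bond term produces. The undamped map
is *not* a contraction at these energy scales (it settles into a
two-cycle), which is why the damping default is load-bearing; the test
suite cross-checks converged solutions against an independent Newton-type
root solve of the same residual and verifies solver-path independence over
damping ∈ {0.25, 0.5, 0.9} to 1e−8 RT. Typical pure-compound solves
converge in ~300 iterations; the full 352-pair screen takes ~30 s on one
CPU at the 51-bin default grid.

Degenerate inputs: zero-area profiles trigger a warning on construction
and are rejected where normalisation is required; empty bins (P_S = 0)
participate with weight zero; grids must match exactly between interacting
profiles (no silent regridding).

## Synthetic profiles

Real sigma profiles come from DFT/continuum-solvation cavity calculations
that are out of scope; the generator produces profiles with the *stated
qualitative structure* of those inputs so every downstream stage is
testable. Peaks are bin-integrated Gaussians (exact erf integration),
renormalised so the total equals the requested area exactly; optional
multiplicative noise is seeded and off by default. Cavity volumes default
to V = 0.85·A, the near-linear area–volume relation of chain-like
molecules. (A V ∝ A^{3/2} law was considered and rejected: for small ions
it yields unphysically tiny volumes — chloride near 9 Å³ — which inflates
the combinatorial term's chain-length sensitivity until it drowns the
residual signal.)

* **DHA-like solute** — hydrophobic bulk (two 190 Å² Gaussians at ±0.004),
  a small hydrogen-donor peak at −0.018 (14 Å², the carboxylic OH) and a
  small acceptor peak at +0.012 (22 Å², carbonyl oxygens). ≥ 80% of the
  area lies in the nonpolar band |σ| ≤ 0.01.
* **Cations** — a polar head of fixed charge density at −0.007 e/Å²
  (family-specific area, 40–52 Å²) plus a neutral tail at σ = 0 growing by
  18 Å² per chain carbon. Chain growth therefore *dilutes* the charge:
  total area strictly increases and area-weighted mean |σ| strictly
  decreases along every family series (property-tested). The head sits
  deliberately *inside* the hydrogen-bond threshold band: quaternary and
  ring cation surfaces are weak hydrogen-bond donors, and an HB-active
  head competes with the solute for the anion's acceptor segments, which
  inverts the chain-length trend.
* **Anions** — an acceptor peak whose centre and width follow a
  deterministic size proxy parsed from the formula-like abbreviation:
  small inorganic anions are sharp and strongly positive (chloride near
  +0.020), bulky organic anions broader and less positive (floor +0.012),
  with an extra nonpolar skeleton peak. Only the proxy's monotone
  qualitative effect is relied upon; the caps mean several large organic
  anions share one profile, which is harmless for the trend analyses and
  keeps broad peaks from leaking donor-side mass.

What the generator does **not** emulate: conformer averaging, real peak
multiplicity and asymmetry, element-resolved surfaces (hence no van der
Waals τ values), ring-specific donor sites (e.g. the imidazolium C2–H),
and any quantitative match to DFT profiles. Passing tests therefore
demonstrate that the *pipeline and model mechanics* behave correctly under
the stated structural assumptions — not that the synthetic screen
reproduces laboratory capacities.

## Trend analyses

Chain-length direction per (cation family, anion) is the sign of the
Spearman rank correlation of capacity vs chain length, mapped to
decreasing / increasing (|ρ| = 1), non-monotone (|ρ| < 1, including
constant series), or undetermined (fewer than two chain lengths). Rank
correlation rather than strict pairwise monotonicity is used because
screening studies themselves report exceptions and fluctuations within
families. Anion-ordering concordance is Kendall τ over the anions shared
with the Hofmeister reference series (SO₄²⁻ > Cl⁻ > NO₃⁻ > Br⁻ > I⁻ >
ClO₄⁻ > SCN⁻), computed per family from mean capacities.

Under the packaged generator the full screen reports "decreasing" for most
(family, anion) cells but not all — the sharpest far acceptors (Cl⁻, Br⁻,
SCN⁻) can show the opposite sign, an honest property of the model: for a
predominantly nonpolar solute, diluting the cation's polar surface both
weakens the solvent's acceptor availability (capacity-decreasing) and
relieves misfit on the solute's bulk (capacity-increasing), and the
balance depends on the anion's peak position. The dedicated
model-property demonstrations therefore use constructed families in which
the mechanism under test is isolated: a cation family differing only by
added neutral tail surface against moderate acceptor solvents (centres
0.014–0.018, width 0.003, 60 Å²) for the chain-dilution effect, and a
solvent family differing only in acceptor-peak area against a
donor-bearing solute for the acceptor-affinity effect.

## Yield arithmetic

DHA %wt = 100 × (DHA peak area)/(total FAME peak area), with
internal-standard peaks excluded from the denominator by the `IS` name
prefix; DHA content (mg/g) = total FAMEs × DHA%/100. Model-experiment
agreement is summarised as the Spearman rank correlation between predicted
capacities and measured yields over the common ILs (≥ 3 required). The
packaged validation table stores the five reported log-capacities
(25.83 … 7.10) and yields (0.18 … 0.09 mg/g); where the narrative source
gives two inconsistent yield figures for the same IL (0.09 vs 0.10 mg/g
for [EMPyrro][Br]) the explicit five-value list is used.

## Ion inventory

The packaged CSV carries 16 cations (imidazolium, pyridinium,
pyrrolidinium, piperidinium families with ethyl→octyl chains, plus
tetramethyl ammonium) and 22 anions. Chain length is the carbon count of
the longest N-substituent. Anion classes: halides, sulfate/hydrogen
sulfate, nitrate, BF₄, PF₆, AlCl₄ and SCN are tagged inorganic; all
carbon-skeleton anions organic. Sulfate is stored with charge −1 as listed
in the source inventory (free sulfate is divalent); the discrepancy is
carried in `IonLibrary.notes` rather than silently corrected.

## Known limitations

* Absolute γ∞ / C∞ values are meaningful only relative to one another
  (synthetic profiles + open parameters); magnitudes become extreme
  (log10 C∞ ≈ 15–25) because the strong HB term acts on a solute whose
  pure-liquid reference offers almost no acceptors.
* Single-solute screening only: no selectivity between two solutes, no
  finite-concentration phase equilibria (LLE/VLE), no
  temperature-dependent re-parametrization.
* The IL-as-ion-pair solvent model treats the salt as one pseudo-compound;
  the dissociated equimolar mode gives the same ensemble distribution and
  differs only in how mole fractions would be counted in extensions.
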