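# Methods

## Equilibrium model

The medium is treated as a closed, well-mixed aqueous phase at fixed pH
in which ferric iron distributes between two binders:

* **Transferrin** with two sequential macroscopic association steps,
  T + Fe³⁺ ⇌ TFe (K₁) and TFe + Fe³⁺ ⇌ TFe₂ (K₂), K₁ = 7.0×10²² L/mol
  and K₂ = 3.6×10²¹ L/mol. These are *conditional* constants, valid at
  pH 7.4 and 3.5 mmol/L bicarbonate; no pH or bicarbonate dependence of
  transferrin binding is modelled. Transferrin's two lobes bind iron
  with different microscopic constants, but only the sequential
  macroscopic constants are available, so the two monoferric species
  are lumped into a single `tf1` pool. The state therefore resolves
  apo, monoferric (lumped) and diferric transferrin.
* **A chelator** L forming cumulative complexes Fe³⁺ + i·L ⇌ FeLᵢ with
  constants βᵢ referring to the fully deprotonated ligand. At medium pH
  most of a hydroxypyridinone ligand is protonated, so the βᵢ are
  converted to conditional constants βᵢ′ = βᵢ·α_L(pH)ⁱ with the
  standard side-reaction coefficient
  α_L = (1 + 10^(pK_m − pH) + 10^(pK_m + pK_{m−1} − 2pH) + …)⁻¹.
  For deferiprone (pKa 3.68, 9.77) at pH 7.4 this costs ≈ 2.37 log
  units per bound ligand, turning log β₃ = 37.43 into ≈ 30.31. The
  correction is **on by default** and is what places deferiprone's
  pFe³⁺ (≈ 20.9) below transferrin's (≈ 23.8); with raw constants
  deferiprone's pFe³⁺ would be ≈ 28 and it would strip transferrin of
  iron, contradicting both the reload experiment and the culture
  outcome. A flag disables the correction for sensitivity analyses.

Excluded on purpose: exchange kinetics (equilibrium only — leaching of
free Fe³⁺ is the sole transfer path), ternary transferrin–iron–chelator
intermediates, Fe²⁺/redox chemistry, and iron hydrolysis species (at
the free-iron levels of interest, ≤ 10⁻²⁰ mol/L, hydroxo complexes are
a negligible iron reservoir).

### pFe³⁺ convention

pFe³⁺ = −log₁₀ [Fe³⁺] at 1 µmol/L total iron and 10 µmol/L total
ligand, pH 7.4. For transferrin, "ligand" is read as protein molecules
(10 µmol/L protein = 20 µmol/L sites), matching the convention under
which the commonly cited literature values (deferiprone 19.3, aTf 22.3)
were produced. The package reproduces the *ordering* of those values;
the exact figures depend on the constant set and protonation treatment
used by each source, and the printed constants plus standard pKa values
give 20.9 / 23.8 here. Only the ordering is asserted.

## Solver

Unknowns are x = ln[Fe³⁺] and y = ln[L] (free iron spans ~25 decades
across compositions, so linear-space iteration is hopeless). Residuals
are the log-ratios of the iron and ligand mass balances to their
totals. The default path is a damped Newton iteration with the analytic
2×2 Jacobian, a composition-derived starting point, an 8-log-unit step
cap and backtracking line search, run to a residual two decades below
the promised tolerance (default rtol 1e-10, max 200 iterations).
Because both balances are strictly increasing in their own log
variable, a nested interval bisection (outer on x, inner on y) is a
guaranteed fallback, followed by a Newton polish. 1-D subsystems
(no chelator, or no iron) use bisection plus Newton polish directly.
Zero pools are floored at 1e-30 mol/L to keep logarithms finite; a
composition with no iron returns the trivial state without iteration.
The returned state is validated against both balances at rtol and all
mass-action laws hold by construction (species are reconstructed from
the free concentrations). Solves are deterministic: identical inputs
produce bit-identical states.

## Time-course

Cellular iron uptake is far slower than extracellular exchange
equilibria, so the culture is simulated quasi-statically: total iron
declines linearly at a constant net volumetric rate and the equilibrium
is re-solved at each grid time. The default rate is 1.7×10⁻⁷ mol/L·h,
the conventional figure for 10⁷ hemoglobinized cells per mL produced
over 96 h; recomputing from that cellular basis
(10⁷ cells/mL × 1.2×10⁹ Fe / 96 h / N_A) actually gives ≈ 2.1×10⁻⁷,
and `UptakeModel.from_cell_production()` exposes that variant — the
~20% discrepancy is inherited from the source figure's rounding and
does not affect any directional conclusion. Uptake draws on *total*
iron regardless of speciation (the sink represents a net average
drain), and iron is hard-clamped at zero with a logged warning when
exhausted rather than modelling uptake saturation, for which no law is
available.

Each step is solved from a deterministic, composition-derived starting
point rather than warm-started from the previous solution. Because the
quasi-static state depends only on the current totals, this makes
states at shared grid times *bit-identical* across different step
sizes, which is both a strong regression property and the honest
statement of the model (the grid is pure sampling). Repeated totals
(zero uptake, post-exhaustion) reuse the previous state object
outright. Cold Newton solves converge in a handful of iterations, so
the three reference scenarios over 96 h at dt = 0.1 h run in well under
a second.

The reference scenario set compares 1000 µg/mL hTf alone against
100 µg/mL hTf plus 26 or 52 µmol/L Def₃·Fe³⁺ — the comparison behind
the claim that a deferiprone top-up maintains more holotransferrin and
less apotransferrin than high-dose transferrin alone.

## Iron accounting

Pure stoichiometry, all linear, full precision returned. Two
transferrin molar-mass conventions deliberately coexist:

* **76,900 g/mol** (`molar_mass_equivalence`) for µg/mL ↔ µmol/L
  conversions — back-solved from the standard equivalence
  1000 µg/mL hTf = 26 µmol/L chelated Fe³⁺;
* **80,000 g/mol** (`molar_mass_budget`, the nominal ~80 kDa) for mass
  budgets — 6×10⁸ transferrins per cell ≈ 80 pg.

They differ by ~4%; silently averaging them would reproduce neither
headline number. The reticulocyte volume default is 200 fL (2×10⁻¹³ L):
a "200 pL" figure sometimes quoted alongside the residual-dose
arithmetic is dimensionally inconsistent with it (and with any real red
cell) by three orders of magnitude, while 200 fL reproduces the
0.14 mg/kg residual deferiprone dose exactly.

## Curve fitting

The hemoglobin dose–response is fitted as Hb = Hb_max·c/(EC₅₀ + c) by
unweighted least squares on the untransformed scale (the data are
reported untransformed), with deterministic data-driven initialization
(Hb_max ← max observed Hb; EC₅₀ ← the positive concentration whose
response is nearest half of that) and positivity bounds. Degenerate
inputs (fewer than three distinct concentrations, no positive
concentration, all-zero response) raise rather than fitting junk.

Oxygen-saturation curves are summarized by a Hill fit
S = p^n/(P₅₀^n + p^n), parametrized in log(P₅₀), log(n) for positivity,
seeded by a model-free P₅₀ from monotone linear interpolation at the
0.5 crossing. The interpolated P₅₀ is carried in the result as an
assumption-free cross-check; the two agree within 2% on clean Hill
curves. P₅₀ is defined operationally (pressure at 50% saturation), so
the Hill form is a summary model choice, not a mechanistic claim;
cooperative multi-state models are out of scope.

## Synthetic data

Generators emulate the statistical structure the analysis assumes:
hyperbolic mean response and Hill-curve saturation with additive
Gaussian noise truncated at physical bounds (experimental readouts are
reported as mean ± SD with approximately symmetric scatter), and noisy
renormalized observations of simulated fraction time-courses. Defaults:
Hb_max 30 pg/cell (the hemoglobin content of a mature cell), EC₅₀
5 µmol/L, the 7-point concentration design {0, 1.3, 2.6, 5.2, 13, 26,
52} µmol/L covering the standard titration, 24 points assigned
round-robin over the design, noise SD 5% of Hb_max; oxygen curves use
P₅₀ 26.8 mmHg (peripheral-blood reference), Hill n 2.7, noise SD 0.01.
Everything is keyed to one integer seed; a manifest (seed + config
hash) suffices for bit-identical regeneration.

What passing recovery tests shows — and does not show: the fits recover
their own generating model under symmetric noise at realistic
signal-to-noise (median |ΔEC₅₀|/EC₅₀ ≈ 7% over 200 replicates of the
default design). Real titration data add donor-level heterogeneity,
concentration-dependent variance and possible deviations from the
hyperbolic form, none of which the generator emulates; recovery here
validates the estimation code, not the biology.

## Known limitations

* The lumped monoferric pool cannot distinguish N- versus C-lobe
  loading, which matters for receptor-binding biology but not for the
  iron balance.
* Under the default (protonation-corrected) constants, loading
  1000 µg/mL apotransferrin from 52 µmol/L Def₃·Fe³⁺ ends with ~94% of
  transferrin iron-loaded but predominantly monoferric (62% mono, 32%
  diferric, 6% apo): the model predicts near-complete *reloading* yet
  not a diferric *majority*. A stronger effective transfer (e.g. the
  literature pFe³⁺ 19.3 for deferiprone, or any kinetic assistance
  beyond free-Fe³⁺ leaching) would push the split further toward
  diferric; with the printed constants plus standard pKa values this is
  where the equilibrium sits.
* Daily medium refreshment, cell-population dynamics and per-cell
  heterogeneity are not modelled; the time-course is a single closed
  volume with a constant sink.
* Transferrin constants are taken as conditional at one (pH,
  bicarbonate) point; media at other pH values only re-scale the
  chelator side, not transferrin.
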