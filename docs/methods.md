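# Methods

`tjbarrier` models the leak pathway of the epithelial tight-junction (TJ)
barrier — the size-nonselective paracellular route used by molecules too
large for claudin pores — with two linked models that share one structural
dynamics: a stochastic compartment model of molecular permeability and a
dynamic resistor network for transepithelial electrical resistance (TER).

## Geometry

The bicellular TJ (bTJ) strand meshwork in the cleft between two cells is
idealized as a 2D brick lattice: `n_strand` horizontal strands (default 4)
enclose `n_strand − 1` rows of small compartments, 100 nm × 100 nm,
50 compartments across (model width 5 µm). Rows alternate between `W`
full-width and `W + 1` compartments with half-width edges, so all rows
span the same width; side walls are sealed. The atomic unit is the
*strand section* — the piece of strand between two compartments (or a
compartment and the basal/apical boundary): vertical connector sections
are `h_comp` long, boundary-strand sections `w_comp` (or `w_comp/2` at
half-width edge compartments), and interior-strand sections `w_comp/2`
(one per brick-overlap interface). A section holds at most one break and
has no internal coordinate.

The tricellular TJ (tTJ) central tube is a static cylindrical pore,
radius 5 nm and height 1 µm, with areal density `rho_tTJ`; it is treated
analytically and combined with the bTJ pathway in parallel.

## Strand dynamics

Each section is an independent two-state Markov chain on a fixed 1-s
grid: intact → broken with probability `p_break·l` per step (`p_break` in
m⁻¹s⁻¹, so longer sections break more often) and broken → intact with
probability `p_seal` (default 0.033 s⁻¹, mean open time ≈ 30 s; break
size `l_break` = 20 nm). Initial states are drawn from the stationary
distribution `p_break·l / (p_break·l + p_seal)`. Probabilities are used
directly as per-step transition probabilities; the 1-s cadence is part of
the model definition, not a numerical discretization.

## Permeability model

Amounts of substance are 2D (per unit depth, m⁻¹). Intact strands pass no
molecules; a broken section transfers with rate constant
`k_ij = l_break·P_break / A_i`, where `P_break = ε_TJ·D₀·H_s(r_m/w_TJ)/h_strand`
is the epithelium-scaled hindered slit permeability (`ε_TJ = 2·w_TJ·l_cb`
is the relative TJ area given the cell-boundary length per area `l_cb`).
The permeant defaults to a 547-Da PEG oligomer with radius
`r_m = 0.29·M^0.454` Å (0.51 nm) and aqueous diffusivity
`D₀ = 9.9×10⁻⁹·M^−0.453` m²/s; confinement uses the Dechadilok–Deen
hindrance polynomials for a slit (`H_s`, breaks) and a cylinder (`H_p`,
tTJ pores). The basal reservoir is clamped at `c_basal` (1 mM; a pure
scaling parameter) and the apical compartment is absorbing. The bTJ
permeability is the slope of the replicate-averaged apical accumulation
divided by `w_model·c_basal`; the total is `P_TJ = P_bTJ + P_tTJ` with
`P_tTJ = π r_tTJ² ρ_tTJ · D₀ · H_p / h_tTJ`.

**Integration.** Within each 1-s state interval the system is linear with
constant coefficients, and only the small clusters of compartments
touched by broken sections evolve. Each cluster generator is
symmetrizable by `diag(1/√A_i)`, so the interval is propagated *exactly*
(eigendecomposition, including the constant basal source term and the
exact time integral of every amount, used for apical accumulation and
mass accounting). This is unconditionally stable against the stiff
transfer rates (`k` ~ 10²–10³ s⁻¹: a broken section equilibrates its
neighbours within milliseconds) and closes the mass balance to ~10⁻¹⁴
relative. The kernel is numba-compiled; one replicate uses one RNG
stream with seed `base_seed + replicate`.

**Equilibrium initialization.** To measure `P_bTJ` without the initial
transient, compartments start from the per-row mean amounts of
zero-initial-condition pre-runs averaged over the linear phase (second
half of the pre-run horizon). The relative row profile depends only on
the lattice, not on the magnitude of the dynamics, so it is computed once
per geometry (defaults: 16 pre-runs of 1 h). A warning is raised when the
pre-run apical trace has not become linear.

**Lag time.** The lag is the back-extrapolated zero crossing of the
linear phase of apical accumulation from empty compartments. Two
estimators are provided. The default fits the *replicate-averaged*
trace. A structural caveat applies: with stationary initial strand
states, rare configurations that span the lattice with simultaneous
breaks conduct from t = 0, so the averaged trace is nearly linear
throughout and the ensemble-level lag is small (for the average
4-strand MDCK II parameters it measures ≈ 0–1 min, with a heavy-tailed
intercept noise inherited from those same full-opening events; a
coupled-run control experiment starting from an all-intact network pins
the initialization-induced offset at ≈ 0.7 min). The alternative
(`method="median"`) extrapolates each replicate separately and returns
the median intercept — a robust measure of the typical
single-realization transit delay, which grows systematically with
strand number and strand stability.

## TER model

The same lattice becomes a planar resistor network: nodes are the
compartments plus the basal and apical reservoirs, and every section is a
resistor. Intact sections conduct through the strand material,
`R = R_strand / l_ij` (`R_strand` in Ω·m is the fitted per-length strand
resistance); broken sections put the 0.2-GΩ break in parallel with the
remaining strand, `R = ((l−l_break)/R_strand + 1/R_break)⁻¹`. The printed
geometric estimate `R_break = ρ_em·h_strand/(2 w_TJ l_break)` ≈ 0.02 GΩ
is available (`r_break_override=None`), but the 0.2-GΩ constant is the
default because the fitted strand resistances and the strand-to-break
resistance ratios (≈90× for MDCK II, ≈2655× for MDCK C7) are consistent
with it. Strand capacitance is ignored.

At each 1-s snapshot the circuit is solved by mesh (loop) analysis: the
loops are the bounded faces of the planar conduction graph plus the outer
loop that closes through the voltage source (`V_s` = 1 V, a pure scaling
parameter); the loop matrix is symmetric positive definite and sparse
(each section borders at most two loops). `R_bTJ = V_s/I_outer ·
w_model/l_cb` converts the 2D solve to an epithelial area resistance; the
static `R_tTJ = ρ_em·h_tTJ/(π r_tTJ² ρ_tTJ)` is combined in parallel, and
the TER trace is time-averaged. Snapshots with an unchanged break pattern
reuse the previous solution. A node-potential (Laplacian) solver is kept
in the test suite as an independent oracle; the two agree to ~10⁻¹³.

## Steady-state comparators

Mean-field static variants replace the dynamics with the *expected*
number of open breaks per strand (fractional, no rounding) and collapse
each compartment row into a well-mixed layer: permeability becomes a
series of `n_strand` layers of conductance
`m_s·l_break·P_break/w_model`; resistance a series of strands, each the
intact strand in parallel with its expected breaks. They bracket the
dynamic models — higher permeability, lower resistance — because they
ignore the rarity of simultaneous openings.

## Calibration

`P_TJ` is monotone in `p_break` and the time-averaged TER is monotone in
`R_strand`, so both are fitted by bisection on the published resolution
grids (0.001 µm⁻¹s⁻¹ and 0.01 GΩ·µm) with common random numbers (the
same replicate seeds for every candidate), which keeps the objective
monotone along the search. The permeability target is
`P_exp − P_tTJ(ρ_tTJ)`; when the tricellular pores alone reach the
measured permeability (MDCK C7) the fit is declared infeasible and the
preset ships the published constant instead. Fitting defaults are 128
replicates of a 1-h horizon; final reported simulations use the 2-h
horizon.

Derived experiments: pathway-share decomposition (tTJ share of
permeability `P_tTJ/P_exp`, capped at 1; tTJ share of TER conductance
`TER_exp/R_tTJ`; simulated variants available), a strand-number sweep
(n = 2..6 with the mean MDCK junction densities `l_cb` = 0.282 µm⁻¹ and
`ρ_tTJ` = 0.049 µm⁻²), a ±25 % one-at-a-time sensitivity analysis, and
the hexagonal-array construction `l_cb = 1/a`, `ρ_tTJ = 1/(√3 a²)` for a
cell of apothem `a` (each hexagon owns two tricellular vertices).

## Problem sizes and numerical choices

The reference configuration averages 512 replicates of a 2-h horizon for
permeability and a 10⁶-s horizon for TER. The package's desk-scale
defaults, used by the test suite and the acceptance script, are 64–256
replicates of the 2-h horizon, a 10⁵-s TER horizon, and 48–64-replicate
1-h fitting simulations; at these sizes the Caco-2 round trip reproduces
the measured permeability and TER to a few percent, and reducing the TER
horizon from 10⁶ to 10⁵ s changes the time average by less than the
replicate spread. Slope fitting uses the trailing 50 % of the horizon
(the equilibrium-initialized trace is nominally linear throughout; the
window guards against residual transients). Seeded runs are
bit-reproducible; identical configs and seeds write byte-identical
summaries.

## Known limitations

One regular strand morphology (no heterogeneity, no vertical variation of
strand number, no apical tightening); no claudin-pore (pore-pathway)
dynamics, so charged-solute and sub-0.4-nm permeation are out of scope;
no macromolecule permeation; no transcellular resistance, so the TER
prediction applies to junction-dominated (low-TER) epithelia; tTJ pores
are identical across epithelia; strand capacitance and electrode geometry
are ignored. The synthetic dynamics emulate stochastic strand breaking
with a single break size and exponential open times; real strand
dynamics show lateral motion and a distribution of break sizes, so
passing tests demonstrate internal consistency and reproduction of the
published calibration targets, not validation against new experimental
data.
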