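# Methods

## Scope and model family

`vasotherm` computes steady-state temperature fields in a perfused tissue
block during hyperthermia treatment, under three nested descriptions of the
blood:

1. **Pennes bioheat equation (PBHTE).** Conduction plus a distributed
   perfusion heat sink,

       div(k grad T) + w_b c_b (T_a - T) + q = 0,

   with arterial supply temperature `T_a = 37 C`. Metabolic heating is
   neglected (its contribution is small against therapeutic power
   densities).

2. **Effective conductivity (K_eff).** Pure conduction with an elevated
   conductivity, `div(K_eff grad T) + q = 0`. With the default
   `K_eff = k_t = 0.5 W/m/C` it is the conduction-only limit.

3. **Countercurrent blood vessel network (CBVN).** The tissue equation
   keeps the Pennes-form sink, and is conjugately coupled to 1-D advective
   energy equations for the blood in a discrete, seven-level countercurrent
   artery/vein tree,

       mdot_i c_b dT_b/ds_i = 2 pi R_i h (T_w - T_b) + q A,   h = Nu k_b / D_i,

   marched with first-order upwinding along the flow direction of every
   segment. The constant Nusselt number (`Nu = 4`) makes the film
   conductance per unit length `pi Nu k_b`, independent of diameter.

The control volume is an 82 x 80 x 80 mm parallelepiped with all faces held
at 37 C, discretized on a uniform node-centered 2-mm lattice (42 x 41 x 41
nodes, nodes on the boundary). Tissue and blood share `k = 0.5 W/m/C`,
`c = c_b = 4000 J/kg/C`, `rho = 1000 kg/m^3`.

## Vessel network geometry

The vasculature is a regular binary-branching tree whose hard features are:
seven levels; the level-1 artery along the central lengthwise axis with
branch sites at x = 2 and x = 42 mm carrying identical downstream patterns;
a 0.1 % through-flow exiting at x = 82 mm; diameters shrinking by a constant
generation ratio `gamma` between branching levels (`D[i+1] = gamma D[i]`),
except the level-6 to 7 transition, which only changes direction; 128
terminal (level-7) arteries, each supplying one terminal subvolume; and a
congruent venous tree offset one node (+2 mm) in x, y and z with reversed
flow (the level-1 vein trunk is kept inside the domain). The level-2..7
arrangement follows the documented margin pathway around the 20-mm tumor
cube at (42,40,40)-(62,60,60) mm: level 2 runs +/-z (20 mm), level 3 +/-y
(20 mm), level 4 chains +x with branch stations every 10 mm, level 5 +/-z
(10 mm), level 6 +/-y (10 mm), level 7 +x (8 mm). Counting maximal
same-level runs as single vessels gives 341 vessels per tree, 682 in all.
The 128 subvolumes (8 x-slabs x 4 x 4 y/z columns; the first slab is 12 mm
because 82 mm is not evenly divisible on the grid) tile the control volume
exactly, and each contains its terminal artery's end node.

Flows follow mass conservation from the bottom up: a terminal carries
`w_b * V_subvolume`; junction sums are exact by construction. With the
default 1-mm level-1 diameter, the level-1 speed is
`w_b V_cv (1 + 0.001) / (rho pi R^2)` — about 334 mm/s at
`w_b = 0.5 kg/m^3/s` and 6.7 mm/s at 0.01, matching the reported ~320 and
~6 mm/s.

## CBVN discretization

Vessel-path nodes are **blood cells embedded in the grid**: they are
excluded from the tissue unknowns, power deposited on them is absorbed
entirely by the blood, and every non-vessel 6-neighbor of a blood cell
exchanges heat with it through a per-cell conductance `U h` split equally
over those neighbors, replacing the plain conduction link of the 7-point
stencil. By default `U = pi Nu k_b` (film-limited: the wall temperature is
identified with the adjacent tissue nodes, which sit one spacing from the
axis); `SolverConfig.r_t_factor > 0` reinstates an explicit wall-to-node
logarithmic resistance `ln(r_t/R)/(2 pi k_t)` in series for sensitivity
studies. Segments carrying zero flow are thermally inert (not embedded), so
a no-flow network reduces the model exactly to pure conduction.

Terminal (level-7) segments carry their subvolume's perfusion along their
length: a terminal artery bleeds off uniformly per cell (its advective
capacity tapers linearly to zero at the tip, and its delivery temperature is
the bleed-weighted mean), and the draining vein symmetrically collects blood
at the subvolume's volume-weighted mean tissue temperature. Vein junctions
mix enthalpy conservatively (flow-weighted averages). The tissue keeps the
same Pennes-form sink `w_b c_b (37 - T)` as the PBHTE; the enthalpy the
collected venous blood carries equals exactly the heat that sink removed
from the subvolume's tissue, while the difference between the delivered
(terminal-artery) and body temperature leaves the model at the terminal
ends. `energy_balance` accounts all channels explicitly — boundary
conduction, outlet enthalpies, blood exchange with clamped boundary nodes,
and the terminal bleed-off residual — and a converged run closes the balance
to well below 0.1 %.

## Numerics

Tissue fields relax by red-black SOR (`omega = 1.8`, max-update tolerance
`1e-6 C`); the conjugate system alternates a couple of tissue sweeps with
upwind blood marches (arteries in flow order, subvolume collection, then
veins) until both the tissue and the blood stop moving. All linear-system
limits were checked against direct sparse solves, the single-vessel march
against the closed-form exponential approach to a clamped wall temperature,
and 1-mm versus 2-mm grids differ by well under 0.5 C on the optimized
Pennes case. Everything is deterministic; there is no randomness anywhere.

## Power-deposition optimization

The feedback loop sets a uniform 1e5 W/m^3 in the treated region, solves,
scores the region against the ideal uniform 43 C with the normalized RMS
criterion `sqrt(mean (43 - T)^2) / 6 < 0.1`, and while unmet adjusts power
pointwise by `dp = 1e4 * (43 - T)` W/m^3, clamped at zero, with no power
outside the region. The criterion is evaluated over **all** region nodes;
the update targets tumor *tissue* nodes (embedded blood cells are heated
through their walls, not aimed at directly).

Two termination regimes arise. For PBHTE the criterion is met after a few
iterations (the field is then ~43 C on average with ~41 C maxima 4 mm
outside the region). For the CBVN the blood cells of the thermally large
(level 1-4) vessels on the tumor margin impose a floor of ~0.11 on the RMS
— they cannot reach 43 C at any finite power — so the criterion is
unattainable and the loop instead runs until the region's total power is
stationary (relative change < 1e-4 per iteration, ~300 iterations). Such a
result reports `converged=False, stationary=True`; it is the scheme's
optimum under the update law. Reported totals use the discrete deposition
`sum(q) h^3` over region nodes (the power the model actually absorbs);
`integrate_power` separately provides the trapezoidal volume integral,
exact for uniform fields.

With the film-limited default coupling, optimized totals are essentially
independent of `gamma` (diameters enter neither the film conductance nor
the flows), consistent with the finding that vessel size barely affects
total power consumption at constant perfusion; the diameter ratio still
controls speeds, surface areas and the optional log-resistance variant.

## What the model does and does not capture

The geometry is a regular synthetic vasculature, not a measured vascular
tree: it reproduces the documented waypoints, level/terminal counts and the
682-vessel total, but per-level segment lengths away from the tumor margin
are a reconstruction, and results that depend on the distal geometry (e.g.
temperatures on planes behind the treated region, where warm terminal
vessels exit) carry the largest uncertainty — our x = 66 mm maxima after
cross-application run ~0.8 C above the reference value, while the front and
in-region planes agree within tolerance. Blood properties are constant;
flow is steady plug flow; there is no thermoregulation, pulsatility or
temperature-dependent perfusion; power deposition is an abstract field with
no acoustics; transient dosimetry is out of scope.
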