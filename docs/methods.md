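# Methods

## Model and discretisation

A population of 2D point neurons `τ dv/dt = F(v)`, `v = (v, w)`, driven by
Poisson spike trains whose arrivals displace the state instantaneously by
an efficacy vector h, is represented by probability mass on a mesh of
quadrilateral cells.  The mesh is built from *characteristics* of F: two
neighbouring integral curves, sampled at multiples of the grid time step
Δt, bound a *strip*; four consecutive samples bound a *cell*.  By
construction, noise-free dynamics maps cell j of a strip onto cell j+1 in
one step, so advection is solved exactly (up to the Δt discretisation of
the characteristics) by incrementing a rotation counter k in the index
function

    I(0, j, k) = j                                  (stationary cells)
    I(i, j, k) = c_cell(i-1) + (j - k) mod n_cell(i),   i >= 1,

with c_cell the cumulative cell count over strips (stationary cells first).
No mass is copied for interior cells; mass addressed by a strip's cell 0
after a rotation has left the strip's spatial end and is transferred by the
*reversal mapping* to a designated target (a reversal bin at an
equilibrium, the closest cell of a limit-cycle ring, or a designated
continuation cell), then the address is zeroed.

Synaptic input is the master equation dM/dt = ν(Σ α_{p,q} M(p,q) − M(i,j)),
advanced by `n_euler` forward-Euler substeps per Δt with all reads/writes
routed through I(·,·,k).  The fractions α are Monte-Carlo estimates: for
each origin cell, N_point uniform samples are translated by h and located
in the mesh (first-match-wins in (strip, cell) lexicographic order, closed
cell boundaries); α = count/N_point exactly, so every matrix row sums to 1
and probability is conserved to machine precision.  The per-step order is
rotate + reversal, master equation, threshold/reset — resetting before the
next rotation, so threshold mass cannot wrap.

### Boundary rules

*Thresholds.*  Cells with a vertex on either side of V_th form the
threshold set; their mass is drained every step through the reset mapping
to the reset cell closest in w (preserving the auxiliary variable), after
an optional refractory delay implemented as a FIFO queue of
(release step, mass, target) entries — the state is undefined during
refraction, so the mass is parked outside the mesh and the conservation
check counts live + queued mass.  A spike-triggered adaptation increment b
replaces the single reset target by the displacement set of the reset cell
translated by (0, b).  Sampled jump events that land strictly above V_th
are attributed to the nearest threshold cell, so no matrix transition ever
targets a supra-threshold cell.

*Gaps.*  Finite meshes and nearly-singular flow regions (nullclines,
separatrices, merging trajectories) leave clefts that jump events can land
in.  Events inside a user-supplied fiducial polygon are reassigned to the
associated cell (a cell with a vertex inside the polygon) closest along
the projection of the jump direction; all other off-mesh events are
reassigned to the cell whose bounding box has the smallest perpendicular
gap to the jump line through the event (parallel gap, then lexicographic
id, break ties), provided both gaps stay below 5 local cell extents —
beyond that the matrix build fails loudly rather than teleport mass.  A
reflecting boundary (e.g. a maximum conductance) needs no special code:
the mesh is clipped at the boundary and overshooting events reassign to
the boundary cells along the jump.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| Δt | per scenario, 5·10⁻⁵–2·10⁻³ s | grid step; sets the cell size along the flow and hence the dispersion of the jump operator.  Rates converge at the few-percent level once cells are no wider than the jump along its direction. |
| N_point | 10⁴ (matrices), 10³ (marginals) | Monte-Carlo events per cell.  Rates are remarkably insensitive (N_point = 10 already works); densities need ~10⁴ to look smooth.  Quenched before simulation. |
| n_euler | 10, auto-raised so νΔt/n < 0.1 | Euler substeps of the master equation. |
| area_min | scenario-specific | area cut that terminates strips; doubles as the state-space boundary detector. |
| reassignment cutoff | 5 cell extents | beyond it a lost event is an error, never silently dropped. |
| ring epsilon | 2% of the cycle bounding-box diagonal (synthetic fixture: 0.05) | half-width of the artificial limit-cycle band. |

All randomness derives from one seed split into named streams (mesh,
matrix, marginal, mc) via `SeedSequence`, so each artifact is independently
reproducible; transition matrices are bit-identical across rebuilds with
the same seed.

## Model conventions

Time is in seconds everywhere; each model declares its own state units.
The conductance-based model uses Table constants τ_m = 20 ms, E_l = E_r =
−65 mV, E_e = 0, V_th = −55 mV and a *time* constant τ_s = 5 ms (the
source table prints an inconsistent unit for it), with conductance in
units of the leak conductance.  A synaptic efficacy quoted in mV maps to a
conductance jump of 0.05 per mV: this is the calibration under which a
3 kHz input reproduces the published reference rates (≈195 Hz unbounded,
≈175 Hz at g_max = 0.8); the peak-PSP interpretation of "1 mV" gives a
jump twice as large and roughly double those rates, so it cannot be what
the quoted efficacies meant.  AdExp uses the standard parameter set
(C_m = 281 pF, g_l = 30 nS, E_l = −70.6 mV, V_T = −50.4 mV, Δ_T = 2 mV,
τ_w = 144 ms, a = 4 nS, b = 80.5 pA), V in mV and w in pA, with a numerical
spike cut at −40 mV.  LIF/QIF use threshold-normalised potentials
(LIF threshold 1; QIF threshold 10, reset −10, F = V² + 1 so the default
registry model is intrinsically bursting).  The deterministic fields never
include synaptic input: noise enters exclusively through transition
matrices — that operator split is the method.

## Meshing the hard models

The AdExp phase plane needs three strip families: forward strips from the
left edge into the basin of the stable equilibrium; the interior band
between the V-nullcline and the separatrix (located by tracing the stable
manifold of the saddle along its stable eigendirection and seeding forward
strips just left of it); and the spike region, integrated backward from
just above the threshold line.  Trajectories merge onto the V-nullcline,
collapsing cell areas, so the slow slide down the nullcline — which
carries the adaptation decay — is meshed as a dedicated one-dimensional
channel strip of fixed width fed by the other families' reversal mappings.
Without that channel, mass teleports to the equilibrium with its
adaptation erased and the steady rate comes out ~20% high; with it, the
density rate at 3 kHz/1 mV agrees with the direct simulation to ~2% at
Δt = 0.5 ms.  The Tsodyks-Markram square has the same structure in milder
form: strips from the r = 0 edge merge onto the r = 1 edge while the
facilitation u is still large, so a u-decay channel along r = 1 plays the
same role.  For Fitzhugh-Nagumo at I = 0.5 the limit cycle is implied
rather than meshed: strips are truncated at a distance ε from the cycle,
the leftover annulus is tiled as a closed ring strip whose rotation (mod n)
is the periodic motion, and every open strip reverses onto its closest
ring cell; the slow region around the central nullcline branch is tiled
with stationary cells bounded by a periodic cubic spline.

## Gain-curve extraction

The linear response to ν(t) = ν₀ + ε sin ωt is the first Fourier
coefficient of the output rate over whole cycles after discarding
max(5 cycles, 0.5 s); an unmodulated run from the identical initial state
is subtracted first, which cancels residual relaxation transients and the
quenched ripple of the Monte-Carlo matrices exactly.  For finite jumps the
response does not decay to zero: a rate modulation instantaneously
modulates the flux of jumps across threshold, giving a flat, zero-lag
transmission floor that the diffusion approximation lacks.  The
high-frequency exponent is therefore measured after subtracting the
complex response at a reference frequency well above the fit band (where
only the floor survives); the log-log slope of the remaining diffusive
branch is fitted over half-octave grids.  In the balanced-input,
small-jump regime this yields slope ≈ −2 for quadratic neurons and ≈ −1
for exponential neurons, the known asymptotics; outside that regime the
floor and the population resonances at harmonics of the firing rate
dominate, which is a genuine property of jump noise, not a numerical
artifact.

## Monte-Carlo reference

The validation oracle simulates N independent neurons directly.  Models
with a closed-form deterministic propagator (LIF, QIF, TM) are advanced
*exactly*: exponential inter-arrival gaps, analytic flow between arrivals,
and analytic drift-crossing times where the drift alone reaches threshold.
Conductance/AdExp/FHN have no closed-form flow and use fixed sub-steps
(RK4, arrival counts Poisson per step, jumps applied at the step start);
the jump-time discretisation bias is O(dt_mc) and dt_mc ≤ Δt/5 is
enforced.  Standard errors of steady rates use the across-neuron variance
of per-neuron spike counts, which is exact for independent neurons.

## What the synthetic scenarios do and do not show

The shipped scenarios reproduce the published operating points (LIF
τ = 50 ms / 800 Hz / h = 0.03; conductance 3 kHz with and without
g_max = 0.8; AdExp and EIF at 3 kHz / 1 mV; TM at 5 Hz presynaptic;
FHN at I = 0.5) at desk scale: meshes of ~0.3–10 k cells instead of the
~10⁵-cell production grids, which is why rate benchmarks carry a few
percent of discretisation bias and are tested against tolerances of a few
percent rather than machine precision.  Passing tests demonstrate the
correctness of the geometry, the mass bookkeeping and the master-equation
dynamics under idealised assumptions — homogeneous populations, exactly
Poisson input, quenched matrices; they do not validate the mean-field
assumption itself for small or correlated biological networks, and
pairwise correlations are outside the scope of any density method.

## Numerical choices and limitations

Characteristics are integrated with DOP853 at rtol 1e-10 (1e-8 for the
large 2D scenario meshes), sampled at exact Δt multiples; exponential
spike runs are frozen above a ceiling a few mV past the threshold cut so
the integrator survives the finite-time blow-up (the frozen part never
enters the mesh).  Geometry predicates use a relative epsilon of 1e-12;
boundary points belong to every touching cell and the lexicographically
first cell wins, so no sampled event is ever double-counted or lost.
Network delays are quantised to ceil(τ_delay/Δt) steps with a minimum of
one step (populations update synchronously from the previous step's
rates, and a self-connection's spiked mass is seen only after its delay).
Mass balance is asserted every step at 1e-8 and the test suite checks
1e-10 across all scenarios.  Known limitations: threshold cells are
drained whole once per step, which advances spikes by up to one cell's
transit time (visible as a small positive rate bias on coarse meshes); the
jump operator disperses mass over the full width of cells wider than the
jump; state-dependent jumps are evaluated at cell centroids; and meshes
for models with strong slow-fast structure (AdExp, FHN) require the
hand-designed seed layouts described above rather than a single automatic
recipe.
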