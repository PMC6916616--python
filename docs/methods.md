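# Methods

## Model

A quadruped is reduced to a point mass `m` at the CoM, halfway along a
stiff back of hip-to-shoulder length `L_back`, moving in a vertical plane
under gravity `g`.  Limbs are massless and act only through momentary
impulses; between impulses the CoM is ballistic.  Strides are periodic
with period `T_stride`, and the impulses over one stride must supply the
total vertical support impulse `m g T_stride`.

Elasticity is ignored on the assumption that hysteresis losses are
gait-independent, so only *relative* positive-work demands are meaningful;
every result involving the zero-pitch gaits is therefore reported as a
ratio to the trot at the same speed and stride period.

### Collision work

An impulse `J` carries the CoM velocity from `U` to `V = U + J/m` along a
straight segment in velocity space.  Kinetic energy lost while the speed
falls is dissipated; energy gained while it rises is costly positive
work.  Writing `V_min` for the segment point nearest zero velocity
(clamped to an endpoint when the perpendicular foot lies outside the
segment):

    W+   = m/2 (|V|² − |V_min|²),      W−  = m/2 (|U|² − |V_min|²).

The package evaluates this both by the exact closed form above and by the
reference procedure of splitting the impulse into `n` equal sub-impulses
(default `n = 100`) and accumulating signed kinetic-energy increments.
The quadrature's only error is the gap between the true `V_min` and the
nearest sub-impulse grid point, bounded by `|J|²/(8 m n²)`; relative to
the impulse's energy turnover `max(W+, W−)` this is at most `~1/n²`, and
the measured worst case over 1000 random impulses at `n = 100` is about
1e−4.  A collision is *pseudoelastic* when `V_min` is strictly interior —
the impulse acts nearly perpendicular to the velocity, redirecting it at
low work.

### Pitch energetics (trot vs tolt)

For vertical-impulse gaits the vertical and pitch kinetic energies reach
their minima simultaneously, so their positive works add.  Trot (two
cycles per stride): takeoff speed `gT/4`, work `m g²T²/16`.  Tolt (four
cycles): takeoff speed `gT/8`, vertical work `m g²T²/32`, plus pitch work
`(m g²T²/32)(m L²_back/4I)` from the alternating hip/shoulder impulses
(`|Δω| = (m g T/4)(L_back/2)/I`, with `ω_max = |Δω|/2` because pitching
reverses through zero at midstance).  Trot is cheaper iff
`Iˆ = 4I/(m L²_back) < 1`.  The same threshold governs the sign of the
shoulder's response to a vertical hip impulse,
`ΔV_shoulder = p/m − p L²_back/(4I)`.

The pitch model and the zero-pitch gait models are deliberately not
coupled: intermediate `Iˆ`, within-stride variation of `I` or `L_back`,
and asymmetric CoM placement are out of scope.

### Zero-pitch gait cycles

In the `Iˆ = 0` limit every impulse must point through the CoM: solo hind
impulses incline forward by θ, solo fore by −θ, synchronous hind–fore
pairs stay vertical.  Each limb's vertical impulse component is its
weight-support share of `m g T`; its horizontal component is
vertical·tanθ.  This parameterization keeps the ballistic timing
independent of θ.  The five cycles (ballistic fractions / impulse shares):

| gait            | ballistic phases | impulses (order, share)                  |
|-----------------|------------------|------------------------------------------|
| trot            | ½, ½             | pair ½, pair ½                           |
| tolt            | ¼ ×4             | hind ¼, fore ¼, hind ¼, fore ¼           |
| canter          | 1                | hind, pair, fore (¼,½,¼ or ⅓,⅓,⅓)        |
| gathered gallop | 1                | hind ¼, hind ¼, fore ¼, fore ¼           |
| even gallop     | ¼ ×4             | hind ¼, hind ¼, fore ¼, fore ¼           |

Clustered impulses act at literally zero elapsed time, in the stated
order, chaining velocities; the canter's single ballistic phase occupies
the whole stride (landing vertical velocity `−gT/2`).  The model is
planar: no left/right limb identity, hence no rotary/transverse
distinction.  Steady cycles are exact: ballistic arcs are symmetric
(±gτ/2), so CoM height is equal at every impulse instant, and the single
free parameter — the horizontal velocity level — is fixed by requiring
the duration-weighted mean of the piecewise-constant horizontal velocity
to equal the mean speed `V̄x`.

The canter's two weight-split schemes exist because the numerical map
uses equal per-limb support (the paired instant carries double weight)
while the analytic canter condition assumes equal thirds per instant; the
gait orderings they produce agree at the reference conditions, and both
are exposed.

### Normalization and sweeps

Speed and stride period are normalized by leg length,
`V̂x = V̄x/√(g L_leg)` and `T̂ = T/√(L_leg/g)`; only their ratio
`V̄x/(gT)` (and θ) enters any cost ratio, which the sweep exploits by
working in units `m = g = T = 1` with the mean speed equal to the ratio.
The default map grid is ratio 0.2–4.0 in steps of 0.02 and θ 0.5°–45° in
steps of 0.5° (the sources print no grid; this resolves every boundary at
desk-scale runtime, ~1 s vectorized).  Ties within a relative tolerance
of 1e−9 — tolt and even gallop coincide exactly at θ = 0 and nearly so at
small θ — are reported as explicit joined labels rather than resolved by
floating-point noise; ordering inside labels follows the fixed precedence
tolt, trot, canter, gathered gallop, even gallop.

### Analytic canter condition

Landing after the full-stride ballistic phase at `U_y = −gT/2`, the CoM
path makes angle `α = atan(gT/(2V̄x))` below horizontal and must be
redirected by 2α across the three impulses at +θ, 0, −θ.  If each impulse
is perfectly pseudoelastic (its `V_min` bisecting the turn) the geometry
collapses to `θ = (2/3)·atan(T̂/(2V̂x))`, inverted as
`V̂x = T̂/(2 tan(3θ/2))`.  `incoming_angle` returns the positive
magnitude of the path angle (no sign convention is imposed).  The model
makes no claim of quantitative agreement with observed trot–canter
transition speeds or limb loading; the curve is checked only for
containment in the numerically canter-optimal region.

## What the computations show (and don't)

* The θ = 10° transect yields the optimal-gait sequence tolt → trot →
  canter → trot over ratio 0.2–4; the canter window is bounded and the
  gathered gallop approaches but never undercuts the trot (its clustered
  hind and fore pairs behave exactly as single doubled impulses).
* At high speed every inclined-impulse gait degenerates to pure
  horizontal work generation/absorption while the trot's cost is speed
  independent, so the trot re-emerges — a prediction that does not match
  animals, which gallop.
* At low speeds tolting wins; the tolt/trot boundary angle rises toward
  45° only in the low-speed limit (the limiting tolt work is
  `(1/32)sec²θ` against trot's `1/16`, equal exactly at 45°).  At ratio
  0.2 the computed boundary is near 30°.
* The model contains no randomness: maps are bit-reproducible.  The only
  seeded quantity anywhere is the random-impulse draw used to measure
  quadrature-vs-closed-form agreement.

No empirical data enter the package; all inputs are model parameters, so
"passing" means internal consistency and the stated qualitative
structure, not agreement with measured gait transitions.  Degenerate
inputs are handled explicitly: zero impulse and zero-speed states are
legal, non-positive masses, periods, grids and unknown gait names raise
parameter errors, and cycle construction rejects impulse shares
inconsistent with the ballistic timing.

## Problem sizes

Default test and acceptance runs use the full 191-point ratio grid at
single inclinations, the full 191×90 grid only implicitly through its
per-θ columns, 1000 random impulses for the oracle comparison, and
100-division quadrature everywhere numeric; the whole suite completes in
a few seconds thanks to the ratio-vectorized sweep path (verified
elementwise against the scalar path in the tests).
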