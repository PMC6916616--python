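# gaitwork

Collisional work minimization for idealized quadrupedal gaits.

Most terrestrial mammals trot at intermediate speeds and canter or gallop
beyond them, yet from a point-mass perspective the two-beat trot looks
wasteful: spreading the same weight support over four smaller impulses (a
tolt, rack or "running walk") halves the vertical collision work.
`gaitwork` implements a reductionist mechanical account of why trotting
nevertheless pays, and why the canter takes over with speed.  It is aimed
at locomotor biomechanists, comparative physiologists and legged-robotics
researchers who want the model's machinery — not just its figures — as a
library.

The model reduces a quadruped to a point centre of mass (CoM) on a stiff
back, supported by momentary limb impulses, with two extensions to plain
collision mechanics:

1. **Pitch energetics.** Unpaired impulses act at hip or shoulder with
   lever arm `L_back/2` and pitch the body against its moment of inertia
   `I`.  Summing vertical and rotational positive work per stride gives
   trot `m g²T²/16` versus tolt `m g²T²/32 · (1 + m L²_back/(4I))`, so the
   trot is cheaper exactly when the normalized inertia
   **`Iˆ = 4I/(m L²_back) < 1`** — equivalently, when a vertical hip
   impulse accelerates the unloaded shoulder downward (hips and shoulders
   inside each other's centre of percussion).
2. **Zero-pitch gaits.** With `Iˆ → 0` every impulse must pass through the
   CoM: solo hind impulses incline forward by θ, solo fore impulses
   backward by θ, pairs stay vertical.  Five idealized footfall patterns
   (tolt, trot, canter, gathered gallop, even gallop) are built as exact
   periodic cycles of ballistic phases and impulse clusters, and each
   impulse is costed by collision mechanics: the CoM velocity traverses
   the straight segment `U → V = U + J/m`, kinetic energy lost up to the
   minimum-speed point is dissipated, and all the energy gained after it
   is counted as (costly) positive muscle work.

Costs depend only on the dimensionless ratio `V̄x/(g T_stride)` — the
ratio of Froude-style dimensionless speed `V̂x = V̄x/√(g L_leg)` and stride
period `T̂ = T_stride/√(L_leg/g)` — and on θ.  Sweeping that plane yields
the map of work-minimizing gaits, with the predicted sequence
**tolt → trot → canter → trot** as speed rises, and an analytic condition
for good cantering, `V̂x = T̂ / (2 tan(3θ/2))`, at which each of the
canter's three impulses is "pseudoelastic" (speed dips, then recovers).

## Worked example

```bash
python examples/optimal_gait_map.py
```

prints (m = g = T = 1, θ = 10°):

```
optimal gaits with increasing speed at theta = 10 deg:
  tolt -> trot -> canter -> trot
    tolt -> trot   at ratio 0.72
    trot -> canter at ratio 1.40
  canter -> trot   at ratio 2.82

canter beats trot on ratio in [1.40, 2.80] (min cost ratio 0.758)
gathered gallop never beats trot: min cost ratio 1.031
```

Ratios are `V̄x/(g T_stride)`; a cost ratio below 1 means the gait needs
less positive CoM work per stride than the trot at the same speed and
stride period.  The canter wins only on a bounded speed window — where the
landing trajectory lets all three of its impulses redirect the CoM
pseudoelastically — and the gathered gallop approaches but never beats the
trot.  The other scripts in `examples/` walk through single collisions,
the pitch-inertia criterion, per-gait costs at one condition and the
analytic canter curve.

The same machinery is scriptable from a shell:

```bash
gaitwork work --gait canter --ratio 2 --theta 10      # per-stride work, JSON
gaitwork map --out map.csv                            # optimal-gait grid, CSV
gaitwork transect --theta 10 --out slice.csv          # cost slice vs trot
gaitwork pitch --batch bodies.csv --out verdicts.csv  # Iˆ criterion, batch
gaitwork analytic-canter --theta 10                   # ideal canter condition
```

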