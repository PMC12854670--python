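# ciliaflow

Hydrodynamics of microbial feeding: does it pay, in purely fluid-mechanical
terms, to swim for your food or to attach and pump?

Many ciliates face exactly this choice — *Vorticella* or *Stentor* tether to
a surface and drive a feeding current with their ciliary crown, while
*Paramecium* or *Volvox* swim; diatoms do neither and simply sink.
`ciliaflow` implements the spherical-cell models needed to compare these
strategies quantitatively: exact axisymmetric Stokes-flow fields for
sessile, swimming, and sinking spheres, a steady advection–diffusion solver
for nutrient uptake, clearance-rate metrics for particle encounter, the
asymptotic Sherwood–Péclet scalings, robustness studies for partial cilia
coverage and partial surface absorption, and a synthetic survey generator
that maps realistic organism sizes and speeds onto the model curves. It is
aimed at biophysicists and aquatic ecologists who want reproducible numbers
rather than figure pixels: every pipeline emits CSV tables.

## Models and metrics

The cell is a no-slip sphere of radius *a* in Stokes flow (η = 1, *a* = 1,
all quantities dimensionless). Ciliary activity is represented two ways:

* **Envelope (squirmer) model** — cilia replaced by a tangential slip
  velocity u<sub>θ</sub>(a) = 𝒰 sin θ. Motile: the classical B₁ squirmer in
  its co-moving frame, swimming at U = 2𝒰/3. Sessile: a tethered pump with
  the same slip, whose far field is the 1/r Stokeslet tail of the tether
  force (stream function ψ = 𝒰 sin²θ (1/2r − r/2)).
* **Stokeslet-sphere model** — the ciliary crown as a point force
  F<sub>cilia</sub> on the axis at distance L > a, pointing at the cell,
  with no-slip on the sphere. The no-slip condition is enforced exactly by
  a Gegenbauer-mode image series; the force the sphere feels reproduces the
  Faxén result, giving the exact force-balance swimming speed
  U = F (1 − 3a/2L + a³/2L³) / 6πηa for the motile state.
* **Sinking sphere** — classical Stokes flow past a rigid sphere.

Nutrient transport solves Pe **u**·∇C = ∇²C with C = 0 on the absorbing
surface and C → 1 far away, where Pe = aU/D. Feeding is scored by

* the **Sherwood number** Sh = I / 4πaDC<sub>∞</sub> (uptake relative to
  pure diffusion), and
* the **clearance rate** Q = −2π ∫<sub>a</sub><sup>R</sup> u·e<sub>z</sub>|₍z=0₎ ρ dρ
  through an equatorial encounter annulus (default R = 1.1a), normalized by
  the advective flux πR²U.

For the sessile envelope model the solver reproduces the closed-form
asymptotes Sh = 1 + (43/720)Pe² (Pe ≪ 1, recovered to 0.1%) and
Sh = (2/√(3π)) Pe<sup>1/2</sup> (Pe ≫ 1).

## Worked example

```python
from ciliaflow import EnvelopeField, solve_sherwood, clearance_rate

for state in ("sessile", "motile"):
    f = EnvelopeField(state)
    r = solve_sherwood(f, 100.0)          # transport solve at Pe = 100
    q = clearance_rate(f, 1.1)            # encounter annulus R = 1.1a
    print(f"{state:8s}  Sh(Pe=100) = {r.sh:.3f}   Q/(pi R^2 U) = {q.Q_normalized:.4f}")
```

prints

```
sessile   Sh(Pe=100) = 6.753   Q/(pi R^2 U) = 0.2367
motile    Sh(Pe=100) = 6.973   Q/(pi R^2 U) = 0.2487
```

Read: at Pe = 100 a swimming envelope-model cell takes up nutrients about
7× faster than diffusion alone, but attaching instead costs it only ~3% of
that uptake and ~1.2 points of normalized clearance — the two strategies
are hydrodynamically nearly equivalent. The large-Pe asymptote
(2/√(3π))·√100 = 6.515 sits within 4% of both.

The command line exposes the same machinery
(`ciliaflow solve --model envelope --state motile --pe 100`,
`ciliaflow figure2|figure3|figure4|survey|clearance|acceptance`); each
figure command writes the corresponding data tables with provenance
headers.

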