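# cytoabm

Agent-based spatial simulation of metabolic pathways: every enzyme,
metabolite and enzyme–substrate complex is an autonomous sphere diffusing
through an attolitre-scale cube of cytoplasm, and reactions happen only when
molecules actually find each other.

## The scientific problem

Classical kinetic models treat a pathway as bulk differential equations and
assume a well-mixed solution in which cognate partners meet by random
encounters alone.  But if biomolecules attract each other through
*long-range electrodynamic forces* — resonant dipole–dipole interactions
decaying as 1/r³ that are not screened at the ~10 Å Debye length — enzymes
would recruit their substrates from far beyond contact range, with visible
consequences for pathway rate, efficiency and oscillations.  `cytoabm`
probes this hypothesis *in silico* on yeast glycolysis: the same network is
simulated three times, with molecular interactions allowed at

* **5 Å** — contact-range, van der Waals-like shape complementarity;
* **10 Å** — electrostatics capped at the Debye screening length;
* **300 Å** — long-range electrodynamic recruitment.

The only thing that differs between regimes is the **perception distance**
`d`: an enzyme of radius *r* projects a perception sphere of radius *r + d*
and probabilistically binds cognate metabolites that enter it, with
probability 1 at surface distances ≤ 5 Å, decaying as 1/s³ beyond, and zero
past `d`.

## The model

* Each molecule is a sphere of radius `r = (3 v̄ M / 4 π N_A)^{1/3}` from its
  molecular weight M and the mean protein partial specific volume
  v̄ = 0.73 cm³/g.
* Diffusion follows Stokes–Einstein, `D = k_B T / 6 π η r` (T = 298.15 K,
  η = 0.0011 Pa·s), discretised into fixed-modulus steps `L = sqrt(2 D Δt)`
  per tick (Δt = 1e-4 s) along isotropic random directions, with specular
  reflection at the walls of the 1000 Å (1 aL) box and hard-sphere collision
  avoidance.
* Binding builds a per-reaction **automaton**: a complex accumulates the
  substrate multiset one molecule at a time (the first bound metabolite
  fixes the direction of a reversible reaction); once saturated it waits
  `1/k_cat` seconds and then releases the products, restoring the free
  enzyme.  Exact integer species conservation holds at every tick.
* Concentrations (mmol/l) count free molecules; complexes are reported
  separately — this is what exposes the short-range stall, where hexokinase–
  glucose complexes persist while free ATP stays flat.

The bundled glycolysis network is the adapted yeast model: glucose →
pyruvate plus the glycerol, trehalose and glycogen branches; fermentation
(PDC1/5/6, ADH1/5), adenylate kinase, ATPase, UDP→UTP and glucose transport
are excluded, hexokinase/glucokinase, phosphofructokinase and pyruvate
kinase are irreversible, and all initial concentrations are scaled below
1 mmol/l so an attolitre holds a tractable few thousand particles.

## Worked example

```python
from cytoabm import engine, fixtures

model = fixtures.glycolysis_model(scale=0.2)          # desk-scale counts
config = fixtures.glycolysis_config(distance=300.0,   # long-range regime
                                    seed=42, duration=0.1, record_every=20)
series, world = engine.run(model, config)

glc, atp, pyr = (series.get(s) for s in ("GLC", "ATP", "PYR"))
print(f"glucose   {glc[0]:.3f} -> {glc[-1]:.3f} mmol/l")
print(f"ATP       {atp[0]:.3f} -> {atp[-1]:.3f} mmol/l")
print(f"pyruvate  {pyr[0]:.3f} -> {pyr[-1]:.3f} mmol/l")
print(f"catalytic events: {sum(world.completed.values())}")
```

prints

```
glucose   0.179 -> 0.156 mmol/l
ATP       0.120 -> 0.093 mmol/l
pyruvate  0.040 -> 0.042 mmol/l
catalytic events: 35
```

— in 0.1 simulated seconds of the long-range regime, glucose is consumed,
ATP is drawn down by the kinases of the preparatory phase, and pyruvate
begins to accumulate; running the same seed at `distance=5.0` instead
leaves ATP nearly untouched while hexokinase–glucose complexes sit waiting
for an ATP they rarely encounter.

The same workflow is available from the shell:

```sh
cytoabm fixtures emit glycolysis -o glyco.xml --scale 0.2
cytoabm simulate glyco.xml --distance 300 --duration 0.1 --seed 42 --out run/
cytoabm analyze run/series.csv --freq F16BP --sync DHAP GAP --deplete GLC
cytoabm convert model.sbml -o model.xml        # SBML import
```

Every run directory contains a manifest (model hash, effective config,
seed) sufficient to reproduce it bit for bit, plus a positions table for
external 3-D viewers.

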