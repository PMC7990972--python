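# celldosim

Monte-Carlo cellular microdosimetry of radioactive gold nanoparticles
(¹⁹⁸AuNP) in a spherical cell model.

Radioactive ¹⁹⁸Au nanoparticles are candidates for internal-emitter therapy
of solid tumours: each decay releases a beta particle (endpoints 961 keV at
99% and 285 keV at 1%) plus gamma lines (412 keV at 96%), and where the
particles sit inside a cell determines which organelle absorbs the dose.
`celldosim` builds a CHO-like cell — a 6 µm-radius sphere with a 10 nm
membrane shell, a 3.3 µm nucleus and 90 mitochondria of radius 463 nm —
places gold nanoparticles either explicitly (randomly in the cytosol or
attached to the nucleus/mitochondria surface) or as a homogeneous gold mass
fraction in the cytosol, samples ¹⁹⁸Au decays, transports the emitted
electrons and photons with a condensed-history scheme (Bethe stopping power,
CSDA range tables, Highland multiple scattering), and scores energy deposits
per organelle in eV per decay.

The central observable is the relative energy deposit

    E_rel(x) = 100% · E(x) / E(0%) ,

where `x` is the fraction of nanoparticles attached to the nucleus surface
and `E(0%)` the all-random baseline. Because decays are independent,
`E(x) = x·E(100%) + (1−x)·E(0%)` in expectation, and the simulated sweep is
linear with R² > 0.99. With all 10⁴ × 5 nm particles nucleus-attached, the
nucleus deposit rises to roughly 260–280% of the baseline while the
whole-cell deposit rises by ~20–27%: targeting moves dose into the
radiosensitive nucleus far more effectively than it raises total dose.
Dose conversion: ~1800–1900 eV/decay over the 0.9 ng cell gives 32–35 Gy
after 10⁵ decays.

See `docs/methods.md` for the model, its assumptions, and known
limitations.

## Worked example

```python
import numpy as np
from celldosim import (build_cho_cell, place_nanoparticles, PlacementSpec,
                       au198_spec, simulate_decays, TransportConfig)

rng = np.random.default_rng(1)
geom = build_cho_cell(rng=rng)                      # nucleus + 90 mitochondria
place_nanoparticles(geom, PlacementSpec(n_np=10_000, r_np=5.0,
                                        fraction_targeted=1.0), rng)
tally = simulate_decays(geom, au198_spec(), "discrete", n_decays=2000,
                        cfg=TransportConfig(), rng=rng)
for region in ("cell", "nucleus", "mitochondrion", "membrane"):
    print(f"{region:14s} {tally.per_decay(region):8.1f} eV/decay")
```

prints (seed 1):

```
cell             1946.7 eV/decay
nucleus           585.5 eV/decay
mitochondrion      66.2 eV/decay
membrane            3.7 eV/decay
```

i.e. with every nanoparticle on the nucleus surface, ~30% of the deposited
energy lands in the nucleus (versus ~14% for randomly distributed
particles), while mitochondria and membrane are nearly unaffected.

The same experiments are scriptable from the shell:

```
celldosim run --config run.cfg --out results/
celldosim report --out results/
celldosim build-geometry --seed 1 --out geom/   # TOPAS-style export + CSV
```

where `run.cfg` is a flat `key = value` file (see `celldosim.cli.RunConfig`
for the schema), selecting one of the experiments `targeting_sweep`,
`continuous_sweep`, `discrete_radii` or `mass_independence`.

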