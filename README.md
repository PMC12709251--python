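# memstress

Lateral stress profiles and curvature-elastic constants of lipid bilayers
from a diffuse-interface (phase-field) membrane model.

The membrane interface is described by a tanh kink of width `epsilon`
(membrane thickness `lme = 6 epsilon`, default 5 nm). From that single
building block the package provides:

- **`memstress.kink`** — the kink profile, its derivative closed forms, the
  stationarity identity, and the weak-limit normalization integrals.
- **`memstress.stress`** — the five closed-form lateral stress components
  (`sB2`, `sB1`, `sB0`, `sG`, `sT`), each proportional to one elastic
  constant (`k`, `mk`, `m²k`, `kG0`, `gamma`), the total profile `s(z)`,
  the central stress `s(0)` and the ratio `kG0/k = −24/35` at which the
  central bump vanishes.
- **`memstress.moments`** — moments P0–P2 of a profile (Simpson for
  tabulated input, adaptive quadrature for closed forms), the
  tension-correction length `zD = sqrt((12+π²)/54)·(lme/2) ≈ 0.64·(lme/2)`,
  and the tension-corrected Gaussian modulus `kG = kG0 + z0²·Σ`.
- **`memstress.sphere`** — radial quadratures of the bending, Gaussian and
  tension energies for a large spherical vesicle, their sharp-interface
  limits (`8πk − 8πmkD + 2πkm²D²`, `4πkG0`, `γπD²`), empirical convergence
  orders, and a 1D gradient-flow relaxation to the planar kink.
- **`memstress.leaflets`** — monolayer→bilayer consistency relations and
  the sign rules for shallow/deep molecule insertion per leaflet.
- **`memstress.extract`** — inverse extraction of elastic constants from
  tabulated profiles (moment inversion and component-shape least squares),
  a seeded noisy-profile generator and bias/RMSE recovery experiments.
- **`memstress.profile_io` / `units` / `figures` / `cli`** — annotated TSV
  profile I/O, kBT↔bar/mN·m⁻¹/kJ·mol⁻¹ conversions, figure-family curve
  export, and the `memstress` command-line tool.

Internal units are kBT, nm, kBT/nm² and kBT/nm³ throughout.

## CLI

```sh
# sample a model profile (k in kBT, m in 1/nm, gamma in kBT/nm^2)
memstress profile --k 20 --kg-ratio -0.7 --m 0.1 --gamma 0.005 \
    --thickness 5 --z-min -20 --z-max 20 --n 2001 --out profile.tsv

# moments P0..P2 and the zD length
memstress moments profile.tsv

# recover the elastic constants (shape fit; --method moments for P0/P1/P2)
memstress extract profile.tsv --fit-epsilon

# spherical-vesicle energies vs. their sharp-interface limits
memstress energy --k 20 --kg0 -14 --m 0.01 --gamma 0.005 --dve 1000
memstress energy --k 20 --kg0 -14 --m 0.01 --dve 1000 --convergence 0.04,0.02,0.01

# bilayer constants from the two monolayers (k,m,kG,Sigma per leaflet)
memstress consistency --leaflet1 10,0.2,-5,0 --leaflet2 10,0.2,-5,0 --z0 1.5

# export curve data for one of the six standard figure families
memstress figures --which 4 --outdir figs/
```

A flat JSON file can replace flags via `memstress --config cfg.json <cmd>`;
`-v` raises log verbosity on stderr; numeric output uses 12 significant
digits.

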