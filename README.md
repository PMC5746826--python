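# fiberweb

Micromechanics of electrospun nanofiber membranes: predict what a **single
nanofiber** does mechanically from what the **membrane** it forms does — and
vice versa.

Sub-micron electrospun fibers (here silk-fibroin/polycaprolactone blends of
~272 nm diameter, a common tissue-engineering scaffold material) are too
fragile to tensile-test routinely one by one, while the nonwoven membranes
they form are easy to test. `fiberweb` implements a representative-volume-
element (RVE) model of the membrane's planar random fiber network that links
the two, plus the tooling around it: a stochastic network simulator that
serves as an independent Monte Carlo check of the closed form, a synthetic
micrograph renderer with fiber-orientation-distribution (FOD) and diameter
estimators, and tensile-curve analysis utilities.

## The model

An RVE is a square of side `L` and thickness `T` holding `Nf` straight,
unbonded fibers of radius `r`, axis angles `α` uniform on `[0, π)`
(`ψ(α) = 1/π`) and lengths in the arithmetic progression `l_i = i·2L/Nf`.
Porosity closure `L²T(1−P) = πr²Σl_i` with `Σl_i = L(Nf+1)` fixes the fiber
count.

A specimen of width `W` cut from the RVE engages the fraction `τ = W/L` of
fibers whose orientation lies within `θ = arctan(k)`, `k = W/L`, of the
tension axis; each contributes the axial force component `σ_f·πr²·cos²α`.
Averaging over the uniform FOD gives the membrane engineering stress

    σ = (1 − P) · (sin θ cos θ + θ) / π · σ_f ,      θ = arctan k,

which is linear in the single-fiber stress `σ_f` and therefore exactly
invertible for `k > 0` (at `k = 0` no fiber bridges the cross-section and
`σ ≡ 0`). Strains map through the in-plane contraction coefficient
`ν_xy = ε_x/ε_y` (the nonwoven analog of a Poisson ratio, often > 1 for
fiber mats):

    ε_f = ε · (1 − ν_xy k²) / (1 + k²).

## Worked example

Predict single-fiber properties from a membrane tensile record at the study
conditions (`P = 0.75`, `k = 0.125`, i.e. a 5 mm wide specimen at 40 mm
gauge):

```sh
$ fiberweb predict-fiber --out-dir demo --log-level WARNING
fiber yield stress: 208.74 MPa (k=0.125, P=0.75)
wrote demo/fiber_curve.csv and demo/comparison.csv
```

`comparison.csv` holds both summaries (columns: E, yield stress/strain,
break stress/strain):

```
membrane,83.88,4.11,0.049,5.394,0.543
fiber_predicted,4444.3,208.74,0.0470,273.97,0.5160
```

Reading: a membrane yielding at 4.11 MPa and 4.9 % strain implies a single
fiber yielding at ≈ 209 MPa — the stress amplification
`1/((1−P)(sinθcosθ+θ)/π) ≈ 50.8` reflects both the porosity (only a quarter
of the volume is solid) and the orientation average (most fibers are not
aligned with the load). The fiber yield strain 0.047 is slightly below the
membrane's 0.049 because the mat contracts transversely faster than a solid
(`ν_xy ≈ 1.65` near yield).

The same library calls are available in Python:

```python
import fiberweb as fw
fw.membrane_stress(400.0, P=0.75, k=0.125)        # 7.876 MPa
fw.fiber_stress_from_membrane(4.11, 0.75, 0.125)  # 208.74 MPa
```

Cross-check the closed form with an explicit stochastic network:

```sh
$ fiberweb simulate --out-dir demo --seed 1
MC mean 7.7676 MPa vs closed form 7.8760 MPa (10 seeds, SE 0.0489)
```

Other subcommands: `surface` (membrane stress over a porosity × `k` grid),
`fod` (render a seeded network and estimate its orientation distribution),
`analyze-curve` (tensile descriptor tables), `predict-membrane` (forward
map), `fixtures` (deterministic synthetic data bundle). All accept
`--config` (YAML/JSON), `--seed`, `--out-dir`, `--log-level`.

## Layout

- `fiberweb.model` — closed-form RVE relations (forward, inverse, strain
  maps, parametric surfaces)
- `fiberweb.network` — stochastic network generator, specimen cut, virtual
  tensile test, network FOD
- `fiberweb.imaging` / `fiberweb.fod` — micrograph rendering,
  structure-tensor FOD estimation, skeleton/distance-transform diameter
  measurement, chi-square uniformity testing
- `fiberweb.curves` — tensile-record I/O, descriptor extraction, contraction
  profiles, fiber-property prediction, replicate statistics
- `fiberweb.synthetic` — seeded generators for study-condition curves,
  diameters and micrograph fields
- `fiberweb.cli` / `fiberweb.config` — command-line interface and run
  configuration

See `docs/methods.md` for the model assumptions, numerical choices and known
limitations.
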