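# osteoadapt

An invertible model of cortical bone adaptation to mechanical loading.

Given a periodic loading regimen (waveform, peak strain or sectional forces,
cycles per day, days per week), the package predicts the section-average bone
formation rate (BFR/BS) and the site-specific mineral apposition rate (MAR)
around a bone cross-section. Because every stage is explicit — and the core
is linear — the chain also runs backwards: from a prescribed MAR distribution
it recovers the sectional loads (normal force plus two bending moments) that
would produce it.

## Model stages

1. **Viscoelastic strain** (`waveforms`): unit loading waveforms (trapezoid,
   haversine, triangle, rectangular pulse, sine, with optional grouped rest
   insertion) drive a Kelvin–Voigt solid to its periodic steady state,
   yielding the peak strain, the crest-to-trough excursion, and their ratio
   ξ — the quantity that makes rest-inserted loading more osteogenic.
2. **Section mechanics** (`section`): polygon cross-sections (periosteal +
   endocortical boundaries), Green's-theorem area properties, and
   unsymmetric-bending strain amplitudes at any in-plane point.
3. **Average BFR law** (`bfr`): B = p·(ε_peak − ε_thres)·ξ·N^q·d^β above a
   strain threshold, zero below; multi-protocol least-squares calibration and
   closed-form inversion for peak strain or cycle count.
4. **Cell network diffusion** (`network`): threshold stimulus at osteocytes,
   steady-state diffusion along 1-D cell processes (graph-Laplacian solve),
   flow rates at osteoblast sinks.
5. **Site-specific MAR** (`site`): MAR = k·q per osteoblast, closed-form
   calibrations of k, and the worked derivations of the gain h, the exponent
   β and the magnitude of k.
6. **Inverse loading** (`inverse`): multi-start Levenberg–Marquardt recovery
   of (F_z⁰, M_x⁰, M_y⁰) from prescribed MAR values.
7. **Statistics** (`circstats`): one-sample t-test for BFR and Watson's U²
   between circular MAR distributions (permutation or asymptotic p).
8. **Fixtures** (`fixtures`): seeded synthetic sections, cell networks,
   protocol presets and noisy observations so the whole chain is testable
   without external data.

## Quick start

```python
from osteoadapt import (ModelParameters, SectionLoads, make_waveform,
                        forward_mar)
from osteoadapt.fixtures import FixtureSpec, make_section, make_cells_and_network

spec = FixtureSpec(seed=1)
section = make_section(spec)
network = make_cells_and_network(section, spec)

params = ModelParameters(q=0.404736, eps_thres_ue=856.126, r_s=0.436235,
                         p=1.06859e-4 / 3**0.465, beta=0.465,
                         h_nm_per_ue=0.123)
wf = make_waveform("trapezoid", {"rise_s": 0.1, "hold_s": 0.8, "fall_s": 0.1},
                   rest_s=10.0)
result = forward_mar(SectionLoads(Mx0_nmm=45.0), wf, n_cycles=50,
                     days_per_week=3, params=params, k_um_per_nmol=-7.908e6,
                     network=network, section=section)
print(result.bfr_by_surface)
```

## CLI

```bash
osteoadapt make-fixture --seed 1 --out fixture/
osteoadapt fit-average --protocols fixture/protocols.json --out fitted.json
osteoadapt predict-average --protocols fixture/protocols.json --params fitted.json --out pred.csv
osteoadapt invert-strain --params fitted.json --bfr 0.4 --n-cycles 50 --days-per-week 3
osteoadapt forward-site --cells fixture/cells.csv --edges fixture/edges.csv \
    --section fixture/section.json --params params.json \
    --protocols fixture/protocols.json --k -7.9e6 --mx 45 --out mar.csv
osteoadapt invert-loads --problem problem.json --cells fixture/cells.csv \
    --edges fixture/edges.csv --section fixture/section.json \
    --params params.json --protocols fixture/protocols.json --out loads.json
osteoadapt compare --model mar_model.csv --observed mar_obs.csv
```

Every command writes a `manifest.json` with input hashes and options.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: the worked
calibration constants (h = 0.123 nM/με, spike 85 nM, β = 0.465,
|k| = 7.908×10⁶ μm/nmol) and a property battery (dense-solve diffusion
oracle, viscoelastic limits, parameter recovery, forward–inverse round
trips, Watson's U² null calibration).

## Units

Lengths μm, forces N, moments N·mm, strains με, concentrations nM at the
interface (nmol/μm³ internally), diffusivity cm²/s at the interface
(μm²/day internally), MAR μm/day, BFR/BS μm³/μm²/day. E defaults to 20 GPa.
Angles are degrees at interfaces, radians internally.

## Scope notes

Woven-bone formation, endocortical-specific responsiveness and age-dependent
resorption, and labeling-day corrections are out of scope: the model
calibrates on periosteal lamellar responses. `k` is carried signed
(negative, since osteoblast flow rates are sinks) and reported as a
magnitude where conventional.
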