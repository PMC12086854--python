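# vcdkit

Vibrational circular dichroism (VCD) and infrared (IR) spectra for small
closed-shell molecules, computed with atomic-orbital-based linear response
over a self-contained all-electron Hartree–Fock mean field.

VCD — the differential absorption of left/right circularly polarized IR
light by a chiral molecule's vibrational transitions — is the standard
spectroscopic probe of absolute configuration. In the double harmonic
approximation each normal mode *i* carries a dipole strength and a
(signed) rotational strength

```
D_i = (1/2ω_i) Σ_α [ Σ_{λβ} P^λ_{αβ} S_i^{λβ} ]²
R_i =          Σ_α [ Σ_{λβ} P^λ_{αβ} S_i^{λβ} ] [ Σ_{λβ} M^λ_{αβ} S_i^{λβ} ]
```

built from the atomic polar tensors `P^λ` (dipole derivatives, length or
velocity form) and atomic axial tensors `M^λ` (magnetic-moment derivatives
with respect to nuclear velocity). The package implements three
perturbation theories over one response machinery:

* **NDPT** — nuclear displacement (real, symmetric; coupled): length-form
  APTs, IR intensities;
* **NVPT** — nuclear velocity (imaginary, antihermitian; velocity atomic
  orbitals): velocity-form APTs and AATs;
* **MFPT** — magnetic field (imaginary, antihermitian; gauge-including
  atomic orbitals, three channels only): origin-free AATs;

and two **independent response solvers** for every channel: the AO-basis
density-matrix solver (exponential parametrization, Löwdin basis,
preconditioned conjugate gradients, nonzero perturbed overlap S⁽¹⁾) and the
MO-basis Sternheimer solver. Their element-wise agreement is the package's
central internal validation. Audience: method developers and students of
molecular property theory who want a compact, fully transparent, heavily
cross-checked reference implementation — not a production quantum
chemistry package.

## Worked example

Chiral hydrogen peroxide (the built-in `h2o2_P` fixture, HF-optimized,
HOOH dihedral −125°), NVPT with both solvers cross-checked:

```python
from vcdkit.cli import RunConfig, run_pipeline

cfg = RunConfig(fixture="h2o2_P", basis="mini", theory="nvpt",
                solver="both", out_dir="out")
res = run_pipeline(cfg)
print(res["strengths"].table.round(6))
print("max AO-vs-MO density deviation:",
      res["meta"]["comparison"]["max_abs_D1_deviation"])
```

prints (about a minute on one CPU)

```
   mode  wavenumber_cm1      D_au  D_1e40esu2cm2  R_au  R_1e44esu2cm2
0     0      184.144125  0.005330     344.334169  -0.0     -18.573507
1     1     1486.837470  0.000002       0.112963   0.0       0.284453
2     2     1589.516489  0.002426     156.707145  -0.0     -36.627200
3     3     1780.808957  0.000231      14.919007   0.0      38.560079
4     4     4140.720761  0.000049       3.183676   0.0       8.904840
5     5     4148.103538  0.000218      14.074193  -0.0     -10.192022
max AO-vs-MO density deviation: 1.5915202489225067e-10
```

Six vibrational modes (torsion, bends, O–O stretch, two O–H stretches);
the rotational strengths (±10–40 × 10⁻⁴⁴ esu² cm²) alternate in sign as
expected for the skew C2 structure, and flip sign exactly for the mirror
fixture `h2o2_M`. The two solvers agree to ~10⁻¹⁰ on every response
density. `out/` receives the APT/AAT tables, per-mode strengths, broadened
IR and VCD spectra (unit-area Lorentzians, FWHM 12 cm⁻¹), and the
cross-solver comparison report.

The same pipeline is available from the shell:

```bash
vcdkit compute --fixture h2o2_P --basis mini --theory nvpt --solver both --out out
vcdkit fixtures --out fixtures/          # XYZ files + built-in basis sets
vcdkit oracles  --fixture h2o --out oracles.json
```

`vcdkit oracles` runs the diagnostics suite: finite-difference oracles for
every perturbed integral (geometric and complex-phase), cross-solver
agreement, APT sum rules, gauge-shift checks, and a deliberate
negative control.

## Layout

| module | contents |
| --- | --- |
| `vcdkit.chemio` | molecules, Gaussian basis sets (NWChem-style), XYZ I/O, constants, gauge origins |
| `vcdkit.integrals` | McMurchie–Davidson engine (numba), moment/derivative maps, all first-order integrals |
| `vcdkit.scf` | restricted Hartree–Fock (DIIS), analytic nuclear gradients |
| `vcdkit.ao_response` | AO density-matrix response solver (the core method) |
| `vcdkit.mo_response` | MO Sternheimer solver (independent validation path) |
| `vcdkit.perturbations` | NDPT/NVPT/MFPT channel builders |
| `vcdkit.tensors` | APTs (length/velocity), AATs (NVPT/MFPT), strengths |
| `vcdkit.vibspec` | seminumerical Hessian, Eckart projection, Lorentzian spectra, geometry optimizer |
| `vcdkit.fixtures` | optimized test molecules (H2, H2O, HOF, H2O2 enantiomer pair, planar saddle) |
| `vcdkit.refint` | slow complex-center reference integrals (test oracle only) |
| `vcdkit.cli` | configuration (TOML), pipeline, diagnostics, `vcdkit` command |

See `docs/methods.md` for the working equations, conventions, numerical
choices, and the validation program's scope and limitations.
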