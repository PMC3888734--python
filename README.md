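# foldcaustic

Stationary-action analysis of torsion-angle chains.

The package models conformational motion as Lagrangian dynamics in a space
of dihedral angles and provides the machinery to study when families of
such motions focus:

- **torsion_model** — chains of angles with diagonal inertia and
  configurable potentials (harmonic springs in the `V = k·θ²` convention,
  one-sided asymmetric springs, the two-control cusp quartic, composites,
  symbolic custom expressions, multiplicative time schedules).
- **dynamics** — velocity-Verlet / RK4 integration of the equations of
  motion on fixed uniform grids; trajectory families shot from a
  parameterized curve of start states; CSV + JSON-sidecar I/O.
- **variation** — action integrals (Simpson), Euler–Lagrange residuals,
  the discretized second-variation quadratic form (piecewise-linear FEM,
  mass-lumped), and conjugate-point location by two independent routes:
  a sliding-endpoint eigenvalue scan and zeros of the Jacobi-field
  determinant.
- **caustics** — family action surfaces S(u, ·), caustic detection via the
  joint vanishing of ∂S/∂u and ∂²S/∂u², geometric envelopes of member
  curves, Hessian-determinant scans of action fields, and confirmation of
  the saddle beyond a caustic by the inertia flip of the second variation.
- **catastrophe** — the registry of the seven elementary normal forms,
  jet-based classification of sampled critical points, seeded
  perturbation-stability tests, Boltzmann moments of catastrophe
  potentials and moment-based recovery of cusp controls.
- **kinetics** — the barrier rate law `rate = γ·exp(−ΔG†/kBT)`, linear
  denaturant chevron curves, and contact-order scaling of folding time.
- **fixtures** — seeded, byte-reproducible generators for every synthetic
  input used in testing (each manifest embeds its analytic ground truth).
- **interface** — strict YAML run configs, the end-to-end scenario
  pipeline, and the umbrella CLI.

Angles are unwrapped radians; energies default to units of kBT = 1.

## CLI

All functionality is reachable through subcommands of `foldcaustic`
(exit codes: 0 ok, 2 validation error, 1 runtime failure):

```bash
foldcaustic fixtures --name harmonic_focus --seed 1 --out fixtures/
foldcaustic run --config fixtures/harmonic_focus.config.yaml --out out/
foldcaustic simulate --config model.yaml --q0 1.0 --v0 0.0 --out traj.csv
foldcaustic conjugate --config model.yaml --traj traj.csv --out points.json
foldcaustic caustic --config model.yaml --family family.csv --out caustic.json
foldcaustic classify --samples field.csv --out class.json
foldcaustic stability --form cusp --a -1 --b 0 --trials 200 --seed 42
foldcaustic moments --a 1 --b 0.2 --kbt 1
foldcaustic chevron --gamma 1e6 --dg0 1.5 --kbt 1 --cmax 8 --n 50 --out chevron.csv
```

`run` executes shoot_family → family_action_surface → detect_caustic →
saddle_check_beyond and writes a versioned `report.json`.

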