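# cisapop

Mass-action ODE modelling of cisplatin-induced apoptosis signalling.

Cisplatin is a platinum chemotherapeutic whose dose-limiting side effect is
renal cell death. Inside the cell its aquated form triggers programmed cell
death along three routes that converge on the executioner caspase-3:

* **Pathway I — death receptor:** FasL activation → caspase-8 → caspase-3;
* **Pathway II — mitochondrial:** a DNA-damage branch (ATR → p53 →
  caspase-2/AIF release and p53 → Bax/Bak → cytochrome *c* release) and a
  ROS branch (mitochondrial ROS → MPTP opening → cytochrome *c* release),
  both feeding caspase-9 → caspase-3;
* **Pathway III — ER stress:** Ca²⁺ release → calpain → caspase-12 →
  caspase-9.

`cisapop` implements this network as a generic mass-action reaction-network
simulator plus a bundled 44-state model (51 reactions, 51 rate constants,
dimensionless units) and drivers for the standard in-silico experiments:
dose–response, single-pathway knockout with cross-talk decomposition,
±30 % parameter perturbation, and local sensitivity analysis. It is aimed
at systems biologists who want to interrogate or extend the model, swap in
their own reaction schemes (YAML config or SBML L3), or reuse the
compilation/conservation machinery for other mass-action networks.

## The model in brief

Each reaction step `consumed + catalysts → produced` contributes the
mass-action rate

```
rate = k · ∏ consumed_iᵛⁱ · ∏ catalyst_j
```

and the ODE system is `dy/dt = N·r(y)` with `N` the net stoichiometric
matrix over the 44 dynamic species. Catalysts (e.g. active caspases in the
apoptosis-producing steps, or the constant inputs Cisplatin/OCT2/FasL/
DNA/Mit/ER) multiply rates without being consumed. Apoptosis (`Apop`) is a
pure accumulator fed by the caspase-9*/3*, caspase-8*/3* and
caspase-2*/AIF fluxes, so it is nondecreasing in time and in cisplatin
dose. The left null space of `N` yields the conserved moieties (each
caspase, p53, Bax, IAP and AIF pool totals 1 along every trajectory), which
the test suite uses as integration oracles.

Pathway knockouts zero the pathway's constant input species (FasL; DNA and
Mit; ER). Running the full model and the three exclusive single-pathway
models decomposes total apoptosis as

```
total = I_only + II_only + III_only + crosstalk
```

with the cross-talk residual exact by construction.

## Worked example

```python
import cisapop as ca

# Pin the model's one free convention: the reporting horizon at which the
# full-dose baseline reaches its reference apoptosis level 0.22512.
t_star = ca.calibrate_horizon()
print(f"calibrated horizon: {t_star:.4f} time units")

settings = ca.SimulationSettings(t_end=t_star)
result = ca.pathway_contributions(settings)
print(result.to_frame().to_string(index=False))

ranking = ca.rank_parameters(
    ca.local_sensitivities(ca.build_cisplatin_network(),
                           "rate_constants", settings=settings)
)
print("most sensitive rate constants:",
      ", ".join(name for name, _ in ranking[:5]))
```

prints

```
calibrated horizon: 6.4547 time units
  component  apoptosis_level    percent
      total         0.225120 100.000000
  pathway_I         0.085821  38.122177
 pathway_II         0.089110  39.583359
pathway_III         0.000250   0.111067
  crosstalk         0.049939  22.183397
most sensitive rate constants: k1+, k37+, k18+, k19+, k13+
```

Read: with all three pathways active the apoptosis readout at the
calibrated horizon is 0.2251; the mitochondrial pathway alone accounts for
the largest exclusive share, the ER-stress pathway is negligible, and about
a fifth of the total is attributable to cross-talk between pathways — no
single-pathway simulation can produce it. The cisplatin-uptake rate
constant `k1+` tops the sensitivity ranking, i.e. apoptosis responds more
strongly to the drug influx step than to any downstream kinetic parameter.

The same experiments are available from the shell:

```
cisapop contributions --t-end 6.4547 --out-dir out/
cisapop dose-response --doses 0,0.01,0.1,0.5,1 --t-end 6.4547 --out-dir out/
cisapop perturb --parameters k1+,k13+ --factors 0.7,1.3 --out-dir out/
cisapop export-sbml --out model.xml
```

Each run writes a CSV table, a JSON summary and a log with the model hash
and settings, so identical invocations are bit-reproducible.

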