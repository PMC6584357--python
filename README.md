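# protrusim

Protrusion-mediated Delta–Notch lateral inhibition in a 1D row of
spinal-cord cells.

During early spinal-cord neurogenesis in zebrafish, neurons of a given
subtype differentiate in a sparse, long-distance pattern, and later
neurons fill in the gaps.  Differentiating neurons transiently extend
two long, Delta-rich basal protrusions along the anteroposterior axis
before growing an axon, and Notch activity rises in the cells they
touch — lateral inhibition delivered several cell diameters beyond the
soma.  `protrusim` is the quantitative companion to that hypothesis:
an agent-based simulator of a 1D row of cells coupling the classic
lateral-inhibition equations to the measured protrusion kinetics,
together with a random-differentiation null, a closed-form limiting
model, a synthetic recording generator, and the spatiotemporal
statistics to compare them all.  It is aimed at quantitative
developmental biologists who want to regenerate, probe, or extend the
model's predictions without any external data.

## The model

Per cell, with `N`, `D` the amounts of active Notch and Delta:

```
dN/dt = R_N · D_in^k / (a + D_in^k) − μN
dD/dt = R_D / (1 + b·N^h)           − ρD
D_in  = α·Σ_soma D + β·Σ_protrusions D
P_diff = p · N_th^q / (N_th^q + N^q)
```

Cells whose Notch falls below the threshold window commit (probability
`P_diff` per Euler step), extend two protrusion arms to independently
sampled caps `l_max ~ Normal(42.6, 20.2) μm` (wild type) or
`Normal(12.3, 4.7) μm` (Laminin-depleted, *lamc1*-like), signal
through them while extended, retract, and drop out of the signaling
pool.  The central statistic is **dx**, the distance between
temporally successive differentiation events within an 80 μm window.

## Worked example

```python
from protrusim import (SimulationConfig, run_experiment, sequential_dx,
                       random_null_experiment, LAMC1)

# 100 wild-type replicates of a 50-cell row, protrusion-only signaling
wt = run_experiment(SimulationConfig(n_replicates=100, seed=1))
s = sequential_dx(wt)                      # 80 um analysis window
print(f"wild-type  dx = {s.mean:.2f} +/- {s.sd:.2f} um  (n={s.n})")

mut = run_experiment(SimulationConfig(n_replicates=100, seed=1, kinetics=LAMC1))
sm = sequential_dx(mut)
print(f"lamc1-like dx = {sm.mean:.2f} +/- {sm.sd:.2f} um  (n={sm.n})")

null = sequential_dx(random_null_experiment(100, 50, master_seed=1))
print(f"random     dx = {null.mean:.2f} +/- {null.sd:.2f} um  (n={null.n})")
```

prints

```
wild-type  dx = 53.95 +/- 18.27 um  (n=829)
lamc1-like dx = 46.51 +/- 19.08 um  (n=1115)
random     dx = 42.24 +/- 21.76 um  (n=1225)
```

Long wild-type protrusions push successive events apart (and deplete
spacings below ~20 μm almost entirely); short mutant protrusions pull
the distribution partway back toward the random null — the spacing
pattern tracks protrusion length.

The same pipeline is scriptable from the shell:

```
protrusim simulate --genotype wild_type --replicates 100 --seed 1 --out wt.tsv
protrusim stats wt.tsv
protrusim null --rows 100 --cells 50 --seed 1 --out null.tsv
protrusim analytic --dx-mean 45.3 --lmax-mean 12.3   # -> {"phi": 0.0244, ...}
protrusim reproduce fig7b --seed 1
```

Every run writes a JSON manifest (resolved parameters, seeds, output
checksums) next to its outputs.

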