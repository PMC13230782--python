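# cosref

Regulated threshold contagion on modular networks: who adopts a spreading
piece of information when transmission inside and between communities can be
throttled independently, and how much throttling is enough?

The package is aimed at researchers in network epidemiology and information
dynamics who study complex contagion — adoption that needs social
reinforcement rather than a single exposure — on community-structured
graphs, and at anyone designing containment policies that trade intervention
cost against spread.

## Model

A network of N nodes is split into communities (reference case: two equal
halves A and B) with per-channel degree distributions P_intra(k), P_inter(k)
and mixing parameter mu = z_inter / (z_intra + z_inter). Nodes are
susceptible (x_i = 0) or adopted (x_i = 1); at each synchronous update a
node of total degree k adopts iff its regulated influence beats a threshold:

    m . omega > theta k          (proportional rule)
    m . omega > C                (constant rule)

with m = (m_intra, m_inter) the adopted-neighbour counts per channel and
omega = (omega_intra, omega_inter) the effective transmissibilities
(1 - omega is the intervention intensity). The order parameter is the final
adoption density rho_inf. Sweeping (omega_intra, omega_inter, mu) produces
three regimes separated by abrupt transitions — non-diffusion
(rho_inf ~ rho0), localized (the seed community saturates, rho_inf ~ 0.5
for equal halves), and global diffusion (rho_inf ~ 1).

Besides the Monte Carlo simulator, a tree-like (cavity/message-passing)
solver computes rho_inf analytically by iterating link-level adoption
probabilities y^I to their fixed point, and an optimiser finds the cheapest
regulation pair inside the controllable region U_free (where diffusion fails
to percolate) under an exponential cost
F(omega) = (e^{-(omega_intra+omega_inter)} - e^{-2}) / (1 - e^{-2}).
SNAP-style edge lists with ground-truth communities can be reduced to
two-community subsystems and run through the same machinery.

## Worked example

Where does the abrupt transition sit when cross-community transmission is
unrestricted? Poisson blocks with total mean degree z = 15, mu = 0.5,
theta = 0.25, a 10% seed placed in community A:

```python
import numpy as np
from cosref import TLModel, find_critical, seeded_rho0, tl_fixed_point

model = TLModel.two_community_poisson(z=15.0, mu=0.5)
rho0 = seeded_rho0(model, 0.1)          # [0.2, 0.0]: the seed community holds all seeds

for wi in (0.5, 0.68, 0.69, 1.0):
    res = tl_fixed_point(model, (wi, 1.0), theta=0.25, rho0=rho0)
    print(f"omega_intra={wi}: rho_inf={res.rho_global:.4f}")

print(find_critical(model, moving="omega_intra", bracket=(0.5, 0.9),
                    theta=0.25, rho0=0.1, omega_inter=1.0))
```

prints

```
omega_intra=0.5: rho_inf=0.1247
omega_intra=0.68: rho_inf=0.1529
omega_intra=0.69: rho_inf=1.0000
omega_intra=1.0: rho_inf=1.0000
```

and the bisected critical point `0.687890625`: below it the system stays on
the non-diffusive plateau (the seeds plus a small fringe of early adopters),
above it a single step of extra intra-community transmissibility tips the
whole network into global adoption. A Monte Carlo ensemble
(`ensemble_rho_inf`, N = 2 x 10^4) reproduces these densities within 0.001.

The same machinery from the shell:

```sh
cosref tl --z 15 --mu 0.5 --theta 0.25 --rho0 0.1 --omega-intra 1 --omega-inter 1
cosref simulate --z 15 --mu 0.5 --theta 0.25 --rho0 0.1 \
    --omega-intra 0.5 --omega-inter 1 --n 20000 --realizations 20 --seed 1
cosref phase --z 15 --theta 0.25 --rho0 0.1 --grid 0.05 --out phase.csv
cosref optimize --z 20 --theta 0.1 --rho0 0.17 --mu-grid 0.1:0.9:0.05
```

`cosref optimize` sweeps the mixing parameter, traces the boundary of the
controllable region for each mu, and reports the minimal cost F(omega_o):
the curve rises from F = 0.22 at mu = 0.1 to a peak of about 0.50 near
mu = 0.45-0.5 and falls to 0.21 at mu = 0.9 — moderately mixed networks are
the most expensive to contain, and the optimal regulation tilts toward the
channel that carries the structure (intra for strong communities, inter for
weak ones).

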