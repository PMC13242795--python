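# pifgen — parameter-interpolation-flow generation for molecular point clouds

`pifgen` is a generative-modelling library for 3D molecules represented as
point clouds (per-atom coordinates in Å plus a categorical atom type).  It is
aimed at researchers studying structure-based molecule generation who want a
small, fully inspectable implementation of *parameter-space* flows: instead of
transporting samples, the model linearly interpolates **distribution
parameters** between a flexible prior and a Dirac embedding of each data
point, for continuous and discrete variables alike.

## The model

Coordinates are modelled per atom as isotropic Gaussians `N(x; μ, ε²I)`
(or, alternatively, factorised Laplace distributions) and atom types as
Dirichlet distributions `Dir(v; α)` over the K-simplex.  A datum is embedded
as the zero-spread limit: `θ_x,data = (x_data, 0)` and `θ_v,data =
onehot(v_data)`.  With priors `θ_x,prior = (0, ε₀)` and `θ_v,prior =
(1/K, …, 1/K)`, the path at time `t ∈ [0, 1]` is

    θ_t = f(t) · θ_data + (1 − f(t)) · θ_prior,     f(t) = 1 − γᵗ

(with linear `f(t) = t` and quadratic `f(t) = t²` variants).  Two geometric
facts make this path attractive, and both are verified to machine precision
by the test suite and `pifgen verify`:

* for 1D Gaussians, linear interpolation of `(μ, ε)` is the **2-Wasserstein
  geodesic**: `W₂(p₀, p_t) = t · W₂(p₀, p₁)`;
* for Dirichlet distributions, linear interpolation of concentrations is an
  **exponential geodesic under the Fisher–Rao metric**: densities along the
  path are normalised geometric mixtures of the endpoints.

A network Φ is trained to predict the data-endpoint parameters from samples
drawn at intermediate `θ_t` (with time weight `(1−γᵗ)²/(2γᵗε₀²)` on the
coordinate term and an elementwise log-gamma/digamma objective on the type
term).  Generation runs the path in reverse: starting from the prior, each of
100 steps samples the current parameters, predicts the data endpoint, and
re-interpolates.  Fixing a substructure as Diracs at every step yields
conditional generation (fragment growing, scaffold hopping).  Training uses
geometry-enhanced masking: with probability 0.3 a random 30% of ligand atoms
become reconstruction targets while the rest are shown to the network as
fixed context.

Defaults: `ε₀ = 1`, `γ = 0.009`, `β₀ = 1`, `P_m = P_am = 0.3`, 100 sampling
steps, K = 4 atom types.

No external dataset is required: `pifgen.synthetic_data` generates ligand-like
point clouds (chains, rings, branched topologies with bond lengths
1.5 ± 0.03 Å and angles 109.5 ± 3°) paired with deterministic pocket stubs,
and `pifgen.predictor` provides both a small trainable E(3)-aware
message-passing network (pure numpy, with its own reverse-mode autodiff) and
an oracle predictor used to validate the sampling machinery independently of
learning.

## Worked example

Verify the analytic geometry claims, then reproduce a molecule exactly with
the oracle-driven sampler:

```bash
$ pifgen verify --seed 0
W2 geodesic max residual: 8.88e-16
Fisher–Rao e-geodesic max residual variance: 1.20e-30
Gaussian KL vs quadrature: 0.00e+00; Dirichlet KL vs quadrature: 2.78e-16
all analytic properties verified
```

```python
import numpy as np
from pifgen import MoleculeTemplate, SamplerConfig, oracle_predictor, sample_denovo
from pifgen.synthetic_data import make_pocket_ligand_pair

pocket, lig = make_pocket_ligand_pair(MoleculeTemplate(), 4, seed=3)
oracle = oracle_predictor({0: lig})
out = sample_denovo(oracle, pocket, lig.n_atoms,
                    SamplerConfig(n_steps=100, seed=5), instance_id=0)
print(np.max(np.abs(out.coords - lig.coords)))   # 0.0
print(np.array_equal(out.types, lig.types))      # True
```

The residuals are at machine epsilon because the interpolation machinery is
exact: the only approximation in the whole pipeline is the learned predictor.
With a perfect predictor the 100-step refinement returns every molecule
bit-for-bit — the strongest possible correctness check of the sampler.

The full command-line pipeline:

```bash
pifgen make-data --template chain --n 100 --seed 7 --out data/
pifgen train --config config.yaml --out run/
pifgen sample --model run/model.json --n-atoms 6 --n-mols 20 --steps 100 \
              --seed 1 --out gen/
pifgen inpaint --model run/model.json --fixed fragment.xyz --n-new 3 \
               --seed 1 --out grown.xyz
pifgen evaluate --ref data/ --gen gen/ --report report.json
```

`evaluate` reports the Jensen–Shannon divergence (bits, 64 bins) between
reference and generated bond-length (`jsd_bond_length`) and bond-angle
(`jsd_bond_angle`) distributions; 0 means identical binned distributions, 1 is
maximal.  See `docs/methods.md` for what the desk-scale reference network can
and cannot achieve on these metrics.

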