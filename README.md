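# shpcvm

Rotation-invariant spherical-harmonics shape descriptors for small
molecules, minimum-redundancy-maximum-relevance (mRMR) feature selection,
and a Probabilistic Classification Vector Machine (PCVM), assembled into a
ligand-based virtual-screening pipeline for compound-activity prediction.

## The problem

Given the 3D structure of a candidate ligand, predict whether it is active
against a target (for example a G protein-coupled receptor) from shape
alone. This requires (a) a fixed-length numeric representation of molecular
shape that does not depend on how the molecule happens to be oriented, and
(b) a classifier that copes with small, imbalanced training sets and
returns calibrated probabilities rather than bare labels.

## The method

**Descriptor.** Each molecule is translated to its centroid and scaled so
that every atom's van der Waals sphere fits in the unit ball. Its shape is
then sampled as a spherical *depth map* f(θ, φ) — the radial extent of the
molecule along each direction of an equiangular 2B × 2B grid — and expanded
in real spherical harmonics:

    c_{l,m} = ∫∫ f(θ, φ) · y_l^m(θ, φ) · sin θ dθ dφ

with y_l^m built from associated Legendre functions and the normalization
S_{l,m} = √((2l+1)(l−m)!/(4π(l+m)!)). Rotating the molecule only mixes
coefficients within a degree l, so the per-degree norms

    ‖v_l‖ = √( Σ_{m=−l}^{l} c_{l,m}² ),   V = (‖v_0‖, …, ‖v_L‖)

are rotation invariant and form the descriptor (length L+1, default 64).

**Feature selection.** mRMR greedily ranks descriptor components by
ψ = D − R, where D is the mean mutual information of the selected set with
the activity label and R the mean pairwise mutual information within the
set. Selection is fitted on training data only; the frozen index set is
applied to held-out data.

**Classifier.** The PCVM is a sparse kernel model
l(x) = ψ(Σ_i w_i φ_{i,θ}(x) + b) with a probit link ψ (the standard normal
CDF) and Gaussian-RBF basis functions on training points. Truncated
Gaussian priors force each weight's sign to match its training label and
prune most basis points during EM training, leaving a small set of
"classification vectors". Trained models report probabilities of activity;
evaluation uses accuracy, precision, recall, Matthews correlation
coefficient and Cohen's κ.

## Worked example

```python
import numpy as np
from shpcvm import (make_benchmark, make_toy_molecule, compute_sh_descriptor,
                    run_experiment, ExperimentConfig)
from shpcvm.shdesc import DescriptorConfig

# descriptor of one rod-shaped toy molecule
mol = make_toy_molecule("elongated", n_atoms=12, noise=0.1, seed=0)
v = compute_sh_descriptor(mol, DescriptorConfig(bandwidth=32, l_max=15))
print(np.round(v.norms[:6], 4))
# [0.8642 0.0056 0.3986 0.0075 0.2352 0.0028]

# full pipeline on the synthetic shape benchmark (100 actives + 30 inactives)
ds = make_benchmark(n_active=100, ratio=0.3, noise=0.05, seed=1)
rep = run_experiment(ds, ExperimentConfig(seed=1,
                                          classifiers=("pcvm", "svm", "nb")))
for name, m in rep.metrics.items():
    print(f"{name:5s} ACC={m.ACC:.3f} MCC={m.MCC:.3f} kappa={m.kappa:.3f}")
# pcvm  ACC=1.000 MCC=1.000 kappa=1.000
# svm   ACC=1.000 MCC=1.000 kappa=1.000
# nb    ACC=1.000 MCC=1.000 kappa=1.000
```

The descriptor of the rod alternates large even-degree norms with
near-zero odd-degree norms — the signature of a centrosymmetric shape. On
the benchmark, compact (active) and elongated (inactive) molecules are
shape-separable by construction, so all classifiers reach perfect held-out
scores on the 26-molecule external test set (104 train / 26 test, the 80/20
split).

The same flow is available from the shell:

```sh
shpcvm synth -o synth/                     # generate XYZ fixtures + labels
shpcvm describe synth/*.xyz -o desc.csv    # descriptors
shpcvm select desc.csv labels.csv -k 60    # mRMR ranking
shpcvm train desc.csv labels.csv -o model.json
shpcvm predict model.json desc.csv
shpcvm run --config cfg.yaml -o run/       # the full experiment
```

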