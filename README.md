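# scads — sparse common and distinctive simultaneous component analysis

`scads` analyzes **multi-block data**: several groups of variables
(questionnaire scales, gene expression, sensor channels, …) measured on
the same observation units.  The goal is to reveal which variables are
linked *across* the blocks (joint mechanisms) and which sources of
variation are specific to one block — with automated variable
selection, so the method scales to blocks with thousands of untargeted
variables.

## The model

The concatenated, standardized data X (I units × J variables) are
decomposed on the weight side,

```
X ≈ X W Pᵀ,      T = X W,      PᵀP = I_Q,
```

so each component score is an explicit linear combination of observed
variables.  Structure is imposed on the weights W only:

* **common/distinctive constraints** — each component draws on a chosen
  subset of blocks (zero-block constraints on W); a component using
  every block is *common*, one restricted to a subset is *distinctive*;
* **lasso + ridge penalties** — estimates minimize

  ```
  ‖X − X W Pᵀ‖²_F + λ1 ‖W‖₁ + λ2 ‖W‖²_F,     PᵀP = I,
  ```

  which sets weights exactly to zero (variable selection) and
  stabilizes the solution when variables outnumber units.

Estimation alternates an analytic orthogonal-Procrustes update for P
with coordinate-descent soft thresholding for W; the loss never
increases.  PCA and sparse PCA of the concatenated data are the
unconstrained special cases.  Model selection (number of components,
common/distinctive structure, penalty strength) uses 10-fold
Eigenvector cross-validation with the one-standard-error rule.  See
`docs/methods.md` for the full account.

## Worked example

Generate a two-block dataset with a known sparse structure (one
distinctive component per block plus one common component), then
recover the structure and weights:

```python
import numpy as np
from scads import (StructureTemplate, generate, template_to_mask,
                   tune_lasso_to_cardinality, select_structure,
                   tucker_congruence, vaf)

truth = StructureTemplate.from_string("D1 D2 C", K=2)
ds = generate(I=100, block_sizes=(250, 250), template=truth,
              sparsity_per_component=(0.2, 0.2, 0.6),
              noise_fraction=0.05, seed=3)

# which structure does cross-validation pick?
template, table = select_structure(ds.data, Q=3, seed=0)
print(table.to_frame().sort_values("mpress").head(3))

# fit with the true structure, lasso tuned to the true sparsity
mask = template_to_mask(truth, ds.data)
res = tune_lasso_to_cardinality(ds.data.values, 3, mask, lambda2=0.05,
                                target_nonzeros=int(np.count_nonzero(ds.W_true)))
print("Tucker congruence:", round(tucker_congruence(ds.W_true, res.model.weights), 3))
print("total %VAF:", round(vaf(ds.data.values, res.model)[0], 1))
```

Output:

```
      label    mpress        se  complexity
9     C C C  0.310473  0.005554      1500.0
4   D1 D2 C  0.310925  0.005638      1000.0
3  D1 D2 D2  0.312161  0.005675       750.0
Tucker congruence: 0.999
total %VAF: 94.9
```

Cross-validation barely separates the leading candidate structures —
the unconstrained `C C C` model edges out the generating `D1 D2 C` by
far less than one standard error, which is why the one-SE rule, not
the raw minimum, is used for selection.  The constrained fit recovers
the true weights almost exactly (congruence 0.999, "near equal"), and
the three components account for 94.9% of the total variance,
consistent with the 5% noise floor in the generated data.

A command-line interface wraps the same functionality:

```bash
scads simulate -i 100 --block-sizes 250,250 --noise 0.05 -o sim/
scads fit sim/block1.csv sim/block2.csv -q 3 --template "D1 D2 C" --lambda1 0.2 -o fit/
scads select sim/block1.csv sim/block2.csv --q-max 6 -o selection/
scads study recovery --reps 20 --seed 1 -o study/
```

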