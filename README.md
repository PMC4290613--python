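# gqsar — fragment-based group QSAR for congeneric series

`gqsar` models the activity of a congeneric series (compounds sharing a
common scaffold, differing only in the substituents at marked sites R1…Rn)
from **fragment-level** descriptors: instead of describing each whole
molecule, every substituent at every site gets its own small descriptor
block, so the fitted model reads directly as *"what should sit at which
site"*. It is aimed at medicinal and computational chemists doing R-group
optimisation — the original use case is a series of arylthioindole tubulin
polymerisation inhibitors.

## The model

For compound *i* with substituents at sites *s*, activity is modelled as

```
pIC50_i = b0 + Σ_j  b_j · d_j(i)
```

where each descriptor `d_j` belongs to one site and one fragment property:

| descriptor | meaning |
|---|---|
| `<site>-HAcceptorCount` | H-bond acceptor atoms in the fragment (default: every N and O) |
| `<site>-slogp` | Wildman–Crippen atomic-contribution log P of the H-capped fragment |
| `<site>-chi2` | simple 2nd-order connectivity index ²χ = Σ over 2-edge paths (δi·δj·δk)^(−1/2) |
| `<site>-NitrogensCount` | nitrogen atoms in the fragment |
| `<site>-MolecularWeight` | sum of atomic weights of the fragment's own atoms (Da) |

Model building follows the classic chemometrics recipe: invariable
descriptors are removed (variance cut-off 0.1), descriptors enter by
**stepwise-forward selection** (partial F-to-enter 4.0 / F-to-remove 3.0,
pairwise cross-correlation cap 0.5, at most n/5 terms), and the selected
block is fitted by **PLS1 (NIPALS)** with the latent-component count chosen
by leave-one-out q². Validation reports r², LOO q², external-test pred_r²
(all referenced to the training-set mean), the overall F on component
degrees of freedom, standard errors and a **Y-randomization** test
(Z = (h − μ)/σ against models refitted on permuted activities).

A fitted model screens **combinatorial substituent libraries**: the full
Cartesian product of per-site pools is enumerated, predicted, flagged for
extrapolation (max range-normalised distance outside the training descriptor
ranges) and ranked.

## Worked example

```python
from gqsar import GroupQSAR, descriptor_block, split
from gqsar.synthetic import arylthioindole_fixture

compounds, split_spec, truth = arylthioindole_fixture()   # 36-compound series
train, test = split(compounds, split_spec)            # 26 training / 10 test

results = GroupQSAR.from_series(train, sites=("R4", "R5", "R6")).fit()
print(results.equation())

X_test = descriptor_block(test, ("R4", "R5", "R6"))
report = results.validate(X_test, [c.pic50 for c in test])
print(f"r2 {results.r2:.4f}  q2 {results.q2:.4f}  "
      f"pred_r2 {report.pred_r2:.4f}  F {results.f_statistic:.1f}")
```

prints

```
pIC50 = (0.131947 × R4-HAcceptorCount) + (-0.209933 × R5-slogp) + (-0.154969 × R6-NitrogensCount) + (0.00116336 × R6-MolecularWeight) + (-0.0883062 × R6-chi2) + 5.25348
r2 0.9809  q2 0.9685  pred_r2 0.9302  F 205.4
```

— the five-term site-resolved equation, its resubstitution r², leave-one-out
q², external-test pred_r² and the overall F statistic. The positive
`R4-HAcceptorCount` and `R6-MolecularWeight` terms say acceptors at R4 and
heavier R6 groups raise predicted potency; the negative `R5-slogp`,
`R6-chi2` and `R6-NitrogensCount` terms say lipophilic R5 groups and
branched or nitrogen-bearing R6 groups lower it.

The same pipeline is scriptable from the shell:

```bash
gqsar simulate --out run/data --fixture
gqsar fit --series run/data/series.tsv --out run/fit \
          --test-ids 10,14,18,21,22,27b,29,30,31,35b
gqsar screen --model run/fit/model.json \
             --pool R4=pools/r4.smi --pool R5=pools/r5.smi --pool R6=pools/r6.smi \
             --out run/screen --top-k 20
```

Substituents are exchanged as SMILES with one `[*]` attachment dummy
(`[*]OC` = methoxy; the bare token `[H]` is the hydrogen substituent; a
bracket atom such as `[*][S]` is a bare heteroatom with no implicit
hydrogen).

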