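# Methods

## Model and assumptions

The package fits a site-resolved linear activity model to a congeneric
series: pIC50 = b0 + Σ b_j·d_j, where each descriptor d_j is computed on one
substituent fragment at one marked scaffold site. The implicit assumptions
are the usual ones of group-contribution QSAR: the scaffold's own
contribution is constant across the series (absorbed into the intercept),
site contributions are additive with no site–site interaction terms, and the
measurement error on pIC50 is homoscedastic — least squares and PLS are both
only optimal under (approximately) Gaussian noise, which is also the error
model the synthetic generator uses.

## Fragment conventions and descriptors

A substituent is a connected fragment with exactly one attachment-point
dummy atom; the reserved token `[H]` denotes the hydrogen substituent (zero
heavy atoms). Two fragment forms are used deliberately:

* **MolecularWeight** uses the *uncapped* substituent: the sum of the
  standard atomic weights of its own atoms, implicit hydrogens included,
  the dummy excluded and no cap added. Implicit-hydrogen counts follow
  SMILES semantics, so `[*]C` is methyl (15.035 Da) while a bracket atom
  such as `[*][S]` contributes the bare atomic weight (32.065 Da); `[*]S`
  is a thiol (33.073 Da). Atomic weights come from a bundled IUPAC table
  (not from the toolkit) so values are bit-reproducible. With this table a
  hydroxymethyl fragment weighs 31.034 Da; some published sources print
  31.021 for the same group, which is not reproducible from standard atomic
  weights and is not used.
* **chi2** and **slogp** use the *hydrogen-capped* fragment. The dummy is
  never a vertex of the descriptor graph — a dummy vertex would add spurious
  two-edge paths, and single-heavy-atom substituents must score ²χ = 0.

`chi2` is the simple second-order molecular connectivity index: the sum over
all simple two-edge paths i–j–k of (δi·δj·δk)^(−1/2) with δ the heavy-atom
degree. The name is sometimes glossed in the application literature as a
chromatographic "retention index of second order"; that description does not
match any graph-theoretic definition, and the standard connectivity index is
what is implemented. `slogp` is the Wildman–Crippen atomic-contribution
log P (hydrogens included), computed through RDKit's Crippen module; Open
Babel's independent implementation of the same published parameterisation
serves as the cross-check oracle in the test suite. The two implementations
assign different parameters to hydrogens on aliphatic amine nitrogens (and
to bare water/ammonia), so the cross-check set spans hydrocarbons,
aromatics, halides, ethers, alcohols, carbonyls, esters, nitriles, thio
compounds and azines, where they agree to 1e-4. The H-acceptor rule defaults
to "count every N and O" and can be switched to a strict variant that
excludes pyrrole-type NH, amide N and furan-type aromatic O — the choice is
a convention, not a measurement, and the default is the more reproducible
one.

## Selection and regression

Stepwise-forward selection operates on ordinary least-squares fits: at each
round the candidate with the largest one-term partial F enters if it clears
F-to-enter (4.0), subject to an absolute pairwise correlation cap (0.5)
against every already-selected descriptor, and any selected term whose
removal F falls to F-to-remove (3.0) or below leaves. At most n/5 terms may
enter. All ties break lexicographically on the canonical descriptor name, so
selection is deterministic and invariant to column order. PLS is applied to
the final selected block only: PLS1 by NIPALS deflation on autoscaled
descriptors and a centred response, with the component count chosen by
leave-one-out q² (ties toward fewer components; every LOO fold repeats the
autoscaling, so no information leaks from the held-out compound). With as
many components as the column rank, the PLS solution equals ordinary least
squares — this identity, against a normal-equations oracle and
scikit-learn's PLSRegression, anchors the regression tests.

The fitted model is stored back-transformed to original descriptor units
(coefficient_j = scaled coefficient / column SD; intercept = ȳ − Σ b_j·x̄_j),
which is exact: predictions through the back-transformed equation match the
latent-space predictions to round-off. Contribution percentages are
normalised absolute autoscaled coefficients, |b_scaled|/Σ|b_scaled|×100 —
the convention used by the original modelling software is unpublished, so
printed percentages from the source study are treated as descriptive, not as
test targets.

The overall F statistic uses latent-component degrees of freedom,
F = (r²/c)/((1−r²)/(n−c−1)): with the study's printed r² = 0.8512, n = 26
and c = 2 this gives 65.79, matching its printed F of 65.7699, whereas
descriptor-count degrees of freedom (k = 5) would give ≈ 22.9.

## Validation statistics

q² (leave-one-out) and pred_r² (external test set) are both computed as
1 − Σ(y−ŷ)²/Σ(y−ȳ_train)² with the **training-set mean** as the reference in
both cases; both can be negative. r² is the squared Pearson correlation of
fitted versus actual; standard errors are √(RSS/(n−df−1)) with df the
component count. Y-randomization permutes the activities, reruns the entire
selection + PLS chain per permutation (100 by default), and summarises the
separation as Z = (h−μ)/σ; a permutation on which selection finds no model
scores zero rather than being skipped, so the null distribution is never
thinned. The empirical tail fraction α (random statistics ≥ h) is reported
alongside the parametric normal-tail p-value, since the two notions are
both in circulation and disagree in small permutation counts.

## The synthetic generator

`gqsar.synthetic` emulates a designed congeneric series: a fixed scaffold,
per-site substituent pools, and activities that are a sparse linear function
of fragment descriptors plus Gaussian noise. Defaults are study-scale: 36
compounds, five true descriptors spread over R4/R5/R6
(R4-HAcceptorCount +, R5-slogp −, R6-chi2 −, R6-NitrogensCount −,
R6-MolecularWeight +), noise SD 0.15 pIC50 units.

Two generator choices matter for what the simulations can show:

* **Balanced sampling.** By default each pool member is used equally often
  per site (counts differ by at most one) with independently shuffled site
  columns — how a chemist designs a series, and what keeps the per-site
  descriptor variances and correlations close to their pool values in a
  36-compound draw. Uniform sampling over the Cartesian product is available
  (`sampling="uniform"`), but under it the nitrogen-count and chi2 columns
  occasionally fall under the 0.1 variance cut-off by sampling accident.
* **Identifiable pools and planted effects.** The default pools were
  composed so that, within each site, the five true descriptors and their
  natural proxies (e.g. acceptor count as a stand-in for nitrogen count)
  have pairwise pool correlations below the 0.5 cross-correlation cap:
  acceptor members span the full size/lipophilicity range, the chi2-carrying
  members have mean weight close to the pool mean, and amine members span
  chain lengths. The planted coefficients keep the published signs but use
  magnitudes giving each descriptor a comparable standardized effect
  (≈0.55–0.6 pIC50 units), i.e. an effect a 36-compound study at 0.15 noise
  can resolve; the published model's own weight coefficient (0.00256/Da)
  corresponds to an effect below that noise floor and would not be reliably
  recoverable at this sample size.

What passing the recovery simulations does and does not show: they show the
selection + PLS chain finds planted, well-separated effects at realistic
sample size and noise, and estimates their coefficients accurately at low
noise. They do not show that every real series is this well-conditioned —
real substituent sets are rarely balanced, fragment descriptors of real
R-groups are more collinear, and activity noise is not exactly Gaussian.

"Recovery" in the tests means every planted descriptor is selected
(screening consistency). Exact-set recovery — no spurious extra term — is
also computed and reported, but cannot be guaranteed at a high rate by any
threshold-based greedy selection: entry accepts the maximum partial F over
all surviving candidates, and with ~14 candidates at F-to-enter 4.0 the
null probability that *some* candidate clears the bar is ≈ 40–60%. The same
order statistics mean pure-noise activities leave the selection empty in
only ~half of replicates, not almost always; the suite asserts the
attainable property (empty in at least 40% of seeded replicates, never more
than a few spurious terms).

The deterministic 36-compound fixture (`arylthioindole_fixture`) uses narrower,
series-like pools (H/alkyl/methoxy at the aryl sites, halogen/amino/nitro/
alkoxy at the indole-core site), milder coefficients and 0.04 noise so all
activities stay within the 4.5–6.0 pIC50 band, with an explicit 26/10 split
whose test IDs mirror the original series' held-out compounds; its internal
seed was fixed once so the split is interpolative by construction.

## Library screening

Enumeration is the full Cartesian product of per-site pools in deterministic
lexicographic order (sites sorted, members by canonical SMILES), streamed;
with top-K requested only K entries are buffered. The extrapolation score is
the maximum over model descriptors of the range-normalised distance outside
the training [min, max] — 0 means fully inside the applicability range; a
zero-width training range contributes 0 on equality and ∞ otherwise. The
max-violation rule was chosen over a leverage statistic because it matches
the "zero or close to zero" screening language of range-based applicability
domains and is trivially interpretable per descriptor. Ranking is by
descending predicted pIC50, then ascending extrapolation, then lexicographic
assignment; reruns are bit-identical.

## Numerical choices and degenerate inputs

* Sample (n−1) standard deviations everywhere, the QSAR-software convention.
* The variance cut-off applies to raw (pre-scaling) descriptor values;
  constant columns are always dropped.
* A zero-variance response yields a zero PLS regression vector (no
  extractable component), not an error.
* A perfect candidate in stepwise selection (zero residual) has infinite
  partial F and enters definitively.
* One global seed drives every stochastic stage (splits, generator,
  permutations); artifacts carry the config hash and seed in a header line
  and reruns are byte-identical.

## Known limitations

* Descriptors are 2D fragment properties only — no 3D, electrostatic or
  field descriptors, so conformation-dependent activity cliffs are invisible
  to the model.
* The hydrogen-capped fragment is a modelling convention: capping changes
  the electronic environment relative to the scaffold attachment, which
  matters most for log P of very small fragments.
* Stepwise selection with fixed F thresholds has the multiplicity behaviour
  described above; selected models should always be read together with the
  Y-randomization report.
* The bundled arylthioindole template records one plausible assignment of
  R1–R6 to scaffold positions; every pipeline stage is template-agnostic and
  a user template with mapped dummies can be substituted throughout.
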