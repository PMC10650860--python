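# Methods

## Scope and data model

`stresskit` analyses balanced multi-environment trials laid out as
genotype × environment × replicate × trait observations. The
environment labels are fixed to the four-sowing design the package
emulates: two normal winter sowings (N1, N2), a late sowing with full
irrigation that synchronizes reproduction with >32 °C temperatures
(SI, terminal heat stress), and a late sowing with irrigation withheld
from flowering (SNI, combined heat-drought stress). Yields are in
g/plot, heights in cm, protein and harvest index in percent, minerals
in mg/kg, grain dimensions in mm/mm². Values are validated on load
(non-negative; percentage traits within [0, 100]; unique keys) with
row-numbered diagnostics.

Index computation starts from per-genotype replicate-mean yields under
one normal/stress pair of the same season. Genotypes observed in only
one member of the pair are dropped with a logged warning — every index
needs both yields — and population means Ȳp, Ȳs are taken over retained
genotypes only. A genotype with Ypᵢ = 0 would make YSI and SSI
undefined and is likewise excluded rather than given sentinel values.

## Indices

With Ypᵢ, Ysᵢ the genotype's normal and stress yields and Ȳp, Ȳs the
population means:

* SI = 1 − Ȳs/Ȳp (stress intensity, dimensionless, 0 = no stress);
* STI = Ypᵢ·Ysᵢ/Ȳp² — the denominator is the squared *population* mean
  (Fernandez's definition); with the per-genotype Ypᵢ² the index would
  collapse to a rescaled YSI;
* TOL = Ypᵢ − Ysᵢ; MP = (Ypᵢ+Ysᵢ)/2; GMP = √(Ypᵢ·Ysᵢ);
  HARM = 2·Ypᵢ·Ysᵢ/(Ypᵢ+Ysᵢ);
* SSI = (1 − Ysᵢ/Ypᵢ)/SI (Fischer–Maurer form); YSI = Ysᵢ/Ypᵢ.

Algebraic consequences used as test oracles: GMP² = MP·HARM exactly;
HARM ≤ GMP ≤ MP (AM–GM); YSI + SI·SSI = 1, so SSI is a strictly
decreasing affine map of YSI and their Pearson correlation is exactly
−1 whenever SI > 0, and any third column correlates with the two at
equal magnitude and opposite sign. Scaling all yields by c > 0 scales
TOL/MP/GMP/HARM by c and leaves SI, STI, SSI, YSI unchanged. SSI with
SI = 0 is undefined and raised as an error unless explicitly allowed
(then reported as NaN).

## Classification chain

The nine columns (Ys, Yp, seven indices) are z-standardized (n−1
denominator) before both PCA and clustering; without this the g/plot
columns would dominate every Euclidean distance. PCA eigendecomposes
the 9×9 correlation matrix (equivalent to PCA of the standardized
data); variance explained per dimension is 100·λ/9 and a variable's
contribution is 100 × its squared unit-eigenvector loading, so
contributions sum to 100 per dimension and eigenvalues to 9.
Eigenvector signs are fixed so the Ys loading is non-negative on every
dimension (eigenvectors are sign-ambiguous; the convention makes
biplots reproducible).

Clustering is agglomerative Ward — the minimum-variance criterion on
Euclidean distances of the standardized rows (the squared-Euclidean
"Ward.D2" objective), cut to k groups (default 4). Merge heights are
non-decreasing; the height recorded for a merge is √(2·ΔSS) where ΔSS
is the increase in within-cluster sum of squares, which the test suite
verifies against an exhaustive small-instance agglomeration.

The four clusters are labelled by a fixed rule on cluster means:
**tolerant** = highest mean GMP; **susceptible** = highest mean SSI
among the rest; of the remaining two, the higher mean YSI is
**moderately tolerant** and the other **moderately susceptible**. The
rule formalizes the qualitative cluster profiles this analysis is used
to report (tolerant clusters lead on GMP/STI/Ys; susceptible clusters
on SSI); exact ties raise an error demanding manual labels rather than
being broken silently. Cluster trait profiles average genotype
replicate-means within each cluster and separate clusters per trait by
Duncan's test at α = 0.05, using the pooled within-cluster variance of
genotype means and the harmonic mean cluster size as effective
replication.

## Trial statistics

*Two-way ANOVA* (genotype × environment) is fitted by OLS with
sequential sums of squares, which on the balanced designs the package
accepts coincide with the textbook cell-mean formulas (the suite checks
this against direct enumeration). Unbalanced inputs are rejected
outright rather than silently resolved into a Type-I/III choice. In
the zero-residual limit F is reported as ∞ for real effects and NaN
(0/0) for absent ones; sums of squares below numerical dust are
snapped to zero first.

*Broad-sense heritability* is the entry-mean variance-components
estimator within one environment: σ̂²_e = MS_error, σ̂²_g = max(0,
(MS_genotype − MS_error)/r), H² = σ̂²_g/(σ̂²_g + σ̂²_e/r). Negative
component estimates are truncated at zero, keeping H² in [0, 1]. This
replaces lattice-aware mixed-model estimation: no block-level
information is modelled (see Limitations).

*Correlation panels* use the product-moment r with two-sided p from
t = r√((n−2)/(1−r²)); stars at p < 0.05 (*) and p < 0.01 (**). The
exactly collinear SSI–YSI pair is printed −1.00 ** by convention even
though the t statistic degenerates. *Mean separation* supports LSD
(t(1−α/2, df)·√(2·MS/r), span-independent) and Duncan's multiple range
test (studentized-range critical value at protection level
(1−α)^(span−1), times √(MS/r)); for a span of two the Duncan range
reduces exactly to the LSD. Letters are assigned greedily from the
largest mean over maximal non-significant runs of the ranked means.

## Synthetic data

The generator exists because the emulated trial deposits no raw
per-plot data; it provides inputs with exactly the structure the
estimators assume, with known truth for recovery scoring.

`simulate_trial` draws value(g,e,r) = mean(trait,e) + G_g + (GE)_ge +
ε_ger with independent normal effects — the additive model behind the
balanced ANOVA and the heritability estimator. The incomplete-block
(alpha-lattice) layout of real trials is *not* simulated: no downstream
stage uses block information. Negative draws are truncated at 0 (with
a logged count) rather than resampled, so the draw count and hence the
random stream never depend on drawn values; all randomness flows
through NumPy's PCG64 `default_rng`, making fixed seeds reproducible
across platforms.

`simulate_yield_pairs` plants a tolerance-group structure directly in
(Yp, YSI) space: per genotype in group c, Yp ~ N(μYp_c, 12²) truncated
positive and YSI ~ N(μYSI_c, 0.03²) truncated to (0.01, 1.2), with
Ys = Yp·YSI and the planted group recorded for scoring.

Presets (fixtures addressable by name):

* `paper_protein` — protein %, treatment means 20.26 (N1, N2), 22.19
  (SI), 21.94 (SNI); SDs 0.4 (genotype), 0.2 (G×E), 0.5 (residual).
  The residual SD is fixed by the study conditions; the genotype and
  G×E SDs are chosen to give the low-to-medium heritability typical of
  protein content in this crop (H² ≈ 0.6–0.7 at r = 2).
* `paper_heat_clusters` — group sizes (11, 5, 12, 15), mean YSI
  (0.55, 0.70, 0.32, 0.20), mean Yp (280, 190, 310, 215) g/plot.
* `paper_sni_clusters` — group sizes (22, 2, 12, 7), mean YSI
  (0.45, 0.75, 0.25, 0.10), mean Yp (280, 170, 320, 260) g/plot.

The cluster-preset group *sizes* are the study's reported four-cluster
partitions; the group means and SDs are package-chosen fixtures,
calibrated only in the qualitative sense that each group carries its
class's profile (tolerant: highest GMP/STI/Ys; moderately tolerant:
highest YSI, lowest TOL/SSI; moderately susceptible: highest Yp and
TOL; susceptible: highest SSI) and that adjacent groups sit ≈7 within-
group SDs apart in at least one of the (Yp, YSI) coordinates. That
margin matters: at ~4.7 SD separation boundary genotypes of the larger
groups are misassigned on a material fraction of seeds, while at ≈7 SD
the chain recovers the planted partition essentially always (measured:
59–60 of 60 seeds). Because the real trial's dispersions are unknown,
recovery on these presets demonstrates correctness of the chain, not
expected accuracy on field data, where cluster separations are far
weaker and cluster membership is correspondingly less stable.

## Numerical choices and degenerate inputs

* Tolerances: index identities hold to 1e-10 relative; ANOVA SS
  decomposition to 1e-9 relative; PCA eigenvalues checked against an
  independent characteristic-polynomial solve to 1e-9.
* Standardization of a zero-variance column, PCA on non-finite data,
  k outside [1, n−1], single-replicate heritability, zero-baseline
  percent change and SSI at SI = 0 all raise typed errors naming the
  offending input.
* Letter display uses a relative tie tolerance of 1e-12 so that
  MS_error = 0 separates any unequal means and groups exact duplicates.
* Pipeline outputs round floats to 6 decimals and stamp every file
  with the seed and a config hash; reruns with identical config are
  byte-identical.

## Limitations

* Only balanced designs are supported; there is no mixed-model REML,
  no spatial or incomplete-block adjustment, and no multiple-testing
  correction beyond per-cell stars.
* The labelling rule assumes the four clusters actually differ in
  GMP/SSI/YSI means; on data without real tolerance structure it will
  still assign labels (or raise on exact ties), and the labels then
  carry no meaning.
* The synthetic generator draws independent normal effects and plants
  well-separated clusters; real trials have correlated traits,
  non-normal residuals and much weaker group separation. Passing
  recovery tests certify the algorithms, not field-data performance.
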