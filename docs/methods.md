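# Methods

## The model

`delphisim` simulates a classic three-round Delphi survey: `r` experts rate
`n` survey questions on a bounded ordinal scale `1..q` (default 1–10), see
the anonymised group result between rounds, and may move their ratings
toward the emerging group opinion. The model rests on three components.

**Round 1 — maximal prior dissensus.** Every score is drawn i.i.d. from the
discrete uniform distribution on `{1..q}`. This represents a panel with no
shared prior opinion; all structure in later rounds is produced by the
convergence dynamic, not seeded into the initial ratings.

**Opinion clusters.** For each question, the ratings of the current round
are scanned with sliding windows of at most `v` consecutive scale points
(default `v = 3` on the 10-point scale). The window holding the most
ratings is the modal cluster (its count is `r_mode`); every further window
that does not overlap an already-selected cluster and holds at least
`p · r_mode` ratings (default `p = 0.5`) is a secondary cluster. A panel
with one cluster is in (emerging) consensus; several clusters are
structured dissensus. Ratings inside no selected window belong to no
cluster.

Candidate windows of width `1..v` are ranked by member count (descending),
then width (descending, so a cluster is reported at its maximal extent),
then lower bound (ascending), and selected greedily subject to
disjointness. This ordering is a package design choice: the window-mode
rule itself does not dictate an enumeration order, and a deterministic
tie-break is required for bit-reproducibility. The same applies to the
selection of `p = 0.5`: the literature recommends `p ≥ 0.5` (smaller values
let marginal outlying windows count as clusters) without fixing a value, so
the package uses the lower end of the recommended range as its default and
exposes it as a parameter. The dependency magnitudes of the strongly
GCI-sensitive indices move by a few hundredths when `p` varies inside the
recommended range, so comparisons across studies should hold `p` fixed.

**Conformity update.** Between round `t` and `t+1`, each expert is assigned
the cluster whose *mean* rating is nearest their current score (the mean is
the convergence target, so distance is measured to it); a score exactly
midway between two cluster means goes to the more populous cluster, and to
the lower-lying one if the counts also tie. The new score is

    round( GCI · mean_cluster + (1 − GCI) · score )

rounded half-away-from-zero to the nearest scale point and clamped to the
scale. The Group Conformity Index (GCI ∈ [0, 1]) is the single behavioural
parameter: 0 is a fully stubborn panel (scores never move), 1 a fully
conforming one (scores jump to the rounded cluster mean). Experts already
inside a cluster still converge toward its mean; all randomness lives in
round 1, so rounds 2 and 3 are deterministic given round 1.

Midway ties are detected with an absolute slack of 1e-9: cluster means are
ratios of small integers, so intended ties (e.g. a score of 6 between means
4.0 and 8.0) sit within a few ulps of exact equality and anything farther
apart is a genuine difference. Exact-half rounding cases arise only from
exactly representable products, where half-away-from-zero is applied
exactly.

## The nine indices

All indices are computed on the final-round matrix; the cluster-based ones
(CPWA, CM) use cluster sets re-identified from the final round itself.
Per-item values are averaged (unweighted) over questions to give the
study-wide value. DM, PWA, CPWA, XCPWA, M, CM live in [0, 1]; IQR in
[0, q−1]; the kappas in (−∞, 1].

| Index | Per item | Notes |
|---|---|---|
| DM | 1 iff all `r` experts agree | unanimity indicator |
| PWA | agreeing pairs / (r(r−1)/2) | equals Σ_j r_ij(r_ij−1)/(r(r−1)) |
| CPWA | Σ_clusters m_j(m_j−1)/(r(r−1)) | scores outside every cluster count 0 |
| XCPWA | CPWA with fixed clusters 1–3 and 8–10 | extremes of the scale |
| M | modal-score share / r | ties do not change the share |
| CM | modal-cluster share / r | ≥ M by construction |
| IQR | q75 − q25 | dispersion; 0 = tight consensus |
| KF | (P − P_e)/(1 − P_e), study-wide | chance from pooled marginals |
| KC | same with P_e,C = P_e − Σ_j s_j²/(r−1) | expert-marginal correction |

Decisions where the definitions leave room:

* **Kappas are study-wide only.** The observed- and chance-agreement sums
  run over all items before the ratio is taken; averaging per-item kappas
  is a different (and noisier) statistic, so `per_item` is empty for KF/KC.
* **Degenerate kappa.** If every expert gives the identical single rating
  everywhere, P = P_e = 1 and the ratio is 0/0. The package returns 1:
  perfect agreement is perfect consensus, not undefined.
* **IQR quantile convention.** Quantiles interpolate linearly between order
  statistics at rank `1 + (r−1)·m/100`. No convention is canonical for
  ordinal data; this common one is fixed so that results are
  bit-reproducible, and documented because small panels are sensitive to it.
* **IQR as criterion vs. as index.** The conventional consensus *criterion*
  (IQR ≤ threshold, default 1.0 scale points) is exposed as
  `iqr_consensus`; the dependency experiments use the raw IQR values.
* **Modal ties** break toward the lower score / lower cluster; the reported
  proportion is unaffected.

## Dependency experiments

One survey characteristic is varied while the other two stay at the
baseline (12 questions, 20 experts, GCI 0.5): question count over the
integers 6–40, panel size over 6–50, GCI over 0.0–1.0 in steps of 0.1 (the
grid granularity within the stated ranges is a package choice; integer
steps and a 0.1 GCI step bracket the extreme medians at modest cost). Each
condition is simulated 1000 times; the median over replicates (mean of the
two central order statistics for even counts) of each study-wide index
represents the condition, and

    dependency = max over grid of medians − min over grid of medians

IQR's dependency is divided by `q − 1 = 9` so that all nine dependencies
read on the same 0 (immune to the characteristic) to 1 (swings across its
whole range) scale. Dependencies are reported to three decimals.

**Random-stream discipline.** Each replicate uses a dedicated child of a
`numpy` `SeedSequence` built from `(master seed, swept parameter, condition
value)` — keyed by the condition's *value*, not its grid position, so
reordering or subsetting the grid cannot change any replicate. No stream is
shared between replicates; a master seed fully determines every table.

## What the generator does and does not emulate

The simulator reproduces the mechanics that drive consensus *indices*:
ordinal scoring, clustered opinion formation, and graded conformity. It
deliberately omits features of real panels: qualitative feedback between
rounds (not modellable non-randomly), expert dropout, per-expert
heterogeneous conformity, informative round-1 priors, and radical opinion
jumps to non-nearest clusters. Passing tests therefore certify the index
implementations and the behaviour of this model — e.g. that IQR reacts
strongly to panel size under uniform priors — not quantitative predictions
for any particular empirical Delphi study, where initial ratings are far
from uniform and conformity varies across experts.

## Numerical and scale choices

* Simulations use the full grids at 1000 replicates per condition in both
  the acceptance script and the heavy acceptance tests (≈ 91 000 studies,
  a few minutes on one core); unit and property tests use small matrices
  and reduced replicate counts (25–200) that keep the Monte-Carlo error of
  a median well inside the asserted tolerances.
* Comparisons against the published dependency values use an absolute band
  of ±0.05, reflecting Monte-Carlo spread plus the under-specified
  clustering details (`p`, tie-breaks, quantile convention) noted above;
  rank-order agreement is the stricter headline check, with observed gaps
  under 0.01 treated as ties because they sit below simulation noise.
  Under the package defaults most dependencies land within the band and
  all large-vs-small orderings agree; the known deviations — the IQR
  panel-size dependency and the GCI dependencies of KF/KC/PWA come out
  smaller than the published 0.396 / 0.504 / 0.501 / 0.480 — trace to the
  secondary-cluster threshold: `p = 0.5` admits more secondary clusters
  (hence weaker convergence, especially in small panels) than the
  reference results appear to reflect.

## Known limitations

* A cluster interval may include empty edge points (a unanimous panel at 4
  reports cluster [2, 4]): width-maximal reporting trades interval
  tightness for rule simplicity; means and member counts are unaffected.
* With `p` at the low end of its recommended range, single isolated
  ratings can form singleton clusters in very small panels, freezing those
  experts in place.
* The midway tie rule operates on floating-point means; ties farther than
  1e-9 apart from exactness are resolved as ordinary distances.
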