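# Methods

## The procedure

`rdscentral` implements a biomarker-identification procedure for
respondent-driven sampling (RDS) surveys. RDS recruits hidden populations
through peer-distributed coupons: each participant may hand out up to 6
coupons, so the referral network is a forest of recruitment trees in which
node degree never exceeds 7 (one's own recruiter plus six recruits) and no
cycles can form (nobody recruits a person already enrolled). The pipeline:

1. **Prep.** Features observed in at least `min_completeness` (default 94%)
   of respondents are retained, pooled across cities; declined-answer codes
   are treated as missing; user-listed metadata columns are dropped.
   Non-ordinal categorical features with k levels are one-hot encoded into
   k binary indicators `{feature}-{level}`; two-level features collapse to a
   single 0/1 indicator so a deviation is not counted twice through a pair of
   perfectly anti-correlated columns.
2. **Forest.** One undirected edge per recruiter–recruit pair, per city.
   Construction rejects orphan recruiter ids, cross-city links and any edge
   that would close a cycle. Acyclicity is enforced and checkable through the
   tree identity `|E| = |V| − #components`.
3. **Centrality.** Per component: closeness `c(v) = N / Σ_y d(y, v)`,
   betweenness `b(v) = Σ_{s≠v≠t} σ_st(v)/σ_st` (in a tree `σ_st = 1`, so this
   is the count of unordered node pairs whose unique path crosses `v`), and
   eigenvector centrality (principal eigenvector of the adjacency matrix,
   unit L2 norm).
4. **Selection.** The 5 highest-scoring nodes from each of the 3 largest
   components per city and measure — 15 central nodes when the components are
   large enough. Spreading the set across components prevents the largest
   chain from monopolising it.
5. **Exceptionality.** An observed attribute value is *deviant* when it lies
   more than two standard deviations from its city mean (mean and SD over the
   observed values of all the city's respondents). An attribute deviant in at
   least `min_count` (default 4) central nodes is reported with score
   `deviant_count / set_size`.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_completeness` | 0.94 | minimum observed fraction for a feature to survive filtering |
| `k_per_component` | 5 | central nodes taken per component |
| `m_components` | 3 | components analysed per city |
| `min_count` | 4 | deviant-count threshold for reporting |
| `closeness_numerator` | `N` | `N` follows the formula as published; `N-1` is the conventional form. The two differ by a constant factor within a component, so rankings and selections are identical |
| `sd_form` | `population` | divide-by-n SD; `sample` selects divide-by-(n−1). At realistic city sizes the difference is negligible; the population form makes the binary boundary below exact |
| eigenvector `tol`, `max_iter` | 1e-10, 10000 | power-iteration stopping rule (max-norm of successive iterates) |

For a binary attribute with city prevalence `p` under the population SD, a 1
is deviant iff `p < 0.2` and a 0 is deviant iff `p > 0.8` — the algebraic
consequence of `|x − p| > 2√(p(1−p))`. The selection denominator is always
the realized set size (it can fall below 15 when a top component has fewer
than 5 nodes); `min_count` does not shrink under shortfall.

## Numerical choices

- **Eigenvector centrality** iterates on `A + I`, not `A`. Trees are
  bipartite, so the spectrum of `A` is symmetric (±λ₁) and plain power
  iteration oscillates between the two extreme eigenvectors; the +I shift
  separates λ₁ + 1 from −λ₁ + 1 without changing eigenvectors.
- **Betweenness** is computed from subtree sizes (deleting `v` splits a tree
  into parts `s_1..s_k`; pairs through `v` = `Σ_{i<j} s_i s_j`), which is
  O(n) per component and exact. No normalization is applied — only
  within-component rankings are consumed.
- **Ties** are broken deterministically everywhere: component-size ties by
  the smallest contained respondent id, score ties at the selection boundary
  by ascending node id. The published procedure never confronts ties;
  determinism is required for reproducible output.
- **Degenerate inputs**: size-1 components score 0 on every measure and are
  never selected; attributes with zero observed values in a city have no
  baseline and are skipped; missing central-node values never count as
  deviant (absence is not treated as evidence).
- An attribute whose city SD is 0 flags any differing value as deviant
  (the 2σ band has zero width).
- No multiple-testing correction is applied, matching the original
  procedure; the report records the number of attributes tested so users can
  post-correct.

## The synthetic cohort

The real survey data are restricted-access, so the generator emulates their
published structure rather than reproducing any empirical finding. Each seed
founds a recruitment tree grown by a branching process: every participant
independently draws a recruit count from `recruit_count_dist` over 0..6;
growth stops after `max_waves` or extinction. Defaults are calibrated once
to the study's stated facts — 3 cities, 137 seeds each (~411 components vs
412), offspring distribution `(0.55, 0.22, 0.11, 0.06, 0.03, 0.02, 0.01)`
with mean 0.90, so the expected component size is ~10 and a cohort lands
near the study's 4,688 participants, with a majority of components of size
1–2 (~68% vs the reported 255/412 ≈ 62%) and occasional chains of hundreds
of nodes. Attributes are drawn independently per respondent (binary
Bernoulli, ordinal binomial over 0..n_levels−1, numeric Gaussian) with a 3%
default missing rate.

What the generator does **not** emulate: homophily-driven attribute
correlation along recruitment edges, differential non-response, coupon
color semantics, or any epidemic process. A green recovery test therefore
establishes that the scoring stage detects a central-node-enriched attribute
against an independent background — not that the method would behave
identically under real-world attribute autocorrelation.

`plant_signal` creates exact ground truth by running the selection stage
first and then re-drawing one binary attribute at `planted_central_rate`
among the selected nodes (kept fully observed, so the truth is exact by
construction) and at the background prevalence elsewhere. Planting after
selection isolates the scoring stage; planting an explicit node set chosen
by topological position (`nodes=` argument) provides the end-to-end mode.
Only binary attributes can be planted: "re-draw at rate r" is Bernoulli
semantics.

## Known limitations

- Centrality is computed on the recruitment tree, not the underlying contact
  network; unobserved edges (loops) are not inferred.
- Betweenness requires tree components (the subtree-size formula); general
  graphs are out of scope since the forest construction guarantees trees.
- The exceptionality score is descriptive, not inferential: with ~140
  encoded attributes and a 4-of-15 threshold, low-prevalence attributes near
  the 0.2 boundary cross the threshold by chance at a non-trivial rate, as
  the null-planting recovery test quantifies.
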