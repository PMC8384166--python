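# rdscentral

Centrality-based biomarker discovery in respondent-driven sampling (RDS)
referral networks.

RDS surveys reach hidden populations (for example low-income MSM and people
who inject drugs in HIV research) through peer recruitment: each participant
receives up to 6 coupons to pass on, so the study's referral network is a
forest of recruitment trees rooted at researcher-chosen seeds. Because
recruitment follows real risk-relevant contacts, nodes that are structurally
central to these trees are plausible targets for disease-prevention
interventions — and attributes unusually common among them are candidate
*biomarkers*.

`rdscentral` is for epidemiologists and network scientists who have (or
simulate) coupon-linked survey records and want a reproducible pipeline
that:

1. filters survey features by completeness (default: keep features observed
   in ≥ 94% of respondents) and one-hot encodes non-ordinal categoricals;
2. builds the per-city referral forest from recruiter links, rejecting
   orphan references, cross-city links and cycles;
3. scores every node of each analysed component with three centralities —
   closeness `c(v) = N / Σ_y d(y, v)`, betweenness
   `b(v) = Σ_{s≠v≠t} σ_st(v)/σ_st` (a pure path count in a tree), and
   eigenvector centrality (principal eigenvector of the adjacency matrix);
4. selects the top-5 nodes from each of the 3 largest components per city
   and measure (15 central nodes per city when components are large enough);
5. flags attributes whose values among central nodes fall more than two
   standard deviations from the city mean, reporting every attribute deviant
   in at least 4 central nodes with the exceptionality score
   `|c_i| / |c|` — the fraction of the central set sharing the deviation.

A synthetic-cohort generator (`rdscentral.synthetic`) stands in for
restricted-access survey data, matching the published structural facts of a
three-city study (~4,700 participants, ~410 components, majority of
components of size 1–2, chains of tens to hundreds, degree cap 7), and can
plant central-node-enriched attributes as exact ground truth for recovery
testing. See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from rdscentral import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    simulate=CohortConfig(),          # default synthetic three-city cohort
    ordinal_features=("income_level",),
    rng_seed=1,
    out_dir="demo_out",
)
report_path = run_pipeline(config)
print(report_path.read_text())
```

prints

```
city,centrality_type,attribute_code,attribute_plaintext,deviant_count,set_size,exceptionality
city1,betweenness,used_heroin,,4,15,0.2667
city1,closeness,drug_other,,4,15,0.2667
city1,eigenvector,used_heroin,,4,15,0.2667
city2,eigenvector,used_heroin,,4,15,0.2667
```

Each row is one exceptional attribute for one city and centrality measure:
`deviant_count` of the `set_size` central nodes (5 from each of the 3
largest components) carry a value more than 2 SDs from the city mean, giving
exceptionality `4/15 = 0.2667`. The default cohort plants no signal, so
these reports are chance threshold crossings by low-prevalence attributes
(`used_heroin` has prevalence 0.15 < 0.2, so every carrier is deviant) —
exactly the false-positive behaviour the recovery tests quantify. The output
directory also receives every intermediate table (`respondents.csv`,
`features.csv`, `edges.csv`, `centrality.csv`, `central_nodes.csv`) and a
`manifest.json` that suffices to reproduce the run bit-for-bit.

The same pipeline runs from the shell:

```bash
rdscentral simulate --seed 1 --out-dir demo_out
rdscentral run-all --table demo_out/respondents.csv --out-dir demo_out
rdscentral plot --table demo_out/respondents.csv --city city1 \
    --component $(head -2 demo_out/central_nodes.csv | tail -1 | cut -d, -f3) \
    --out component.png
```

Real data are supplied as a CSV with columns `respondent_id`, `city`,
`recruiter_id` (empty for seeds) followed by one column per raw survey
feature (empty string = missing/declined).

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch on the
default synthetic cohort — generation, prep, forest construction, the three
centralities, selection and exceptionality scoring — and writes its target
values as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The intermediate tables of the run land next to the JSON under
`results/pipeline_run/`.
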