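# nemameta

Metacommunity-structure analysis for soil nematode communities (and any
other site-by-taxon survey data): elements of metacommunity structure (EMS)
with the full structure decision tree, C-score/SES co-occurrence null
models, Mantel distance tests, and permutation variable importance of
ordination site scores — plus a synthetic study-design generator so the
whole pipeline is testable without any external data.

## The problem

Metacommunity ecology asks how local communities connected by dispersal are
organized: do taxa replace each other in discrete blocks along an
environmental gradient (Clementsian), shift idiosyncratically (Gleasonian),
form nested subsets, exclude each other in checkerboards, space out evenly,
or show no structure at all? The EMS framework answers this by ordering the
presence–absence matrix with reciprocal averaging (RA, the first
correspondence-analysis axis) and evaluating three elements against null
models:

* **coherence** — embedded absences Abs (gaps inside taxon/site ranges),
  tested by `z = (Abs − mean_null)/sd_null`;
* **turnover** — replacements Rep (opposing presence/absence pairs over all
  site pairs × taxon pairs, ranges filled first);
* **boundary clumping** — Morisita's index
  `I = n·Σ f_i(f_i−1)/(F(F−1))` on the per-site counts of range boundaries,
  with a chi-squared dispersion test (df = n−1).

A decision tree over the three p-values and directions assigns one of
twelve structure labels (including quasi-structures when turnover is not
significant and nested loss subtypes). Co-occurrence is screened with the
C-score — the mean number of checkerboard units `(R_i−S)(R_j−S)` over all
taxon pairs — against a fixed-margins (sequential swap) null;
`SES = (C_obs − mean_sim)/sd_sim` beyond ±2 flags non-random segregation
(+) or aggregation (−). Environmental vs. spatial drivers are weighed with
Spearman Mantel tests (Bray–Curtis community dissimilarity against
standardized-Euclidean environmental and great-circle spatial distance) and
by permutation importance of soil/spatial variables for the RA site scores.

The bundled survey summary (`nemameta.datasets.ems_survey_summary`) carries
the published per-unit EMS statistics of a 72-sample soil-nematode survey
across four stations in Northeast China (4 stations × 3 land covers ×
3 plots × 2 years); the synthetic generator emulates exactly that design.

## Worked example

```python
import nemameta as nm

# a community with 3 Clementsian compartments along a 24-site gradient
table = nm.generate_metacommunity(
    nm.SyntheticScenario(structure="clementsian", n_sites=24, n_taxa=30, seed=4)
)
res = nm.ems_pipeline(table, scale="local", land_cover="grassland",
                      site="S1", n_sims=500, seed=4)
print(f"structure: {res.label}")
print(f"coherence: Abs={res.coherence.abs_obs} mean={res.coherence.null.mean:.2f} "
      f"z={res.coherence.z:.2f} p={res.coherence.p:.4f}")
print(f"turnover:  Rep={res.turnover.rep_obs} mean={res.turnover.null.mean:.2f} "
      f"z={res.turnover.z:.2f} p={res.turnover.p:.4f}")
print(f"boundary:  I={res.boundary.morisita_i:.2f} p={res.boundary.p:.4f}")

co = nm.cooccurrence_analysis(table, n_sims=2000, seed=4)
print(f"C-score={co.c_obs:.2f} SES={co.ses:.2f} ({co.interpretation})")
```

prints

```
structure: Clementsian
coherence: Abs=6 mean=601.80 z=-24.99 p=0.0000
turnover:  Rep=18552 mean=5065.87 z=17.27 p=0.0000
boundary:  I=3.61 p=0.0000
C-score=41.55 SES=136.22 (segregated)
```

Read: the ordered matrix has far fewer embedded absences than its null
(significant positive coherence), significantly more replacements than
expected (positive turnover), and strongly clumped range boundaries
(I = 3.61 ≫ 1, p < .05) — the tree returns Clementsian, the generating
structure. The compartmented ranges also produce a C-score far above the
fixed-margins null (SES > 2): the taxa of different compartments almost
never co-occur.

The same machinery runs over a full survey from the command line:

```bash
nemameta simulate --seed 1 --out data/synthetic     # 72-sample design
nemameta run-all  --seed 1 --config run.yaml        # all four reports
```

with a YAML config naming the four input tables and any setting overrides:

```yaml
community: data/synthetic/community.csv
metadata: data/synthetic/sample_metadata.csv
environment: data/synthetic/environment.csv
trophic: data/synthetic/trophic_groups.csv
out_dir: results
n_sims_ems: 1000
n_sims_cooccurrence: 10000
```

or through the numbered drivers in `analysis/` (simulate → EMS →
co-occurrence → Mantel → importance), which write Table-style delimited
reports under `results/`: one EMS row per analysis unit (12 local + 3
regional), co-occurrence per unit × trophic group (plant parasites,
bacterivores, fungivores, omnivores–predators), Mantel r/p per unit for
environment and space, and per-variable importance with significance stars.

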