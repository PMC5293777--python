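# axoquant

Quantification pipeline for rodent ocular-hypertension experiments:
reconstruction of flattened retinotopic anterograde-transport maps from
serial superior-colliculus (SC) sections with a percent-intact-transport
statistic, immunolabel percent-area and microbead:saline ratio analysis,
DAPI-gated nuclear-localization scoring, retinal morphometry, and the
accompanying statistical battery. A synthetic-data module generates every
pipeline input with exact ground truth, so the full analysis chain is
testable without any acquired imagery.

## Modules

| Module | What it does |
| --- | --- |
| `axoquant.synthetic_data` | Seeded generators for SC section series (sector-shaped transport deficits), immunolabel fields, DAPI+signal nuclei fields, layered retinal cross-sections and IOP tonometry series — each with recomputable ground truth. TIFF + JSON sidecar I/O. |
| `axoquant.transport_mapping` | Background normalization, mediolateral section profiles, retinotopic map assembly, percent intact transport (density ≥ 70% of the map's reference maximum, inclusive). |
| `axoquant.immunolabel_quant` | Positive-label thresholding (fixed or pooled-pair Otsu), exact percent-area, per-animal microbead:saline ratios with group mean ± SEM. |
| `axoquant.nuclear_localization` | Watershed DAPI segmentation, per-nucleus nuclear fraction (nuclear mean over nuclear + perinuclear-annulus mean), optional co-label classing, ratio analysis. |
| `axoquant.morphometry` | Layer thickness from boundary curves (perpendicular distance at n sampling locations) and CTB+/DAPI+ soma counts/density in the ganglion cell layer. |
| `axoquant.stats_reporting` | Shapiro–Wilk-gated t-test / Mann–Whitney routing, one-sided test against unity, one-way ANOVA + Holm–Šidák, percent-change arithmetic with report rounding, IOP baseline and elevation summaries, observed power (report-only). |
| `axoquant.pipeline_io` | Cohort layout, manifest/config (YAML), deterministic cohort simulation with group-dependent effect sizes, end-to-end orchestration, report bundle with config hash. |

## CLI

```sh
axoquant simulate --out cohort/ --seed 1 --n-per-group 6   # synthetic cohort
axoquant run --cohort cohort/ --out results/ --seed 1       # all stages -> report bundle
axoquant transport --sections cohort/V1/SC/SALINE --out transport.json --png map.png
axoquant stats --input cohort/iop.csv --out iop_summary.csv
```

The report bundle contains per-stage CSV tables (`transport.csv`,
`label.csv`, `nucloc.csv`, `morphometry.csv`, `iop_summary.csv`, ...),
`report.json`, and the serialized `config.yaml` whose hash is embedded in
the report; re-running with the same cohort and config reproduces every
byte.

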