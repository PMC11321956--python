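# faersig

Disproportionality signal detection for FAERS-style spontaneous
adverse-event report data.

The package implements the standard pharmacovigilance analysis chain on
the FDA Adverse Event Reporting System quarterly ASCII releases (or any
corpus in the same dialect):

1. **faers_io** — read/write the "$"-delimited quarterly tables
   (DEMO/DRUG/REAC/OUTC), including the legacy `ISR`/`CASE` column shim.
2. **preprocess** — per-case deduplication (latest receipt date wins,
   ties broken by primaryid), age unit conversion and anomaly censoring,
   dictionary-based drug-name standardization, referential assembly.
3. **meddra** — PT → SOC lookups from a *user-supplied* hierarchy table
   (MedDRA is licensed and is not bundled; a small test fixture covers
   the terms used in the test-suite).
4. **signal_engine** — per-term 2×2 contingency tables over
   (report, term) pairs for a primary-suspect drug, and four statistics
   with their conventional signal rules:
   ROR (Woolf 95% CI > 1), PRR (≥2 with χ² ≥ 4), BCPNN information
   component (closed-form IC025 > 0) and EBGM (EB05 > 2), all gated on a
   minimum report count (default 3). Optional Haldane +0.5 zero-cell
   policy, Yates-corrected χ², and a gamma-mixture empirical-Bayes
   (MGPS-style) EBGM backend.
5. **summaries** — demographic/outcome summary tables, quarterly report
   series, and sex-stratified signal scans.
6. **synthetic** — a FAERS-like corpus simulator with planted
   drug–event relative risks (optionally sex-specific), duplicate case
   versions, missing demographics and per-drug marketing-start
   quarters; it keeps independent ground-truth bookkeeping so the whole
   pipeline can be validated end to end.
7. **cli** — end-to-end orchestration.

## CLI

```bash
# generate a synthetic corpus (config is YAML; see tests/test_cli.py)
faersig simulate --config sim.yaml --out data/

# full analysis: signal tables (PT + SOC), demographics, quarterly
# series, sex scans, structured run log
faersig run --data data/ --start 2015Q1 --end 2016Q4 \
    --drug drugx --synonyms data/synonyms.tsv \
    --hierarchy data/hierarchy.tsv --out results/

# individual stages
faersig signals ... / faersig summary ... / faersig sexscan ...
```

Exit codes: 0 success, 2 configuration error, 3 data error. All outputs
are tab-separated text; every stage's row counts land in `run_log.tsv`.

## Input formats

- Quarterly tables: `DEMOyyQq.txt` etc., "$"-delimited, header row.
- Synonym dictionary: two-column TSV `verbatim<TAB>standard`,
  `#` comments.
- PT → SOC hierarchy: TSV with `pt` and `soc` columns.
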