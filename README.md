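# faersignal

Adverse-event signal detection for FAERS-style spontaneous-report data.

Spontaneous reporting systems such as the FDA Adverse Event Reporting System
(FAERS) collect voluntary reports of suspected adverse drug reactions. They
have no denominator — nobody knows how many patients took a drug safely — so
drug-safety signals are found by *disproportionality analysis*: asking
whether a drug–event pair is reported more often than expected if the drug
and the event were independent across the database. `faersignal` packages
that workflow end to end for one target drug (the bundled study conditions
emulate an oral-retinoid cohort like isotretinoin):

* **I/O** for the FAERS quarterly ASCII dialect (`$`-delimited DEMO, DRUG,
  REAC, THER, OUTC, INDI tables) and the user-supplied lookup CSVs (MedDRA
  PT→SOC map, important-medical-event list, drug-label list, drug synonyms).
* **Cleaning**: case deduplication (per CASEID keep the latest FDA_DT, ties
  broken by the higher PRIMARYID) and drug-cohort construction (reports
  naming the target drug as primary suspect, matched against its trade and
  generic names).
* **Disproportionality** at MedDRA PT and SOC level from 2×2 tables
  (a = target-drug reports with the term, b = without, c/d = the same for
  all other drugs, N = a+b+c+d):

  | estimator | definition | signal threshold |
  |---|---|---|
  | ROR | ad/bc, CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))` | n ≥ 3 and CI lower bound > 1 |
  | PRR | `[a/(a+b)] / [c/(c+d)]` with Pearson χ² | PRR ≥ 2, χ² ≥ 4, n ≥ 3 |
  | BCPNN IC | posterior `log2 P(drug,event)/[P(drug)P(event)]` | IC025 > 0 |
  | MGPS EBGM | empirical-Bayes geometric mean of λ = a/E, E = (a+b)(a+c)/N | EBGM ≥ 2 |

  A term is a **consensus signal** only when all four methods pass, and
  flagged terms are annotated as important medical events (IME) and as
  unlabeled (absent from the drug label).
* **Time to onset**: event date minus earliest therapy start, with reports
  excluded for missing/partial dates or negative intervals, summarized as
  median/IQR and day bins.
* **Demographics**: sex, age group, reporter class, country, outcome,
  indication and reports-per-year summaries.
* **A synthetic-data generator** that emits all six linked tables with known
  ground truth (designed reporting-rate multipliers, duplicate ledger), so
  every stage is testable without redistributing regulatory data.

## Worked example

`examples/` contains one narrative script per capability. The core loop —
simulate a cohort with a designed signal, detect it — looks like:

```python
from faersignal import analyze_tables, generate_faers_tables
from faersignal.io import LookupTables
from faersignal.synthetic import SignalSpec, default_config

config = default_config(
    n_cases=20_000, seed=42,
    signal_spec=[SignalSpec("RETINOID-A", "Inflammatory bowel disease", 10.0)],
)
tables, truth = generate_faers_tables(config)
lookups = LookupTables(
    pt_to_soc={p.name.casefold(): p.soc for p in config.pt_catalog},
    ime_list={"inflammatory bowel disease"}, label_list=set(),
    synonyms={"RETINOID-A"},
)
result = analyze_tables(tables, lookups, level="pt")
columns = ["term", "n", "ror", "ror_lo", "ror_hi", "prr", "chi2",
           "ebgm", "ebgm05", "ic", "ic025", "consensus"]
print(result.signal_pt[columns].head(2).round(3).to_string(index=False))
```

which prints (from `examples/02_signal_detection.py`, which adds a second
designed signal with multiplier 3 on "Suicidal ideation"):

```
                      term   n   ror  ror_lo  ror_hi   prr     chi2  ebgm  ebgm05     ic  ic025  consensus
Inflammatory bowel disease 618 8.165   7.128   9.354 7.603 1266.225 3.303   3.303  1.717  1.569       True
         Suicidal ideation 281 2.788   2.393   3.250 2.725  187.066 1.856   1.688  1.016  0.816      False
```

The designed multiplier-10 term tops the table and passes all four gates
(n = 618 ≥ 3, ROR CI lower bound 7.13 > 1, PRR 7.6 ≥ 2 with χ² ≫ 4,
IC025 1.57 > 0, EBGM 3.3 ≥ 2). A moderate multiplier-3 signal illustrates
the conservatism of the consensus rule: its EBGM is shrunk below 2, so it is
ranked but not flagged. Background terms sit near ROR 1 and are never
flagged.

The same pipeline runs from the shell over files:

```bash
faersignal simulate --n-cases 5000 --seed 9 --out sim/ \
    --signal "RETINOID-A:Inflammatory bowel disease:10"
faersignal run --tables sim/ --pt-to-soc lookups/pt_to_soc.csv \
    --synonyms lookups/synonyms.csv --out out/
```

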