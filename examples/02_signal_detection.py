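"""Four-estimator disproportionality analysis on a small synthetic cohort.

Generates 20,000 cases with a strong designed signal, runs deduplication,
drug-cohort selection and PT-level disproportionality, and prints the signal
table columns a pharmacovigilance report would tabulate: n, ROR (95% CI),
PRR (χ²), EBGM (EBGM05), IC (IC025), and the consensus flag.
"""

from faersignal import analyze_tables, generate_faers_tables
from faersignal.io import LookupTables
from faersignal.synthetic import SignalSpec, default_config

config = default_config(
    n_cases=20_000,
    seed=42,
    dup_rate=0.10,
    signal_spec=[
        SignalSpec("RETINOID-A", "Inflammatory bowel disease", 10.0),
        SignalSpec("RETINOID-A", "Suicidal ideation", 3.0),
    ],
)
tables, _ = generate_faers_tables(config)

lookups = LookupTables(
    pt_to_soc={p.name.casefold(): p.soc for p in config.pt_catalog},
    ime_list={"inflammatory bowel disease", "suicidal ideation",
              "dandy-walker syndrome"},
    label_list={"inflammatory bowel disease", "lip dry", "dry skin", "rash"},
    synonyms={"RETINOID-A"},
)

result = analyze_tables(tables, lookups, level="pt")
columns = ["term", "n", "ror", "ror_lo", "ror_hi", "prr", "chi2",
           "ebgm", "ebgm05", "ic", "ic025", "consensus", "is_ime"]
print(result.signal_pt[columns].head(8).round(3).to_string(index=False))
print("\n-> terms are ranked by ROR; 'consensus' means all four estimators")
print("   cleared their thresholds (n>=3 & ROR CI low >1; PRR>=2 & chi2>=4;")
print("   IC025>0; EBGM>=2). The two designed signals lead the table, but")
print("   only the strong one survives every gate: empirical-Bayes shrinkage")
print("   can pull a moderate signal's EBGM below 2, which is exactly the")
print("   false-positive control the consensus rule is meant to provide.")
print("   Background terms sit near ROR 1 and stay unflagged.")
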