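"""Time-to-onset analysis with exact exclusion accounting.

Computes onset intervals (event date minus earliest therapy start of the
target drug), excludes reports with missing/partial dates or negative
intervals, and prints the median, interquartile range and the day-bin
distribution of the included reports.
"""

from faersignal import analyze_tables, generate_faers_tables
from faersignal.io import LookupTables
from faersignal.synthetic import default_config

config = default_config(n_cases=20_000, seed=5, dup_rate=0.10)
tables, _ = generate_faers_tables(config)
lookups = LookupTables(
    pt_to_soc={p.name.casefold(): p.soc for p in config.pt_catalog},
    ime_list=set(),
    label_list=set(),
    synonyms={"RETINOID-A"},
)
result = analyze_tables(tables, lookups, level="pt")

m = result.manifest
print(f"analyzed cases:        {m['cases.analyzed']}")
print(f"  onset computable:    {m['tto.included']}")
print(f"  missing/partial date {m['tto.excluded_missing_date']}")
print(f"  negative interval:   {m['tto.excluded_negative']}")

s = result.tto_summary
print(f"\nmedian onset: {s.median_days:.0f} days (IQR {s.q1:.0f}-{s.q3:.0f})")
print(s.to_frame().round(3).to_string(index=False))
print("\n-> the generator draws onsets from a log-normal with median 81 days,")
print("   so the recovered median should sit near 81; the three exclusion")
print("   counts always sum exactly to the number of analyzed cases.")
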