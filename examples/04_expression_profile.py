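"""Reads-per-million normalisation and salt-response categories.

Takes raw per-library counts, normalises them against the library
clean-read totals and assigns each miRNA a fold-change category; exclusive
detection is decided on raw counts.
"""

from mirnod import build_records, summarize
from mirnod.expression import to_frame

counts = {
    "miR-a": {"NSN": 100, "SSN": 420},    # strongly induced by salt
    "miR-b": {"NSN": 300, "SSN": 150},    # repressed two-fold
    "miR-c": {"NSN": 220, "SSN": 260},    # below the 2-fold threshold
    "miR-d": {"NSN": 48, "SSN": 0},       # detected only without stress
}
totals = {"NSN": 2_000_000, "SSN": 2_000_000}

records, dropped = build_records(counts, totals, control="NSN", treated="SSN")
print(to_frame(records, ["NSN", "SSN"]).to_string(index=False))
print("\ncategory tally:", summarize(records)["categories"])
# RPM = count / clean-read total x 1e6; a miRNA is salt-responsive when its
# SSN/NSN RPM ratio reaches 2 in either direction or it vanishes from one
# library entirely.
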