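"""Derive reduced band configurations and merge them across products.

Uses the published per-product three-band (P2) selections to build the
minimum viable configuration for each data type, and prints the merged
tables with repeated bands marked.
"""

import cyanospec as cs
from cyanospec.reference_bands import p1_selection, p2_selection

for data_type in ("RRS", "TOAR", "BRR"):
    sels = [p2_selection(p, data_type) for p in ("chl_a", "pc", "car")]
    merged = cs.merge_configs(sels)
    marked = [f"{c:g}{'*' if k > 1 else ''}"
              for c, k in zip(merged.centers, merged.counts)]
    print(f"{data_type:>4}: {len(merged.centers)} bands -> {', '.join(marked)}")
print("(* = selected by more than one product)")

optimal = cs.merge_configs([p1_selection(p, d)
                            for p in ("chl_a", "pc", "car")
                            for d in ("RRS", "TOAR", "BRR")])
print(f"\noptimal configuration (all P1 sets merged): "
      f"{len(optimal.centers)} distinct bands")
print("red/NIR coverage is near-continuous between 650 and 780 nm.")
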