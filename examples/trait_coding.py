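"""Occurrence-based trait coding: depth ranges, size and larval ecology.

The conservative depth range takes the species minimum as the lowest
*maximum* station depth (so at least one specimen certainly occurred
that shallow) and the species maximum as the highest *minimum* station
depth; binary codings use the 100 m (depth) and 25 mm (shell length)
thresholds, and protoconch whorl counts diagnose larval ecology.
"""

from terebra import (classify_protoconch, code_depth_binary,
                     code_size_binary, simulate_occurrences,
                     species_depth_range)
from terebra.occurrence import depth_ranges_from_table

occ = simulate_occurrences(
    {"Hastula_like": (0, 3), "Pellifronia_like": (400, 780),
     "Widespread": (20, 350)},
    n_stations=8, dredge_width=40, seed=42)
ranges = depth_ranges_from_table(occ)
print(ranges)

for sp, row in ranges.iterrows():
    state = code_depth_binary((row["depth_min_m"], row["depth_max_m"]))
    print(f"{sp}: {row['depth_min_m']:.0f}-{row['depth_max_m']:.0f} m -> "
          f"{'deep (1)' if state else 'shallow (0)'}")
# Species whose conservative minimum lies at or above 100 m code as deep.

sizes = {"Partecosta_like": 10.0, "Oxymeris_like": 274.0, "Median_sp": 25.0}
states, report = code_size_binary(sizes)
print(f"\nSize states: {states.to_dict()} "
      f"(empirical 25th percentile {report['quartile_25_mm']:.1f} mm)")

for whorls, nucleus in [(3.25, None), (2.0, None), (2.5, None), (2.5, True)]:
    print(f"protoconch {whorls} whorls, small nucleus={nucleus}: "
          f"{classify_protoconch(whorls, nucleus)}")
# 2.5-whorl intermediates need the nucleus character or manual review.
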