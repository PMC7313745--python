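"""Enumerate a Petri dish split into six wedge segments.

Each segment carries a different sample dilution, so it is counted as a
separate region of interest; a segment count times six gives the
full-plate equivalent used to compare against whole-plate enumerations.
"""

from colonycount import PlateLayout, SyntheticPlateSpec, enumerate_plate, generate_plate

layout = PlateLayout(center_row_px=405, center_col_px=405,
                     dish_radius_px=400, n_segments=6)
per_segment = [2, 4, 6, 2, 4, 6]  # two segments per dilution level
spec = SyntheticPlateSpec(layout=layout, n_colonies=per_segment,
                          diameter_range_mm=(0.5, 0.8), seed=44)

image, truth = generate_plate(spec)
result = enumerate_plate(image, layout)

print("segment   truth  counted  full-plate equivalent (x6)")
for rc, n_true in zip(result.per_roi, per_segment):
    print(f"{rc.label:<10}{n_true:>5}{rc.count:>9}{rc.full_plate_equivalent:>12}")
print(f"total counted on the dish: {result.total_count}")
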