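# Plate-layout configuration consumed by `colonycount count/synth --layout`.
# Keys mirror the PlateLayout fields; unknown keys are rejected.

center_row_px: 1374      # dish center, image row (0-based pixels)
center_col_px: 1374      # dish center, image column
dish_radius_px: 1300     # dish radius in pixels
n_segments: 6            # 1 = whole plate, 6 = wedge segments
rim_inset_mm: 3.0        # countable area stops this far short of the rim
segment_gap_deg: 4.0     # colony-free strip between adjacent wedges
rotation_deg: 0.0        # orientation of the first segment boundary
pixel_pitch_um: 40.0     # physical size of one pixel
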