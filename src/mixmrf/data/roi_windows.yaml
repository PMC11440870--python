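# Regions of interest on the 29x58 reference raster.
#
# Each window is [row_start, row_stop, col_start, col_stop] with 0-based,
# half-open index ranges (numpy slice convention).  The windows are fixed
# once for the reference phantom layout and reused unchanged for both
# simulation phantoms, so that region-wise errors are comparable.
#
# Semantics:
#   1, 2 : high-contrast edges of the hot regions
#   3, 4 : interiors of hot regions (smooth once blurred)
#   5, 6 : smooth background
#   7, 8 : high-contrast edges in the background (cool-area boundaries)
windows:
  1: [10, 17, 31, 36]
  2: [1, 7, 9, 17]
  3: [10, 17, 37, 44]
  4: [18, 22, 11, 21]
  5: [1, 7, 24, 31]
  6: [24, 29, 26, 33]
  7: [20, 27, 45, 53]
  8: [22, 26, 9, 17]
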