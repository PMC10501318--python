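"""Pixelwise-SD activity maps and the category-sorted heatmap.

The SD map marks pixels whose fluorescence varied most over all episodes of
one stimulus site; responding footprints should light up in the map of the
site they respond to.  The heatmap layout orders included responders in
Internal / External gentle / External noxious blocks, descending by peak
dF/F.  Printed: in-footprint vs background SD for one internal cell, and the
heatmap row order.
"""

from drgcal import (
    RoiSet,
    Site,
    annulus_correct,
    call_responders,
    classify_cells,
    compute_dff,
    flag_exclusions,
    sd_map,
    simulate_session,
    sort_heatmap,
)

cells, schedule, movie = simulate_session(seed=1)
rois = RoiSet.from_cells(cells, movie.frame_shape)
dff = compute_dff(annulus_correct(movie, rois), schedule)
table = call_responders(dff, schedule)
cls = classify_cells(table, flag_exclusions(dff, table, rois, schedule), schedule)

amap = sd_map(movie, schedule, Site.INTERNAL)
internal_cell = cells[0]
inside = amap.sd_image[internal_cell.rows, internal_cell.cols].mean()
outside = amap.sd_image[~rois.any_labeled_mask()].mean()
print(f"internal-site SD map: mean SD inside an internal cell's footprint "
      f"{inside:.2f} vs background {outside:.2f}")

layout = sort_heatmap(dff, cls)
print(f"heatmap rows (top to bottom): {layout.row_order}")
for cat, (lo, hi) in layout.block_boundaries.items():
    print(f"  {cat.value:18s} rows {lo}..{hi - 1}" if hi > lo
          else f"  {cat.value:18s} (empty)")
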