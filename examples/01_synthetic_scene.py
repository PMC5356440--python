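"""Build a synthetic epithelial field: cell mosaic, cortical puncta, image.

The mosaic's internal Voronoi edges stand in for traced cell-cell
junctions; puncta are enriched along them the way a junctional protein
accumulates at the cortex.
"""

from mtcortex import synthetic as sy

field = (30.0, 30.0)  # µm
mosaic = sy.make_cell_mosaic(n_cells=8, field=field, seed=1)
puncta, image = sy.place_cortical_puncta(
    mosaic, field, base_density=0.05, junction_density=6.0,
    band_width=0.4, enrichment_factor=1.0, noise_sd=1.0, seed=2)

n_junctional = sum(p.on_junction for p in puncta)
print(f"mosaic: {len(mosaic)} internal junction edges, "
      f"total length {sum(j.length for j in mosaic):.1f} µm")
print(f"puncta: {len(puncta)} total, {n_junctional} junctional")
print(f"image: {image.shape[0]}x{image.shape[1]} px at "
      f"{image.pixel_size} µm/px")
# The junctional count scales with junction_density x enrichment_factor x
# total junction length; halving the enrichment halves that expectation.
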