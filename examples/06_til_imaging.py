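"""TIL detection and density on a histology-like image.

Trains the radial-SVM nucleus classifier on synthetic training images,
detects lymphocytes on a fresh image with the published score/size
filters, and converts the count into a density per mm^2 of tissue.
"""

from tmedyn import imaging
from tmedyn.simulate import simulate_histology_image

classifier = imaging.train_default_classifier(seed=1, n_images=4)

image, truth = simulate_histology_image(900, 900, 80, 30, seed=42)
candidates = imaging.tile_process(image, classifier)
lymphocytes, non_lymphocytes, large_cells = imaging.filter_lymphocytes(candidates)

quant = imaging.compute_density(len(lymphocytes), image,
                                large_cell_count=len(large_cells))
planted = int((truth.cell_type == "lymphocyte").sum())
print(f"planted lymphocytes: {planted}, detected: {quant.lymphocyte_count}")
print(f"tissue area: {quant.tissue_area_mm2:.3f} mm^2 at {quant.um_per_px} um/px")
print(f"TIL density: {quant.density_per_mm2:.0f} cells/mm^2")
# Detection applies the full filter chain: area in [60, 150] px and
# classifier probability >= 0.97; larger irregular nuclei are rejected.
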