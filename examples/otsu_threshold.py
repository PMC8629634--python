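"""Automatic thresholding of a cytology phantom by maximum between-class variance.

Generates a single-cell phantom, computes its gray-level histogram, finds the
threshold t* maximizing the between-class variance σ²_B(t), and applies it.
The printed class means show the bright background separating from the cell.
"""

import numpy as np

from cytoseg import (
    PhantomSpec,
    binary_threshold,
    generate_scene,
    histogram,
    max_variance_threshold,
)

image, truth = generate_scene(PhantomSpec.herlev(seed=1))
hist = histogram(image)
t_star, stats = max_variance_threshold(hist)

print(f"optimal threshold t* = {t_star}")
print(f"class probabilities  θ1 = {stats.theta1:.3f}, θ2 = {stats.theta2:.3f}")
print(f"class means          μ1 = {stats.mu1:.1f}, μ2 = {stats.mu2:.1f}, μ = {stats.mu:.1f}")
print(f"between-class var    σ²_B = {stats.sigmaB2:.1f}")

# pixels >= t* are the bright background; the cell is the complement
cell_mask = ~binary_threshold(image, t_star)
true_area = truth.cells[0].cytoplasm.area
print(f"thresholded cell area {cell_mask.area} px vs true cytoplasm {true_area} px")
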