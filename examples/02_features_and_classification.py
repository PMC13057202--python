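"""Rank feature combinations for maximum-likelihood species classification.

Computes spectral bands, vegetation indices and canopy height for a
synthetic scene, then scores the V1 (visible bands only) through V15
(bands + indices + height) combinations on a 70/30 stratified pixel split.
"""

import warnings

from mangrovecarbon import classify as cl
from mangrovecarbon import features as ft
from mangrovecarbon import synthetic as syn

# flat classes (soil/water/shadow) have zero canopy-height variance, so
# their covariances are ridge-regularized; silence the advisory warnings
warnings.filterwarnings("ignore", message=".*singular covariance.*")

fractions = {
    "A_marina": 0.28, "R_stylosa": 0.16, "A_corniculatum": 0.12,
    "B_gymnorrhiza": 0.09, "soil": 0.15, "water": 0.14, "shadow": 0.06,
}
signatures = syn.default_signatures()
label_map = syn.generate_species_map((160, 160), fractions, 8.0, seed=1)
scene = syn.generate_scene(label_map, signatures, noise_seed=2)

# textures are not needed by V1–V15, so skip the GLCM layers here
stack = ft.build_feature_stack(scene, include_textures=False)
table = cl.labeled_pixel_table(stack, scene.species_true,
                               max_per_class=500, seed=4)

combos = [cl.DEFAULT_COMBINATIONS[f"V{i}"] for i in (1, 4, 8, 12, 15)]
ranking = cl.evaluate_combinations(table, combos, seed=4)
print(ranking[["combination", "n_features", "OA"]].round(4).to_string(index=False))
# OA rises as red-edge/NIR bands, vegetation indices and canopy height
# are fused in — V15 should rank first, V1 (visible only) last.
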