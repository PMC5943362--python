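"""Generate a small synthetic dataset of annotated z-stacks.

Builds six bright-field-like stacks (31 slices, Δz = 1 µm) with known
ground-truth defocus, writes them as multi-page TIFFs with JSON sidecars,
and splits them into train/test.
"""

import tempfile
from pathlib import Path

from zfocus import SceneConfig, generate_dataset, read_zstack, split_dataset

out = Path(tempfile.mkdtemp(prefix="zfocus_demo_"))
config = SceneConfig(field_shape=(300, 300), n_cells_range=(8, 15))
manifest = generate_dataset(6, out, seed=1, scene_config=config)
manifest = split_dataset(manifest, train_fraction=0.8, seed=1)

print(manifest.table[["path", "focal_index", "z_step_um", "split"]].to_string(index=False))
stack = read_zstack(manifest.paths[0])
print(f"\nfirst stack: {stack.n_slices} slices of {stack.data.shape[1:]} px, "
      f"z from {stack.z_positions[0]:+.0f} to {stack.z_positions[-1]:+.0f} µm")
# Each row is one stack; 'split' tags the 80/20 train/test partition.
# z_positions are signed defocus values relative to the annotated focal slice.
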