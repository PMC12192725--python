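"""Generate a synthetic nuclei-like dataset with exact ground truth.

Writes PNG image/mask pairs plus a train/val/test manifest, then verifies
that the stored masks score perfectly against themselves -- the property
that makes the fixtures usable as an exact reference for every other
capability.
"""

from pathlib import Path

from rmisnet import SynthConfig, evaluate_masks, generate_dataset, load_pair

out_dir = Path("scratch/example_synth")
config = SynthConfig(n_images=16, image_size=(64, 64), seed=0)
manifest = generate_dataset(config, out_dir)

sizes = {s: len(manifest.subset(s)) for s in ("train", "val", "test")}
print(f"wrote {len(manifest.records)} image/mask pairs under {out_dir}")
print(f"split sizes: {sizes}")

image, mask = load_pair(*manifest.resolve(manifest.records[0]))
print(f"image shape {image.shape}, intensity range [{image.min():.2f}, {image.max():.2f}]")
print(f"foreground fraction of first mask: {mask.mean():.3f}")

self_score = evaluate_masks([mask], [mask])
print(f"mask vs itself -> {self_score}")
print("all five metrics equal 1.0 because the stored mask is the exact disk union")
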