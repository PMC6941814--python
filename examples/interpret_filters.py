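"""Distil first-layer filters into PPMs and sequence logos.

Trains CNN-25 briefly, scans its 30 first-layer filters over held-out
sequences, keeps subsequences activating above 70% of each filter's
maximum, and stacks them into position probability matrices. Filters that
have started learning a motif produce high-information logos; the rest
stay near-uniform (low total bits).
"""
from pathlib import Path

from motifcnn import (TrainConfig, build_model, build_ppm, export_meme,
                      generate_dataset, information_content,
                      load_default_pool, make_variant, render_logo,
                      scan_activations, train)

out = Path("example_output")
out.mkdir(exist_ok=True)

pool = load_default_pool()
ds = generate_dataset(pool, n_sequences=2000, seed=0)
model = build_model(make_variant("CNN-25"), 200, seed=1)
trained = train(model, ds, TrainConfig(max_epochs=10, learning_rate=2.5e-3,
                                       seed=1))

Xte, _ = ds.subset("test")
scan = scan_activations(trained, layer=1, sequences=Xte)
ppms = build_ppm(scan, Xte, threshold_frac=0.7)

print("filter  n_sites  total bits")
for p in ppms:
    bits = 0.0 if p.empty else information_content(p).sum()
    print(f"  {p.filter_index:3d}   {p.n_sites:6d}   {bits:6.1f}")

n = export_meme(ppms, out / "filters.meme")
best = max((p for p in ppms if not p.empty),
           key=lambda p: information_content(p).sum())
render_logo(best, out / f"filter_{best.filter_index}.png",
            title=f"filter {best.filter_index}")
print(f"\nwrote {n} PPMs to {out}/filters.meme and the highest-information "
      f"logo to filter_{best.filter_index}.png")
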