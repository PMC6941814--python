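"""Train one CNN variant on synthetic data and evaluate per-class AU-ROC.

Uses a small budget (5,000 sequences, 25 epochs; about a minute of CPU);
expect partial convergence — TF classes are discovered sequentially, so
some reach AU-ROC near 1 while others remain near chance. The full
protocol (25,000 sequences, 100 epochs) drives every class high.
"""
from motifcnn import (TrainConfig, build_model, evaluate, generate_dataset,
                      load_default_pool, make_variant, train)

pool = load_default_pool()
ds = generate_dataset(pool, n_sequences=5000, seed=0)

spec = make_variant("CNN-25")   # pools (25, 4): strong spatial bottleneck
model = build_model(spec, input_length=200, seed=1)
print(f"{spec.name}: {model.n_parameters()} parameters")

trained = train(model, ds, TrainConfig(max_epochs=25, learning_rate=2.5e-3,
                                       seed=1), verbose=True)
print(f"best epoch by validation loss: {trained.best_epoch}")

metrics = evaluate(trained, ds, "test")
print(f"\nmean test AU-ROC: {metrics['mean_auroc']:.3f}")
for name, a in zip(ds.class_names, metrics["auroc"]):
    print(f"  {name:6s} {a:.3f}")
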