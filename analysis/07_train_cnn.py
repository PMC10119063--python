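"""Train the 5-class spectral CNN and report the learning curves.

A moderate run (800 spectra per class, 40 epochs) of the 18-conv/4-dense
network on raw synthetic spectra with map-like variability (random
nucleus/cytoplasm mixing, baselines, water background).  The full
scaled-down experiment (1,500 per class, 30 epochs) lives in
scripts/acceptance.py.  Saves the model to results/cnn_model/ and the
per-epoch history to results/cnn_history.csv.
"""

from pathlib import Path

from ramanpath.cnn import CNNConfig, build_model, prepare_dataset, save_model, train
from ramanpath.synthgen import generate_training_set

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = CNNConfig(epochs=40, seed=0)
    spectra = generate_training_set(
        n_per_class=800, seed=0,
        mixture_range=(0.0, 1.0), baseline_sd=0.12, water_background=0.25,
    )
    dataset = prepare_dataset(spectra, cfg)
    model = build_model(cfg)
    print(f"{model.n_conv_layers} conv + {model.n_dense_layers} dense layers, "
          f"{model.n_parameters} parameters; "
          f"{len(dataset.X_train)} train / {len(dataset.X_test)} test spectra")
    history = train(model, dataset, cfg, verbose=True)
    save_model(model, OUT / "cnn_model")
    with open(OUT / "cnn_history.csv", "w") as fh:
        fh.write("epoch,loss,accuracy,val_loss,val_accuracy\n")
        for e in range(cfg.epochs):
            fh.write(f"{e+1},{history['loss'][e]:.6f},{history['accuracy'][e]:.6f},"
                     f"{history['val_loss'][e]:.6f},{history['val_accuracy'][e]:.6f}\n")
    print(f"\nfinal: train acc {history['accuracy'][-1]:.4f}, "
          f"val acc {history['val_accuracy'][-1]:.4f}, "
          f"val loss {history['val_loss'][-1]:.4f}")
    print(f"model -> {OUT / 'cnn_model'}, history -> {OUT / 'cnn_history.csv'}")


if __name__ == "__main__":
    main()
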