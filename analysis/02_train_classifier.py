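#!/usr/bin/env python
"""Train the small residual identity classifier on intact images.

Uses the dataset written by 01_generate_dataset.py; 15 epochs of momentum
SGD.  Writes the checkpoint and the per-epoch history (loss, validation
accuracy) under scratch/run<seed>/model.
"""

import argparse
from pathlib import Path

import pandas as pd

from facelesion.classifier import ClassifierConfig, build_model, train
from facelesion.io import load_dataset


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--run-dir", type=Path, default=None)
    args = ap.parse_args()
    run_dir = args.run_dir or Path("scratch") / f"run{args.seed}"

    ds = load_dataset(run_dir / "data")
    cfg = ClassifierConfig(n_classes=ds.n_identities, epochs=15,
                           learning_rate=0.03, seed=args.seed)
    model, history = train(build_model(cfg), ds)
    out = run_dir / "model"
    out.mkdir(parents=True, exist_ok=True)
    model.save(out / "model.npz")
    pd.DataFrame(history).to_csv(out / "history.csv", index=False)
    print(f"final intact validation accuracy: "
          f"{history[-1]['val_accuracy']:.3f} "
          f"(chance {1 / ds.n_identities:.3f}); checkpoint -> {out}")


if __name__ == "__main__":
    main()
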