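#!/usr/bin/env python
"""Layer-wise activation-magnitude analysis, coupled vs uncoupled.

Generates synthetic per-layer activation-magnitude profiles for two
network conditions — "coupled" (layer magnitudes increasingly coupled
to memorability across the hierarchy, standing in for a task-trained
network) and "uncoupled" (no coupling anywhere, standing in for random
initialization) — then estimates each layer's magnitude-memorability
correlation with a percentile bootstrap and tests the coupled condition
against the uncoupled one one-sidedly.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from popmag.network import layer_correlation_profile, trained_vs_random_test
from popmag.synthetic import generate_layer_activations

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--images", type=int, default=2000)
    parser.add_argument("--replicates", type=int, default=10_000)
    args = parser.parse_args()

    betas = np.linspace(0.2, 2.0, 5)  # coupling grows across the hierarchy
    coupled, uncoupled = generate_layer_activations(
        args.images, len(betas), betas, seed=args.seed
    )
    boot_c = layer_correlation_profile(
        coupled.magnitudes, coupled.memorability,
        n_replicates=args.replicates, seed=args.seed, condition="coupled",
    )
    boot_u = layer_correlation_profile(
        uncoupled.magnitudes, uncoupled.memorability,
        n_replicates=args.replicates, seed=args.seed, condition="uncoupled",
    )
    p = trained_vs_random_test(boot_c, boot_u)

    table = boot_c.frame().rename(
        columns={c: f"coupled_{c}" for c in ("r", "r_boot_mean", "ci_low", "ci_high")}
    )
    for c in ("r", "ci_low", "ci_high"):
        table[f"uncoupled_{c}"] = boot_u.frame()[c]
    table["p_one_sided"] = p

    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "layer_correlations.csv", index=False)
    (RESULTS / "network_summary.json").write_text(
        json.dumps(
            {
                "seed": args.seed,
                "n_images": args.images,
                "n_replicates": args.replicates,
                "coupled_r_by_layer": [float(v) for v in boot_c.r],
                "uncoupled_r_by_layer": [float(v) for v in boot_u.r],
                "p_one_sided_by_layer": [float(v) for v in p],
            },
            indent=1,
            sort_keys=True,
        )
    )

    print(f"{args.images} images, {args.replicates} bootstrap replicates")
    for i, layer in enumerate(boot_c.layer_names):
        print(f"  {layer}: coupled r = {boot_c.r[i]:.2f} "
              f"[{boot_c.ci_low[i]:.2f}, {boot_c.ci_high[i]:.2f}], "
              f"uncoupled r = {boot_u.r[i]:.2f}, one-sided p = {p[i]:.4g}")
    print("correlation strength increases across the hierarchy in the coupled "
          "condition and stays at zero in the uncoupled one")
    print(f"wrote {RESULTS / 'layer_correlations.csv'}")


if __name__ == "__main__":
    main()
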