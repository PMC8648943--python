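#!/usr/bin/env python
"""Simulate the four dynamic-force-spectroscopy conditions and the
height-clamp dataset, with ground truth.

The four bond states correspond to the kinetic-parameter columns of the
published analysis: wild type probed at 2 ms and 52 ms contact time, and
the two mutants (cytoplasmic-helix deletion, hydrophilic-groove charge
reversal) at 2 ms. Each condition gets rupture events at the five pulling
velocities; event totals mirror the published experiment sizes. Writes
ground-truth event tables (small) plus a 20-curve demonstration curve
table under results/data/.
"""

import sys
from pathlib import Path

import numpy as np

from bondscape import BondModel, ExperimentConfig, generate_clamp_events, generate_dfs_events
from bondscape.io import write_curve_table
from bondscape.synthetic import generate_dfs_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results" / "data"

# condition -> (k0 1/s, x_beta nm, total event count)
CONDITIONS = {
    "wt-2ms": (0.03, 2.0, 460),
    "wt-52ms": (2.0, 0.81, 372),
    "dCH2-2ms": (0.07, 2.2, 322),
    "R366E-2ms": (0.03, 2.3, 311),
}

CLAMP = {"t0": 0.32, "x_beta": 0.57, "n": 134}


def main(seed: int = 1) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    for i, (name, (k0, x_beta, n_total)) in enumerate(CONDITIONS.items()):
        bond = BondModel(k0=k0, x_beta=x_beta)
        per_velocity = max(n_total // 5, 5)
        config = ExperimentConfig(bond=bond, events_per_velocity=per_velocity,
                                  seed=seed * 100 + i)
        events = generate_dfs_events(config)
        out = RESULTS / f"dfs_truth_{name}.tsv"
        events.to_csv(out, sep="\t", index=False)
        print(f"{name}: {len(events)} rupture events "
              f"(k0={k0} 1/s, x_beta={x_beta} nm) -> {out.name}")

    clamp_bond = BondModel(k0=1.0 / CLAMP["t0"], x_beta=CLAMP["x_beta"])
    clamp = generate_clamp_events(CLAMP["n"], clamp_bond, force_range=(20.0, 120.0),
                                  rng=np.random.default_rng(seed * 100 + 50))
    clamp_out = RESULTS / "clamp_truth.tsv"
    clamp.to_csv(clamp_out, sep="\t", index=False)
    print(f"height clamp: {len(clamp)} events (t0={CLAMP['t0']} s, "
          f"x_beta={CLAMP['x_beta']} nm) -> {clamp_out.name}")

    # rendered demonstration set goes to scratch/ — curve tables are bulky,
    # and the full sets are regenerated in memory by 02_detect_events.py
    scratch = Path(__file__).resolve().parent.parent / "scratch"
    scratch.mkdir(exist_ok=True)
    bond = BondModel(k0=2.0, x_beta=0.81)
    demo_cfg = ExperimentConfig(bond=bond, events_per_velocity=4, seed=seed)
    curves, truth = generate_dfs_dataset(demo_cfg)
    write_curve_table(curves, scratch / "demo_curves.tsv")
    truth.to_csv(scratch / "demo_curves_truth.tsv", sep="\t", index=False)
    print(f"demo: {len(curves)} rendered retract curves -> scratch/demo_curves.tsv")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
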