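#!/usr/bin/env python
"""Measured drug response: trapezoidal AUC over simulated viability plates.

Simulates replicated relative-ATP dose-response plates (nine doses over
0.015-100 nM, six technical replicates) for GBM and NPC samples, computes
each sample's trapezoidal AUC on the log10-dose axis, compares the groups
(Wilcoxon + Hodges-Lehmann), and checks the integration against the
noise-free curves.
"""

from pathlib import Path

import pandas as pd

from drugsense import io
from drugsense.dose_response import auc_trapezoid, compare_measured
from drugsense.simulate import SimulationConfig, generate_dose_response

OUT = Path("results")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    curves, labels, true_auc = generate_dose_response(cfg)
    io.write_dose_response(curves, OUT / "dose_response_plates.tsv")

    auc = pd.Series({c.sample_id: auc_trapezoid(c) for c in curves},
                    name="auc")
    table = pd.DataFrame({"sample_id": auc.index, "auc": auc.to_numpy(),
                          "true_auc": true_auc.reindex(auc.index).to_numpy(),
                          "group": labels.reindex(auc.index).to_numpy()})
    io.write_table(table, OUT / "measured_auc.tsv")

    p, hle = compare_measured(auc, labels)
    io.write_table(pd.DataFrame([{"comparison": "GBM_vs_NPC", "p": p,
                                  "hle": hle, "axis": "log10_dose"}]),
                   OUT / "dose_comparison.tsv")

    err = (auc - true_auc.reindex(auc.index)).abs()
    print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
    print(f"GBM vs NPC: exact Wilcoxon p={p:.4f}, HLE={hle:.1f} "
          f"(negative = GBM more sensitive)")
    print(f"max |AUC - noise-free AUC| = {err.max():.1f} "
          f"(replicate noise sd 4% ATP)")


if __name__ == "__main__":
    main()
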