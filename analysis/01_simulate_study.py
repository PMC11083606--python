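#!/usr/bin/env python
"""Generate the default synthetic study and write its input tables.

Produces the inputs every later analysis consumes: a 210-gene x 500-line
training panel with a partially missing drug screen, five clinical cohorts
(GBM vs control, 100 + 100 samples each), one avatar cohort (GBM vs NPC),
and the ground-truth JSON (causal roles, weights, AUC rescaling).
"""

from pathlib import Path

from drugsense import io
from drugsense.simulate import SimulationConfig, generate_study

OUT = Path("results/data")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED, n_drugs=3)
    study = generate_study(cfg, n_clinical=5, include_avatar=True)

    io.write_expression(study.panel_expression, OUT / "panel_expression.tsv")
    io.write_screen(study.screen, OUT / "screen.tsv")
    io.write_truth(study.truth, OUT / "truth.json")
    for cohort in study.cohorts:
        io.write_expression(cohort.expression,
                            OUT / f"expression_{cohort.dataset_id}.tsv")
        io.write_labels(cohort.labels, OUT / f"labels_{cohort.dataset_id}.tsv")

    n_missing = study.screen.isna().to_numpy().mean()
    print(f"panel: {study.panel_expression.shape[0]} genes x "
          f"{study.panel_expression.shape[1]} cell lines, "
          f"{study.screen.shape[1]} drugs ({n_missing:.0%} screens missing)")
    for d, t in study.truth.drugs.items():
        print(f"  {d}: parents={sorted(t.parents)} children={sorted(t.children)} "
              f"confounded={sorted(t.confounded)} sensitive={t.sensitive}")
    print(f"cohorts: {[c.dataset_id for c in study.cohorts]} -> {OUT}")


if __name__ == "__main__":
    main()
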