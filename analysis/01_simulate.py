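#!/usr/bin/env python
"""Generate the full set of synthetic pipeline inputs with planted structure.

Writes reference interactomes, ortholog tables, domain/DDI tables, a GO DAG
with annotations, FL/SNF expression matrices and the seed-protein list into
results/run/, together with ground_truth.json recording what was planted
(interolog edges, module assignment, connector hubs) so later stages can
score their own recovery.
"""

from pathlib import Path

from rhizonet import simulate as sim

RUN = Path(__file__).resolve().parent.parent / "results" / "run"
SEED = 1


def main() -> None:
    cfg = sim.SimConfig(seed=SEED)
    manifest = sim.simulate_all(cfg, RUN)
    print(f"wrote {len(manifest)} input files to {RUN}")
    print("conditions: "
          f"{cfg.n_target_proteins} target proteins, "
          f"{cfg.n_reference_species} reference species, "
          f"ortholog fraction {cfg.ortholog_fraction}, "
          f"rho={cfg.coexpression_rho}, {cfg.n_replicates} replicates, "
          f"{cfg.n_planted_modules} planted modules + {cfg.n_toms} connector hubs")


if __name__ == "__main__":
    main()
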