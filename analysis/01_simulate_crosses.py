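#!/usr/bin/env python
"""Simulate the two-cross pooled-segregant study.

Generates the default study-shaped scenario — 16 yeast chromosomes,
~2,000 markers, four planted QTLs (two major superior-linked, one minor
inferior-linked that epistatically masks a second minor QTL) — and runs
both crosses:

* original parents: 950 segregants, top-58 selected pool (pool 1);
* downgraded parents (major superior QTL and the masking inferior QTL
  neutralised): 2,464 segregants, unselected pool of 58 (pool 0) and
  top-58 selected pool (pool 2).

Writes parent and pool count tables, genotype matrices and the scenario
file under scratch/data/ (bulky raw tables; downstream drivers read them
from there).
"""

from pathlib import Path

from bsamap.pipeline import simulate_study, write_study
from bsamap.scenario import default_scenario, write_scenario

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"
SEED = 1


def main() -> None:
    scenario = default_scenario(n_markers=2000, seed=SEED)
    data = simulate_study(scenario)
    paths = write_study(data, OUT)
    write_scenario(scenario, OUT / "scenario.cfg")
    print(f"simulated {scenario.original.n_segregants} + "
          f"{scenario.downgraded.n_segregants} segregants, "
          f"{scenario.layout.n_markers()} markers")
    for name, path in sorted(paths.items()):
        print(f"  {name}: {path.relative_to(OUT.parent.parent)}")
    sel = data.crosses["original"].phenotypes[data.crosses["original"].selected_ids]
    all_ = data.crosses["original"].phenotypes
    print(f"original cross phenotype: mean {all_.mean():.2f}, "
          f"selected-pool mean {sel.mean():.2f} (transgressive selection)")


if __name__ == "__main__":
    main()
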