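#!/usr/bin/env python
"""Generate the study-like synthetic communities used by the later steps.

Writes two fixtures under results/fixtures/:

* ``bundled/`` — the default conditions (5 taxa, 40 degradative CAZyme
  families, one station with SF/SP/BF/BP/S samples at 1e5 reads each, planted
  overlap s = 0.6 between taxa 1-2 and s = 0.3 between taxa 3-4), plus the
  exact truth tables implied by the generating proportions;
* ``planted_fl_pa/`` — a 6 + 6 free-living vs particle-associated design with
  eight families planted at a 4-fold abundance multiplier in the PA group,
  used for the group-comparison step.
"""

from pathlib import Path

from glyconiche.synthetic import SimConfig, simulate, write_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "fixtures"
SEED = 42


def planted_fl_pa_config(seed: int) -> SimConfig:
    fams = SimConfig(seed=0).family_labels()
    planted = {fams[j]: 4.0 for j in range(0, 40, 5)}
    groups = {f"ST{i:02d}SF": "SF" for i in range(1, 7)}
    groups |= {f"ST{i:02d}SP": "SP" for i in range(1, 7)}
    return SimConfig(seed=seed, group_design=groups, group_effects={"SP": planted})


def main() -> None:
    bundled = simulate(SimConfig(seed=SEED))
    paths = write_fixture(bundled, OUT / "bundled")
    print(f"bundled community: {len(bundled.genes)} genes, {len(bundled.samples)} samples")
    print(f"  truth niche width (B_A): {bundled.truth.niche['B_A'].round(3).to_dict()}")
    print(f"  planted overlaps: ", {
        (i, k): round(bundled.truth.overlap.iloc[i, k], 3)
        for i, k, _ in bundled.config.overlap_design
    })

    planted = simulate(planted_fl_pa_config(SEED))
    write_fixture(planted, OUT / "planted_fl_pa")
    n_planted = len(planted.truth.differential_families(fold=4.0)["SP"])
    print(f"planted FL-vs-PA community: {len(planted.genes)} genes, "
          f"{len(planted.samples)} samples, {n_planted} families at 4-fold")
    print("wrote", *[str(p) for p in paths.values()], sep="\n  ")


if __name__ == "__main__":
    main()
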