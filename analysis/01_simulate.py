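#!/usr/bin/env python
"""Generate the two synthetic study datasets and their ground truth.

Writes under results/data/:
  replica.csv  — 20 individuals x 3 operators (60 records, single sex)
  study.csv    — 906 individuals, one operator each, unbalanced
                 sex-by-operator cells (102/61, 106/163, 252/222 F/M)
  *_truth.json — generator parameters and designed variance shares
"""

import json
from pathlib import Path

import morphoerror as me

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, maker, gen in (
        ("replica", me.replica_spec, me.generate_replica_study),
        ("study", me.study_spec, me.generate_study_sample),
    ):
        spec = maker(seed=SEED)
        ds, truth = gen(spec)
        me.write_landmark_table(ds, OUT / f"{name}.csv")
        (OUT / f"{name}_truth.json").write_text(
            json.dumps(
                {
                    "seed": truth.seed,
                    "design_fractions": truth.design_fractions,
                    "noise_sd_bone": spec.noise_sd_bone,
                    "noise_sd_soft": spec.noise_sd_soft,
                    "individual_shape_sd": spec.individual_shape_sd,
                },
                indent=1,
                sort_keys=True,
            )
        )
        cells = ds.meta().groupby(["operator_id", "sex"]).size()
        print(f"{name}: {len(ds)} records -> {OUT / (name + '.csv')}")
        print(cells.to_string())
        print(
            "designed shape-variance shares:",
            {k: round(v, 3) for k, v in truth.design_fractions.items()},
        )


if __name__ == "__main__":
    main()
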