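"""Generate the synthetic compound panels used by the downstream analyses.

Writes a seven-channel panel (the full-panel screening shape) and a
three-channel panel (the hERG / Cav 1.2 / Nav 1.5-peak assay shape) in
both CSV dialects under results/data/.
"""

from pathlib import Path

import bnetbench as bb

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20260920


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panels = {
        "seven": bb.GeneratorConfig(n_compounds=200, seed=SEED),
        "three": bb.three_channel_config(n_compounds=200, seed=SEED + 1),
    }
    for mode, config in panels.items():
        ic50_path = OUT / f"panel_{mode}_ic50.csv"
        pre_path = OUT / f"panel_{mode}_precomputed.csv"
        records, categories = bb.write_synthetic_dataset(config, ic50_path, pre_path)
        positives = sum(bb.labels_for_scheme(categories, bb.QT_TDEP).values())
        print(
            f"{mode}-channel panel: {len(records)} compounds, "
            f"{positives} QT/TdeP-positive -> {ic50_path.name}, {pre_path.name}"
        )


if __name__ == "__main__":
    main()
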