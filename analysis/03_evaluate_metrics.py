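"""Leave-one-out evaluation of all risk metrics on the generated panels.

For each panel, channel mode and classification scheme, computes the
LOOCV ROC AUC of the net-block score, the two (synthetic stand-in)
ΔAPD90 columns and hERG-only block, and writes the combined table to
results/evaluation_tables.csv — the layout of the published
model-comparison tables.
"""

from pathlib import Path

import pandas as pd

import bnetbench as bb

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    frames = []
    for mode in ("three", "seven"):
        path = ROOT / "data" / "panel_seven_precomputed.csv"
        for scheme in ("QT_TdeP", "TdeP"):
            config = bb.RunConfig(
                input_path=str(path),
                dialect="precomputed",
                scheme=scheme,
                channel_mode=mode,
                out_dir=str(ROOT / "runs" / f"{mode}_{scheme}"),
            )
            table = bb.run(config)
            frame = pd.DataFrame(table.to_records())
            frame.insert(0, "channel_mode", mode)
            frames.append(frame)
    combined = pd.concat(frames, ignore_index=True)
    out = ROOT / "evaluation_tables.csv"
    combined.to_csv(out, index=False)
    print(combined.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    wide = combined.pivot_table(
        index=["channel_mode", "scheme"], columns="metric", values="loocv_roc_auc"
    )
    print("\nLOOCV ROC AUC by mode and scheme:")
    print(wide.to_string(float_format=lambda v: f"{v:.3f}"))
    best = wide.idxmax(axis=1)
    print("\nBest metric per row:")
    print(best.to_string())


if __name__ == "__main__":
    main()
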