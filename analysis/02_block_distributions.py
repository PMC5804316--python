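"""Summarise the per-channel distribution of fractional block at the EFTPC.

Reads the generated panels and writes five-number summaries per channel
to results/block_summary_<mode>.csv.  On the seven-channel panel the
generator's activity pattern should be visible: IKr is the most often
and most strongly hit current, ICaL next.
"""

from pathlib import Path

import bnetbench as bb

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for mode in ("seven", "three"):
        path = ROOT / "data" / f"panel_{mode}_precomputed.csv"
        profiles, _, _ = bb.read_precomputed_dataset(path, bb.DEFAULT_REGISTRY)
        summary = bb.summarise_blocks(profiles)
        out = ROOT / f"block_summary_{mode}.csv"
        summary.to_csv(out, index=False)
        print(f"--- {mode}-channel panel ({len(profiles)} compounds) -> {out.name}")
        print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))


if __name__ == "__main__":
    main()
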