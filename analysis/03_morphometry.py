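"""Skeleton morphometry of microglia in the demo sections.

Segments the microglia channel with the Li threshold, skeletonizes it,
selects components that represent individual cells (exactly one soma,
plausible total length) and writes per-cell endpoint / branch / length
metrics, mirroring the morphology readout used to ask whether microglial
shape (rather than number) differs between groups.
"""

from pathlib import Path

import pandas as pd

from plaqueband.morphometry import select_cells, skeleton_metrics, skeletonize
from plaqueband.plaques import detect_somata
from plaqueband.segmentation import MORPHOMETRY_METHOD, read_stack, segment_channel

SECTIONS = Path(__file__).resolve().parent.parent / "results" / "sections"
OUT = SECTIONS.parent / "morphometry"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for tiff in sorted(SECTIONS.glob("*.tiff")):
        stack = read_stack(tiff)
        px = stack.pixel_size_um
        seg = segment_channel(stack, "microglia", method=MORPHOMETRY_METHOD,
                              ball_radius_px=8, sigma_px=1.0)
        somata = detect_somata(seg.mask, px)
        skel = skeletonize(seg.mask)
        sel = select_cells(skel, somata, px)
        for cid, crop, _ in sel.cells:
            met = skeleton_metrics(crop, px, cell_id=cid)
            rows.append(
                {
                    "section": tiff.stem,
                    "group": tiff.stem.split("_")[0],
                    "cell_id": cid,
                    "endpoints": met.endpoints,
                    "branch_points": met.branch_points,
                    "length_um": met.total_length_um,
                }
            )
        print(f"{tiff.stem}: {len(sel.cells)} cells "
              f"({sel.rejected_merged} merged, {sel.rejected_fragment} fragments rejected)")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "cells.csv", index=False)
    print(df.groupby("group")[["endpoints", "length_um"]].mean().round(2).to_string())


if __name__ == "__main__":
    main()
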