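"""Generate the demo cohort of synthetic sections.

Writes a small two-group cohort (control vs diet/T2D condition factor
0.6, 3 sections per group) as multi-channel TIFFs plus ground-truth
JSON/CSV under results/sections/.  Subsequent scripts quantify these
sections and run the group statistics.
"""

from pathlib import Path

from plaqueband.experiments import power_section_config
from plaqueband.segmentation import write_stack
from plaqueband.synthetic import generate_cohort, save_config, write_ground_truth

OUT = Path(__file__).resolve().parent.parent / "results" / "sections"
SEED = 20240
N_PER_GROUP = 3


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    ctrl = power_section_config(1.0)
    cond = power_section_config(0.6)
    save_config(ctrl, OUT / "config_control.yaml")
    save_config(cond, OUT / "config_condition.yaml")
    cohort = generate_cohort(ctrl, cond, N_PER_GROUP, seed=SEED)
    for i, (stack, gt, label) in enumerate(cohort):
        stem = f"{label}_{i % N_PER_GROUP:02d}"
        write_stack(OUT / f"{stem}.tiff", stack)
        write_ground_truth(gt, OUT / f"{stem}_gt.json", OUT / f"{stem}_gt.csv")
        print(f"{stem}: {len(gt.plaques)} plaques, {len(gt.microglia)} microglia")
    print(f"wrote {len(cohort)} sections to {OUT}")


if __name__ == "__main__":
    main()
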