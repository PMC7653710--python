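"""End-to-end orchestration: simulate -> segment -> quantify -> statistics.

``measure_section`` runs the full image-analysis chain on one stack and
returns tidy per-plaque measurements; ``run_pipeline`` drives a whole
study (simulated or loaded sections) and assembles a
:class:`StudyReport`; ``run_cohort_experiment`` repeats a two-group
simulated experiment many times and reports the fraction of replicates
in which the condition (diet/T2D) effect on plaque-associated microglia
reaches significance — the power / type-I calibration harness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import synthetic
from .plaques import (
    BAND_WIDTH_UM,
    MIN_PLAQUE_DIAMETER_UM,
    STRUCTURE_8,
    band_mask,
    count_plaque_microglia,
    detect_plaques,
    detect_somata,
    diameter_neurite_relation,
    plaque_burden,
    quantify_band,
)
from .segmentation import DEFAULT_METHODS, ImageStack, segment_channel
from .stats import mann_whitney
from .synthetic import SectionConfig, generate_cohort

log = logging.getLogger("plaqueband")


@dataclass
class RunConfig:
    """Parameters of a pipeline run; defaults match the study protocol."""

    simulation: SectionConfig | None = None
    n_sections: int = 3
    input_paths: tuple = ()
    band_width_um: float = BAND_WIDTH_UM
    min_diameter_um: float = MIN_PLAQUE_DIAMETER_UM
    ball_radius_px: int | None = 25
    sigma_px: float = 2.0
    threshold_methods: dict = field(default_factory=dict)  # role -> method override
    soma_min_area_um2: float = 20.0
    markers: tuple = ("microglia", "lysosome", "neurite")
    include_clipped: bool = False
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d


@dataclass
class SectionMeasurements:
    """All measurements from one section."""

    plaques: list
    bands: list
    burden: object
    band_quants: dict  # role -> list[BandQuantification]
    microglia_counts: list
    params: dict

    def per_plaque_table(self) -> pd.DataFrame:
        base_cols = [
            "plaque_id", "diameter_um", "area_um2", "centroid_y_um",
            "centroid_x_um", "border_clipped", "band_clipped", "band_area_um2",
        ]
        if not self.plaques:
            return pd.DataFrame(columns=base_cols)
        rows = []
        mg = {c.plaque_id: c for c in self.microglia_counts}
        for i, p in enumerate(self.plaques):
            row = {
                "plaque_id": p.id,
                "diameter_um": p.equivalent_diameter_um,
                "area_um2": p.area_um2,
                "centroid_y_um": p.centroid_um[0],
                "centroid_x_um": p.centroid_um[1],
                "border_clipped": p.border_clipped,
                "band_clipped": self.bands[i].clipped,
                "band_area_um2": self.bands[i].area_um2,
            }
            for role, quants in self.band_quants.items():
                q = quants[i]
                row[f"{role}_area_inside_um2"] = q.positive_area_inside_um2
                row[f"{role}_area_band_um2"] = q.positive_area_band_um2
                row[f"{role}_intensity_band"] = q.mean_intensity_band
                row[f"{role}_objects_band"] = q.object_count_band
            if p.id in mg:
                row["microglia_within"] = mg[p.id].n_within
                row["microglia_around"] = mg[p.id].n_around
                row["microglia_total"] = mg[p.id].n_total
            rows.append(row)
        return pd.DataFrame(rows)


def measure_section(stack: ImageStack, config: RunConfig) -> SectionMeasurements:
    """Segment every channel and quantify all plaques of one section."""
    methods = {**DEFAULT_METHODS, **config.threshold_methods}
    seg_kwargs = dict(ball_radius_px=config.ball_radius_px, sigma_px=config.sigma_px)
    pseg = segment_channel(stack, "plaque", method=methods["plaque"], **seg_kwargs)
    px = stack.pixel_size_um
    plaques = detect_plaques(pseg.mask, px, config.min_diameter_um)
    if not config.include_clipped:
        plaques = [p for p in plaques if not p.border_clipped]
    bands = [band_mask(p, config.band_width_um, pseg.mask.shape, px) for p in plaques]
    roi = np.ones(pseg.mask.shape, dtype=bool)
    burden = plaque_burden(pseg.mask, roi, px)

    available = set(stack.channel_roles.values())
    band_quants: dict = {}
    somata = []
    for role in config.markers:
        if role not in available:
            continue
        seg = segment_channel(stack, role, method=methods[role], **seg_kwargs)
        labels, _ = ndi.label(seg.mask, structure=STRUCTURE_8)
        image = stack.channel(role)
        band_quants[role] = [
            quantify_band(image, seg.mask, p, b, role, labels)
            for p, b in zip(plaques, bands)
        ]
        if role == "microglia":
            somata = detect_somata(seg.mask, px, config.soma_min_area_um2)
    counts = count_plaque_microglia(somata, plaques, bands) if somata else []
    log.info(
        "section measured: %d plaques, burden %.2f%%, %d somata",
        len(plaques), burden.burden_percent, len(somata),
    )
    return SectionMeasurements(
        plaques=plaques,
        bands=bands,
        burden=burden,
        band_quants=band_quants,
        microglia_counts=counts,
        params={**config.to_dict(), "pixel_size_um": px},
    )


@dataclass
class StudyReport:
    per_section: list  # (section_id, group, SectionMeasurements)
    group_tests: dict
    correlations: dict
    config: RunConfig

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for sid, group, m in self.per_section:
            df = m.per_plaque_table()
            row = {
                "section_id": sid,
                "group": group,
                "n_plaques": len(df),
                "burden_percent": m.burden.burden_percent,
            }
            if len(df):
                if "neurite_objects_band" in df:
                    row["mean_neurites_per_plaque"] = df["neurite_objects_band"].mean()
                if "microglia_total" in df:
                    row["mean_microglia_per_plaque"] = df["microglia_total"].mean()
                if "microglia_area_band_um2" in df:
                    row["mean_microglia_area_band_um2"] = df["microglia_area_band_um2"].mean()
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config.to_dict(),
                "sections": self.summary_table().to_dict(orient="records"),
                "group_tests": {
                    k: {"statistic": v.statistic, "p_value": v.p_value, "name": v.name}
                    for k, v in self.group_tests.items()
                },
                "correlations": self.correlations,
            },
            indent=1,
            default=float,
        )


def run_pipeline(config: RunConfig) -> StudyReport:
    """Run the full pipeline on simulated or loaded sections."""
    logging.basicConfig(level=config.log_level)
    sections = []
    if config.simulation is not None:
        for i in range(config.n_sections):
            sub = int(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(0, i)).generate_state(1)[0]
                % (2**31)
            )
            cfg = dataclasses.replace(config.simulation, seed=sub)
            stack, gt = synthetic.generate_section(cfg)
            sections.append((f"sim{i:02d}", gt.condition_label, stack))
    elif config.input_paths:
        from .segmentation import read_stack

        for path in config.input_paths:
            sections.append((Path(path).stem, "unknown", read_stack(path)))
    else:
        raise ValueError("run_pipeline needs a simulation config or input paths")

    per_section = []
    for sid, group, stack in sections:
        m = measure_section(stack, config)
        per_section.append((sid, group, m))

    # pooled diameter-neurite correlation
    correlations: dict = {}
    all_plaques, all_counts = [], []
    for _, _, m in per_section:
        if "neurite" in m.band_quants:
            all_plaques.extend(m.plaques)
            all_counts.extend(q.object_count_band for q in m.band_quants["neurite"])
    if len(all_plaques) >= 3:
        r, rho, n = diameter_neurite_relation(all_plaques, all_counts)
        correlations["diameter_vs_neurites"] = {"pearson_r": r, "spearman_rho": rho, "n": n}

    # group comparison on per-section means, when two groups are present
    group_tests: dict = {}
    summary = StudyReport(per_section, {}, correlations, config).summary_table()
    groups = [g for g in summary["group"].unique() if g != "unknown"]
    if len(groups) == 2:
        for metric in ("mean_microglia_per_plaque", "mean_neurites_per_plaque",
                       "mean_microglia_area_band_um2"):
            if metric not in summary:
                continue
            a = summary.loc[summary["group"] == groups[0], metric].dropna()
            b = summary.loc[summary["group"] == groups[1], metric].dropna()
            if len(a) and len(b):
                group_tests[metric] = mann_whitney(a, b)

    report = StudyReport(per_section, group_tests, correlations, config)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, group, m in per_section:
            m.per_plaque_table().to_csv(out / f"{sid}_plaques.csv", index=False)
        report.summary_table().to_csv(out / "sections.csv", index=False)
        (out / "report.json").write_text(report.to_json())
    return report


def condition_effect_pvalue(
    config_control: SectionConfig,
    config_condition: SectionConfig,
    n_per_group: int,
    seed: int,
    run_config: RunConfig | None = None,
) -> tuple[float, dict]:
    """One simulated two-group experiment; Mann-Whitney p for the
    condition effect on per-section mean plaque-associated microglia."""
    rc = run_config or RunConfig(markers=("microglia",))
    cohort = generate_cohort(config_control, config_condition, n_per_group, seed)
    means: dict = {"control": [], "condition": []}
    for stack, gt, label in cohort:
        m = measure_section(stack, rc)
        vals = [c.n_total for c in m.microglia_counts]
        means[label].append(float(np.mean(vals)) if vals else 0.0)
    res = mann_whitney(means["control"], means["condition"])
    return res.p_value, means


def run_cohort_experiment(
    config_control: SectionConfig,
    config_condition: SectionConfig,
    n_per_group: int,
    replicates: int,
    seed: int,
    run_config: RunConfig | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Replicate the two-group experiment; per-replicate p-values.

    The returned frame has one row per replicate with the Mann-Whitney
    p-value and group means; ``(frame["p_value"] < alpha).mean()`` is the
    empirical power (or type-I rate when the two configs are identical).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for rep in range(replicates):
        sub = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(rep,)).generate_state(1)[0]
            % (2**31)
        )
        p, means = condition_effect_pvalue(
            config_control, config_condition, n_per_group, sub, run_config
        )
        rows.append(
            {
                "replicate": rep,
                "p_value": p,
                "significant": p < alpha,
                "mean_control": float(np.mean(means["control"])),
                "mean_condition": float(np.mean(means["condition"])),
            }
        )
    return pd.DataFrame(rows)
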