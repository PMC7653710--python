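"""Seeded synthetic multi-channel fluorescence sections with ground truth.

Emulates the structure of hippocampal / cortical sections carrying
beta-amyloid pathology: plaques with log-normally distributed diameters,
dystrophic-neurite puncta whose per-plaque count grows linearly with
plaque diameter, microglia clustered around plaques (soma disk plus
random-walk processes) whose density is scaled by a diet/T2D condition
factor, lysosomal puncta inside microglia, plus a smooth background
gradient and additive Gaussian noise.

Every planted object is recorded in a :class:`SectionGroundTruth` before
noise, so all downstream stages (segmentation, band quantification,
morphometry, group statistics) can be validated by exact recovery.

Rendering is 2D; optional z-stacks replicate the section with per-slice
intensity jitter whose maximum slice equals the 2D render, so ground
truth is defined on the maximum-intensity projection.  Intensities are
arbitrary units in [0, 255].

The four channels are rendered in the fixed order
``plaque, microglia, lysosome, neurite``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .segmentation import ImageStack

CHANNEL_ORDER = ("plaque", "microglia", "lysosome", "neurite")

#: peak rendered intensity per channel (arbitrary units, 8-bit-like scale)
PEAK = {"plaque": 200.0, "microglia": 180.0, "lysosome": 200.0, "neurite": 200.0}

#: Gaussian shoulder of the plaque radial profile (px).  The plateau edge is
#: placed so the half-maximum radius equals the nominal plaque radius; with
#: this narrow shoulder any threshold between ~5% and ~95% of the peak
#: recovers the equivalent diameter within one pixel.
PLAQUE_SHOULDER_PX = 0.35

_HALF_MAX_Z = math.sqrt(2.0 * math.log(2.0))  # shoulder widths from edge to half max


@dataclass
class SectionConfig:
    """Parameters of one synthetic section.

    Densities are per mm^2, sizes in um.  ``condition_factor`` multiplies
    the plaque-associated microglia rate and the lysosomal-puncta rate
    (1.0 = control; < 1 models the diet/T2D suppression of microglial
    clustering).  Identical config + seed gives bit-identical output.
    """

    field_size_um: tuple = (400.0, 400.0)
    pixel_size_um: float = 1.0
    z_slices: int = 1
    z_spacing_um: float = 1.0
    plaque_density: float = 30.0
    plaque_diameter_lognormal: tuple = (math.log(18.0), 0.35)
    diameter_min_um: float = 10.5
    diameter_max_um: float = 45.0
    neurite_rate: tuple = (1.0, 0.25)  # Poisson mean = alpha + beta * diameter_um
    microglia_per_plaque_mean: float = 8.0
    condition_factor: float = 1.0
    background_microglia_density: float = 40.0
    noise_sigma: float = 6.0
    background_gradient_amp: float = 20.0
    seed: int = 0
    # --- rendering and placement details -------------------------------
    lysosome_per_cell_mean: float = 3.0
    soma_diameter_um: tuple = (8.0, 12.0)
    processes_per_cell: tuple = (2, 6)
    process_length_um: tuple = (8.0, 15.0)
    process_persistence: float = 0.85
    band_width_um: float = 30.0
    min_outline_gap_um: float = 65.0
    microglia_within_fraction: float = 0.25
    soma_min_separation_um: float = 25.0
    neurite_margin_um: float = 2.0
    forced_plaques: tuple | None = None  # ((y_um, x_um, diameter_um), ...)

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.diameter_min_um >= self.diameter_max_um:
            raise ValueError("diameter_min_um must be < diameter_max_um")
        for name in (
            "plaque_density",
            "microglia_per_plaque_mean",
            "condition_factor",
            "background_microglia_density",
            "noise_sigma",
            "background_gradient_amp",
            "lysosome_per_cell_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.field_size_um) < 2.0 * self.diameter_max_um:
            raise ValueError(
                "field smaller than twice the maximum plaque diameter: "
                "annulus geometry undefined"
            )
        if self.z_slices < 1:
            raise ValueError("z_slices must be >= 1")

    @property
    def shape_px(self) -> tuple:
        return (
            int(round(self.field_size_um[0] / self.pixel_size_um)),
            int(round(self.field_size_um[1] / self.pixel_size_um)),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SectionConfig":
        d = dict(d)
        for key in ("field_size_um", "plaque_diameter_lognormal", "neurite_rate",
                    "soma_diameter_um", "processes_per_cell", "process_length_um"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("forced_plaques") is not None:
            d["forced_plaques"] = tuple(tuple(p) for p in d["forced_plaques"])
        return cls(**d)


@dataclass
class GTPlaque:
    id: int
    center_um: tuple  # (y, x)
    diameter_um: float
    neurite_count: int = 0
    neurite_positions_um: list = field(default_factory=list)


@dataclass
class GTMicroglia:
    id: int
    soma_center_um: tuple
    soma_radius_um: float
    associated_plaque_id: int | None
    within_plaque: bool
    process_endpoint_count: int
    total_process_length_um: float
    process_paths_px: list = field(default_factory=list)  # list of (n, 2) int arrays
    lysosome_positions_um: list = field(default_factory=list)


@dataclass
class SectionGroundTruth:
    """Everything that was planted in a section, recorded before noise."""

    config: SectionConfig
    plaques: list
    microglia: list
    masks: dict  # role -> boolean GT mask (pre-noise)
    condition_label: str = "control"

    @property
    def plaque_diameters(self) -> np.ndarray:
        return np.array([p.diameter_um for p in self.plaques])

    @property
    def neurite_counts(self) -> np.ndarray:
        return np.array([p.neurite_count for p in self.plaques])

    def microglia_per_plaque(self) -> dict:
        """Planted plaque-associated microglia count per plaque id."""
        counts = {p.id: 0 for p in self.plaques}
        for m in self.microglia:
            if m.associated_plaque_id is not None:
                counts[m.associated_plaque_id] += 1
        return counts


# ----------------------------------------------------------------------
# rendering primitives (all operate on small crops around each object)


def _paint_disk(channel, cy_px, cx_px, radius_px, peak, shoulder_px):
    """Plateau disk with a Gaussian shoulder; half maximum at radius_px."""
    h, w = channel.shape
    r_ext = radius_px + 4.0 * shoulder_px + 2
    y0, y1 = max(int(cy_px - r_ext), 0), min(int(cy_px + r_ext) + 2, h)
    x0, x1 = max(int(cx_px - r_ext), 0), min(int(cx_px + r_ext) + 2, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(yy - cy_px, xx - cx_px)
    r_core = radius_px - _HALF_MAX_Z * shoulder_px
    prof = peak * np.exp(-np.clip(r - r_core, 0, None) ** 2 / (2.0 * shoulder_px**2))
    np.maximum(channel[y0:y1, x0:x1], prof, out=channel[y0:y1, x0:x1])


def _paint_gaussian_spot(channel, cy_px, cx_px, sigma_px, peak):
    h, w = channel.shape
    r_ext = 4.0 * sigma_px + 1
    y0, y1 = max(int(cy_px - r_ext), 0), min(int(cy_px + r_ext) + 2, h)
    x0, x1 = max(int(cx_px - r_ext), 0), min(int(cx_px + r_ext) + 2, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r2 = (yy - cy_px) ** 2 + (xx - cx_px) ** 2
    prof = peak * np.exp(-r2 / (2.0 * sigma_px**2))
    np.maximum(channel[y0:y1, x0:x1], prof, out=channel[y0:y1, x0:x1])


def _disk_mask(shape, cy_px, cx_px, radius_px):
    h, w = shape
    y0, y1 = max(int(cy_px - radius_px) - 1, 0), min(int(cy_px + radius_px) + 2, h)
    x0, x1 = max(int(cx_px - radius_px) - 1, 0), min(int(cx_px + radius_px) + 2, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    out = np.zeros(shape, dtype=bool)
    out[y0:y1, x0:x1] = np.hypot(yy - cy_px, xx - cx_px) <= radius_px
    return out


def _path_length_um(path_px: np.ndarray, pixel_size_um: float) -> float:
    """Chain length with unit orthogonal and sqrt(2) diagonal steps."""
    if len(path_px) < 2:
        return 0.0
    steps = np.abs(np.diff(path_px, axis=0))
    diag = (steps == 1).all(axis=1)
    return float(np.where(diag, math.sqrt(2.0), 1.0).sum()) * pixel_size_um


def _random_walk_process(rng, start_yx, theta0, n_steps, persistence, occupied, shape):
    """Fixed-step (1 px) random walk with directional persistence.

    The walk stops early if it would leave the field or run onto /
    next to previously occupied pixels of the same cell (``occupied``,
    excluding its own recent tail); this keeps each cell's skeleton free
    of self-contacts so its topology is known exactly.
    """
    turn_sd = (1.0 - persistence) * 1.2
    pos = np.array(start_yx, dtype=float)
    theta = theta0
    path = [tuple(np.round(pos).astype(int))]
    own = set(path)
    for _ in range(n_steps):
        theta += rng.normal(0.0, turn_sd)
        pos = pos + np.array([math.sin(theta), math.cos(theta)])
        pix = tuple(np.round(pos).astype(int))
        if not (1 <= pix[0] < shape[0] - 1 and 1 <= pix[1] < shape[1] - 1):
            break
        if pix == path[-1]:
            continue
        # the walk must not run onto or next to other processes of the
        # same cell, nor onto its own earlier pixels (a loop would change
        # the planted topology); the recent tail is its own neighborhood
        recent = set(path[-3:])
        blocked = (occupied | own) - recent
        clash = any(
            (pix[0] + dy, pix[1] + dx) in blocked
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
        )
        if clash:
            break
        path.append(pix)
        own.add(pix)
    return np.array(path, dtype=int)


# ----------------------------------------------------------------------


def generate_section(config: SectionConfig) -> tuple[ImageStack, SectionGroundTruth]:
    """Render one synthetic section and its ground truth.

    Returns the (noisy) :class:`~plaqueband.segmentation.ImageStack` and
    the :class:`SectionGroundTruth` recorded before noise and gradient.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    px = config.pixel_size_um
    shape = config.shape_px
    h_um, w_um = config.field_size_um
    channels = {role: np.zeros(shape, dtype=float) for role in CHANNEL_ORDER}
    masks = {role: np.zeros(shape, dtype=bool) for role in CHANNEL_ORDER}

    plaques = _place_plaques(rng, config)
    for p in plaques:
        cy, cx = p.center_um[0] / px, p.center_um[1] / px
        r_px = 0.5 * p.diameter_um / px
        _paint_disk(channels["plaque"], cy, cx, r_px, PEAK["plaque"], PLAQUE_SHOULDER_PX)
        masks["plaque"] |= _disk_mask(shape, cy, cx, r_px)

    _place_neurites(rng, config, plaques, channels, masks)
    microglia = _place_microglia(rng, config, plaques, channels, masks)

    gt = SectionGroundTruth(
        config=config,
        plaques=plaques,
        microglia=microglia,
        masks=masks,
        condition_label="control" if config.condition_factor >= 1.0 else "condition",
    )

    data = _assemble_stack(rng, config, channels)
    stack = ImageStack(
        data=data,
        pixel_size_um=px,
        channel_roles={i: role for i, role in enumerate(CHANNEL_ORDER)},
        provenance=f"synthetic seed={config.seed}",
    )
    return stack, gt


def _place_plaques(rng, config) -> list[GTPlaque]:
    px = config.pixel_size_um
    h_um, w_um = config.field_size_um
    if config.forced_plaques is not None:
        specs = [(y, x, d) for (y, x, d) in config.forced_plaques]
    else:
        area_mm2 = (h_um / 1000.0) * (w_um / 1000.0)
        n = rng.poisson(config.plaque_density * area_mm2)
        mu, sig = config.plaque_diameter_lognormal
        specs = []
        placed = []  # (y, x, r)
        for _ in range(n):
            d = _truncated_lognormal(rng, mu, sig, config.diameter_min_um, config.diameter_max_um)
            r = 0.5 * d
            margin = r + config.band_width_um + 2.0
            if 2 * margin >= min(h_um, w_um):
                continue
            for _try in range(200):
                y = rng.uniform(margin, h_um - margin)
                x = rng.uniform(margin, w_um - margin)
                gap_ok = all(
                    math.hypot(y - py, x - px_) >= r + pr + config.min_outline_gap_um
                    for (py, px_, pr) in placed
                )
                if gap_ok:
                    placed.append((y, x, r))
                    specs.append((y, x, d))
                    break
    return [
        GTPlaque(id=i, center_um=(float(y), float(x)), diameter_um=float(d))
        for i, (y, x, d) in enumerate(specs)
    ]


def _truncated_lognormal(rng, mu, sigma, lo, hi):
    for _ in range(1000):
        d = rng.lognormal(mu, sigma)
        if lo <= d <= hi:
            return d
    return 0.5 * (lo + hi)


def _place_neurites(rng, config, plaques, channels, masks):
    """Dystrophic-neurite puncta, uniform in each plaque's proximity band."""
    px = config.pixel_size_um
    shape = channels["neurite"].shape
    alpha, beta = config.neurite_rate
    margin = config.neurite_margin_um
    # flat-top puncta (plateau + narrow shoulder) give the neurite channel a
    # genuine second intensity mode, which the intermodes threshold needs
    radius_px = max(1.5 / px, 1.2)
    min_sep_um = max(4.0 * px, 3.0)
    for p in plaques:
        r0 = 0.5 * p.diameter_um
        lam = max(alpha + beta * p.diameter_um, 0.0)
        n = rng.poisson(lam)
        placed = []
        for _ in range(n):
            for _try in range(100):
                # uniform by area between the two radii
                r_in, r_out = r0 + margin, r0 + config.band_width_um - margin
                u = rng.uniform(r_in**2, r_out**2)
                rad = math.sqrt(u)
                ang = rng.uniform(0, 2 * math.pi)
                y = p.center_um[0] + rad * math.sin(ang)
                x = p.center_um[1] + rad * math.cos(ang)
                if all(math.hypot(y - qy, x - qx) >= min_sep_um for (qy, qx) in placed):
                    placed.append((y, x))
                    break
        for (y, x) in placed:
            _paint_disk(channels["neurite"], y / px, x / px, radius_px, PEAK["neurite"], 0.4)
            masks["neurite"] |= _disk_mask(shape, y / px, x / px, radius_px)
        p.neurite_count = len(placed)
        p.neurite_positions_um = placed


def _place_microglia(rng, config, plaques, channels, masks) -> list[GTMicroglia]:
    px = config.pixel_size_um
    shape = channels["microglia"].shape
    h_um, w_um = config.field_size_um
    cells: list[GTMicroglia] = []
    soma_centers: list[tuple] = []
    cell_id = 0

    def try_place(center, soma_r):
        y, x = center
        if not (soma_r + 2 <= y <= h_um - soma_r - 2 and soma_r + 2 <= x <= w_um - soma_r - 2):
            return False
        return all(
            math.hypot(y - sy, x - sx) >= config.soma_min_separation_um
            for (sy, sx) in soma_centers
        )

    lam_assoc = config.microglia_per_plaque_mean * config.condition_factor
    for p in plaques:
        r0 = 0.5 * p.diameter_um
        n = rng.poisson(lam_assoc)
        for _ in range(n):
            soma_r = 0.5 * rng.uniform(*config.soma_diameter_um)
            within = rng.uniform() < config.microglia_within_fraction and r0 > 4.0
            placed = None
            for _try in range(100):
                if within:
                    rad = math.sqrt(rng.uniform(0, max(r0 - 3.0, 0.5) ** 2))
                else:
                    r_in, r_out = r0 + 4.0, r0 + config.band_width_um - 4.0
                    rad = math.sqrt(rng.uniform(r_in**2, r_out**2))
                ang = rng.uniform(0, 2 * math.pi)
                cand = (p.center_um[0] + rad * math.sin(ang), p.center_um[1] + rad * math.cos(ang))
                if try_place(cand, soma_r):
                    placed = cand
                    break
            if placed is None:
                continue
            soma_centers.append(placed)
            cells.append(
                _render_microglia(rng, config, channels, masks, cell_id, placed, soma_r, p.id, within)
            )
            cell_id += 1

    area_mm2 = (h_um / 1000.0) * (w_um / 1000.0)
    n_bg = rng.poisson(config.background_microglia_density * area_mm2)
    keepout = [(p.center_um[0], p.center_um[1], 0.5 * p.diameter_um + config.band_width_um + 8.0)
               for p in plaques]
    for _ in range(n_bg):
        soma_r = 0.5 * rng.uniform(*config.soma_diameter_um)
        placed = None
        for _try in range(100):
            cand = (rng.uniform(10, h_um - 10), rng.uniform(10, w_um - 10))
            if not try_place(cand, soma_r):
                continue
            if all(math.hypot(cand[0] - ky, cand[1] - kx) >= kr for (ky, kx, kr) in keepout):
                placed = cand
                break
        if placed is None:
            continue
        soma_centers.append(placed)
        cells.append(
            _render_microglia(rng, config, channels, masks, cell_id, placed, soma_r, None, False)
        )
        cell_id += 1
    return cells


def _render_microglia(rng, config, channels, masks, cell_id, center_um, soma_r_um, plaque_id, within):
    px = config.pixel_size_um
    shape = channels["microglia"].shape
    cy, cx = center_um[0] / px, center_um[1] / px
    soma_r_px = soma_r_um / px
    _paint_disk(channels["microglia"], cy, cx, soma_r_px, PEAK["microglia"], 0.35)
    soma = _disk_mask(shape, cy, cx, soma_r_px)
    masks["microglia"] |= soma

    n_proc = int(rng.integers(config.processes_per_cell[0], config.processes_per_cell[1] + 1))
    base = rng.uniform(0, 2 * math.pi)
    occupied: set = set()
    paths = []
    total_len = 0.0
    for i in range(n_proc):
        theta = base + 2 * math.pi * i / n_proc + rng.normal(0, 0.15)
        length_um = rng.uniform(*config.process_length_um)
        n_steps = max(int(round(length_um / px)), 3)
        start = (cy + (soma_r_px - 0.5) * math.sin(theta), cx + (soma_r_px - 0.5) * math.cos(theta))
        path = _random_walk_process(
            rng, start, theta, n_steps, config.process_persistence, occupied, shape
        )
        # keep only processes that clearly emerge from the soma
        outside = [
            tuple(q) for q in path if math.hypot(q[0] - cy, q[1] - cx) > soma_r_px + 1.0
        ]
        if len(outside) < 3:
            continue
        occupied.update(map(tuple, path))
        paths.append(path)
        total_len += _path_length_um(path, px)
        channels["microglia"][path[:, 0], path[:, 1]] = np.maximum(
            channels["microglia"][path[:, 0], path[:, 1]], PEAK["microglia"]
        )
        masks["microglia"][path[:, 0], path[:, 1]] = True

    lysosomes = []
    n_lys = rng.poisson(config.lysosome_per_cell_mean * config.condition_factor)
    for _ in range(n_lys):
        ang = rng.uniform(0, 2 * math.pi)
        rad = math.sqrt(rng.uniform(0, max(soma_r_px - 1.5, 0.5) ** 2))
        ly, lx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
        _paint_gaussian_spot(channels["lysosome"], ly, lx, 0.8 / px if px < 0.8 else 0.9, PEAK["lysosome"])
        masks["lysosome"] |= _disk_mask(shape, ly, lx, 1.0)
        lysosomes.append((ly * px, lx * px))

    return GTMicroglia(
        id=cell_id,
        soma_center_um=(float(center_um[0]), float(center_um[1])),
        soma_radius_um=float(soma_r_um),
        associated_plaque_id=plaque_id,
        within_plaque=within,
        process_endpoint_count=len(paths),
        total_process_length_um=total_len,
        process_paths_px=paths,
        lysosome_positions_um=lysosomes,
    )


def _assemble_stack(rng, config, channels) -> np.ndarray:
    """Add gradient + noise, replicate across z with per-slice jitter."""
    shape = config.shape_px
    base = np.stack([channels[r] for r in CHANNEL_ORDER])
    if config.background_gradient_amp > 0:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        phi = rng.uniform(0, 2 * math.pi)
        ramp = math.cos(phi) * xx / max(shape[1] - 1, 1) + math.sin(phi) * yy / max(shape[0] - 1, 1)
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-12)
        base = base + config.background_gradient_amp * ramp[None]
    if config.z_slices == 1:
        out = base[:, None] if False else base
        if config.noise_sigma > 0:
            out = out + rng.normal(0, config.noise_sigma, size=out.shape)
        return np.clip(out, 0, 255).astype(np.float32)
    factors = rng.uniform(0.7, 1.0, size=config.z_slices)
    factors[rng.integers(config.z_slices)] = 1.0  # projection equals the 2D render
    data = base[:, None, :, :] * factors[None, :, None, None]
    if config.noise_sigma > 0:
        data = data + rng.normal(0, config.noise_sigma, size=data.shape)
    return np.clip(data, 0, 255).astype(np.float32)


def generate_cohort(
    config_control: SectionConfig,
    config_condition: SectionConfig,
    n_per_group: int,
    seed: int,
) -> list[tuple[ImageStack, SectionGroundTruth, str]]:
    """Two groups of sections with counter-derived per-section seeds.

    Each of the ``2 * n_per_group`` sections gets a sub-seed derived from
    ``seed`` and its (group, index) position, so any section can be
    regenerated independently of generation order.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    out = []
    for g, (cfg, label) in enumerate(
        [(config_control, "control"), (config_condition, "condition")]
    ):
        for i in range(n_per_group):
            sub = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(g, i)).generate_state(1)[0]
                % (2**31)
            )
            section_cfg = dataclasses.replace(cfg, seed=sub)
            stack, gt = generate_section(section_cfg)
            gt.condition_label = label
            out.append((stack, gt, label))
    return out


# ----------------------------------------------------------------------
# config / ground-truth serialization


def load_config(path) -> SectionConfig:
    """Read a section config from YAML or JSON."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SectionConfig.from_dict(data)


def save_config(config: SectionConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(config.to_dict()), fh, sort_keys=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_ground_truth(gt: SectionGroundTruth, json_path, csv_path=None) -> None:
    """Ground truth as JSON (+ optional per-plaque CSV)."""
    payload = {
        "config": _jsonable(gt.config.to_dict()),
        "condition_label": gt.condition_label,
        "plaques": [
            {
                "id": p.id,
                "center_um": list(p.center_um),
                "diameter_um": p.diameter_um,
                "neurite_count": p.neurite_count,
                "neurite_positions_um": _jsonable(p.neurite_positions_um),
            }
            for p in gt.plaques
        ],
        "microglia": [
            {
                "id": m.id,
                "soma_center_um": list(m.soma_center_um),
                "soma_radius_um": m.soma_radius_um,
                "associated_plaque_id": m.associated_plaque_id,
                "within_plaque": m.within_plaque,
                "process_endpoint_count": m.process_endpoint_count,
                "total_process_length_um": m.total_process_length_um,
            }
            for m in gt.microglia
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    if csv_path is not None:
        import pandas as pd

        mg = gt.microglia_per_plaque()
        pd.DataFrame(
            {
                "plaque_id": [p.id for p in gt.plaques],
                "diameter_um": [p.diameter_um for p in gt.plaques],
                "neurite_count": [p.neurite_count for p in gt.plaques],
                "microglia_count": [mg[p.id] for p in gt.plaques],
            }
        ).to_csv(csv_path, index=False)
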