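"""Synthetic fluorescence fields with full ground truth.

The generator emulates the phenomena a dense human neuronal culture presents
to the segmentation pipeline: live neuronal nuclei with attached somata,
non-neuronal nuclei, small/bright/rugged dead nuclei, clumped-cell regions,
branching neurite trees with bright-thick major and dim-thin minor segments,
neurites routed through foreign somata, channel- and compartment-specific
intensities, and Poisson + Gaussian noise.  Per-compound effects act as
multiplicative scales on phospho-tau intensity (per compartment) and on total
neurite length.

Strokes are rendered at integer width with no anti-aliasing, so true
compartment areas are exact pixel counts and the ground truth is bit-exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon
from skimage.filters import gaussian
from skimage.morphology import dilation, disk as disk_footprint

from .errors import UnmappedTreatmentError
from .io import CHANNELS, FieldImage, PlateLayout

#: Compartments with distinct rendered intensities.
COMPARTMENTS = ("background", "nucleus_live", "nucleus_dead", "soma",
                "neurite_major", "neurite_minor")


def default_intensity_model() -> dict[str, dict[str, float]]:
    """Mean clean intensity (arbitrary fluorescence units) per channel and compartment.

    DNA stain is nuclear only; dead nuclei are markedly brighter than live
    ones.  The cytoskeletal/tau channels label somata and neurites, with minor
    neurites dimmer than major ones, and phospho-tau strongest along neurites
    (axonal enrichment).
    """
    return {
        "dna": {"background": 80.0, "nucleus_live": 600.0, "nucleus_dead": 1500.0,
                "soma": 80.0, "neurite_major": 80.0, "neurite_minor": 80.0},
        "tubulin": {"background": 80.0, "nucleus_live": 80.0, "nucleus_dead": 80.0,
                    "soma": 500.0, "neurite_major": 550.0, "neurite_minor": 260.0},
        "total_tau": {"background": 80.0, "nucleus_live": 80.0, "nucleus_dead": 80.0,
                      "soma": 450.0, "neurite_major": 500.0, "neurite_minor": 240.0},
        "p_tau": {"background": 80.0, "nucleus_live": 80.0, "nucleus_dead": 80.0,
                  "soma": 300.0, "neurite_major": 500.0, "neurite_minor": 250.0},
    }


@dataclass
class NeuriteTreeConfig:
    """Morphology of the random-walk neurite trees grown from each soma."""

    n_primary: tuple[int, int] = (2, 4)
    tree_length: tuple[int, int] = (60, 200)   # px of walk per primary tree
    step: float = 3.0                          # px advanced per direction update
    branch_prob: float = 0.05                  # per-step branching probability
    major_width: int = 3
    minor_width: int = 1
    minor_fraction: float = 0.3                # fraction of trees that are minor
    curvature_sd: float = 0.25                 # radians of heading change per step
    crossing_prob: float = 0.08                # tree aimed through a foreign soma


@dataclass
class NoiseModel:
    gaussian_sd: float = 8.0
    poisson: bool = True


@dataclass
class EffectParams:
    """Multiplicative treatment effect applied at render time."""

    p_tau_scale_neurite: float = 1.0
    p_tau_scale_soma: float = 1.0
    neurite_area_scale: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.p_tau_scale_neurite, self.p_tau_scale_soma,
                  self.neurite_area_scale):
            if not v > 0:
                raise ValueError("effect multipliers must be > 0")


@dataclass
class SynthFieldConfig:
    grid_shape: tuple[int, int] = (1024, 1024)
    n_neurons: int = 30
    n_nonneuronal: int = 10
    n_dead: int = 5
    clump_fraction: float = 0.1
    soma_radius: tuple[float, float] = (7.0, 10.0)
    live_nucleus_radius: tuple[float, float] = (5.5, 7.5)
    dead_nucleus_radius: tuple[float, float] = (3.5, 5.0)
    clump_margin: int = 4
    neurite_tree: NeuriteTreeConfig = field(default_factory=NeuriteTreeConfig)
    intensity_model: dict = field(default_factory=default_intensity_model)
    noise: NoiseModel = field(default_factory=NoiseModel)
    effect: EffectParams = field(default_factory=EffectParams)
    blur_sigma: float = 0.0                    # optional optics blur, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dead_nucleus_radius[1] >= self.live_nucleus_radius[0]:
            raise ValueError("dead nuclei must be strictly smaller than live nuclei")
        im = self.intensity_model
        if im["dna"]["nucleus_dead"] <= im["dna"]["nucleus_live"]:
            raise ValueError("dead nuclei must be brighter than live in DNA channel")
        for ch in ("tubulin", "total_tau", "p_tau"):
            if im[ch]["neurite_minor"] >= im[ch]["neurite_major"]:
                raise ValueError("minor neurites must be dimmer than major")


@dataclass
class GroundTruth:
    """Simulator-side truth for recovery tests.

    ``true_mean`` holds, per channel and compartment, the mean clean (pre-noise)
    intensity over that compartment's exclusive pixels; effect multipliers are
    already applied, so intensity-effect ratios are exact.  Compartment keys:
    ``soma`` excludes neurite crossings (neurites are painted last), ``neurite``
    is every neurite pixel.
    """

    nucleus_labels: np.ndarray
    nucleus_classes: dict[int, str]            # neuronal_live | nonneuronal | dead
    soma_labels: np.ndarray
    neurite_mask: np.ndarray
    clump_mask: np.ndarray
    true_mean: dict[str, dict[str, float]]
    effect: EffectParams


def _sample_centers(rng, n, shape, margin, min_sep, existing):
    """Rejection-sample n centres at least min_sep from existing/each other."""
    pts = list(existing)
    out = []
    tries = 0
    while len(out) < n and tries < 200 * max(n, 1):
        tries += 1
        p = (rng.uniform(margin, shape[0] - margin),
             rng.uniform(margin, shape[1] - margin))
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep ** 2 for q in pts):
            pts.append(p)
            out.append(p)
    return out


def _rugged_polygon(rng, center, radius, shape):
    """A spiky star polygon emulating a pyknotic (dead) nucleus outline."""
    n_vert = 2 * int(rng.integers(5, 8))
    angles = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
    angles = angles + rng.uniform(-0.15, 0.15, n_vert) + rng.uniform(0, 2 * np.pi)
    radii = np.where(np.arange(n_vert) % 2 == 0,
                     radius * rng.uniform(1.0, 1.2, n_vert),
                     radius * rng.uniform(0.3, 0.45, n_vert))
    rr = center[0] + radii * np.sin(angles)
    cc = center[1] + radii * np.cos(angles)
    return draw_polygon(rr, cc, shape=shape)


def _walk_tree(rng, start, direction, length, cfg: NeuriteTreeConfig,
               shape, target=None):
    """Random-walk polyline pixels for one neurite tree (with branching).

    Returns row/col index arrays of the 1-px-wide path.  If ``target`` is
    given the heading is steered toward it (crossing a foreign soma).
    """
    rows, cols = [], []
    stack = [(np.array(start, float), float(direction), float(length))]
    while stack:
        pos, ang, remaining = stack.pop()
        while remaining > 0:
            if target is not None:
                to_t = np.arctan2(target[0] - pos[0], target[1] - pos[1])
                d = (to_t - ang + np.pi) % (2 * np.pi) - np.pi
                ang += 0.3 * d
            ang += rng.normal(0.0, cfg.curvature_sd)
            new = pos + cfg.step * np.array([np.sin(ang), np.cos(ang)])
            r0, c0 = int(round(pos[0])), int(round(pos[1]))
            r1, c1 = int(round(new[0])), int(round(new[1]))
            r1 = min(max(r1, 0), shape[0] - 1)
            c1 = min(max(c1, 0), shape[1] - 1)
            rr, cc = draw_line(r0, c0, r1, c1)
            rows.append(rr)
            cols.append(cc)
            pos = np.array([r1, c1], float)
            remaining -= cfg.step
            if rng.random() < cfg.branch_prob and remaining > 3 * cfg.step:
                stack.append((pos.copy(), ang + rng.choice([-1.0, 1.0]) *
                              rng.uniform(0.5, 1.1), remaining * 0.6))
                remaining *= 0.7
    if not rows:
        return np.empty(0, int), np.empty(0, int)
    return np.concatenate(rows), np.concatenate(cols)


def generate_field(config: SynthFieldConfig) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Deterministic for a fixed ``config.seed``.  Compartments overflowing the
    grid are clipped; zero cells of any class is allowed.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    tree_cfg = config.neurite_tree

    nucleus_labels = np.zeros(shape, np.int32)
    soma_labels = np.zeros(shape, np.int32)
    neurite_major = np.zeros(shape, bool)
    neurite_minor = np.zeros(shape, bool)
    clump_mask = np.zeros(shape, bool)
    nucleus_classes: dict[int, str] = {}

    margin = 2 * config.soma_radius[1]
    min_sep = 2 * config.live_nucleus_radius[1] + 6.0

    # -- clump membership: groups of >=3 neurons fused at one site
    n_clump_members = int(round(config.clump_fraction * config.n_neurons))
    if n_clump_members < 3:
        n_clump_members = 0
    n_free = config.n_neurons - n_clump_members
    clump_sizes = []
    left = n_clump_members
    while left >= 3:
        size = 3 if left < 6 else int(rng.integers(3, min(left - 2, 6) + 1))
        if left - size in (1, 2):
            size = left
        clump_sizes.append(size)
        left -= size

    free_centers = _sample_centers(rng, n_free, shape, margin, min_sep, [])
    clump_centers = _sample_centers(rng, len(clump_sizes), shape, margin,
                                    2 * min_sep, free_centers)

    label = 0
    neuron_info = []  # (label, center, soma_r, clumped)
    for center in free_centers:
        label += 1
        r_nuc = rng.uniform(*config.live_nucleus_radius)
        r_soma = rng.uniform(*config.soma_radius)
        rr, cc = draw_disk(center, r_nuc, shape=shape)
        nucleus_labels[rr, cc] = label
        nucleus_classes[label] = "neuronal_live"
        neuron_info.append((label, center, r_soma, False))
    for c_center, size in zip(clump_centers, clump_sizes):
        members = []
        for _ in range(size):
            label += 1
            ang = rng.uniform(0, 2 * np.pi)
            d = rng.uniform(1.1, 1.9) * config.live_nucleus_radius[0]
            center = (c_center[0] + d * np.sin(ang), c_center[1] + d * np.cos(ang))
            r_nuc = rng.uniform(*config.live_nucleus_radius)
            r_soma = rng.uniform(*config.soma_radius)
            rr, cc = draw_disk(center, r_nuc, shape=shape)
            nucleus_labels[rr, cc] = label
            nucleus_classes[label] = "neuronal_live"
            neuron_info.append((label, center, r_soma, True))
            members.append((center, r_nuc))
        blob = np.zeros(shape, bool)
        for center, r_nuc in members:
            rr, cc = draw_disk(center, r_nuc, shape=shape)
            blob[rr, cc] = True
        clump_mask |= dilation(blob, disk_footprint(config.clump_margin))

    for label_, center, r_soma, _clumped in neuron_info:
        rr, cc = draw_disk(center, r_soma, shape=shape)
        free = soma_labels[rr, cc] == 0
        soma_labels[rr[free], cc[free]] = label_

    occupied = [c for _, c, _, _ in neuron_info]
    nn_centers = _sample_centers(rng, config.n_nonneuronal, shape, margin,
                                 min_sep, occupied)
    for center in nn_centers:
        label += 1
        r_nuc = rng.uniform(*config.live_nucleus_radius)
        rr, cc = draw_disk(center, r_nuc, shape=shape)
        nucleus_labels[rr, cc] = label
        nucleus_classes[label] = "nonneuronal"
    occupied += nn_centers
    dead_centers = _sample_centers(rng, config.n_dead, shape,
                                   config.dead_nucleus_radius[1] + 2,
                                   min_sep, occupied)
    for center in dead_centers:
        label += 1
        r_nuc = rng.uniform(*config.dead_nucleus_radius)
        rr, cc = _rugged_polygon(rng, center, r_nuc, shape)
        nucleus_labels[rr, cc] = label
        nucleus_classes[label] = "dead"

    # -- neurite trees grown from soma boundaries of non-clumped neurons
    foreign = [(lbl, c) for lbl, c, _, cl in neuron_info if not cl]
    for label_, center, r_soma, clumped in neuron_info:
        if clumped:
            continue
        n_primary = int(rng.integers(tree_cfg.n_primary[0],
                                     tree_cfg.n_primary[1] + 1))
        for _ in range(n_primary):
            ang = rng.uniform(0, 2 * np.pi)
            start = (center[0] + (r_soma - 1.0) * np.sin(ang),
                     center[1] + (r_soma - 1.0) * np.cos(ang))
            length = rng.uniform(*tree_cfg.tree_length)
            length *= config.effect.neurite_area_scale
            target = None
            if len(foreign) > 1 and rng.random() < tree_cfg.crossing_prob:
                others = [c for lbl, c in foreign if lbl != label_]
                target = others[int(rng.integers(len(others)))]
            rr, cc = _walk_tree(rng, start, ang, length, tree_cfg, shape,
                                target=target)
            minor = rng.random() < tree_cfg.minor_fraction
            tgt = neurite_minor if minor else neurite_major
            tgt[rr, cc] = True

    w = tree_cfg.major_width
    if w > 1:
        neurite_major = dilation(neurite_major, disk_footprint((w - 1) // 2))
    w = tree_cfg.minor_width
    if w > 1:
        neurite_minor = dilation(neurite_minor, disk_footprint((w - 1) // 2))
    neurite_minor &= ~neurite_major
    neurite_mask = neurite_major | neurite_minor

    # -- paint clean channels; later compartments overwrite earlier ones so
    #    every pixel has exactly one compartment intensity (exact truth)
    live_mask = np.isin(nucleus_labels,
                        [l for l, c in nucleus_classes.items() if c != "dead"]) \
        if nucleus_classes else np.zeros(shape, bool)
    dead_mask = np.isin(nucleus_labels,
                        [l for l, c in nucleus_classes.items() if c == "dead"]) \
        if nucleus_classes else np.zeros(shape, bool)
    soma_mask = soma_labels > 0

    eff = config.effect
    clean: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        im = config.intensity_model[ch]
        img = np.full(shape, float(im["background"]))
        img[clump_mask] = 1.75 * im["background"]      # elevated clump background
        scale_soma = eff.p_tau_scale_soma if ch == "p_tau" else 1.0
        scale_neur = eff.p_tau_scale_neurite if ch == "p_tau" else 1.0
        if ch == "dna":
            # DNA stain is nuclear: nuclei sit on top of everything
            img[soma_mask] = im["soma"] * scale_soma
            img[neurite_major] = im["neurite_major"] * scale_neur
            img[neurite_minor] = im["neurite_minor"] * scale_neur
            img[live_mask] = im["nucleus_live"]
            img[dead_mask] = im["nucleus_dead"]
        else:
            # cytoplasmic markers fill the soma over the nucleus in projection;
            # neurites painted last so their intensities (and effect scales)
            # are exact on every neurite pixel
            img[live_mask] = im["nucleus_live"]
            img[dead_mask] = im["nucleus_dead"]
            img[soma_mask] = im["soma"] * scale_soma
            img[neurite_major] = im["neurite_major"] * scale_neur
            img[neurite_minor] = im["neurite_minor"] * scale_neur
        clean[ch] = img

    # -- exclusive compartment pixels for the truth means
    comp_pixels = {
        "neurite": neurite_mask,
        "soma": soma_mask & ~neurite_mask & ~live_mask,
        "nucleus_live": live_mask & ~neurite_mask,
        "nucleus_dead": dead_mask & ~neurite_mask,
        "background": ~(neurite_mask | soma_mask | live_mask | dead_mask),
    }
    true_mean = {
        ch: {comp: (float(clean[ch][px].mean()) if px.any() else float("nan"))
             for comp, px in comp_pixels.items()}
        for ch in CHANNELS
    }

    channels: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        img = clean[ch]
        if config.blur_sigma > 0:
            img = gaussian(img, config.blur_sigma, preserve_range=True)
        if config.noise.poisson:
            img = rng.poisson(img).astype(float)
        if config.noise.gaussian_sd > 0:
            img = img + rng.normal(0.0, config.noise.gaussian_sd, shape)
        channels[ch] = np.clip(img, 0.0, None).astype(np.float32)

    field_img = FieldImage(well_id="A1", field_index=0, channels=channels)
    truth = GroundTruth(
        nucleus_labels=nucleus_labels,
        nucleus_classes=nucleus_classes,
        soma_labels=soma_labels,
        neurite_mask=neurite_mask,
        clump_mask=clump_mask,
        true_mean=true_mean,
        effect=eff,
    )
    return field_img, truth


def field_seed(master_seed: int, well_id: str, field_index: int) -> int:
    """Stable per-field seed derived from (master seed, well, field)."""
    ss = np.random.SeedSequence(
        [int(master_seed), zlib.crc32(well_id.encode()), int(field_index)]
    )
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_plate(
    layout: PlateLayout,
    base: SynthFieldConfig,
    compound_effects: Mapping[tuple[str, float], EffectParams],
    seed: int,
    positive_control_effect: EffectParams | None = None,
) -> Iterator[tuple[FieldImage, GroundTruth]]:
    """Stream fields for every populated well of a plate.

    DMSO wells render with unit effect multipliers; positive-control wells use
    ``positive_control_effect`` (default: phospho-tau halved in both
    compartments, the designated reference-inhibitor effect); compound wells
    look up ``(compound_id, dose)`` in ``compound_effects``.
    """
    if positive_control_effect is None:
        positive_control_effect = EffectParams(0.5, 0.5, 1.0)
    for well_id in sorted(layout.wells):
        treat = layout.wells[well_id]
        if treat.kind == "empty":
            continue
        if treat.kind == "dmso":
            eff = EffectParams()
        elif treat.kind == "positive_control":
            eff = positive_control_effect
        else:
            key = (treat.compound_id, treat.dose)
            if key not in compound_effects:
                raise UnmappedTreatmentError(
                    f"unmapped treatment {treat.compound_id} @ {treat.dose}"
                )
            eff = compound_effects[key]
        for fi in range(layout.fields_per_well):
            cfg = replace(base, effect=eff,
                          seed=field_seed(seed, well_id, fi))
            field_img, truth = generate_field(cfg)
            field_img.well_id = well_id
            field_img.field_index = fi
            yield field_img, truth
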