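"""Segmentation pipeline for dense neuronal cultures.

Stages, orchestrated by :func:`segment_field`:

1. nucleus detection by gradient-magnitude edge detection on the DNA channel
   (closed contours filled and labelled), with dead-nucleus exclusion by the
   combined size / brightness / ruggedness rule;
2. neuronal cell-body segmentation by geodesic growth from each live nucleus
   through pixels with contiguous tubulin *and* total-tau support;
3. iterative neurite extraction: a local-contrast (top-hat) response on the
   per-pixel maximum of the three cytoskeletal/tau channels, thresholded with
   a monotone non-increasing cutoff schedule; the first (strictest) pass seeds
   the mask, later passes may only add pixels 8-connected to the accumulated
   mask or to somata, so the mask grows monotonically while successive passes
   recover dim minor neurites and improve path continuity;
4. a per-segment test separating true minor neurites from background signal
   (local contrast and skeleton length);
5. non-random gap closing: skeleton endpoints are bridged only when their
   tangent directions agree and point toward each other, never on distance
   alone;
6. clump detection and exclusion;
7. finalisation: image-math subtraction of cell bodies (and clumps) from the
   neurite mask, and restriction of cell-body quantification to areas not
   crossed by neurites.

All cutoffs are derived from robust per-field background statistics scaled by
at most three run-level adjustment multipliers, so the pipeline is equivariant
under global intensity changes.  Stringency throughout favours false
negatives over false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line
from skimage.filters import apply_hysteresis_threshold, gaussian, sobel
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import (
    closing as grey_closing,
    dilation as grey_dilation,
    disk as disk_footprint,
    skeletonize,
    white_tophat,
)

from .errors import MaskGeometryError
from .io import FieldImage

_EIGHT = np.ones((3, 3), bool)


def _robust_sigma(values: np.ndarray) -> float:
    """1.4826 x median absolute deviation; ~sigma for Gaussian noise."""
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def default_cutoff_schedule(n: int, final: float = 0.4) -> tuple[float, ...]:
    """Geometric relaxation of the contrast cutoff from 1.0 to ``final``."""
    return tuple(np.geomspace(1.0, final, n))


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation pipeline.

    Cutoffs are expressed relative to per-field robust statistics (noise sigma
    or background median), so defaults transfer across global intensity
    changes; `global_intensity_adjustments` holds the up-to-three run-level
    multipliers applied on top of the derived cutoffs.
    """

    # nuclei
    dna_smooth_sigma: float = 0.8
    edge_gradient_threshold: float = 8.0      # gradient cutoff, in noise sigmas
    nucleus_area_range: tuple[float, float] = (70.0, 250.0)
    min_object_area: float = 15.0
    nucleus_intensity_min_rel: float = 1.25   # object mean over field median
    dead_area_max: float = 55.0
    dead_intensity_min: float = 1.5           # x median live-nucleus DNA mean
    dead_solidity_max: float = 0.85
    # cell bodies
    soma_area_range: tuple[float, float] = (100.0, 450.0)
    soma_channel_sigma: float = 8.0           # tubulin/total-tau support cutoff
    soma_contiguity: float = 0.7              # required support fraction per channel
    # neurites
    neurite_iterations: int = 10
    cutoff_schedule: tuple[float, ...] | None = None
    neurite_base_sigma: float = 12.0          # base contrast cutoff, in noise sigmas
    tophat_radius: int = 5
    gap_max_length: float = 10.0
    gap_angle_tol: float = 0.5                # radians
    minor_contrast_min: float = 1.2
    minor_min_length: float = 20.0
    # clumps
    clump_nucleus_count_min: int = 3
    clump_area_factor: float = 1.0            # x max(nucleus_area_range)
    clump_margin: int = 6
    # run-to-run intensity compensation (at most 3 multipliers)
    global_intensity_adjustments: dict[str, float] = field(
        default_factory=lambda: {"dna": 1.0, "soma": 1.0, "neurite": 1.0}
    )

    def __post_init__(self) -> None:
        if self.neurite_iterations < 1:
            raise ValueError("neurite_iterations must be >= 1")
        if self.cutoff_schedule is None:
            self.cutoff_schedule = default_cutoff_schedule(self.neurite_iterations)
        self.cutoff_schedule = tuple(float(c) for c in self.cutoff_schedule)
        if len(self.cutoff_schedule) != self.neurite_iterations:
            raise ValueError("cutoff_schedule length must equal neurite_iterations")
        if np.any(np.diff(self.cutoff_schedule) > 1e-12):
            raise ValueError("cutoff_schedule must be non-increasing")
        if self.dead_area_max >= self.nucleus_area_range[0]:
            raise ValueError("dead_area_max must lie below the live-nucleus range")
        if len(self.global_intensity_adjustments) > 3:
            raise ValueError("at most 3 global intensity adjustments per run")


@dataclass
class NucleusRecord:
    label: int
    area: float
    dna_mean: float
    solidity: float
    klass: str     # neuronal_live | nonneuronal | dead_excluded | clumped_excluded


@dataclass
class SegmentationMasks:
    """All masks produced for one field, including the two quantification masks."""

    nucleus_labels: np.ndarray
    nuclei: list[NucleusRecord]
    soma_labels: np.ndarray
    neurite_mask_total: np.ndarray
    neurite_mask_final: np.ndarray
    clump_mask: np.ndarray
    soma_quant_labels: np.ndarray
    neurite_quant_mask: np.ndarray

    def validate(self) -> None:
        grids = (self.nucleus_labels, self.soma_labels, self.neurite_mask_total,
                 self.neurite_mask_final, self.clump_mask,
                 self.soma_quant_labels, self.neurite_quant_mask)
        if len({g.shape for g in grids}) != 1:
            raise MaskGeometryError("mask geometry mismatch")
        if (self.neurite_quant_mask & (self.soma_labels > 0)).any():
            raise AssertionError("neurite quant mask overlaps somata")
        if ((self.soma_quant_labels > 0) & (self.soma_labels == 0)).any():
            raise AssertionError("soma quant labels escape soma mask")
        if (self.clump_mask & (self.neurite_quant_mask
                               | (self.soma_quant_labels > 0))).any():
            raise AssertionError("clump pixels leaked into quantification masks")


# ---------------------------------------------------------------------------
# nuclei


def detect_nuclei(field: FieldImage, params: SegmentationParams
                  ) -> tuple[np.ndarray, list[NucleusRecord]]:
    """Detect nuclei on the DNA channel and classify dead ones for exclusion.

    Candidate objects come from gradient-magnitude edge detection (hysteresis
    linking) followed by contour closing and hole filling; inclusion and the
    dead-nucleus rule both act on the mean intensity of the entire object
    rather than a global intensity threshold.  Dead nuclei must be small
    (area <= dead_area_max), bright (DNA mean >= dead_intensity_min x the
    median of size-qualified nuclei) and rugged (solidity <= dead_solidity_max).
    """
    dna = np.asarray(field.channels["dna"], float)
    adj = params.global_intensity_adjustments.get("dna", 1.0)
    sm = gaussian(dna, params.dna_smooth_sigma, preserve_range=True)
    grad = sobel(sm)
    sigma = _robust_sigma(grad)
    if sigma <= 0:
        sigma = grad.mean() + 1e-12
    hi = params.edge_gradient_threshold * sigma * adj
    edges = apply_hysteresis_threshold(grad, 0.4 * hi, hi)
    closed = grey_closing(edges, disk_footprint(2))
    filled = ndi.binary_fill_holes(closed)
    # the edge ring inflates objects; restrict each to its intensity core
    # (half-way between the field background and the object's bright level,
    # on the raw channel) so size and shape criteria see the nucleus itself
    med_field = float(np.median(dna))
    raw_labels, n_raw = ndi.label(filled, structure=_EIGHT)
    core = np.zeros_like(filled)
    for sl, lab in zip(ndi.find_objects(raw_labels), range(1, n_raw + 1)):
        if sl is None:
            continue
        obj = raw_labels[sl] == lab
        vals = dna[sl][obj]
        thr = 0.5 * (np.percentile(vals, 90) + med_field)
        core[sl] |= obj & (dna[sl] >= thr)
    labels, _ = ndi.label(core, structure=_EIGHT)
    records: list[NucleusRecord] = []
    keep = np.zeros(labels.max() + 1, bool)
    props = regionprops(labels, intensity_image=dna)
    # median DNA mean of size-qualified (live-sized) objects
    qual = [p.intensity_mean for p in props
            if params.nucleus_area_range[0] <= p.area <= params.nucleus_area_range[1]]
    med_live = float(np.median(qual)) if qual else med_field
    for p in props:
        if p.area < params.min_object_area:
            continue
        if p.intensity_mean < params.nucleus_intensity_min_rel * med_field:
            continue
        is_dead = (p.area <= params.dead_area_max
                   and p.intensity_mean >= params.dead_intensity_min * med_live
                   and p.solidity <= params.dead_solidity_max)
        if not is_dead and p.area < params.nucleus_area_range[0]:
            continue  # sub-nuclear debris
        keep[p.label] = True
        records.append(NucleusRecord(
            label=p.label, area=float(p.area),
            dna_mean=float(p.intensity_mean), solidity=float(p.solidity),
            klass="dead_excluded" if is_dead else "neuronal_live",
        ))
    out = np.where(keep[labels], labels, 0).astype(np.int32)
    # relabel densely, keeping record order stable
    mapping = {r.label: i + 1 for i, r in enumerate(records)}
    relabel = np.zeros(labels.max() + 1, np.int32)
    for old, new in mapping.items():
        relabel[old] = new
    out = relabel[out]
    for r in records:
        r.label = mapping[r.label]
    return out, records


# ---------------------------------------------------------------------------
# cell bodies


def _channel_cutoff(img: np.ndarray, k_sigma: float, adj: float) -> float:
    med = float(np.median(img))
    return med + k_sigma * _robust_sigma(img) * adj


def segment_cell_bodies(field: FieldImage, nucleus_labels: np.ndarray,
                        nuclei: list[NucleusRecord],
                        params: SegmentationParams) -> np.ndarray:
    """Grow somata from live nuclei through contiguous tubulin AND total-tau.

    A candidate soma is the set of support pixels geodesically connected to
    its nucleus, assigned to the nearest nucleus where claims overlap, and
    capped at the radius implied by the soma area range.  Candidates failing
    the area range or the per-channel support ("contiguity") fraction emit no
    soma and their nucleus is classed non-neuronal.
    """
    tub = np.asarray(field.channels["tubulin"], float)
    ttau = np.asarray(field.channels["total_tau"], float)
    adj = params.global_intensity_adjustments.get("soma", 1.0)
    c_tub = _channel_cutoff(tub, params.soma_channel_sigma, adj)
    c_tt = _channel_cutoff(ttau, params.soma_channel_sigma, adj)
    support_t = tub >= c_tub
    support_k = ttau >= c_tt
    support = support_t & support_k
    # a cell body is a compact region: opening strips neurite-width support
    # so growth cannot leak out along processes
    support_core = ndi.binary_opening(support, structure=disk_footprint(2))

    soma_labels = np.zeros_like(nucleus_labels)
    live = [r for r in nuclei if r.klass == "neuronal_live"
            and params.nucleus_area_range[0] <= r.area <= params.nucleus_area_range[1]]
    if not live:
        for r in nuclei:
            if r.klass == "neuronal_live":
                r.klass = "nonneuronal"
        return soma_labels

    live_ids = np.array([r.label for r in live])
    nuc_mask = np.isin(nucleus_labels, live_ids)
    # nearest live nucleus per pixel (Euclidean tie-break toward the closer
    # nucleus; equal distances resolve to the lower label via scan order)
    dist, (ir, ic) = ndi.distance_transform_edt(~nuc_mask, return_indices=True)
    nearest = nucleus_labels[ir, ic]
    r_max = float(np.sqrt(params.soma_area_range[1] / np.pi)) + 2.0

    allowed = (support_core | nuc_mask) & (dist <= r_max)
    pad = int(np.ceil(r_max)) + 1
    for rec in live:
        obj = nucleus_labels == rec.label
        sl = ndi.find_objects(obj.astype(np.int8))[0]
        sl = tuple(slice(max(s.start - pad, 0), s.stop + pad) for s in sl)
        local_seed = obj[sl]
        local_allowed = allowed[sl] & (nearest[sl] == rec.label)
        grown = ndi.binary_propagation(local_seed, mask=local_allowed | local_seed,
                                       structure=_EIGHT)
        area = int(grown.sum())
        cap = int(params.soma_area_range[1])
        if area > cap:
            # keep the pixels nearest the nucleus: trims thin leakage along
            # neurites while preserving the compact cell body
            dvals = np.where(grown, dist[sl], np.inf)
            cut = np.partition(dvals.ravel(), cap - 1)[cap - 1]
            grown &= dvals <= cut
            area = int(grown.sum())
        frac_t = support_t[sl][grown].mean() if area else 0.0
        frac_k = support_k[sl][grown].mean() if area else 0.0
        ok = (params.soma_area_range[0] <= area <= params.soma_area_range[1]
              and frac_t >= params.soma_contiguity
              and frac_k >= params.soma_contiguity)
        if ok:
            region = soma_labels[sl]
            region[grown & (region == 0)] = rec.label
        else:
            rec.klass = "nonneuronal"
    for rec in nuclei:
        if rec.klass == "neuronal_live" and rec.label not in set(np.unique(soma_labels)):
            rec.klass = "nonneuronal"
    return soma_labels


# ---------------------------------------------------------------------------
# neurites


def neurite_response(field: FieldImage, params: SegmentationParams) -> np.ndarray:
    """Local-contrast response: white top-hat of the max of the three
    cytoskeletal/tau channels, which passes thin ridges and suppresses wide
    blobs (somata, clumps)."""
    composite = np.maximum.reduce([
        np.asarray(field.channels["tubulin"], float),
        np.asarray(field.channels["total_tau"], float),
        np.asarray(field.channels["p_tau"], float),
    ])
    return white_tophat(composite, disk_footprint(params.tophat_radius))


def extract_neurite_mask(field: FieldImage, soma_labels: np.ndarray,
                         params: SegmentationParams,
                         response: np.ndarray | None = None) -> np.ndarray:
    """Iterative neurite extraction with a relaxing cutoff schedule.

    Pass 1 thresholds the contrast response at the strictest cutoff and seeds
    the mask with every super-threshold pixel (bright major segments).  Each
    later pass lowers the cutoff and admits only pixels 8-connected to the
    accumulated mask or to somata, so dim minor neurites and path gaps are
    recovered without re-opening the field to isolated noise.
    """
    if response is None:
        response = neurite_response(field, params)
    adj = params.global_intensity_adjustments.get("neurite", 1.0)
    sigma = _robust_sigma(response)
    if sigma <= 0:
        sigma = float(response.std()) + 1e-12
    base = params.neurite_base_sigma * sigma * adj
    schedule = params.cutoff_schedule
    mask = response >= schedule[0] * base
    soma_mask = soma_labels > 0
    for cut in schedule[1:]:
        cand = response >= cut * base
        seed = mask | soma_mask
        grown = ndi.binary_propagation(seed, mask=cand | seed, structure=_EIGHT)
        mask |= grown & cand
    return mask


def test_neurite_segments(candidate: np.ndarray, field: FieldImage,
                          soma_labels: np.ndarray,
                          params: SegmentationParams) -> np.ndarray:
    """Differentiate true neurite segments from background signal.

    Segments touching a soma are kept.  An isolated segment survives only if
    its mean composite intensity is at least ``minor_contrast_min`` times the
    local background mean *and* its skeleton is at least ``minor_min_length``
    px long.  This also absorbs antibody-dependent background, which fails the
    local-contrast test.
    """
    composite = np.maximum.reduce([
        np.asarray(field.channels["tubulin"], float),
        np.asarray(field.channels["total_tau"], float),
        np.asarray(field.channels["p_tau"], float),
    ])
    labels = cc_label(candidate, connectivity=2)
    if labels.max() == 0:
        return candidate.copy()
    soma_adj = grey_dilation(soma_labels > 0, _EIGHT)
    touching = np.unique(labels[soma_adj & candidate])
    touching = set(int(t) for t in touching if t != 0)
    keep = np.zeros(labels.max() + 1, bool)
    objects = ndi.find_objects(labels)
    for lab in range(1, labels.max() + 1):
        if lab in touching:
            keep[lab] = True
            continue
        sl = objects[lab - 1]
        pad = 6
        sl = tuple(slice(max(s.start - pad, 0), min(s.stop + pad, n))
                   for s, n in zip(sl, labels.shape))
        seg = labels[sl] == lab
        skel_len = int(skeletonize(seg).sum())
        if skel_len < params.minor_min_length:
            continue
        ring = grey_dilation(seg, disk_footprint(4)) & ~grey_dilation(seg, _EIGHT)
        ring &= ~candidate[sl] & (soma_labels[sl] == 0)
        if not ring.any():
            continue
        bg_mean = float(composite[sl][ring].mean())
        seg_mean = float(composite[sl][seg].mean())
        if bg_mean <= 0 or seg_mean / bg_mean >= params.minor_contrast_min:
            keep[lab] = True
    return keep[labels]


def _endpoint_tangents(skel: np.ndarray, max_back: int = 5):
    """Skeleton endpoints with outward tangent unit vectors and component ids."""
    nbr = ndi.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8),
                       mode="constant") - skel
    endpoints = np.argwhere(skel & (nbr == 1))
    comp = cc_label(skel, connectivity=2)
    pts, dirs, comps = [], [], []
    skel_set = None
    for r, c in endpoints:
        # walk back along the skeleton to estimate the local tangent
        prev = None
        cur = (int(r), int(c))
        path = [cur]
        for _ in range(max_back):
            nxt = None
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    q = (cur[0] + dr, cur[1] + dc)
                    if (0 <= q[0] < skel.shape[0] and 0 <= q[1] < skel.shape[1]
                            and skel[q] and q != prev and q not in path):
                        nxt = q
                        break
                if nxt:
                    break
            if nxt is None:
                break
            prev, cur = cur, nxt
            path.append(cur)
        if len(path) < 2:
            continue
        v = np.array(path[0], float) - np.array(path[-1], float)
        n = np.linalg.norm(v)
        if n == 0:
            continue
        pts.append(path[0])
        dirs.append(v / n)
        comps.append(int(comp[path[0]]))
    return pts, dirs, comps


def close_gaps(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Non-random gap closing between skeleton endpoints.

    Endpoint pairs in *different* components, closer than ``gap_max_length``,
    are bridged by a straight path dilated to the local neurite width — but
    only when each endpoint's tangent points toward the other within
    ``gap_angle_tol``; distance alone never bridges.  Idempotent: bridged
    endpoints share a component on a second application and are skipped.
    """
    if not mask.any():
        return mask.copy()
    skel = skeletonize(mask)
    pts, dirs, comps = _endpoint_tangents(skel)
    if len(pts) < 2:
        return mask.copy()
    out = mask.copy()
    dt = ndi.distance_transform_edt(mask)
    tree = cKDTree(np.asarray(pts, float))
    pairs = sorted(tree.query_pairs(params.gap_max_length),
                   key=lambda ij: np.hypot(*(np.array(pts[ij[0]], float)
                                             - np.array(pts[ij[1]], float))))
    used: set[int] = set()
    cos_tol = np.cos(params.gap_angle_tol)
    for i, j in pairs:
        if i in used or j in used or comps[i] == comps[j]:
            continue
        pi = np.array(pts[i], float)
        pj = np.array(pts[j], float)
        v = pj - pi
        n = np.linalg.norm(v)
        if n == 0:
            continue
        v = v / n
        if np.dot(dirs[i], v) < cos_tol or np.dot(dirs[j], -v) < cos_tol:
            continue
        rr, cc = draw_line(*map(int, pts[i]), *map(int, pts[j]))
        bridge = np.zeros_like(mask)
        bridge[rr, cc] = True
        width = max(dt[pts[i]], dt[pts[j]])
        if width > 1.0:
            bridge = grey_dilation(bridge, disk_footprint(int(round(width - 1))))
        out |= bridge
        used.update((i, j))
    return out


# ---------------------------------------------------------------------------
# clumps and finalisation


def detect_clumps(field: FieldImage, nucleus_labels: np.ndarray,
                  nuclei: list[NucleusRecord],
                  params: SegmentationParams) -> np.ndarray:
    """Mark contiguous high-DNA regions where several nuclei have merged.

    A region qualifies when it fuses >= ``clump_nucleus_count_min`` detected
    nuclei or when a single object exceeds ``clump_area_factor`` times the
    live-nucleus area maximum; the mask is dilated by ``clump_margin`` px.
    Member nuclei are reclassified as clumped_excluded.
    """
    blob = nucleus_labels > 0
    if not blob.any():
        return np.zeros_like(blob)
    merged = grey_closing(blob, disk_footprint(3))
    regions = cc_label(merged, connectivity=2)
    area_max = params.clump_area_factor * params.nucleus_area_range[1]
    clump_core = np.zeros_like(blob)
    by_label = {r.label: r for r in nuclei}
    for sl, lab in zip(ndi.find_objects(regions), range(1, regions.max() + 1)):
        region = regions[sl] == lab
        members = np.unique(nucleus_labels[sl][region])
        members = [int(m) for m in members if m != 0]
        is_clump = (len(members) >= params.clump_nucleus_count_min
                    or int(region.sum()) >= area_max)
        if is_clump:
            clump_core[sl] |= region
            for m in members:
                if m in by_label and by_label[m].klass != "dead_excluded":
                    by_label[m].klass = "clumped_excluded"
    if not clump_core.any():
        return clump_core
    return grey_dilation(clump_core, disk_footprint(params.clump_margin))


def finalize_masks(nucleus_labels: np.ndarray, nuclei: list[NucleusRecord],
                   soma_labels: np.ndarray, neurite_total: np.ndarray,
                   neurite_final: np.ndarray,
                   clump_mask: np.ndarray) -> SegmentationMasks:
    """Image-math subtraction producing the two quantification masks.

    ``neurite_quant = neurite_final - somata - clumps``; cell-body
    quantification is restricted to soma areas not crossed by neurites and
    outside clumps.
    """
    grids = (nucleus_labels, soma_labels, neurite_total, neurite_final, clump_mask)
    if len({g.shape for g in grids}) != 1:
        raise MaskGeometryError("mask geometry mismatch")
    soma_mask = soma_labels > 0
    neurite_quant = neurite_final & ~soma_mask & ~clump_mask
    soma_quant = soma_labels.copy()
    soma_quant[neurite_final | clump_mask] = 0
    masks = SegmentationMasks(
        nucleus_labels=nucleus_labels,
        nuclei=nuclei,
        soma_labels=soma_labels,
        neurite_mask_total=neurite_total,
        neurite_mask_final=neurite_final,
        clump_mask=clump_mask,
        soma_quant_labels=soma_quant,
        neurite_quant_mask=neurite_quant,
    )
    masks.validate()
    return masks


def segment_field(field: FieldImage,
                  params: SegmentationParams | None = None) -> SegmentationMasks:
    """Run the full pipeline on one field; deterministic for fixed inputs."""
    if params is None:
        params = SegmentationParams()
    nucleus_labels, nuclei = detect_nuclei(field, params)
    soma_labels = segment_cell_bodies(field, nucleus_labels, nuclei, params)
    response = neurite_response(field, params)
    total = extract_neurite_mask(field, soma_labels, params, response=response)
    tested = test_neurite_segments(total, field, soma_labels, params)
    closed = close_gaps(tested, params)
    clump_mask = detect_clumps(field, nucleus_labels, nuclei, params)
    return finalize_masks(nucleus_labels, nuclei, soma_labels, total,
                          closed, clump_mask)
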