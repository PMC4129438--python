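"""Fluorescence target detection: iterative threshold-crossing particle
analysis, circularity filtering, and the cross-plane priority rule.

The detection stage turns a 12-bit fluorescence stack into a 3-D map of soma
targets.  Per plane, a threshold starts near the image maximum and drops by a
fixed increment per partition; at each partition, 4-connected bright
components within an area window become candidate ROIs.  A new component that
fully contains exactly one earlier ROI replaces it (the particle simply grew);
a component enveloping two or more earlier ROIs is discarded and the earlier
ROIs kept, which avoids conflating adjacent cells into a single target.

Each surviving ROI is scored by circularity C = 4*pi*a / p**2 (area a,
perimeter p, clipped to <= 1): near 1 for a disc-like soma, near 0 for an
elongated dendrite shaft.  ROIs pass only when C strictly exceeds the cutoff
(default 0.75).  Finally the priority rule deduplicates somata detected in
more than one focal plane: among overlapping accepted ROIs in adjacent planes
(sharing >= 1 (x, y) pixel), only the deepest/earliest detection survives and
becomes a target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as _perimeter

__all__ = [
    "Roi",
    "TargetRecord",
    "TargetMap",
    "DetectionConfig",
    "circularity",
    "iterative_threshold_rois",
    "circularity_filter",
    "priority_rule",
    "detect_targets",
]

MAX_INTENSITY = 4095
DEFAULT_INCREMENT = 16          # -> 256 partitions of the 12-bit range
DEFAULT_AREA_RANGE_UM2 = (20.0, 400.0)
DEFAULT_CUTOFF = 0.75


def circularity(area: float, perimeter: float) -> float:
    """Shape score C = 4*pi*area / perimeter**2, clipped to <= 1.

    1 for an ideal circle (a = pi r^2, p = 2 pi r); pi/4 ~ 0.785 for a square;
    near 0 for elongated polygons.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return min(1.0, 4.0 * np.pi * area / perimeter**2)


@dataclass
class Roi:
    """A candidate particle on one focal plane.

    The mask is a single 4-connected component stored as (row, col) index
    arrays; area/perimeter are in pixels with physical equivalents derived
    from the pixel size.
    """

    plane: int
    rows: np.ndarray
    cols: np.ndarray
    area_px: int
    perimeter_px: float
    centroid_px: tuple  # (x, y) in pixel units
    pixel_size_um: float = 1.0
    status: str = "candidate"

    @property
    def area_um2(self) -> float:
        return self.area_px * self.pixel_size_um**2

    @property
    def perimeter_um(self) -> float:
        return self.perimeter_px * self.pixel_size_um

    @property
    def circularity(self) -> float:
        return circularity(self.area_px, self.perimeter_px)

    @property
    def centroid_um(self) -> tuple:
        return (self.centroid_px[0] * self.pixel_size_um,
                self.centroid_px[1] * self.pixel_size_um)

    def pixel_set(self) -> set:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


def _component_roi(local_mask: np.ndarray, offset: tuple, plane: int,
                   pixel_size_um: float) -> Roi:
    r0, c0 = offset
    lr, lc = np.nonzero(local_mask)
    rows, cols = lr + r0, lc + c0
    # corner-weighted contour length; raw edge counting biases C low for
    # small discs (pad so border pixels contribute their outer edges)
    per = float(_perimeter(np.pad(local_mask, 1), neighborhood=4))
    if per <= 0:  # single pixel or degenerate: fall back to box perimeter
        per = 4.0
    cy, cx = rows.mean(), cols.mean()
    return Roi(plane=plane, rows=rows, cols=cols, area_px=int(rows.size),
               perimeter_px=per, centroid_px=(float(cx) + 0.5, float(cy) + 0.5),
               pixel_size_um=pixel_size_um)


def iterative_threshold_rois(
    image,
    increment: int = DEFAULT_INCREMENT,
    area_range_px: tuple = (30, 650),
    plane: int = 0,
    pixel_size_um: float = 1.0,
) -> list[Roi]:
    """Iterative threshold-crossing particle detection on one plane.

    The threshold starts at the largest partition boundary below the image
    maximum and decreases by ``increment`` per partition down to zero (the
    number of partitions is 4096 / increment for a 12-bit image).  At each
    step, 4-connected components of supra-threshold pixels whose pixel area
    lies within ``area_range_px`` are candidate ROIs; the containment rules
    described in the module docstring merge or reject them against the
    running mask.  A blank image yields an empty list.
    """
    if increment < 1 or increment > MAX_INTENSITY:
        raise ValueError("increment must lie in [1, 4095]")
    amin, amax = area_range_px
    if amin <= 0 or amin >= amax:
        raise ValueError("area range must be positive with min < max")
    img = np.asarray(image)
    if img.max() == 0:
        return []

    # running mask state: label image of current ROIs plus per-ROI
    # (bounding slice, local mask) records
    current_label = np.zeros(img.shape, dtype=np.int32)
    masks: dict[int, tuple] = {}
    next_id = 1
    four_connected = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])

    top = (int(img.max()) // increment) * increment
    for thr in range(top, -1, -increment):
        lab, n_comp = ndimage.label(img > thr, structure=four_connected)
        if n_comp == 0:
            continue
        areas = np.bincount(lab.ravel())
        in_range = [c for c in range(1, n_comp + 1) if amin <= areas[c] <= amax]
        if not in_range:
            continue
        slices = ndimage.find_objects(lab)
        for comp in in_range:
            sl = slices[comp - 1]
            comp_mask = lab[sl] == comp
            prior_ids = np.unique(current_label[sl][comp_mask])
            prior_ids = prior_ids[prior_ids > 0]
            if prior_ids.size >= 2:
                continue  # envelopes several cells: keep the priors
            if prior_ids.size == 1:
                pid = int(prior_ids[0])
                psl, pmask = masks[pid]
                region = current_label[psl]
                region[pmask] = 0
                del masks[pid]
            masks[next_id] = (sl, comp_mask)
            current_label[sl][comp_mask] = next_id
            next_id += 1

    return [_component_roi(m, (sl[0].start, sl[1].start), plane, pixel_size_um)
            for _, (sl, m) in sorted(masks.items())]


def circularity_filter(rois, cutoff: float = DEFAULT_CUTOFF):
    """Partition ROIs into (accepted, rejected): accepted iff C > cutoff
    (strict — a score of exactly the cutoff is rejected).  Statuses are
    updated in place."""
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    accepted, rejected = [], []
    for r in rois:
        if r.circularity > cutoff:
            r.status = "accepted"
            accepted.append(r)
        else:
            r.status = "rejected_circularity"
            rejected.append(r)
    return accepted, rejected


@dataclass
class TargetRecord:
    id: int
    x_um: float
    y_um: float
    plane: int
    depth_um: float
    side: str


@dataclass
class TargetMap:
    """Validated 3-D soma targets plus the per-plane ROI audit trail."""

    targets: list[TargetRecord] = field(default_factory=list)
    rois_by_plane: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.targets)

    def counts_by_side(self) -> dict:
        out: dict = {}
        for t in self.targets:
            out[t.side] = out.get(t.side, 0) + 1
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(t) for t in self.targets])


def priority_rule(
    accepted_by_plane: dict,
    z_step_um: float = 10.0,
    pixel_size_um: float | None = None,
    field_extent_um: float | None = None,
) -> TargetMap:
    """Deduplicate accepted ROIs across adjacent focal planes.

    Two ROIs in *adjacent* planes overlap when their masks share at least one
    (x, y) pixel.  Overlap chains are resolved as connected components of the
    overlap graph; within each component exactly one ROI survives — the one in
    the deepest plane (largest depth), ties broken by acquisition order
    (earliest first).  Survivors become targets centered on their centroids;
    the rest are marked ``rejected_priority``.  Running the rule on its own
    output is a no-op.
    """
    planes = sorted(accepted_by_plane)
    rois: list[tuple[int, int, Roi]] = []  # (plane, within-plane order, roi)
    for p in planes:
        for k, r in enumerate(accepted_by_plane[p]):
            rois.append((p, k, r))

    # union-find over the overlap graph
    parent = list(range(len(rois)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    pixels_by_index = [r.pixel_set() for _, _, r in rois]
    idx_by_plane: dict[int, list[int]] = {}
    for i, (p, _, _) in enumerate(rois):
        idx_by_plane.setdefault(p, []).append(i)
    for p in planes:
        for i in idx_by_plane.get(p, []):
            for j in idx_by_plane.get(p + 1, []):
                if not pixels_by_index[i].isdisjoint(pixels_by_index[j]):
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(rois)):
        groups.setdefault(find(i), []).append(i)

    tmap = TargetMap()
    for members in groups.values():
        # deepest plane wins; earliest acquisition breaks ties
        winner = max(members, key=lambda i: (rois[i][0], -rois[i][1]))
        for i in members:
            p, _, r = rois[i]
            if i == winner:
                r.status = "accepted"
                x_um, y_um = (r.centroid_um if pixel_size_um is None else
                              (r.centroid_px[0] * pixel_size_um,
                               r.centroid_px[1] * pixel_size_um))
                side = "unknown"
                if field_extent_um is not None:
                    side = "left" if x_um < field_extent_um else "right"
                tmap.targets.append(TargetRecord(
                    id=-1, x_um=x_um, y_um=y_um, plane=p,
                    depth_um=p * z_step_um, side=side))
            else:
                r.status = "rejected_priority"
    # canonical order (plane, then position) so ids are reproducible
    tmap.targets.sort(key=lambda t: (t.plane, t.y_um, t.x_um))
    for k, t in enumerate(tmap.targets):
        t.id = k
    return tmap


@dataclass
class DetectionConfig:
    increment: int = DEFAULT_INCREMENT
    area_range_um2: tuple = DEFAULT_AREA_RANGE_UM2
    cutoff: float = DEFAULT_CUTOFF


def detect_targets(stack, config: DetectionConfig | None = None) -> TargetMap:
    """Full detection on an :class:`~ablatio.synthgen.ImageStack`:
    per-plane iterative thresholding, circularity filtering, then the
    cross-plane priority rule.  Reproducible for fixed inputs; the per-plane
    ROI lists (all statuses) are retained in the returned map for audit.
    """
    cfg = config or DetectionConfig()
    px = stack.pixel_size_um
    area_px = (max(1, int(round(cfg.area_range_um2[0] / px**2))),
               int(round(cfg.area_range_um2[1] / px**2)))
    accepted_by_plane: dict[int, list[Roi]] = {}
    all_by_plane: dict[int, list[Roi]] = {}
    for p in range(stack.n_planes):
        rois = iterative_threshold_rois(
            stack.planes[p], increment=cfg.increment, area_range_px=area_px,
            plane=p, pixel_size_um=px)
        acc, _ = circularity_filter(rois, cfg.cutoff)
        accepted_by_plane[p] = acc
        all_by_plane[p] = rois
    tmap = priority_rule(accepted_by_plane, z_step_um=stack.z_step_um,
                         field_extent_um=stack.field_extent_um)
    tmap.rois_by_plane = all_by_plane
    tmap.provenance = {
        "increment": cfg.increment,
        "area_range_um2": list(cfg.area_range_um2),
        "cutoff": cfg.cutoff,
        "pixel_size_um": px,
        "z_step_um": stack.z_step_um,
    }
    return tmap


def write_target_map(tmap: TargetMap, csv_path, audit_json_path=None):
    """TargetMap CSV (id, x_um, y_um, plane, depth_um, side) plus an optional
    JSON audit of per-plane ROI counts by status."""
    tmap.to_frame().to_csv(csv_path, index=False)
    if audit_json_path is not None:
        import json

        audit = {}
        for p, rois in tmap.rois_by_plane.items():
            counts: dict = {}
            for r in rois:
                counts[r.status] = counts.get(r.status, 0) + 1
            audit[str(p)] = counts
        with open(audit_json_path, "w") as fh:
            json.dump({"provenance": tmap.provenance, "roi_counts": audit}, fh,
                      indent=2)
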