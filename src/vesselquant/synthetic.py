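"""Synthetic lymph-node vessel fields with a known ground-truth ledger.

Real CD34-stained nodal regions carry hundreds to thousands of vessel
profiles whose areas follow a heavily right-skewed distribution (medians
around 60–130 µm², maxima orders of magnitude larger).  The generator
emulates those fields with three shape families — filled discs (capillary
cross-sections), annuli (vessels with an unstained lumen), and dilated
curved polylines (longitudinally cut vessels) — placed by rejection
sampling so that instances never touch and no two centroids fall within
each other's non-maximum-suppression gate.

A *degradation* model then turns the truth into a realistic "prediction",
reproducing the error modes of a segmentation model: instance dropout,
small false-positive specks, fragmentation of large vessels into several
pieces, centroid jitter and multiplicative area noise.  Every event is
recorded in a :class:`TruthLedger`, so the expected true-positive /
false-positive / false-negative composition of any downstream evaluation is
known exactly.

All randomness flows from a single explicit seed through one
``numpy.random.Generator``; identical seeds give bit-identical fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Point

from .errors import InputError
from .geometry import InstanceRecord, PixelCalibration
from .mask_io import LabelField, extract_instances

# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of a synthetic ground-truth vessel field.

    The area distribution is log-normal, parameterized by its median (µm²)
    and the log-scale sigma, clipped below at ``min_area_um2``; a small
    fraction of instances (``large_vessel_rate``) is drawn instead from a
    uniform large-vessel range to reproduce the heavy right tail.
    ``shape_mix`` gives the (disc, annulus, tube) proportions.
    """

    width_um: float = 500.0
    height_um: float = 500.0
    target_count: int = 150
    median_area_um2: float = 100.0
    sigma_log: float = 0.8
    min_area_um2: float = 8.0
    shape_mix: tuple[float, float, float] = (0.3, 0.4, 0.3)
    large_vessel_rate: float = 0.005
    large_area_range_um2: tuple[float, float] = (3000.0, 8000.0)
    microns_per_pixel: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise InputError("field dimensions must be positive")
        if self.target_count < 0:
            raise InputError("target_count must be non-negative")
        if abs(sum(self.shape_mix) - 1.0) > 1e-9:
            raise InputError(f"shape_mix must sum to 1, got {self.shape_mix}")
        if not 0 <= self.large_vessel_rate <= 1:
            raise InputError("large_vessel_rate must lie in [0, 1]")

    @property
    def calib(self) -> PixelCalibration:
        return PixelCalibration(self.microns_per_pixel)

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um


@dataclass(frozen=True)
class DegradeSpec:
    """Parameters of the prediction-degradation model.

    fn_rate : per-instance dropout probability (missed vessels).
    fp_speck_rate : expected spurious specks per 10⁴ µm² of field area.
    fp_speck_area_range_um2 : speck areas; the default stays below the 6-µm²
        post-processing threshold so specks exercise the minimum-area filter.
    fragment_prob : probability that a vessel larger than
        ``fragment_min_area_um2`` is returned as several broken pieces
        instead of one object.
    centroid_jitter_sd_um / area_noise_cv : localization and size noise of
        surviving detections.
    """

    fn_rate: float = 0.0
    fp_speck_rate: float = 0.0
    fp_speck_area_range_um2: tuple[float, float] = (2.0, 5.5)
    fragment_prob: float = 0.0
    fragment_min_area_um2: float = 1000.0
    fragment_count_range: tuple[int, int] = (3, 6)
    centroid_jitter_sd_um: float = 0.0
    area_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fn_rate", "fragment_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must lie in [0, 1], got {v}")
        if self.centroid_jitter_sd_um < 0 or self.area_noise_cv < 0:
            raise InputError("noise magnitudes must be non-negative")
        if self.fp_speck_rate < 0:
            raise InputError("fp_speck_rate must be non-negative")


@dataclass
class TruthEntry:
    survived: bool
    pred_ids: list[int] = dc_field(default_factory=list)


@dataclass
class PredEntry:
    origin: str  # "true" | "speck" | "fragment"
    truth_id: Optional[int] = None


@dataclass
class TruthLedger:
    """Event record linking every predicted instance to its origin."""

    truth: dict[int, TruthEntry] = dc_field(default_factory=dict)
    preds: dict[int, PredEntry] = dc_field(default_factory=dict)

    @property
    def survivor_ids(self) -> list[int]:
        return [t for t, e in self.truth.items() if e.survived]

    @property
    def dropped_ids(self) -> list[int]:
        return [t for t, e in self.truth.items() if not e.survived]

    @property
    def speck_ids(self) -> list[int]:
        return [p for p, e in self.preds.items() if e.origin == "speck"]

    @property
    def fragment_ids(self) -> list[int]:
        return [p for p, e in self.preds.items() if e.origin == "fragment"]

    @property
    def true_detection_ids(self) -> list[int]:
        return [p for p, e in self.preds.items() if e.origin == "true"]


@dataclass
class SyntheticField:
    field: LabelField
    instances: list[InstanceRecord]
    target_count: int

    @property
    def achieved_count(self) -> int:
        return len(self.instances)

    @property
    def shortfall(self) -> int:
        return self.target_count - self.achieved_count

    @property
    def centroids(self) -> np.ndarray:
        return np.array(
            [[r.centroid_x_um, r.centroid_y_um] for r in self.instances]
        ).reshape(-1, 2)


@dataclass
class Scenario:
    """A bundled deterministic fixture for end-to-end tests."""

    name: str
    truth: SyntheticField
    pred_field: LabelField
    pred_instances: list[InstanceRecord]
    roi_points: np.ndarray
    ledger: TruthLedger
    expected: dict


# ---------------------------------------------------------------------------
# Shape rasterizers (local boolean canvases)
# ---------------------------------------------------------------------------


def _disc_mask(area_px: int) -> np.ndarray:
    r = max(1.0, math.sqrt(area_px / math.pi))
    n = int(math.ceil(2 * r)) + 3
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= r * r


def _annulus_mask(area_px: int, rng: np.random.Generator) -> np.ndarray:
    f = rng.uniform(0.35, 0.6)
    R = math.sqrt(area_px / (math.pi * (1 - f * f)))
    r_in = f * R
    if R - r_in < 2.0 or r_in < 1.0:
        return _disc_mask(area_px)
    n = int(math.ceil(2 * R)) + 3
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    return (d2 <= R * R) & (d2 > r_in * r_in)


def _tube_mask(area_px: int, s_um: float, rng: np.random.Generator) -> np.ndarray:
    """Dilated quadratic Bézier polyline emulating a longitudinal vessel cut."""
    w_um = rng.uniform(1.5, 3.0)  # half-width in µm
    w_px = max(1, int(round(w_um / s_um)))
    length = area_px / (2.0 * w_px)
    if length < 2.0 * w_px or length > 200.0:
        # too stubby or too long to rasterize as a tube at this scale;
        # large vessels are rendered as discs instead
        return _disc_mask(area_px)
    # endpoints roughly `length` apart, control point bowed off-axis
    theta = rng.uniform(0, 2 * math.pi)
    bow = rng.uniform(-0.35, 0.35) * length
    p0 = np.array([0.0, 0.0])
    p2 = length * np.array([math.cos(theta), math.sin(theta)])
    mid = 0.5 * (p0 + p2)
    normal = np.array([-math.sin(theta), math.cos(theta)])
    p1 = mid + bow * normal
    t = np.linspace(0, 1, max(32, int(2 * length)))[:, None]
    curve = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    lo = curve.min(axis=0) - (w_px + 2)
    hi = curve.max(axis=0) + (w_px + 2)
    shape = np.ceil(hi - lo).astype(int) + 1
    canvas = np.zeros((shape[1], shape[0]), dtype=bool)  # rows = y
    pts = np.round(curve - lo).astype(int)
    canvas[pts[:, 1], pts[:, 0]] = True
    canvas = ndimage.binary_dilation(canvas, _disk_structure(w_px))
    return canvas


def _disk_structure(radius: int) -> np.ndarray:
    n = 2 * radius + 1
    yy, xx = np.mgrid[0:n, 0:n] - radius
    return yy * yy + xx * xx <= radius * radius


def _resize_mask(mask: np.ndarray, target_px: int) -> np.ndarray:
    """Grow or shrink a connected mask to an exact pixel count.

    Shrinking peels boundary pixels (largest interior distance kept);
    growing annexes the nearest background pixels.  The canvas is padded so
    growth never clips.
    """
    cur = int(mask.sum())
    if target_px <= 0:
        raise InputError("target pixel count must be positive")
    if cur == target_px:
        return mask
    if target_px > cur:
        grow_r = int(math.ceil(math.sqrt(target_px / math.pi))) + 2
        mask = np.pad(mask, grow_r)
        dist = ndimage.distance_transform_edt(~mask)
        order = np.argsort(dist.ravel(), kind="stable")
        flat = mask.ravel().copy()
        add = target_px - cur
        for idx in order:
            if add == 0:
                break
            if not flat[idx] and dist.ravel()[idx] > 0:
                flat[idx] = True
                add -= 1
        return flat.reshape(mask.shape)
    dist = ndimage.distance_transform_edt(mask)
    flat_idx = np.nonzero(mask.ravel())[0]
    keep_order = flat_idx[np.argsort(-dist.ravel()[flat_idx], kind="stable")]
    flat = np.zeros(mask.size, dtype=bool)
    flat[keep_order[:target_px]] = True
    return flat.reshape(mask.shape)


def _mask_centroid_um(mask: np.ndarray, origin: tuple[int, int], s: float) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    cy = (rows.mean() + origin[0] + 0.5) * s
    cx = (cols.mean() + origin[1] + 0.5) * s
    return cx, cy


# ---------------------------------------------------------------------------
# Field generation
# ---------------------------------------------------------------------------


def _sample_areas(spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    mu = math.log(spec.median_area_um2)
    areas = rng.lognormal(mean=mu, sigma=spec.sigma_log, size=spec.target_count)
    areas = np.maximum(areas, spec.min_area_um2)
    is_large = rng.random(spec.target_count) < spec.large_vessel_rate
    areas[is_large] = rng.uniform(*spec.large_area_range_um2, size=is_large.sum())
    return areas


def generate_field(spec: FieldSpec) -> SyntheticField:
    """Generate a non-overlapping labelled vessel field.

    Instances are placed largest-first by rejection sampling; each placement
    must keep a one-pixel clearance from every other instance (so connected-
    component labelling of the binary union cannot merge neighbours) and a
    centroid separation greater than min(equivalent radii) of the pair (so
    distinct true vessels are never inside each other's NMS gate at any
    supported factor).  If the requested density cannot be met the achieved
    count falls short and the shortfall is reported on the result.
    """
    s = spec.microns_per_pixel
    H = int(round(spec.height_um / s))
    W = int(round(spec.width_um / s))
    rng = np.random.default_rng(spec.seed)
    areas_um2 = _sample_areas(spec, rng)
    if areas_um2.sum() > 0.6 * spec.area_um2:
        raise InputError(
            f"requested instance area {areas_um2.sum():.0f} µm² exceeds 60% of "
            f"the field ({spec.area_um2:.0f} µm²); enlarge the field or lower "
            "target_count"
        )
    order = np.argsort(-areas_um2)
    labels = np.zeros((H, W), dtype=np.int32)
    occupied = np.zeros((H, W), dtype=bool)
    placed_centroids: list[tuple[float, float]] = []  # (x_um, y_um)
    placed_radii: list[float] = []
    next_label = 1
    shape_cut = np.cumsum(spec.shape_mix)
    for k in order:
        area_px = max(4, int(round(areas_um2[k] / (s * s))))
        u = rng.random()
        if u < shape_cut[0]:
            shape = _disc_mask(area_px)
        elif u < shape_cut[1]:
            shape = _annulus_mask(area_px, rng)
        else:
            shape = _tube_mask(area_px, s, rng)
        shape = shape[np.ix_(shape.any(axis=1), shape.any(axis=0))]  # tight crop
        h, w = shape.shape
        if h + 2 >= H or w + 2 >= W:
            continue  # cannot fit this instance at all
        # one-pixel halo keeps neighbours 8-disconnected after binarization
        halo = ndimage.binary_dilation(np.pad(shape, 1), _disk_structure(1))
        r_eq = math.sqrt(area_px * s * s / math.pi)
        rows, cols = np.nonzero(shape)
        local_cy, local_cx = rows.mean(), cols.mean()
        for _attempt in range(300):
            i0 = int(rng.integers(1, H - h - 1))
            j0 = int(rng.integers(1, W - w - 1))
            cx = (local_cx + j0 + 0.5) * s
            cy = (local_cy + i0 + 0.5) * s
            ok = True
            for (px, py), pr in zip(placed_centroids, placed_radii):
                if math.hypot(cx - px, cy - py) <= 1.001 * min(r_eq, pr):
                    ok = False
                    break
            if not ok:
                continue
            window = occupied[i0 - 1 : i0 + h + 1, j0 - 1 : j0 + w + 1]
            if (window & halo).any():
                continue
            labels[i0 : i0 + h, j0 : j0 + w][shape] = next_label
            occupied[i0 : i0 + h, j0 : j0 + w] |= shape
            placed_centroids.append((cx, cy))
            placed_radii.append(r_eq)
            next_label += 1
            break
    # relabel in raster order for contiguous ids 1..K
    field = LabelField(labels=_relabel_contiguous(labels), calib=spec.calib)
    instances = extract_instances(field)
    return SyntheticField(field=field, instances=instances, target_count=spec.target_count)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    return lut[labels]


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------


def _paste(
    target: np.ndarray, mask: np.ndarray, origin: tuple[int, int], label: int
) -> bool:
    """Paste a mask into the label raster, clipping at borders and skipping
    pixels already claimed by another predicted instance.  Returns False if
    nothing landed."""
    H, W = target.shape
    h, w = mask.shape
    i0, j0 = origin
    ti0, tj0 = max(i0, 0), max(j0, 0)
    ti1, tj1 = min(i0 + h, H), min(j0 + w, W)
    if ti0 >= ti1 or tj0 >= tj1:
        return False
    sub = mask[ti0 - i0 : ti1 - i0, tj0 - j0 : tj1 - j0]
    window = target[ti0:ti1, tj0:tj1]
    paint = sub & (window == 0)
    if not paint.any():
        return False
    window[paint] = label
    return True


def degrade(
    truth: SyntheticField, spec: DegradeSpec
) -> tuple[LabelField, TruthLedger]:
    """Derive a degraded "prediction" field from a ground-truth field.

    Applies, in order and per instance: dropout, fragmentation of large
    vessels, centroid jitter, and multiplicative area noise; then injects
    small false-positive specks inside the convex hull of the truth
    centroids.  Every event is written to the returned ledger.
    """
    s = truth.field.calib.microns_per_pixel
    rng = np.random.default_rng(spec.seed)
    labels = truth.field.labels
    pred = np.zeros_like(labels, dtype=np.int32)
    ledger = TruthLedger()
    next_label = 1
    objects = ndimage.find_objects(labels)
    by_id = {r.id: r for r in truth.instances}
    for tid in sorted(by_id):
        rec = by_id[tid]
        entry = TruthEntry(survived=True)
        ledger.truth[tid] = entry
        if rng.random() < spec.fn_rate:
            entry.survived = False
            continue
        sl = objects[tid - 1]
        mask = labels[sl] == tid
        origin = (sl[0].start, sl[1].start)
        fragment = (
            rec.area_um2 > spec.fragment_min_area_um2
            and rng.random() < spec.fragment_prob
        )
        if fragment:
            pieces = _fragment_mask(mask, rng, spec.fragment_count_range)
            for piece in pieces:
                if _paste(pred, piece, origin, next_label):
                    ledger.preds[next_label] = PredEntry("fragment", truth_id=tid)
                    entry.pred_ids.append(next_label)
                    next_label += 1
            continue
        out_mask = mask
        if spec.area_noise_cv > 0:
            factor = max(0.2, 1.0 + rng.normal(0.0, spec.area_noise_cv))
            target_px = max(1, int(round(mask.sum() * factor)))
            out_mask = _resize_mask(mask, target_px)
            if out_mask.shape != mask.shape:  # grown masks come back padded
                origin = (
                    origin[0] - (out_mask.shape[0] - mask.shape[0]) // 2,
                    origin[1] - (out_mask.shape[1] - mask.shape[1]) // 2,
                )
        if spec.centroid_jitter_sd_um > 0:
            di = int(round(rng.normal(0.0, spec.centroid_jitter_sd_um) / s))
            dj = int(round(rng.normal(0.0, spec.centroid_jitter_sd_um) / s))
            origin = (origin[0] + di, origin[1] + dj)
        if _paste(pred, out_mask, origin, next_label):
            ledger.preds[next_label] = PredEntry("true", truth_id=tid)
            entry.pred_ids.append(next_label)
            next_label += 1
        else:
            entry.survived = False
    next_label = _inject_specks(pred, truth, spec, rng, ledger, next_label)
    return LabelField(labels=pred, calib=truth.field.calib), ledger


def _fragment_mask(
    mask: np.ndarray, rng: np.random.Generator, count_range: tuple[int, int]
) -> list[np.ndarray]:
    """Split a mask into k nearest-seed pieces separated by eroded borders,
    mimicking the broken, discontinuous outlines seen on large vessels."""
    k = int(rng.integers(count_range[0], count_range[1] + 1))
    rows, cols = np.nonzero(mask)
    if len(rows) < 2 * k:
        return [mask]
    seed_idx = rng.choice(len(rows), size=k, replace=False)
    seeds = np.stack([rows[seed_idx], cols[seed_idx]], axis=1)
    pix = np.stack([rows, cols], axis=1)
    nearest = np.argmin(
        ((pix[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    pieces = []
    for i in range(k):
        piece = np.zeros_like(mask)
        sel = nearest == i
        piece[rows[sel], cols[sel]] = True
        eroded = ndimage.binary_erosion(piece)
        pieces.append(eroded if eroded.any() else piece)
    return pieces


def _inject_specks(
    pred: np.ndarray,
    truth: SyntheticField,
    spec: DegradeSpec,
    rng: np.random.Generator,
    ledger: TruthLedger,
    next_label: int,
) -> int:
    if spec.fp_speck_rate <= 0:
        return next_label
    s = truth.field.calib.microns_per_pixel
    H, W = pred.shape
    field_area_um2 = H * W * s * s
    n = int(rng.poisson(spec.fp_speck_rate * field_area_um2 / 1e4))
    hull = None
    if len(truth.instances) >= 3:
        geom = MultiPoint([tuple(c) for c in truth.centroids]).convex_hull
        if geom.geom_type == "Polygon":
            hull = geom
    for _ in range(n):
        area_um2 = rng.uniform(*spec.fp_speck_area_range_um2)
        target_px = max(1, int(area_um2 / (s * s)))  # floor keeps area < range top
        disc = _resize_mask(_disc_mask(max(target_px, 4)), target_px)
        disc = disc[np.ix_(disc.any(axis=1), disc.any(axis=0))]
        h, w = disc.shape
        for _attempt in range(100):
            i0 = int(rng.integers(0, max(1, H - h)))
            j0 = int(rng.integers(0, max(1, W - w)))
            cx = (j0 + w / 2.0) * s
            cy = (i0 + h / 2.0) * s
            if hull is not None and not hull.covers(Point(cx, cy)):
                continue
            window = pred[i0 : i0 + h, j0 : j0 + w]
            if (window[disc] != 0).any():
                continue
            window[disc] = next_label
            ledger.preds[next_label] = PredEntry("speck")
            next_label += 1
            break
    return next_label


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

SCENARIO_NAMES = (
    "clean",
    "speck-noise",
    "fragmented-large",
    "dropout",
    "low-prevalence",
)


def make_scenario(name: str, seed: int = 0) -> Scenario:
    """Build a named deterministic end-to-end fixture.

    ``clean`` — faithful prediction, expected F1 = 1 after the pipeline.
    ``speck-noise`` — sub-6-µm² false-positive specks only; the minimum-area
    filter must remove every one.
    ``fragmented-large`` — an elevated share of large vessels, all of which
    fragment into pieces.
    ``dropout`` — 20% of 500 instances dropped, nothing else degraded.
    ``low-prevalence`` — a sparse region of roughly 40 vessels, where
    per-count metrics are volatile and Wilson intervals widen.
    """
    if name == "clean":
        fspec = FieldSpec(target_count=150, seed=seed)
        dspec = DegradeSpec(seed=seed + 1)
    elif name == "speck-noise":
        fspec = FieldSpec(target_count=150, seed=seed)
        dspec = DegradeSpec(fp_speck_rate=1.2, seed=seed + 1)
    elif name == "fragmented-large":
        fspec = FieldSpec(
            target_count=120,
            large_vessel_rate=0.08,
            width_um=700.0,
            height_um=700.0,
            seed=seed,
        )
        dspec = DegradeSpec(fragment_prob=1.0, fragment_min_area_um2=1000.0, seed=seed + 1)
    elif name == "dropout":
        fspec = FieldSpec(
            target_count=500, width_um=900.0, height_um=900.0, seed=seed
        )
        dspec = DegradeSpec(fn_rate=0.2, seed=seed + 1)
    elif name == "low-prevalence":
        fspec = FieldSpec(target_count=40, width_um=400.0, height_um=400.0, seed=seed)
        dspec = DegradeSpec(seed=seed + 1)
    else:
        raise InputError(
            f"unknown scenario {name!r}; known: {', '.join(SCENARIO_NAMES)}"
        )
    truth = generate_field(fspec)
    pred_field, ledger = degrade(truth, dspec)
    pred_instances = extract_instances(pred_field)
    expected = {
        "gt_count": truth.achieved_count,
        "survivors": len(ledger.survivor_ids),
        "dropped": len(ledger.dropped_ids),
        "specks": len(ledger.speck_ids),
        "fragments": len(ledger.fragment_ids),
    }
    return Scenario(
        name=name,
        truth=truth,
        pred_field=pred_field,
        pred_instances=pred_instances,
        roi_points=truth.centroids,
        ledger=ledger,
        expected=expected,
    )
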