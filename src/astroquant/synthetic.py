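"""Synthetic fixtures with machine-readable ground truth.

Three generators cover every input the pipeline consumes:

* :func:`generate_image` — multi-channel fluorescence fields of disk-shaped
  cells with disk nuclei, curvilinear mitochondrial filaments with a
  controllable perinuclear placement fraction, marker-positive nucleus and
  GFAP-positive cytoplasm subsets, and punctate channels with controllable
  overlap.  Filaments are stamped as binary curves (no sub-pixel rendering)
  so the emitted ground-truth masks are exact pixel-count oracles.
* :func:`generate_flux_trace` — plateau-shaped Mito Stress OCR/ECAR traces
  whose true parameters are returned alongside; at zero noise the extractor
  round-trips them exactly.
* :func:`generate_expression` — gene x sample matrices with an additive
  group effect.

Every generator is bit-exactly reproducible under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .flux import INJECTION_ORDER, FluxTrace, MitoStressParams
from .imaging import ImageStack, LabelMask
from .mito import grow_perinuclear_zone

CHANNELS = ("DAPI", "MitoTracker", "H2AX", "GFAP", "TOMM20", "LC3B")


class CellPlacementError(RuntimeError):
    """The requested cells could not be packed into the field."""


class FilamentPlacementError(RuntimeError):
    """Non-touching filaments could not be packed into their region."""


def _check_fraction(name: str, value: float | None) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SyntheticImageSpec:
    """Parameters of a synthetic multi-channel field.

    ``perinuclear_fraction`` is the fraction of mitochondrial filament
    pixels placed inside the perinuclear zone (nucleus grown to 1.2x its
    area); ``None`` requests uniform placement, i.e. each cell's zone
    receives its area-proportional share.  ``min_separation_um`` > 0
    enforces non-touching filaments (needed for exact count oracles);
    set it to 0 to allow dense, touching networks.
    """

    image_size_px: tuple = (512, 512)
    pixel_size_um: float = 0.2
    n_cells: int = 5
    nucleus_radius_um: tuple = (4.0, 6.0)
    cell_radius_um: tuple = (12.0, 18.0)
    mito_per_cell: int = 10
    mito_length_um: tuple = (2.0, 4.0)
    mito_width_um: float = 0.5
    perinuclear_fraction: float | None = None
    frac_marker_pos_nuclei: float = 0.0
    frac_gfap_pos_cells: float = 0.0
    frac_gfap_among_pos: float | None = None
    puncta_per_cell: int = 0
    puncta_radius_um: float = 0.4
    puncta_overlap_fraction: float = 0.0
    min_separation_um: float = 1.0
    background_level: float = 10.0
    signal_level: float = 100.0
    noise_sd: float = 0.0
    n_z: int = 1
    seed: int = 0

    def __post_init__(self):
        for nm in (
            "frac_marker_pos_nuclei",
            "frac_gfap_pos_cells",
            "puncta_overlap_fraction",
        ):
            _check_fraction(nm, getattr(self, nm))
        _check_fraction("perinuclear_fraction", self.perinuclear_fraction)
        _check_fraction("frac_gfap_among_pos", self.frac_gfap_among_pos)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_cells < 0 or self.mito_per_cell < 0 or self.puncta_per_cell < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        for nm in ("nucleus_radius_um", "cell_radius_um", "mito_length_um"):
            lo, hi = getattr(self, nm)
            if not (0 < lo <= hi):
                raise ValueError(f"{nm} must be an increasing positive range")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticImageSpec":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("image_size_px", "nucleus_radius_um", "cell_radius_um",
                    "mito_length_um"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one synthetic field.

    ``table`` has one row per cell (ids matching the emitted label masks);
    ``masks`` holds the noiseless binary ground-truth masks whose pixel
    counts the table's area columns equal exactly.
    """

    table: pd.DataFrame
    masks: dict


def _disk_mask(shape, cy, cx, r) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _place_cells(rng, spec: SyntheticImageSpec):
    """Non-overlapping cell disk centers/radii via bounded rejection."""
    h, w = spec.image_size_px
    px = spec.pixel_size_um
    r_lo, r_hi = (r / px for r in spec.cell_radius_um)
    placed = []  # (cy, cx, r_cell, r_nuc)
    n_lo, n_hi = (r / px for r in spec.nucleus_radius_um)
    max_tries = 3000
    for i in range(spec.n_cells):
        for attempt in range(max_tries):
            r = rng.uniform(r_lo, r_hi)
            if 2 * (r + 2) >= min(h, w):
                continue
            cy = rng.uniform(r + 2, h - r - 2)
            cx = rng.uniform(r + 2, w - r - 2)
            if all(
                (cy - py) ** 2 + (cx - px_) ** 2 > (r + pr + 2) ** 2
                for py, px_, pr, _ in placed
            ):
                r_nuc = min(rng.uniform(n_lo, n_hi), 0.7 * r)
                placed.append((cy, cx, r, r_nuc))
                break
        else:
            raise CellPlacementError(
                f"could not place cell {i + 1}/{spec.n_cells} after "
                f"{max_tries} tries: {spec.n_cells} non-overlapping cells of "
                f"radius {spec.cell_radius_um} um do not fit in a "
                f"{h}x{w} px field at {px} um/px"
            )
    return placed


def _filament_path(rng, region, length_px):
    """Random-walk pixel path of ~length_px steps confined to ``region``.

    The walk reflects off the region boundary (resampling its heading) so a
    filament keeps its full length instead of being truncated, which keeps
    the realized per-region pixel allocation unbiased.
    """
    ys, xs = np.nonzero(region)
    if len(ys) == 0:
        return []
    k = rng.integers(len(ys))
    y, x = float(ys[k]), float(xs[k])
    theta = rng.uniform(0, 2 * np.pi)
    h, w = region.shape
    path = [(int(round(y)), int(round(x)))]
    for _ in range(length_px):
        for _attempt in range(36):
            ny, nx = y + np.sin(theta), x + np.cos(theta)
            iy, ix = int(round(ny)), int(round(nx))
            if 0 <= iy < h and 0 <= ix < w and region[iy, ix]:
                y, x = ny, nx
                path.append((iy, ix))
                break
            theta = rng.uniform(0, 2 * np.pi)
        else:
            break
        theta += rng.normal(0, 0.3)
    return path


def _stamp_path(shape, path, width_px):
    mask = np.zeros(shape, dtype=bool)
    if not path:
        return mask
    ys, xs = zip(*path)
    mask[list(ys), list(xs)] = True
    if width_px > 1:
        from scipy.ndimage import binary_dilation
        from skimage.morphology import disk

        mask = binary_dilation(mask, structure=disk(width_px // 2))
    return mask


def _scatter_filaments(rng, spec, cell_mask, zone_mask, n_total):
    """Place filaments in one cell; returns (mito_mask, n_placed, per-filament masks).

    The zone receives round(p * n_total) filaments where p is the requested
    perinuclear fraction (or the zone's area share of the cell for uniform
    placement); anchors are rejection-sampled inside/outside the zone and
    walks reflect at the region boundary.
    """
    px = spec.pixel_size_um
    width_px = max(int(round(spec.mito_width_um / px)), 1)
    sep_px = int(round(spec.min_separation_um / px))
    zone_in_cell = zone_mask & cell_mask
    outside = cell_mask & ~zone_mask
    p = (
        spec.perinuclear_fraction
        if spec.perinuclear_fraction is not None
        else zone_in_cell.sum() / max(cell_mask.sum(), 1)
    )
    n_zone = int(round(p * n_total))
    # confine the walk to the region eroded by the stamp radius so the
    # dilated filament stays inside its allocated region
    if width_px > 1:
        from scipy.ndimage import binary_erosion
        from skimage.morphology import disk as _disk

        se = _disk(width_px // 2)
        zone_walk = binary_erosion(zone_in_cell, structure=se)
        outside_walk = binary_erosion(outside, structure=se)
        if not zone_walk.any():
            zone_walk = zone_in_cell
        if not outside_walk.any():
            outside_walk = outside
    else:
        zone_walk, outside_walk = zone_in_cell, outside
    regions = [zone_walk] * n_zone + [outside_walk] * (n_total - n_zone)
    occupancy = np.zeros(spec.image_size_px, dtype=bool)
    filaments = []
    from scipy.ndimage import binary_dilation
    from skimage.morphology import disk

    for f_idx, region in enumerate(regions):
        if not region.any():
            region = cell_mask
        lo, hi = spec.mito_length_um
        length_px = max(int(round(rng.uniform(lo, hi) / px)), 1)
        for attempt in range(60):
            path = _filament_path(rng, region, length_px)
            stamp = _stamp_path(spec.image_size_px, path, width_px) & cell_mask
            if not stamp.any():
                continue
            if sep_px > 0:
                grown = binary_dilation(stamp, structure=disk(sep_px))
                if (grown & occupancy).any():
                    continue
            filaments.append(stamp)
            occupancy |= stamp
            break
        else:
            raise FilamentPlacementError(
                f"could not place filament {f_idx + 1}/{n_total} with "
                f"min_separation_um={spec.min_separation_um}; reduce "
                "mito_per_cell, the separation, or enlarge the cell"
            )
    return occupancy, filaments


def _place_puncta(rng, spec, cell_mask, nucleus_mask):
    """TOMM20/LC3B-style puncta with a controlled overlapping subset."""
    px = spec.pixel_size_um
    r = max(int(round(spec.puncta_radius_um / px)), 1)
    cytoplasm = cell_mask & ~nucleus_mask
    ys, xs = np.nonzero(cytoplasm)
    shape = cell_mask.shape
    a_mask = np.zeros(shape, dtype=bool)
    b_mask = np.zeros(shape, dtype=bool)
    if len(ys) == 0 or spec.puncta_per_cell == 0:
        return a_mask, b_mask
    centers_a = []
    for _ in range(spec.puncta_per_cell):
        for attempt in range(200):
            k = rng.integers(len(ys))
            cy, cx = int(ys[k]), int(xs[k])
            if all((cy - py) ** 2 + (cx - qx) ** 2 > (2 * r + 2) ** 2
                   for py, qx in centers_a):
                break
        centers_a.append((cy, cx))
        a_mask |= _disk_mask(shape, cy, cx, r) & cell_mask
    n_overlap = int(round(spec.puncta_overlap_fraction * len(centers_a)))
    for cy, cx in centers_a[:n_overlap]:  # concentric -> full overlap
        b_mask |= _disk_mask(shape, cy, cx, r) & cell_mask
    for _ in range(len(centers_a) - n_overlap):
        for attempt in range(200):
            k = rng.integers(len(ys))
            cy, cx = int(ys[k]), int(xs[k])
            if all((cy - py) ** 2 + (cx - qx) ** 2 > (2 * r + 2) ** 2
                   for py, qx in centers_a):
                b_mask |= _disk_mask(shape, cy, cx, r) & cell_mask
                break
    return a_mask, b_mask


def _render(rng, spec, signal_masks: dict):
    """Render channels: background + signal * mask, replicated over z, noised."""
    h, w = spec.image_size_px
    planes = []
    for name in CHANNELS:
        base = np.full((h, w), spec.background_level, dtype=np.float32)
        mask = signal_masks.get(name)
        if mask is not None:
            base[mask] = spec.background_level + spec.signal_level
        planes.append(base)
    stack = np.stack(planes)[:, None].repeat(spec.n_z, axis=1)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=stack.shape)
        stack = np.clip(stack + noise, 0.0, None).astype(np.float32)
    return ImageStack(
        pixels=stack.astype(np.float32),
        channel_names=CHANNELS,
        pixel_size_um=spec.pixel_size_um,
        z_step_um=1.2 if spec.n_z > 1 else 0.0,
    )


_TRUTH_COLUMNS = [
    "cell_id", "nucleus_id", "n_mito_true", "mito_area_px",
    "mito_perinuclear_px", "marker_pos", "gfap_pos", "puncta_overlap_px",
]


def generate_image(spec: SyntheticImageSpec):
    """Render a field; returns (ImageStack, nuclei, cells, SyntheticTruth)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size_px
    shape = (h, w)

    cells_lab = np.zeros(shape, dtype=np.int32)
    nuclei_lab = np.zeros(shape, dtype=np.int32)
    placements = _place_cells(rng, spec) if spec.n_cells > 0 else []
    nucleus_masks, cell_masks, zone_masks = {}, {}, {}
    for i, (cy, cx, r_cell, r_nuc) in enumerate(placements, start=1):
        cmask = _disk_mask(shape, cy, cx, r_cell)
        nmask = _disk_mask(shape, cy, cx, r_nuc)
        cells_lab[cmask] = i
        nuclei_lab[nmask] = i
        cell_masks[i] = cmask
        nucleus_masks[i] = nmask
        zone_masks[i] = grow_perinuclear_zone(nmask)

    ids = sorted(cell_masks)
    n = len(ids)

    # marker-positive nuclei and GFAP-positive cytoplasm assignments
    order = rng.permutation(ids) if n else np.array([], dtype=int)
    n_pos = int(round(spec.frac_marker_pos_nuclei * n))
    pos_ids = set(int(i) for i in order[:n_pos])
    neg_ids = [int(i) for i in order[n_pos:]]
    if spec.frac_gfap_among_pos is not None:
        n_gp = int(round(spec.frac_gfap_among_pos * len(pos_ids)))
        gfap_ids = set(sorted(pos_ids)[:0])  # built below deterministically
        pos_order = [int(i) for i in order[:n_pos]]
        gfap_ids = set(pos_order[:n_gp])
        n_gn = int(round(spec.frac_gfap_pos_cells * len(neg_ids)))
        gfap_ids |= set(neg_ids[:n_gn])
    else:
        n_g = int(round(spec.frac_gfap_pos_cells * n))
        gfap_ids = set(int(i) for i in rng.permutation(ids)[:n_g])

    mito_mask = np.zeros(shape, dtype=bool)
    puncta_a = np.zeros(shape, dtype=bool)
    puncta_b = np.zeros(shape, dtype=bool)
    gfap_mask = np.zeros(shape, dtype=bool)
    h2ax_mask = np.zeros(shape, dtype=bool)
    zone_all = np.zeros(shape, dtype=bool)
    rows = []
    for cid in ids:
        cmask, nmask, zmask = cell_masks[cid], nucleus_masks[cid], zone_masks[cid]
        zone_all |= zmask
        cell_mito = np.zeros(shape, dtype=bool)
        n_placed = 0
        if spec.mito_per_cell > 0:
            cell_mito, filaments = _scatter_filaments(
                rng, spec, cmask, zmask, spec.mito_per_cell
            )
            n_placed = len(filaments)
            mito_mask |= cell_mito
        a, b = _place_puncta(rng, spec, cmask, nmask)
        puncta_a |= a
        puncta_b |= b
        if cid in gfap_ids:
            gfap_mask |= cmask & ~nmask
        if cid in pos_ids:
            h2ax_mask |= nmask
        rows.append(
            {
                "cell_id": cid,
                "nucleus_id": cid,
                "n_mito_true": n_placed,
                "mito_area_px": int(cell_mito.sum()),
                "mito_perinuclear_px": int((cell_mito & zmask).sum()),
                "marker_pos": cid in pos_ids,
                "gfap_pos": cid in gfap_ids,
                "puncta_overlap_px": int((a & b).sum()),
            }
        )

    stack = _render(
        rng,
        spec,
        {
            "DAPI": nuclei_lab > 0,
            "MitoTracker": mito_mask,
            "H2AX": h2ax_mask,
            "GFAP": gfap_mask,
            "TOMM20": puncta_a,
            "LC3B": puncta_b,
        },
    )
    truth = SyntheticTruth(
        table=pd.DataFrame(rows, columns=_TRUTH_COLUMNS),
        masks={
            "mito": mito_mask,
            "puncta_a": puncta_a,
            "puncta_b": puncta_b,
            "gfap": gfap_mask,
            "marker_nuclei": h2ax_mask,
            "perinuclear_zone": zone_all,
        },
    )
    return (
        stack,
        LabelMask(nuclei_lab, kind="nuclei"),
        LabelMask(cells_lab, kind="cells"),
        truth,
    )


# ---------------------------------------------------------------------------
# flux traces


@dataclass
class SyntheticFluxSpec:
    """True Mito Stress parameters of a simulated well (rates per well).

    The OCR trace is a sequence of plateaus: basal + non_mito before
    oligomycin, proton_leak + non_mito after oligomycin, maximal + non_mito
    after FCCP, and non_mito after rotenone/antimycin.  ECAR sits at
    ecar_basal and rises by ecar_oligo_delta after oligomycin.  Consistency
    (basal = atp_linked + proton_leak, maximal >= basal, non_mito >= 0) is
    enforced at construction.
    """

    basal: float = 120.0
    maximal: float = 300.0
    atp_linked: float = 90.0
    proton_leak: float = 30.0
    non_mito: float = 40.0
    ecar_basal: float = 20.0
    ecar_oligo_delta: float = 15.0
    n_measurements_per_phase: int = 3
    measurement_interval_min: float = 6.5
    noise_sd: float = 0.0
    n_cells_per_well: int = 20000
    well_id: str = "well"
    seed: int = 0

    def __post_init__(self):
        if self.n_measurements_per_phase < 3:
            raise ValueError(
                "n_measurements_per_phase must be >= 3 (three-point phases)"
            )
        if self.non_mito < 0:
            raise ValueError("non_mito must be >= 0")
        if self.maximal < self.basal:
            raise ValueError("maximal must be >= basal")
        if abs(self.basal - (self.atp_linked + self.proton_leak)) > 1e-9:
            raise ValueError(
                "inconsistent parameters: basal must equal "
                "atp_linked + proton_leak"
            )
        if min(self.atp_linked, self.proton_leak) < 0:
            raise ValueError("atp_linked and proton_leak must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def true_params(self) -> MitoStressParams:
        basal = self.basal
        return MitoStressParams(
            basal=basal,
            maximal=self.maximal,
            spare=self.maximal - basal,
            spare_pct=100.0 * self.maximal / basal if basal > 0 else float("nan"),
            atp_linked=self.atp_linked,
            coupling_eff_pct=(
                100.0 * self.atp_linked / basal if basal > 0 else float("nan")
            ),
            non_mito=self.non_mito,
            proton_leak=self.proton_leak,
            ecar_basal=self.ecar_basal,
            ecar_oligo_delta=self.ecar_oligo_delta,
            well_id=self.well_id,
        )


def generate_flux_trace(spec: SyntheticFluxSpec):
    """Simulate one well; returns (FluxTrace, true MitoStressParams)."""
    rng = np.random.default_rng(spec.seed)
    npp, dt = spec.n_measurements_per_phase, spec.measurement_interval_min
    times = np.arange(4 * npp, dtype=float) * dt + dt
    injections = tuple(
        (name, times[npp * (k + 1) - 1] + dt / 2.0)
        for k, name in enumerate(INJECTION_ORDER)
    )
    ocr_levels = (
        spec.basal + spec.non_mito,
        spec.proton_leak + spec.non_mito,
        spec.maximal + spec.non_mito,
        spec.non_mito,
    )
    ecar_levels = (
        spec.ecar_basal,
        spec.ecar_basal + spec.ecar_oligo_delta,
        spec.ecar_basal + spec.ecar_oligo_delta,
        spec.ecar_basal + spec.ecar_oligo_delta,
    )
    ocr = np.repeat(ocr_levels, npp).astype(float)
    ecar = np.repeat(ecar_levels, npp).astype(float)
    if spec.noise_sd > 0:
        ocr = ocr + rng.normal(0, spec.noise_sd, size=ocr.shape)
        ecar = ecar + rng.normal(0, spec.noise_sd, size=ecar.shape)
    trace = FluxTrace(
        times=times,
        ocr=ocr,
        ecar=ecar,
        injections=injections,
        well_id=spec.well_id,
        n_cells=spec.n_cells_per_well,
    )
    return trace, spec.true_params()


# ---------------------------------------------------------------------------
# expression matrices


def generate_expression(
    ng: int,
    ns: int,
    group_effect: float | np.ndarray = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 10.0,
    n_reference: int | None = None,
    group_labels: tuple = ("CTRL", "AD"),
):
    """Gene x sample expression with an additive group effect.

    e_ij = baseline + effect_i * group_j + noise, where group_j is 0 for the
    first ``n_reference`` samples (default ns // 2 rounded up) and 1 for the
    rest.  Returns (ExpressionMatrix, sample -> group Series).
    """
    if ng < 1 or ns < 1:
        raise ValueError("ng and ns must be >= 1")
    rng = np.random.default_rng(seed)
    n_ref = n_reference if n_reference is not None else (ns + 1) // 2
    if not 0 <= n_ref <= ns:
        raise ValueError("n_reference must be between 0 and ns")
    effect = np.broadcast_to(np.asarray(group_effect, dtype=float), (ng,))
    group = np.array([0] * n_ref + [1] * (ns - n_ref))
    e = baseline + effect[:, None] * group[None, :]
    if noise_sd > 0:
        e = e + rng.normal(0, noise_sd, size=e.shape)
    genes = [f"gene{i + 1}" for i in range(ng)]
    samples = [f"sample{j + 1}" for j in range(ns)]
    frame = pd.DataFrame(e, index=genes, columns=samples)
    labels = pd.Series(
        [group_labels[g] for g in group], index=samples, name="group"
    )
    return ExpressionMatrix(frame), labels
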