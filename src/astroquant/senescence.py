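"""Halo-based senescent-cell counting and generic marker quantification.

The brain-section workflow: count DAPI nuclei, call marker-positive nuclei
(H2A.X, the DNA damage / senescence proxy) by their mean intensity, dilate
each positive nucleus by 1.89 um to create a halo, and call a positive
nucleus an astrocyte when the second channel (GFAP) lights up a sufficient
fraction of its halo.  Reported are total cells, percent positive, and the
percent of positives that are astrocytes.

``marker_quantify`` covers the generic immunofluorescence readouts used for
other markers: percent positive cells, positive area per cell, mean
intensity per cell, and soma area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, morphology

from .imaging import LabelMask


@dataclass(frozen=True)
class SenescenceResult:
    n_cells: int
    n_pos: int
    pct_pos: float
    n_pos_astro: int
    pct_pos_astro: float  # NaN when n_pos == 0


@dataclass(frozen=True)
class MarkerQuantResult:
    """Field-level aggregation of a generic marker quantification."""

    n_cells: int
    pct_positive_cells: float
    positive_area_per_cell_um2: float
    mean_intensity_per_cell: float
    mean_soma_area_um2: float
    per_cell: pd.DataFrame


def _per_label_means(channel: np.ndarray, labels: np.ndarray, ids) -> np.ndarray:
    return ndi.mean(channel, labels=labels, index=ids)


def _otsu_exact(values: np.ndarray) -> float:
    """Exact Otsu threshold of a small 1-D sample.

    Evaluates the between-class variance at every split of the sorted
    values instead of binning into a histogram (which can misplace the cut
    by a bin width when one class is small and far away), and returns the
    midpoint of the gap at the best split.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 2 or v[0] == v[-1]:
        return float(v[-1])
    csum = np.cumsum(v)
    total = csum[-1]
    best_sigma, best_thr = -np.inf, float(v[-1])
    for k in range(1, n):  # classes v[:k] and v[k:]
        if v[k] == v[k - 1]:
            continue
        w0, w1 = k, n - k
        mu0, mu1 = csum[k - 1] / w0, (total - csum[k - 1]) / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma = sigma
            best_thr = 0.5 * (v[k - 1] + v[k])
    return best_thr


def classify_positive_nuclei(
    marker_channel: np.ndarray,
    nuclei: LabelMask,
    threshold: float | None = None,
) -> set:
    """Ids of nuclei whose mean marker intensity exceeds the threshold.

    The default threshold is Otsu over the distribution of per-nucleus mean
    intensities (a fixed value can be supplied instead).  An empty mask, or
    a per-nucleus intensity distribution with no contrast, yields an empty
    set.
    """
    ids = nuclei.ids
    if len(ids) == 0:
        return set()
    means = np.asarray(
        _per_label_means(np.asarray(marker_channel, dtype=float), nuclei.labels, ids)
    )
    if threshold is None:
        if np.ptp(means) == 0:
            return set()
        threshold = _otsu_exact(means)
    return {int(i) for i, m in zip(ids, means) if m > threshold}


def halo_colocalize(
    pos_ids: set,
    nuclei: LabelMask,
    second_channel: np.ndarray,
    pixel_size_um: float,
    halo_um: float = 1.89,
    min_halo_frac: float = 0.05,
    second_threshold: float | None = None,
) -> set:
    """Positive nuclei whose dilation halo contains the second marker.

    Each positive nucleus is dilated by ``round(halo_um / pixel_size_um)``
    pixels; the halo is the dilation ring minus the nucleus.  A nucleus
    passes when at least ``min_halo_frac`` of its halo pixels exceed the
    second channel's threshold (Otsu of the whole channel by default).
    """
    if halo_um <= 0:
        raise ValueError("halo_um must be > 0")
    radius_px = int(round(halo_um / pixel_size_um))
    if radius_px < 1:
        raise ValueError(
            f"halo of {halo_um} um is below one pixel at {pixel_size_um} "
            "um/px; use a finer calibration"
        )
    if not pos_ids:
        return set()
    chan = np.asarray(second_channel, dtype=float)
    if chan.max() == chan.min():
        return set()
    thr = (
        second_threshold
        if second_threshold is not None
        else filters.threshold_otsu(chan)
    )
    above = chan > thr
    selem = morphology.disk(radius_px)
    out = set()
    for nid in sorted(pos_ids):
        nucleus = nuclei.labels == nid
        if not nucleus.any():
            continue
        # dilate within a cropped window for speed
        ys, xs = np.nonzero(nucleus)
        pad = radius_px + 1
        y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, nucleus.shape[0])
        x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, nucleus.shape[1])
        sub = nucleus[y0:y1, x0:x1]
        halo = ndi.binary_dilation(sub, structure=selem) & ~sub
        n_halo = int(halo.sum())
        if n_halo == 0:
            continue
        n_hit = int((above[y0:y1, x0:x1] & halo).sum())
        if n_hit >= min_halo_frac * n_halo:
            out.add(int(nid))
    return out


def senescence_summary(
    nuclei: LabelMask, pos_ids: set, astro_ids: set
) -> SenescenceResult:
    """Counts and percentages from the nucleus / positive / astrocyte sets."""
    all_ids = {int(i) for i in nuclei.ids}
    pos_ids = {int(i) for i in pos_ids}
    astro_ids = {int(i) for i in astro_ids}
    if not pos_ids <= all_ids:
        raise ValueError(
            f"positive ids not in mask: {sorted(pos_ids - all_ids)}"
        )
    if not astro_ids <= pos_ids:
        raise ValueError(
            f"astrocyte ids not among positives: {sorted(astro_ids - pos_ids)}"
        )
    n = len(all_ids)
    n_pos = len(pos_ids)
    n_astro = len(astro_ids)
    return SenescenceResult(
        n_cells=n,
        n_pos=n_pos,
        pct_pos=100.0 * n_pos / n if n else 0.0,
        n_pos_astro=n_astro,
        pct_pos_astro=100.0 * n_astro / n_pos if n_pos else float("nan"),
    )


def count_senescent(
    marker_channel: np.ndarray,
    second_channel: np.ndarray,
    nuclei: LabelMask,
    pixel_size_um: float,
    halo_um: float = 1.89,
    min_halo_frac: float = 0.05,
    marker_threshold: float | None = None,
    second_threshold: float | None = None,
) -> SenescenceResult:
    """Full field pipeline: classify positives, halo-colocalize, summarize."""
    pos = classify_positive_nuclei(marker_channel, nuclei, threshold=marker_threshold)
    astro = halo_colocalize(
        pos,
        nuclei,
        second_channel,
        pixel_size_um,
        halo_um=halo_um,
        min_halo_frac=min_halo_frac,
        second_threshold=second_threshold,
    )
    return senescence_summary(nuclei, pos, astro)


def marker_quantify(
    channel: np.ndarray,
    cells: LabelMask,
    pixel_size_um: float,
    threshold: float | None = None,
    positive_rule_threshold: float | None = None,
) -> MarkerQuantResult:
    """Generic per-cell marker quantification with field aggregation.

    ``threshold`` binarizes the channel for the positive-area measurement
    (Otsu default); a cell is called positive when its mean intensity
    exceeds ``positive_rule_threshold`` (Otsu over per-cell means by
    default).
    """
    chan = np.asarray(channel, dtype=float)
    ids = cells.ids
    if len(ids) == 0:
        return MarkerQuantResult(0, 0.0, 0.0, 0.0, 0.0, pd.DataFrame())
    flat = chan.max() == chan.min()
    if flat:
        binary = np.zeros(chan.shape, dtype=bool)
    else:
        thr = threshold if threshold is not None else filters.threshold_otsu(chan)
        binary = chan > thr
    means = np.asarray(_per_label_means(chan, cells.labels, ids))
    if positive_rule_threshold is None:
        if np.ptp(means) == 0:
            pos_calls = np.zeros(len(ids), dtype=bool)
        else:
            pos_calls = means > _otsu_exact(means)
    else:
        pos_calls = means > positive_rule_threshold
    px2 = pixel_size_um**2
    rows = []
    for i, cid in enumerate(ids):
        sel = cells.labels == cid
        rows.append(
            {
                "cell_id": int(cid),
                "soma_area_um2": float(sel.sum()) * px2,
                "positive_area_um2": float((binary & sel).sum()) * px2,
                "mean_intensity": float(means[i]),
                "positive": bool(pos_calls[i]),
            }
        )
    per_cell = pd.DataFrame(rows)
    return MarkerQuantResult(
        n_cells=len(ids),
        pct_positive_cells=100.0 * per_cell["positive"].mean(),
        positive_area_per_cell_um2=float(per_cell["positive_area_um2"].mean()),
        mean_intensity_per_cell=float(per_cell["mean_intensity"].mean()),
        mean_soma_area_um2=float(per_cell["soma_area_um2"].mean()),
        per_cell=per_cell,
    )
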