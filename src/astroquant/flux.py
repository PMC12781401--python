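"""Mito Stress Test parameterization of extracellular-flux traces.

An OCR/ECAR time series from the sequential oligomycin -> FCCP ->
rotenone/antimycin injection protocol is decomposed into the standard
respiration parameters (basal, ATP-linked, proton leak, maximal, spare,
non-mitochondrial) using the conventional min/max/last-point phase rules,
plus basal ECAR and the ECAR rise after oligomycin as glycolysis readouts.
Rates can be normalized per cell; the same per-cell normalization and a
blank-well subtraction helper serve plate assays such as glutamate uptake.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

INJECTION_ORDER = ("oligomycin", "FCCP", "rotenone_antimycin")
PHASES = ("baseline", "oligomycin", "FCCP", "rotenone_antimycin")


class MissingPhaseError(ValueError):
    """A phase of the Mito Stress protocol has no measurements."""


@dataclass(frozen=True)
class FluxTrace:
    """One well's OCR/ECAR time series with injection annotations.

    times are minutes and strictly increasing; ``injections`` is an ordered
    sequence of (name, time_min) with names following the canonical
    oligomycin -> FCCP -> rotenone/antimycin order.
    """

    times: np.ndarray
    ocr: np.ndarray
    ecar: np.ndarray
    injections: tuple
    well_id: str = "well"
    n_cells: int | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        ocr = np.asarray(self.ocr, dtype=float)
        ecar = np.asarray(self.ecar, dtype=float)
        if not (len(t) == len(ocr) == len(ecar)):
            raise ValueError("times, ocr and ecar must have equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        inj = tuple((str(n), float(tt)) for n, tt in self.injections)
        names = [n for n, _ in inj]
        if tuple(names) != INJECTION_ORDER:
            raise ValueError(
                f"injections must be {INJECTION_ORDER} in order, got {names}"
            )
        if any(b[1] <= a[1] for a, b in zip(inj, inj[1:])):
            raise ValueError("injection times must be increasing")
        if self.n_cells is not None and self.n_cells <= 0:
            raise ValueError("n_cells must be positive when given")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ocr", ocr)
        object.__setattr__(self, "ecar", ecar)
        object.__setattr__(self, "injections", inj)

    def phase_of(self, time_min: float) -> str:
        """Phase of a measurement: the most recent injection strictly before it."""
        phase = "baseline"
        for name, t_inj in self.injections:
            if time_min > t_inj:
                phase = name
        return phase

    def phase_slices(self) -> dict:
        phases = np.array([self.phase_of(t) for t in self.times])
        return {p: np.nonzero(phases == p)[0] for p in PHASES}


@dataclass(frozen=True)
class MitoStressParams:
    """Derived respiration/glycolysis parameters of one well.

    All rate fields share the units of the input trace (per cell when the
    trace carried a cell count and normalization was requested).
    """

    basal: float
    maximal: float
    spare: float
    spare_pct: float
    atp_linked: float
    coupling_eff_pct: float
    non_mito: float
    proton_leak: float
    ecar_basal: float
    ecar_oligo_delta: float
    well_id: str = "well"
    reliable: bool = True

    def as_dict(self) -> dict:
        return {
            "well_id": self.well_id,
            "basal": self.basal,
            "maximal": self.maximal,
            "spare": self.spare,
            "spare_pct": self.spare_pct,
            "atp_linked": self.atp_linked,
            "coupling_eff_pct": self.coupling_eff_pct,
            "non_mito": self.non_mito,
            "proton_leak": self.proton_leak,
            "ecar_basal": self.ecar_basal,
            "ecar_oligo_delta": self.ecar_oligo_delta,
            "reliable": self.reliable,
        }


def extract_mitostress(
    trace: FluxTrace,
    basal_rule: str = "last",
    per_cell: bool = True,
) -> MitoStressParams:
    """Decompose a Mito Stress trace into respiration parameters.

    Rules (the conventional ones for this protocol):

    * non-mitochondrial = minimum OCR after rotenone/antimycin
    * basal             = last pre-oligomycin OCR - non-mito
    * maximal           = maximum post-FCCP OCR - non-mito
    * ATP-linked        = last pre-oligomycin OCR - minimum post-oligomycin OCR
    * proton leak       = minimum post-oligomycin OCR - non-mito
    * spare             = maximal - basal; spare% = 100 * maximal / basal
    * coupling efficiency% = 100 * ATP-linked / basal
    * basal ECAR        = last pre-oligomycin ECAR
    * ECAR oligo delta  = maximum post-oligomycin ECAR - basal ECAR

    ``basal_rule`` may be ``"last"`` (default) or ``"mean"`` — the latter uses
    the mean of each phase instead of last/extreme points.
    """
    if basal_rule not in ("last", "mean"):
        raise ValueError("basal_rule must be 'last' or 'mean'")
    sl = trace.phase_slices()
    for p in PHASES:
        if len(sl[p]) == 0:
            raise MissingPhaseError(f"no measurements in phase {p!r}")

    ocr, ecar = trace.ocr, trace.ecar
    if basal_rule == "last":
        pre = ocr[sl["baseline"][-1]]
        oligo = ocr[sl["oligomycin"]].min()
        fccp = ocr[sl["FCCP"]].max()
        non_mito = ocr[sl["rotenone_antimycin"]].min()
        ecar_basal = ecar[sl["baseline"][-1]]
        ecar_oligo = ecar[sl["oligomycin"]].max()
    else:
        pre = ocr[sl["baseline"]].mean()
        oligo = ocr[sl["oligomycin"]].mean()
        fccp = ocr[sl["FCCP"]].mean()
        non_mito = ocr[sl["rotenone_antimycin"]].mean()
        ecar_basal = ecar[sl["baseline"]].mean()
        ecar_oligo = ecar[sl["oligomycin"]].mean()

    basal = pre - non_mito
    maximal = fccp - non_mito
    atp_linked = pre - oligo
    proton_leak = oligo - non_mito
    spare = maximal - basal

    reliable = True
    if basal <= 0:
        warnings.warn(
            f"well {trace.well_id}: basal respiration <= 0; parameters "
            "flagged unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
        reliable = False
    if spare < 0:
        warnings.warn(
            f"well {trace.well_id}: maximal < basal (no FCCP response); "
            "spare capacity reported negative",
            RuntimeWarning,
            stacklevel=2,
        )
    spare_pct = 100.0 * maximal / basal if basal > 0 else float("nan")
    coupling = 100.0 * atp_linked / basal if basal > 0 else float("nan")

    scale = 1.0
    if per_cell and trace.n_cells is not None:
        scale = 1.0 / trace.n_cells

    return MitoStressParams(
        basal=basal * scale,
        maximal=maximal * scale,
        spare=spare * scale,
        spare_pct=spare_pct,
        atp_linked=atp_linked * scale,
        coupling_eff_pct=coupling,
        non_mito=non_mito * scale,
        proton_leak=proton_leak * scale,
        ecar_basal=ecar_basal * scale,
        ecar_oligo_delta=(ecar_oligo - ecar_basal) * scale,
        well_id=trace.well_id,
        reliable=reliable,
    )


def normalize_per_cell(value: float, n_cells: int) -> float:
    """Rate per cell: value / n_cells (n_cells must be positive)."""
    if n_cells <= 0:
        raise ValueError(f"n_cells must be > 0, got {n_cells}")
    return value / n_cells


def blank_subtract(sample_value: float, blank_value: float) -> float:
    """Amount consumed relative to a cell-free blank well.

    Returns blank - sample, floored at 0 (with a warning) when the sample
    reads above the blank.
    """
    if sample_value < 0 or blank_value < 0:
        raise ValueError("concentrations must be non-negative")
    consumed = blank_value - sample_value
    if consumed < 0:
        warnings.warn(
            "sample concentration exceeds blank; consumption floored at 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return consumed


# ---------------------------------------------------------------------------
# CSV interface: long trace table + injections table + optional cell counts


def traces_from_frames(
    traces: pd.DataFrame,
    injections: pd.DataFrame,
    cell_counts: pd.DataFrame | None = None,
) -> list:
    """Build FluxTrace objects from tidy CSV-style tables.

    ``traces``: columns well, time_min, ocr, ecar.
    ``injections``: columns name, time_min (shared by all wells).
    ``cell_counts``: columns well, n_cells (optional).
    """
    inj = tuple(
        (str(r["name"]), float(r["time_min"]))
        for _, r in injections.sort_values("time_min").iterrows()
    )
    counts = {}
    if cell_counts is not None:
        counts = dict(
            zip(cell_counts["well"].astype(str), cell_counts["n_cells"].astype(int))
        )
    out = []
    for well, grp in traces.groupby("well", sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            FluxTrace(
                times=grp["time_min"].to_numpy(),
                ocr=grp["ocr"].to_numpy(),
                ecar=grp["ecar"].to_numpy(),
                injections=inj,
                well_id=str(well),
                n_cells=counts.get(str(well)),
            )
        )
    return out


def params_frame(params: Sequence[MitoStressParams]) -> pd.DataFrame:
    return pd.DataFrame([p.as_dict() for p in params])
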