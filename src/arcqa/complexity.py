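"""Per-arc plan-complexity features from MLC control-point geometry.

Eighteen features are computed per arc: two static parameters, six dynamic
parameters derived from a delivery-time model, and ten aperture-complexity
metrics.  Column names are exported in :data:`FEATURE_NAMES`.

Segment attribution
-------------------
Delivery happens between control points, so per-control-point quantities
are combined into per-segment values by averaging the two bounding control
points, weighted by the segment's MU.  Equivalently, control point *k*
carries weight ``(dMU[k-1] + dMU[k]) / 2``.

Time model
----------
Each segment's duration is the slowest of the three machine constraints:
``t = max(dMU/max_dose_rate, |dGantry|/max_gantry_speed,
max_leaf_travel/max_leaf_speed)``.  Dose rate, gantry speed, and leaf
speeds follow from the reconstructed durations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plan_model import ArcBeam, ControlPoint, MachineSpec

__all__ = [
    "FEATURE_NAMES",
    "MetricError",
    "ApertureShape",
    "SegmentDynamics",
    "aperture_geometry",
    "segment_time_model",
    "static_metrics",
    "dynamic_metrics",
    "gap_statistics",
    "mcs",
    "mean_tgi",
    "mi_total",
    "bi_bm",
    "edge_metric",
    "lt_al",
    "compute_arc_features",
    "extract_features",
]

#: Feature columns, in canonical order.
FEATURE_NAMES = [
    "Area", "MUOverDosePerFraction",
    "MeanMLCSpeed", "MLCSpeedModulation", "MeanRR", "RRModulation",
    "MeanGS", "GSModulation",
    "Q1 MLCGap", "Median MLCGap", "SAS10", "MeanTGI", "MCS", "MITotal",
    "BI", "BM", "EdgeMetric", "LT/AL",
]


class MetricError(ValueError):
    """A metric precondition failed for an arc (e.g. fully closed MLC)."""


@dataclass
class ApertureShape:
    """Geometry of one control point's MLC aperture."""

    area: float  # mm^2
    perimeter: float  # mm
    side_length: float  # mm of exposed leaf-side edges
    open_gaps: np.ndarray  # raw gaps of open pairs, mm
    open_mask: np.ndarray  # (60,) bool
    intervals: np.ndarray  # (60, 2) jaw-clipped [lo, hi] per pair


@dataclass
class SegmentDynamics:
    """Reconstructed delivery dynamics for each inter-control-point segment."""

    t: np.ndarray  # s, (n_seg,)
    delta_mu: np.ndarray  # MU
    delta_gantry: np.ndarray  # deg, signed
    dose_rate: np.ndarray  # MU/min
    gantry_speed: np.ndarray  # deg/s
    leaf_speed: np.ndarray  # cm/s, (n_seg, 120): bank A then bank B
    pair_mask: np.ndarray  # (n_seg, 60) bool: pair open at either bounding CP
    total_mu: float
    arc_length: float

    @property
    def leaf_mask(self) -> np.ndarray:
        """(n_seg, 120) mask: a pair's two leaves share its in-field state."""
        return np.concatenate([self.pair_mask, self.pair_mask], axis=1)


# ---------------------------------------------------------------------------
# Aperture geometry
# ---------------------------------------------------------------------------

@dataclass
class _ApertureData:
    """Vectorized per-CP aperture geometry for a whole arc."""

    open_mask: np.ndarray  # (n_cp, 60)
    gaps: np.ndarray  # raw gaps (n_cp, 60)
    lo: np.ndarray  # clipped interval lows (n_cp, 60)
    hi: np.ndarray  # clipped interval highs (n_cp, 60)
    eff_width: np.ndarray  # jaw-clipped widths (n_cp, 60)
    area: np.ndarray  # (n_cp,)
    perimeter: np.ndarray  # (n_cp,)
    side_length: np.ndarray  # (n_cp,)


def _aperture_data(A: np.ndarray, B: np.ndarray, jaws: np.ndarray,
                   machine: MachineSpec) -> _ApertureData:
    """Compute aperture geometry for stacked control points.

    A, B: (n_cp, 60) bank positions; jaws: (n_cp, 4) as (x1, x2, y1, y2).
    """
    bounds = machine.leaf_boundaries
    y_lo, y_hi = bounds[:-1], bounds[1:]
    x1, x2 = jaws[:, 0:1], jaws[:, 1:2]
    y1, y2 = jaws[:, 2:3], jaws[:, 3:4]

    eff_width = np.clip(np.minimum(y_hi, y2) - np.maximum(y_lo, y1), 0.0, None)
    gaps = B - A
    open_mask = (gaps > machine.min_gap) & (eff_width > 0)

    lo = np.clip(A, x1, x2)
    hi = np.clip(B, x1, x2)
    clipped = np.where(open_mask, np.clip(hi - lo, 0.0, None), 0.0)
    area = np.sum(clipped * eff_width * open_mask, axis=1)

    # Horizontal exposure at the 61 inter-pair boundaries: symmetric
    # difference of adjacent open intervals; full gap next to a closed pair.
    n_cp = A.shape[0]
    om = np.zeros((n_cp, 62), dtype=bool)
    om[:, 1:-1] = open_mask
    lo_p = np.zeros((n_cp, 62))
    hi_p = np.zeros((n_cp, 62))
    lo_p[:, 1:-1], hi_p[:, 1:-1] = lo, hi
    a, b = lo_p[:, :-1], hi_p[:, :-1]  # pair above boundary
    c, d = lo_p[:, 1:], hi_p[:, 1:]  # pair below boundary
    both = om[:, :-1] & om[:, 1:]
    overlap = np.clip(np.minimum(b, d) - np.maximum(a, c), 0.0, None)
    symdiff = (b - a) + (d - c) - 2.0 * overlap
    single = (b - a) * (om[:, :-1] & ~om[:, 1:]) + (d - c) * (~om[:, :-1] & om[:, 1:])
    exposure = np.where(both, symdiff, single)
    side_length = np.sum(exposure, axis=1)
    perimeter = side_length + 2.0 * np.sum(eff_width * open_mask, axis=1)
    return _ApertureData(open_mask=open_mask, gaps=gaps, lo=lo, hi=hi,
                         eff_width=eff_width, area=area, perimeter=perimeter,
                         side_length=side_length)


def _arc_aperture(arc: ArcBeam, machine: MachineSpec | None = None) -> _ApertureData:
    machine = machine or arc.machine
    jaws = np.array([cp.jaws for cp in arc.control_points])
    return _aperture_data(arc.bank_a_matrix, arc.bank_b_matrix, jaws, machine)


def aperture_geometry(cp: ControlPoint, machine: MachineSpec) -> ApertureShape:
    """Area, perimeter and exposed side length of one control point."""
    data = _aperture_data(cp.bank_a[None, :], cp.bank_b[None, :],
                          np.array([cp.jaws]), machine)
    mask = data.open_mask[0]
    return ApertureShape(area=float(data.area[0]),
                         perimeter=float(data.perimeter[0]),
                         side_length=float(data.side_length[0]),
                         open_gaps=data.gaps[0][mask],
                         open_mask=mask,
                         intervals=np.stack([data.lo[0], data.hi[0]], axis=1))


def _cp_weights(arc: ArcBeam) -> np.ndarray:
    """MU attribution per control point (sums to total MU)."""
    dmu = arc.delta_mu
    w = np.zeros(arc.n_cp)
    w[:-1] += dmu / 2.0
    w[1:] += dmu / 2.0
    return w


# ---------------------------------------------------------------------------
# Time model and dynamic metrics
# ---------------------------------------------------------------------------

def segment_time_model(arc: ArcBeam, machine: MachineSpec | None = None,
                       aperture: _ApertureData | None = None) -> SegmentDynamics:
    """Reconstruct per-segment durations, dose rates and speeds."""
    machine = machine or arc.machine
    A, B = arc.bank_a_matrix, arc.bank_b_matrix
    dmu = arc.delta_mu
    dg = arc.delta_gantry
    dA = np.diff(A, axis=0)
    dB = np.diff(B, axis=0)
    travel = np.concatenate([np.abs(dA), np.abs(dB)], axis=1)  # mm
    max_travel = travel.max(axis=1)

    t = np.maximum.reduce([
        dmu / machine.max_dose_rate * 60.0,
        np.abs(dg) / machine.max_gantry_speed,
        max_travel / (10.0 * machine.max_leaf_speed),
    ])
    if np.any(t <= 0):
        k = int(np.argmax(t <= 0))
        raise MetricError(f"{arc.arc_id}: zero-duration segment {k} "
                          "(no MU, gantry motion, or leaf motion)")
    dose_rate = dmu / t * 60.0
    gantry_speed = np.abs(dg) / t
    leaf_speed = travel / t[:, None] / 10.0  # cm/s

    ap = aperture if aperture is not None else _arc_aperture(arc, machine)
    pair_mask = ap.open_mask[:-1] | ap.open_mask[1:]
    return SegmentDynamics(t=t, delta_mu=dmu, delta_gantry=dg,
                           dose_rate=dose_rate, gantry_speed=gantry_speed,
                           leaf_speed=leaf_speed, pair_mask=pair_mask,
                           total_mu=arc.total_mu, arc_length=arc.arc_length)


def static_metrics(arc: ArcBeam, aperture: _ApertureData | None = None
                   ) -> tuple[float, float]:
    """(Area, MUOverDosePerFraction).

    Area is the MU-weighted mean control-point aperture area (mm^2);
    MUOverDosePerFraction is total MU over prescribed dose per fraction.
    """
    ap = aperture if aperture is not None else _arc_aperture(arc)
    w = _cp_weights(arc)
    area = float(np.sum(w * ap.area) / arc.total_mu)
    return area, arc.total_mu / arc.dose_per_fraction


def dynamic_metrics(dyn: SegmentDynamics, arc_length: float | None = None
                    ) -> tuple[float, float, float, float, float, float]:
    """The six delivery-dynamics features.

    Returns (MeanMLCSpeed, MLCSpeedModulation, MeanRR, RRModulation,
    MeanGS, GSModulation).  With a single segment all modulation terms are
    zero by convention.
    """
    arc_length = dyn.arc_length if arc_length is None else arc_length
    mask = dyn.leaf_mask
    v = dyn.leaf_speed
    mean_speed = float(v[mask].mean()) if mask.any() else 0.0

    n_seg = v.shape[0]
    if n_seg >= 2:
        pair_ok = mask[:-1] & mask[1:]
        dv = np.abs(np.diff(v, axis=0))
        travel = np.sum(v * dyn.t[:, None] * 10.0 * mask)  # mm
        speed_mod = float(np.sum(dv * pair_ok) / travel) if travel > 0 else 0.0
        rr_mod = float(np.sum(np.abs(np.diff(dyn.dose_rate))) / arc_length)
        gs_mod = float(np.sum(np.abs(np.diff(dyn.gantry_speed))) / arc_length)
    else:
        speed_mod = rr_mod = gs_mod = 0.0

    total_t = float(dyn.t.sum())
    mean_rr = float(dyn.delta_mu.sum() / total_t * 60.0)
    mean_gs = arc_length / total_t
    return mean_speed, speed_mod, mean_rr, rr_mod, mean_gs, gs_mod


# ---------------------------------------------------------------------------
# Aperture statistics
# ---------------------------------------------------------------------------

def gap_statistics(arc: ArcBeam, sas_threshold: float = 10.0,
                   mu_weighted: bool = False,
                   aperture: _ApertureData | None = None
                   ) -> tuple[float, float, float]:
    """(Q1 MLCGap, Median MLCGap, SAS) from the pooled open-gap distribution.

    Gaps from all control points are pooled unweighted by default; set
    ``mu_weighted`` to weight each control point's gaps by its MU share.
    """
    ap = aperture if aperture is not None else _arc_aperture(arc)
    if not ap.open_mask.any():
        raise MetricError(f"{arc.arc_id}: no open leaf pair in the arc")
    gaps = ap.gaps[ap.open_mask]
    if not mu_weighted:
        q1, med = np.percentile(gaps, [25.0, 50.0])
        sas = float(np.mean(gaps < sas_threshold))
        return float(q1), float(med), sas
    w_cp = _cp_weights(arc)
    weights = np.broadcast_to(w_cp[:, None], ap.gaps.shape)[ap.open_mask]
    order = np.argsort(gaps)
    g, w = gaps[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    q1, med = np.interp([0.25, 0.5], cw, g)
    sas = float(w[g < sas_threshold].sum() / w.sum())
    return float(q1), float(med), sas


def mcs(arc: ArcBeam, aperture: _ApertureData | None = None) -> float:
    """Modulation complexity score in (0, 1]; 1 for an unmodulated arc."""
    ap = aperture if aperture is not None else _arc_aperture(arc)
    machine = arc.machine
    clipped = np.where(ap.open_mask, np.clip(ap.hi - ap.lo, 0.0, None), 0.0)
    max_gap = clipped.max(axis=0)  # per-pair max open gap over the arc
    denom = float(np.sum(max_gap * machine.leaf_widths))
    aav = ap.area / denom if denom > 0 else np.ones(arc.n_cp)

    lsv = np.empty(arc.n_cp)
    A, B = arc.bank_a_matrix, arc.bank_b_matrix
    for k in range(arc.n_cp):
        idx = np.where(ap.open_mask[k])[0]
        lsv[k] = _lsv_cp(A[k, idx]) * _lsv_cp(B[k, idx])

    # product of per-segment means, each mean = avg of the bounding CPs
    dmu = arc.delta_mu
    seg = dmu / arc.total_mu * ((aav[:-1] + aav[1:]) / 2.0) * ((lsv[:-1] + lsv[1:]) / 2.0)
    return float(seg.sum())


def _lsv_cp(x: np.ndarray) -> float:
    """Leaf-sequence variability of one bank's in-field positions."""
    n = len(x)
    if n < 2:
        return 1.0
    pos_max = float(x.max() - x.min())
    if pos_max <= 0:
        return 1.0
    return float(np.sum(pos_max - np.abs(np.diff(x))) / ((n - 1) * pos_max))


def mean_tgi(arc: ArcBeam, aperture: _ApertureData | None = None) -> float:
    """MU-weighted mean tongue-and-groove index.

    Per control point: total tip stagger between consecutive open pairs on
    both banks, over twice the total open gap.  Control points without open
    pairs are skipped from the weighted mean.
    """
    ap = aperture if aperture is not None else _arc_aperture(arc)
    A, B = arc.bank_a_matrix, arc.bank_b_matrix
    both = ap.open_mask[:, :-1] & ap.open_mask[:, 1:]
    stagger = (np.abs(np.diff(A, axis=1)) + np.abs(np.diff(B, axis=1))) * both
    gap_sum = np.sum(ap.gaps * ap.open_mask, axis=1)
    valid = gap_sum > 0
    if not valid.any():
        raise MetricError(f"{arc.arc_id}: no open leaf pair in the arc")
    tgi = np.zeros(arc.n_cp)
    tgi[valid] = stagger.sum(axis=1)[valid] / (2.0 * gap_sum[valid])
    w = _cp_weights(arc)[valid]
    if w.sum() <= 0:
        return float(tgi[valid].mean())
    return float(np.sum(w * tgi[valid]) / w.sum())


def mi_total(dyn: SegmentDynamics, machine: MachineSpec,
             alpha: float = 1.0, beta: float = 1.0,
             f_max: float = 2.0, f_step: float = 0.01) -> float:
    """Total modulation index.

    ``z(f)`` is the weighted fraction of in-field (leaf, segment) speed
    observations exceeding ``f`` standard deviations, with segment weights
    amplified by dose-rate and gantry-speed changes; the index integrates
    ``z`` over ``f`` in [0, f_max] by the trapezoid rule.
    """
    mask = dyn.leaf_mask
    v = dyn.leaf_speed[mask]
    if v.size == 0:
        return 0.0
    sigma = float(np.std(v))
    if sigma == 0:
        return 0.0

    # each inter-segment rate change contributes half to both adjoining
    # segments, keeping the weighting symmetric under arc reversal
    w_seg = np.ones(len(dyn.t))
    if len(dyn.t) >= 2:
        bump = (alpha * np.abs(np.diff(dyn.dose_rate)) / machine.max_dose_rate
                + beta * np.abs(np.diff(dyn.gantry_speed)) / machine.max_gantry_speed)
        w_seg[:-1] += bump / 2.0
        w_seg[1:] += bump / 2.0
    w_obs = np.broadcast_to(w_seg[:, None], mask.shape)[mask]

    order = np.argsort(v)
    v_sorted = v[order]
    w_sorted = w_obs[order]
    cum = np.concatenate([[0.0], np.cumsum(w_sorted)])
    total = cum[-1]
    grid = np.arange(0.0, f_max + f_step / 2, f_step)
    # weight of observations with v > f * sigma (strict)
    idx = np.searchsorted(v_sorted, grid * sigma, side="right")
    z = (total - cum[idx]) / total
    return float(np.trapezoid(z, grid))


def bi_bm(arc: ArcBeam, aperture: _ApertureData | None = None
          ) -> tuple[float, float]:
    """(Beam irregularity, beam modulation).

    BI is the MU-weighted mean of ``perimeter^2 / (4 pi area)`` over control
    points with open aperture.  BM compares the MU-weighted mean aperture
    area with the area of the union of all apertures in the arc.
    """
    ap = aperture if aperture is not None else _arc_aperture(arc)
    valid = ap.area > 0
    if not valid.any():
        raise MetricError(f"{arc.arc_id}: zero-area arc")
    w = _cp_weights(arc)[valid]
    circ = ap.perimeter[valid] ** 2 / (4.0 * np.pi * ap.area[valid])
    bi = float(np.sum(w * circ) / w.sum()) if w.sum() > 0 else float(circ.mean())

    union_area = 0.0
    widths = arc.machine.leaf_widths
    for i in range(60):
        sel = ap.open_mask[:, i]
        if not sel.any():
            continue
        union_area += _union_length(ap.lo[sel, i], ap.hi[sel, i]) * widths[i]
    mean_area, _ = static_metrics(arc, aperture=ap)
    bm = 1.0 - mean_area / union_area
    return bi, float(bm)


def _union_length(lo: np.ndarray, hi: np.ndarray) -> float:
    """Total length of the union of 1D intervals."""
    order = np.argsort(lo)
    lo, hi = lo[order], hi[order]
    cummax = np.maximum.accumulate(hi)
    holes = np.clip(lo[1:] - cummax[:-1], 0.0, None)
    return float(cummax[-1] - lo[0] - holes.sum())


def edge_metric(arc: ArcBeam, aperture: _ApertureData | None = None) -> float:
    """MU-weighted mean ratio of exposed MLC side length to aperture area."""
    ap = aperture if aperture is not None else _arc_aperture(arc)
    valid = ap.area > 0
    if not valid.any():
        raise MetricError(f"{arc.arc_id}: zero-area arc")
    ratio = ap.side_length[valid] / ap.area[valid]
    w = _cp_weights(arc)[valid]
    if w.sum() <= 0:
        return float(ratio.mean())
    return float(np.sum(w * ratio) / w.sum())


def lt_al(arc: ArcBeam, aperture: _ApertureData | None = None) -> float:
    """Mean in-field leaf travel divided by arc length (mm/deg)."""
    ap = aperture if aperture is not None else _arc_aperture(arc)
    ever_open = ap.open_mask.any(axis=0)
    if not ever_open.any():
        return 0.0
    A, B = arc.bank_a_matrix, arc.bank_b_matrix
    travel_a = np.sum(np.abs(np.diff(A[:, ever_open], axis=0)), axis=0)
    travel_b = np.sum(np.abs(np.diff(B[:, ever_open], axis=0)), axis=0)
    mean_travel = float(np.concatenate([travel_a, travel_b]).mean())
    return mean_travel / arc.arc_length


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def compute_arc_features(arc: ArcBeam, machine: MachineSpec | None = None,
                         sas_threshold: float = 10.0,
                         alpha: float = 1.0, beta: float = 1.0,
                         mu_weighted_gaps: bool = False) -> dict[str, float]:
    """All 18 features for a single arc, keyed by :data:`FEATURE_NAMES`."""
    machine = machine or arc.machine
    ap = _arc_aperture(arc, machine)
    dyn = segment_time_model(arc, machine, aperture=ap)
    area, mu_per_gy = static_metrics(arc, aperture=ap)
    v, vmod, rr, rrmod, gs, gsmod = dynamic_metrics(dyn)
    q1, med, sas = gap_statistics(arc, sas_threshold, mu_weighted_gaps, aperture=ap)
    bi, bm = bi_bm(arc, aperture=ap)
    return {
        "Area": area,
        "MUOverDosePerFraction": mu_per_gy,
        "MeanMLCSpeed": v,
        "MLCSpeedModulation": vmod,
        "MeanRR": rr,
        "RRModulation": rrmod,
        "MeanGS": gs,
        "GSModulation": gsmod,
        "Q1 MLCGap": q1,
        "Median MLCGap": med,
        "SAS10": sas,
        "MeanTGI": mean_tgi(arc, aperture=ap),
        "MCS": mcs(arc, aperture=ap),
        "MITotal": mi_total(dyn, machine, alpha, beta),
        "BI": bi,
        "BM": bm,
        "EdgeMetric": edge_metric(arc, aperture=ap),
        "LT/AL": lt_al(arc, aperture=ap),
    }


def extract_features(arcs: list[ArcBeam], machine: MachineSpec | None = None,
                     qa_records=None, **metric_kwargs) -> "FeatureTable":
    """Build the per-arc feature table.

    Arcs whose metrics cannot be computed (e.g. fully closed MLC) are
    excluded from the table; the reasons are collected in
    ``FeatureTable.failures``.
    """
    rows = []
    failures: list[tuple[str, str]] = []
    for arc in arcs:
        try:
            feats = compute_arc_features(arc, machine, **metric_kwargs)
        except (MetricError, ValueError) as exc:
            failures.append((arc.arc_id, str(exc)))
            continue
        feats["arc_id"] = arc.arc_id
        feats["patient_id"] = arc.patient_id
        feats["treatment_date"] = arc.treatment_date
        rows.append(feats)
    frame = pd.DataFrame(rows, columns=["arc_id", "patient_id", "treatment_date",
                                        *FEATURE_NAMES])
    if qa_records is not None:
        gpr = pd.DataFrame({"arc_id": [q.arc_id for q in qa_records],
                            "measured_gpr": [q.measured_gpr for q in qa_records]})
        frame = frame.merge(gpr, on="arc_id", how="left")
    return FeatureTable(frame=frame, failures=failures)


@dataclass
class FeatureTable:
    """Feature matrix plus per-arc extraction failures."""

    frame: pd.DataFrame
    failures: list[tuple[str, str]]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, parse_dates=["treatment_date"])
        frame["treatment_date"] = frame["treatment_date"].dt.date
        return cls(frame=frame, failures=[])
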