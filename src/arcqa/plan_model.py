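"""Domain model for dynamic-arc treatment beams.

Provides the core value types (:class:`MachineSpec`, :class:`ControlPoint`,
:class:`ArcBeam`, :class:`QARecord`), RTPLAN-subset reading/writing built on
:mod:`arcqa._dicom`, and mechanical validation of arcs against machine
limits.

Conventions
-----------
* Leaf bank A is the left bank (more negative X); the gap of pair *i* is
  ``bank_b[i] - bank_a[i]`` and must be non-negative.  Positions are in mm
  projected to the isocenter plane.
* A leaf pair is *closed* when its gap is at most ``MachineSpec.min_gap``
  or the pair lies fully outside the Y-jaw aperture; closed pairs are
  excluded from aperture statistics downstream.
* Cumulative meterset weights are normalized to [0, 1] on read.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from . import _dicom
from ._dicom import Dataset

__all__ = [
    "MachineSpec",
    "ControlPoint",
    "ArcBeam",
    "QARecord",
    "Violation",
    "UnsupportedPlanError",
    "MalformedPlanError",
    "PlanValidationError",
    "hd120_leaf_widths",
    "read_rtplan",
    "write_rtplan",
    "validate_arc",
]


class UnsupportedPlanError(ValueError):
    """Plan content outside the supported dynamic-arc subset."""


class MalformedPlanError(ValueError):
    """Structurally invalid plan content (e.g. non-monotone meterset)."""


class PlanValidationError(ValueError):
    """Arc data violates its own type invariants."""


def hd120_leaf_widths() -> np.ndarray:
    """Per-pair leaf widths (mm) of an HD120-style MLC: 14x5, 32x2.5, 14x5."""
    return np.array([5.0] * 14 + [2.5] * 32 + [5.0] * 14)


@dataclass(frozen=True)
class MachineSpec:
    """Mechanical limits and MLC layout of the delivery machine.

    Defaults are Edge-like and configurable; leaf widths follow the HD120
    layout (220 mm total in Y).
    """

    leaf_widths: np.ndarray = field(default_factory=hd120_leaf_widths)
    max_dose_rate: float = 1400.0  # MU/min
    max_gantry_speed: float = 4.8  # deg/s
    max_leaf_speed: float = 2.5  # cm/s
    min_gap: float = 0.5  # mm
    field_extent: float = 200.0  # mm, |x| limit for leaf positions

    def __post_init__(self):
        w = np.asarray(self.leaf_widths, dtype=float)
        object.__setattr__(self, "leaf_widths", w)
        if w.ndim != 1 or len(w) != 60:
            raise PlanValidationError("leaf_widths must have 60 entries")
        if np.any(w <= 0):
            raise PlanValidationError("leaf widths must be positive")
        for name in ("max_dose_rate", "max_gantry_speed", "max_leaf_speed",
                     "min_gap", "field_extent"):
            if getattr(self, name) <= 0:
                raise PlanValidationError(f"{name} must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_widths)

    @property
    def leaf_boundaries(self) -> np.ndarray:
        """61 Y boundaries (mm), symmetric about 0."""
        edges = np.concatenate([[0.0], np.cumsum(self.leaf_widths)])
        return edges - edges[-1] / 2.0

    def to_json(self) -> dict:
        return {
            "leaf_widths": self.leaf_widths.tolist(),
            "max_dose_rate": self.max_dose_rate,
            "max_gantry_speed": self.max_gantry_speed,
            "max_leaf_speed": self.max_leaf_speed,
            "min_gap": self.min_gap,
            "field_extent": self.field_extent,
        }

    @classmethod
    def from_json(cls, d: dict) -> "MachineSpec":
        return cls(
            leaf_widths=np.asarray(d["leaf_widths"], dtype=float),
            max_dose_rate=d["max_dose_rate"],
            max_gantry_speed=d["max_gantry_speed"],
            max_leaf_speed=d["max_leaf_speed"],
            min_gap=d["min_gap"],
            field_extent=d["field_extent"],
        )


@dataclass
class ControlPoint:
    """Machine-state snapshot along an arc."""

    index: int
    cum_weight: float  # cumulative meterset weight, [0, 1]
    gantry_angle: float  # deg, [0, 360)
    bank_a: np.ndarray  # 60 left-bank positions, mm
    bank_b: np.ndarray  # 60 right-bank positions, mm
    jaws: tuple[float, float, float, float] = (-110.0, 110.0, -110.0, 110.0)

    def __post_init__(self):
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        self.bank_b = np.asarray(self.bank_b, dtype=float)
        if self.bank_a.shape != (60,) or self.bank_b.shape != (60,):
            raise PlanValidationError("leaf banks must have 60 positions")

    @property
    def gaps(self) -> np.ndarray:
        return self.bank_b - self.bank_a


@dataclass
class ArcBeam:
    """A single dynamic arc: the unit of QA prediction."""

    arc_id: str
    patient_id: str
    treatment_date: dt.date
    control_points: list[ControlPoint]
    total_mu: float
    dose_per_fraction: float  # Gy
    machine: MachineSpec = field(default_factory=MachineSpec)

    def __post_init__(self):
        if len(self.control_points) < 2:
            raise PlanValidationError(f"{self.arc_id}: needs >= 2 control points")
        if self.total_mu <= 0:
            raise PlanValidationError(f"{self.arc_id}: total_mu must be > 0")
        if self.dose_per_fraction <= 0:
            raise PlanValidationError(f"{self.arc_id}: dose_per_fraction must be > 0")

    # -- array views -----------------------------------------------------
    @property
    def n_cp(self) -> int:
        return len(self.control_points)

    @property
    def cum_weights(self) -> np.ndarray:
        return np.array([cp.cum_weight for cp in self.control_points])

    @property
    def gantry_angles(self) -> np.ndarray:
        return np.array([cp.gantry_angle for cp in self.control_points])

    @property
    def bank_a_matrix(self) -> np.ndarray:
        return np.stack([cp.bank_a for cp in self.control_points])

    @property
    def bank_b_matrix(self) -> np.ndarray:
        return np.stack([cp.bank_b for cp in self.control_points])

    @property
    def delta_mu(self) -> np.ndarray:
        """Per-segment MU (length n_cp - 1)."""
        return np.diff(self.cum_weights) * self.total_mu

    @property
    def delta_gantry(self) -> np.ndarray:
        """Signed shortest per-segment gantry rotation, deg."""
        d = np.diff(self.gantry_angles)
        return (d + 180.0) % 360.0 - 180.0

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.abs(self.delta_gantry)))


@dataclass
class QARecord:
    """Measured QA outcome for one arc."""

    arc_id: str
    measured_gpr: float  # percent
    action_limit: float = 95.0  # percent

    def __post_init__(self):
        if not 0.0 <= self.measured_gpr <= 100.0:
            raise PlanValidationError(
                f"{self.arc_id}: measured_gpr {self.measured_gpr} outside [0, 100]")

    @property
    def pass_label(self) -> bool:
        return self.measured_gpr >= self.action_limit


@dataclass(frozen=True)
class Violation:
    """A single mechanical-validity finding; data, not an exception."""

    kind: str
    message: str
    cp_index: int | None = None
    pair: int | None = None


def validate_arc(arc: ArcBeam, machine: MachineSpec | None = None) -> list[Violation]:
    """Check an arc against machine limits.

    Returns an empty list iff: cumulative weights are monotone with
    endpoints 0 and 1; no leaf pair is crossed; every gap is either fully
    closed or at least ``min_gap``; positions lie within ``field_extent``;
    and implied leaf speeds stay within ``max_leaf_speed`` when segment
    durations are set by the MU and gantry constraints alone.
    """
    machine = machine or arc.machine
    out: list[Violation] = []
    cw = arc.cum_weights
    if abs(cw[0]) > 1e-9 or abs(cw[-1] - 1.0) > 1e-9:
        out.append(Violation("meterset", "cumulative weights must span [0, 1]"))
    if np.any(np.diff(cw) < -1e-12):
        k = int(np.argmax(np.diff(cw) < -1e-12))
        out.append(Violation("meterset", "non-monotone cumulative weight",
                             cp_index=k + 1))

    A, B = arc.bank_a_matrix, arc.bank_b_matrix
    gaps = B - A
    for k, i in zip(*np.where(gaps < -1e-9)):
        out.append(Violation("crossed_pair",
                             f"bank B below bank A (gap {gaps[k, i]:.2f} mm)",
                             cp_index=int(k), pair=int(i)))
    partial = (gaps > 1e-6) & (gaps < machine.min_gap - 1e-9)
    for k, i in zip(*np.where(partial)):
        out.append(Violation("min_gap",
                             f"open gap {gaps[k, i]:.2f} mm below minimum "
                             f"{machine.min_gap} mm",
                             cp_index=int(k), pair=int(i)))
    ext = machine.field_extent
    for k, i in zip(*np.where((np.abs(A) > ext + 1e-9) | (np.abs(B) > ext + 1e-9))):
        out.append(Violation("extent", "leaf position outside field extent",
                             cp_index=int(k), pair=int(i)))

    # Implied leaf speed: durations from MU / gantry constraints only, so an
    # arc that would force the machine to wait for the leaves is flagged.
    dmu = arc.delta_mu
    dg = np.abs(arc.delta_gantry)
    t_mg = np.maximum(dmu / machine.max_dose_rate * 60.0, dg / machine.max_gantry_speed)
    travel = np.maximum(np.abs(np.diff(A, axis=0)), np.abs(np.diff(B, axis=0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = travel / t_mg[:, None] / 10.0  # cm/s
    bad = speed > machine.max_leaf_speed + 1e-9
    for k, i in zip(*np.where(bad)):
        out.append(Violation("leaf_speed",
                             f"implied leaf speed {speed[k, i]:.2f} cm/s exceeds "
                             f"{machine.max_leaf_speed} cm/s",
                             cp_index=int(k), pair=int(i)))
    return out


# ---------------------------------------------------------------------------
# RTPLAN I/O
# ---------------------------------------------------------------------------

_T_PATIENT_ID = (0x0010, 0x0020)
_T_PLAN_DATE = (0x300A, 0x0006)
_T_PLAN_LABEL = (0x300A, 0x0002)
_T_FRACTION_GROUP_SEQ = (0x300A, 0x0070)
_T_NUM_FRACTIONS = (0x300A, 0x0078)
_T_REF_BEAM_SEQ = (0x300C, 0x0004)
_T_REF_BEAM_NUMBER = (0x300C, 0x0006)
_T_BEAM_DOSE = (0x300A, 0x0084)
_T_BEAM_METERSET = (0x300A, 0x0086)
_T_BEAM_SEQ = (0x300A, 0x00B0)
_T_BLD_SEQ = (0x300A, 0x00B6)
_T_BLD_TYPE = (0x300A, 0x00B8)
_T_LEAF_BOUNDARIES = (0x300A, 0x00BE)
_T_BEAM_NUMBER = (0x300A, 0x00C0)
_T_BEAM_NAME = (0x300A, 0x00C2)
_T_BEAM_DESCRIPTION = (0x300A, 0x00C3)
_T_BEAM_TYPE = (0x300A, 0x00C4)
_T_DELIVERY_TYPE = (0x300A, 0x00CE)
_T_FINAL_CUM_WEIGHT = (0x300A, 0x010E)
_T_NUM_CP = (0x300A, 0x0110)
_T_CP_SEQ = (0x300A, 0x0111)
_T_CP_INDEX = (0x300A, 0x0112)
_T_GANTRY_ANGLE = (0x300A, 0x011E)
_T_BLD_POS_SEQ = (0x300A, 0x011A)
_T_LEAF_JAW_POS = (0x300A, 0x011C)
_T_CUM_WEIGHT = (0x300A, 0x0134)


def _fmt_ds(x: float) -> str:
    """Format a float as a DICOM DS string (<= 16 chars)."""
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def write_rtplan(arcs: list[ArcBeam], path) -> None:
    """Write arcs as a minimal standard-conformant RTPLAN file.

    The file is readable by :func:`read_rtplan` and lossless for every
    ``ArcBeam`` field.  Per-arc treatment dates are carried in the beam
    description (ISO format) since DICOM has no per-beam date attribute.
    """
    if not arcs:
        raise PlanValidationError("cannot write an empty arc list")
    for arc in arcs:
        cw = arc.cum_weights
        if np.any(np.diff(cw) < -1e-12):
            raise PlanValidationError(f"{arc.arc_id}: non-monotone meterset weight")
        if np.any(arc.bank_b_matrix - arc.bank_a_matrix < -1e-9):
            raise PlanValidationError(f"{arc.arc_id}: crossed leaf pair")

    machine = arcs[0].machine
    ds = Dataset()
    ds.set((0x0008, 0x0016), "UI", _dicom.SOP_CLASS_RTPLAN)
    uid = _dicom.IMPLEMENTATION_UID + f".{abs(hash(arcs[0].arc_id)) % 10**8}"
    ds.set((0x0008, 0x0018), "UI", uid)
    ds.set((0x0008, 0x0060), "CS", "RTPLAN")
    ds.set(_T_PATIENT_ID, "LO", arcs[0].patient_id)
    ds.set(_T_PLAN_LABEL, "SH", "arcqa")
    ds.set(_T_PLAN_DATE, "DA", arcs[0].treatment_date.strftime("%Y%m%d"))

    ref_items = []
    beam_items = []
    for n, arc in enumerate(arcs, start=1):
        ref = Dataset()
        ref.set(_T_REF_BEAM_NUMBER, "IS", str(n))
        ref.set(_T_BEAM_DOSE, "DS", _fmt_ds(arc.dose_per_fraction))
        ref.set(_T_BEAM_METERSET, "DS", _fmt_ds(arc.total_mu))
        ref_items.append(ref)
        beam_items.append(_encode_beam(arc, n, machine))

    fg = Dataset()
    fg.set(_T_NUM_FRACTIONS, "IS", "1")
    fg.set(_T_REF_BEAM_SEQ, "SQ", ref_items)
    ds.set(_T_FRACTION_GROUP_SEQ, "SQ", [fg])
    ds.set(_T_BEAM_SEQ, "SQ", beam_items)
    _dicom.write_file(path, ds, uid)


def _encode_beam(arc: ArcBeam, number: int, machine: MachineSpec) -> Dataset:
    beam = Dataset()
    beam.set(_T_BEAM_NUMBER, "IS", str(number))
    beam.set(_T_BEAM_NAME, "LO", arc.arc_id)
    beam.set(_T_BEAM_DESCRIPTION, "ST", arc.treatment_date.isoformat())
    beam.set(_T_BEAM_TYPE, "CS", "DYNAMIC")
    beam.set(_T_DELIVERY_TYPE, "CS", "TREATMENT")
    beam.set(_T_FINAL_CUM_WEIGHT, "DS", "1")
    beam.set(_T_NUM_CP, "IS", str(arc.n_cp))
    bld = Dataset()
    bld.set(_T_BLD_TYPE, "CS", "MLCX")
    bld.set(_T_LEAF_BOUNDARIES, "DS",
            [_fmt_ds(b) for b in machine.leaf_boundaries])
    beam.set(_T_BLD_SEQ, "SQ", [bld])

    cps = []
    for cp in arc.control_points:
        item = Dataset()
        item.set(_T_CP_INDEX, "IS", str(cp.index))
        item.set(_T_CUM_WEIGHT, "DS", _fmt_ds(cp.cum_weight))
        item.set(_T_GANTRY_ANGLE, "DS", _fmt_ds(cp.gantry_angle % 360.0))
        jaw_x = Dataset()
        jaw_x.set(_T_BLD_TYPE, "CS", "ASYMX")
        jaw_x.set(_T_LEAF_JAW_POS, "DS", [_fmt_ds(cp.jaws[0]), _fmt_ds(cp.jaws[1])])
        jaw_y = Dataset()
        jaw_y.set(_T_BLD_TYPE, "CS", "ASYMY")
        jaw_y.set(_T_LEAF_JAW_POS, "DS", [_fmt_ds(cp.jaws[2]), _fmt_ds(cp.jaws[3])])
        mlc = Dataset()
        mlc.set(_T_BLD_TYPE, "CS", "MLCX")
        mlc.set(_T_LEAF_JAW_POS, "DS",
                [_fmt_ds(x) for x in np.concatenate([cp.bank_a, cp.bank_b])])
        item.set(_T_BLD_POS_SEQ, "SQ", [jaw_x, jaw_y, mlc])
        cps.append(item)
    beam.set(_T_CP_SEQ, "SQ", cps)
    return beam


def read_rtplan(path, machine: MachineSpec | None = None) -> list[ArcBeam]:
    """Read an RTPLAN file into one :class:`ArcBeam` per treatment arc.

    Setup/imaging beams (non-TREATMENT delivery type, static beams, or
    beams without meterset) are skipped.  Cumulative meterset weights are
    normalized to [0, 1].
    """
    machine = machine or MachineSpec()
    ds = _dicom.read_file(path)
    patient_id = ds.get_str(_T_PATIENT_ID, "") or ""
    plan_date = _parse_date(ds.get_str(_T_PLAN_DATE))

    metersets: dict[int, tuple[float, float]] = {}
    for fg in ds.get(_T_FRACTION_GROUP_SEQ, []) or []:
        for ref in fg.get(_T_REF_BEAM_SEQ, []) or []:
            n = ref.get_int(_T_REF_BEAM_NUMBER)
            metersets[n] = (ref.get_float(_T_BEAM_METERSET, 0.0),
                            ref.get_float(_T_BEAM_DOSE, 0.0))

    arcs: list[ArcBeam] = []
    for beam in ds.get(_T_BEAM_SEQ, []) or []:
        number = beam.get_int(_T_BEAM_NUMBER, 0)
        name = beam.get_str(_T_BEAM_NAME, f"beam{number}")
        delivery = beam.get_str(_T_DELIVERY_TYPE, "TREATMENT")
        beam_type = beam.get_str(_T_BEAM_TYPE, "DYNAMIC")
        mu, dose = metersets.get(number, (0.0, 0.0))
        if delivery != "TREATMENT" or beam_type != "DYNAMIC" or mu <= 0:
            continue  # setup / imaging / static beam
        arcs.append(_decode_beam(beam, name, patient_id, plan_date, mu, dose, machine))
    return arcs


def _parse_date(text: str | None) -> dt.date:
    if not text:
        return dt.date(2000, 1, 1)
    text = text.strip()
    if "-" in text:
        return dt.date.fromisoformat(text)
    return dt.date(int(text[:4]), int(text[4:6]), int(text[6:8]))


def _decode_beam(beam: Dataset, name: str, patient_id: str, plan_date: dt.date,
                 mu: float, dose: float, machine: MachineSpec) -> ArcBeam:
    cp_items = beam.get(_T_CP_SEQ)
    if not cp_items:
        raise UnsupportedPlanError(f"beam {name!r}: no control point sequence")
    desc = beam.get_str(_T_BEAM_DESCRIPTION)
    date = plan_date
    if desc:
        try:
            date = dt.date.fromisoformat(desc)
        except ValueError:
            pass

    final_cw = beam.get_float(_T_FINAL_CUM_WEIGHT, 1.0) or 1.0
    control_points: list[ControlPoint] = []
    bank_a = bank_b = None
    jaws = (-110.0, 110.0, -110.0, 110.0)
    gantry = 0.0
    prev_cw = -np.inf
    for idx, item in enumerate(cp_items):
        cw = item.get_float(_T_CUM_WEIGHT)
        if cw is None:
            raise MalformedPlanError(f"beam {name!r}: control point {idx} "
                                     "missing cumulative meterset weight")
        cw /= final_cw
        if cw < prev_cw - 1e-9:
            raise MalformedPlanError(f"beam {name!r}: non-monotone cumulative "
                                     f"meterset weight at control point {idx}")
        prev_cw = cw
        g = item.get_float(_T_GANTRY_ANGLE)
        if g is not None:
            gantry = g
        for bld in item.get(_T_BLD_POS_SEQ, []) or []:
            kind = bld.get_str(_T_BLD_TYPE)
            pos = bld.get_floats(_T_LEAF_JAW_POS)
            if kind == "MLCX":
                if len(pos) != 120:
                    raise UnsupportedPlanError(
                        f"beam {name!r}: expected 120 MLCX positions, got {len(pos)}")
                bank_a = np.array(pos[:60])
                bank_b = np.array(pos[60:])
            elif kind == "ASYMX":
                jaws = (pos[0], pos[1], jaws[2], jaws[3])
            elif kind == "ASYMY":
                jaws = (jaws[0], jaws[1], pos[0], pos[1])
        if bank_a is None:
            raise UnsupportedPlanError(f"beam {name!r}: no MLC positions by "
                                       f"control point {idx}")
        control_points.append(ControlPoint(index=idx, cum_weight=cw,
                                           gantry_angle=gantry,
                                           bank_a=bank_a.copy(),
                                           bank_b=bank_b.copy(), jaws=jaws))
    # normalize endpoints exactly
    if control_points:
        control_points[0] = replace(control_points[0],
                                    cum_weight=max(control_points[0].cum_weight, 0.0))
        control_points[-1] = replace(control_points[-1], cum_weight=1.0)
    return ArcBeam(arc_id=name, patient_id=patient_id, treatment_date=date,
                   control_points=control_points, total_mu=mu,
                   dose_per_fraction=dose if dose > 0 else 1.0, machine=machine)
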