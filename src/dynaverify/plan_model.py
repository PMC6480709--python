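"""TPS-style plan data model: control points, beams, DICOM RTPLAN I/O,
and control-point densification by linear interpolation.

A deliverable VMAT plan is an ordered list of control points; each carries
the cumulative meterset weight (fraction of the beam's monitor units in
[0, 1]), the gantry angle, the jaw openings and the MLC aperture. The
"segment" between two consecutive control points is the transition interval
the dynalog's segment counter indexes.

Leaf/jaw positions use the opening-direction sign convention of
:mod:`dynaverify.dynalog_io`: a leaf pair's aperture spans
``[-pos_B, +pos_A]`` on the leaf-travel axis. On DICOM export this maps to
the standard MLCX convention (bank 1 edges = ``-pos_B``, bank 2 edges =
``+pos_A``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .exceptions import DynaverifyError, UnsupportedPlanError

#: Beam provenance labels.
PROVENANCE = (
    "original",
    "reconstructed_expected",
    "reconstructed_actual",
    "densified",
    "magnified",
)


@dataclass
class ControlPoint:
    cumulative_weight: float          # fraction of beam meterset, [0, 1]
    gantry_deg: float
    jaws_cm: np.ndarray               # (4,) x-neg, x-pos, y-neg, y-pos openings
    mlc_cm: np.ndarray                # (2 * leaf_count_per_bank,) bank A then B

    def __eq__(self, other) -> bool:
        if not isinstance(other, ControlPoint):
            return NotImplemented
        return (
            self.cumulative_weight == other.cumulative_weight
            and self.gantry_deg == other.gantry_deg
            and np.array_equal(self.jaws_cm, other.jaws_cm)
            and np.array_equal(self.mlc_cm, other.mlc_cm)
        )


@dataclass
class Beam:
    control_points: list[ControlPoint]
    meterset_mu: float
    leaf_count_per_bank: int
    provenance: str = "original"
    name: str = "beam"

    def validate(self) -> None:
        cps = self.control_points
        if len(cps) < 2:
            raise DynaverifyError("a beam needs at least 2 control points")
        if self.provenance not in PROVENANCE:
            raise DynaverifyError(f"unknown provenance {self.provenance!r}")
        w = np.array([cp.cumulative_weight for cp in cps])
        if abs(w[0]) > 1e-9 or abs(w[-1] - 1.0) > 1e-9:
            raise DynaverifyError("cumulative weights must run from 0 to 1")
        if np.any(np.diff(w) < -1e-12):
            raise DynaverifyError("cumulative weights must be non-decreasing")
        n = 2 * self.leaf_count_per_bank
        for i, cp in enumerate(cps):
            if len(cp.mlc_cm) != n:
                raise DynaverifyError(f"control point {i}: expected {n} leaves")

    @property
    def weights(self) -> np.ndarray:
        return np.array([cp.cumulative_weight for cp in self.control_points])

    @property
    def mlc(self) -> np.ndarray:
        """(n_cp, 2*leaf_count_per_bank) stacked leaf positions, cm."""
        return np.stack([cp.mlc_cm for cp in self.control_points])

    def __eq__(self, other) -> bool:
        if not isinstance(other, Beam):
            return NotImplemented
        return (
            self.control_points == other.control_points
            and self.meterset_mu == other.meterset_mu
            and self.leaf_count_per_bank == other.leaf_count_per_bank
            and self.provenance == other.provenance
            and self.name == other.name
        )


@dataclass
class Plan:
    beams: list[Beam]
    patient_id: str = "ANON"
    plan_label: str = "dynaverify"

    def validate(self) -> None:
        if not self.beams:
            raise DynaverifyError("a plan needs at least one beam")
        for b in self.beams:
            b.validate()

    def __eq__(self, other) -> bool:
        if not isinstance(other, Plan):
            return NotImplemented
        return (
            self.beams == other.beams
            and self.patient_id == other.patient_id
            and self.plan_label == other.plan_label
        )


# ----------------------------------------------------------------------
# interpolation helpers
# ----------------------------------------------------------------------

def _unwrap_gantry(deg: np.ndarray) -> np.ndarray:
    """Unwrap gantry angles onto a continuous axis (shortest-arc steps)."""
    deg = np.asarray(deg, dtype=float)
    steps = np.diff(deg)
    steps = (steps + 180.0) % 360.0 - 180.0
    return np.concatenate([[deg[0]], deg[0] + np.cumsum(steps)])


def sample_beam(beam: Beam, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate (gantry, jaws, mlc) at cumulative weights.

    The gantry is interpolated on an unwrapped (shortest-arc) axis so arcs
    crossing 0/360 degrees behave; results are reduced back to [0, 360).
    Returns arrays of shape (m,), (m, 4) and (m, n_leaves).
    """
    w = beam.weights
    weights = np.asarray(weights, dtype=float)
    gantry_u = _unwrap_gantry(np.array([cp.gantry_deg for cp in beam.control_points]))
    gantry = np.interp(weights, w, gantry_u) % 360.0
    jaws = np.stack([cp.jaws_cm for cp in beam.control_points])
    jaws_i = np.stack([np.interp(weights, w, jaws[:, k]) for k in range(4)], axis=1)
    mlc = beam.mlc
    mlc_i = np.stack(
        [np.interp(weights, w, mlc[:, k]) for k in range(mlc.shape[1])], axis=1
    )
    return gantry, jaws_i, mlc_i


def densify_plan(beam: Beam, target_cp_count: int) -> Beam:
    """Insert control points by linear interpolation in cumulative weight.

    New control points are placed on a uniform cumulative-weight grid of
    ``target_cp_count`` values (endpoints included); the original control
    points are preserved, so the result can exceed ``target_cp_count``
    where grids do not coincide. The piecewise-linear leaf trajectories are
    unchanged, hence the meterset-weighted aperture integral is conserved.
    """
    beam.validate()
    if target_cp_count < len(beam.control_points):
        raise DynaverifyError(
            f"target count {target_cp_count} below current {len(beam.control_points)}"
        )
    if target_cp_count == len(beam.control_points):
        return beam
    grid = np.linspace(0.0, 1.0, target_cp_count)
    w = np.unique(np.concatenate([beam.weights, grid]))
    gantry, jaws, mlc = sample_beam(beam, w)
    cps = [
        ControlPoint(float(w[i]), float(gantry[i]), jaws[i].copy(), mlc[i].copy())
        for i in range(len(w))
    ]
    return replace(beam, control_points=cps, provenance="densified")


# ----------------------------------------------------------------------
# DICOM RTPLAN I/O
# ----------------------------------------------------------------------

_RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"


def _ds(x: float) -> float:
    """Round for DICOM DS encoding (16-char limit on decimal strings)."""
    return round(float(x), 8)


def write_rtplan(plan: Plan, path) -> None:
    """Write a DICOM RTPLAN with dynamic-MLC control point sequences.

    Fresh SOP/series/study instance UIDs are generated on every write; all
    other content is deterministic, so two writes differ only in UIDs.
    """
    plan.validate()
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.Modality = "RTPLAN"
    ds.PatientID = plan.patient_id
    ds.PatientName = plan.patient_id
    ds.RTPlanLabel = plan.plan_label
    ds.RTPlanGeometry = "PATIENT"

    frac = Dataset()
    frac.FractionGroupNumber = 1
    frac.NumberOfFractionsPlanned = 1
    frac.ReferencedBeamSequence = []

    ds.BeamSequence = []
    for bi, beam in enumerate(plan.beams, start=1):
        n = beam.leaf_count_per_bank
        bds = Dataset()
        bds.BeamNumber = bi
        bds.BeamName = beam.name
        bds.BeamType = "DYNAMIC"
        bds.RadiationType = "PHOTON"
        bds.TreatmentDeliveryType = "TREATMENT"
        bds.NumberOfControlPoints = len(beam.control_points)
        bds.FinalCumulativeMetersetWeight = 1.0

        # leaf boundary geometry: uniform strips centred on the axis
        bld_mlc = Dataset()
        bld_mlc.RTBeamLimitingDeviceType = "MLCX"
        bld_mlc.NumberOfLeafJawPairs = n
        width = 0.5  # cm per leaf strip (toy Millennium-like geometry)
        bounds_cm = (np.arange(n + 1) - n / 2.0) * width
        bld_mlc.LeafPositionBoundaries = [_ds(b * 10.0) for b in bounds_cm]
        bds.BeamLimitingDeviceSequence = [bld_mlc]

        bds.ControlPointSequence = []
        for ci, cp in enumerate(beam.control_points):
            cds = Dataset()
            cds.ControlPointIndex = ci
            cds.CumulativeMetersetWeight = _ds(cp.cumulative_weight)
            cds.GantryAngle = _ds(cp.gantry_deg)
            cds.GantryRotationDirection = "CW"
            cds.BeamLimitingDevicePositionSequence = []

            for dev, positions_mm in (
                ("ASYMX", [-cp.jaws_cm[0] * 10.0, cp.jaws_cm[1] * 10.0]),
                ("ASYMY", [-cp.jaws_cm[2] * 10.0, cp.jaws_cm[3] * 10.0]),
                ("MLCX", list(-cp.mlc_cm[n:] * 10.0) + list(cp.mlc_cm[:n] * 10.0)),
            ):
                dds = Dataset()
                dds.RTBeamLimitingDeviceType = dev
                dds.LeafJawPositions = [_ds(p) for p in positions_mm]
                cds.BeamLimitingDevicePositionSequence.append(dds)
            bds.ControlPointSequence.append(cds)
        ds.BeamSequence.append(bds)

        rb = Dataset()
        rb.ReferencedBeamNumber = bi
        rb.BeamMeterset = _ds(beam.meterset_mu)
        frac.ReferencedBeamSequence.append(rb)

    ds.FractionGroupSequence = [frac]
    pydicom.dcmwrite(Path(path), ds, enforce_file_format=True)


def read_rtplan(path) -> Plan:
    """Read a DICOM RTPLAN with dynamic MLC into a :class:`Plan`.

    Cumulative meterset weights are normalised to [0, 1]. Gantry angle and
    device positions missing from a control point are carried forward from
    the previous one (the DICOM convention for unchanged values).
    """
    ds = pydicom.dcmread(Path(path))
    if getattr(ds, "Modality", None) != "RTPLAN" or "BeamSequence" not in ds:
        raise UnsupportedPlanError(f"{path}: not an RTPLAN with beams")

    metersets = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[int(rb.ReferencedBeamNumber)] = float(
                getattr(rb, "BeamMeterset", 0.0)
            )

    beams = []
    for bds in ds.BeamSequence:
        if getattr(bds, "TreatmentDeliveryType", "TREATMENT") != "TREATMENT":
            continue
        n = None
        for bld in getattr(bds, "BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType.startswith("MLC"):
                n = int(bld.NumberOfLeafJawPairs)
        cps_ds = getattr(bds, "ControlPointSequence", [])
        if n is None or len(cps_ds) < 2:
            raise UnsupportedPlanError(
                f"beam {getattr(bds, 'BeamNumber', '?')}: no dynamic MLC "
                "control-point sequence"
            )

        final_w = float(getattr(bds, "FinalCumulativeMetersetWeight", 1.0)) or 1.0
        gantry = 0.0
        jaws = np.zeros(4)
        mlc = np.zeros(2 * n)
        have_mlc = False
        cps = []
        for cds in cps_ds:
            if "GantryAngle" in cds:
                gantry = float(cds.GantryAngle)
            for dds in getattr(cds, "BeamLimitingDevicePositionSequence", []):
                pos = np.asarray(dds.LeafJawPositions, dtype=float)
                dev = dds.RTBeamLimitingDeviceType
                if dev in ("ASYMX", "X"):
                    jaws = np.array([-pos[0] / 10.0, pos[1] / 10.0, jaws[2], jaws[3]])
                elif dev in ("ASYMY", "Y"):
                    jaws = np.array([jaws[0], jaws[1], -pos[0] / 10.0, pos[1] / 10.0])
                elif dev.startswith("MLC"):
                    b1, b2 = pos[:n] / 10.0, pos[n:] / 10.0
                    mlc = np.concatenate([b2, -b1])  # bank A = +edge, bank B = -edge
                    have_mlc = True
            cps.append(
                ControlPoint(
                    float(cds.CumulativeMetersetWeight) / final_w,
                    gantry, jaws.copy(), mlc.copy(),
                )
            )
        if not have_mlc:
            raise UnsupportedPlanError(
                f"beam {getattr(bds, 'BeamNumber', '?')}: static beam without "
                "MLC positions is out of scope"
            )
        beam = Beam(
            cps,
            metersets.get(int(getattr(bds, "BeamNumber", 1)), 0.0),
            n,
            "original",
            str(getattr(bds, "BeamName", "beam")),
        )
        beam.validate()
        beams.append(beam)
    if not beams:
        raise UnsupportedPlanError(f"{path}: no treatment beams found")
    return Plan(beams, str(ds.PatientID), str(ds.RTPlanLabel))


# ----------------------------------------------------------------------
# JSON dump (debugging / provenance)
# ----------------------------------------------------------------------

def plan_to_json(plan: Plan) -> str:
    """Serialise a plan to an indented JSON document (debug format)."""
    doc = {
        "patient_id": plan.patient_id,
        "plan_label": plan.plan_label,
        "beams": [
            {
                "name": b.name,
                "meterset_mu": b.meterset_mu,
                "leaf_count_per_bank": b.leaf_count_per_bank,
                "provenance": b.provenance,
                "control_points": [
                    {
                        "cumulative_weight": cp.cumulative_weight,
                        "gantry_deg": cp.gantry_deg,
                        "jaws_cm": list(map(float, cp.jaws_cm)),
                        "mlc_cm": list(map(float, cp.mlc_cm)),
                    }
                    for cp in b.control_points
                ],
            }
            for b in plan.beams
        ],
    }
    return json.dumps(doc, indent=2)


def plan_from_json(text: str) -> Plan:
    doc = json.loads(text)
    beams = [
        Beam(
            [
                ControlPoint(
                    cp["cumulative_weight"], cp["gantry_deg"],
                    np.asarray(cp["jaws_cm"], dtype=float),
                    np.asarray(cp["mlc_cm"], dtype=float),
                )
                for cp in b["control_points"]
            ],
            b["meterset_mu"], b["leaf_count_per_bank"], b["provenance"], b["name"],
        )
        for b in doc["beams"]
    ]
    return Plan(beams, doc["patient_id"], doc["plan_label"])
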