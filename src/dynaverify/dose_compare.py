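"""Quantitative comparison of 3D dose distributions.

Implements the three agreement measures used for dynalog-based treatment
verification:

Percentage of agreement (PA)
    A DVH-similarity score. For two cumulative dose-volume histograms with
    a common bin width ``dd``,

        PA = 100 * [1 - delta_A / max(A1, A2)],
        delta_A = dd * sum_i |V1_i - V2_i|,

    where ``A_k = dd * sum_i V_k,i`` is the area under histogram k. PA is
    100 exactly when the histograms coincide bin-wise and 0 when one
    histogram is empty.

Gamma pass rate (GPR)
    Percentage of voxels passing the gamma test at given dose-difference
    (% of the global normalisation dose) and distance-to-agreement
    criteria. The evaluated distribution is tri-linearly interpolated on a
    sub-voxel search grid around each reference voxel; voxels below a
    low-dose cutoff are excluded.

Systematic differences (alpha/Delta)
    For statistically noisy (Monte Carlo style) dose grids, the per-voxel
    systematic deviation is estimated by subtracting the combined
    statistical variance in quadrature,

        s_i = sqrt(max(0, d_i^2 - (sigma_ref,i^2 + sigma_eval,i^2))),

    and alpha(Delta) is the percentage of voxels (within the body and above
    a dose threshold, 30% of the reference maximum by default) whose
    systematic deviation is at least Delta percent of the reference
    maximum dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import map_coordinates

from .exceptions import DoseComparisonError, UncertaintyRequiredError

MM_PER_CM = 10.0


# ----------------------------------------------------------------------
# containers
# ----------------------------------------------------------------------

@dataclass
class DoseGrid:
    """A 3D voxel dose array with geometry and optional uncertainty.

    ``values[ix, iy, iz]`` is the dose at position
    ``origin_cm + (ix, iy, iz) * spacing_cm``. ``sigma``, when present, is
    the per-voxel standard statistical uncertainty in the same unit.
    """

    values: np.ndarray
    spacing_cm: np.ndarray
    origin_cm: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spacing_cm = np.asarray(self.spacing_cm, dtype=float)
        self.origin_cm = np.asarray(self.origin_cm, dtype=float)
        if self.values.ndim != 3:
            raise DoseComparisonError("dose values must be a 3D array")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise DoseComparisonError("dose values must be finite and >= 0")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.values.shape or np.any(self.sigma < 0):
                raise DoseComparisonError("sigma must match values and be >= 0")

    @property
    def shape(self):
        return self.values.shape

    def congruent_with(self, other: "DoseGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_cm, other.spacing_cm)
            and np.allclose(self.origin_cm, other.origin_cm)
        )

    # ---- fixture I/O (single .npz, runtime artifact) -------------------
    def save_npz(self, path) -> None:
        data = dict(values=self.values, spacing_cm=self.spacing_cm,
                    origin_cm=self.origin_cm)
        if self.sigma is not None:
            data["sigma"] = self.sigma
        np.savez_compressed(Path(path), **data)

    @classmethod
    def load_npz(cls, path) -> "DoseGrid":
        with np.load(Path(path)) as z:
            return cls(z["values"], z["spacing_cm"], z["origin_cm"],
                       z["sigma"] if "sigma" in z.files else None)


@dataclass
class StructureMask:
    """Boolean voxel mask for one structure, congruent with a DoseGrid."""

    name: str
    voxels: np.ndarray
    spacing_cm: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)

    @property
    def voxel_count(self) -> int:
        return int(np.sum(self.voxels))

    def volume_cm3(self) -> float:
        if self.spacing_cm is None:
            raise DoseComparisonError(f"mask {self.name!r} has no voxel spacing")
        return float(self.voxel_count * np.prod(self.spacing_cm))


@dataclass
class DVH:
    """Cumulative dose-volume histogram on a uniform dose grid.

    ``volumes[i]`` is the percentage of the structure volume receiving a
    dose of at least ``i * bin_width``.
    """

    bin_width: float
    volumes: np.ndarray

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)

    @property
    def area(self) -> float:
        """A = bin_width * sum_i V_i (the discrete area under the DVH)."""
        return float(self.bin_width * np.sum(self.volumes))


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma-analysis criteria: dose %, DTA mm, cutoff and search settings."""

    dose_percent: float = 3.0
    dta_mm: float = 3.0
    low_dose_cutoff_percent: float = 10.0
    normalization: str = "global_max_reference"
    search_step_fraction: float = 0.1    # sub-grid step, fraction of dta
    search_radius_factor: float = 3.0    # search radius, multiples of dta

    def validate(self) -> None:
        if self.dose_percent <= 0 or self.dta_mm <= 0:
            raise DoseComparisonError("gamma criteria must be positive")
        if self.normalization != "global_max_reference":
            raise DoseComparisonError(
                f"unsupported normalization {self.normalization!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.dose_percent:g},{self.dta_mm:g}"


@dataclass
class SystematicDiff:
    """alpha/Delta pairs: percentage of voxels with systematic deviation
    of at least Delta percent of the reference maximum dose."""

    pairs: list[tuple[float, float]] = field(default_factory=list)  # (alpha, delta)

    def alpha_at(self, delta_percent: float) -> float:
        for alpha, delta in self.pairs:
            if np.isclose(delta, delta_percent):
                return alpha
        raise KeyError(f"no alpha tabulated at Delta = {delta_percent}%")


# ----------------------------------------------------------------------
# DICOM RTDOSE I/O
# ----------------------------------------------------------------------

_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


def write_rtdose(dose: DoseGrid, path) -> None:
    """Write a DoseGrid as a multi-frame DICOM RTDOSE (GY, 32-bit).

    Frames run along z; per-voxel sigma is not part of the RTDOSE object
    and is dropped (use :meth:`DoseGrid.save_npz` to keep it).
    """
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.Modality = "RTDOSE"
    ds.PatientID = "ANON"
    ds.PatientName = "ANON"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"

    nx, ny, nz = dose.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.ImagePositionPatient = [float(c * 10.0) for c in dose.origin_cm]
    ds.PixelSpacing = [float(dose.spacing_cm[1] * 10.0),
                       float(dose.spacing_cm[0] * 10.0)]
    ds.GridFrameOffsetVector = [float(k * dose.spacing_cm[2] * 10.0)
                                for k in range(nz)]
    vmax = float(dose.values.max())
    scaling = (vmax / (2**32 - 1)) if vmax > 0 else 1.0
    ds.DoseGridScaling = scaling
    pixels = np.round(dose.values / scaling).astype(np.uint32)
    # (x, y, z) -> frames (z, rows=y, cols=x)
    ds.PixelData = np.ascontiguousarray(pixels.transpose(2, 1, 0)).tobytes()
    pydicom.dcmwrite(Path(path), ds, enforce_file_format=True)


def read_rtdose(path) -> DoseGrid:
    """Read a multi-frame DICOM RTDOSE into a DoseGrid (no sigma)."""
    ds = pydicom.dcmread(Path(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise DoseComparisonError(f"{path}: not an RTDOSE file")
    frames = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if frames.ndim == 2:
        frames = frames[None]
    values = frames.transpose(2, 1, 0)  # -> (x, y, z)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) / 10.0 if len(offsets) > 1 else 1.0
    spacing = np.array([float(ds.PixelSpacing[1]) / 10.0,
                        float(ds.PixelSpacing[0]) / 10.0, dz])
    origin = np.asarray(ds.ImagePositionPatient, dtype=float) / 10.0
    return DoseGrid(values, spacing, origin)


# ----------------------------------------------------------------------
# DVH and PA
# ----------------------------------------------------------------------

def compute_dvh(dose: DoseGrid, mask: StructureMask, bin_width: float) -> DVH:
    """Cumulative DVH of ``dose`` over ``mask`` with fixed bin width.

    Bin i counts the percentage of masked voxels with dose >= i*bin_width;
    the histogram always ends on a zero bin beyond the maximum dose.
    """
    if bin_width <= 0:
        raise DoseComparisonError("bin_width must be positive")
    if mask.voxels.shape != dose.shape:
        raise DoseComparisonError("mask and dose grid are not congruent")
    d = dose.values[mask.voxels]
    if d.size == 0:
        raise DoseComparisonError(f"mask {mask.name!r} is empty")
    n_bins = int(np.floor(d.max() / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    volumes = 100.0 * np.mean(d[None, :] >= edges[:, None], axis=1)
    return DVH(bin_width, volumes)


def percentage_of_agreement(dvh1: DVH, dvh2: DVH) -> float:
    """PA = 100 * [1 - delta_A / max(A1, A2)] of two same-bin-width DVHs."""
    if not np.isclose(dvh1.bin_width, dvh2.bin_width):
        raise DoseComparisonError("DVHs must share one bin width")
    n = max(len(dvh1.volumes), len(dvh2.volumes))
    v1 = np.zeros(n)
    v2 = np.zeros(n)
    v1[: len(dvh1.volumes)] = dvh1.volumes
    v2[: len(dvh2.volumes)] = dvh2.volumes
    dd = dvh1.bin_width
    delta_a = dd * float(np.sum(np.abs(v1 - v2)))
    a_max = max(dd * float(np.sum(v1)), dd * float(np.sum(v2)))
    if a_max == 0:
        raise DoseComparisonError("both DVH areas are zero; PA undefined")
    return 100.0 * (1.0 - delta_a / a_max)


# ----------------------------------------------------------------------
# gamma analysis
# ----------------------------------------------------------------------

def gamma_search_offsets(criteria: GammaCriteria) -> tuple[np.ndarray, np.ndarray]:
    """Search displacements (cm) within the gamma radius, sorted by distance.

    Returns ``(offsets, distances_mm)`` with the zero offset first. The
    sub-grid step is ``dta * search_step_fraction`` and the radius
    ``dta * search_radius_factor``.
    """
    step_mm = criteria.dta_mm * criteria.search_step_fraction
    radius_mm = criteria.dta_mm * criteria.search_radius_factor
    k = int(np.floor(radius_mm / step_mm))
    axis = np.arange(-k, k + 1) * step_mm
    ox, oy, oz = np.meshgrid(axis, axis, axis, indexing="ij")
    off_mm = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    dist_mm = np.linalg.norm(off_mm, axis=1)
    keep = dist_mm <= radius_mm + 1e-12
    off_mm, dist_mm = off_mm[keep], dist_mm[keep]
    order = np.argsort(dist_mm, kind="stable")
    return off_mm[order] / MM_PER_CM, dist_mm[order]


def _interp_eval(evaluated: DoseGrid, points_cm: np.ndarray) -> np.ndarray:
    """Tri-linear interpolation of the evaluated dose at physical points."""
    idx = (points_cm - evaluated.origin_cm) / evaluated.spacing_cm
    return map_coordinates(evaluated.values, idx.T, order=1, mode="nearest")


def gamma_values(reference: DoseGrid, evaluated: DoseGrid, mask: StructureMask,
                 criteria: GammaCriteria, norm_dose: float | None = None) -> np.ndarray:
    """Gamma index of every eligible masked voxel (flat array).

    Offsets are visited shell by shell in order of increasing distance; a
    voxel stops searching once the distance term alone exceeds its current
    best gamma, which makes the search exact (identical to exhaustive
    enumeration over the same offset set) but far cheaper on agreeing
    distributions.
    """
    criteria.validate()
    if not reference.congruent_with(evaluated):
        raise DoseComparisonError("reference and evaluated grids not congruent")
    dmax = float(np.max(reference.values)) if norm_dose is None else float(norm_dose)
    if dmax <= 0:
        raise DoseComparisonError("normalization dose is zero")
    dose_tol = criteria.dose_percent / 100.0 * dmax
    cutoff = criteria.low_dose_cutoff_percent / 100.0 * dmax

    eligible = mask.voxels & (reference.values >= cutoff)
    idx = np.argwhere(eligible)
    if idx.shape[0] == 0:
        raise DoseComparisonError("no voxels above the low-dose cutoff")
    pos = reference.origin_cm + idx * reference.spacing_cm
    ref_d = reference.values[eligible]

    offsets_cm, dist_mm = gamma_search_offsets(criteria)
    dta = criteria.dta_mm
    best = np.full(len(ref_d), np.inf)
    active = np.arange(len(ref_d))

    shell_edges = np.nonzero(np.diff(dist_mm) > 1e-12)[0] + 1
    shells = np.split(np.arange(len(dist_mm)), shell_edges)
    for shell in shells:
        r2 = (dist_mm[shell[0]] / dta) ** 2
        active = active[best[active] > r2]
        if active.size == 0:
            break
        pts = pos[active][:, None, :] + offsets_cm[shell][None, :, :]
        ev = _interp_eval(evaluated, pts.reshape(-1, 3)).reshape(len(active), -1)
        g2 = ((ev - ref_d[active][:, None]) / dose_tol) ** 2 + r2
        np.minimum.at(best, active, g2.min(axis=1))
    return np.sqrt(best)


def gamma_pass_rate(reference: DoseGrid, evaluated: DoseGrid, mask: StructureMask,
                    criteria: GammaCriteria, norm_dose: float | None = None) -> float:
    """Percentage of eligible voxels with gamma index <= 1."""
    g = gamma_values(reference, evaluated, mask, criteria, norm_dose)
    return 100.0 * float(np.mean(g <= 1.0))


# ----------------------------------------------------------------------
# systematic differences (alpha/Delta)
# ----------------------------------------------------------------------

DEFAULT_DELTA_GRID_PERCENT = tuple(np.round(np.arange(0.1, 5.01, 0.1), 10))


def systematic_differences(
    reference: DoseGrid,
    evaluated: DoseGrid,
    mask: StructureMask,
    dose_threshold_percent: float = 30.0,
    delta_grid_percent=DEFAULT_DELTA_GRID_PERCENT,
) -> SystematicDiff:
    """alpha(Delta) table of systematic dose deviations above noise.

    Both grids must carry per-voxel statistical uncertainty. Voxels are
    restricted to the mask and to doses above ``dose_threshold_percent`` of
    the reference maximum inside the mask.
    """
    if reference.sigma is None or evaluated.sigma is None:
        raise UncertaintyRequiredError(
            "systematic-difference analysis requires per-voxel sigma on both grids"
        )
    if not reference.congruent_with(evaluated):
        raise DoseComparisonError("reference and evaluated grids not congruent")
    if mask.voxel_count == 0:
        raise DoseComparisonError(f"mask {mask.name!r} is empty")

    dmax = float(np.max(reference.values[mask.voxels]))
    if dmax <= 0:
        raise DoseComparisonError("reference dose is zero inside the mask")
    domain = mask.voxels & (reference.values > dose_threshold_percent / 100.0 * dmax)
    if not np.any(domain):
        raise DoseComparisonError("no voxels above the dose threshold")

    d = evaluated.values[domain] - reference.values[domain]
    var = reference.sigma[domain] ** 2 + evaluated.sigma[domain] ** 2
    s = np.sqrt(np.maximum(0.0, d ** 2 - var))

    pairs = []
    for delta in delta_grid_percent:
        thresh = delta / 100.0 * dmax
        alpha = 100.0 * float(np.mean(s >= thresh))
        pairs.append((alpha, float(delta)))
    return SystematicDiff(pairs)


# ----------------------------------------------------------------------
# aggregated report
# ----------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """PA / GPR per structure plus field-level RMS, MLE and alpha/Delta."""

    schema_version: int = 1
    structures: dict = field(default_factory=dict)   # name -> {"pa": .., "gpr": {label: ..}}
    rms_mm: float | None = None
    mle_mm: float | None = None
    scale_factor: float | None = None
    alpha_delta: list | None = None                  # [(alpha, delta), ...]
    verdict: str | None = None

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "structures": self.structures,
            "rms_mm": self.rms_mm,
            "mle_mm": self.mle_mm,
            "scale_factor": self.scale_factor,
            "alpha_delta": self.alpha_delta,
            "verdict": self.verdict,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        doc = json.loads(text)
        ad = doc.get("alpha_delta")
        return cls(
            schema_version=doc["schema_version"],
            structures=doc["structures"],
            rms_mm=doc.get("rms_mm"),
            mle_mm=doc.get("mle_mm"),
            scale_factor=doc.get("scale_factor"),
            alpha_delta=[tuple(p) for p in ad] if ad is not None else None,
            verdict=doc.get("verdict"),
        )


def compare(
    reference: DoseGrid,
    evaluated: DoseGrid,
    masks: dict[str, StructureMask],
    criteria_list: tuple[GammaCriteria, ...] = (GammaCriteria(2, 2), GammaCriteria(3, 3)),
    dvh_bin_width: float | None = None,
    with_alpha_delta: bool = False,
    body_mask_name: str | None = None,
) -> ComparisonReport:
    """Per-structure PA and GPR (and optionally alpha/Delta) in one report.

    The global normalisation dose for gamma and Delta is the reference
    maximum inside the body mask (``body_mask_name``, or the largest mask
    when unspecified), following the convention that percentages refer to
    the in-patient maximum dose.
    """
    if not masks:
        raise DoseComparisonError("no structures to compare")
    if body_mask_name is None:
        body_mask_name = max(masks, key=lambda k: masks[k].voxel_count)
    body = masks[body_mask_name]
    dmax = float(np.max(reference.values[body.voxels]))
    if dvh_bin_width is None:
        dvh_bin_width = dmax / 1000.0 if dmax > 0 else 1e-3

    report = ComparisonReport()
    for name, mask in masks.items():
        dvh_ref = compute_dvh(reference, mask, dvh_bin_width)
        dvh_eval = compute_dvh(evaluated, mask, dvh_bin_width)
        entry = {"pa": percentage_of_agreement(dvh_ref, dvh_eval), "gpr": {}}
        for crit in criteria_list:
            entry["gpr"][crit.label] = gamma_pass_rate(
                reference, evaluated, mask, crit, norm_dose=dmax
            )
        report.structures[name] = entry
    if with_alpha_delta:
        report.alpha_delta = systematic_differences(reference, evaluated, body).pairs
    return report
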