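"""Synthetic plans, phantoms and dynalog deliveries with controlled errors.

Everything downstream (parsing, reconstruction, magnification, dose
comparison) is exercised on data from this module, so its defaults define
the study conditions:

* a single-arc VMAT beam with a sliding, "breathing" MLC window and
  uniform cumulative meterset weights;
* a delivery emulator that writes one dynalog record per 50 ms controller
  tick with roughly 8.5 records per original control-point transition
  (the regime of clinical logs, where ~180-CP arcs produce ~1500 records);
* leaf-position error models: ``none``, ``gaussian`` (zero-mean, errors in
  both directions), ``unidirectional`` (half-normal, every error shrinks
  the aperture — the signature of e.g. a failing carriage), and ``drift``
  (error growing linearly with time).

For a gaussian model with standard deviation sigma the RMS of the
generated leaf errors converges to sigma; the half-normal unidirectional
model with the same scale parameter also has RMS equal to sigma, which is
what makes "same RMS, different directionality" comparisons clean.

All randomness flows through one seeded generator per call; identical
seeds give identical outputs, and generated positions are quantised to
0.001 cm (hundredths of a millimetre — the file resolution of integer
dynalog dialects) so write/parse round trips are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynalog_io import (
    DynalogBankFile,
    DynalogField,
    DynalogRecord,
    TICK_MS,
    merge_banks,
)
from .exceptions import DynaverifyError
from .plan_model import Beam, ControlPoint, Plan, sample_beam
from .toy_dose import Phantom

ERROR_KINDS = ("none", "gaussian", "unidirectional", "drift")


@dataclass(frozen=True)
class ErrorModel:
    """Leaf-position error statistics for :func:`simulate_delivery`.

    kind : {"none", "gaussian", "unidirectional", "drift"}
    sigma_mm : scale of the random component (std for gaussian; half-normal
        scale for unidirectional).
    mean_mm : additional constant aperture-shrinking offset (unidirectional).
    drift_mm_per_s : linear error growth with time (drift).
    seed : seed of the dedicated random generator.
    """

    kind: str = "none"
    sigma_mm: float = 0.0
    mean_mm: float = 0.0
    drift_mm_per_s: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in ERROR_KINDS:
            raise DynaverifyError(f"unknown error model {self.kind!r}")
        if self.sigma_mm < 0:
            raise DynaverifyError("sigma_mm must be >= 0")

    def realize_cm(self, n_records: int, n_leaves: int,
                   time_s: np.ndarray) -> np.ndarray:
        """Draw the (n_records, n_leaves) error field, cm (eps = P_e - P_a)."""
        self.validate()
        rng = np.random.default_rng(self.seed)
        sig_cm = self.sigma_mm * 0.1
        if self.kind == "none":
            return np.zeros((n_records, n_leaves))
        if self.kind == "gaussian":
            return rng.normal(0.0, sig_cm, (n_records, n_leaves))
        if self.kind == "unidirectional":
            # positive eps always shrinks the aperture (opening coordinate)
            half = np.abs(rng.normal(0.0, sig_cm, (n_records, n_leaves)))
            return half + self.mean_mm * 0.1
        # drift
        ramp = (self.drift_mm_per_s * 0.1) * time_s[:, None]
        return np.broadcast_to(ramp, (n_records, n_leaves)).copy()


def make_phantom(
    shape: tuple[int, int, int] = (31, 31, 17),
    spacing_cm: tuple[float, float, float] = (0.5, 0.5, 0.5),
    body_semiaxes_cm: tuple[float, float, float] | None = None,
    ptv_radius_cm: float = 2.0,
    ptv_center_cm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    oar_halfwidths_cm: tuple[float, float, float] = (1.5, 1.0, 1.5),
    oar_center_cm: tuple[float, float, float] = (4.0, 0.0, 0.0),
) -> Phantom:
    """Deterministic voxel phantom: ellipsoidal body, spherical PTV, box OAR.

    Coordinates are centred on the isocenter at the grid midpoint. The PTV
    is clipped to the body, so PTV ⊂ body always holds.
    """
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing_cm, dtype=float)
    origin = -((np.asarray(shape) - 1) / 2.0) * spacing
    ax = [origin[k] + np.arange(shape[k]) * spacing[k] for k in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")

    if body_semiaxes_cm is None:
        body_semiaxes_cm = tuple(0.95 * (np.asarray(shape) - 1) / 2.0 * spacing)
    bx, by, bz = body_semiaxes_cm
    body = (gx / bx) ** 2 + (gy / by) ** 2 + (gz / bz) ** 2 <= 1.0

    px, py, pz = ptv_center_cm
    ptv = ((gx - px) ** 2 + (gy - py) ** 2 + (gz - pz) ** 2
           <= ptv_radius_cm ** 2) & body

    ox, oy, oz = oar_center_cm
    hx, hy, hz = oar_halfwidths_cm
    oar = ((np.abs(gx - ox) <= hx) & (np.abs(gy - oy) <= hy)
           & (np.abs(gz - oz) <= hz) & body)

    return Phantom(shape, spacing, origin,
                   {"body": body, "ptv": ptv, "oar": oar},
                   isocenter_cm=np.zeros(3))


def make_vmat_plan(
    cp_count: int = 178,
    arc_start_deg: float = 181.0,
    arc_stop_deg: float = 179.0,
    leaf_count_per_bank: int = 60,
    open_leaves: int = 12,
    base_gap_cm: float = 4.0,
    gap_amplitude_cm: float = 1.5,
    sweep_amplitude_cm: float = 2.0,
    jaw_halfwidth_cm: float = 5.0,
    meterset_mu: float = 200.0,
    taper: bool = True,
) -> Plan:
    """A single-arc VMAT plan with smoothly varying apertures.

    The central ``open_leaves`` leaf pairs form a window whose centre
    sweeps sinusoidally across the field (amplitude ``sweep_amplitude_cm``)
    while its gap breathes between ``base_gap_cm - gap_amplitude_cm`` and
    ``base_gap_cm + gap_amplitude_cm``; the remaining pairs stay closed
    behind the jaws. The arc runs the long way from ``arc_start_deg`` to
    ``arc_stop_deg`` (through 0 by default); weights are uniform.
    """
    if cp_count < 2:
        raise DynaverifyError("cp_count must be >= 2")
    n = leaf_count_per_bank
    t = np.linspace(0.0, 1.0, cp_count)

    # full-arc gantry path crossing 0/360
    total_arc = (arc_stop_deg - arc_start_deg) % 360.0
    gantry = (arc_start_deg + t * total_arc) % 360.0

    lo = n // 2 - open_leaves // 2
    hi = lo + open_leaves
    cps = []
    for k, tk in enumerate(t):
        center = sweep_amplitude_cm * np.sin(2.0 * np.pi * tk)
        gap = base_gap_cm + gap_amplitude_cm * np.sin(4.0 * np.pi * tk + 1.0)
        # taper the window ends so the aperture is round-ish
        j = np.arange(n)
        if taper:
            shape_fac = np.clip(1.0 - ((j - (lo + hi - 1) / 2.0)
                                       / max(open_leaves / 2.0, 1)) ** 2, 0.0, 1.0)
        else:
            shape_fac = np.ones(n)
        half_gap = np.where((j >= lo) & (j < hi), 0.5 * gap * shape_fac, 0.0)
        pos_a = np.where(half_gap > 0, center + half_gap, -0.05)
        pos_b = np.where(half_gap > 0, half_gap - center, 0.05)
        mlc = np.round(np.concatenate([pos_a, pos_b]), 3)
        jaws = np.array([jaw_halfwidth_cm, jaw_halfwidth_cm,
                         0.5 * open_leaves * 0.5 + 0.5,
                         0.5 * open_leaves * 0.5 + 0.5])
        cps.append(ControlPoint(float(np.round(tk, 8)),
                                float(np.round(gantry[k], 4)), jaws, mlc))
    cps[-1].cumulative_weight = 1.0
    beam = Beam(cps, meterset_mu, n, "original", "synthetic-arc")
    beam.validate()
    return Plan([beam], patient_id="SYNTH", plan_label="synthetic-vmat")


def simulate_delivery(
    plan: Plan,
    error_model: ErrorModel = ErrorModel(),
    tick_ms: int = 50,
    records_per_cp: float = 8.5,
    linac_type: str = "Clinac",
    active_leaves_only: bool = False,
) -> tuple[DynalogBankFile, DynalogBankFile]:
    """Emulate the MLC controller writing one A/B dynalog pair.

    Records are laid down at every tick from field start to end; the total
    delivery time is ``records_per_cp`` ticks per original control point,
    keeping the record-to-control-point ratio in the clinical regime.
    Expected positions are the plan's apertures linearly interpolated in
    cumulative weight (dose fraction is linear in time); actual positions
    are expected minus the realised error; the segment counter indexes the
    bracketing original control-point interval.

    With ``active_leaves_only`` errors are applied only to leaves whose
    pair forms an open aperture (gap > 1 mm); parked leaves track their
    expected position exactly, as closed leaves do in practice.
    """
    plan.validate()
    if TICK_MS.get(linac_type) != tick_ms:
        raise DynaverifyError(
            f"tick {tick_ms} ms does not match linac type {linac_type!r}"
        )
    beam = plan.beams[0]
    n = beam.leaf_count_per_bank
    n_records = max(int(round(records_per_cp * len(beam.control_points))), 2)
    times_ms = np.arange(n_records) * tick_ms
    frac = times_ms / times_ms[-1]

    gantry, jaws, expected = sample_beam(beam, frac)
    expected = np.round(expected, 3)
    jaws = np.round(jaws, 3)
    gantry = np.round(gantry, 1)

    eps = error_model.realize_cm(n_records, 2 * n, times_ms / 1000.0)
    if active_leaves_only:
        gap = expected[:, :n] + expected[:, n:]
        active = gap > 0.1
        eps = eps * np.concatenate([active, active], axis=1)
    actual = np.round(expected - eps, 3)

    w = beam.weights
    segment = np.clip(np.searchsorted(w, frac, side="right") - 1,
                      0, len(w) - 2)

    def bank(bank_id: str, sl: slice) -> DynalogBankFile:
        records = [
            DynalogRecord(
                int(times_ms[i]),
                beam_on=True,
                beam_hold=False,
                segment=int(segment[i]),
                gantry_deg=float(gantry[i]),
                jaws_cm=jaws[i].copy(),
                dose_fraction=float(np.round(frac[i], 8)),
                expected_cm=expected[i, sl].copy(),
                actual_cm=actual[i, sl].copy(),
            )
            for i in range(n_records)
        ]
        return DynalogBankFile(bank_id, linac_type, {"plan": plan.plan_label},
                               records)

    return bank("A", slice(0, n)), bank("B", slice(n, 2 * n))


def simulate_field(plan: Plan, error_model: ErrorModel = ErrorModel(),
                   tick_ms: int = 50, records_per_cp: float = 8.5,
                   active_leaves_only: bool = False) -> DynalogField:
    """Convenience: simulate a delivery and merge the two banks."""
    a, b = simulate_delivery(plan, error_model, tick_ms, records_per_cp,
                             active_leaves_only=active_leaves_only)
    return merge_banks(a, b)
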