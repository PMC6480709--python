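"""Reconstruction of a deliverable beam from a merged dynalog field.

Three record-sampling strategies are provided; the reconstructed control
points can be built from either the *expected* or the *actual* leaf
positions recorded in the logs:

``UR`` (uniform reconstruction)
    Records are taken at a fixed time interval, a multiple of the
    controller tick. At the minimum interval (one tick) every record
    becomes a control point.
``PSR`` (per-segment reconstruction)
    Only records at which the stored segment counter changes are taken, so
    the reconstructed beam has the same number of control points as the
    original plan whenever every transition appears once in the stream.
``PSR_ED`` (per-segment with error detection)
    The PSR records plus every record in which at least one leaf's
    position error exceeds a tolerance. Tolerance zero selects all
    records; a tolerance at or above the maximum leaf error reduces to
    PSR exactly.

The cumulative meterset weight of each control point comes from the
dynalog's cumulative dose fraction, shifted and renormalised so the first
selected record has weight 0 and the last has weight 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynalog_io import CM_PER_MM, DynalogField, leaf_errors
from .exceptions import ReconstructionError
from .plan_model import Beam, ControlPoint

logger = logging.getLogger(__name__)

MODES = ("UR", "PSR", "PSR_ED")
SOURCES = ("expected", "actual")


@dataclass(frozen=True)
class ReconstructionConfig:
    """Sampling strategy and position source for :func:`reconstruct`.

    Parameters
    ----------
    mode : {"UR", "PSR", "PSR_ED"}
    source : {"expected", "actual"}
        Which recorded leaf positions populate the control points.
    interval_ms : int, optional
        UR sampling interval; must be a multiple of the tick. Defaults to
        the tick itself (all records).
    tolerance_mm : float
        PSR_ED leaf-error tolerance, millimetres.
    """

    mode: str = "UR"
    source: str = "expected"
    interval_ms: int | None = None
    tolerance_mm: float = 0.0

    def validate(self, tick_ms: int) -> None:
        if self.mode not in MODES:
            raise ReconstructionError(f"unknown mode {self.mode!r}")
        if self.source not in SOURCES:
            raise ReconstructionError(f"unknown source {self.source!r}")
        if self.mode == "UR":
            interval = self.interval_ms if self.interval_ms is not None else tick_ms
            if interval < tick_ms or interval % tick_ms != 0:
                raise ReconstructionError(
                    f"UR interval {interval} ms must be a positive multiple of "
                    f"the {tick_ms} ms tick"
                )
        if not np.isfinite(self.tolerance_mm) or self.tolerance_mm < 0:
            raise ReconstructionError("tolerance_mm must be finite and >= 0")


def _psr_indices(field: DynalogField) -> np.ndarray:
    """Records at which the segment counter first takes each new value.

    Beam-hold records deliver no dose and are never used as control points;
    a transition landing on a hold is deferred to the next non-hold record.
    """
    seg = field.segment
    hold = field.beam_hold
    change = np.zeros(len(seg), dtype=bool)
    change[0] = True
    change[1:] = seg[1:] != seg[:-1]
    picked = []
    pending = False
    for i in range(len(seg)):
        pending = pending or change[i]
        if pending and not hold[i]:
            picked.append(i)
            pending = False
    return np.asarray(picked, dtype=int)


def selected_indices(field: DynalogField, cfg: ReconstructionConfig) -> np.ndarray:
    """Exact, ordered record indices :func:`reconstruct` will use.

    The first and last records of the field are always included so the
    reconstructed beam has well-defined weight-0 and weight-1 endpoints.
    """
    cfg.validate(field.tick_ms)
    n = len(field.records)
    if n < 2:
        raise ReconstructionError("field has fewer than 2 records")
    if not np.any(field.beam_on):
        raise ReconstructionError("field has no beam-on records")

    if cfg.mode == "UR":
        interval = cfg.interval_ms if cfg.interval_ms is not None else field.tick_ms
        step = interval // field.tick_ms
        idx = set(range(0, n, step))
        if np.any(field.beam_hold[sorted(idx)]):
            logger.warning(
                "UR selection includes %d beam-hold records",
                int(np.sum(field.beam_hold[sorted(idx)])),
            )
    elif cfg.mode == "PSR":
        idx = set(_psr_indices(field).tolist())
    else:  # PSR_ED
        idx = set(_psr_indices(field).tolist())
        eps_mm = np.abs(leaf_errors(field)) / CM_PER_MM
        if cfg.tolerance_mm == 0.0:
            # tolerance chosen "starting from zero": every record qualifies
            flagged = np.ones(n, dtype=bool)
        else:
            flagged = np.any(eps_mm > cfg.tolerance_mm, axis=1)
        flagged &= ~field.beam_hold
        idx |= set(np.nonzero(flagged)[0].tolist())

    idx |= {0, n - 1}
    out = np.array(sorted(idx), dtype=int)
    if len(out) < 2:
        raise ReconstructionError("selection produced fewer than 2 control points")
    return out


def reconstruct(field: DynalogField, cfg: ReconstructionConfig,
                meterset_mu: float = 0.0) -> Beam:
    """Build a deliverable beam from the selected dynalog records.

    Control points are the selected records in time order. MLC positions
    come from ``cfg.source``; gantry, jaws and dose fraction come from the
    shared record scalars. Weights are renormalised over the selection.
    """
    idx = selected_indices(field, cfg)
    df = field.dose_fraction[idx]
    span = df[-1] - df[0]
    if span <= 0:
        raise ReconstructionError(
            "no cumulative dose delivered across the selected records"
        )
    weights = (df - df[0]) / span
    # guard against counter jitter: clip monotone
    weights = np.maximum.accumulate(weights)

    pos = field.expected if cfg.source == "expected" else field.actual
    gantry = field.gantry_deg
    jaws = field.jaws_cm
    cps = [
        ControlPoint(float(weights[k]), float(gantry[i]),
                     jaws[i].copy(), pos[i].copy())
        for k, i in enumerate(idx)
    ]
    beam = Beam(
        cps,
        meterset_mu,
        field.leaf_count_per_bank,
        provenance=f"reconstructed_{cfg.source}",
        name=f"recon-{cfg.mode.lower()}-{cfg.source}",
    )
    beam.validate()
    logger.info(
        "reconstructed %d/%d records (mode=%s source=%s)",
        len(idx), len(field.records), cfg.mode, cfg.source,
    )
    return beam
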