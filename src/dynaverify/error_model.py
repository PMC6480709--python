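"""Controlled magnification of recorded leaf-position errors.

For sensitivity studies the position errors captured in a dynalog field
are rescaled so that the largest error reaches a target value Sigma. With
eps = P_e - P_a the error of a leaf, the altered actual position is

    P'_a = P_e - f * eps          (signed mode)
    P'_a = P_e - f * |eps|        (absolute mode)

with a single scale factor f = Sigma / MLE, where MLE is the maximum
absolute leaf error found in the field before scaling (over both banks
jointly). In absolute mode every altered leaf defines a *smaller* aperture
than the expected one, emulating errors that are predominantly in one
direction (e.g. a failing carriage); signed mode preserves the recorded
error directions. Errors at or below a floor (0.01 mm by default) are not
magnified; in absolute mode their sign is still folded so that no leaf
ever enlarges its aperture.

Magnified positions are clipped to the leaf travel range and pushed apart
if a leaf pair would overlap (aperture gap < 0); both events are counted
and logged, since at large Sigma the linear scaling can produce physically
impossible positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .dynalog_io import CM_PER_MM, DynalogField, leaf_errors, max_leaf_error
from .exceptions import MagnificationError

logger = logging.getLogger(__name__)

#: Sigma sweep (mm) used for the standard sensitivity experiment.
DEFAULT_SIGMA_SWEEP_MM = (2.0, 3.0, 4.0, 5.0, 10.0, 30.0)

#: Millennium-style leaf travel range in the opening-direction coordinate, cm.
LEAF_TRAVEL_CM = (-20.0, 20.0)


@dataclass(frozen=True)
class MagnificationConfig:
    """Target maximum error and scaling mode for :func:`magnify_errors`.

    Parameters
    ----------
    sigma_mm : float
        Target maximum leaf error Sigma after scaling, millimetres.
    mode : {"signed", "absolute"}
        Keep the sign of each error, or force every error aperture-shrinking
        by using its absolute value.
    floor_mm : float
        Errors with magnitude at or below this floor are not magnified.
    clip_travel : bool
        Clip altered positions to the leaf travel range and enforce a
        non-negative aperture gap per leaf pair.
    """

    sigma_mm: float
    mode: str = "signed"
    floor_mm: float = 0.01
    clip_travel: bool = True

    def validate(self) -> None:
        if not (self.sigma_mm > 0):
            raise MagnificationError("sigma_mm must be positive")
        if self.mode not in ("signed", "absolute"):
            raise MagnificationError(f"unknown mode {self.mode!r}")
        if self.floor_mm < 0:
            raise MagnificationError("floor_mm must be >= 0")


def scale_factor(field: DynalogField, sigma_mm: float) -> float:
    """f = Sigma / MLE, from the field's pre-scaling maximum leaf error."""
    mle = max_leaf_error(field)
    if mle <= 0:
        raise MagnificationError("field has no leaf error to magnify")
    return sigma_mm / mle


def magnify_errors(field: DynalogField, cfg: MagnificationConfig) -> DynalogField:
    """Return a new field with actual positions replaced by magnified ones.

    Expected positions are unchanged. The post-condition (when no clipping
    triggers) is ``max_leaf_error(result) == cfg.sigma_mm`` because
    ``f * MLE = Sigma`` by construction.
    """
    cfg.validate()
    mle = max_leaf_error(field)
    if mle <= cfg.floor_mm:
        raise MagnificationError(
            f"maximum leaf error {mle:.4f} mm is at/below the magnification "
            f"floor {cfg.floor_mm} mm; nothing to magnify"
        )
    f = cfg.sigma_mm / mle

    expected = field.expected
    eps = leaf_errors(field)                       # cm
    mag = eps if cfg.mode == "signed" else np.abs(eps)
    floor_cm = cfg.floor_mm * CM_PER_MM
    small = np.abs(eps) <= floor_cm
    new_actual = expected - f * mag
    # below-floor errors are not magnified; in absolute mode their sign is
    # still folded so no leaf ever enlarges its aperture
    small_vals = field.actual if cfg.mode == "signed" else expected - np.abs(eps)
    new_actual[small] = small_vals[small]

    n_clipped = 0
    if cfg.clip_travel:
        lo, hi = LEAF_TRAVEL_CM
        out_of_range = (new_actual < lo) | (new_actual > hi)
        n_clipped += int(np.sum(out_of_range))
        new_actual = np.clip(new_actual, lo, hi)
        # collision guard: opening coordinates a + b must stay >= 0
        nb = field.leaf_count_per_bank
        a = new_actual[:, :nb]
        b = new_actual[:, nb:]
        gap = a + b
        bad = gap < 0
        if np.any(bad):
            n_clipped += int(np.sum(bad))
            shift = np.where(bad, -gap / 2.0, 0.0)
            a = a + shift
            b = b + shift
            new_actual = np.concatenate([a, b], axis=1)
        if n_clipped:
            logger.warning(
                "magnification to sigma=%.1f mm clipped %d leaf positions",
                cfg.sigma_mm, n_clipped,
            )

    records = [
        replace(r, actual_cm=new_actual[i].copy())
        for i, r in enumerate(field.records)
    ]
    return DynalogField(records, field.leaf_count_per_bank, field.tick_ms)
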