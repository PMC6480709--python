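"""End-to-end verification workflow.

Ties the pipeline together: merge the A/B dynalog pair, reconstruct one
beam from the *expected* and one from the *actual* leaf positions, compute
both doses with the toy engine on a phantom, and compare them per
structure (PA, GPR at the configured criteria, and optionally
alpha/Delta), together with the field's leaf-error statistics (RMS, MLE).

The verdict follows the percentage-of-agreement rule: the delivery fails
verification when the PA of any target (PTV) structure drops to or below
the threshold, 99% by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dose_compare import ComparisonReport, GammaCriteria, compare
from .dynalog_io import DynalogField, max_leaf_error, rms_error
from .reconstruction import ReconstructionConfig, reconstruct
from .toy_dose import KernelConfig, Phantom, compute_dose

#: PA at or below this value fails treatment verification.
DEFAULT_PA_FAIL_THRESHOLD = 99.0


@dataclass(frozen=True)
class VerificationConfig:
    """Settings for :func:`verify_delivery`."""

    mode: str = "UR"
    interval_ms: int | None = None
    tolerance_mm: float = 0.0
    criteria: tuple[GammaCriteria, ...] = (GammaCriteria(2, 2), GammaCriteria(3, 3))
    pa_fail_threshold: float = DEFAULT_PA_FAIL_THRESHOLD
    with_alpha_delta: bool = False
    kernel: KernelConfig = field(default_factory=KernelConfig)
    meterset_mu: float = 100.0


def verify_delivery(field_: DynalogField, phantom: Phantom,
                    config: VerificationConfig = VerificationConfig()
                    ) -> ComparisonReport:
    """Expected-vs-actual dose verification of one delivered field.

    The expected-position reconstruction provides the reference dose and
    the actual-position reconstruction the evaluated dose; both use the
    same sampling mode so any disagreement is attributable to leaf errors.
    """
    common = dict(mode=config.mode, interval_ms=config.interval_ms,
                  tolerance_mm=config.tolerance_mm)
    beam_exp = reconstruct(field_, ReconstructionConfig(source="expected", **common),
                           meterset_mu=config.meterset_mu)
    beam_act = reconstruct(field_, ReconstructionConfig(source="actual", **common),
                           meterset_mu=config.meterset_mu)

    dose_exp = compute_dose(beam_exp, phantom, config.kernel)
    dose_act = compute_dose(beam_act, phantom, config.kernel)

    report = compare(
        dose_exp, dose_act, phantom.structure_masks(),
        criteria_list=config.criteria,
        with_alpha_delta=config.with_alpha_delta,
        body_mask_name="body" if "body" in phantom.masks else None,
    )
    report.rms_mm = rms_error(field_)
    report.mle_mm = max_leaf_error(field_)

    targets = [n for n in report.structures if "ptv" in n.lower()]
    if not targets:
        targets = list(report.structures)
    worst = min(report.structures[n]["pa"] for n in targets)
    report.verdict = "pass" if worst > config.pa_fail_threshold else "fail"
    return report
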