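"""Deterministic toy dose engine for reconstructed-plan comparison.

This is deliberately *not* a radiation-transport model: no scatter, no
heterogeneity, no tongue-and-groove, no MU-to-Gy calibration. It exists so
that plans reconstructed from dynalogs produce comparable 3D dose grids
with physically sensible behaviour — dose is linear in meterset, additive
over beams, and shrinking any leaf aperture can only decrease dose — which
is exactly what the PA / GPR / alpha-Delta pipelines need to respond to
leaf-position errors in the right direction.

Model per control-point interval: the mean aperture of the interval's two
bounding control points is rendered as a binary fluence map on the
isocenter plane (jaw ∩ MLC opening per leaf strip), blurred with a
Gaussian penumbra; every voxel is projected through the interval's mean
gantry direction onto that plane with simple cone divergence (source-axis
distance SAD) and picks up the fluence there, attenuated exponentially
with depth along the beam. Interval doses are summed weighted by the
interval's meterset fraction, and scaled by the beam meterset.

Optional Gaussian noise with a given relative sigma emulates the
statistical uncertainty of a Monte Carlo dose and fills the grid's
``sigma`` field (for alpha/Delta testing); it is seeded and off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .dose_compare import DoseGrid, StructureMask
from .exceptions import DynaverifyError
from .plan_model import Beam, Plan


@dataclass
class Phantom:
    """Voxel phantom: geometry plus body / PTV / OAR masks."""

    shape: tuple[int, int, int]
    spacing_cm: np.ndarray
    origin_cm: np.ndarray
    masks: dict[str, np.ndarray]          # name -> boolean array
    isocenter_cm: np.ndarray = None

    def __post_init__(self):
        self.spacing_cm = np.asarray(self.spacing_cm, dtype=float)
        self.origin_cm = np.asarray(self.origin_cm, dtype=float)
        if self.isocenter_cm is None:
            self.isocenter_cm = self.origin_cm + (
                (np.asarray(self.shape) - 1) / 2.0
            ) * self.spacing_cm
        self.isocenter_cm = np.asarray(self.isocenter_cm, dtype=float)
        for name, m in self.masks.items():
            if m.shape != tuple(self.shape):
                raise DynaverifyError(f"mask {name!r} not congruent with phantom")

    def structure_masks(self) -> dict[str, StructureMask]:
        return {
            name: StructureMask(name, m, self.spacing_cm)
            for name, m in self.masks.items()
        }

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) physical centre of every voxel, cm."""
        ax = [self.origin_cm[k] + np.arange(self.shape[k]) * self.spacing_cm[k]
              for k in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)


@dataclass(frozen=True)
class KernelConfig:
    """Toy-engine parameters.

    penumbra_sigma_cm : Gaussian blur of the aperture fluence (cm at iso).
    mu_attenuation_per_cm : exponential depth-attenuation coefficient.
    sad_cm : source-axis distance used for cone divergence.
    buildup_cm : depth offset so the isocenter plane sits at positive depth.
    fluence_resolution_cm : pixel size of the 2D fluence map.
    noise_relative_sigma : if > 0, multiplicative Gaussian noise level
        (fraction of the local dose, with an absolute floor of the same
        fraction of the maximum dose) applied after summation; seeded.
    """

    penumbra_sigma_cm: float = 0.3
    mu_attenuation_per_cm: float = 0.04
    sad_cm: float = 100.0
    buildup_cm: float = 10.0
    fluence_resolution_cm: float = 0.25
    fluence_halfwidth_cm: float = 12.0
    leaf_width_cm: float = 0.5
    noise_relative_sigma: float = 0.0
    noise_seed: int = 0


def _aperture_fluence(mlc_cm: np.ndarray, jaws_cm: np.ndarray,
                      leaf_count_per_bank: int, cfg: KernelConfig,
                      u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Binary open-field map on the isocenter plane, then penumbra blur.

    ``u`` runs along leaf travel, ``v`` across the leaf strips. Leaf pair
    j covers v in [(j - n/2) * w, (j + 1 - n/2) * w] and opens u in
    [-pos_B_j, +pos_A_j]; the jaws clip the whole field.
    """
    n = leaf_count_per_bank
    w = cfg.leaf_width_cm
    uu, vv = np.meshgrid(u, v, indexing="ij")
    strip = np.floor(vv / w + n / 2.0).astype(int)
    inside = (strip >= 0) & (strip < n)
    strip_c = np.clip(strip, 0, n - 1)
    a = mlc_cm[:n][strip_c]
    b = mlc_cm[n:][strip_c]
    # strict bounds: a zero-width aperture exposes no pixels
    open_mlc = inside & (uu > -b) & (uu < a)
    open_jaw = ((uu >= -jaws_cm[0]) & (uu <= jaws_cm[1])
                & (vv >= -jaws_cm[2]) & (vv <= jaws_cm[3]))
    fluence = (open_mlc & open_jaw).astype(float)
    sigma_px = cfg.penumbra_sigma_cm / cfg.fluence_resolution_cm
    return gaussian_filter(fluence, sigma_px, mode="constant")


def compute_dose(beam: Beam | Plan, phantom: Phantom,
                 config: KernelConfig = KernelConfig()) -> DoseGrid:
    """Deterministic toy dose of a beam (or sum over a plan's beams)."""
    if isinstance(beam, Plan):
        total = None
        for b in beam.beams:
            d = compute_dose(b, phantom, config)
            total = d if total is None else DoseGrid(
                total.values + d.values, total.spacing_cm, total.origin_cm
            )
        return _with_noise(total, config)

    beam.validate()
    cfg = config
    half = cfg.fluence_halfwidth_cm
    res = cfg.fluence_resolution_cm
    u = np.arange(-half, half + res / 2, res)
    v = np.arange(-half, half + res / 2, res)

    r = phantom.voxel_centers() - phantom.isocenter_cm   # (N, 3)
    dose = np.zeros(r.shape[0])

    weights = beam.weights
    cps = beam.control_points
    for i in range(len(cps) - 1):
        dw = weights[i + 1] - weights[i]
        if dw <= 0:
            continue
        cp0, cp1 = cps[i], cps[i + 1]
        mlc = 0.5 * (cp0.mlc_cm + cp1.mlc_cm)
        jaws = 0.5 * (cp0.jaws_cm + cp1.jaws_cm)
        dg = (cp1.gantry_deg - cp0.gantry_deg + 180.0) % 360.0 - 180.0
        g = np.deg2rad(cp0.gantry_deg + 0.5 * dg)

        fluence = _aperture_fluence(mlc, jaws, beam.leaf_count_per_bank, cfg, u, v)

        # beam frame: source direction s = (sin g, 0, cos g); lateral axes
        # e_u = (cos g, 0, -sin g) (leaf travel), e_v = (0, 1, 0) (strips)
        sing, cosg = np.sin(g), np.cos(g)
        depth_axis = r[:, 0] * sing + r[:, 2] * cosg       # toward source
        w_depth = -depth_axis                               # downstream of iso
        ru = r[:, 0] * cosg - r[:, 2] * sing
        rv = r[:, 1]
        scale = cfg.sad_cm / np.maximum(cfg.sad_cm + w_depth, 1e-6)
        pu = ru * scale
        pv = rv * scale

        iu = (pu + half) / res
        iv = (pv + half) / res
        f = map_coordinates(fluence, np.stack([iu, iv]), order=1, mode="constant")
        atten = np.exp(-cfg.mu_attenuation_per_cm
                       * np.maximum(w_depth + cfg.buildup_cm, 0.0))
        dose += dw * f * atten

    dose *= max(beam.meterset_mu, 1.0) / 100.0
    grid = DoseGrid(
        dose.reshape(phantom.shape), phantom.spacing_cm, phantom.origin_cm
    )
    return _with_noise(grid, config)


def _with_noise(grid: DoseGrid, cfg: KernelConfig) -> DoseGrid:
    """Add seeded Gaussian noise emulating Monte Carlo uncertainty."""
    if cfg.noise_relative_sigma <= 0:
        return grid
    rng = np.random.default_rng(cfg.noise_seed)
    dmax = float(grid.values.max())
    sigma = cfg.noise_relative_sigma * np.maximum(grid.values, 0.1 * dmax)
    noisy = np.maximum(grid.values + rng.normal(0.0, 1.0, grid.shape) * sigma, 0.0)
    return DoseGrid(noisy, grid.spacing_cm, grid.origin_cm, sigma=sigma)
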