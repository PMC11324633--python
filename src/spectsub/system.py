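"""Acquisition model: geometry, forward/back projection, calibration, noise.

The system is a deliberately simple parallel-beam model — uniformly spaced
views over a circular arc, attenuation along each ray, and a
depth-dependent Gaussian collimator PSF.  It is shared by the simulation
and the reconstruction, so every subtraction strategy sees exactly the
same physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._projector import Projector
from .volumes import ActivityVolume, AttenuationVolume

__all__ = [
    "SystemGeometry",
    "ProjectionSet",
    "SystemModel",
    "forward_project",
    "back_project",
    "add_poisson_noise",
    "calibrate_counts",
]

#: Default system sensitivity, counts per second per MBq in the field of
#: view.  Chosen so a 75 MBq injection imaged for 600 s yields 1e6 counts,
#: a realistic level for a short interventional scan.
DEFAULT_SENSITIVITY_CPS_PER_MBQ = 1.0e6 / (75.0 * 600.0)

#: Mean photon transmission of the default torso at 140 keV, folded into the
#: count calibration so that the configured sensitivity is realized at the
#: detector for a default-sized patient.  Objects that attenuate more or
#: less than this reference yield proportionally fewer or more counts.
REFERENCE_TRANSMISSION = 0.127


@dataclass
class SystemGeometry:
    """Acquisition geometry and calibration.

    ``detector_shape``/``detector_pixel_mm`` default to the reconstruction
    grid's in-plane x size and axial z size at the voxel pitch; this
    projector requires that matched sampling.
    """

    n_views: int = 120
    arc_deg: float = 360.0
    detector_shape: tuple[int, int] | None = None
    detector_pixel_mm: float | None = None
    psf_fwhm0_mm: float = 4.0
    psf_slope_mm_per_mm: float = 0.05
    sensitivity_cps_per_MBq: float = DEFAULT_SENSITIVITY_CPS_PER_MBQ
    scan_duration_s: float = 600.0
    reference_transmission: float = REFERENCE_TRANSMISSION

    def __post_init__(self):
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.psf_fwhm0_mm < 0 or self.psf_slope_mm_per_mm < 0:
            raise ValueError("PSF parameters must be non-negative")

    @property
    def angles_deg(self) -> np.ndarray:
        """View angles, uniformly spaced over the arc."""
        return np.arange(self.n_views) * self.arc_deg / self.n_views

    @property
    def count_scale(self) -> float:
        """Counts per (MBq * view) applied to every projection bin."""
        return (
            self.sensitivity_cps_per_MBq
            * self.scan_duration_s
            / self.n_views
            / self.reference_transmission
        )

    def without_psf(self) -> "SystemGeometry":
        return replace(self, psf_fwhm0_mm=0.0, psf_slope_mm_per_mm=0.0)


@dataclass
class ProjectionSet:
    """A stack of 2D projections, one per view.

    ``counts`` holds expected (real-valued) counts for noise-free data and
    integer-valued counts after Poisson sampling.  ``noisy`` marks sampled
    data; ``clipped`` marks data produced by truncating negatives (as in
    projection-domain subtraction).
    """

    counts: np.ndarray
    angles_deg: np.ndarray
    noisy: bool = False
    clipped: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.counts.ndim != 3:
            raise ValueError("counts must be [view, u, v]")
        if self.counts.shape[0] != len(self.angles_deg):
            raise ValueError("one angle per view required")
        if not self.clipped and self.counts.min() < -1e-9:
            raise ValueError("negative counts in a non-clipped projection set")

    @property
    def n_views(self) -> int:
        return self.counts.shape[0]

    def total(self) -> float:
        return float(self.counts.sum())

    def same_geometry(self, other: "ProjectionSet") -> bool:
        return self.counts.shape == other.counts.shape and np.allclose(
            self.angles_deg, other.angles_deg
        )


class SystemModel:
    """Projector bound to one attenuation map and geometry.

    Precomputes per-view rotation operators and transmission maps once so
    that repeated OSEM passes (and all subtraction strategies sharing the
    same scan geometry) reuse them.
    """

    def __init__(self, mu: AttenuationVolume, geom: SystemGeometry):
        self.mu = mu
        self.geom = geom
        nx, ny, nz = mu.grid_shape
        if geom.detector_shape is not None and tuple(geom.detector_shape) != (nx, nz):
            raise ValueError(
                f"detector shape {geom.detector_shape} must match the grid ({nx}, {nz})"
            )
        if (
            geom.detector_pixel_mm is not None
            and abs(geom.detector_pixel_mm - mu.voxel_size_mm) > 1e-9
        ):
            raise ValueError("detector pixel must match the voxel size")
        self._proj = Projector(
            mu.values,
            mu.voxel_size_mm,
            geom.angles_deg,
            geom.psf_fwhm0_mm,
            geom.psf_slope_mm_per_mm,
            geom.count_scale,
        )

    @property
    def grid_shape(self):
        return self.mu.grid_shape

    def forward(self, values: np.ndarray, views=None) -> np.ndarray:
        return self._proj.forward(values, views)

    def backproject(self, proj: np.ndarray, views=None) -> np.ndarray:
        return self._proj.backproject(proj, views)


def forward_project(
    vol: ActivityVolume, mu: AttenuationVolume, geom: SystemGeometry
) -> ProjectionSet:
    """Expected-count projections of an activity volume.

    Linear in the activity; includes attenuation to the detector and the
    depth-dependent collimator blur; scaled by sensitivity x duration.
    """
    if not vol.same_grid(mu):
        raise ValueError("activity and attenuation volumes must share a grid")
    if vol.values.min() < 0:
        raise ValueError("cannot forward project a volume with negative activity")
    model = SystemModel(mu, geom)
    return ProjectionSet(model.forward(vol.values), geom.angles_deg)


def back_project(
    proj: ProjectionSet, mu: AttenuationVolume, geom: SystemGeometry
) -> np.ndarray:
    """Exact adjoint of :func:`forward_project`; returns a volume-shaped array."""
    if proj.n_views != geom.n_views or not np.allclose(proj.angles_deg, geom.angles_deg):
        raise ValueError("projection set does not match the geometry")
    model = SystemModel(mu, geom)
    return model.backproject(proj.counts)


def add_poisson_noise(proj: ProjectionSet, seed) -> ProjectionSet:
    """One Poisson realization of an expected-count projection set.

    ``seed`` may be an int or any numpy ``SeedSequence``-compatible entropy;
    identical seeds give identical realizations.
    """
    if proj.counts.min() < 0:
        raise ValueError("expected counts must be non-negative before sampling")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(proj.counts).astype(np.float64)
    return ProjectionSet(noisy, proj.angles_deg.copy(), noisy=True, clipped=proj.clipped)


def calibrate_counts(total_activity_MBq: float, geom: SystemGeometry) -> float:
    """Expected total counts over all views for a given total activity.

    This is the calibration identity ``activity x sensitivity x duration``;
    it is exact for an object with the reference transmission and
    proportionally lower/higher for more/less attenuating objects.
    """
    if total_activity_MBq < 0:
        raise ValueError("activity must be non-negative")
    return total_activity_MBq * geom.sensitivity_cps_per_MBq * geom.scan_duration_s
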