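"""OSEM reconstruction and the four SPECT subtraction strategies.

All strategies estimate the *difference* distribution — the tracer added by
a second injection — from a baseline scan (``y_pre``) and a combined scan
acquired after the second injection (``y_post``):

- ``image_subtraction``: reconstruct both scans independently and subtract
  the images at matched iteration counts; negatives are kept.
- ``projection_subtraction``: subtract the measured projections, truncate
  negatives to zero, and reconstruct the clipped difference projections.
- ``projection_addition``: reconstruct against ``y_post`` with the measured
  pre-injection counts entering the forward model as an additive background
  term (the scatter-compensation trick applied to subtraction).
- ``image_addition``: jointly reconstruct the difference image and the
  baseline image; their summed forward projections are corrected against
  ``y_post`` while the baseline image is additionally corrected against
  ``y_pre``.

``conventional`` reconstructs a separately acquired scan of the difference
distribution alone and serves as the reference for what a two-session
protocol would achieve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .system import ProjectionSet, SystemModel

__all__ = [
    "METHODS",
    "ReconSettings",
    "ReconTrace",
    "osem",
    "reconstruct_conventional",
    "image_subtraction",
    "projection_subtraction",
    "projection_addition",
    "image_addition",
    "SPECTSubtraction",
    "SPECTSubtractionResults",
]

METHODS = (
    "conventional",
    "image_subtraction",
    "projection_subtraction",
    "projection_addition",
    "image_addition",
)

#: Denominator clamp for the multiplicative EM updates.
EPS = 1e-12


@dataclass
class ReconSettings:
    n_iterations: int = 25
    n_subsets: int = 8
    method: str = "conventional"
    snapshot_every: int = 1

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")


@dataclass
class ReconTrace:
    """Per-iteration snapshots of the reconstructed difference image.

    For ``image_addition`` the jointly reconstructed baseline images are
    stored in ``pre_volumes``; for ``image_subtraction`` the two
    independent reconstructions are kept there as well so baseline-image
    quality can be evaluated without a second run.
    """

    volumes: list[np.ndarray]
    method: str
    settings: ReconSettings
    voxel_size_mm: float
    pre_volumes: list[np.ndarray] | None = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def final(self) -> np.ndarray:
        return self.volumes[-1]


def _subset_views(n_views: int, n_subsets: int) -> list[np.ndarray]:
    """Stride-interleaved subsets in bit-reversed processing order."""
    if n_views % n_subsets:
        raise ValueError(f"n_subsets={n_subsets} must divide n_views={n_views}")
    order = list(range(n_subsets))
    bits = n_subsets.bit_length() - 1
    if 2**bits == n_subsets and bits > 0:
        order = [int(f"{s:0{bits}b}"[::-1], 2) for s in range(n_subsets)]
    return [np.arange(s, n_views, n_subsets) for s in order]


def _uniform_init(total_counts: float, model: SystemModel, support: np.ndarray) -> np.ndarray:
    """Scale-matched uniform start: measured counts mapped back to activity
    per voxel through the system sensitivity."""
    geom = model.geom
    s_eff = geom.count_scale * geom.n_views  # counts per MBq over the full scan
    n_vox = int(support.sum())
    x = np.zeros(model.grid_shape)
    if n_vox and total_counts > 0:
        x[support] = total_counts / s_eff / n_vox
    return x


def _em_factor(y_s, f_s, bg_s, sens_s, model, views, support):
    """One multiplicative EM correction factor A^T[y / (A x + b)] / A^T 1."""
    ratio = y_s / np.maximum(f_s + bg_s, EPS)
    back = model.backproject(ratio, views)
    factor = back / np.maximum(sens_s, EPS)
    factor[~support] = 0.0
    return factor


def osem(
    y: ProjectionSet,
    model: SystemModel,
    settings: ReconSettings | None = None,
    background: ProjectionSet | None = None,
    callback: Callable[[int, np.ndarray], None] | None = None,
) -> ReconTrace:
    """Ordered-subset EM reconstruction of a single projection set.

    Per subset ``s``: ``x <- x / (A_s^T 1) * A_s^T[y_s / (A_s x + b_s)]``
    with ``b`` an optional fixed additive background in count units.
    Iterates are non-negative; voxels with zero sensitivity are frozen at
    zero; denominators are clamped at ``1e-12``.
    """
    settings = settings or ReconSettings()
    if y.counts.min() < 0:
        raise ValueError("OSEM requires non-negative measured counts")
    if background is not None:
        if background.counts.shape != y.counts.shape:
            raise ValueError("background projections must match the data shape")
        if background.counts.min() < 0:
            raise ValueError("background term must be non-negative")
    subsets = _subset_views(y.n_views, settings.n_subsets)
    sens = [model.backproject(np.ones((len(v),) + (model.grid_shape[0], model.grid_shape[2])), v) for v in subsets]
    support = sum(s for s in sens) > 0
    x = _uniform_init(y.total(), model, support)

    volumes = []
    for it in range(settings.n_iterations):
        for views, sens_s in zip(subsets, sens):
            f_s = model.forward(x, views)
            bg_s = background.counts[views] if background is not None else 0.0
            x = x * _em_factor(y.counts[views], f_s, bg_s, sens_s, model, views, support)
        if (it + 1) % settings.snapshot_every == 0 or it == settings.n_iterations - 1:
            volumes.append(x.copy())
        if callback is not None:
            callback(it + 1, x)
    return ReconTrace(
        volumes=volumes,
        method=settings.method,
        settings=settings,
        voxel_size_mm=model.mu.voxel_size_mm,
        provenance={"total_counts": y.total(), "background": background is not None},
    )


def reconstruct_conventional(
    y_diff_scan: ProjectionSet, model: SystemModel, settings: ReconSettings | None = None
) -> ReconTrace:
    """Plain OSEM on a separately acquired scan of the difference
    distribution — the two-session reference."""
    settings = replace(settings or ReconSettings(), method="conventional")
    return osem(y_diff_scan, model, settings)


def image_subtraction(
    y_pre: ProjectionSet,
    y_post: ProjectionSet,
    model: SystemModel,
    settings: ReconSettings | None = None,
) -> ReconTrace:
    """Independent reconstructions subtracted at matched iteration counts.

    Negative voxels in the difference are preserved.  The trace element at
    iteration k is ``recon_post[k] - recon_pre[k]``.
    """
    if not y_pre.same_geometry(y_post):
        raise ValueError("pre and post scans must share acquisition geometry")
    settings = replace(settings or ReconSettings(), method="image_subtraction")
    t_post = osem(y_post, model, settings)
    t_pre = osem(y_pre, model, settings)
    diffs = [p - q for p, q in zip(t_post.volumes, t_pre.volumes)]
    return ReconTrace(
        volumes=diffs,
        method="image_subtraction",
        settings=settings,
        voxel_size_mm=model.mu.voxel_size_mm,
        pre_volumes=t_pre.volumes,
        provenance={"post_volumes": t_post.volumes},
    )


def projection_subtraction(
    y_pre: ProjectionSet,
    y_post: ProjectionSet,
    model: SystemModel,
    settings: ReconSettings | None = None,
) -> ReconTrace:
    """OSEM on the truncated difference projections ``max(y_post - y_pre, 0)``."""
    if not y_pre.same_geometry(y_post):
        raise ValueError("pre and post scans must share acquisition geometry")
    settings = replace(settings or ReconSettings(), method="projection_subtraction")
    raw = y_post.counts - y_pre.counts
    clipped_fraction = float(np.mean(raw < 0))
    d = ProjectionSet(
        np.maximum(raw, 0.0),
        y_post.angles_deg.copy(),
        noisy=y_post.noisy or y_pre.noisy,
        clipped=True,
    )
    trace = osem(d, model, settings)
    trace.method = "projection_subtraction"
    trace.provenance["clipped_fraction"] = clipped_fraction
    return trace


def projection_addition(
    y_pre: ProjectionSet,
    y_post: ProjectionSet,
    model: SystemModel,
    settings: ReconSettings | None = None,
) -> ReconTrace:
    """OSEM against ``y_post`` with the measured pre-injection counts as a
    fixed additive background in the forward model."""
    if not y_pre.same_geometry(y_post):
        raise ValueError("pre and post scans must share acquisition geometry")
    settings = replace(settings or ReconSettings(), method="projection_addition")
    trace = osem(y_post, model, settings, background=y_pre)
    trace.method = "projection_addition"
    return trace


def image_addition(
    y_pre: ProjectionSet,
    y_post: ProjectionSet,
    model: SystemModel,
    settings: ReconSettings | None = None,
) -> ReconTrace:
    """Joint reconstruction of the difference and baseline images.

    Per subset, with forward projections ``f_d = A x_diff`` and
    ``f_p = A x_pre``:

    - ``x_diff`` receives the multiplicative EM factor from the post-scan
      data term ``y_post / (f_d + f_p)``;
    - ``x_pre`` receives the product of the factors from the pre-scan term
      ``y_pre / f_p`` and the post-scan term.

    Both images start uniform and scaled to their own data (the baseline
    from the pre-scan counts, the difference from the count excess of the
    post scan), and both remain non-negative.  When the pre scan carries no
    counts the baseline image stays at zero and the update for ``x_diff``
    reduces exactly to conventional OSEM on ``y_post``.
    """
    if not y_pre.same_geometry(y_post):
        raise ValueError("pre and post scans must share acquisition geometry")
    settings = replace(settings or ReconSettings(), method="image_addition")
    subsets = _subset_views(y_post.n_views, settings.n_subsets)
    sens = [
        model.backproject(
            np.ones((len(v),) + (model.grid_shape[0], model.grid_shape[2])), v
        )
        for v in subsets
    ]
    support = sum(s for s in sens) > 0
    x_p = _uniform_init(y_pre.total(), model, support)
    excess = max(y_post.total() - y_pre.total(), 0.0)
    x_d = _uniform_init(excess if excess > 0 else y_post.total(), model, support)

    volumes, pre_volumes = [], []
    for it in range(settings.n_iterations):
        for views, sens_s in zip(subsets, sens):
            f_d = model.forward(x_d, views)
            f_p = model.forward(x_p, views) if x_p.any() else np.zeros_like(f_d)
            post_factor = _em_factor(
                y_post.counts[views], f_d, f_p, sens_s, model, views, support
            )
            x_d = x_d * post_factor
            if x_p.any():
                pre_factor = _em_factor(
                    y_pre.counts[views], f_p, 0.0, sens_s, model, views, support
                )
                x_p = x_p * pre_factor * post_factor
        volumes.append(x_d.copy())
        pre_volumes.append(x_p.copy())
    return ReconTrace(
        volumes=volumes,
        method="image_addition",
        settings=settings,
        voxel_size_mm=model.mu.voxel_size_mm,
        pre_volumes=pre_volumes,
        provenance={"joint": True},
    )


_METHOD_FUNCS = {
    "image_subtraction": image_subtraction,
    "projection_subtraction": projection_subtraction,
    "projection_addition": projection_addition,
    "image_addition": image_addition,
}


class SPECTSubtraction:
    """Difference-image estimation model for a pair of SPECT scans.

    Statsmodels-style front end: construct from the data (the measured
    projection sets, an attenuation map and the acquisition geometry),
    choose a subtraction ``method``, and call :meth:`fit` to run the
    iterative reconstruction.  ``method='conventional'`` treats ``y_post``
    as a directly acquired scan of the difference distribution and ignores
    ``y_pre``.

    Examples
    --------
    >>> model = SPECTSubtraction(y_post, y_pre, mu, geom,
    ...                          method="image_addition")   # doctest: +SKIP
    >>> res = model.fit(n_iterations=25, n_subsets=8)       # doctest: +SKIP
    >>> res.difference.shape                                # doctest: +SKIP
    (54, 54, 48)
    """

    def __init__(self, y_post, y_pre=None, mu=None, geometry=None, method="image_subtraction"):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
        if method != "conventional" and y_pre is None:
            raise ValueError(f"{method} requires a pre-injection scan")
        if mu is None or (geometry is None and not isinstance(mu, SystemModel)):
            raise ValueError("an attenuation map and a geometry are required")
        self.y_post = y_post
        self.y_pre = y_pre
        self.method = method
        self.model = mu if isinstance(mu, SystemModel) else SystemModel(mu, geometry)

    def fit(self, n_iterations: int = 25, n_subsets: int = 8) -> "SPECTSubtractionResults":
        settings = ReconSettings(
            n_iterations=n_iterations, n_subsets=n_subsets, method=self.method
        )
        if self.method == "conventional":
            trace = reconstruct_conventional(self.y_post, self.model, settings)
        else:
            trace = _METHOD_FUNCS[self.method](self.y_pre, self.y_post, self.model, settings)
        return SPECTSubtractionResults(self, trace)


class SPECTSubtractionResults:
    """Fitted difference image plus its full per-iteration trace."""

    def __init__(self, model: SPECTSubtraction, trace: ReconTrace):
        self.model = model
        self.trace = trace

    @property
    def difference(self) -> np.ndarray:
        """The difference-image estimate after the final iteration."""
        return self.trace.final

    @property
    def pre_image(self) -> np.ndarray | None:
        """The baseline-image estimate, where the method produces one."""
        if self.trace.pre_volumes:
            return self.trace.pre_volumes[-1]
        return None

    def metrics(self, masks, true_diff) -> "pandas.DataFrame":  # noqa: F821
        """Per-iteration VOI metrics of the difference trace."""
        from .metrics import trace_metrics, true_voi_means

        return trace_metrics(self.trace, masks, true_voi_means(true_diff, masks))

    def summary(self) -> str:
        t = self.trace
        s = t.settings
        lines = [
            "SPECT difference reconstruction",
            "=" * 34,
            f"method:          {t.method}",
            f"iterations:      {s.n_iterations} (x {s.n_subsets} subsets)",
            f"grid:            {t.final.shape} @ {t.voxel_size_mm:g} mm",
            f"total activity:  {t.final.sum():.3f} MBq (difference image)",
            f"min voxel:       {t.final.min():.5f} MBq",
        ]
        if "clipped_fraction" in t.provenance:
            lines.append(f"clipped bins:    {100 * t.provenance['clipped_fraction']:.2f} %")
        return "\n".join(lines)
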