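"""Synthetic phase-separated monolayer images with known ground truth.

Mixed DOPC–DPPC films phase-separate into a fluid DOPC-rich matrix with
embedded gel-phase DPPC-rich domains that sit higher (Δh a few tenths of
a nm) and carry a more positive surface potential (ΔV a few hundred mV).
This module renders paired topography/potential images of such films so
the segmentation and cross-section estimators can be validated against a
known mask: two domain morphologies (isolated disks/polygons, or
irregular coagulated blobs), Langmuir–Blodgett deposition streaks along
one axis, a plane tilt, finite tip–sample averaging on the potential
channel, and white Gaussian noise per channel.

Presets mirror the three film compositions studied experimentally
(a pure-lipid control and films doped with 12-3-12 or 16-3-16 gemini
surfactant), with (Δh, ΔV) of (0.33 nm, 336 mV), (0.28 nm, 304 mV) and
(0.57 nm, 658 mV) respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .scan_io import ScanImage

__all__ = [
    "MonolayerSpec",
    "GroundTruth",
    "generate_mask",
    "render_pair",
    "control_like_spec",
    "gs12_like_spec",
    "gs16_like_spec",
    "PRESETS",
]

#: tolerance on |realized - target| coverage (area fraction)
COVERAGE_TOL = 0.02


@dataclass(frozen=True)
class MonolayerSpec:
    """Ground-truth parameters for one synthetic film.

    ``coverage`` is the target area fraction of the high (DPPC-like)
    phase; ``delta_h`` / ``delta_v`` are the high-minus-low offsets in
    nm / mV.  ``tilt`` is (nm per pixel along rows, along columns).
    ``tip_blur_sigma`` (nm) applies to the potential channel only and
    models the longer-range electrostatic tip–sample averaging of KPFM.
    ``seed`` fixes all randomness.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 10.0
    coverage: float = 0.27
    delta_h: float = 0.33
    delta_v: float = 336.0
    base_h: float = 0.0
    base_v: float = 0.0
    morphology: str = "disks"
    n_domains: int = 40
    noise_sigma_h: float = 0.05
    noise_sigma_v: float = 20.0
    streak_amplitude: float = 0.05
    streak_axis: str = "x"
    tilt: tuple[float, float] = (0.0, 0.0)
    tip_blur_sigma: float = 20.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage < 1.0):
            raise ValueError(f"coverage must be in (0, 1), got {self.coverage}")
        if self.morphology not in ("disks", "coagulated"):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if self.streak_axis not in ("x", "y"):
            raise ValueError(f"streak_axis must be 'x' or 'y', got {self.streak_axis!r}")
        for name in ("delta_h", "noise_sigma_h", "noise_sigma_v",
                     "streak_amplitude", "tip_blur_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.shape) < 16:
            raise ValueError(f"shape too small for domain synthesis: {self.shape}")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be > 0")


@dataclass
class GroundTruth:
    """Binary high-phase mask plus its exact realized coverage."""

    mask: np.ndarray
    realized_coverage: float
    spec: MonolayerSpec

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        exact = float(self.mask.mean())
        if abs(exact - self.realized_coverage) > 1e-12:
            raise ValueError("realized_coverage inconsistent with mask")


class CoverageUnreachableError(RuntimeError):
    """Disk placement could not reach the target coverage.

    Raised after a bounded number of attempts; try fewer, larger domains
    (lower ``n_domains``) or a lower target coverage.
    """


def generate_mask(spec: MonolayerSpec) -> GroundTruth:
    """Generate the binary high-phase mask for ``spec``.

    ``disks`` mode places non-overlapping disks or regular 5–8-gons by
    random sequential adsorption, radii from a lognormal law, until the
    realized coverage is within ±0.02 of target.  ``coagulated`` mode
    thresholds a Gaussian-smoothed random field (correlation length ~8
    pixels) at the quantile matching the target coverage, which yields
    irregular connected blobs resembling jointly coagulated domains.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.morphology == "coagulated":
        fld = gaussian_filter(rng.standard_normal(spec.shape), sigma=8.0, mode="wrap")
        thr = np.quantile(fld, 1.0 - spec.coverage)
        mask = fld > thr
    else:
        mask = _disks_mask(spec, rng)
    return GroundTruth(mask=mask, realized_coverage=float(mask.mean()), spec=spec)


def _disks_mask(spec: MonolayerSpec, rng: np.random.Generator) -> np.ndarray:
    nrow, ncol = spec.shape
    n_px = nrow * ncol
    target = spec.coverage
    # median radius such that n_domains mean-area disks tile the target fraction
    r_med = max(3.0, np.sqrt(target * n_px / (np.pi * spec.n_domains)))
    log_sigma = 0.3
    mask = np.zeros(spec.shape, dtype=bool)
    placed: list[tuple[float, float, float]] = []  # (row, col, radius)
    covered = 0
    max_attempts = 20000
    for _ in range(max_attempts):
        frac = covered / n_px
        if frac >= target - COVERAGE_TOL / 2:
            break
        r = float(rng.lognormal(np.log(r_med), log_sigma))
        r = min(r, min(nrow, ncol) / 4.0)
        remaining = (target + COVERAGE_TOL / 2) * n_px - covered
        if np.pi * r * r > remaining:
            r = max(2.0, np.sqrt(remaining / np.pi) * 0.95)
        cr = rng.uniform(r, nrow - r)
        cc = rng.uniform(r, ncol - r)
        if any((cr - p[0]) ** 2 + (cc - p[1]) ** 2 < (r + p[2] + 1.0) ** 2 for p in placed):
            continue
        if rng.random() < 0.5:
            rr, cc_idx = draw_disk((cr, cc), r, shape=spec.shape)
        else:
            n_sides = int(rng.integers(5, 9))
            theta = rng.uniform(0, 2 * np.pi) + np.linspace(0, 2 * np.pi, n_sides, endpoint=False)
            rr, cc_idx = draw_polygon(cr + r * np.sin(theta), cc + r * np.cos(theta),
                                      shape=spec.shape)
        new = np.count_nonzero(~mask[rr, cc_idx])
        if (covered + new) / n_px > target + COVERAGE_TOL / 2:
            continue
        mask[rr, cc_idx] = True
        covered += new
        placed.append((cr, cc, r))
    realized = covered / n_px
    if abs(realized - target) > COVERAGE_TOL:
        raise CoverageUnreachableError(
            f"disks mode reached coverage {realized:.3f}, target {target:.3f}: "
            "try fewer/larger domains (reduce n_domains) or lower coverage"
        )
    return mask


def _streaks(spec: MonolayerSpec, rng: np.random.Generator) -> np.ndarray:
    """Deposition streaks: smooth full-length ridges along streak_axis."""
    nrow, ncol = spec.shape
    # streaks run along the axis; their profile varies across it
    across = nrow if spec.streak_axis == "x" else ncol
    n_streaks = max(1, across // 20)
    coord = np.arange(across, dtype=float)
    profile = np.zeros(across)
    for _ in range(n_streaks):
        center = rng.uniform(0, across)
        width = rng.uniform(1.0, 3.0)
        amp = spec.streak_amplitude * rng.uniform(0.3, 1.0)
        profile += amp * np.exp(-0.5 * ((coord - center) / width) ** 2)
    if spec.streak_axis == "x":
        return np.broadcast_to(profile[:, None], spec.shape).copy()
    return np.broadcast_to(profile[None, :], spec.shape).copy()


def render_pair(truth: GroundTruth) -> tuple[ScanImage, ScanImage]:
    """Render (topography, potential) images from a ground-truth mask.

    Topography: ``base_h + delta_h*mask + tilt plane + streaks + noise``.
    Potential: ``base_v + delta_v*mask`` blurred by an isotropic Gaussian
    of width ``tip_blur_sigma`` (reflective boundary, mean-preserving),
    plus noise.  Both channels share the mask and pixel geometry.
    """
    spec = truth.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    nrow, ncol = spec.shape
    rows = np.arange(nrow, dtype=float)[:, None]
    cols = np.arange(ncol, dtype=float)[None, :]

    topo = spec.base_h + spec.delta_h * truth.mask.astype(float)
    topo = topo + spec.tilt[0] * rows + spec.tilt[1] * cols
    if spec.streak_amplitude > 0:
        topo = topo + _streaks(spec, rng)
    if spec.noise_sigma_h > 0:
        topo = topo + rng.normal(0.0, spec.noise_sigma_h, spec.shape)

    pot = spec.base_v + spec.delta_v * truth.mask.astype(float)
    if spec.tip_blur_sigma > 0:
        pot = gaussian_filter(pot, sigma=spec.tip_blur_sigma / spec.pixel_size,
                              mode="reflect")
    if spec.noise_sigma_v > 0:
        pot = pot + rng.normal(0.0, spec.noise_sigma_v, spec.shape)

    meta = {"composition": spec.label or spec.morphology, "seed": str(spec.seed)}
    return (
        ScanImage(topo, spec.pixel_size, "topography", dict(meta)),
        ScanImage(pot, spec.pixel_size, "potential", dict(meta)),
    )


def control_like_spec(**overrides) -> MonolayerSpec:
    """Preset emulating the pure-lipid 1:1 DOPC–DPPC control film.

    Disk/polygon domains at 27% coverage, Δh = 0.33 nm, ΔV = 336 mV.
    """
    spec = MonolayerSpec(coverage=0.27, delta_h=0.33, delta_v=336.0,
                         morphology="disks", label="control")
    return replace(spec, **overrides)


def gs12_like_spec(**overrides) -> MonolayerSpec:
    """Preset emulating the film doped with the short-tail (12-3-12) GS.

    Morphology and coverage like the control; Δh = 0.28 nm, ΔV = 304 mV.
    """
    spec = MonolayerSpec(coverage=0.27, delta_h=0.28, delta_v=304.0,
                         morphology="disks", label="gs12")
    return replace(spec, **overrides)


def gs16_like_spec(**overrides) -> MonolayerSpec:
    """Preset emulating the film doped with the long-tail (16-3-16) GS.

    Irregular coagulated domains at raised coverage; Δh = 0.57 nm,
    ΔV = 658 mV.
    """
    spec = MonolayerSpec(coverage=0.35, delta_h=0.57, delta_v=658.0,
                         morphology="coagulated", label="gs16")
    return replace(spec, **overrides)


PRESETS = {
    "control": control_like_spec,
    "gs12": gs12_like_spec,
    "gs16": gs16_like_spec,
}


def spec_to_dict(spec: MonolayerSpec) -> dict:
    """JSON/YAML-friendly echo of a spec (tuples become lists)."""
    d = asdict(spec)
    d["shape"] = list(d["shape"])
    d["tilt"] = list(d["tilt"])
    return d


def spec_from_dict(d: dict) -> MonolayerSpec:
    d = dict(d)
    if "shape" in d:
        d["shape"] = tuple(d["shape"])
    if "tilt" in d:
        d["tilt"] = tuple(d["tilt"])
    return MonolayerSpec(**d)
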