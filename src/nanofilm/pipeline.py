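"""End-to-end analysis: level → segment → profile → report.

Orchestrates the full measurement chain on a paired topography /
potential image set from the same sample area: the topography is
levelled and segmented (both coverage methods plus their model
average), the resulting high-domain mask drives boundary-profile
placement, and the same profile lines are read out on both channels to
produce Δh and ΔV with 95% confidence margins.  Everything is
deterministic under the configured seed.

Per standard KPFM practice the potential channel is analysed raw
(unlevelled); the topography channel is plane-levelled with per-line
median correction before segmentation and profiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from skimage import morphology

from . import electrostatics, profiles, segmentation, synth
from .scan_io import Report, ScanImage, config_hash, read_scan, write_report

__all__ = ["AnalysisConfig", "run_analysis", "analyze_pair", "predict_dv"]

log = logging.getLogger("nanofilm")


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run.

    Provide either the two input image paths or a synthesis spec, not
    neither.  All parameters are serialized into the report provenance
    hash.
    """

    topography_path: Optional[str] = None
    potential_path: Optional[str] = None
    dialect: str = "ascii_matrix"
    pixel_size: float = 10.0
    spec: Optional[synth.MonolayerSpec] = None
    n_bins: int = 256
    smooth_bandwidth: int = 5
    min_area: Optional[float] = None
    connectivity: int = 8
    n_profiles: int = 100
    profile_length_nm: float = 400.0
    profile_samples: int = 64
    exclusion: float = 0.2
    confidence: float = 0.95
    output_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_paths = self.topography_path is not None and self.potential_path is not None
        if not has_paths and self.spec is None:
            raise ValueError("config needs input paths or a synthesis spec")

    def to_dict(self) -> dict:
        """Analysis-relevant parameters only: presentation settings
        (output directory, log level) are excluded so the provenance
        hash is stable across output locations."""
        d = asdict(self)
        d.pop("output_dir")
        d.pop("log_level")
        if self.spec is not None:
            d["spec"] = synth.spec_to_dict(self.spec)
        return d


def _load_pair(config: AnalysisConfig) -> tuple[ScanImage, ScanImage]:
    if config.spec is not None:
        log.info("generate: spec=%s seed=%d", config.spec.label or config.spec.morphology,
                 config.spec.seed)
        truth = synth.generate_mask(config.spec)
        return synth.render_pair(truth)
    topo = read_scan(config.topography_path, dialect=config.dialect,
                     pixel_size=config.pixel_size, channel="topography")
    pot = read_scan(config.potential_path, dialect=config.dialect,
                    pixel_size=config.pixel_size, channel="potential")
    return topo, pot


def analyze_pair(topo: ScanImage, pot: ScanImage, config: AnalysisConfig) -> Report:
    """Run the measurement chain on an in-memory image pair."""
    topo.require_channel("topography")
    pot.require_channel("potential")
    if topo.shape != pot.shape:
        raise ValueError(
            f"channel shape mismatch: topography {topo.shape} vs potential {pot.shape}")

    # two-pass flatten: a plane-only first pass supplies the exclusion mask
    # so the final plane fit and line medians see only the background phase
    # (an unmasked line-median pass would wreck scan lines that are mostly
    # high phase, pinning their median to the wrong level)
    log.info("level: order=1 per_line=True (two-pass, mask-excluded)")
    first = segmentation.level_image(topo, order=1, per_line=False)
    seed_mask = segmentation.coverage_histogram(
        first, n_bins=config.n_bins, smooth_bandwidth=config.smooth_bandwidth).mask
    levelled = segmentation.level_image(topo, order=1, per_line=True,
                                        exclude_mask=seed_mask)

    log.info("segment: n_bins=%d bandwidth=%d connectivity=%d",
             config.n_bins, config.smooth_bandwidth, config.connectivity)
    hist = segmentation.coverage_histogram(levelled, n_bins=config.n_bins,
                                           smooth_bandwidth=config.smooth_bandwidth)
    part = segmentation.coverage_particle(levelled, threshold=hist.threshold,
                                          min_area=config.min_area,
                                          connectivity=config.connectivity)
    cov_h = (hist.coverage_percent, 0.0)
    cov_p = (part.coverage_percent, 0.0)
    cov_avg = segmentation.model_average(cov_h, cov_p, ndigits=None)
    log.info("segment: coverage histogram=%.1f%% particle=%.1f%%",
             cov_h[0], cov_p[0])

    # profile placement needs clean domain geometry: drop speckle
    # components and pinholes that noise imprints on the threshold mask
    place_mask = morphology.remove_small_holes(
        morphology.remove_small_objects(hist.mask, max_size=16), max_size=16)
    log.info("profile: n=%d length=%.0f nm seed=%d",
             config.n_profiles, config.profile_length_nm, config.seed)
    topo_profiles = profiles.sample_boundary_profiles(
        levelled, place_mask, n_profiles=config.n_profiles,
        length=config.profile_length_nm, seed=config.seed,
        n_samples=config.profile_samples)
    if len(topo_profiles) < 2:
        raise ValueError("fewer than 2 usable boundary profiles; "
                         "is the image actually two-phase?")
    dh_deltas, dv_deltas = [], []
    for prof in topo_profiles:
        p0, p1 = prof.endpoints
        pot_prof = profiles.extract_profile(pot, p0, p1,
                                            n_samples=config.profile_samples)
        try:
            dh = profiles.step_delta(prof, exclusion=config.exclusion)
            dv = profiles.step_delta(pot_prof, exclusion=config.exclusion)
        except profiles.NoStepError:
            continue
        dh_deltas.append(dh)
        dv_deltas.append(dv)
    log.info("aggregate: %d paired profiles, confidence=%.2f",
             len(dh_deltas), config.confidence)
    dh = profiles.aggregate_contrast(dh_deltas, confidence=config.confidence)
    dv = profiles.aggregate_contrast(dv_deltas, confidence=config.confidence)

    provenance = {
        "inputs": [str(config.topography_path), str(config.potential_path)]
        if config.spec is None else ["synthetic"],
        "config_hash": config_hash(config.to_dict()),
    }
    return Report(
        coverage_histogram=cov_h,
        coverage_particle=cov_p,
        coverage_model_average=cov_avg,
        delta_h=(dh.mean_delta, dh.margin),
        delta_v=(dv.mean_delta, dv.margin),
        n_profiles=dh.n,
        provenance=provenance,
    )


def run_analysis(config: AnalysisConfig) -> Report:
    """Execute the full pipeline for ``config``; write reports if configured."""
    logging.basicConfig(level=config.log_level)
    topo, pot = _load_pair(config)
    report = analyze_pair(topo, pot, config)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_report(report, outdir / "report")
        log.info("report: written to %s", outdir / "report.json")
    return report


def predict_dv(entry_high: electrostatics.LipidEntry,
               entry_low: electrostatics.LipidEntry) -> float:
    """Dipole-sheet prediction of the potential contrast between two films.

    Uses each entry's measured potential when present, otherwise
    computes it from the dipole moment and area per molecule.
    """
    def potential(entry: electrostatics.LipidEntry) -> float:
        if entry.potential is not None:
            return float(entry.potential)
        return electrostatics.dipole_sheet_potential(entry.dipole, entry.area)

    return electrostatics.phase_potential_difference(potential(entry_high),
                                                     potential(entry_low))
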