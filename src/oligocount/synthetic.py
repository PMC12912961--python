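"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: cluster
compositions (independent Poisson monomers superposed with Poisson-distributed
fixed-size K-mers), Bernoulli vesicle-capture outcomes conditioned on the
latent oligomer count, stepwise photobleaching traces, and paired two-channel
lipid-domain images with enriched, self-quenched reporter lipid.

The generating model for cluster compositions: a cluster holds
``true_monomers ~ Poisson(monomer_mean)`` and ``true_oligomers ~
Poisson(oligomer_mean)`` drawn independently, and the observed copy number is

    N = true_monomers + K * true_oligomers.

Zero-copy draws are retained (an empty cluster is not optically detectable;
:func:`filter_observable` removes them downstream), so both the full-ensemble
mean ``monomer_mean + K * oligomer_mean`` and the observed (N >= 1) mean are
available to tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._util import ConfigError, rng_for
from .bleach import BleachTrace
from .imaging import DomainImageSet

__all__ = [
    "ClusterObservation",
    "TraceParams",
    "ImageParams",
    "SyntheticConfig",
    "simulate_cluster_compositions",
    "filter_observable",
    "simulate_capture_outcomes",
    "simulate_bleach_trace",
    "simulate_domain_images",
]

log = logging.getLogger(__name__)


@dataclass
class ClusterObservation:
    """One diffraction-limited cluster.

    ``vesicle_bound`` is tri-state: ``None`` means no capture observation or
    simulation was attached. ``true_monomers``/``true_oligomers`` carry the
    latent composition and are present only for synthetic data.
    """

    cluster_id: int
    copy_number: int
    condition: str = ""
    vesicle_bound: Optional[bool] = None
    true_monomers: Optional[int] = None
    true_oligomers: Optional[int] = None

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ConfigError("copy_number must be non-negative")


@dataclass
class TraceParams:
    """Parameters of the stepwise-bleaching trace generator.

    ``unit_step`` is the fluorescence intensity of one fluorophore (camera
    units); ``bleach_prob`` the per-frame survival complement, so the ensemble
    expectation decays as ``unit_step * N * (1 - bleach_prob)**frame``.
    """

    unit_step: float = 100.0
    bleach_prob: float = 0.04
    noise_sd: float = 0.0
    n_frames: int = 200
    baseline: float = 0.0
    frame_interval: float = 1.0

    def validate(self) -> None:
        if self.unit_step <= 0:
            raise ConfigError("unit_step must be positive")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be positive")
        if not 0.0 < self.bleach_prob < 1.0:
            raise ConfigError("bleach_prob must be in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


@dataclass
class ImageParams:
    """Parameters of the paired lipid-domain image generator.

    Densities are molecules/µm²; ``enrichment`` is the fold-concentration of
    the reporter lipid inside domains relative to the uniform no-lipopeptide
    bilayer, and ``quench`` multiplies the per-molecule brightness inside
    domains (self-quenching at high density).
    """

    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.16
    n_domains: int = 12
    mean_domain_area_um2: float = 1.7
    sd_domain_area_um2: float = 0.2
    bulk_density: float = 50.0
    enrichment: float = 3.0
    quench: float = 0.75
    brightness: float = 1.0
    peptide_brightness: float = 50.0
    noise_sd: float = 0.0
    background: float = 0.0

    def validate(self) -> None:
        if self.enrichment < 1:
            raise ConfigError("enrichment fold must be >= 1")
        if not 0.0 < self.quench <= 1.0:
            raise ConfigError("quench factor must be in (0, 1]")
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        if self.n_domains < 1:
            raise ConfigError("n_domains must be >= 1")
        field_area = self.shape[0] * self.shape[1] * self.pixel_size_um**2
        if self.n_domains * self.mean_domain_area_um2 >= field_area:
            raise ConfigError("total domain area must be smaller than the field")


@dataclass
class SyntheticConfig:
    """Full description of one synthetic experiment."""

    seed: int
    oligomer_size: int = 3
    monomer_mean: float = 2.2
    oligomer_mean: float = 4.4 / 3.0
    n_clusters: int = 878
    condition: str = "synthetic"
    capture_probs: Optional[Sequence[float]] = None
    trace_params: TraceParams = field(default_factory=TraceParams)
    image_params: ImageParams = field(default_factory=ImageParams)

    def __post_init__(self) -> None:
        if self.oligomer_size < 1:
            raise ConfigError("oligomer_size K must be >= 1")
        if self.monomer_mean < 0 or self.oligomer_mean < 0:
            raise ConfigError("Poisson means must be non-negative")
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.capture_probs is not None:
            _validate_capture_probs(self.capture_probs)


def _validate_capture_probs(probs: Sequence[float]) -> None:
    arr = np.asarray(probs, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ConfigError("capture_probs must be a 1-D vector")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ConfigError("capture probabilities must lie in [0, 1]")
    if arr[0] != 0:
        raise ConfigError("capture_probs[0] (zero oligomers) must be 0")


def simulate_cluster_compositions(config: SyntheticConfig) -> list[ClusterObservation]:
    """Draw cluster compositions from the monomer + K-mer mixture.

    Returns one :class:`ClusterObservation` per cluster with latent truth
    attached. Zero-copy clusters are retained; identical seeds give identical
    output.
    """
    rng = rng_for(config.seed, "cluster-compositions")
    monomers = rng.poisson(config.monomer_mean, size=config.n_clusters)
    oligomers = rng.poisson(config.oligomer_mean, size=config.n_clusters)
    copies = monomers + config.oligomer_size * oligomers
    return [
        ClusterObservation(
            cluster_id=i,
            condition=config.condition,
            copy_number=int(copies[i]),
            true_monomers=int(monomers[i]),
            true_oligomers=int(oligomers[i]),
        )
        for i in range(config.n_clusters)
    ]


def filter_observable(clusters: Sequence[ClusterObservation]) -> list[ClusterObservation]:
    """Keep clusters with at least one copy (empty clusters are invisible)."""
    kept = [c for c in clusters if c.copy_number >= 1]
    removed = len(clusters) - len(kept)
    if removed:
        log.info("filter_observable: removed %d zero-copy cluster(s)", removed)
    if not kept:
        log.warning("filter_observable: no observable clusters remain")
    return kept


def simulate_capture_outcomes(
    clusters: Sequence[ClusterObservation],
    capture_probs: Sequence[float],
    seed: int,
) -> list[ClusterObservation]:
    """Assign Bernoulli vesicle-capture outcomes from the latent oligomer count.

    ``capture_probs`` is indexed from n = 0 oligomers (entry 0 must be 0);
    oligomer counts beyond the last index saturate at the last entry. Returns
    new observations; inputs are not mutated.
    """
    _validate_capture_probs(capture_probs)
    probs = np.asarray(capture_probs, dtype=float)
    if any(c.true_oligomers is None for c in clusters):
        raise ConfigError("capture simulation requires latent true_oligomers")
    n_olig = np.array([c.true_oligomers for c in clusters])
    p = probs[np.minimum(n_olig, probs.size - 1)]
    rng = rng_for(seed, "capture-outcomes")
    bound = rng.random(len(clusters)) < p
    return [replace(c, vesicle_bound=bool(b)) for c, b in zip(clusters, bound)]


def simulate_bleach_trace(
    copy_number: int, trace_params: TraceParams, seed: int
) -> BleachTrace:
    """Simulate one stepwise photobleaching trace.

    Each of ``copy_number`` fluorophores independently survives each frame
    transition with probability ``1 - bleach_prob`` (geometric lifetime, no
    blinking); frame 0 shows all fluorophores alive. Gaussian camera noise is
    added on top of ``unit_step * survivors + baseline``.
    """
    if copy_number < 1:
        raise ConfigError("copy_number must be >= 1")
    trace_params.validate()
    tp = trace_params
    rng = rng_for(seed, "bleach-trace")
    # lifetime in frames of each fluorophore: geometric, support >= 1
    lifetimes = rng.geometric(tp.bleach_prob, size=copy_number)
    frames = np.arange(tp.n_frames)
    survivors = (lifetimes[None, :] > frames[:, None]).sum(axis=1)
    intensity = tp.unit_step * survivors + tp.baseline
    if tp.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, tp.noise_sd, size=tp.n_frames)
    return BleachTrace(
        trace_id=f"sim-{seed}-N{copy_number}",
        intensity=intensity.astype(float),
        frame_interval=tp.frame_interval,
        baseline=tp.baseline,
    )


def _place_domains(
    params: ImageParams, rng: np.random.Generator
) -> tuple[np.ndarray, list[float]]:
    """Rasterize non-overlapping disk domains; returns (label map, radii in px)."""
    h, w = params.shape
    px = params.pixel_size_um
    mean, sd = params.mean_domain_area_um2, params.sd_domain_area_um2
    if sd > 0:
        shape_k = (mean / sd) ** 2
        areas = rng.gamma(shape_k, mean / shape_k, size=params.n_domains)
    else:
        areas = np.full(params.n_domains, mean)
    radii_px = np.sqrt(areas / math.pi) / px
    labels = np.zeros((h, w), dtype=np.int32)
    centers: list[tuple[float, float, float]] = []
    yy, xx = np.mgrid[0:h, 0:w]
    for i, r in enumerate(sorted(radii_px, reverse=True), start=1):
        placed = False
        for _ in range(2000):  # rejection sampling; gap >= 2 px between disks
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            if all(
                math.hypot(cy - y0, cx - x0) > r + r0 + 2 for y0, x0, r0 in centers
            ):
                placed = True
                break
        if not placed:
            raise ConfigError(
                "could not place non-overlapping domains; reduce count or area"
            )
        centers.append((cy, cx, r))
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = i
    return labels, [r for _, _, r in centers]


def simulate_domain_images(image_params: ImageParams, seed: int) -> DomainImageSet:
    """Generate a with/without-lipopeptide image pair with conserved molecules.

    The without-lipopeptide bilayer carries uniform reporter density d0. With
    lipopeptide, domain pixels carry density E*d0 and the out-of-domain density
    is lowered so the total molecule count matches the uniform image exactly.
    Per-molecule fluorescence inside domains is multiplied by the quench
    factor; the lipopeptide channel is nonzero only inside domains.
    """
    image_params.validate()
    p = image_params
    rng = rng_for(seed, "domain-images")
    labels, _ = _place_domains(p, rng)
    mask = labels > 0
    pixel_area = p.pixel_size_um**2
    n_pix = labels.size
    n_dom_pix = int(mask.sum())
    n_out_pix = n_pix - n_dom_pix

    d0 = p.bulk_density * pixel_area  # molecules per pixel
    total = d0 * n_pix
    dom_density = p.enrichment * d0
    out_density = (total - dom_density * n_dom_pix) / n_out_pix
    if out_density < 0:
        raise ConfigError("enriched domains would exceed the total molecule budget")

    mol_without = np.full(p.shape, d0)
    mol_with = np.where(mask, dom_density, out_density)

    bright = np.where(mask, p.quench, 1.0) * p.brightness
    pip2_with = mol_with * bright + p.background
    pip2_without = mol_without * p.brightness + p.background
    peptide = np.where(mask, p.peptide_brightness, 0.0)
    if p.noise_sd > 0:
        pip2_with = pip2_with + rng.normal(0, p.noise_sd, p.shape)
        pip2_without = pip2_without + rng.normal(0, p.noise_sd, p.shape)
        peptide = peptide + rng.normal(0, p.noise_sd, p.shape) * mask

    _, counts = np.unique(labels[labels > 0], return_counts=True)
    areas_um2 = counts * pixel_area
    truth = {
        "enrichment": p.enrichment,
        "quench": p.quench,
        "mask": mask,
        "labels": labels,
        "areas_um2": areas_um2,
        "molecules_without": mol_without,
        "molecules_with": mol_with,
    }
    return DomainImageSet(
        image_with=np.stack([pip2_with, peptide]),
        image_without=pip2_without,
        pixel_size=p.pixel_size_um,
        background=(p.background, 0.0),
        truth=truth,
    )
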