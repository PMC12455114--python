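"""Synthetic data generator for the nanochannel analysis pipeline.

Every input the pipeline consumes can be generated here with known ground
truth: multi-frame image stacks of YOYO-1-labeled DNA in parallel
nanochannels, fluorescence titration tables, photobleaching traces, and
gel lane densitometry profiles.

The image model: each molecule is a 1-D boxcar of its per-frame extension
placed in its nanochannel line.  The extension follows a stationary
mean-reverting (Ornstein-Uhlenbeck) process emulating thermal fluctuation
of confined DNA.  Fluorescence is proportional to the number of surviving
dyes; dyes bleach independently with a per-dye exponential lifetime.
Bound dyes also photo-nick the DNA; two nicks on opposite strands within
a small window produce a double-strand break and the two fragments drift
apart along the channel.  The photon image is blurred by a Gaussian PSF
and read out with Poisson shot noise, Gaussian read noise, gain, and
offset, as for an sCMOS/EMCCD camera.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .kymo import ImageStack
from .binding import solve_free_ligand, TitrationSeries
from .photokinetics import GelLaneProfile

__all__ = [
    "SimConfig",
    "MoleculeGroundTruth",
    "simulate_kymograph_stack",
    "simulate_titration",
    "simulate_gel_lanes",
    "write_stack",
    "write_ground_truth",
]

DYE_SATURATION_PER_BP = 0.25  # one bis-intercalator per 4 bp


@dataclass
class SimConfig:
    """Parameters of the image-stack simulator.

    Defaults emulate the extension/intensity imaging condition: lambda-DNA
    (48.5 kbp) at 1:10 dye:bp in 100x150 nm channels, 15 frames of 100 ms,
    110 nm pixels.  For photodamage movies use :meth:`photodamage`.
    """

    genome_length_bp: int = 48_500
    pixel_size: float = 110.0        # nm / pixel
    psf_sigma: float = 100.0         # nm
    frame_count: int = 15
    exposure: float = 0.1            # s (also the frame interval)
    channel_spacing: int = 5         # pixel rows between channel lines
    extension_mean: float = 5.0      # um, linear monomer
    extension_sd: float = 0.3        # um, stationary SD of the OU process
    ou_relaxation: float = 0.5       # s, OU correlation time
    dye_per_bp: float = 0.1          # 1:10 dye:bp
    photons_per_dye: float = 5.0     # detected photons per dye per frame
    bleach_rate: float = 0.1         # 1/s per dye
    nick_rate: float = 0.0           # 1/s per bound dye
    dsb_window_bp: int = 10
    drift_speed: float = 1.0         # px/frame separation speed after a DSB
    camera_gain: float = 1.0         # camera units per photon
    read_noise_sd: float = 2.0       # camera units
    offset: float = 100.0            # camera units
    image_width_px: int | None = None
    edge_margin_px: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dye_per_bp < 0 or self.dye_per_bp > DYE_SATURATION_PER_BP:
            raise ValueError(
                f"dye_per_bp must lie in [0, {DYE_SATURATION_PER_BP}]"
            )
        if self.dsb_window_bp < 1:
            raise ValueError("dsb_window_bp must be >= 1")
        for name in ("pixel_size", "psf_sigma", "exposure", "extension_mean",
                     "extension_sd", "ou_relaxation", "bleach_rate",
                     "nick_rate", "photons_per_dye", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.frame_count < 1 or self.channel_spacing < 1:
            raise ValueError("frame_count and channel_spacing must be >= 1")

    @classmethod
    def photodamage(cls, **overrides) -> "SimConfig":
        """Continuous-imaging condition for bleaching/fragmentation movies."""
        base = dict(frame_count=80, exposure=0.05, bleach_rate=0.5,
                    nick_rate=5e-3)
        base.update(overrides)
        return cls(**base)


@dataclass
class MoleculeGroundTruth:
    """Per-molecule generating truth returned alongside the image stack."""

    molecule_id: int
    class_label: str                      # linear-monomer|circle|fragment|concatemer
    channel_row: int
    center_px: float
    true_extension_um: np.ndarray         # per frame
    true_intensity_photons: np.ndarray    # expected photons per frame
    fragmentation_time: float | None
    nick_positions: list = field(default_factory=list)  # (time_s, bp, strand)

    @property
    def mean_extension_um(self) -> float:
        return float(np.mean(self.true_extension_um))


def first_dsb_time(nicks, window_bp: int):
    """Brute-force double-strand-break scan over all nick pairs.

    A DSB forms when two nicks on opposite strands lie within ``window_bp``;
    the break time is the later of the two nick times.  Returns
    ``(time, position_bp)`` of the earliest such pair, or ``(None, None)``.
    """
    best_t, best_pos = None, None
    for i in range(len(nicks)):
        t1, p1, s1 = nicks[i]
        for j in range(i + 1, len(nicks)):
            t2, p2, s2 = nicks[j]
            if s1 != s2 and abs(p1 - p2) <= window_bp:
                t = max(t1, t2)
                if best_t is None or t < best_t:
                    best_t = t
                    best_pos = 0.5 * (p1 + p2)
    return best_t, best_pos


def _ou_path(rng, n, mean, sd, tau, dt):
    """Discrete Ornstein-Uhlenbeck path with stationary mean/SD."""
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    if tau <= 0 or sd == 0:
        x[:] = mean + sd * rng.standard_normal(n) if sd else mean
        return x
    phi = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.standard_normal(n - 1)
    for t in range(1, n):
        x[t] = mean + phi * (x[t - 1] - mean) + innov_sd * eps[t - 1]
    return x


def _add_boxcar(line: np.ndarray, left: float, right: float, photons: float) -> None:
    """Deposit ``photons`` uniformly over [left, right] px with subpixel edges."""
    if right <= left or photons <= 0:
        return
    density = photons / (right - left)
    i0 = max(int(np.floor(left)), 0)
    i1 = min(int(np.ceil(right)), line.size)
    if i1 <= i0:
        return   # segment drifted out of the field of view
    idx = np.arange(i0, i1)
    cover = np.clip(np.minimum(right, idx + 1.0) - np.maximum(left, idx), 0.0, 1.0)
    line[i0:i1] += density * cover


_CLASS_EXT_FACTOR = {
    "linear-monomer": 1.0,
    "circle": 0.58,        # self-hybridized overhangs halve the apparent contour
    "concatemer": 2.0,     # dimer of two end-joined genomes
}


def simulate_kymograph_stack(
    config: SimConfig,
    n_molecules: int,
    class_fractions: dict | None = None,
    shot_noise: bool = True,
):
    """Render an image stack of nanochannel-confined molecules.

    One molecule per channel line (a horizontal pixel row); channels are
    ``config.channel_spacing`` rows apart.  ``class_fractions`` maps class
    labels to sampling probabilities (default: all linear monomers).
    Returns ``(ImageStack, list[MoleculeGroundTruth])``.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(config.seed)
    if class_fractions is None:
        class_fractions = {"linear-monomer": 1.0}
    labels = list(class_fractions)
    probs = np.array([class_fractions[k] for k in labels], dtype=float)
    probs = probs / probs.sum()

    px_um = config.pixel_size / 1000.0   # um per pixel
    max_ext_px = (max(_CLASS_EXT_FACTOR.get(l, 1.0) for l in labels)
                  * (config.extension_mean + 5 * config.extension_sd) / px_um)
    width = config.image_width_px or int(np.ceil(max_ext_px)) + 2 * config.edge_margin_px + 8
    if max_ext_px + 2 > width:
        raise ValueError("molecule extension does not fit in the image width")
    n_rows = n_molecules * config.channel_spacing + config.channel_spacing
    T = config.frame_count
    dt = config.exposure
    psf_px = config.psf_sigma / config.pixel_size

    photon_stack = np.zeros((T, n_rows, width), dtype=float)
    truths: list[MoleculeGroundTruth] = []
    p_survive = np.exp(-config.bleach_rate * dt)

    for m in range(n_molecules):
        label = labels[rng.choice(len(labels), p=probs)]
        row = config.channel_spacing * (m + 1) - 1
        factor = _CLASS_EXT_FACTOR.get(label)
        if label == "fragment":
            factor = rng.uniform(0.20, 0.45)
        ext_mean = config.extension_mean * factor
        sd_scale = {"circle": 0.6, "concatemer": 1.2}.get(label, np.sqrt(factor))
        ext_sd = config.extension_sd * sd_scale
        ext_um = _ou_path(rng, T, ext_mean, ext_sd, config.ou_relaxation, dt)
        ext_um = np.clip(ext_um, 0.2 * ext_mean, None)

        genome_bp = int(round(config.genome_length_bp * factor))
        n_dyes = rng.binomial(genome_bp, min(config.dye_per_bp, 1.0)) \
            if config.dye_per_bp > 0 else 0

        half_span = 0.5 * ext_mean / px_um
        lo = half_span + config.edge_margin_px
        hi = width - half_span - config.edge_margin_px
        center = rng.uniform(lo, hi) if hi > lo else width / 2.0

        nicks: list = []          # (time_s, bp, strand)
        frag_time: float | None = None
        frag_pos_frac = 0.5
        intensity = np.zeros(T)

        for t in range(T):
            time_s = t * dt
            # photo-nicking by currently bound dyes; a new nick forms a DSB
            # if the opposite strand already holds one within the window
            if config.nick_rate > 0 and n_dyes > 0 and frag_time is None:
                k = rng.poisson(config.nick_rate * n_dyes * dt)
                for _ in range(k):
                    pos = int(rng.integers(0, genome_bp))
                    strand = int(rng.integers(0, 2))
                    nicks.append((time_s, pos, strand))
                    if frag_time is None:
                        opp = np.array([p for _, p, s in nicks[:-1]
                                        if s != strand])
                        if opp.size:
                            d = np.abs(opp - pos)
                            j = int(np.argmin(d))
                            if d[j] <= config.dsb_window_bp:
                                frag_time = time_s
                                frag_pos_frac = 0.5 * (pos + opp[j]) / genome_bp

            intensity[t] = n_dyes * config.photons_per_dye
            ext_px = ext_um[t] / px_um
            line = photon_stack[t, row]
            photons = n_dyes * config.photons_per_dye
            if frag_time is None:
                _add_boxcar(line, center - ext_px / 2, center + ext_px / 2, photons)
            else:
                frames_since = max(time_s - frag_time, 0.0) / dt
                gap = config.drift_speed * frames_since
                f = frag_pos_frac
                l1, l2 = ext_px * f, ext_px * (1 - f)
                split = center - ext_px / 2 + l1
                _add_boxcar(line, split - l1 - gap / 2, split - gap / 2, photons * f)
                _add_boxcar(line, split + gap / 2, split + l2 + gap / 2, photons * (1 - f))

            # per-dye exponential bleaching between frames
            if config.bleach_rate > 0 and n_dyes > 0:
                n_dyes = int(rng.binomial(n_dyes, p_survive))

        truths.append(MoleculeGroundTruth(
            molecule_id=m,
            class_label=label,
            channel_row=row,
            center_px=center,
            true_extension_um=ext_um,
            true_intensity_photons=intensity,
            fragmentation_time=frag_time,
            nick_positions=nicks,
        ))

    if psf_px > 0:
        for t in range(T):
            photon_stack[t] = gaussian_filter(photon_stack[t], psf_px, mode="constant")
    if shot_noise:
        photon_stack = rng.poisson(photon_stack).astype(float)
    frames = config.camera_gain * photon_stack + config.offset
    if config.read_noise_sd > 0:
        frames = frames + rng.normal(0.0, config.read_noise_sd, frames.shape)
    frames = np.clip(frames, 0, 65535)

    stack = ImageStack(frames=frames, pixel_size=config.pixel_size,
                       frame_interval=dt)
    return stack, truths


def simulate_titration(
    ka: float,
    n_site: float,
    s_total: float,
    l_total_grid,
    scale: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    condition: dict | None = None,
) -> TitrationSeries:
    """Fluorescence titration obeying the simplified MvH isotherm.

    signal = scale * (L_T - L_f) * (1 + eps), eps ~ N(0, noise_cv); L_f is
    the exact free-ligand solution for (ka, n_site, s_total).
    """
    if ka < 0 or n_site <= 0 or s_total <= 0:
        raise ValueError("require ka >= 0, n_site > 0, s_total > 0")
    rng = np.random.default_rng(seed)
    lt = np.asarray(l_total_grid, dtype=float)
    lf = solve_free_ligand(lt, s_total, ka, n_site)
    signal = scale * (lt - lf)
    if noise_cv > 0:
        signal = signal * (1.0 + rng.normal(0.0, noise_cv, signal.shape))
    signal = np.clip(signal, 0.0, None)
    return TitrationSeries(s_total=s_total, l_total=lt, signal=signal,
                           condition=condition or {})


def simulate_gel_lanes(
    intact_fraction_grid,
    lane_length_px: int = 500,
    band_position: int = 100,
    band_sigma: float = 8.0,
    smear_decay_px: float = 120.0,
    total_area: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[GelLaneProfile]:
    """Gel lanes with an intact band over a fragment smear.

    Position increases with migration distance, so the fragment smear
    (higher mobility) lies at positions beyond the intact band.  Band area
    is proportional to the intact fraction, smear area to its complement.
    """
    rng = np.random.default_rng(seed)
    pos = np.arange(lane_length_px, dtype=float)
    lanes = []
    band_lo = band_position - 3.0 * band_sigma
    band_hi = band_position + 3.0 * band_sigma
    smear_start = band_hi + band_sigma
    for i, frac in enumerate(np.atleast_1d(intact_fraction_grid)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("intact fractions must lie in [0, 1]")
        band = np.exp(-0.5 * ((pos - band_position) / band_sigma) ** 2)
        band *= frac * total_area / (band_sigma * np.sqrt(2 * np.pi))
        smear = np.where(pos > smear_start,
                         np.exp(-(pos - smear_start) / smear_decay_px), 0.0)
        area = np.trapezoid(smear, pos)
        smear = smear * (1.0 - frac) * total_area / area if area > 0 else smear
        profile = band + smear
        if noise_sd > 0:
            profile = np.clip(profile + rng.normal(0, noise_sd, profile.shape), 0, None)
        lanes.append(GelLaneProfile(
            position=pos.copy(), intensity=profile,
            band_window=(band_lo, band_hi), lane_id=i,
        ))
    return lanes


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a 16-bit multi-frame grayscale TIFF."""
    import tifffile

    tifffile.imwrite(path, np.clip(stack.frames, 0, 65535).astype(np.uint16),
                     metadata={"pixel_size_nm": stack.pixel_size,
                               "frame_interval_s": stack.frame_interval})


def write_ground_truth(out_dir, config: SimConfig,
                       truths: list[MoleculeGroundTruth]) -> None:
    """Ground truth as a per-molecule CSV plus a JSON sidecar with the config."""
    out_dir = Path(out_dir)
    rows = []
    for gt in truths:
        rows.append({
            "molecule_id": gt.molecule_id,
            "class_label": gt.class_label,
            "channel_row": gt.channel_row,
            "center_px": gt.center_px,
            "mean_extension_um": gt.mean_extension_um,
            "extension_sd_um": float(np.std(gt.true_extension_um)),
            "mean_intensity_photons": float(np.mean(gt.true_intensity_photons)),
            "fragmentation_time_s": gt.fragmentation_time,
            "n_nicks": len(gt.nick_positions),
        })
    pd.DataFrame(rows).to_csv(out_dir / "ground_truth.csv", index=False)
    with open(out_dir / "sim_config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
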