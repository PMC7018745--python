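"""Synthetic data generators with ground truth.

Every input class the analysis pipeline consumes can be generated here
with a :class:`TruthBundle` recording the generating parameters, so each
analysis stage can be tested by planting known truth and checking
recovery:

* behavioral withdrawal-threshold tables following a Hill dose-response
  (optionally with a high-dose collapse) plus per-animal Gaussian noise
  on the MPA scale,
* miniature-IPSC traces built from the gating-model event waveform at
  Poisson event times,
* punctate immunofluorescence (PSF-blurred discs over background with
  Poisson shot noise and Gaussian read noise, 12-bit clipped),
* membrane-ring cell images with planted membrane/intracellular
  contrast, and
* RNAscope-like images: a Nissl soma channel plus transcript-dot
  channels with known per-cell counts.

All randomness flows through explicit integer seeds; generation is
bit-reproducible.  Noise defaults are stated free choices, not
literature calibrations (per-animal WD50 variance in particular is not
published).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .imaging import ImagePlane
from .kinetics import (
    DEFAULT_PULSE,
    GatingParams,
    TransmitterPulse,
    simulate_gating,
)
from .pharmacology import (
    CollapseParams,
    HillParams,
    collapse_factor,
    hill_response,
)

__all__ = [
    "BehavioralTruth",
    "ImageTruth",
    "TruthBundle",
    "VON_FREY_FILAMENTS_G",
    "gen_behavioral",
    "gen_mipsc_trace",
    "gen_puncta_image",
    "gen_membrane_image",
    "gen_rnascope_image",
    "write_behavioral_csv",
    "write_image_tiff",
]

#: The twelve von Frey filament forces (g) used for threshold testing.
VON_FREY_FILAMENTS_G = np.array(
    [0.04, 0.07, 0.16, 0.4, 0.6, 1.0, 2.0, 4.0, 6.0, 8.0, 15.0, 60.0]
)

BIT_DEPTH = 12
MAX_INTENSITY = 2**BIT_DEPTH - 1

#: Default PSF sigma (um): isotropic Gaussian with FWHM ~0.25 um,
#: matching 60x/1.4 NA-class optics.
DEFAULT_PSF_SIGMA = 0.25 / 2.355


@dataclass(frozen=True)
class BehavioralTruth:
    """Ground truth of a behavioral dose-response experiment.

    MPA follows ``hill`` (times the ``collapse`` factor if present); the
    two baselines convert MPA to withdrawal thresholds in grams.
    ``noise_sd`` is the per-animal Gaussian SD on the MPA scale (%).
    """

    hill: HillParams
    collapse: Optional[CollapseParams] = None
    baseline_wd50_prepni: float = 26.0
    wd50_predrug: float = 2.0
    n_animals: int = 8
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.wd50_predrug < self.baseline_wd50_prepni:
            raise ValueError("need 0 < predrug < prePNI baseline")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")

    def model_mpa(self, dose) -> np.ndarray:
        mpa = hill_response(dose, self.hill)
        if self.collapse is not None:
            mpa = mpa * collapse_factor(dose, self.collapse)
        return mpa


@dataclass(frozen=True)
class ImageTruth:
    """Ground truth of a synthetic image: geometry, levels and noise model."""

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.1  # um
    psf_sigma: float = DEFAULT_PSF_SIGMA  # um
    positions: tuple = ()  # (y, x) in pixels
    amplitudes: tuple = ()
    sizes: tuple = ()  # object radius, pixels
    labels: tuple = ()
    background: float = 50.0
    read_noise_sd: float = 2.0
    poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0 or self.pixel_size <= 0:
            raise ValueError("psf_sigma and pixel_size must be > 0")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")
        h, w = self.shape
        for (y, x) in self.positions:
            if not (0 <= y < h and 0 <= x < w):
                raise ValueError(f"object at ({y}, {x}) outside frame {self.shape}")


@dataclass
class TruthBundle:
    """Generating parameters emitted with every synthetic dataset."""

    kind: str
    truth: object
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return {"kind": self.kind, "truth": enc(self.truth), "extras": enc(self.extras)}


def gen_behavioral(
    truth: BehavioralTruth,
    doses: Sequence[float],
    timepoints: Sequence[float] = (1.0, 2.0, 3.0, 4.0),
    group: str = "pni",
    snap_to_filaments: bool = False,
) -> tuple[pd.DataFrame, TruthBundle]:
    """Per-animal withdrawal-threshold table under a planted dose-response.

    Noise is additive Gaussian on the MPA scale; the noisy MPA is mapped
    back to WD50 through the exact inverse of the MPA definition and
    clipped to [0, prePNI baseline], keeping the MPA equation exactly
    invertible at zero noise.  ``snap_to_filaments`` optionally rounds
    thresholds to the nearest physical von Frey filament (off by default).

    Columns: animal_id, group, dose_mgkg, time_h, wd50_g.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("at least one dose required")
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0")
    rng = np.random.default_rng(truth.seed)
    span = truth.baseline_wd50_prepni - truth.wd50_predrug
    rows = []
    for dose in doses:
        model = float(truth.model_mpa(dose))
        for animal in range(truth.n_animals):
            for t in timepoints:
                mpa = model + rng.normal(0.0, truth.noise_sd) if truth.noise_sd else model
                wd50 = truth.wd50_predrug + mpa / 100.0 * span
                wd50 = float(np.clip(wd50, 0.0, truth.baseline_wd50_prepni))
                if snap_to_filaments:
                    wd50 = float(
                        VON_FREY_FILAMENTS_G[
                            np.abs(VON_FREY_FILAMENTS_G - wd50).argmin()
                        ]
                    )
                rows.append(
                    {
                        "animal_id": f"{group}_{dose:g}_{animal:02d}",
                        "group": group,
                        "dose_mgkg": dose,
                        "time_h": t,
                        "wd50_g": wd50,
                    }
                )
    table = pd.DataFrame(rows)
    return table, TruthBundle(kind="behavioral", truth=truth)


def gen_mipsc_trace(
    preset: GatingParams,
    event_rate: float = 2.0,  # events / s
    amplitude_mean: float = 30.0,  # pA
    amplitude_sd: float = 8.0,
    noise_sd: float = 2.0,  # pA baseline Gaussian noise
    duration: float = 10_000.0,  # ms
    seed: int = 0,
    pulse: TransmitterPulse = DEFAULT_PULSE,
    dt: float = 0.1,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Miniature-IPSC trace: gating-model event waveforms at Poisson times.

    A single event waveform is the open-fraction time course of the gating
    model normalized to unit peak; events are drawn as a Poisson process
    at ``event_rate`` with truncated-Gaussian amplitudes, summed, and
    Gaussian baseline noise added.  Inward currents are negative (pA).
    Returns (trace table with time_ms / current_pa, event time array).
    """
    if event_rate < 0:
        raise ValueError("event_rate must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration / dt))
    t = np.arange(n_samples) * dt
    current = np.zeros(n_samples)

    n_events = rng.poisson(event_rate * duration / 1000.0)
    event_times = np.sort(rng.uniform(0.0, duration, size=n_events))
    if n_events:
        traj = simulate_gating(preset, pulse, duration=min(300.0, duration), dt=dt)
        waveform = traj.o / traj.o.max()
        amps = np.clip(
            rng.normal(amplitude_mean, amplitude_sd, size=n_events), 0.0, None
        )
        for t0, amp in zip(event_times, amps):
            i0 = int(round(t0 / dt))
            seg = min(waveform.size, n_samples - i0)
            current[i0 : i0 + seg] -= amp * waveform[:seg]
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, size=n_samples)
    trace = pd.DataFrame({"time_ms": t, "current_pa": current})
    return trace, event_times


def _render_discs(truth: ImageTruth) -> np.ndarray:
    """Ideal (pre-noise) image: PSF-blurred discs plus flat background."""
    from scipy import ndimage

    field_ = np.zeros(truth.shape)
    for (y, x), amp, radius in zip(truth.positions, truth.amplitudes, truth.sizes):
        yy, xx = np.ogrid[: truth.shape[0], : truth.shape[1]]
        field_[(yy - y) ** 2 + (xx - x) ** 2 <= radius**2] += amp
    sigma_px = truth.psf_sigma / truth.pixel_size
    blurred = ndimage.gaussian_filter(field_, sigma_px)
    # blurring conserves flux; rescale so the planted amplitude is the
    # object's peak level rather than its integrated brightness
    if blurred.max() > 0 and field_.max() > 0:
        blurred *= field_.max() / blurred.max()
    return blurred + truth.background


def _apply_noise(ideal: np.ndarray, truth: ImageTruth, rng: np.random.Generator):
    img = ideal
    if truth.poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if truth.read_noise_sd > 0:
        img = img + rng.normal(0.0, truth.read_noise_sd, size=img.shape)
    return np.clip(img, 0, MAX_INTENSITY)


def gen_puncta_image(truth: ImageTruth) -> tuple[ImagePlane, ImageTruth]:
    """Single-channel punctum image from planted disc objects."""
    rng = np.random.default_rng(truth.seed)
    img = _apply_noise(_render_discs(truth), truth, rng)
    return ImagePlane(img, pixel_size=truth.pixel_size, bit_depth=BIT_DEPTH), truth


@dataclass(frozen=True)
class CellGeometry:
    """A round cell: center (pixels), radius (pixels), membrane thickness."""

    center: tuple[float, float]
    radius: float
    membrane_thickness: float = 2.0


def gen_membrane_image(
    cells: Sequence[CellGeometry],
    membrane_level: float = 900.0,
    intracellular_level: float = 400.0,
    background: float = 100.0,
    psf_sigma: float = DEFAULT_PSF_SIGMA,
    noise_sd: float = 5.0,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.1,
    seed: int = 0,
) -> tuple[ImagePlane, ImageTruth]:
    """Membrane-ring cell image with planted membrane/intracellular contrast.

    Each cell is a filled disc at ``intracellular_level`` with an annulus
    at ``membrane_level``; requires membrane >= intracellular >=
    background >= 0.  Overlapping cells are rejected.
    """
    from scipy import ndimage

    if not membrane_level >= intracellular_level >= background >= 0:
        raise ValueError("need membrane >= intracellular >= background >= 0")
    for i, a in enumerate(cells):
        for b in cells[i + 1 :]:
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d < a.radius + b.radius:
                raise ValueError("cells overlap beyond tolerance")
    rng = np.random.default_rng(seed)
    img = np.full(shape, float(background))
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    for cell in cells:
        r2 = (yy - cell.center[0]) ** 2 + (xx - cell.center[1]) ** 2
        half_t = cell.membrane_thickness / 2.0
        inside = r2 <= (cell.radius + half_t) ** 2
        # membrane annulus centered on the nominal radius, so the blurred
        # intensity peaks sit a planted diameter apart
        ring = inside & (r2 >= (cell.radius - half_t) ** 2)
        img[inside] = intracellular_level
        img[ring] = membrane_level
    img = ndimage.gaussian_filter(img, psf_sigma / pixel_size)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0, MAX_INTENSITY)
    truth = ImageTruth(
        shape=shape,
        pixel_size=pixel_size,
        psf_sigma=psf_sigma,
        positions=tuple(c.center for c in cells),
        amplitudes=(membrane_level,) * len(cells),
        sizes=tuple(c.radius for c in cells),
        labels=("cell",) * len(cells),
        background=background,
        read_noise_sd=noise_sd,
        poisson=False,
        seed=seed,
    )
    return ImagePlane(img, pixel_size=pixel_size, bit_depth=BIT_DEPTH), truth


@dataclass(frozen=True)
class SomaGeometry:
    """Elliptical soma: center (pixels), semi-axes, orientation (rad)."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float = 0.0
    intensity: float = 800.0

    @property
    def eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.semi_minor / self.semi_major) ** 2))


def gen_rnascope_image(
    somata: Sequence[SomaGeometry],
    dots_per_cell: dict[str, Sequence[int]],
    dot_amplitude: float = 1200.0,
    dot_radius: float = 1.5,
    background: float = 30.0,
    noise_sd: float = 3.0,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.094,
    psf_sigma: float = DEFAULT_PSF_SIGMA,
    seed: int = 0,
) -> tuple[dict[str, ImagePlane], ImageTruth, pd.DataFrame]:
    """Multi-channel in-situ-hybridization image with known dot counts.

    Returns a dict of channels — ``"nissl"`` (soma bodies) plus one dot
    channel per key of ``dots_per_cell`` (values: one planted count per
    soma) — the image truth, and a per-soma table of planted counts and
    dot positions.  Dots are placed uniformly inside their soma.
    """
    rng = np.random.default_rng(seed)
    for k, counts in dots_per_cell.items():
        if len(counts) != len(somata):
            raise ValueError(f"channel {k}: one count per soma required")
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    nissl = np.full(shape, float(background))
    soma_masks = []
    for s in somata:
        cy, cx = s.center
        ca, sa = np.cos(s.angle), np.sin(s.angle)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        mask = (u / s.semi_major) ** 2 + (v / s.semi_minor) ** 2 <= 1.0
        nissl[mask] += s.intensity
        soma_masks.append(mask)

    from scipy import ndimage

    channels = {"nissl": np.clip(nissl + rng.normal(0, noise_sd, shape), 0, MAX_INTENSITY)}
    rows = []
    truth_positions: dict[str, list] = {}
    for ch, counts in dots_per_cell.items():
        img = np.full(shape, float(background))
        positions = []
        for mask, count in zip(soma_masks, counts):
            inside = np.argwhere(mask)
            for _ in range(int(count)):
                y, x = inside[rng.integers(inside.shape[0])]
                img[(yy - y) ** 2 + (xx - x) ** 2 <= dot_radius**2] += dot_amplitude
                positions.append((float(y), float(x)))
        img = ndimage.gaussian_filter(img, psf_sigma / pixel_size)
        if img.max() > background:
            img = background + (img - background) * (
                dot_amplitude / (img.max() - background)
            )
        img = np.clip(img + rng.normal(0, noise_sd, shape), 0, MAX_INTENSITY)
        channels[ch] = img
        truth_positions[ch] = positions
    for i, (s, mask) in enumerate(zip(somata, soma_masks)):
        row = {
            "soma": i,
            "center_y": s.center[0],
            "center_x": s.center[1],
            "eccentricity": s.eccentricity,
            "area_px": int(mask.sum()),
        }
        for ch, counts in dots_per_cell.items():
            row[f"n_{ch}"] = int(counts[i])
        rows.append(row)
    truth = ImageTruth(
        shape=shape,
        pixel_size=pixel_size,
        psf_sigma=psf_sigma,
        positions=tuple(s.center for s in somata),
        amplitudes=tuple(s.intensity for s in somata),
        sizes=tuple(s.semi_major for s in somata),
        labels=("soma",) * len(somata),
        background=background,
        read_noise_sd=noise_sd,
        poisson=False,
        seed=seed,
    )
    planes = {
        k: ImagePlane(v, pixel_size=pixel_size, bit_depth=BIT_DEPTH)
        for k, v in channels.items()
    }
    return planes, truth, pd.DataFrame(rows)


def write_behavioral_csv(path, table: pd.DataFrame, bundle: TruthBundle) -> None:
    """Write the withdrawal table as CSV with a JSON truth sidecar."""
    path = Path(path)
    table.to_csv(path, index=False)
    path.with_suffix(".truth.json").write_text(json.dumps(bundle.to_dict(), indent=2))


def write_image_tiff(path, image: ImagePlane, truth: ImageTruth) -> None:
    """Write a 16-bit TIFF with a JSON sidecar (pixel size and truth)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.round(image.data).astype(np.uint16))
    sidecar = TruthBundle(kind="image", truth=truth, extras={"pixel_size_um": image.pixel_size})
    path.with_suffix(".truth.json").write_text(json.dumps(sidecar.to_dict(), indent=2))
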