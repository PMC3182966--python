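"""Scanner-realistic synthetic arrays with full ground truth.

The generator renders a printed layout into a 16-bit image the way the
scanner would see it: spots as flat-top disks with a soft (error-function)
rim at the layout pitch, per-spot expected net volume following the shared
4PL response at the spot's dilution, log-normal spot-to-spot printing
variation, a smooth non-uniform background (constant + linear gradient),
per-pixel Gaussian read noise, optional per-spot positional jitter and a
global image shift, and compact high-intensity dust specks.  Everything is
a pure function of (configuration, seed), and the returned
:class:`SimulationTruth` carries the per-spot centers, boundary masks,
dust-free net volumes, the background surface and the per-series
log-concentrations, so every downstream stage can be audited exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .images import MAX_INTENSITY, ArrayImage
from .layout import ArrayLayout
from .supercurve import SuperCurveParams, evaluate


def expected_intensity(params: SuperCurveParams, log_conc: float,
                       dilution_factor: float) -> float:
    """Noise-free net volume of a spot at ``dilution_factor`` of a series
    with the given log-concentration: the shared 4PL evaluated at
    ``v = ln(dilution_factor) + log_conc``."""
    return float(evaluate(params, dilution_factor, log_conc))


@dataclass(frozen=True)
class NoiseSpec:
    """Noise and distortion levels for the renderer.

    All units physical: intensities in counts, lengths in µm.  The
    defaults emulate a clean laser scan: 10% spot-to-spot printing CV,
    light read noise, a visible but smooth background gradient, sub-pixel
    jitter and no global shift.
    """

    multiplicative_cv: float = 0.10
    read_noise_sd: float = 8.0
    background_level: float = 150.0
    background_gradient: float = 100.0
    spot_jitter_sd: float = 5.0
    spot_jitter_max: float | None = None  # truncation radius; default 3*sd
    global_shift: tuple[float, float] = (0.0, 0.0)  # (dy, dx) µm

    def __post_init__(self):
        if not (0 <= self.multiplicative_cv < 1):
            raise ValueError("multiplicative CV must be in [0, 1)")
        for name in ("read_noise_sd", "background_level",
                     "background_gradient", "spot_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SpotTruth:
    address: tuple[int, int, int]
    center: tuple[float, float]  # true (y, x), pixels
    net_volume: float  # dust-free added foreground, post printing noise
    expected_volume: float  # noise-free 4PL value
    n_clipped: int = 0


@dataclass
class DustSpeck:
    center: tuple[int, int]
    pixels: np.ndarray  # (n, 2) int coordinates
    added_intensity: float  # total counts added (pre-clipping)
    on_spot: tuple[int, int, int] | None = None


@dataclass
class SimulationTruth:
    """Ground truth paired with a rendered image."""

    seed: int
    spots: dict[tuple[int, int, int], SpotTruth]
    labels: np.ndarray  # int32 label image; spot i+1 in layout order, 0 = bg
    background: np.ndarray  # float background surface (no read noise)
    log_conc: dict[str, float]  # per-series log relative concentration
    dust: list[DustSpeck] = field(default_factory=list)

    def mask_of(self, layout: ArrayLayout,
                address: tuple[int, int, int]) -> np.ndarray:
        i = next(k for k, s in enumerate(layout.spots) if s.address == address)
        return self.labels == i + 1


def _spot_profile(shape, center, r0, rim_sigma, donut_dip=0.0):
    """Radial amplitude profile on the full frame around ``center``."""
    h, w = shape
    cy, cx = center
    y0 = max(0, int(np.floor(cy - r0 - 4 * rim_sigma - 1)))
    y1 = min(h, int(np.ceil(cy + r0 + 4 * rim_sigma + 2)))
    x0 = max(0, int(np.floor(cx - r0 - 4 * rim_sigma - 1)))
    x1 = min(w, int(np.ceil(cx + r0 + 4 * rim_sigma + 2)))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(yy - cy, xx - cx)
    from scipy.special import erf
    amp = 0.5 * (1.0 + erf((r0 - r) / rim_sigma))
    if donut_dip > 0:
        amp = amp * (1.0 - donut_dip * np.exp(-(r / (0.6 * r0)) ** 2))
    return (slice(y0, y1), slice(x0, x1)), amp


def render_array(
    layout: ArrayLayout,
    params: SuperCurveParams,
    concentrations: dict[str, float],
    noise: NoiseSpec | None = None,
    seed: int = 0,
    image_shape: tuple[int, int] | None = None,
    spot_radius_frac: float = 0.35,
    rim_frac: float = 0.15,
    donut_dip: float = 0.0,
) -> tuple[ArrayImage, SimulationTruth]:
    """Render the layout into a 16-bit image plus its ground truth.

    ``concentrations`` maps each series id to its relative concentration
    (linear scale; the top dilution of a series at concentration ``C`` has
    expected response ``4PL(ln C)``).  Spot radius defaults to 35% of the
    pitch with a rim width 15% of the radius; the truth boundary mask of a
    spot is its rendered support (pixels receiving >= 0.5 counts).  The
    same seed always reproduces the identical image bit for bit.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    pitch_px = layout.pitch_px
    if image_shape is None:
        image_shape = layout.frame_shape(margin_pitches=1.0)
    h, w = image_shape
    r0 = spot_radius_frac * pitch_px
    # rim_frac is the 10-90% transition width as a fraction of the radius;
    # the erf scale is that width / 1.81
    rim_sigma = max(rim_frac * r0 / 1.81, 0.3)
    jmax = noise.spot_jitter_max
    if jmax is None:
        jmax = 3.0 * noise.spot_jitter_sd
    gshift = np.array(noise.global_shift, dtype=float) / layout.pixel_size

    fg = np.zeros(image_shape, dtype=float)
    best = np.zeros(image_shape, dtype=float)  # strongest single-spot claim
    labels = np.zeros(image_shape, dtype=np.int32)
    spots: dict[tuple[int, int, int], SpotTruth] = {}
    log_conc = {sid: float(np.log(c)) for sid, c in concentrations.items()}

    for i, ann in enumerate(layout.spots):
        nominal = np.array(layout.nominal_center(ann.address))
        jitter = rng.normal(0.0, noise.spot_jitter_sd / layout.pixel_size, 2)
        n = np.hypot(*jitter)
        jmax_px = jmax / layout.pixel_size
        if n > jmax_px > 0:
            jitter *= jmax_px / n
        center = nominal + gshift + jitter
        mult = float(np.exp(rng.normal(0.0, _lognorm_sigma(noise.multiplicative_cv))
                            - _lognorm_sigma(noise.multiplicative_cv) ** 2 / 2)) \
            if noise.multiplicative_cv > 0 else 1.0
        if ann.role == "empty" or (ann.role == "sample"
                                   and ann.sample_id not in log_conc):
            continue
        if not (r0 + 1 <= center[0] <= h - r0 - 1
                and r0 + 1 <= center[1] <= w - r0 - 1):
            raise ValueError(f"spot {ann.address} overflows the image frame")
        lc = log_conc[ann.sample_id] if ann.role == "sample" else 0.0
        expected = expected_intensity(params, lc, ann.dilution_factor)
        vol = expected * mult
        win, amp = _spot_profile(image_shape, center, r0, rim_sigma, donut_dip)
        total = amp.sum()
        pix = vol * amp / total
        fg[win] += pix
        claim = pix > np.maximum(best[win], 0.5 - 1e-12)
        labels[win] = np.where(claim, i + 1, labels[win])
        best[win] = np.maximum(best[win], pix)
        spots[ann.address] = SpotTruth(
            address=ann.address, center=tuple(center),
            net_volume=float(vol), expected_volume=float(expected))

    yy, xx = np.mgrid[0:h, 0:w]
    background = noise.background_level + noise.background_gradient * (
        yy / max(h - 1, 1) + xx / max(w - 1, 1)) / 2.0
    img_f = fg + background
    if noise.read_noise_sd > 0:
        img_f = img_f + rng.normal(0.0, noise.read_noise_sd, image_shape)
    clipped = img_f > MAX_INTENSITY
    pixels = np.clip(np.rint(img_f), 0, MAX_INTENSITY).astype(np.uint16)
    for i, ann in enumerate(layout.spots):
        if ann.address in spots:
            spots[ann.address].n_clipped = int(np.sum(clipped[labels == i + 1]))

    image = ArrayImage(pixels=pixels, bit_depth=16, pixel_size=layout.pixel_size)
    truth = SimulationTruth(seed=seed, spots=spots, labels=labels,
                            background=background, log_conc=log_conc)
    return image, truth


def _lognorm_sigma(cv: float) -> float:
    return float(np.sqrt(np.log(1.0 + cv * cv)))


def inject_dust(
    image: ArrayImage,
    truth: SimulationTruth,
    n_specks: int,
    seed: int = 0,
    radius_range: tuple[float, float] = (1.0, 2.5),
    intensity_range: tuple[float, float] = (2000.0, 20000.0),
    on_spot_fraction: float = 0.5,
    volume_fraction_range: tuple[float, float] | None = None,
) -> tuple[ArrayImage, SimulationTruth]:
    """Add compact high-intensity dust specks; truth records every speck.

    A fraction ``on_spot_fraction`` of specks is centered on a randomly
    chosen spot mask pixel, the rest on background.  Speck pixels get a
    flat intensity addition drawn from ``intensity_range`` (per pixel);
    with ``volume_fraction_range`` set, on-spot speck amplitudes are
    instead scaled so the speck adds that fraction of the host spot's
    true net volume.  Dust-free truth volumes are left untouched.
    """
    rng = np.random.default_rng(seed)
    pixels = image.pixels.astype(float)
    h, w = pixels.shape
    specks: list[DustSpeck] = []
    for _ in range(n_specks):
        on_spot = rng.random() < on_spot_fraction and len(truth.spots) > 0
        if on_spot:
            lab = int(rng.choice(np.unique(truth.labels[truth.labels > 0])))
            cand = np.argwhere(truth.labels == lab)
            cy, cx = cand[rng.integers(len(cand))]
            addr = _address_of_label(truth, lab)
        else:
            cy = int(rng.integers(2, h - 2))
            cx = int(rng.integers(2, w - 2))
            addr = None
        r = float(rng.uniform(*radius_range))
        yy, xx = np.mgrid[max(0, cy - 4):min(h, cy + 5),
                          max(0, cx - 4):min(w, cx + 5)]
        disk = np.hypot(yy - cy, xx - cx) <= r
        coords = np.stack([yy[disk], xx[disk]], axis=1)
        if addr is not None and volume_fraction_range is not None:
            frac = rng.uniform(*volume_fraction_range)
            amp = frac * truth.spots[addr].net_volume / len(coords)
        else:
            amp = float(rng.uniform(*intensity_range))
        pixels[coords[:, 0], coords[:, 1]] += amp
        specks.append(DustSpeck(center=(int(cy), int(cx)), pixels=coords,
                                added_intensity=float(amp * len(coords)),
                                on_spot=addr))
    out_pixels = np.clip(np.rint(pixels), 0, MAX_INTENSITY).astype(np.uint16)
    out_truth = SimulationTruth(
        seed=truth.seed, spots=truth.spots, labels=truth.labels,
        background=truth.background, log_conc=truth.log_conc,
        dust=truth.dust + specks)
    return ArrayImage(out_pixels, 16, image.pixel_size), out_truth


def _address_of_label(truth: SimulationTruth, lab: int):
    # labels are 1-based in layout order, but truth.spots only holds
    # rendered spots; match by center, falling back to mask centroid
    for addr, st in truth.spots.items():
        cy, cx = int(round(st.center[0])), int(round(st.center[1]))
        if truth.labels[cy, cx] == lab:
            return addr
    m = truth.labels == lab
    if m.any():
        ys, xs = np.nonzero(m)
        return min(truth.spots,
                   key=lambda a: (truth.spots[a].center[0] - ys.mean()) ** 2
                   + (truth.spots[a].center[1] - xs.mean()) ** 2)
    return None


# -- truth serialization ----------------------------------------------------

def save_truth(truth: SimulationTruth, json_path, labels_path=None):
    """Serialize truth as JSON (+ optional 16-bit label TIFF)."""
    doc = {
        "seed": truth.seed,
        "log_conc": truth.log_conc,
        "background": {"kind": "rendered", "mean": float(truth.background.mean())},
        "spots": [
            {"address": list(s.address), "center": list(s.center),
             "net_volume": s.net_volume, "expected_volume": s.expected_volume,
             "n_clipped": s.n_clipped}
            for s in truth.spots.values()
        ],
        "dust": [
            {"center": list(d.center), "n_pixels": int(len(d.pixels)),
             "added_intensity": d.added_intensity,
             "on_spot": list(d.on_spot) if d.on_spot else None}
            for d in truth.dust
        ],
    }
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
    if labels_path is not None:
        tifffile.imwrite(labels_path, truth.labels.astype(np.uint16))
    return json_path
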