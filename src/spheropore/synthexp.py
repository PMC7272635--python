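"""Synthetic ratiometric calcium-imaging experiment.

Stands in for the wet-lab stage: renders two-channel (340 nm / 380 nm
excitation) image time-lapses of elongated elliptical cells at random
orientations, whose calcium response -- and hence 340/380 ratio rise --
depends on orientation class, pulse duration and field strength.  The same
module then runs the analysis pipeline used on real data: segment cells,
fit ellipses from image moments, classify orientation relative to the field
axis, extract the background-corrected ratio trace, and compute the
per-experiment parallel-minus-perpendicular response difference.

Acquisition layout mirrors the experimental protocol: 15 frames, one every
5 s (70 s total), pulse delivered at 7 s, calcium peak 8 s after the pulse
(the 15 s frame).  The ratio is scaled by 100, as in the acquisition
software, and the baseline frame at time zero is subtracted from responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage import measure

from .pulses import experimental_field_grid

__all__ = [
    "SyntheticCell",
    "SyntheticScene",
    "CellMeasurement",
    "generate_scene",
    "default_effect_model",
    "compute_ratio_trace",
    "classify_orientation",
    "measure_scene",
    "parallel_minus_perpendicular",
    "FRAME_TIMES",
    "PULSE_TIME",
    "PEAK_TIME",
]

#: Acquisition times of the 15 frames (s).
FRAME_TIMES = np.arange(15) * 5.0
#: Pulse delivery time (s), between the 2nd and 3rd acquired frame.
PULSE_TIME = 7.0
#: Time of peak calcium response: 8 s after the pulse.
PEAK_TIME = PULSE_TIME + 8.0
#: Index of the peak frame in FRAME_TIMES.
PEAK_FRAME = int(np.argmin(np.abs(FRAME_TIMES - PEAK_TIME)))

#: Field axis of the synthetic images: +x (image columns).
#: Angles are folded to [0, 90] degrees relative to this axis.

# class-boundary guard bands for the sampler: rendered-pixel moment fits
# carry sub-degree / few-percent discretisation error, so sampled ground
# truth stays this far from the 20/70 degree and a = 2b decision boundaries
ANGLE_GUARD_DEG = 3.0
ELONGATION_GUARD = 0.12


def classify_orientation(a: float, b: float, angle_deg: float) -> str:
    """Orientation class of an ellipse relative to the field axis.

    ``parallel`` requires substantial elongation (a > 2b) and a long axis
    within 20 degrees of the field; ``perpendicular`` the same within 20
    degrees of the normal (angle >= 70); everything else is ``rest``.
    """
    if not (a >= b > 0):
        raise ValueError(f"require a >= b > 0, got a={a}, b={b}")
    if not 0.0 <= angle_deg <= 90.0:
        raise ValueError(f"angle must lie in [0, 90] degrees, got {angle_deg}")
    if a > 2.0 * b:
        if angle_deg <= 20.0:
            return "parallel"
        if angle_deg >= 70.0:
            return "perpendicular"
    return "rest"


@dataclass(frozen=True)
class SyntheticCell:
    """Ground truth for one rendered cell."""

    center: tuple[float, float]      # (x, y) px
    a: float                         # long semi-axis, px
    b: float                         # short semi-axis, px
    angle_deg: float                 # long axis to field axis, [0, 90]
    orientation_class: str
    amplitude: float                 # peak ratio response, A.U.


@dataclass
class SyntheticScene:
    """Rendered two-channel stack plus ground truth."""

    ch340: np.ndarray                # (15, H, W)
    ch380: np.ndarray                # (15, H, W)
    bg340: float
    bg380: float
    cells: list[SyntheticCell]
    noise_sd: float
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.ch340.shape[1:]

    def content_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        h.update(self.ch340.tobytes())
        h.update(self.ch380.tobytes())
        return h.hexdigest()


def _response_shape(t: np.ndarray) -> np.ndarray:
    """Unit-peak temporal response: linear rise from pulse to peak, slow decay."""
    t = np.asarray(t, dtype=float)
    rise = (t - PULSE_TIME) / (PEAK_TIME - PULSE_TIME)
    decay = np.exp(-(t - PEAK_TIME) / 40.0)
    return np.where(t <= PULSE_TIME, 0.0,
                    np.where(t <= PEAK_TIME, np.clip(rise, 0.0, 1.0), decay))


def default_effect_model(
    duration: float, field_V_per_cm: float, orientation_class: str
) -> float:
    """Mean peak ratio response (A.U.) per condition and orientation class.

    Encodes the orientation-dependence of calcium uptake observed across
    pulse durations: at 100 ns perpendicular cells respond more (negative
    parallel-perpendicular difference), in the 1-100 us range the classes
    respond alike, and at 1-10 ms parallel cells respond more.  Amplitudes
    scale linearly with field strength relative to the strongest field
    tested at that duration.
    """
    base = {
        100e-9: {"parallel": 3.0, "perpendicular": 11.0},
        1e-6: {"parallel": 2.0, "perpendicular": 2.0},
        10e-6: {"parallel": 3.0, "perpendicular": 3.0},
        100e-6: {"parallel": 4.0, "perpendicular": 4.0},
        1e-3: {"parallel": 16.0, "perpendicular": 3.0},
        10e-3: {"parallel": 12.0, "perpendicular": 4.0},
    }
    grid = experimental_field_grid()
    key = min(base, key=lambda d: abs(np.log(duration / d)))
    f = field_V_per_cm / max(grid[key])
    amp = base[key]
    if orientation_class == "rest":
        value = 0.5 * (amp["parallel"] + amp["perpendicular"])
    else:
        value = amp[orientation_class]
    return float(value * f)


def _sample_cell_shape(
    rng: np.random.Generator, force_class: str | None = None
) -> tuple[float, float, float]:
    """Sample (a, b, angle) away from the classification decision boundaries.

    With ``force_class`` the sample is drawn from the parallel or
    perpendicular region only (rejection sampling, still seeded).
    """
    while True:
        a = rng.uniform(12.0, 26.0)
        ratio = rng.uniform(1.4, 5.0)
        if abs(ratio - 2.0) < ELONGATION_GUARD:
            continue
        angle = rng.uniform(0.0, 90.0)
        if abs(angle - 20.0) < ANGLE_GUARD_DEG or abs(angle - 70.0) < ANGLE_GUARD_DEG:
            continue
        if force_class is not None:
            if classify_orientation(a, a / ratio, angle) != force_class:
                continue
        return a, a / ratio, angle


def generate_scene(
    n_cells: int,
    effect_model: Callable[[float, float, str], float],
    noise_sd: float,
    seed: int,
    duration: float = 1e-3,
    field_V_per_cm: float = 200.0,
    image_shape: tuple[int, int] = (192, 192),
    cell_sd: float = 1.5,
    bg340: float = 100.0,
    bg380: float = 100.0,
    cell_f380: float = 400.0,
    baseline_ratio: float = 100.0,
    max_tries: int = 2000,
) -> SyntheticScene:
    """Render a two-channel time-lapse of ``n_cells`` responding cells.

    Cells are ellipses placed without overlap (an error is raised past the
    packing limit), each with a ground-truth orientation class and a peak
    response drawn from ``effect_model`` plus cell-to-cell variability of
    ``cell_sd`` (A.U.).  Pixel noise is additive Gaussian with ``noise_sd``
    counts on both channels.  Fully reproducible for a fixed seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = image_shape
    margin = 4.0

    cells: list[SyntheticCell] = []
    placed: list[tuple[float, float, float]] = []   # (x, y, clearance radius)
    tries = 0
    while len(cells) < n_cells:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_cells} non-overlapping cells in a "
                f"{W}x{H} image after {max_tries} tries (packing limit)"
            )
        tries += 1
        # the first two cells are drawn from the parallel and perpendicular
        # regions so every scene contains both classes (n_cells >= 2);
        # remaining cells sample the full orientation distribution
        force = (None if len(cells) >= 2 or n_cells < 2
                 else ("parallel", "perpendicular")[len(cells)])
        a, b, angle = _sample_cell_shape(rng, force)
        x = rng.uniform(a + margin, W - a - margin)
        y = rng.uniform(a + margin, H - a - margin)
        r = a + margin
        if any((x - px) ** 2 + (y - py) ** 2 < (r + pr) ** 2 for px, py, pr in placed):
            continue
        cls = classify_orientation(a, b, angle)
        amp = effect_model(duration, field_V_per_cm, cls)
        if cell_sd > 0:
            amp += rng.normal(0.0, cell_sd)
        placed.append((x, y, r))
        cells.append(SyntheticCell((x, y), a, b, angle, cls, amp))

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    f380 = np.zeros((H, W))
    amp_map = np.zeros((H, W))
    for c in cells:
        th = np.deg2rad(c.angle_deg)
        dx, dy = xx - c.center[0], yy - c.center[1]
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        mask = (u / c.a) ** 2 + (v / c.b) ** 2 <= 1.0
        f380[mask] = cell_f380
        amp_map[mask] = c.amplitude

    shape_t = _response_shape(FRAME_TIMES)
    ch380 = np.empty((len(FRAME_TIMES), H, W))
    ch340 = np.empty_like(ch380)
    for k, s in enumerate(shape_t):
        ratio = baseline_ratio + amp_map * s
        ch380[k] = bg380 + f380
        ch340[k] = bg340 + f380 * ratio / 100.0
    if noise_sd > 0:
        ch340 += rng.normal(0.0, noise_sd, ch340.shape)
        ch380 += rng.normal(0.0, noise_sd, ch380.shape)
    return SyntheticScene(ch340, ch380, bg340, bg380, cells, noise_sd, seed)


def compute_ratio_trace(
    ch340: np.ndarray,
    ch380: np.ndarray,
    region: np.ndarray,
    bg340: float = 0.0,
    bg380: float = 0.0,
) -> np.ndarray:
    """Per-frame mean 340/380 ratio (x100) over a boolean pixel region.

    Pixels whose background-corrected 380 nm signal is not positive are
    excluded from the mean with a warning.  Returns the raw trace; subtract
    the time-zero baseline for response quantification.
    """
    region = np.asarray(region, dtype=bool)
    if region.sum() == 0:
        raise ValueError("empty region")
    num = ch340[:, region] - bg340
    den = ch380[:, region] - bg380
    bad = den <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.any(axis=0).sum())} region pixel(s) with non-positive "
            "380 nm signal excluded from the ratio",
            stacklevel=2,
        )
    ratio = np.where(bad, np.nan, 100.0 * num / np.where(bad, 1.0, den))
    return np.nanmean(ratio, axis=1)


@dataclass(frozen=True)
class CellMeasurement:
    """Pipeline output for one segmented cell."""

    a: float                      # fitted long semi-axis, px
    b: float                      # fitted short semi-axis, px
    angle_deg: float              # fitted long axis to field axis, [0, 90]
    orientation_class: str
    trace: np.ndarray             # raw ratio trace, 15 frames, A.U.
    peak: float                   # baseline-subtracted ratio at the peak frame

    def __post_init__(self):
        if len(self.trace) != len(FRAME_TIMES):
            raise ValueError("trace must have one value per acquisition frame")


def _moment_ellipse(mask: np.ndarray) -> tuple[float, float, float]:
    """Image-moment ellipse fit of a binary region: (a, b, angle to +x)."""
    m = measure.moments(mask.astype(float), order=2)
    cy, cx = m[1, 0] / m[0, 0], m[0, 1] / m[0, 0]
    mu = measure.moments_central(mask.astype(float), center=(cy, cx), order=2)
    mxx = mu[0, 2] / mu[0, 0]      # variance along columns (x)
    myy = mu[2, 0] / mu[0, 0]      # variance along rows (y)
    mxy = mu[1, 1] / mu[0, 0]
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)
    a = 2.0 * np.sqrt(evals[1])    # semi-axes of the equivalent ellipse
    b = 2.0 * np.sqrt(evals[0])
    vx, vy = evecs[:, 1]
    angle = np.degrees(np.arctan2(abs(vy), abs(vx)))   # folded to [0, 90]
    return float(a), float(b), float(angle)


def measure_scene(scene: SyntheticScene, threshold: float | None = None) -> list[CellMeasurement]:
    """Segment the 380 nm channel and measure every detected cell.

    Segmentation thresholds the time-averaged 380 nm image midway between
    background and cell plateau (or at ``threshold``), labels connected
    components, fits an image-moment ellipse per component, classifies its
    orientation, and extracts the baseline-subtracted ratio response.
    """
    mean380 = scene.ch380.mean(axis=0)
    if threshold is None:
        threshold = 0.5 * (mean380.min() + mean380.max())
    labels = measure.label(mean380 > threshold)
    out: list[CellMeasurement] = []
    for region in measure.regionprops(labels):
        if region.area < 20:        # reject noise specks
            continue
        mask = labels == region.label
        a, b, angle = _moment_ellipse(mask)
        trace = compute_ratio_trace(scene.ch340, scene.ch380, mask,
                                    scene.bg340, scene.bg380)
        peak = float(trace[PEAK_FRAME] - trace[0])
        out.append(CellMeasurement(
            a=a, b=b, angle_deg=angle,
            orientation_class=classify_orientation(max(a, b), min(a, b), angle),
            trace=trace, peak=peak,
        ))
    return out


def parallel_minus_perpendicular(measurements: Sequence[CellMeasurement]) -> float:
    """Mean peak response of parallel cells minus that of perpendicular cells.

    Negative values mean perpendicular cells responded (were electroporated)
    more; positive values mean parallel cells did.
    """
    peaks = {"parallel": [], "perpendicular": []}
    for m in measurements:
        if m.orientation_class in peaks:
            peaks[m.orientation_class].append(m.peak)
    for cls, vals in peaks.items():
        if not vals:
            raise ValueError(f"no cells in the {cls!r} class")
    return float(np.mean(peaks["parallel"]) - np.mean(peaks["perpendicular"]))
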