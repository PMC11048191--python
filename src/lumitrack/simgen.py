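"""Synthetic-data generator: ground-truth cell populations and EM-CCD renders.

The generator plants a fully known truth — per-cell positions at both imaging
sessions, a between-session fate (retained / displaced / lost), a response
class (responder / non-responder) with a multiplicative treatment effect on
the luciferase photon rate, and a constitutive GFP rate — and renders it into
paired-timepoint 16-bit images so that every downstream stage (detection,
photometry, tracking, classification) can be verified against that truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .config import (
    ConfigError,
    KineticsConfig,
    OpticsConfig,
    PopulationConfig,
    child_rng,
)

__all__ = [
    "CellTruth",
    "PlacementError",
    "sample_population",
    "render_field",
    "simulate_timecourse",
    "truth_to_frame",
    "write_truth_csv",
    "read_truth_csv",
    "write_tiff",
    "read_tiff",
]

FATES = ("retained", "displaced", "lost")
CHANNELS = ("luminescence", "fluorescence")
TIMEPOINTS = ("t0", "t1")


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed at the requested separation."""


@dataclass(frozen=True)
class CellTruth:
    """Planted ground truth of one cell.

    ``rate_t0``/``rate_t1`` are expected luminescence photon counts per
    exposure; ``gfp_rate`` the (time-constant) fluorescence rate.  For
    ``fate == "lost"`` the t1 position and rate are absent (None).
    """

    cell_id: int
    pos_t0: Tuple[float, float]
    pos_t1: Optional[Tuple[float, float]]
    fate: str
    rate_t0: float
    rate_t1: Optional[float]
    response_class: str
    gfp_rate: float


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

def _place_points(
    n: int,
    field_size: Tuple[int, int],
    min_sep: float,
    margin: float,
    rng: np.random.Generator,
    max_attempts_per_point: int = 200,
) -> np.ndarray:
    """Uniform hard-disc placement by grid-accelerated rejection sampling."""
    w, h = field_size
    lo_x, hi_x = margin, w - margin
    lo_y, hi_y = margin, h - margin
    if n == 0:
        return np.empty((0, 2))
    cell = max(min_sep, 1.0)
    nx = max(1, int((hi_x - lo_x) // cell) + 1)
    ny = max(1, int((hi_y - lo_y) // cell) + 1)
    grid: dict = {}
    pts = np.empty((n, 2))
    sep2 = min_sep * min_sep
    placed = 0
    attempts = 0
    budget = n * max_attempts_per_point
    while placed < n:
        if attempts > budget:
            raise PlacementError(
                f"placed only {placed}/{n} cells at separation {min_sep}"
            )
        attempts += 1
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        gx, gy = int((x - lo_x) // cell), int((y - lo_y) // cell)
        ok = True
        for ix in range(max(0, gx - 1), min(nx, gx + 2)):
            for iy in range(max(0, gy - 1), min(ny, gy + 2)):
                for j in grid.get((ix, iy), ()):
                    dx = pts[j, 0] - x
                    dy = pts[j, 1] - y
                    if dx * dx + dy * dy < sep2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = (x, y)
            grid.setdefault((gx, gy), []).append(placed)
            placed += 1
    return pts


def _truncated_normal_offset(
    n: int, sd: float, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Isotropic Gaussian 2-D offsets with norm truncated at ``radius``."""
    out = np.zeros((n, 2))
    if sd == 0 or n == 0:
        return out
    todo = np.arange(n)
    while todo.size:
        cand = rng.normal(0.0, sd, size=(todo.size, 2))
        ok = np.hypot(cand[:, 0], cand[:, 1]) <= radius
        out[todo[ok]] = cand[ok]
        todo = todo[~ok]
    return out


def sample_population(config: PopulationConfig) -> List[CellTruth]:
    """Draw a ground-truth population under the given scenario.

    Fates are i.i.d. categorical over (lost, displaced, retained); the
    response class is an independent Bernoulli(p_responder) draw; the
    post-treatment rate is ``rate_t0 * exp(logFC)`` with the log fold-change
    drawn from the class's Gaussian (responders may additionally fall in the
    complete-shutdown component, see :class:`~lumitrack.config.MixtureConfig`).
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    n = config.n_cells
    rng = child_rng(config.seed, "population")
    try:
        pos0 = _place_points(
            n, config.field_size, config.min_separation, config.margin, rng
        )
    except PlacementError:
        raise
    mu, sigma = config.intensity_lognormal
    rate0 = np.exp(rng.normal(mu, sigma, size=n))
    gmu, gsigma = config.gfp_lognormal
    gfp = np.exp(rng.normal(gmu, gsigma, size=n))

    mob = config.mobility
    u = rng.uniform(size=n)
    fate = np.where(
        u < mob.p_lost,
        "lost",
        np.where(u < mob.p_lost + mob.p_displaced, "displaced", "retained"),
    )

    mix = config.mixture
    is_resp = rng.uniform(size=n) < mix.p_responder
    logfc = np.empty(n)
    nr_mu, nr_sd = mix.nonresponder_logfc
    logfc[~is_resp] = rng.normal(nr_mu, nr_sd, size=int((~is_resp).sum()))
    idx_resp = np.flatnonzero(is_resp)
    deep = rng.uniform(size=idx_resp.size) < mix.p_deep_given_responder
    r_mu, r_sd = mix.responder_logfc
    d_mu, d_sd = mix.deep_logfc
    logfc[idx_resp[~deep]] = rng.normal(r_mu, r_sd, size=int((~deep).sum()))
    logfc[idx_resp[deep]] = rng.normal(d_mu, d_sd, size=int(deep.sum()))
    rate1 = rate0 * np.exp(logfc)

    jitter = _truncated_normal_offset(n, mob.jitter_sd, mob.match_radius, rng)

    w, h = config.field_size
    lo_x, hi_x = config.margin, w - config.margin
    lo_y, hi_y = config.margin, h - config.margin

    cells: List[CellTruth] = []
    for i in range(n):
        x0, y0 = float(pos0[i, 0]), float(pos0[i, 1])
        f = str(fate[i])
        if f == "lost":
            p1 = None
            r1 = None
        elif f == "displaced":
            # re-drawn uniformly, rejected within match_radius of the origin
            # so a displaced cell is untrackable by construction
            while True:
                x1 = rng.uniform(lo_x, hi_x)
                y1 = rng.uniform(lo_y, hi_y)
                if math.hypot(x1 - x0, y1 - y0) > mob.match_radius:
                    break
            p1 = (float(x1), float(y1))
            r1 = float(rate1[i])
        else:
            x1 = min(max(x0 + jitter[i, 0], lo_x), hi_x)
            y1 = min(max(y0 + jitter[i, 1], lo_y), hi_y)
            p1 = (float(x1), float(y1))
            r1 = float(rate1[i])
        cells.append(
            CellTruth(
                cell_id=i,
                pos_t0=(x0, y0),
                pos_t1=p1,
                fate=f,
                rate_t0=float(rate0[i]),
                rate_t1=r1,
                response_class="responder" if is_resp[i] else "nonresponder",
                gfp_rate=float(gfp[i]),
            )
        )
    return cells


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _stamp_disc(
    field: np.ndarray, x: float, y: float, radius: float, total: float, ss: int = 4
) -> None:
    """Accumulate a uniform disc of integrated value ``total`` onto ``field``.

    Pixel coverage is computed by ``ss``x``ss`` supersampling so sub-pixel
    centroids are honoured; the stamped sum equals ``total`` exactly (up to
    clipping at the field border, which the placement margin prevents).
    """
    h, w = field.shape
    r = radius + 1.0
    x0, x1 = int(np.floor(x - r)), int(np.ceil(x + r)) + 1
    y0, y1 = int(np.floor(y - r)), int(np.ceil(y + r)) + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    # supersampled subpixel centres of the patch
    off = (np.arange(ss) + 0.5) / ss - 0.5
    xs = (np.arange(x0c, x1c)[:, None] + off[None, :]).ravel()
    ys = (np.arange(y0c, y1c)[:, None] + off[None, :]).ravel()
    dx2 = (xs - x) ** 2
    dy2 = (ys - y) ** 2
    inside = (dy2[:, None] + dx2[None, :]) <= radius * radius
    cov = inside.reshape(y1c - y0c, ss, x1c - x0c, ss).mean(axis=(1, 3))
    s = cov.sum()
    if s > 0:
        field[y0c:y1c, x0c:x1c] += total * (cov / s)


def expected_field(
    cells: Sequence[CellTruth],
    channel: str,
    timepoint: str,
    optics: OpticsConfig,
    field_size: Tuple[int, int],
) -> np.ndarray:
    """Noise-free expected photon image (no background, no gain)."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    w, h = field_size
    field = np.zeros((h, w), dtype=np.float64)
    for c in cells:
        pos = c.pos_t0 if timepoint == "t0" else c.pos_t1
        if pos is None:
            continue  # lost cells are simply absent at t1
        if channel == "luminescence":
            rate = c.rate_t0 if timepoint == "t0" else c.rate_t1
        else:
            rate = c.gfp_rate
        if rate is None or rate <= 0:
            continue
        x, y = pos
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"cell {c.cell_id} outside field at {timepoint}")
        _stamp_disc(field, x, y, optics.cell_radius, float(rate))
    return gaussian_filter(field, optics.psf_sigma, mode="nearest")


def render_field(
    cells: Sequence[CellTruth],
    channel: str,
    timepoint: str,
    optics: OpticsConfig,
    seed: int,
    field_size: Tuple[int, int],
    noise: bool = True,
) -> np.ndarray:
    """Render one channel/timepoint into a 2-D counts image.

    Each cell contributes a uniform disc (radius ``cell_radius``) convolved
    with a Gaussian PSF and carrying its full photon rate.  With ``noise``
    the photon image (signal + background) is Poisson-sampled, multiplied by
    ``em_gain``, Gaussian read noise is added, and the result is rounded and
    clipped to ``[0, saturation]``.  Without noise the exact expectation is
    returned as floats.
    """
    optics.validate()
    expected = expected_field(cells, channel, timepoint, optics, field_size)
    bg_photons = optics.background_level / optics.em_gain
    if not noise:
        return optics.em_gain * expected + optics.background_level
    rng = child_rng(seed, "render", channel, timepoint)
    lam = expected + bg_photons
    img = optics.em_gain * rng.poisson(lam).astype(np.float64)
    if optics.read_noise_sd > 0:
        img += rng.normal(0.0, optics.read_noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, optics.saturation)
    return img.astype(np.uint16 if optics.saturation <= 65535 else np.uint32)


# ---------------------------------------------------------------------------
# substrate kinetics
# ---------------------------------------------------------------------------

def simulate_timecourse(
    rate0: float,
    kinetics: KineticsConfig,
    seed: int,
    optics: Optional[OpticsConfig] = None,
    noise: bool = True,
    aperture_area: float = 177.0,
) -> pd.DataFrame:
    """Per-cell intensity time course after substrate addition.

    The expected intensity at time ``t`` is
    ``rate0 * exp(-decay_rate * (t - t_start))``.  Observations carry the
    camera noise aggregated over a photometric aperture: Poisson shot noise
    on the expected photons scaled by ``em_gain`` plus a Gaussian term for
    the residual background noise summed over ``aperture_area`` pixels.

    Returns a frame with columns ``time_min`` and ``intensity``.
    """
    if rate0 < 0:
        raise ValueError("rate0 must be >= 0")
    kinetics.validate()
    optics = optics or OpticsConfig()
    times = np.arange(kinetics.t_start, kinetics.t_end + 1e-9, kinetics.dt)
    lam = rate0 * np.exp(-kinetics.decay_rate * (times - kinetics.t_start))
    if not noise:
        obs = optics.em_gain * lam
    else:
        rng = child_rng(seed, "timecourse")
        agg_sd = optics.background_pixel_sd * np.sqrt(aperture_area)
        obs = optics.em_gain * rng.poisson(lam).astype(float)
        obs += rng.normal(0.0, agg_sd, size=times.size)
    return pd.DataFrame({"time_min": times, "intensity": obs})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def truth_to_frame(cells: Sequence[CellTruth]) -> pd.DataFrame:
    rows = []
    for c in cells:
        x1, y1 = (c.pos_t1 if c.pos_t1 is not None else (np.nan, np.nan))
        rows.append(
            dict(
                cell_id=c.cell_id,
                x0=c.pos_t0[0],
                y0=c.pos_t0[1],
                x1=x1,
                y1=y1,
                fate=c.fate,
                response_class=c.response_class,
                rate_t0=c.rate_t0,
                rate_t1=c.rate_t1 if c.rate_t1 is not None else np.nan,
                gfp_rate=c.gfp_rate,
            )
        )
    cols = [
        "cell_id", "x0", "y0", "x1", "y1", "fate",
        "response_class", "rate_t0", "rate_t1", "gfp_rate",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_truth_csv(cells: Sequence[CellTruth], path) -> None:
    truth_to_frame(cells).to_csv(path, index=False)


def read_truth_csv(path) -> List[CellTruth]:
    df = pd.read_csv(path)
    cells = []
    for row in df.itertuples(index=False):
        lost = isinstance(row.fate, str) and row.fate == "lost"
        cells.append(
            CellTruth(
                cell_id=int(row.cell_id),
                pos_t0=(float(row.x0), float(row.y0)),
                pos_t1=None if lost else (float(row.x1), float(row.y1)),
                fate=str(row.fate),
                rate_t0=float(row.rate_t0),
                rate_t1=None if lost else float(row.rate_t1),
                response_class=str(row.response_class),
                gfp_rate=float(row.gfp_rate),
            )
        )
    return cells


def write_tiff(image: np.ndarray, path) -> None:
    """Write a 16-bit grayscale TIFF (floats are rounded and clipped)."""
    if image.dtype != np.uint16:
        image = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), image)


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))
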