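"""Synthetic two-channel time-lapse microscopy of yeast nuclei.

Renders nuclei as bright nuclear-envelope shells plus a diffuse
nucleoplasmic pool over a noisy background, with a programmable
envelope<->nucleoplasm partition schedule, anaphase-style chromatin
distortion, and separating spindle-pole-body (SPB) puncta.  Every frame
carries a known ground truth, so the downstream quantification stages
(masking, line profiles, event calling) can be validated against the
values that generated the pixels.

The ground-truth analog of the detachment index is
``DI_true(t) = c_np(t) / c_ne(t)``, the ratio of nucleoplasmic to
envelope fluorophore concentration.

Channel layout follows the acquisition this emulates: channel 0 is the
tagged nucleoporin (shell + pool), channel 1 is the reference marker —
either a histone-labelled chromatin mass or SPB puncta.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "SimCellConfig",
    "GroundTruthTable",
    "render_frame",
    "simulate_timelapse",
    "detachment_partition",
    "rendered_compartment_areas",
    "simulate_detachment_cohort",
    "simulate_spb_cohort",
    "write_stack",
    "substream",
]

# Default physical calibration.  The pixel size is an arbitrary but
# realistic wide-field scale; it is configurable everywhere it matters.
DEFAULT_PIXEL_SIZE_UM = 0.107
DEFAULT_Z_STEP_UM = 0.5


def substream(seed: int, name: str) -> np.random.Generator:
    """Named random substream derived from one top-level seed.

    Keeps module-level reruns stable: the stream for e.g. ``"imaging"``
    does not depend on how much randomness other modules consumed.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimCellConfig:
    """Per-cell simulation parameters.

    Time-varying quantities are arrays indexed by frame; scalars are
    broadcast.  Concentrations are in arbitrary units per pixel.
    """

    cell_id: str
    center: tuple[float, float]  # (y, x) in pixels
    radius: float  # outer nuclear radius, px
    shell_thickness: float  # envelope shell thickness, px
    c_ne: np.ndarray  # envelope concentration per frame
    c_np: np.ndarray  # nucleoplasmic concentration per frame
    background: float = 100.0
    noise_sigma: float = 0.0
    poisson: bool = False
    marker: str = "histone"  # "histone" or "spb"
    histone_radius_frac: float = 0.7
    anaphase_onset: float | None = None  # minutes
    elongation: np.ndarray | None = None  # per-frame ellipse elongation
    split_distance: np.ndarray | None = None  # per-frame lobe separation, px
    spb_positions: np.ndarray | None = None  # (T, n_puncta, 2) px
    spb_amplitude: float = 400.0
    spb_sigma: float = 1.2
    t_detach: float | None = None  # minutes, programmed truth
    t_reattach: float | None = None
    t_spb_sep: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.c_ne = np.atleast_1d(np.asarray(self.c_ne, dtype=float))
        self.c_np = np.atleast_1d(np.asarray(self.c_np, dtype=float))
        if self.radius <= 0:
            raise ValueError(f"{self.cell_id}: nucleus radius must be positive")
        if not 0 < self.shell_thickness < self.radius:
            raise ValueError(
                f"{self.cell_id}: shell thickness must lie in (0, radius)"
            )
        if (self.c_ne < 0).any() or (self.c_np < 0).any():
            raise ValueError(f"{self.cell_id}: concentrations must be >= 0")
        if self.c_ne.shape != self.c_np.shape:
            raise ValueError(f"{self.cell_id}: c_ne and c_np must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.c_ne)

    def di_true(self) -> np.ndarray:
        """Ground-truth detachment index per frame (NaN where c_ne == 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(self.c_ne > 0, self.c_np / self.c_ne, np.nan)
        return out


@dataclass
class GroundTruthTable:
    """Truth channel accompanying a simulated stack.

    ``events`` has one row per cell (programmed anaphase onset, SPB
    separation, detachment and reattachment times, in minutes);
    ``di`` has one row per cell x frame with the true detachment index.
    """

    events: pd.DataFrame
    di: pd.DataFrame

    def to_csv(self, events_path, di_path) -> None:
        self.events.to_csv(events_path, index=False)
        self.di.to_csv(di_path, index=False)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _disk_coverage(shape: tuple[int, int], center: tuple[float, float],
                   radius: float) -> np.ndarray:
    """Anti-aliased disk: per-pixel coverage fraction in [0, 1].

    Edge pixels get a linear ramp over one pixel, a good approximation of
    exact area coverage that keeps sub-pixel placement from aliasing the
    intensity truth.
    """
    if radius <= 0:
        return np.zeros(shape)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    r = np.hypot(yy - center[0], xx - center[1])
    return np.clip(radius - r + 0.5, 0.0, 1.0)


def _ellipse_coverage(shape, center, a, b, ):
    """Anti-aliased axis-aligned ellipse (semi-axes a along y, b along x)."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    rn = np.sqrt(((yy - center[0]) / a) ** 2 + ((xx - center[1]) / b) ** 2)
    # approximate signed edge distance in pixels
    return np.clip((1.0 - rn) * min(a, b) + 0.5, 0.0, 1.0)


def _slice_radii(radius: float, shell: float, dz_px: float) -> tuple[float, float]:
    """In-plane outer/inner radii of a spherical shell cut at height dz."""
    outer_sq = radius**2 - dz_px**2
    outer = np.sqrt(outer_sq) if outer_sq > 0 else 0.0
    inner_r = radius - shell
    inner_sq = inner_r**2 - dz_px**2
    inner = np.sqrt(inner_sq) if inner_sq > 0 else 0.0
    return outer, inner


def render_frame(
    config: SimCellConfig,
    frame: int,
    shape: tuple[int, int] = (96, 96),
    nz: int = 1,
    z_step_px: float = DEFAULT_Z_STEP_UM / DEFAULT_PIXEL_SIZE_UM,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one timepoint as a (2, nz, Y, X) float array.

    Channel 0: nucleoporin — envelope shell at ``c_ne`` plus filled
    interior at ``c_np``, over ``background``.  Channel 1: marker
    (histone mass or SPB puncta).  With noise off the construction is
    exact: interior pixels equal ``background + c_np``, full shell
    pixels ``background + c_ne``.
    """
    if not 0 <= frame < config.n_frames:
        raise ValueError(f"frame {frame} outside simulated range")
    c_ne = float(config.c_ne[frame])
    c_np = float(config.c_np[frame])
    img = np.zeros((2, nz, shape[0], shape[1]), dtype=float)
    z_mid = (nz - 1) / 2.0
    for z in range(nz):
        dz = (z - z_mid) * z_step_px if nz > 1 else 0.0
        outer, inner = _slice_radii(config.radius, config.shell_thickness, dz)
        cov_out = _disk_coverage(shape, config.center, outer)
        cov_in = _disk_coverage(shape, config.center, inner)
        img[0, z] = config.background + c_np * cov_in + c_ne * (cov_out - cov_in)
        img[1, z] = config.background + _render_marker(config, frame, shape, dz)
    if config.noise_sigma > 0 or config.poisson:
        if rng is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, frame])
            )
        if config.poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
        img = np.clip(img, 0.0, None)
    return img


def _render_marker(config: SimCellConfig, frame: int, shape, dz: float) -> np.ndarray:
    if config.marker == "spb":
        out = np.zeros(shape)
        if config.spb_positions is None:
            return out
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        for (py, px) in np.atleast_2d(config.spb_positions[frame]):
            d2 = (yy - py) ** 2 + (xx - px) ** 2
            out += config.spb_amplitude * np.exp(-d2 / (2 * config.spb_sigma**2))
        return out
    # histone chromatin mass: disk -> elongated ellipse -> two lobes
    hr_full = config.histone_radius_frac * config.radius
    hr_sq = hr_full**2 - dz**2
    if hr_sq <= 0:
        return np.zeros(shape)
    hr = np.sqrt(hr_sq)
    amp = 300.0
    split = 0.0
    elong = 0.0
    if config.split_distance is not None:
        split = float(config.split_distance[frame])
    if config.elongation is not None:
        elong = float(config.elongation[frame])
    cy, cx = config.center
    if split > 0:
        lobes = _disk_coverage(shape, (cy, cx - split / 2), hr * 0.75)
        lobes = np.maximum(
            lobes, _disk_coverage(shape, (cy, cx + split / 2), hr * 0.75)
        )
        return amp * lobes
    if elong > 0:
        a, b = hr / (1 + elong), hr * (1 + elong)
        return amp * _ellipse_coverage(shape, (cy, cx), a, b)
    return amp * _disk_coverage(shape, (cy, cx), hr)


# ---------------------------------------------------------------------------
# partition schedules and full-stack simulation
# ---------------------------------------------------------------------------


def rendered_compartment_areas(
    radius: float,
    shell_thickness: float,
    shape: tuple[int, int],
    center: tuple[float, float],
) -> tuple[float, float]:
    """Pixel-exact (anti-aliased) areas of the rendered shell and interior.

    These are the coverage-map sums the renderer itself integrates over,
    so partition schedules built from them conserve total fluorophore to
    floating-point precision on the rendered frames.
    """
    cov_out = _disk_coverage(shape, center, radius)
    cov_in = _disk_coverage(shape, center, radius - shell_thickness)
    return float((cov_out - cov_in).sum()), float(cov_in.sum())


def detachment_partition(
    times: np.ndarray,
    t_detach: float,
    t_reattach: float,
    c_ne0: float,
    c_np0: float,
    radius: float,
    shell_thickness: float,
    detached_fraction: float = 0.8,
    areas: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Envelope/nucleoplasm concentration schedules for a detachment event.

    During [t_detach, t_reattach) a fraction of the envelope pool moves
    into the nucleoplasm.  Total fluorophore (concentration x compartment
    area) is conserved, so the transferred concentration is scaled by the
    shell-to-interior area ratio.  ``areas`` overrides the analytic
    (shell, interior) areas with pixel-exact ones from
    :func:`rendered_compartment_areas` for bit-level conservation on
    rendered frames.
    """
    times = np.asarray(times, dtype=float)
    if areas is not None:
        area_shell, area_int = areas
    else:
        r_in = radius - shell_thickness
        area_shell = np.pi * (radius**2 - r_in**2)
        area_int = np.pi * r_in**2
    phi = ((times >= t_detach) & (times < t_reattach)).astype(float)
    moved = c_ne0 * detached_fraction * phi
    c_ne = c_ne0 - moved
    c_np = c_np0 + moved * (area_shell / area_int)
    return c_ne, c_np


def simulate_timelapse(
    configs: Sequence[SimCellConfig],
    field_shape: tuple[int, int] = (96, 96),
    interval: float = 5.0,
    nz: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruthTable]:
    """Render a multi-cell stack with shape (T, C, Z, Y, X) plus truth.

    All cells must share a frame count; nuclei may not overlap (an
    overlap raises, naming the colliding cell ids).  Stacks from a given
    (configs, seed) pair are bit-identical across calls.
    """
    if interval <= 0:
        raise ValueError("frame interval must be positive")
    if not configs:
        raise ValueError("need at least one cell config")
    n_frames = configs[0].n_frames
    for c in configs:
        if c.n_frames != n_frames:
            raise ValueError("all cells must share the same number of frames")
    for i, a in enumerate(configs):
        for b in configs[i + 1:]:
            dist = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if dist < a.radius + b.radius + 2:
                raise ValueError(
                    f"nuclei overlap: cells {a.cell_id!r} and {b.cell_id!r}"
                )
    stack = np.zeros((n_frames, 2, nz, *field_shape), dtype=float)
    for ci, c in enumerate(configs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, ci]))
        for t in range(n_frames):
            frame = render_frame(c, t, field_shape, nz=nz, rng=rng)
            # subtract the per-cell background so cells superpose additively
            stack[t] += frame - (0 if len(configs) == 1 else c.background)
    times = np.arange(n_frames) * interval
    ev_rows, di_rows = [], []
    for c in configs:
        ev_rows.append(
            dict(
                cell_id=c.cell_id,
                anaphase_onset=c.anaphase_onset,
                t_spb_sep=c.t_spb_sep,
                t_detach=c.t_detach,
                t_reattach=c.t_reattach,
            )
        )
        di = c.di_true()
        for t in range(n_frames):
            di_rows.append(
                dict(cell_id=c.cell_id, frame=t, t_min=times[t], di_true=di[t])
            )
    truth = GroundTruthTable(pd.DataFrame(ev_rows), pd.DataFrame(di_rows))
    return stack, truth


def write_stack(path, stack: np.ndarray, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                interval_min: float = 5.0) -> None:
    """Write a (T, C, Z, Y, X) stack as 16-bit multi-page TIFF.

    Floating point internally, unsigned 16-bit on disk; axis order is
    recorded in the TIFF metadata.
    """
    arr = np.clip(np.round(stack), 0, 2**16 - 1).astype(np.uint16)
    tifffile.imwrite(
        path,
        arr,
        metadata={
            "axes": "TCZYX",
            "pixel_size_um": pixel_size_um,
            "interval_min": interval_min,
        },
    )


def config_to_yaml(configs: Sequence[SimCellConfig], path) -> None:
    docs = []
    for c in configs:
        d = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in c.__dict__.items()
        }
        docs.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(docs, fh)


# ---------------------------------------------------------------------------
# cohort generators for event-timing studies
# ---------------------------------------------------------------------------


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal draws truncated at 0 by resampling (durations are nonnegative)."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out <= 0
    return out


def simulate_detachment_cohort(
    n_cells: int,
    interval: float = 5.0,
    t_max: float = 70.0,
    duration_mean: float = 10.3,
    duration_sd: float = 2.9,
    onset_window: tuple[float, float] = (20.0, 40.0),
    baseline_di: float = 0.2,
    detached_di: float = 1.0,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort of per-cell DI time series with programmed detachment events.

    Each cell detaches at an anaphase onset drawn uniformly (continuous,
    so events land off-grid as in real acquisitions) and reattaches after
    a Normal(duration_mean, duration_sd) duration truncated at 0.  The DI
    trace steps from ``baseline_di`` to ``detached_di`` during the event,
    plus Gaussian measurement noise, sampled every ``interval`` minutes.

    Returns (di_long, truth): tidy DI series (cell_id, t_min, di) and the
    per-cell truth table (onset = programmed anaphase onset = detachment).
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + 1e-9, interval)
    onsets = rng.uniform(*onset_window, n_cells)
    durations = _truncated_normal(rng, duration_mean, duration_sd, n_cells)
    di_rows, truth_rows = [], []
    for i in range(n_cells):
        cid = f"cell{i:04d}"
        inside = (times >= onsets[i]) & (times < onsets[i] + durations[i])
        di = np.where(inside, detached_di, baseline_di)
        di = np.clip(di + rng.normal(0, noise_sd, di.shape), 0, None)
        for t, v in zip(times, di):
            di_rows.append(dict(cell_id=cid, t_min=t, di=v))
        truth_rows.append(
            dict(
                cell_id=cid,
                anaphase_onset=onsets[i],
                t_detach=onsets[i],
                t_reattach=onsets[i] + durations[i],
                duration=durations[i],
            )
        )
    return pd.DataFrame(di_rows), pd.DataFrame(truth_rows)


def simulate_spb_cohort(
    n_cells: int,
    interval: float = 5.0,
    t_max: float = 95.0,
    offset_mean: float = 24.2,
    offset_sd: float = 5.4,
    sep_window: tuple[float, float] = (10.0, 30.0),
    duration_mean: float = 10.3,
    duration_sd: float = 2.9,
    baseline_di: float = 0.2,
    detached_di: float = 1.0,
    noise_sd: float = 0.02,
    frame_shape: tuple[int, int] = (48, 48),
    initial_separation: float = 3.5,
    separation_rate: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, np.ndarray], pd.DataFrame]:
    """Cohort anchored on SPB separation.

    Each cell's SPB separates at a uniform continuous time t0; two
    Gaussian puncta then sit ``initial_separation`` px apart (resolvable
    immediately) and drift apart at ``separation_rate`` px/min.
    Detachment is programmed at t0 plus a Normal(offset_mean, offset_sd)
    offset truncated at 0, lasting a truncated-normal duration.

    Returns (di_long, spb_stacks, truth) where ``spb_stacks`` maps
    cell_id to a (T, Y, X) marker-channel movie for SPB detection.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + 1e-9, interval)
    t0s = rng.uniform(*sep_window, n_cells)
    offsets = _truncated_normal(rng, offset_mean, offset_sd, n_cells)
    durations = _truncated_normal(rng, duration_mean, duration_sd, n_cells)
    center = (frame_shape[0] / 2.0, frame_shape[1] / 2.0)
    di_rows, truth_rows = [], []
    stacks: dict[str, np.ndarray] = {}
    for i in range(n_cells):
        cid = f"cell{i:04d}"
        t_det = t0s[i] + offsets[i]
        inside = (times >= t_det) & (times < t_det + durations[i])
        di = np.where(inside, detached_di, baseline_di)
        di = np.clip(di + rng.normal(0, noise_sd, di.shape), 0, None)
        sep = np.where(
            times >= t0s[i],
            initial_separation + separation_rate * (times - t0s[i]),
            0.0,
        )
        pos = np.zeros((len(times), 2, 2))
        pos[:, 0] = center
        pos[:, 1] = center
        pos[:, 0, 1] -= sep / 2
        pos[:, 1, 1] += sep / 2
        cfg = SimCellConfig(
            cell_id=cid,
            center=center,
            radius=14.0,
            shell_thickness=3.0,
            c_ne=np.zeros(len(times)),
            c_np=np.zeros(len(times)),
            background=100.0,
            noise_sigma=5.0,
            marker="spb",
            spb_positions=pos,
            seed=int(rng.integers(0, 2**31)),
        )
        movie = np.empty((len(times), *frame_shape))
        cell_rng = np.random.default_rng(np.random.SeedSequence([seed, 7, i]))
        for t in range(len(times)):
            movie[t] = render_frame(cfg, t, frame_shape, rng=cell_rng)[1, 0]
        stacks[cid] = movie
        for t, v in zip(times, di):
            di_rows.append(dict(cell_id=cid, t_min=t, di=v))
        truth_rows.append(
            dict(
                cell_id=cid,
                t_spb_sep=t0s[i],
                t_detach=t_det,
                t_reattach=t_det + durations[i],
                offset=offsets[i],
                duration=durations[i],
            )
        )
    return pd.DataFrame(di_rows), stacks, pd.DataFrame(truth_rows)
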