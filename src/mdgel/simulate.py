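"""Synthetic 2-DE gel scenes with known ground truth.

The generator emulates the structure of a pooled-dialysate 2-DE
experiment: ~300 detectable spots per gel, a 100 kDa membrane-passage
cutoff (solutes above the microdialysis catheter cutoff never reach
the gel), a linear pH 3–10 first dimension, a log-linear apparent-MW
second dimension, group-specific two-fold-or-greater abundance shifts
in a designated subset of spots, per-gel global staining scale
factors, and additive background plus Gaussian (optionally Poisson)
noise. Spots are rendered as 2-D Gaussians whose discrete integral
equals the true spot volume times the gel scale factor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AxisCalibration, GelImage


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition parameters for one synthetic scene.

    Defaults reproduce the benchmark scene: 300 spots, 20% of them
    truly differential with |log2 ratio| in [1, 3] (at least two-fold),
    the rest drawn tightly around ratio 1, and noise set so the
    weakest spot's peak amplitude is ten times the noise SD.
    """

    n_spots: int = 300
    membrane_cutoff: float = 100.0  # kDa
    ph_range: tuple[float, float] = (3.0, 10.0)
    mw_range: tuple[float, float] = (10.0, 100.0)  # kDa
    frac_differential: float = 0.2
    fold_log2_range: tuple[float, float] = (1.0, 3.0)
    null_log2_sd: float = 0.15
    null_log2_max: float = 0.5
    gel_scale_factors: dict = field(
        default_factory=lambda: {"case": 1.0, "control": 1.3}
    )
    volume_range: tuple[float, float] = (200.0, 15000.0)
    volume_log_sigma: float = 0.8
    background_level: float = 60.0
    noise_sd: float = 0.8
    poisson_noise: bool = False
    spot_sd: tuple[float, float] = (2.0, 2.0)  # (row, col) px
    min_separation_px: float = 16.0
    image_shape: tuple[int, int] = (768, 1024)
    bit_depth: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_differential <= 1:
            raise ConfigError("frac_differential must be in [0, 1]")
        if self.ph_range[0] >= self.ph_range[1]:
            raise ConfigError("ph_range must be increasing")
        if self.mw_range[0] > self.membrane_cutoff:
            raise ConfigError("mw_range lower bound exceeds membrane cutoff")
        if any(s <= 0 for s in self.gel_scale_factors.values()):
            raise ConfigError("gel scale factors must be > 0")


@dataclass
class GelScene:
    """Ground truth plus rendered images for a simulated two-group study."""

    config: SimulationConfig
    truth: pd.DataFrame
    images: dict[str, GelImage] = field(default_factory=dict)


def _place_spots(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample (pI, MW) pairs with a minimum pixel separation."""
    cal = AxisCalibration(
        shape=config.image_shape, ph_range=config.ph_range, mw_range=config.mw_range
    )
    mw_hi = min(config.mw_range[1], config.membrane_cutoff)
    log_lo, log_hi = np.log10(config.mw_range[0]), np.log10(mw_hi)
    margin = 0.03
    placed: list[tuple[float, float]] = []  # (row, col)
    coords = np.empty((config.n_spots, 2))
    attempts = 0
    while len(placed) < config.n_spots:
        attempts += 1
        if attempts > 200 * config.n_spots:
            raise ConfigError(
                "could not place spots at the requested minimum separation"
            )
        pi = rng.uniform(*config.ph_range)
        pi = config.ph_range[0] + (config.ph_range[1] - config.ph_range[0]) * (
            margin + (1 - 2 * margin) * (pi - config.ph_range[0])
            / (config.ph_range[1] - config.ph_range[0])
        )
        mw = 10 ** rng.uniform(log_lo + margin * (log_hi - log_lo),
                               log_hi - margin * (log_hi - log_lo))
        r, c = cal.row_of_mw(mw), cal.col_of_pi(pi)
        if any((r - r0) ** 2 + (c - c0) ** 2 < config.min_separation_px ** 2
               for r0, c0 in placed):
            continue
        coords[len(placed)] = (pi, mw)
        placed.append((r, c))
    return coords


def simulate_proteome(config: SimulationConfig) -> pd.DataFrame:
    """Draw the ground-truth spot table for a two-group scene.

    Columns: spot_id, pi, mw_kda, volume_control, volume_case,
    true_ratio (case/control), differential. Exactly
    ``round(frac_differential * n_spots)`` spots are differential with
    |log2 ratio| drawn uniformly from ``fold_log2_range`` (so every
    designated spot is at least two-fold changed); the remainder draw
    a truncated-normal log2 ratio well inside (0.5, 2).
    """
    columns = ["spot_id", "pi", "mw_kda", "volume_control", "volume_case",
               "true_ratio", "differential"]
    if config.n_spots == 0:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            columns, [str, float, float, float, float, float, bool])})
    rng = np.random.default_rng(config.seed)
    coords = _place_spots(config, rng)
    n = config.n_spots
    n_diff = round(config.frac_differential * n)
    differential = np.zeros(n, dtype=bool)
    differential[rng.choice(n, size=n_diff, replace=False)] = True

    lo, hi = config.volume_range
    centre = np.sqrt(lo * hi)
    volume = np.clip(
        centre * np.exp(rng.normal(0.0, config.volume_log_sigma, size=n)), lo, hi
    )

    log2r = np.clip(
        rng.normal(0.0, config.null_log2_sd, size=n),
        -config.null_log2_max, config.null_log2_max,
    )
    mag = rng.uniform(*config.fold_log2_range, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    log2r[differential] = (sign * mag)[differential]

    # Equal protein load per gel (as in pooled-gel 2-DE): rescale the
    # case gel to the control total, so the per-spot ratio is
    # compositional — exactly what ppm normalization measures. The
    # rescale shifts every log2 ratio by a common constant, so the
    # designated differential spots are nudged back to their drawn
    # magnitude until the fixed point where both constraints hold.
    lo_mag = config.fold_log2_range[0]
    f = log2r.copy()
    for _ in range(100):
        c = np.log2(volume.sum() / (volume * 2.0 ** f).sum())
        realized = f + c
        viol = differential & (np.abs(realized) < lo_mag - 1e-12)
        if not viol.any():
            break
        f[viol] = (sign * mag)[viol] - c
    ratio = 2.0 ** (f + c)

    return pd.DataFrame({
        "spot_id": [f"s{i:04d}" for i in range(n)],
        "pi": coords[:, 0],
        "mw_kda": coords[:, 1],
        "volume_control": volume,
        "volume_case": volume * ratio,
        "true_ratio": ratio,
        "differential": differential,
    })


def render_gel(
    truth: pd.DataFrame, group: str, config: SimulationConfig, rng=None
) -> GelImage:
    """Render one gel: Gaussian spots + background + noise.

    Each spot's discrete integral equals its true volume times the
    group's gel scale factor. Spots whose centre maps outside the
    image are dropped (counted in ``image.meta['n_dropped']``). Pixel
    values are clipped to the detector's 12-bit range; the clipped
    fraction is reported in ``image.meta`` (zero on default scenes).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    nrow, ncol = config.image_shape
    cal = AxisCalibration(
        shape=config.image_shape, ph_range=config.ph_range, mw_range=config.mw_range
    )
    scale = config.gel_scale_factors[group]
    sr, sc = config.spot_sd
    img = np.zeros((nrow, ncol))
    vol_col = f"volume_{group}"
    n_dropped = 0
    half = int(np.ceil(5 * max(sr, sc)))
    for row in truth.itertuples():
        r0, c0 = cal.row_of_mw(row.mw_kda), cal.col_of_pi(row.pi)
        if not (0 <= r0 < nrow and 0 <= c0 < ncol):
            n_dropped += 1
            continue
        v = getattr(row, vol_col) * scale
        r_lo, r_hi = max(0, int(r0) - half), min(nrow, int(r0) + half + 1)
        c_lo, c_hi = max(0, int(c0) - half), min(ncol, int(c0) + half + 1)
        rr = np.arange(r_lo, r_hi)[:, None]
        cc = np.arange(c_lo, c_hi)[None, :]
        g = np.exp(-0.5 * (((rr - r0) / sr) ** 2 + ((cc - c0) / sc) ** 2))
        img[r_lo:r_hi, c_lo:c_hi] += v / (2 * np.pi * sr * sc) * g
    img += config.background_level
    if config.poisson_noise:
        img = rng.poisson(np.maximum(img, 0)).astype(float)
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.maximum(img, 0.0)
    top = 2 ** config.bit_depth - 1
    clipped_fraction = float(np.mean(img > top))
    # the detector range is physical: values are always clipped, and the
    # clipped fraction is reported so a saturated scene is visible
    img = np.minimum(img, top)
    image = GelImage(
        pixels=img,
        bit_depth=config.bit_depth,
        calibration=cal,
        gel_id=group,
        meta={"n_dropped": n_dropped, "clipped_fraction": clipped_fraction,
              "scale_factor": scale},
    )
    return image


def simulate_scene(config: SimulationConfig) -> GelScene:
    """Ground truth plus one rendered gel per group, fully seeded."""
    truth = simulate_proteome(config)
    rng = np.random.default_rng(config.seed + 1)
    images = {
        group: render_gel(truth, group, config, rng=rng)
        for group in sorted(config.gel_scale_factors)
    }
    return GelScene(config=config, truth=truth, images=images)


def export_truth(scene: GelScene, out_dir: str | Path) -> list[Path]:
    """Write truth CSV, per-gel TIFFs and the config; return paths."""
    from .io import write_gel_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    truth_path = out / "truth.csv"
    scene.truth.to_csv(truth_path, index=False)
    written.append(truth_path)
    cfg_path = out / "config.json"
    cfg = dataclasses.asdict(scene.config)
    cfg_path.write_text(json.dumps(cfg, indent=2, default=list), encoding="utf-8")
    written.append(cfg_path)
    for group, image in scene.images.items():
        p = out / f"gel_{group}.tiff"
        write_gel_image(image, p)
        written.append(p)
    return written


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
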