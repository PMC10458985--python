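"""Procedural ground-truth objects and paired LR/HR dataset construction.

Real FPM training corpora pair high-resolution intensity/phase images with the
low-resolution complex amplitudes a one-sweep phase retrieval produces from
the simulated captures.  No such corpus is deposited for this problem, so HR
content is generated procedurally with controllable spectral properties; every
style is built to carry energy beyond the coherent cutoff NA/lambda so that
the LR input genuinely loses information the network must restore.

Styles
------
blobs
    Sums of random Gaussian bumps at mixed scales plus fine smoothed noise;
    emulates sparse cell-like amplitude objects.
fbm_texture
    Power-law (1/f^beta) filtered noise; emulates tissue-like broadband
    texture.
checker
    Random-offset checkerboard (period 4 px) blended with a smooth ramp; a
    worst-case object whose square-wave harmonics extend far past the cutoff.

Intensity channels lie in [0.1, 1] (non-zero background keeps phase
observable); phase channels span the full [0, 1], i.e. [-pi, pi] after
decoding, to exercise phase wrapping.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .optics import DEFAULT_GEOMETRY, OpticsGeometry, simulate_stack, spectral_overlap
from .retrieval import channels_to_complex, one_iteration_init

__all__ = [
    "SamplePair",
    "DatasetManifest",
    "Dataset",
    "generate_hr_pair",
    "build_dataset",
    "degrade_with_noise_level",
    "load_dataset",
    "super_cutoff_energy_fraction",
    "STYLES",
]

STYLES = ("blobs", "fbm_texture", "checker")

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class SamplePair:
    """One training example: LR 2-channel input and HR 2-channel target."""

    lr: np.ndarray
    hr: np.ndarray
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        if self.lr.shape != self.hr.shape:
            raise ValueError("lr and hr must share shape")
        for name, arr in (("lr", self.lr), ("hr", self.hr)):
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"{name} channel values must lie in [0, 1]")


@dataclass(frozen=True)
class DatasetManifest:
    """Everything needed to rebuild a dataset bit-for-bit."""

    n_samples: int = 256
    geometry: OpticsGeometry = DEFAULT_GEOMETRY
    noise_sigma: float = 3e-4
    master_seed: int = 0
    split: tuple = (0.8, 0.1, 0.1)
    styles: tuple = STYLES

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for s in self.styles:
            if s not in STYLES:
                raise ValueError(f"unknown style {s!r}")

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "geometry": self.geometry.to_dict(),
            "noise_sigma": self.noise_sigma,
            "master_seed": self.master_seed,
            "split": list(self.split),
            "styles": list(self.styles),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetManifest":
        d = dict(d)
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = OpticsGeometry(**d["geometry"])
        if "split" in d:
            d["split"] = tuple(d["split"])
        if "styles" in d:
            d["styles"] = tuple(d["styles"])
        return cls(**d)


@dataclass
class Dataset:
    """In-memory paired dataset: lr/hr arrays of shape (N, 2, H, W)."""

    lr: np.ndarray
    hr: np.ndarray
    seeds: np.ndarray
    manifest: DatasetManifest

    def __len__(self) -> int:
        return self.lr.shape[0]

    def subset(self, idx) -> "Dataset":
        return Dataset(self.lr[idx], self.hr[idx], self.seeds[idx], self.manifest)

    def splits(self) -> tuple:
        """(train, val, test) subsets per the manifest's split fractions."""
        n = len(self)
        f_train, f_val, _ = self.manifest.split
        n_train = int(round(n * f_train))
        n_val = int(round(n * f_val))
        return (
            self.subset(slice(0, n_train)),
            self.subset(slice(n_train, n_train + n_val)),
            self.subset(slice(n_train + n_val, n)),
        )


# ---------------------------------------------------------------------------
# Procedural HR content
# ---------------------------------------------------------------------------

def _rescale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = x.max() - x.min()
    if span <= 0:
        return np.full_like(x, 0.5 * (lo + hi))
    return lo + (hi - lo) * (x - x.min()) / span


def _blobs(rng: np.random.Generator, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    img = np.zeros((size, size))
    n_blobs = int(rng.integers(6, 14))
    for _ in range(n_blobs):
        cx, cy = rng.uniform(0, size, 2)
        sx, sy = rng.uniform(1.0, size / 8.0, 2)
        amp = rng.uniform(0.3, 1.0)
        img += amp * np.exp(-(((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2))
    # fine smoothed texture adds energy past the coherent cutoff
    img += 0.25 * ndimage.gaussian_filter(rng.standard_normal((size, size)), 0.8)
    return img


def _fbm(rng: np.random.Generator, size: int, beta: float = 1.8) -> np.ndarray:
    f = np.fft.fftfreq(size)
    rad = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    rad[0, 0] = 1.0
    spec = rng.standard_normal((size, size)) + 1j * rng.standard_normal((size, size))
    spec *= rad ** (-beta / 2.0)
    spec[0, 0] = 0.0
    return np.fft.ifft2(spec).real


def _checker(rng: np.random.Generator, size: int, period: int = 4) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    ox, oy = rng.integers(0, period, 2)
    board = (((xx + ox) // (period // 2)) + ((yy + oy) // (period // 2))) % 2
    ramp = _fbm(rng, size, beta=3.0)
    return 0.7 * board.astype(np.float64) + 0.3 * _rescale(ramp, 0.0, 1.0)


_STYLE_FN = {"blobs": _blobs, "fbm_texture": _fbm, "checker": _checker}


def generate_hr_pair(size: int, seed: int, style: str = "blobs") -> np.ndarray:
    """Deterministic (2, size, size) HR image: intensity in [0.1, 1], phase in [0, 1].

    Intensity and phase are statistically independent draws from the same style
    family; same (size, seed, style) always yields identical images.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    if style not in _STYLE_FN:
        raise ValueError(f"unknown style {style!r}; choose from {STYLES}")
    fn = _STYLE_FN[style]
    rng_i = np.random.default_rng((seed, 0))
    rng_p = np.random.default_rng((seed, 1))
    intensity = np.clip(_rescale(fn(rng_i, size), 0.1, 1.0), 0.1, 1.0)
    phase = np.clip(_rescale(fn(rng_p, size), 0.0, 1.0), 0.0, 1.0)
    return np.stack([intensity, phase])


def super_cutoff_energy_fraction(
    image: np.ndarray, geometry: OpticsGeometry
) -> float:
    """Fraction of mean-removed spectral energy beyond the coherent cutoff.

    DC is excluded because a bright background otherwise swamps the ratio.
    """
    img = np.asarray(image, dtype=np.float64)
    spec = np.fft.fftshift(np.fft.fft2(img - img.mean()))
    n = img.shape[-1]
    df = geometry.freq_step
    u = (np.arange(n) - n // 2) * df
    uu, vv = np.meshgrid(u, u, indexing="xy")
    outside = uu**2 + vv**2 > geometry.cutoff_frequency**2
    total = float(np.sum(np.abs(spec) ** 2))
    if total == 0:
        return 0.0
    return float(np.sum(np.abs(spec[outside]) ** 2)) / total


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------

def _sample_seed(master_seed: int, i: int) -> int:
    return (master_seed + i) % _SEED_MOD


def make_sample(
    i: int, manifest: DatasetManifest
) -> SamplePair:
    """Build sample i: HR pair -> complex object -> noisy stack -> 1-sweep LR."""
    g = manifest.geometry
    seed = _sample_seed(manifest.master_seed, i)
    style = manifest.styles[i % len(manifest.styles)]
    hr = generate_hr_pair(g.hr_size, seed, style)
    obj = channels_to_complex(hr, pixel_size=g.hr_pixel)
    stack = simulate_stack(obj, g, manifest.noise_sigma, seed=seed)
    lr = one_iteration_init(stack)
    lr = np.clip(lr, 0.0, 1.0)
    return SamplePair(lr=lr, hr=hr, noise_sigma=manifest.noise_sigma, seed=seed)


def build_dataset(
    manifest: DatasetManifest, out_path: str | Path | None = None
) -> Dataset:
    """Materialize the dataset described by ``manifest``.

    Pure function of the manifest: rebuilding yields byte-identical arrays.
    Persists NPZ + JSON manifest when ``out_path`` (a directory) is given.
    Raises if the geometry's adjacent-pupil spectral overlap is below 0.5,
    because phase retrieval on such a dataset is ill-posed.
    """
    overlap = spectral_overlap(manifest.geometry)
    if overlap < 0.5:
        raise ValueError(
            f"spectral overlap {overlap:.3f} < 0.5: dataset would be unreconstructable"
        )
    pairs = [make_sample(i, manifest) for i in range(manifest.n_samples)]
    ds = Dataset(
        lr=np.stack([p.lr for p in pairs]).astype(np.float32),
        hr=np.stack([p.hr for p in pairs]).astype(np.float32),
        seeds=np.array([p.seed for p in pairs], dtype=np.int64),
        manifest=manifest,
    )
    if out_path is not None:
        save_dataset(ds, out_path)
    return ds


def degrade_with_noise_level(manifest: DatasetManifest, sigma: float) -> Dataset:
    """Same HR pairs (same seeds), stacks re-simulated at noise level ``sigma``.

    Enables paired noise-robustness comparisons: the targets are identical
    across noise levels; only the LR inputs change.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return build_dataset(dataclasses.replace(manifest, noise_sigma=sigma))


def save_dataset(ds: Dataset, out_path: str | Path) -> None:
    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "dataset.npz", lr=ds.lr, hr=ds.hr, seeds=ds.seeds)
    (out / "manifest.json").write_text(json.dumps(ds.manifest.to_dict(), indent=2))


def export_sample_tiffs(ds: Dataset, out_path: str | Path, limit: int | None = None) -> int:
    """Optional per-sample TIFF export for visual inspection.

    Writes ``sample_####_{lr,hr}.tif`` (float32, channel-first) and returns
    the number of samples written.
    """
    import tifffile

    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    n = len(ds) if limit is None else min(limit, len(ds))
    for i in range(n):
        tifffile.imwrite(out / f"sample_{i:04d}_lr.tif", ds.lr[i].astype(np.float32))
        tifffile.imwrite(out / f"sample_{i:04d}_hr.tif", ds.hr[i].astype(np.float32))
    return n


def load_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    manifest = DatasetManifest.from_dict(json.loads((path / "manifest.json").read_text()))
    with np.load(path / "dataset.npz") as z:
        return Dataset(z["lr"], z["hr"], z["seeds"], manifest)
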