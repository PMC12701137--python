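"""Synthetic single-cell blood-smear crops.

Generates balanced two-class datasets of labelled single-cell images that
mimic the structure of public single-cell leukemia benchmarks: one white
blood cell per crop over a light background, H&E-like staining common to
both classes, and a class difference carried entirely by nuclear morphology
(nucleus/cell area fraction, boundary irregularity, chromatin texture).
Blast cells have enlarged, irregular, coarsely textured nuclei; healthy
lymphocytes compact regular ones.

Every operation is a pure function of its spec and seed: per-sample random
streams are derived from ``(seed, sample index)``, renders are quantized to
the 8-bit grid before return, and files are written as lossless PNG, so
in-memory samples, written files and re-read files are bit-identical.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from ._seeding import sample_rng
from .errors import InvalidGeometryError, LabelParsingError

__all__ = [
    "StainParams",
    "CellGeometry",
    "SyntheticDatasetSpec",
    "ImageSample",
    "ManifestRecord",
    "DatasetManifest",
    "HEALTHY_GEOMETRY",
    "BLAST_GEOMETRY",
    "DEFAULT_STAIN",
    "default_spec",
    "render_cell",
    "sample_dataset",
    "generate_dataset",
    "read_manifest",
    "load_image",
    "load_samples",
]

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}
_MAX_HARMONIC = 8  # low-order radial Fourier perturbation only


def _check_rgb(name: str, color: Sequence[float]) -> tuple[float, float, float]:
    c = tuple(float(v) for v in color)
    if len(c) != 3 or any(not (0.0 <= v <= 1.0) for v in c):
        raise ValueError(f"{name} must be an RGB triple in [0, 1], got {color!r}")
    return c  # type: ignore[return-value]


@dataclass(frozen=True)
class StainParams:
    """H&E-like stain model shared by both classes.

    Colours are RGB triples in [0, 1]; ``color_jitter_sd`` perturbs the three
    base colours per image (slide-to-slide stain variation) and
    ``pixel_noise_sd`` adds per-pixel sensor noise.
    """

    nucleus_color: tuple[float, float, float] = (0.36, 0.22, 0.54)
    cytoplasm_color: tuple[float, float, float] = (0.80, 0.58, 0.72)
    background_color: tuple[float, float, float] = (0.93, 0.90, 0.94)
    color_jitter_sd: float = 0.02
    pixel_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("nucleus_color", "cytoplasm_color", "background_color"):
            object.__setattr__(self, name, _check_rgb(name, getattr(self, name)))
        if self.color_jitter_sd < 0 or self.pixel_noise_sd < 0:
            raise ValueError("jitter/noise standard deviations must be >= 0")


@dataclass(frozen=True)
class CellGeometry:
    """Morphology distribution for one class.

    ``nucleus_fraction`` is nucleus radius over cell radius (dimensionless,
    in (0, 1)); ``boundary_irregularity`` scales a low-order radial Fourier
    perturbation of both contours; ``texture_grain`` is the amplitude of the
    chromatin intensity field inside the nucleus.
    """

    cell_radius_mean: float = 27.0
    cell_radius_sd: float = 2.5
    nucleus_fraction_mean: float = 0.52
    nucleus_fraction_sd: float = 0.05
    boundary_irregularity: float = 0.04
    texture_grain: float = 0.03

    def __post_init__(self) -> None:
        if not (0.0 < self.nucleus_fraction_mean < 1.0):
            raise ValueError("nucleus_fraction_mean must lie in (0, 1)")
        for name in ("cell_radius_sd", "nucleus_fraction_sd", "boundary_irregularity", "texture_grain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cell_radius_mean <= 0:
            raise ValueError("cell_radius_mean must be > 0")


#: Default class morphologies, calibrated so that descriptor features separate
#: the classes essentially perfectly at separability 1.
HEALTHY_GEOMETRY = CellGeometry()
BLAST_GEOMETRY = CellGeometry(
    cell_radius_mean=30.0,
    cell_radius_sd=2.5,
    nucleus_fraction_mean=0.82,
    nucleus_fraction_sd=0.05,
    boundary_irregularity=0.16,
    texture_grain=0.10,
)
DEFAULT_STAIN = StainParams()


def interpolate_geometry(healthy: CellGeometry, blast: CellGeometry, separability: float) -> CellGeometry:
    """Blast geometry actually used: healthy + separability * (blast - healthy), fieldwise."""
    s = float(separability)
    fields = {
        f.name: (1 - s) * getattr(healthy, f.name) + s * getattr(blast, f.name)
        for f in dataclasses.fields(CellGeometry)
    }
    return CellGeometry(**fields)


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Full recipe for one dataset; with ``seed`` it determines every pixel."""

    n_healthy: int = 130
    n_blast: int = 130
    image_size: int = 96
    healthy_geometry: CellGeometry = field(default_factory=lambda: HEALTHY_GEOMETRY)
    blast_geometry: CellGeometry = field(default_factory=lambda: BLAST_GEOMETRY)
    stain: StainParams = field(default_factory=lambda: DEFAULT_STAIN)
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_blast < 0:
            raise ValueError("class counts must be >= 0")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not (0.0 <= self.separability <= 1.0):
            raise ValueError("separability must lie in [0, 1]")

    @property
    def effective_blast_geometry(self) -> CellGeometry:
        """Blast morphology after the separability interpolation toward healthy."""
        return interpolate_geometry(self.healthy_geometry, self.blast_geometry, self.separability)


@dataclass(frozen=True)
class ImageSample:
    """One labelled single-cell crop: H x W x 3 pixels in [0, 1]."""

    pixels: np.ndarray
    label: int
    sample_id: str

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] != p.shape[1]:
            raise ValueError("pixels must be a square H x W x 3 array")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (healthy) or 1 (blast)")
        object.__setattr__(self, "pixels", p)


@dataclass(frozen=True)
class ManifestRecord:
    file: str
    sample_id: str
    label: int


@dataclass(frozen=True)
class DatasetManifest:
    records: tuple[ManifestRecord, ...]
    seed: int | None = None
    spec: SyntheticDatasetSpec | None = None

    def __post_init__(self) -> None:
        for r in self.records:
            stem = Path(r.file).stem
            if not stem.endswith(f"_{r.label}"):
                raise ValueError(f"file name {r.file!r} does not carry the `_{r.label}` label suffix")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


def _fourier_radius(theta: np.ndarray, coeffs: np.ndarray, irregularity: float) -> np.ndarray:
    """Radial modulation 1 + irregularity * sum_k a_k cos(k theta) + b_k sin(k theta), k = 2..8."""
    mod = np.ones_like(theta)
    for i, k in enumerate(range(2, _MAX_HARMONIC + 1)):
        mod += irregularity * (coeffs[i, 0] * np.cos(k * theta) + coeffs[i, 1] * np.sin(k * theta))
    return np.clip(mod, 0.3, None)


def _render_arrays(
    geometry: CellGeometry, stain: StainParams, image_size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render pixels plus the internally known cell and nucleus masks."""
    size = int(image_size)
    if size < 32:
        raise ValueError("image_size must be >= 32")

    radius = float(rng.normal(geometry.cell_radius_mean, geometry.cell_radius_sd))
    if radius > size / 2:
        raise InvalidGeometryError(
            f"sampled cell radius {radius:.1f} px exceeds image_size/2 = {size / 2:.1f} px"
        )
    radius = max(radius, 3.0)
    nucleus_fraction = float(np.clip(rng.normal(geometry.nucleus_fraction_mean, geometry.nucleus_fraction_sd), 0.05, 0.95))

    center = size / 2 + rng.uniform(-2.0, 2.0, size=2)
    # k-th harmonic amplitude ~ N(0, 1/k): smooth, low-order contours
    ks = np.arange(2, _MAX_HARMONIC + 1, dtype=float)
    cell_coeffs = rng.normal(0.0, 1.0, size=(len(ks), 2)) / ks[:, None]
    nuc_coeffs = rng.normal(0.0, 1.0, size=(len(ks), 2)) / ks[:, None]
    nucleus_radius = nucleus_fraction * radius
    max_off = 0.5 * (radius - nucleus_radius)
    nucleus_center = center + rng.uniform(-1.0, 1.0, size=2) * max_off

    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = rows - center[0], cols - center[1]
    theta = np.arctan2(dy, dx)
    cell_mask = np.hypot(dy, dx) <= radius * _fourier_radius(theta, cell_coeffs, geometry.boundary_irregularity)

    ndy, ndx = rows - nucleus_center[0], cols - nucleus_center[1]
    ntheta = np.arctan2(ndy, ndx)
    # nucleus contours run rougher than the cell outline (chromatin lobes)
    nucleus_mask = (
        np.hypot(ndy, ndx)
        <= nucleus_radius * _fourier_radius(ntheta, nuc_coeffs, 1.5 * geometry.boundary_irregularity)
    ) & cell_mask

    jitter = (
        rng.normal(0.0, stain.color_jitter_sd, size=3) if stain.color_jitter_sd > 0 else np.zeros(3)
    )
    background = np.asarray(stain.background_color) + jitter
    cytoplasm = np.asarray(stain.cytoplasm_color) + jitter
    nucleus = np.asarray(stain.nucleus_color) + jitter

    pixels = np.empty((size, size, 3), dtype=np.float64)
    pixels[:] = background
    pixels[cell_mask] = cytoplasm
    pixels[nucleus_mask] = nucleus

    if geometry.texture_grain > 0:
        grain = gaussian_filter(rng.standard_normal((size, size)), sigma=1.2)
        sd = grain.std()
        if sd > 0:
            grain /= sd
        pixels[nucleus_mask] += geometry.texture_grain * grain[nucleus_mask, None]

    if stain.pixel_noise_sd > 0:
        pixels += rng.normal(0.0, stain.pixel_noise_sd, size=pixels.shape)

    # quantize to the 8-bit grid so rendered, written and re-read pixels agree exactly
    pixels = np.round(np.clip(pixels, 0.0, 1.0) * 255.0) / 255.0
    return pixels, cell_mask, nucleus_mask


def render_cell(
    geometry: CellGeometry,
    stain: StainParams,
    label: int,
    image_size: int,
    rng: np.random.Generator,
    sample_id: str = "cell",
    return_masks: bool = False,
):
    """Render one labelled cell crop.

    With ``return_masks=True`` also returns the ground-truth cell and nucleus
    boolean masks (used for calibration and testing only; they are not part
    of the dataset contract).
    """
    pixels, cell_mask, nucleus_mask = _render_arrays(geometry, stain, image_size, rng)
    sample = ImageSample(pixels=pixels, label=int(label), sample_id=sample_id)
    if return_masks:
        return sample, cell_mask, nucleus_mask
    return sample


def _sample_id(index: int, label: int) -> str:
    return f"Im{index + 1:03d}_{label}"


def sample_dataset(spec: SyntheticDatasetSpec) -> list[ImageSample]:
    """Draw the full dataset in memory (healthy samples first, then blasts).

    Sample ``i`` uses an independent stream seeded from ``(spec.seed, i)``,
    so the dataset is reproducible and extensible.
    """
    blast_geometry = spec.effective_blast_geometry
    samples: list[ImageSample] = []
    for i in range(spec.n_healthy + spec.n_blast):
        label = 0 if i < spec.n_healthy else 1
        geometry = spec.healthy_geometry if label == 0 else blast_geometry
        samples.append(
            render_cell(
                geometry,
                spec.stain,
                label,
                spec.image_size,
                sample_rng(spec.seed, i),
                sample_id=_sample_id(i, label),
            )
        )
    return samples


def _write_png(path: Path, pixels: np.ndarray) -> None:
    Image.fromarray(np.round(pixels * 255.0).astype(np.uint8), mode="RGB").save(path, format="PNG")


def generate_dataset(spec: SyntheticDatasetSpec, output_dir: str | Path) -> DatasetManifest:
    """Write the dataset as PNG files plus a ``manifest.csv`` and return its manifest."""
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc

    records: list[ManifestRecord] = []
    for sample in sample_dataset(spec):
        fname = f"{sample.sample_id}.png"
        _write_png(out / fname, sample.pixels)
        records.append(ManifestRecord(file=fname, sample_id=sample.sample_id, label=sample.label))

    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "sample_id", "label"])
        for r in records:
            writer.writerow([r.file, r.sample_id, r.label])

    return DatasetManifest(records=tuple(records), seed=spec.seed, spec=spec)


def _label_from_stem(stem: str) -> int | None:
    if stem.endswith("_0"):
        return 0
    if stem.endswith("_1"):
        return 1
    return None


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a dataset manifest from a directory or an explicit manifest CSV.

    A ``manifest.csv`` (header ``file,sample_id,label``) takes precedence;
    otherwise labels are parsed from the ``_0``/``_1`` filename suffix and
    records are sorted lexicographically by file name.
    """
    path = Path(path)
    csv_path = path if path.is_file() else path / "manifest.csv"
    if csv_path.is_file():
        records = []
        with open(csv_path, newline="") as fh:
            for row in csv.DictReader(fh):
                label = int(row["label"])
                if label not in (0, 1):
                    raise LabelParsingError(f"manifest label for {row['file']!r} must be 0 or 1")
                records.append(ManifestRecord(file=row["file"], sample_id=row["sample_id"], label=label))
        return DatasetManifest(records=tuple(records))

    if not path.is_dir():
        raise FileNotFoundError(f"no manifest CSV or image directory at {path}")
    records = []
    for f in sorted(path.iterdir()):
        if f.suffix.lower() not in _IMAGE_EXTENSIONS:
            continue
        label = _label_from_stem(f.stem)
        if label is None:
            raise LabelParsingError(
                f"cannot label {f.name!r}: no `_0`/`_1` filename suffix and no manifest.csv"
            )
        records.append(ManifestRecord(file=f.name, sample_id=f.stem, label=label))
    return DatasetManifest(records=tuple(records))


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF crop as H x W x 3 float64 in [0, 1]."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"), dtype=np.float64)
    return arr / 255.0


def load_samples(manifest: DatasetManifest, root: str | Path) -> list[ImageSample]:
    """Materialize a manifest's records as :class:`ImageSample` objects."""
    root = Path(root)
    return [
        ImageSample(pixels=load_image(root / r.file), label=r.label, sample_id=r.sample_id)
        for r in manifest.records
    ]


def default_spec(seed: int = 0, **overrides) -> SyntheticDatasetSpec:
    """The standard 130 + 130 balanced dataset recipe."""
    return SyntheticDatasetSpec(seed=seed, **overrides)
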