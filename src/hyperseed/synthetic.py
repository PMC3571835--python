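"""Seeded synthetic hypercube datasets emulating a six-variety seed study.

Each variety is defined by a smooth reflectance signature over
380-1030 nm (a baseline plus Gaussian bumps), a spatial texture pattern
(stripes, checker or blobs) that modulates the signature multiplicatively,
a per-sample illumination gain, and additive Gaussian noise:

    reflectance(r, c, l) = gain * signature(l) * (1 + texture(r, c)) + noise

The default roster contains six varieties whose signatures are pairwise
distinct except for one deliberate twin pair (varieties II and V) that
share a near-identical signature but different texture patterns — so
spectral features alone cannot fully separate the classes and texture
features are genuinely required, which is the statistical structure the
classification pipeline is designed to exploit.

Samples are converted to "raw" camera intensity by inverting the
reflectance calibration against the dataset's shared white/black reference
frames (raw = reflectance * (W - B) + B), so the calibration stage of the
pipeline exactly recovers the generated reflectance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GenerationError, ParameterError
from .hypercube_io import Hypercube, ReferencePair, write_envi

__all__ = [
    "TextureSpec",
    "VarietySpec",
    "SyntheticDataset",
    "default_varieties",
    "make_references",
    "generate_sample",
    "generate_dataset",
    "signature_values",
    "signature_distance",
    "write_dataset",
    "load_dataset",
]

VARIETY_NAMES = ("I", "II", "III", "IV", "V", "VI")


@dataclass(frozen=True)
class TextureSpec:
    pattern: str  # stripes | checker | blobs
    period_px: float
    amplitude: float  # multiplicative contrast, dimensionless


@dataclass(frozen=True)
class VarietySpec:
    name: str
    baseline: float
    bumps: tuple  # of (center_nm, width_nm, amplitude)
    texture: TextureSpec
    noise_sd: float = 0.01


def signature_values(spec: VarietySpec, wavelengths: np.ndarray) -> np.ndarray:
    """Smooth reflectance signature: baseline + sum of Gaussian bumps."""
    wl = np.asarray(wavelengths, dtype=float)
    sig = np.full_like(wl, spec.baseline)
    for center, width, amp in spec.bumps:
        sig = sig + amp * np.exp(-((wl - center) ** 2) / (2.0 * width**2))
    return sig


def signature_distance(a: VarietySpec, b: VarietySpec, wavelengths: np.ndarray) -> float:
    """RMS difference between two signatures over a wavelength grid."""
    da = signature_values(a, wavelengths)
    db = signature_values(b, wavelengths)
    return float(np.sqrt(np.mean((da - db) ** 2)))


def default_varieties(seed: int = 0, noise_sd: float = 0.01) -> list[VarietySpec]:
    """Six variety specs; II and V are spectral twins with different textures.

    The seed jitters bump centers by at most +-2 nm so distinct seeds give
    distinct (but statistically equivalent) rosters; the twin pair always
    shares its jitter, keeping the twins twins.
    """
    rng = np.random.default_rng(seed)
    jit = rng.uniform(-2.0, 2.0, size=8)

    twin_bumps = ((600.0 + jit[2], 60.0, 0.22), (760.0 + jit[3], 50.0, 0.10))
    base = [
        # name, baseline, bumps, texture
        ("I", 0.12, ((850.0 + jit[0], 80.0, 0.06),),
         TextureSpec("stripes", 8.0, 0.10)),
        ("II", 0.30, twin_bumps,
         TextureSpec("stripes", 6.0, 0.08)),
        ("III", 0.22, ((570.0 + jit[4], 45.0, 0.18), (880.0 + jit[5], 70.0, 0.12)),
         TextureSpec("checker", 7.0, 0.09)),
        ("IV", 0.38, ((620.0 + jit[6], 55.0, 0.25),),
         TextureSpec("blobs", 10.0, 0.10)),
        # twin of II: one bump amplitude nudged by 0.005
        ("V", 0.30, ((twin_bumps[0][0], 60.0, 0.225), twin_bumps[1]),
         TextureSpec("checker", 5.0, 0.09)),
        ("VI", 0.46, ((640.0 + jit[7], 60.0, 0.22),),
         TextureSpec("stripes", 12.0, 0.07)),
    ]
    return [
        VarietySpec(name, baseline, bumps, tex, noise_sd)
        for name, baseline, bumps, tex in base
    ]


def make_references(
    side: int, bands: int, lo_nm: float = 380.0, hi_nm: float = 1030.0, seed: int = 0
) -> ReferencePair:
    """White (0.95 with a mild spatial gain ripple) and black (0.02) frames."""
    wl = np.linspace(lo_nm, hi_nm, bands)
    r = np.arange(side)[:, None]
    c = np.arange(side)[None, :]
    ripple = 0.02 * np.sin(2 * np.pi * r / side) * np.sin(2 * np.pi * c / side)
    white2d = 0.95 * (1.0 + ripple)
    white = np.broadcast_to(white2d[:, :, None], (side, side, bands)).copy()
    black = np.full((side, side, bands), 0.02)
    return ReferencePair(
        Hypercube(white, wl, kind="raw"), Hypercube(black, wl, kind="raw")
    )


def _texture_field(tex: TextureSpec, side: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean spatial pattern with peak amplitude tex.amplitude."""
    r = np.arange(side)[:, None]
    c = np.arange(side)[None, :]
    if tex.pattern == "stripes":
        phase = rng.uniform(0, 2 * np.pi)
        field = np.sin(2 * np.pi * c / tex.period_px + phase) * np.ones((side, 1))
    elif tex.pattern == "checker":
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        field = np.sin(2 * np.pi * r / tex.period_px + p1) * np.sin(
            2 * np.pi * c / tex.period_px + p2
        )
    elif tex.pattern == "blobs":
        noise = rng.standard_normal((side, side))
        field = gaussian_filter(noise, sigma=tex.period_px / 2.0, mode="wrap")
        sd = field.std()
        field = field / sd if sd > 0 else field
        field = np.clip(field, -2.5, 2.5) / 2.5
    else:
        raise GenerationError(f"unknown texture pattern {tex.pattern!r}")
    field = field - field.mean()
    return tex.amplitude * field


def generate_sample(
    spec: VarietySpec,
    refs: ReferencePair,
    seed: int,
    gain_sd: float = 0.02,
    noise_sd: float | None = None,
    signature_jitter_sd: float = 0.008,
) -> Hypercube:
    """One raw sample cube on the reference frames' spatial/spectral grid.

    Per-sample variability: an illumination gain ~ N(1, gain_sd), a jitter
    of each bump amplitude ~ N(0, signature_jitter_sd) (within-class
    biological variation, comparable in size to the twin pair's signature
    gap so spectra alone cannot fully separate the twins), plus i.i.d.
    Gaussian pixel noise.
    """
    side, side2, bands = refs.white.shape
    if side < 8 or bands < 8:
        raise ParameterError("need side >= 8 and bands >= 8")
    wl = refs.white.wavelengths
    sig = signature_values(spec, wl)
    if sig.min() <= 0 or sig.max() >= 1:
        raise GenerationError(
            f"signature of variety {spec.name} leaves (0, 1): "
            f"[{sig.min():.3f}, {sig.max():.3f}]"
        )
    if spec.texture.amplitude >= sig.min():
        raise GenerationError(
            f"texture amplitude {spec.texture.amplitude} >= signature minimum "
            f"{sig.min():.3f}; reflectance could go nonpositive"
        )
    nsd = spec.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    gain = 1.0 + gain_sd * rng.standard_normal() if gain_sd > 0 else 1.0
    if signature_jitter_sd > 0 and spec.bumps:
        jit = rng.normal(0.0, signature_jitter_sd, size=len(spec.bumps))
        jittered = VarietySpec(
            spec.name,
            spec.baseline,
            tuple((c, w, a + dj) for (c, w, a), dj in zip(spec.bumps, jit)),
            spec.texture,
            spec.noise_sd,
        )
        sig = signature_values(jittered, wl)
    tex = _texture_field(spec.texture, side, rng)
    refl = gain * sig[None, None, :] * (1.0 + tex[:, :, None])
    if nsd > 0:
        refl = refl + rng.normal(0.0, nsd, size=(side, side2, bands))
    raw = refl * (refs.white.data - refs.black.data) + refs.black.data
    return Hypercube(raw, wl.copy(), kind="raw")


@dataclass
class SyntheticDataset:
    samples: list  # raw Hypercubes
    labels: np.ndarray
    refs: ReferencePair
    manifest: dict = field(default_factory=dict)


def generate_dataset(
    n_per_variety: int,
    side: int = 64,
    bands: int = 128,
    lo_nm: float = 380.0,
    hi_nm: float = 1030.0,
    noise_sd: float = 0.01,
    gain_sd: float = 0.02,
    signature_jitter_sd: float = 0.008,
    seed: int = 42,
) -> SyntheticDataset:
    """6 * n_per_variety labeled raw cubes plus one shared reference pair.

    All randomness derives from ``seed``; the returned manifest carries
    every parameter, so ``generate_dataset(**manifest)`` regenerates the
    dataset bit-identically.
    """
    if n_per_variety < 2:
        raise ParameterError(f"n_per_variety must be >= 2, got {n_per_variety}")
    root = np.random.SeedSequence(seed)
    n_total = 6 * n_per_variety
    children = root.spawn(2 + n_total)
    as_int = lambda ss: int(ss.generate_state(1)[0] & 0x7FFFFFFF)

    varieties = default_varieties(as_int(children[0]), noise_sd)
    refs = make_references(side, bands, lo_nm, hi_nm, as_int(children[1]))

    samples, labels = [], []
    k = 2
    for spec in varieties:
        for _ in range(n_per_variety):
            samples.append(
                generate_sample(
                    spec, refs, as_int(children[k]), gain_sd, noise_sd,
                    signature_jitter_sd,
                )
            )
            labels.append(spec.name)
            k += 1

    manifest = {
        "n_per_variety": n_per_variety,
        "side": side,
        "bands": bands,
        "lo_nm": lo_nm,
        "hi_nm": hi_nm,
        "noise_sd": noise_sd,
        "gain_sd": gain_sd,
        "signature_jitter_sd": signature_jitter_sd,
        "seed": seed,
    }
    return SyntheticDataset(samples, np.array(labels), refs, manifest)


def write_dataset(ds: SyntheticDataset, outdir, interleave: str = "bil") -> Path:
    """Write a dataset as ENVI pairs + labels CSV + manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_envi(ds.refs.white, outdir / "white.hdr", interleave)
    write_envi(ds.refs.black, outdir / "black.hdr", interleave)
    lines = ["sample_id,label,header"]
    for i, (cube, label) in enumerate(zip(ds.samples, ds.labels)):
        name = f"sample_{i:04d}.hdr"
        write_envi(cube, outdir / name, interleave)
        lines.append(f"{i},{label},{name}")
    (outdir / "labels.csv").write_text("\n".join(lines) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(ds.manifest, indent=2) + "\n")
    return outdir


def load_dataset(indir) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    from .hypercube_io import read_envi

    indir = Path(indir)
    refs = ReferencePair(read_envi(indir / "white.hdr"), read_envi(indir / "black.hdr"))
    samples, labels = [], []
    rows = (indir / "labels.csv").read_text().strip().splitlines()[1:]
    for row in rows:
        _, label, header = row.split(",")
        samples.append(read_envi(indir / header))
        labels.append(label)
    manifest = {}
    mpath = indir / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
    return SyntheticDataset(samples, np.array(labels), refs, manifest)
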