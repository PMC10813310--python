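"""Procedural CT-like lung phantoms with five-lobe ground truth.

Each phantom is a torso-shaped soft-tissue shell containing two air-filled
ellipsoidal lung fields.  The left lung is split into upper/lower lobes by
one smooth fissure surface; the right lung into upper/middle/lower by two.
Fissures are oblique planes displaced by low-frequency sinusoids, so lobe
boundaries are curved but each lobe stays a single connected component.
Intensities are Hounsfield-like (air ~ -1000 HU, lung parenchyma ~ -850 HU,
soft tissue ~ +40 HU); normalization to [0, 1] is deliberately left to the
preprocessing stage.  Optional lesions are Gaussian intensity blobs inside a
lung that never alter the labels, emulating consolidations of diseased lungs
without changing ground-truth semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import LabelMap, Volume

HU_AIR = -1000.0
HU_LUNG = -860.0
HU_TISSUE = 40.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic lung volume.

    grid_shape : voxels per axis (z, y, x), each >= 16.
    spacing_mm : physical spacing (z, y, x); z in the 1-5 mm range typical of
        clinical reconstructions.
    noise_sd : intensity noise scale in HU.
    lesion_rate : probability of inserting lesion blobs into the volume.
    seed : RNG seed; identical spec+seed reproduces bit-identical output.
    """

    grid_shape: tuple[int, int, int] = (64, 128, 128)
    spacing_mm: tuple[float, float, float] = (3.0, 2.0, 2.0)
    noise_sd: float = 25.0
    lesion_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(g) < 16 for g in self.grid_shape):
            raise ValueError(f"grid_shape: all axes must be >= 16, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm: all axes must be > 0, got {self.spacing_mm}")
        if not 0.0 <= self.lesion_rate <= 1.0:
            raise ValueError(f"lesion_rate: must lie in [0, 1], got {self.lesion_rate}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd: must be >= 0, got {self.noise_sd}")


def _fissure_surface(
    yy: np.ndarray, xx: np.ndarray, level: float, tilt: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth fissure height field over (y, x), as a fraction of lung z-extent.

    A tilted plane plus two low-frequency sinusoids, clipped away from the
    lung poles so no lobe ever becomes empty.  `tilt` sets the mean
    anterior-posterior slope: oblique fissures run steeply through the lung
    (so axial slices show them as lines crossing the lung field), the
    horizontal fissure stays nearly flat.
    """
    tilt_y = tilt + rng.uniform(-0.08, 0.08)
    tilt_x = rng.uniform(-0.08, 0.08)
    amp1, amp2 = rng.uniform(0.02, 0.06), rng.uniform(0.01, 0.04)
    ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
    surf = (
        level
        + tilt_y * yy
        + tilt_x * xx
        + amp1 * np.sin(np.pi * yy + ph1)
        + amp2 * np.sin(np.pi * xx + ph2)
    )
    return np.clip(surf, 0.10, 0.90)


def _enforce_connectivity(labels: np.ndarray, lung: np.ndarray, lobe_labels: list[int]) -> None:
    """Reattach stray fragments so each lobe is one connected component.

    Discretization can strand small islands where a fissure surface grazes
    the lung rim; they are reassigned to the label of the nearest voxel of a
    kept (largest) component, iterating until stable.
    """
    for _ in range(4):
        stray = np.zeros_like(lung)
        for lbl in lobe_labels:
            comp, n = ndimage.label(labels == lbl)
            if n <= 1:
                continue
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
            keep = 1 + int(np.argmax(sizes))
            stray |= (comp > 0) & (comp != keep)
        if not stray.any():
            return
        kept = lung & ~stray
        _, (iz, iy, ix) = ndimage.distance_transform_edt(~kept, return_indices=True)
        labels[stray] = labels[iz[stray], iy[stray], ix[stray]]


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap]:
    """Generate one phantom volume and its aligned five-lobe label map.

    Returns (Volume, LabelMap) whose label set is exactly {0,...,5}: left
    lung = {1, 2} split by one fissure, right lung = {3, 4, 5} split by two.
    """
    spec.validate()
    # independent streams: lesion/noise draws must not perturb label geometry
    ss = np.random.SeedSequence(spec.seed)
    rng, lesion_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    nz, ny, nx = (int(g) for g in spec.grid_shape)

    z = np.linspace(-1, 1, nz)[:, None, None]
    y = np.linspace(-1, 1, ny)[None, :, None]
    x = np.linspace(-1, 1, nx)[None, None, :]

    # torso: elliptic cylinder tapering slightly toward the z extremes
    taper = 1.0 - 0.08 * z**2
    body = (y / (0.82 * taper)) ** 2 + (x / (0.88 * taper)) ** 2 <= 1.0

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    intensity = np.full((nz, ny, nx), HU_AIR, dtype=np.float32)
    intensity[body] = HU_TISSUE

    # (center x, semi-axes (z,y,x), fissures as (level, tilt, above, below));
    # oblique fissures (splitting off the lower lobes) run steeply, the right
    # horizontal fissure (upper/middle boundary) stays nearly axial
    lung_defs = [
        (+0.42, (0.80, 0.52, 0.27), [(0.52, 0.45, 1, 2)]),  # left: upper=1 / lower=2
        (-0.42, (0.82, 0.55, 0.29), [(0.68, 0.12, 3, 4), (0.42, 0.45, 4, 5)]),  # right: 3/4/5
    ]
    for cx0, axes, fissures in lung_defs:
        cx = cx0 + rng.uniform(-0.02, 0.02)
        cy = rng.uniform(-0.05, 0.02)
        cz = rng.uniform(-0.04, 0.04)
        az, ay, ax_ = (a * rng.uniform(0.95, 1.05) for a in axes)
        lung = ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax_) ** 2 <= 1.0
        # fractional height within the lung's z-extent, in [0, 1]
        t = (z - (cz - az)) / (2 * az)
        t = np.broadcast_to(t, lung.shape)
        yy = np.broadcast_to((y - cy) / ay, lung.shape)
        xx = np.broadcast_to((x - cx) / ax_, lung.shape)

        # top fissure first: everything above it is the upper lobe, then
        # continue downward; below the last fissure is the lowest lobe
        region = np.array(lung)
        surfaces = []
        for level, tilt, above_label, below_label in fissures:
            surf = _fissure_surface(yy[0], xx[0], level, tilt, rng)  # fields are z-invariant
            surfaces.append(surf)
            upper = region & (t >= surf)
            labels[upper] = above_label
            labels[region & ~upper] = below_label
            region = region & ~upper

        _enforce_connectivity(labels, lung, [f[2] for f in fissures] + [fissures[-1][3]])

        parenchyma = HU_LUNG + 45.0 * np.clip(t, 0, 1)  # mild gravity-like gradient
        # fissures image as thin dense sheets, as on real CT
        for surf in surfaces:
            parenchyma = parenchyma + 220.0 * np.exp(-(((t - surf) / 0.035) ** 2))
        intensity[lung] = parenchyma[lung].astype(np.float32)

        if lesion_rng.random() < spec.lesion_rate:
            n_lesions = lesion_rng.integers(1, 4)
            lz, lyy, lxx = np.nonzero(lung)
            for _ in range(n_lesions):
                i = lesion_rng.integers(len(lz))
                c = np.array([lz[i], lyy[i], lxx[i]], dtype=float)
                sig = lesion_rng.uniform(1.5, 4.0, size=3) * np.array([nz, ny, nx]) / 64.0
                amp = lesion_rng.uniform(300.0, 800.0)
                zi = np.arange(nz)[:, None, None]
                yi = np.arange(ny)[None, :, None]
                xi = np.arange(nx)[None, None, :]
                blob = amp * np.exp(
                    -(
                        ((zi - c[0]) / sig[0]) ** 2
                        + ((yi - c[1]) / sig[1]) ** 2
                        + ((xi - c[2]) / sig[2]) ** 2
                    )
                    / 2.0
                )
                intensity += np.where(lung, blob, 0.0).astype(np.float32)

    if spec.noise_sd > 0:
        smooth = ndimage.gaussian_filter(noise_rng.standard_normal((nz, ny, nx)), sigma=2.0)
        fine = noise_rng.standard_normal((nz, ny, nx))
        intensity += spec.noise_sd * (0.6 * smooth / max(smooth.std(), 1e-9) + 0.4 * fine).astype(
            np.float32
        )

    vol = Volume(intensity.astype(np.float32), spec.spacing_mm)
    lab = LabelMap(labels, spec.spacing_mm)
    return vol, lab


def generate_dataset(
    n_volumes: int, spec: PhantomSpec, seed: int, out_dir: str | Path
) -> list[dict]:
    """Write `n_volumes` phantom pairs as NIfTI and return the manifest.

    Per-volume seeds are derived deterministically from the master seed, so
    the same (spec, seed) always produces byte-identical files.  The manifest
    (also written to ``manifest.json``) records file paths, the per-volume
    seed, and per-label voxel counts.
    """
    if n_volumes < 1:
        raise ValueError(f"n_volumes must be >= 1, got {n_volumes}")
    spec.validate()
    from . import cli_io  # deferred: cli_io imports nothing from phantom

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_volumes) % (2**31)
    manifest = []
    for i, child in enumerate(child_seeds):
        sub = PhantomSpec(
            grid_shape=spec.grid_shape,
            spacing_mm=spec.spacing_mm,
            noise_sd=spec.noise_sd,
            lesion_rate=spec.lesion_rate,
            seed=int(child),
        )
        vol, lab = generate_phantom(sub)
        vol_path = out_dir / f"phantom_{i:03d}.nii.gz"
        lab_path = out_dir / f"phantom_{i:03d}_labels.nii.gz"
        cli_io.write_volume(vol, vol_path)
        cli_io.write_labelmap(lab, vol, lab_path)
        manifest.append(
            {
                "volume": str(vol_path),
                "labels": str(lab_path),
                "seed": int(child),
                "label_counts": lab.label_counts(),
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
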