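"""Procedural anatomy-like phantoms and paired sparse/dense sinogram datasets.

Real training data for sparse-view reconstruction would be patient CT
volumes; this module replaces them with piecewise-smooth synthetic slices:
a body ellipse, nested soft-tissue ellipses, a smooth texture field, and a
population of fine high-frequency structures (thin high-contrast rods and
sub-5-pixel discs).  The fine structures are deliberately denser than in
natural anatomy so that streak artifacts and detail-recovery differences
remain measurable at 64-256 pixel scale.

``make_dataset`` writes, per phantom: the sparse sinogram, the
intermediate-view sinogram label, the reference image (FBP of the
standard-view sinogram — the same reference a full-dose scan would give),
and the sparse-FBP baseline, to an HDF5 file with a JSON manifest sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import CTImage, FanBeamGeometry, FanBeamProjector

__all__ = ["PhantomSpec", "make_phantom", "make_dataset", "shepp_logan_like",
           "PhantomDataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Sampling distribution for one random phantom; ``seed`` fixes everything."""

    image_size: int = 64
    n_ellipses: tuple = (4, 8)          # inclusive range of tissue ellipses
    attenuation_range: tuple = (0.05, 0.35)   # contrast of tissue ellipses
    n_fine_structures: tuple = (6, 12)  # thin rods + small discs per phantom
    texture_amplitude: float = 0.02
    noise_model: str = "none"           # {none, gaussian, poisson}
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def _ellipse_mask(n, cy, cx, ay, ax, phi, supersample=2):
    """Anti-aliased ellipse indicator via supersampled rasterisation."""
    s = supersample
    coords = (np.arange(n * s) + 0.5) / s - 0.5
    Y, X = np.meshgrid(coords, coords, indexing="ij")
    ct, st = np.cos(phi), np.sin(phi)
    xr = (X - cx) * ct + (Y - cy) * st
    yr = -(X - cx) * st + (Y - cy) * ct
    m = ((xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0).astype(np.float64)
    return m.reshape(n, s, n, s).mean(axis=(1, 3))


def _rod_mask(n, cy, cx, length, width, phi, supersample=2):
    s = supersample
    coords = (np.arange(n * s) + 0.5) / s - 0.5
    Y, X = np.meshgrid(coords, coords, indexing="ij")
    ct, st = np.cos(phi), np.sin(phi)
    xr = (X - cx) * ct + (Y - cy) * st
    yr = -(X - cx) * st + (Y - cy) * ct
    m = ((np.abs(xr) <= length / 2) & (np.abs(yr) <= width / 2)).astype(np.float64)
    return m.reshape(n, s, n, s).mean(axis=(1, 3))


def make_phantom(spec: PhantomSpec) -> CTImage:
    """Generate one piecewise-smooth phantom with fine structures, in [0, 1].

    Deterministic given ``spec`` (bit-identical across calls).  With
    ``n_ellipses=(0, 0)`` and ``n_fine_structures=(0, 0)`` the output is the
    uniform background body ellipse only.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    c = (n - 1) / 2.0
    tissue = np.zeros((n, n))

    # body ellipse, kept inside the inscribed-circle field of view
    body_a = 0.46 * n * rng.uniform(0.9, 1.0)
    body_b = 0.46 * n * rng.uniform(0.75, 0.95)
    body_phi = rng.uniform(0, np.pi)
    body = _ellipse_mask(n, c, c, body_b, body_a, body_phi)

    lo, hi = spec.n_ellipses
    n_ell = int(rng.integers(lo, hi + 1)) if hi >= lo and hi > 0 else 0
    amin, amax = spec.attenuation_range
    for _ in range(n_ell):
        r = 0.30 * n * rng.uniform(0.15, 1.0)
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.55) * 0.46 * n
        cy, cx = c + rad * np.sin(ang), c + rad * np.cos(ang)
        ay = r * rng.uniform(0.5, 1.0)
        axx = r * rng.uniform(0.5, 1.0)
        mu = rng.uniform(amin, amax) * rng.choice([-1.0, 1.0])
        tissue += mu * _ellipse_mask(n, cy, cx, ay, axx, rng.uniform(0, np.pi))

    # smooth texture field (low-frequency, body-limited)
    if spec.texture_amplitude > 0:
        from scipy.ndimage import gaussian_filter

        noise = rng.standard_normal((n, n))
        tex = gaussian_filter(noise, sigma=n / 16.0)
        tex /= max(np.abs(tex).max(), 1e-12)
        tissue += spec.texture_amplitude * tex

    # fine high-frequency structures: thin rods and 1-4 px discs
    lo, hi = spec.n_fine_structures
    n_fine = int(rng.integers(lo, hi + 1)) if hi >= lo and hi > 0 else 0
    for _ in range(n_fine):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.7) * 0.46 * n
        cy, cx = c + rad * np.sin(ang), c + rad * np.cos(ang)
        mu = rng.uniform(0.3, 0.6) * rng.choice([-1.0, 1.0])
        if rng.random() < 0.5:
            tissue += mu * _rod_mask(n, cy, cx, rng.uniform(0.1, 0.3) * n,
                                     rng.uniform(1.0, 2.0), rng.uniform(0, np.pi))
        else:
            r_px = rng.uniform(1.0, 4.0) / 2.0
            tissue += mu * _ellipse_mask(n, cy, cx, r_px, r_px, 0.0, supersample=4)

    # anti-aliased body rim, tissue confined to the body support
    img = 0.25 * body + tissue * (body > 0.5)

    if spec.noise_model == "gaussian" and spec.noise_level > 0:
        img = img + spec.noise_level * rng.standard_normal((n, n)) * (body > 0.5)
    elif spec.noise_model == "poisson" and spec.noise_level > 0:
        lam = np.clip(img, 0, None) / max(spec.noise_level, 1e-12)
        img = rng.poisson(lam).astype(np.float64) * spec.noise_level

    img = np.clip(img, 0.0, 1.0)
    return CTImage(img, pixel_size=1.0)


# ---------------------------------------------------------------------------
# fixed deterministic fixture
# ---------------------------------------------------------------------------

# classic head-phantom ellipse table (x, y, a, b, angle deg, grey level),
# modified grey levels for display contrast, unit square coordinates
_SL_ELLIPSES = [
    (0.0, 0.0, 0.69, 0.92, 0, 1.0),
    (0.0, -0.0184, 0.6624, 0.874, 0, -0.8),
    (0.22, 0.0, 0.11, 0.31, -18, -0.2),
    (-0.22, 0.0, 0.16, 0.41, 18, -0.2),
    (0.0, 0.35, 0.21, 0.25, 0, 0.1),
    (0.0, 0.1, 0.046, 0.046, 0, 0.1),
    (0.0, -0.1, 0.046, 0.046, 0, 0.1),
    (-0.08, -0.605, 0.046, 0.023, 0, 0.1),
    (0.0, -0.605, 0.023, 0.023, 0, 0.1),
    (0.06, -0.605, 0.023, 0.046, 0, 0.1),
]


def shepp_logan_like(image_size: int = 256, scale: float = 0.92) -> CTImage:
    """Deterministic head-like test phantom (nested analytic ellipses).

    Rasterised with 2x supersampling so edges are consistent across sizes;
    ``scale`` keeps the phantom strictly inside the field-of-view circle.
    """
    n = image_size
    c = (n - 1) / 2.0
    img = np.zeros((n, n))
    half = n / 2.0
    for (x, y, a, b, ang, mu) in _SL_ELLIPSES:
        img += mu * _ellipse_mask(n, c - y * half * scale, c + x * half * scale,
                                  b * half * scale, a * half * scale,
                                  -np.deg2rad(ang))
    return CTImage(np.clip(img, 0.0, 1.0), pixel_size=1.0)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def make_dataset(n_train: int, n_test: int, spec: PhantomSpec,
                 geometry: FanBeamGeometry, out_path,
                 filter_name: str = "cosine") -> dict:
    """Simulate paired sparse/intermediate/full data for ``n_train + n_test`` phantoms.

    For each phantom writes datasets ``/case_<id>/{sparse_sino, inter_sino,
    full_image, sparse_fbp, phantom}``; ``full_image`` is the FBP of the
    standard-view sinogram (the reference a practitioner would call ground
    truth), and ``phantom`` is the underlying noiseless object kept as an
    extra oracle.  Returns the manifest (also written as a JSON sidecar).
    """
    import h5py

    if n_train < 1 or n_test < 1:
        raise ValueError("need at least one training and one test phantom")
    out_path = Path(out_path)
    n = spec.image_size
    g = geometry
    proj_std = FanBeamProjector(g, g.view_angles(g.n_views_standard), n,
                                filter_name=filter_name)
    proj_sparse = FanBeamProjector(g, g.view_angles(g.n_views_sparse), n,
                                   filter_name=filter_name)
    stride_int = g.n_views_standard // g.n_views_intermediate
    stride_sp = g.n_views_standard // g.n_views_sparse

    master = np.random.SeedSequence(spec.seed)
    case_seeds = master.generate_state(n_train + n_test)

    manifest = {"n_train": n_train, "n_test": n_test,
                "train": [], "test": [], "image_size": n,
                "pixel_size": proj_std.pixel_size,
                "geometry": g.to_dict(), "seed": spec.seed}
    with h5py.File(out_path, "w") as f:
        f.attrs["geometry"] = json.dumps(g.to_dict())
        f.attrs["pixel_size"] = proj_std.pixel_size
        for i in range(n_train + n_test):
            case_spec = PhantomSpec(**{**spec.__dict__, "seed": int(case_seeds[i])})
            ph = make_phantom(case_spec)
            full_sino = proj_std.project(ph.data)
            inter = full_sino[::stride_int]
            sparse = full_sino[::stride_sp]
            y_ref = proj_std.fbp(full_sino)
            y_sparse = proj_sparse.fbp(sparse)
            grp = f.create_group(f"case_{i:04d}")
            grp.create_dataset("sparse_sino", data=sparse.astype(np.float32))
            grp.create_dataset("inter_sino", data=inter.astype(np.float32))
            grp.create_dataset("full_image", data=y_ref.astype(np.float32))
            grp.create_dataset("sparse_fbp", data=y_sparse.astype(np.float32))
            grp.create_dataset("phantom", data=ph.data.astype(np.float32))
            key = "train" if i < n_train else "test"
            manifest[key].append(f"case_{i:04d}")
    out_path.with_suffix(out_path.suffix + ".json").write_text(
        json.dumps(manifest, indent=1))
    return manifest


class PhantomDataset:
    """In-memory view over a dataset file written by :func:`make_dataset`."""

    def __init__(self, path):
        import h5py

        self.path = Path(path)
        manifest_path = self.path.with_suffix(self.path.suffix + ".json")
        self.manifest = json.loads(manifest_path.read_text())
        self.geometry = FanBeamGeometry.from_dict(self.manifest["geometry"])
        self.pixel_size = float(self.manifest["pixel_size"])
        self._cases = {}
        with h5py.File(self.path, "r") as f:
            for name in self.manifest["train"] + self.manifest["test"]:
                g = f[name]
                self._cases[name] = {k: g[k][...].astype(np.float64)
                                     for k in ("sparse_sino", "inter_sino",
                                               "full_image", "sparse_fbp",
                                               "phantom")}

    @property
    def train_cases(self):
        return list(self.manifest["train"])

    @property
    def test_cases(self):
        return list(self.manifest["test"])

    def __getitem__(self, name):
        return self._cases[name]

    def __len__(self):
        return len(self._cases)
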