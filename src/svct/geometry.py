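"""Fan-beam projection geometry, forward projector and filtered back-projection.

The scanner model is a rotating point source with a flat, equally spaced
detector (element pitch given in mm).  Projection and back-projection are
exposed both as plain ndarray functions and as exact (forward, adjoint)
linear-operator pairs, so they can sit inside a training graph as the
"reconstruction layer" linking the projection and image domains.

Conventions
-----------
* Lengths are millimetres.  The default scanner has the source 645 mm from
  the detector and 322.5 mm from the rotation centre, 736 detector elements
  of 0.3 mm pitch, and view angles ``k * 2*pi / n_views`` on ``[0, 2*pi)``.
* Sparse view sets are evenly decimated subsets of the standard set, so the
  30/60-view angles are literal subsets of the 180- and 720-view angles.
* Images are square, centred on the rotation centre; the default pixel size
  makes the field of view the inscribed circle covered by the detector at
  iso-centre magnification.
* Sinograms hold dimensionless line integrals of the (normalised)
  attenuation map: integral of image values along the ray, with image values
  interpreted per millimetre of path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.fft import irfft, rfft

from .autodiff import Tensor, linear_op

__all__ = [
    "FanBeamGeometry",
    "Sinogram",
    "CTImage",
    "FanBeamProjector",
    "forward_project",
    "fbp",
    "adjointness_check",
    "save_sinogram",
    "load_sinogram",
    "save_image",
    "load_image",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FanBeamGeometry:
    """Full description of the fan-beam scanner.

    Distances are in mm (defaults: 645 mm source-detector, 322.5 mm
    source-centre), the flat detector has ``n_detectors`` elements of
    ``detector_pitch`` mm, and a full scan covers ``[0, 2*pi)``.
    ``n_views_standard`` / ``n_views_intermediate`` / ``n_views_sparse``
    define the reference, interpolation-target and sparse acquisitions;
    the sparse angles must be subsets of the denser sets.
    """

    source_to_detector_distance: float = 645.0
    source_to_center_distance: float = 322.5
    n_detectors: int = 736
    detector_pitch: float = 0.3
    n_views_standard: int = 720
    n_views_intermediate: int = 180
    n_views_sparse: int = 60
    detector_model: str = "flat_equally_spaced"

    def __post_init__(self):
        if not (self.source_to_detector_distance > self.source_to_center_distance > 0):
            raise ValueError("require source_to_detector > source_to_center > 0")
        if self.detector_model != "flat_equally_spaced":
            raise ValueError(f"unsupported detector model {self.detector_model!r}")
        if self.n_views_intermediate % self.n_views_sparse:
            raise ValueError("n_views_sparse must divide n_views_intermediate")
        if self.n_views_standard % self.n_views_intermediate:
            raise ValueError("n_views_intermediate must divide n_views_standard")

    @property
    def fov_radius(self) -> float:
        """Radius (mm) of the field of view covered by every fan."""
        half_span = 0.5 * self.n_detectors * self.detector_pitch
        gamma = np.arctan2(half_span, self.source_to_detector_distance)
        return float(self.source_to_center_distance * np.sin(gamma))

    def view_angles(self, n_views: int) -> np.ndarray:
        """``n_views`` evenly spaced angles on the half-open ``[0, 2*pi)``."""
        return np.arange(n_views) * (2.0 * np.pi / n_views)

    def default_pixel_size(self, image_size: int) -> float:
        """Pixel size making the FOV the inscribed circle of the image."""
        return 2.0 * self.fov_radius / image_size

    def to_dict(self) -> dict:
        return {
            "source_to_detector_distance": self.source_to_detector_distance,
            "source_to_center_distance": self.source_to_center_distance,
            "n_detectors": self.n_detectors,
            "detector_pitch": self.detector_pitch,
            "n_views_standard": self.n_views_standard,
            "n_views_intermediate": self.n_views_intermediate,
            "n_views_sparse": self.n_views_sparse,
            "detector_model": self.detector_model,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FanBeamGeometry":
        return cls(**d)


@dataclass
class Sinogram:
    """views x detectors array of line integrals with its acquisition geometry."""

    data: np.ndarray
    view_angles: np.ndarray
    geometry: FanBeamGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64) \
            if self.data.dtype.kind != "f" else np.asarray(self.data)
        self.view_angles = np.asarray(self.view_angles, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("sinogram must be 2-D (views x detectors)")
        if self.data.shape != (len(self.view_angles), self.geometry.n_detectors):
            raise ValueError("sinogram shape inconsistent with angles/geometry")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")
        a = self.view_angles
        if np.any(a < 0) or np.any(a >= 2 * np.pi) or np.any(np.diff(a) <= 0):
            raise ValueError("view angles must be strictly increasing in [0, 2*pi)")

    @property
    def n_views(self) -> int:
        return self.data.shape[0]


@dataclass
class CTImage:
    """Square H x W attenuation image (normalised units) with pixel size in mm."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("CT image must be square and 2-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    @property
    def size(self) -> int:
        return self.data.shape[0]

    def to_hu(self, mu_water: float = 0.2, window=None) -> np.ndarray:
        """Display-only mapping to Hounsfield units (mu_water in image units)."""
        hu = 1000.0 * (self.data - mu_water) / mu_water
        if window is not None:
            lo, hi = window
            hu = np.clip(hu, lo, hi)
        return hu


# ---------------------------------------------------------------------------
# projector
# ---------------------------------------------------------------------------

class FanBeamProjector:
    """Joseph-style fan-beam projector for a fixed view set and image grid.

    ``project`` integrates the bilinearly interpolated image along each
    source-detector ray with step <= half a pixel; ``adjoint`` is the exact
    transpose (scatter with the same interpolation weights), so the pair
    passes an inner-product adjointness test to floating precision.
    ``fbp`` implements flat-detector fan-beam filtered back-projection:
    cosine weighting, ramp filtering along the detector axis, and
    distance-weighted back-projection; ``fbp_adjoint`` is its exact
    transpose (used when FBP sits inside a gradient graph).
    """

    def __init__(self, geometry: FanBeamGeometry, view_angles: np.ndarray,
                 image_size: int, pixel_size: float | None = None,
                 step_fraction: float = 0.5, filter_name: str = "cosine"):
        angles = np.asarray(view_angles, dtype=np.float64)
        if angles.ndim != 1 or len(angles) < 1:
            raise ValueError("need at least one view angle")
        if np.any(angles < 0) or np.any(angles >= 2 * np.pi):
            raise ValueError("angles outside [0, 2*pi)")
        self.geometry = geometry
        self.view_angles = angles
        self.image_size = int(image_size)
        self.pixel_size = float(pixel_size if pixel_size is not None
                                else geometry.default_pixel_size(image_size))
        if geometry.fov_radius < 0.5 * self.image_size * self.pixel_size - 1e-9:
            # detector span must cover the inscribed-circle field of view
            raise ValueError("detector does not cover the requested image FOV")
        self.step = step_fraction * self.pixel_size
        self.filter_name = filter_name

        g = geometry
        self._t = (np.arange(g.n_detectors) - (g.n_detectors - 1) / 2.0) * g.detector_pitch
        # sampling positions along each ray, parameterised by distance from source
        half_diag = 0.5 * np.sqrt(2.0) * self.image_size * self.pixel_size
        d0 = g.source_to_center_distance
        n_steps = int(np.ceil(2 * half_diag / self.step)) + 1
        self._ray_ts = d0 - half_diag + self.step * np.arange(n_steps)
        self._center = (self.image_size - 1) / 2.0
        # small systems are assembled once as sparse matrices (training speed);
        # large ones stream view by view to bound memory
        self._nnz_estimate = len(angles) * g.n_detectors * n_steps * 4
        self._A = None
        self._B = None

    # -- forward / adjoint ------------------------------------------------
    def _ray_geometry(self, beta: float):
        g = self.geometry
        src = g.source_to_center_distance * np.array([np.cos(beta), np.sin(beta)])
        u_hat = np.array([-np.sin(beta), np.cos(beta)])       # detector axis
        c_hat = -np.array([np.cos(beta), np.sin(beta)])       # central ray direction
        det = src + g.source_to_detector_distance * c_hat[None, :] \
            + self._t[:, None] * u_hat[None, :]
        rays = det - src[None, :]
        rays /= np.linalg.norm(rays, axis=1, keepdims=True)
        return src, rays

    def _sample_coords(self, beta: float):
        src, rays = self._ray_geometry(beta)
        pts = src[None, None, :] + rays[:, None, :] * self._ray_ts[None, :, None]
        # pixel coordinates: x -> column, y -> row
        col = pts[..., 0] / self.pixel_size + self._center
        row = pts[..., 1] / self.pixel_size + self._center
        return row, col

    def _bilinear_terms(self, row, col):
        n = self.image_size
        r0 = np.floor(row).astype(np.int64)
        c0 = np.floor(col).astype(np.int64)
        fr = row - r0
        fc = col - c0
        terms = []
        for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                          (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
            rr, cc = r0 + dr, c0 + dc
            valid = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
            terms.append((np.where(valid, rr, 0), np.where(valid, cc, 0),
                          np.where(valid, w, 0.0)))
        return terms

    def _system_matrix(self):
        """Assembled CSR forward projector (bit-equal weights to streaming)."""
        if self._A is None:
            from scipy.sparse import coo_matrix

            n = self.image_size
            nd = self.geometry.n_detectors
            rows_i, cols_i, vals = [], [], []
            for k, beta in enumerate(self.view_angles):
                row, col = self._sample_coords(beta)
                ray_idx = np.broadcast_to(
                    (k * nd + np.arange(nd))[:, None], row.shape)
                for rr, cc, w in self._bilinear_terms(row, col):
                    nz = w != 0
                    rows_i.append(ray_idx[nz])
                    cols_i.append((rr * n + cc)[nz])
                    vals.append(w[nz] * self.step)
            A = coo_matrix(
                (np.concatenate(vals),
                 (np.concatenate(rows_i), np.concatenate(cols_i))),
                shape=(len(self.view_angles) * nd, n * n))
            self._A = A.tocsr()
        return self._A

    @property
    def _use_matrix(self) -> bool:
        return self._nnz_estimate <= 3e7

    def project(self, image: np.ndarray) -> np.ndarray:
        """Forward project an (n, n) image to a (n_views, n_detectors) sinogram."""
        image = np.asarray(image)
        if image.shape != (self.image_size, self.image_size):
            raise ValueError("image shape does not match projector grid")
        shape = (len(self.view_angles), self.geometry.n_detectors)
        dtype = image.dtype if image.dtype.kind == "f" else np.float64
        if self._use_matrix:
            return (self._system_matrix() @ image.ravel().astype(np.float64)) \
                .reshape(shape).astype(dtype, copy=False)
        out = np.zeros(shape, dtype=dtype)
        for k, beta in enumerate(self.view_angles):
            row, col = self._sample_coords(beta)
            acc = np.zeros(row.shape, dtype=out.dtype)
            for rr, cc, w in self._bilinear_terms(row, col):
                acc += w.astype(out.dtype) * image[rr, cc]
            out[k] = acc.sum(axis=1) * self.step
        return out

    def adjoint(self, sino: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`project` (unfiltered back-scatter)."""
        sino = np.asarray(sino)
        n = self.image_size
        dtype = sino.dtype if sino.dtype.kind == "f" else np.float64
        if self._use_matrix:
            return (self._system_matrix().T @ sino.ravel().astype(np.float64)) \
                .reshape(n, n).astype(dtype, copy=False)
        out = np.zeros((n, n), dtype=dtype)
        for k, beta in enumerate(self.view_angles):
            row, col = self._sample_coords(beta)
            vals = (sino[k][:, None] * self.step) * np.ones_like(row)
            for rr, cc, w in self._bilinear_terms(row, col):
                np.add.at(out, (rr.ravel(), cc.ravel()),
                          (w.astype(out.dtype) * vals).ravel())
        return out

    # -- filtered back-projection ----------------------------------------
    def _filter_response(self, n_pad: int, ds: float) -> np.ndarray:
        """Frequency response of the band-limited ramp with apodisation."""
        # spatial-domain Ram-Lak impulse response (Kak & Slaney)
        m = np.arange(-n_pad // 2, n_pad // 2)
        h = np.zeros(n_pad)
        h[m == 0] = 1.0 / (4.0 * ds * ds)
        odd = m % 2 == 1
        h[odd] = -1.0 / (np.pi * m[odd] * ds) ** 2
        H = np.real(rfft(np.fft.ifftshift(h)))
        f = np.arange(len(H)) / n_pad            # cycles per sample, Nyquist at 0.5
        if self.filter_name == "ramlak":
            win = np.ones_like(f)
        elif self.filter_name == "cosine":
            win = np.cos(np.pi * f)              # raised-cosine rolloff to 0 at Nyquist
        elif self.filter_name == "hann":
            win = 0.5 * (1.0 + np.cos(2.0 * np.pi * f))
        else:
            raise ValueError(f"unknown filter {self.filter_name!r}")
        return H * win

    def _filter_rows(self, rows: np.ndarray, ds: float, transpose: bool = False) -> np.ndarray:
        # circular-convolution ramp filtering with zero padding; the padded
        # kernel is real and even, so the operator is self-adjoint and
        # ``transpose`` is accepted only for interface symmetry.
        n = rows.shape[1]
        n_pad = 1 << int(np.ceil(np.log2(4 * n)))
        H = self._filter_response(n_pad, ds)
        spec = rfft(rows, n=n_pad, axis=1) * H[None, :]
        return irfft(spec, n=n_pad, axis=1)[:, :n] * ds

    def _iso_coords(self):
        g = self.geometry
        scale = g.source_to_center_distance / g.source_to_detector_distance
        s = self._t * scale
        ds = g.detector_pitch * scale
        return s, ds

    def _pixel_grid(self):
        n = self.image_size
        ax = (np.arange(n) - self._center) * self.pixel_size
        X, Y = np.meshgrid(ax, ax, indexing="xy")   # X: columns, Y: rows
        return X, Y

    def fbp(self, sino: np.ndarray) -> np.ndarray:
        """Flat-detector fan-beam FBP onto the projector's image grid."""
        sino = np.asarray(sino)
        if sino.shape[0] < 2:
            raise ValueError("FBP needs at least 2 views")
        g = self.geometry
        s, ds = self._iso_coords()
        D = g.source_to_center_distance
        w_cos = D / np.sqrt(D * D + s * s)
        q = self._filter_rows(sino * w_cos[None, :], ds)
        X, Y = self._pixel_grid()
        dbeta = 2.0 * np.pi / len(self.view_angles)
        out = np.zeros_like(X, dtype=q.dtype)
        for k, beta in enumerate(self.view_angles):
            L = D - (X * np.cos(beta) + Y * np.sin(beta))
            tau = -X * np.sin(beta) + Y * np.cos(beta)
            sp = tau * D / L
            idx = (sp - s[0]) / ds
            i0 = np.floor(idx).astype(np.int64)
            fi = idx - i0
            valid0 = (i0 >= 0) & (i0 < len(s))
            valid1 = (i0 + 1 >= 0) & (i0 + 1 < len(s))
            qk = q[k]
            v = np.where(valid0, qk[np.clip(i0, 0, len(s) - 1)], 0.0) * (1 - fi) \
                + np.where(valid1, qk[np.clip(i0 + 1, 0, len(s) - 1)], 0.0) * fi
            out += v * (D / L) ** 2
        res = out * (dbeta / 2.0)
        # rfft/irfft promote to float64; preserve the caller's dtype
        return res.astype(sino.dtype, copy=False) if sino.dtype.kind == "f" \
            else res

    def fbp_adjoint(self, image: np.ndarray) -> np.ndarray:
        """Exact transpose of :meth:`fbp` (gradient of FBP w.r.t. the sinogram)."""
        image = np.asarray(image)
        g = self.geometry
        s, ds = self._iso_coords()
        D = g.source_to_center_distance
        w_cos = D / np.sqrt(D * D + s * s)
        X, Y = self._pixel_grid()
        dbeta = 2.0 * np.pi / len(self.view_angles)
        gq = np.zeros((len(self.view_angles), g.n_detectors), dtype=image.dtype)
        src_img = image * (dbeta / 2.0)
        for k, beta in enumerate(self.view_angles):
            L = D - (X * np.cos(beta) + Y * np.sin(beta))
            tau = -X * np.sin(beta) + Y * np.cos(beta)
            sp = tau * D / L
            idx = (sp - s[0]) / ds
            i0 = np.floor(idx).astype(np.int64)
            fi = idx - i0
            vals = src_img * (D / L) ** 2
            for ii, w in ((i0, 1 - fi), (i0 + 1, fi)):
                valid = (ii >= 0) & (ii < len(s))
                np.add.at(gq[k], np.clip(ii, 0, len(s) - 1)[valid],
                          (vals * w)[valid])
        res = self._filter_rows(gq, ds) * w_cos[None, :]
        return res.astype(image.dtype, copy=False) if image.dtype.kind == "f" \
            else res

    # -- autodiff layers ---------------------------------------------------
    def project_t(self, image: Tensor) -> Tensor:
        """Forward projection as a differentiable graph node."""
        return linear_op(image, self.project, self.adjoint)

    def fbp_t(self, sino: Tensor) -> Tensor:
        """FBP as a differentiable graph node (reconstruction layer)."""
        return linear_op(sino, self.fbp, self.fbp_adjoint)


# ---------------------------------------------------------------------------
# functional interface
# ---------------------------------------------------------------------------

def forward_project(image: CTImage, geometry: FanBeamGeometry,
                    view_angles: np.ndarray) -> Sinogram:
    """Fan-beam line integrals of ``image`` along the given view angles."""
    proj = FanBeamProjector(geometry, view_angles, image.size,
                            pixel_size=image.pixel_size)
    return Sinogram(proj.project(image.data), np.asarray(view_angles, float), geometry)


def fbp(sino: Sinogram, image_size: int, pixel_size: float | None = None,
        filter_name: str = "cosine") -> CTImage:
    """Filtered back-projection of a sinogram onto a square image grid."""
    proj = FanBeamProjector(sino.geometry, sino.view_angles, image_size,
                            pixel_size=pixel_size, filter_name=filter_name)
    return CTImage(proj.fbp(sino.data), proj.pixel_size)


def adjointness_check(geometry: FanBeamGeometry, image_size: int, seed: int,
                      n_views: int = 60) -> float:
    """Relative inner-product mismatch |<Au, v> - <u, A^T v>| / (|Au| |v|).

    ``A`` is the forward projector, ``A^T`` the unfiltered back-projection
    used as its gradient.  Values near machine precision certify that
    gradient flow through the reconstruction layer is exact.
    """
    if image_size < 8:
        raise ValueError("image_size must be >= 8")
    rng = np.random.default_rng(seed)
    proj = FanBeamProjector(geometry, geometry.view_angles(n_views), image_size)
    u = rng.standard_normal((image_size, image_size))
    v = rng.standard_normal((n_views, geometry.n_detectors))
    Au = proj.project(u)
    Atv = proj.adjoint(v)
    num = abs(float(np.vdot(Au, v)) - float(np.vdot(u, Atv)))
    den = float(np.linalg.norm(Au) * np.linalg.norm(v))
    return num / den


# ---------------------------------------------------------------------------
# HDF5 / TIFF persistence
# ---------------------------------------------------------------------------

def save_sinogram(path, sino: Sinogram) -> None:
    import h5py

    with h5py.File(path, "a") as f:
        if "sinogram" in f:
            del f["sinogram"]
        d = f.create_dataset("sinogram", data=sino.data)
        d.attrs["view_angles"] = sino.view_angles
        d.attrs["geometry"] = json.dumps(sino.geometry.to_dict())


def load_sinogram(path) -> Sinogram:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["sinogram"]
        geom = FanBeamGeometry.from_dict(json.loads(d.attrs["geometry"]))
        return Sinogram(d[...], np.asarray(d.attrs["view_angles"]), geom)


def save_image(path, image: CTImage) -> None:
    import h5py

    with h5py.File(path, "a") as f:
        if "image" in f:
            del f["image"]
        d = f.create_dataset("image", data=image.data)
        d.attrs["pixel_size"] = image.pixel_size


def load_image(path) -> CTImage:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["image"]
        return CTImage(d[...], float(d.attrs["pixel_size"]))


def export_tiff(path, image: CTImage) -> None:
    """Preview export (float32 TIFF)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image.data, dtype=np.float32))


def load_dicom_image(path) -> CTImage:
    """Import a DICOM slice as a CTImage (requires pydicom; real-data users)."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    inter = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + inter
    # normalise a typical soft-tissue window into [0, 1]
    lo, hi = -1000.0, 2000.0
    data = np.clip((hu - lo) / (hi - lo), 0.0, 1.0)
    px = float(getattr(ds, "PixelSpacing", [1.0, 1.0])[0])
    n = min(data.shape)
    return CTImage(data[:n, :n], px)
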