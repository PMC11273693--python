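"""Image-quality metric suite: RMSE, PSNR, SSIM, VIF and GMSD.

PSNR and SSIM use the standard definitions (SSIM with an 11-tap Gaussian
window, K1=0.01, K2=0.03, via scikit-image).  GMSD follows its source
definition: Prewitt gradient magnitudes, the similarity map
``(2 g1 g2 + c) / (g1^2 + g2^2 + c)``, and its standard deviation.  VIF is
the pixel-domain multi-scale approximation (no steerable pyramid), with the
conventional noise variance of 2 on a 255-level scale.  All metrics are
computed after mapping both images onto ``[0, 255] * (value / data_range)``
so ``data_range`` makes the intensity unit explicit.

A perfect match would give infinite PSNR; tables report the capped sentinel
999 dB instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve, gaussian_filter
from skimage.metrics import structural_similarity

__all__ = ["MetricsReport", "evaluate_pair", "rmse", "psnr", "ssim",
           "vif_pixel", "gmsd", "MetricsTable"]

PSNR_CAP = 999.0


def rmse(test: np.ndarray, reference: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(test, float) - reference) ** 2)))


def psnr(test: np.ndarray, reference: np.ndarray, data_range: float) -> float:
    """10 log10(data_range^2 / MSE), capped at 999 dB on exact match."""
    err = float(np.mean((np.asarray(test, float) - reference) ** 2))
    if err == 0:
        return PSNR_CAP
    return min(float(10.0 * np.log10(data_range ** 2 / err)), PSNR_CAP)


def ssim(test: np.ndarray, reference: np.ndarray, data_range: float) -> float:
    return float(structural_similarity(
        np.asarray(reference, float), np.asarray(test, float),
        data_range=data_range, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


_PREWITT_X = np.array([[1.0, 0.0, -1.0]] * 3) / 3.0
_PREWITT_Y = _PREWITT_X.T.copy()


def gmsd(test: np.ndarray, reference: np.ndarray, data_range: float,
         c: float = 170.0) -> float:
    """Gradient-magnitude similarity deviation (0 for identical images).

    ``c`` is the similarity constant on the squared-gradient scale of
    255-level images; inputs are rescaled accordingly via ``data_range``.
    """
    t = np.asarray(test, float) * (255.0 / data_range)
    r = np.asarray(reference, float) * (255.0 / data_range)
    gt = np.hypot(convolve(t, _PREWITT_X, mode="nearest"),
                  convolve(t, _PREWITT_Y, mode="nearest"))
    gr = np.hypot(convolve(r, _PREWITT_X, mode="nearest"),
                  convolve(r, _PREWITT_Y, mode="nearest"))
    gms = (2.0 * gt * gr + c) / (gt ** 2 + gr ** 2 + c)
    return float(np.std(gms))


def vif_pixel(test: np.ndarray, reference: np.ndarray, data_range: float,
              sigma_nsq: float = 2.0) -> float:
    """Pixel-domain visual information fidelity (multi-scale Gaussian form).

    Equals 1 when test == reference, decreases with information loss, and
    can exceed 1 for contrast-enhanced images (a property of VIF itself).
    """
    dist = np.asarray(test, float) * (255.0 / data_range)
    ref = np.asarray(reference, float) * (255.0 / data_range)
    num = den = 0.0
    for scale in range(1, 5):
        N = 2 ** (4 - scale + 1) + 1
        sd = N / 5.0
        if scale > 1:
            ref = gaussian_filter(ref, sd)[::2, ::2]
            dist = gaussian_filter(dist, sd)[::2, ::2]
        mu1 = gaussian_filter(ref, sd)
        mu2 = gaussian_filter(dist, sd)
        mu1_sq, mu2_sq, mu1_mu2 = mu1 * mu1, mu2 * mu2, mu1 * mu2
        sigma1_sq = gaussian_filter(ref * ref, sd) - mu1_sq
        sigma2_sq = gaussian_filter(dist * dist, sd) - mu2_sq
        sigma12 = gaussian_filter(ref * dist, sd) - mu1_mu2
        sigma1_sq = np.maximum(sigma1_sq, 0.0)
        sigma2_sq = np.maximum(sigma2_sq, 0.0)
        g = sigma12 / (sigma1_sq + 1e-10)
        sv_sq = sigma2_sq - g * sigma12
        g = np.where(sigma1_sq < 1e-10, 0.0, g)
        sv_sq = np.where(sigma1_sq < 1e-10, sigma2_sq, sv_sq)
        sv_sq = np.where(g < 0, sigma2_sq, sv_sq)
        g = np.maximum(g, 0.0)
        sv_sq = np.maximum(sv_sq, 1e-10)
        num += float(np.sum(np.log10(1.0 + g * g * sigma1_sq
                                     / (sv_sq + sigma_nsq))))
        den += float(np.sum(np.log10(1.0 + sigma1_sq / sigma_nsq)))
    return num / den if den > 0 else 1.0


@dataclass
class MetricsReport:
    """Five-metric comparison of a test image against a reference."""

    rmse: float
    psnr: float
    ssim: float
    vif: float
    gmsd: float
    data_range: float

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "psnr": self.psnr, "ssim": self.ssim,
                "vif": self.vif, "gmsd": self.gmsd,
                "data_range": self.data_range}


def evaluate_pair(test, reference, data_range: float | None = None) -> MetricsReport:
    """All five metrics for one image pair.

    ``data_range`` defaults to the reference's max - min (its display
    window); pass an explicit value to fix the intensity unit across cases.
    """
    t = np.asarray(getattr(test, "data", test), float)
    r = np.asarray(getattr(reference, "data", reference), float)
    if t.shape != r.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {r.shape}")
    if data_range is None:
        data_range = float(r.max() - r.min())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return MetricsReport(
        rmse=rmse(t, r),
        psnr=psnr(t, r, data_range),
        ssim=ssim(t, r, data_range),
        vif=vif_pixel(t, r, data_range),
        gmsd=gmsd(t, r, data_range),
        data_range=data_range,
    )


class MetricsTable:
    """Per-case metric rows plus mean/sd summary; CSV and JSON export."""

    COLUMNS = ("rmse", "psnr", "ssim", "vif", "gmsd")

    def __init__(self):
        self.rows = []  # (case, method, MetricsReport)

    def add(self, case: str, method: str, report: MetricsReport):
        self.rows.append((case, method, report))

    def summary(self) -> dict:
        out = {}
        methods = sorted({m for _, m, _ in self.rows})
        for m in methods:
            reps = [r for _, mm, r in self.rows if mm == m]
            out[m] = {}
            for c in self.COLUMNS:
                vals = np.array([getattr(r, c) for r in reps])
                out[m][c] = {"mean": float(vals.mean()),
                             "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
        return out

    def to_csv(self, path):
        lines = ["case,method," + ",".join(self.COLUMNS)]
        for case, method, r in self.rows:
            lines.append(",".join([case, method] +
                                  [f"{getattr(r, c):.6g}" for c in self.COLUMNS]))
        with open(path, "w") as f:
            f.write("\n".join(lines) + "\n")

    def to_json(self, path):
        with open(path, "w") as f:
            json.dump(self.summary(), f, indent=1)
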