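"""Dynamic OCT contrasts from repeated complex frames.

Two complementary contrasts are computed from a stack of co-located B-scan
frames:

* **LIV** (logarithmic intensity variance): the per-pixel population variance
  (divisor N) of the dB-scale intensity over the N frames. With a
  multi-second observation window it responds to slow, second-scale
  dynamics. No noise correction is applied to LIV.

* **Fast-DOCT**: one minus the magnitude of the noise-corrected complex
  correlation between frames milliseconds apart, i.e. complex-decorrelation
  angiography applied to tissue dynamics. The detector-noise energy
  ``|K| * n_pairs * sigma_n^2`` is subtracted from the correlation
  denominators so that noise does not masquerade as decorrelation; pixels
  whose corrected energy falls below a guard ``delta`` are reported in a
  validity mask instead of being silently clipped.

The per-pixel correlation magnitude is a sample-coherence estimate over
``M = |K| * n_pairs`` samples and is biased upward at low coherence
(E[rho_hat] ~ sqrt(pi/4) / sqrt(M) for independent data). Quantitative
region statistics therefore use :func:`pooled_decorrelation`, whose bias
vanishes with the region size; the kernel map is for display and structure
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "LivImage",
    "FastDoctImage",
    "OctVolume",
    "to_db_intensity",
    "liv",
    "bulk_phase_correct",
    "fast_doct",
    "pooled_decorrelation",
    "pooled_correlation_multilag",
    "estimate_tau",
    "estimate_tau_map",
    "estimate_noise_variance",
    "volume_assemble",
    "coherence_floor",
]

DB_EPS = 1e-12


@dataclass
class LivImage:
    values: np.ndarray  # dB^2, (nz, nx), >= 0
    n_frames: int
    window_seconds: float | None = None


@dataclass
class FastDoctImage:
    values: np.ndarray  # decorrelation in [0, 1]
    valid: np.ndarray  # False where corrected energy <= delta
    n_pairs: int
    kernel: tuple[int, int]
    noise_variance: float


@dataclass
class OctVolume:
    """Scalar volume on the (z, x, y) grid with physical pixel pitches."""

    data: np.ndarray  # (nz, nx, ny)
    pixel_pitch_um: tuple[float, float, float]
    kind: str  # "dB" | "LIV" | "FDOCT" | ...
    window_seconds: float | None = None
    extras: dict = field(default_factory=dict)


def to_db_intensity(frames: np.ndarray, eps: float = DB_EPS) -> np.ndarray:
    """dB-scale intensity ``10 log10(|A|^2 + eps)`` of complex frames.

    ``eps`` floors zero intensity so air stays finite (default 1e-12 of full
    scale, i.e. -120 dB).
    """
    return 10.0 * np.log10(np.abs(np.asarray(frames)) ** 2 + eps)


def liv(db_frames: np.ndarray, timestamps: np.ndarray | None = None) -> LivImage:
    """Logarithmic intensity variance over the frame axis (axis 0).

    Population variance with divisor N. Shift-invariant in dB, zero for
    constant stacks, and insensitive to frame order.
    """
    db = np.asarray(db_frames, dtype=float)
    if db.ndim < 1 or db.shape[0] < 2:
        raise ValueError("LIV needs at least 2 frames")
    if not np.all(np.isfinite(db)):
        raise ValueError("non-finite dB input")
    mean = db.mean(axis=0)
    values = np.mean((db - mean) ** 2, axis=0)
    window = None
    if timestamps is not None:
        t = np.asarray(timestamps, dtype=float)
        if t.shape[0] != db.shape[0]:
            raise ValueError("one timestamp per frame required")
        window = float(t[-1] - t[0])
    return LivImage(values=values, n_frames=db.shape[0], window_seconds=window)


def bulk_phase_correct(
    frames: np.ndarray, intensity_quantile: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove per-frame global phase offsets (bulk-motion phase instability).

    For each consecutive pair the global phase ``phi = arg sum_m A_i^* A_{i+1}``
    is estimated over an intensity-weighted mask (pixels above the given
    quantile of the mean intensity) and frame ``i+1`` is rotated by
    ``exp(-i phi)`` cumulatively. Returns ``(corrected, phases, skipped)``
    where ``phases`` are the cumulative corrections applied per frame and
    ``skipped[i]`` flags pairs where a frame carried no energy and the
    correction was skipped.
    """
    a = np.asarray(frames)
    if a.ndim != 3 or a.shape[0] < 2:
        raise ValueError("need a (n_frames, nz, nx) stack with >= 2 frames")
    mean_i = np.mean(np.abs(a) ** 2, axis=0)
    thr = np.quantile(mean_i, intensity_quantile)
    mask = mean_i >= thr
    out = a.copy()
    phases = np.zeros(a.shape[0])
    skipped = np.zeros(a.shape[0] - 1, dtype=bool)
    cum = 0.0
    for i in range(a.shape[0] - 1):
        # measured against the already-corrected previous frame, so the angle
        # is the full correction for frame i+1, not an increment
        s = np.sum(np.conj(out[i])[mask] * a[i + 1][mask])
        if s == 0:
            skipped[i] = True
        else:
            cum = float(np.angle(s))
        phases[i + 1] = cum
        out[i + 1] = a[i + 1] * np.exp(-1j * cum)
    return out, phases, skipped


def _kernel_sum(img: np.ndarray, kernel: tuple[int, int]) -> np.ndarray:
    """Moving-window sum with edge replication."""
    area = kernel[0] * kernel[1]
    if np.iscomplexobj(img):
        return area * (
            uniform_filter(img.real, size=kernel, mode="nearest")
            + 1j * uniform_filter(img.imag, size=kernel, mode="nearest")
        )
    return area * uniform_filter(img, size=kernel, mode="nearest")


def fast_doct(
    frames: np.ndarray,
    noise_variance: float,
    kernel: tuple[int, int] = (3, 3),
    delta_rel: float = 0.5,
    delta_abs: float = 1e-12,
) -> FastDoctImage:
    """Noise-corrected complex-decorrelation map from >= 2 frames.

    With spatial kernel K and the lag-1 frame pairs,

        rho = |sum_K sum_pairs A_i^* A_{i+1}|
              / sqrt(max(E_0 - M sigma_n^2, delta) * max(E_1 - M sigma_n^2, delta))

    where ``E_0/E_1`` are the kernel-summed pair energies, ``M = |K| n_pairs``
    and ``delta = max(delta_rel * M * sigma_n^2, delta_abs)``. The output is
    ``clip(1 - rho, 0, 1)``; pixels whose corrected energy <= delta are
    flagged invalid. Frames are expected bulk-phase-corrected.
    """
    a = np.asarray(frames)
    if a.ndim != 3 or a.shape[0] < 2:
        raise ValueError("need a (n_frames, nz, nx) stack with >= 2 frames")
    if kernel[0] > a.shape[1] or kernel[1] > a.shape[2]:
        raise ValueError(f"kernel {kernel} larger than frame {a.shape[1:]}")
    n_pairs = a.shape[0] - 1
    num = np.zeros(a.shape[1:], dtype=complex)
    e0 = np.zeros(a.shape[1:])
    e1 = np.zeros(a.shape[1:])
    for i in range(n_pairs):
        num += np.conj(a[i]) * a[i + 1]
        e0 += np.abs(a[i]) ** 2
        e1 += np.abs(a[i + 1]) ** 2
    num_k = _kernel_sum(num, kernel)
    e0_k = _kernel_sum(e0, kernel)
    e1_k = _kernel_sum(e1, kernel)
    m = kernel[0] * kernel[1] * n_pairs
    noise_energy = m * noise_variance
    delta = max(delta_rel * noise_energy, delta_abs)
    c0 = e0_k - noise_energy
    c1 = e1_k - noise_energy
    valid = (c0 > delta) & (c1 > delta)
    rho = np.abs(num_k) / np.sqrt(np.maximum(c0, delta) * np.maximum(c1, delta))
    values = np.clip(1.0 - rho, 0.0, 1.0)
    return FastDoctImage(
        values=values,
        valid=valid,
        n_pairs=n_pairs,
        kernel=tuple(kernel),
        noise_variance=noise_variance,
    )


def coherence_floor(n_samples: int | float) -> float:
    """Expected sample-coherence magnitude of truly independent data pooled
    over ``n_samples`` complex samples: ``sqrt(pi)/2 / sqrt(M)`` (Rayleigh
    mean of the zero-coherence estimate)."""
    return float(np.sqrt(np.pi) / 2.0 / np.sqrt(n_samples))


def _pooled_rho(
    a: np.ndarray, lag: int, noise_variance: float, mask: np.ndarray | None
) -> tuple[float, int]:
    n = a.shape[0]
    num = 0.0 + 0.0j
    e0 = 0.0
    e1 = 0.0
    count = 0
    for i in range(n - lag):
        x, y = a[i], a[i + lag]
        if mask is not None:
            x, y = x[mask], y[mask]
        num += np.sum(np.conj(x) * y)
        e0 += np.sum(np.abs(x) ** 2)
        e1 += np.sum(np.abs(y) ** 2)
        count += x.size
    c0 = max(e0 - count * noise_variance, 1e-300)
    c1 = max(e1 - count * noise_variance, 1e-300)
    return float(np.abs(num) / np.sqrt(c0 * c1)), count


def pooled_decorrelation(
    frames: np.ndarray,
    noise_variance: float = 0.0,
    mask: np.ndarray | None = None,
    lag: int = 1,
) -> float:
    """Region-pooled complex decorrelation ``1 - |rho|``.

    A single correlation estimate over all masked pixels and lag-``lag``
    frame pairs; the magnitude bias decays as 1/sqrt(total samples), making
    this the estimator of choice for quantitative comparisons against the
    closed-form ``1 - exp(-dt/tau)``.
    """
    a = np.asarray(frames)
    if a.ndim != 3 or a.shape[0] < lag + 1:
        raise ValueError("need a (n_frames, nz, nx) stack with > lag frames")
    rho, _ = _pooled_rho(a, lag, noise_variance, mask)
    return float(np.clip(1.0 - rho, 0.0, 1.0))


def pooled_correlation_multilag(
    frames: np.ndarray,
    timestamps: np.ndarray,
    noise_variance: float = 0.0,
    mask: np.ndarray | None = None,
    max_lag: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled |rho| at lags 1..max_lag and the corresponding time offsets.

    Returns ``(dt, rho, n_samples)``. Timestamps must be (close to)
    uniformly spaced so a lag maps to a single time offset.
    """
    a = np.asarray(frames)
    t = np.asarray(timestamps, dtype=float)
    gaps = np.diff(t)
    if np.any(gaps <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if np.ptp(gaps) > 1e-9 * gaps.mean():
        raise ValueError("multi-lag correlation requires uniform frame spacing")
    dt = gaps.mean()
    max_lag = min(max_lag, a.shape[0] - 1)
    dts, rhos, counts = [], [], []
    for lag in range(1, max_lag + 1):
        rho, count = _pooled_rho(a, lag, noise_variance, mask)
        dts.append(lag * dt)
        rhos.append(rho)
        counts.append(count)
    return np.asarray(dts), np.asarray(rhos), np.asarray(counts)


def estimate_tau(
    frames: np.ndarray,
    timestamps: np.ndarray,
    noise_variance: float = 0.0,
    mask: np.ndarray | None = None,
    max_lag: int = 3,
    floor_factor: float = 5.0,
) -> float:
    """Correlation time from multi-lag pooled decorrelation.

    Fits ``ln rho(dt) = -dt / tau`` through the origin over the lags whose
    pooled |rho| clears ``floor_factor`` times the zero-coherence floor (so
    lags lost in estimator noise do not drag the fit). NaN when no lag
    qualifies.
    """
    dts, rhos, counts = pooled_correlation_multilag(
        frames, timestamps, noise_variance, mask, max_lag
    )
    floors = np.array([coherence_floor(c) for c in counts])
    ok = rhos > np.maximum(floor_factor * floors, 1e-6)
    ok &= rhos < 1.0
    if not np.any(ok):
        return float("nan")
    x = dts[ok]
    y = np.log(rhos[ok])
    slope = np.sum(x * y) / np.sum(x * x)
    if slope >= 0:
        return float("inf")
    return float(-1.0 / slope)


def estimate_tau_map(
    frames: np.ndarray,
    timestamps: np.ndarray,
    noise_variance: float = 0.0,
    kernel: tuple[int, int] = (7, 7),
    max_lag: int = 3,
    floor_factor: float = 2.5,
) -> np.ndarray:
    """Per-pixel correlation-time map from kernel-pooled multi-lag |rho|.

    Each lag's correlation is pooled over the spatial kernel; lags whose
    magnitude does not clear ``floor_factor`` times the kernel's
    zero-coherence floor are excluded per pixel. NaN where no lag qualifies.
    The kernel floor (not region-pooled) biases magnitudes upward, so maps
    of very fast dynamics are noisier than region estimates from
    :func:`estimate_tau`.
    """
    a = np.asarray(frames)
    t = np.asarray(timestamps, dtype=float)
    gaps = np.diff(t)
    if np.ptp(gaps) > 1e-9 * gaps.mean():
        raise ValueError("multi-lag correlation requires uniform frame spacing")
    dt = gaps.mean()
    max_lag = min(max_lag, a.shape[0] - 1)
    area = kernel[0] * kernel[1]

    num_x = 0.0
    den_x = 0.0
    any_ok = np.zeros(a.shape[1:], dtype=bool)
    for lag in range(1, max_lag + 1):
        num = np.zeros(a.shape[1:], dtype=complex)
        e0 = np.zeros(a.shape[1:])
        e1 = np.zeros(a.shape[1:])
        for i in range(a.shape[0] - lag):
            num += np.conj(a[i]) * a[i + lag]
            e0 += np.abs(a[i]) ** 2
            e1 += np.abs(a[i + lag]) ** 2
        m = area * (a.shape[0] - lag)
        c0 = np.maximum(_kernel_sum(e0, kernel) - m * noise_variance, 1e-300)
        c1 = np.maximum(_kernel_sum(e1, kernel) - m * noise_variance, 1e-300)
        rho = np.abs(_kernel_sum(num, kernel)) / np.sqrt(c0 * c1)
        ok = (rho > floor_factor * coherence_floor(m)) & (rho < 1.0)
        any_ok |= ok
        x = lag * dt
        y = np.where(ok, np.log(np.clip(rho, 1e-300, 1.0)), 0.0)
        num_x = num_x + np.where(ok, x * y, 0.0)
        den_x = den_x + np.where(ok, x * x, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = num_x / den_x
        tau = -1.0 / slope
    tau = np.where(any_ok & (slope < 0), tau, np.nan)
    return tau


def estimate_noise_variance(frames: np.ndarray, air_mask: np.ndarray) -> float:
    """Detector-noise variance as the mean |A|^2 over air voxels and frames.

    ``air_mask`` marks noise-only pixels (above the segmented surface) in
    each frame. Raises on an empty mask: the caller must then supply
    sigma_n^2 from configuration.
    """
    a = np.asarray(frames)
    mask = np.asarray(air_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("air mask is empty; supply noise variance from config")
    if mask.ndim == a.ndim:
        if mask.shape != a.shape:
            raise ValueError("air mask shape must match the frames")
        vals = a[mask]
    elif mask.ndim == a.ndim - 1:
        if mask.shape != a.shape[1:]:
            raise ValueError("air mask shape must match one frame")
        vals = a[:, mask]
    else:
        raise ValueError("air mask must match the frames or one frame")
    return float(np.mean(np.abs(vals) ** 2))


def volume_assemble(
    images: dict[int, np.ndarray] | list[tuple[int, np.ndarray]],
    pixel_pitch_um: tuple[float, float, float],
    kind: str,
    window_seconds: float | None = None,
) -> OctVolume:
    """Stack per-location 2D images into a (z, x, y) volume.

    ``images`` maps slow-axis location index -> (nz, nx) image. Every index
    from 0 to max must be present; insertion order is irrelevant.
    """
    items = dict(images if isinstance(images, dict) else list(images))
    ny = max(items) + 1
    missing = [i for i in range(ny) if i not in items]
    if missing:
        raise ValueError(f"missing location images: {missing}")
    shapes = {np.asarray(v).shape for v in items.values()}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent image shapes: {shapes}")
    nz, nx = shapes.pop()
    data = np.empty((nz, nx, ny), dtype=np.asarray(items[0]).dtype)
    for i in range(ny):
        data[:, :, i] = items[i]
    return OctVolume(
        data=data, pixel_pitch_um=tuple(pixel_pitch_um), kind=kind, window_seconds=window_seconds
    )
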