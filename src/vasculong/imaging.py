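"""Image-domain measurements: rigid angiogram registration, cross-section
extraction, Gaussian FWHM diameters (1D for pial vessels, 2D for
penetrating vessels) and area-integral Doppler flow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import structure_tensor
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _rotate

log = logging.getLogger(__name__)

#: FWHM of a Gaussian of width sigma
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class MeasurementRejected(ValueError):
    """Raised when a fit is too degenerate to yield a diameter."""


@dataclass
class RigidTransform:
    """In-plane rigid alignment: translation (voxels or µm, caller's
    units) plus rotation in degrees about the image centre."""

    shift: tuple
    rotation_deg: float
    correlation: float = np.nan
    low_confidence: bool = False


@dataclass
class CrossSection:
    """Averaged intensity profile orthogonal to a vessel."""

    positions_um: np.ndarray
    intensity: np.ndarray
    n_averaged: int = 10
    truncated: bool = False

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    d = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / d) if d else 0.0


def register_rigid(moving: np.ndarray, reference: np.ndarray,
                   max_rotation_deg: float = 15.0,
                   coarse_step_deg: float = 1.0,
                   corr_threshold: float = 0.2,
                   refine_iters: int = 1) -> RigidTransform:
    """Recover the shift + rotation aligning ``moving`` onto ``reference``.

    Coarse search over rotation angles (each evaluated with FFT phase
    correlation for the best shift), followed by a golden-section
    refinement of the angle and sub-pixel shift estimation. The returned
    transform maps moving -> reference: rotate by ``rotation_deg`` about
    the centre, then translate by ``shift`` (row, col).
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    # Hann window + mean subtraction: suppresses edge/fill artifacts and the
    # DC term that otherwise pin the correlation peak at zero lag
    win = np.outer(np.hanning(ref.shape[0]), np.hanning(ref.shape[1]))
    refw = (ref - ref.mean()) * win
    mr, mc = max(ref.shape[0] // 10, 2), max(ref.shape[1] // 10, 2)

    def _rotmat(deg):
        th = np.deg2rad(deg)
        return np.array([[np.cos(th), -np.sin(th)],
                         [np.sin(th), np.cos(th)]])

    ones = np.ones_like(mov)

    def _overlap_ncc(aligned, valid):
        good = valid > 0.9
        good[:mr, :] = good[-mr:, :] = False
        good[:, :mc] = good[:, -mc:] = False
        if good.sum() < 64:
            return -1.0
        return _ncc(aligned[good], ref[good])

    # joint coarse search: per trial angle an un-windowed phase correlation
    # (robust to large translations) supplies the best shift; scoring is
    # restricted to the genuinely overlapping pixels
    best = (-np.inf, 0.0, np.zeros(2))
    for ang in np.arange(-max_rotation_deg, max_rotation_deg + 1e-9,
                         coarse_step_deg):
        rot = _rotate(mov, ang, preserve_range=True)
        s, _, _ = phase_cross_correlation(ref - ref.mean(),
                                          rot - rot.mean(),
                                          upsample_factor=4,
                                          normalization=None)
        aligned = ndimage.shift(rot, s, order=1)
        valid = ndimage.shift(_rotate(ones, ang, preserve_range=True),
                              s, order=1)
        c = _overlap_ncc(aligned, valid)
        if c > best[0]:
            best = (c, float(ang), np.asarray(s, dtype=float))

    # re-centre, then windowed sub-pixel refinement around the coarse angle
    s_pre = _rotmat(-best[1]) @ best[2]
    mov_c = ndimage.shift(mov, s_pre, order=3)
    ones_c = ndimage.shift(ones, s_pre, order=1)

    def score(angle, up=4):
        rot = _rotate(mov_c, angle, preserve_range=True)
        shift, _, _ = phase_cross_correlation(
            refw, (rot - rot.mean()) * win, upsample_factor=up,
            normalization=None)
        aligned = ndimage.shift(rot, shift, order=3)
        valid = ndimage.shift(_rotate(ones_c, angle, preserve_range=True),
                              shift, order=1)
        return _overlap_ncc(aligned, valid), shift

    lo, hi = best[1] - coarse_step_deg, best[1] + coarse_step_deg
    res = optimize.minimize_scalar(lambda a: -score(a, up=10)[0],
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 0.01})
    ang = float(res.x)
    corr, s1 = score(ang, up=20)
    # compose: shift_{s1}(rot(shift_{s_pre}(x))) = shift_{s1 + M s_pre}(rot(x))
    shift = np.asarray(s1, dtype=float) + _rotmat(ang) @ s_pre
    tf = RigidTransform(shift=tuple(float(s) for s in shift),
                        rotation_deg=ang, correlation=corr)
    # a second pass on the aligned image removes the residual coupling
    # between a large translation and the rotation estimate
    for _ in range(refine_iters):
        aligned = apply_rigid(mov, tf)
        d = register_rigid(aligned, ref, max_rotation_deg=2.0,
                           coarse_step_deg=0.5, refine_iters=0,
                           corr_threshold=corr_threshold)
        if d.correlation <= tf.correlation:
            break
        th2 = np.deg2rad(d.rotation_deg)
        m2 = np.array([[np.cos(th2), -np.sin(th2)],
                       [np.sin(th2), np.cos(th2)]])
        tf = RigidTransform(
            shift=tuple(np.asarray(d.shift) + m2 @ np.asarray(tf.shift)),
            rotation_deg=tf.rotation_deg + d.rotation_deg,
            correlation=d.correlation)
    tf.low_confidence = tf.correlation < corr_threshold
    if tf.low_confidence:
        log.warning("registration correlation %.3f below threshold",
                    tf.correlation)
    return tf


def apply_rigid(image: np.ndarray, tf: RigidTransform) -> np.ndarray:
    """Apply a recovered transform (rotation about centre, then shift)."""
    out = _rotate(np.asarray(image, dtype=float), tf.rotation_deg,
                  preserve_range=True)
    return ndimage.shift(out, tf.shift, order=1)


# ---------------------------------------------------------------------------
# cross-sections
# ---------------------------------------------------------------------------

def local_orientation(image: np.ndarray, point, sigma: float = 3.0) -> float:
    """Vessel orientation (radians, in-plane) at ``point`` (row, col) from
    the structure tensor: the eigenvector of the smaller eigenvalue points
    along the vessel."""
    Arr, Arc, Acc = structure_tensor(np.asarray(image, dtype=float),
                                     sigma=sigma, order="rc")
    r, c = int(round(point[0])), int(round(point[1]))
    t = np.array([[Arr[r, c], Arc[r, c]], [Arc[r, c], Acc[r, c]]])
    w, v = np.linalg.eigh(t)
    vec = v[:, 0]  # smallest eigenvalue: direction of least gradient energy
    return float(np.arctan2(vec[1], vec[0]))


def extract_cross_section(image: np.ndarray, point, pixel_um: float = 1.0,
                          orientation_rad: float | None = None,
                          half_width_um: float = 30.0,
                          n_averaged: int = 10,
                          step_um: float | None = None) -> CrossSection:
    """Intensity profile along the line orthogonal to the vessel at
    ``point`` (row, col), averaging ``n_averaged`` adjacent profiles taken
    along the vessel direction for robustness to local thickness
    fluctuation."""
    img = np.asarray(image, dtype=float)
    if orientation_rad is None:
        orientation_rad = local_orientation(img, point)
    if step_um is None:
        step_um = pixel_um / 2.0
    along = np.array([np.cos(orientation_rad), np.sin(orientation_rad)])
    ortho = np.array([-along[1], along[0]])
    s = np.arange(-half_width_um, half_width_um + 1e-9, step_um)
    offsets = (np.arange(n_averaged) - (n_averaged - 1) / 2.0) * pixel_um
    p0 = np.asarray(point, dtype=float)
    profiles = []
    truncated = False
    for off in offsets:
        centre = p0 + off * along / pixel_um
        rows = centre[0] + s * ortho[0] / pixel_um
        cols = centre[1] + s * ortho[1] / pixel_um
        if (rows.min() < 0 or cols.min() < 0 or rows.max() > img.shape[0] - 1
                or cols.max() > img.shape[1] - 1):
            truncated = True
        profiles.append(ndimage.map_coordinates(img, [rows, cols], order=1,
                                                mode="nearest"))
    if truncated:
        log.warning("cross-section line exits the image; profile truncated")
    return CrossSection(positions_um=s, intensity=np.mean(profiles, axis=0),
                        n_averaged=n_averaged, truncated=truncated)


# ---------------------------------------------------------------------------
# Gaussian-fit diameters
# ---------------------------------------------------------------------------

def _gauss1d(x, off, amp, mu, sigma):
    return off + amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))


def fit_fwhm_diameter(cs: CrossSection, max_rel_residual: float = 0.5
                      ) -> float:
    """Vessel diameter (µm) as the FWHM of a Gaussian fitted to the
    cross-sectional profile: offset + A·exp(−(x−µ)²/2σ²), diameter =
    2√(2 ln 2)·σ. Degenerate or non-convergent fits raise
    :class:`MeasurementRejected` with the reason."""
    x, y = cs.positions_um, cs.intensity
    amp0 = float(y.max() - y.min())
    noise = float(np.std(np.diff(y)) / np.sqrt(2.0)) if len(y) > 3 else 0.0
    if amp0 <= 0 or amp0 <= 3.0 * noise:
        raise MeasurementRejected("no dominant peak above the noise floor")
    mu0 = float(x[np.argmax(y)])
    w = np.clip(y - y.min(), 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (x - mu0) ** 2) / np.sum(w))) or 1.0
    try:
        popt, _ = optimize.curve_fit(
            _gauss1d, x, y, p0=[float(y.min()), amp0, mu0, sigma0],
            maxfev=5000)
    except RuntimeError as e:
        raise MeasurementRejected(f"Gaussian fit did not converge: {e}")
    off, amp, mu, sigma = popt
    resid = y - _gauss1d(x, *popt)
    if amp <= 0 or abs(amp) <= 3.0 * noise:
        raise MeasurementRejected("fitted amplitude at or below noise")
    if np.linalg.norm(resid) / (np.linalg.norm(y - y.mean()) + 1e-12) > max_rel_residual:
        raise MeasurementRejected("relative residual above 0.5")
    return float(FWHM_FACTOR * abs(sigma))


def _gauss2d(coords, off, amp, mu_r, mu_c, sig_r, sig_c, theta):
    r, c = coords
    ct, st = np.cos(theta), np.sin(theta)
    u = (r - mu_r) * ct + (c - mu_c) * st
    v = -(r - mu_r) * st + (c - mu_c) * ct
    return off + amp * np.exp(-(u ** 2 / (2 * sig_r ** 2)
                                + v ** 2 / (2 * sig_c ** 2)))


def fit_gaussian2d_diameter(patch: np.ndarray, pixel_um: float = 1.0,
                            max_rel_residual: float = 0.5) -> float:
    """Penetrating-vessel diameter from an en-face patch: least-squares
    elliptical 2D Gaussian; diameter = geometric mean of the two FWHMs,
    in µm."""
    img = np.asarray(patch, dtype=float)
    r, c = np.mgrid[0: img.shape[0], 0: img.shape[1]]
    amp0 = float(img.max() - img.min())
    if amp0 <= 0:
        raise MeasurementRejected("flat patch")
    mu_r0, mu_c0 = np.unravel_index(np.argmax(img), img.shape)
    w = np.clip(img - img.min(), 0, None)
    sr0 = float(np.sqrt(np.sum(w * (r - mu_r0) ** 2) / np.sum(w))) or 1.0
    sc0 = float(np.sqrt(np.sum(w * (c - mu_c0) ** 2) / np.sum(w))) or 1.0
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d, (r.ravel(), c.ravel()), img.ravel(),
            p0=[float(img.min()), amp0, float(mu_r0), float(mu_c0),
                sr0, sc0, 0.0], maxfev=8000)
    except RuntimeError as e:
        raise MeasurementRejected(f"2D Gaussian fit did not converge: {e}")
    off, amp, mu_r, mu_c, sig_r, sig_c, theta = popt
    resid = img.ravel() - _gauss2d((r.ravel(), c.ravel()), *popt)
    if amp <= 0:
        raise MeasurementRejected("non-positive fitted amplitude")
    if (np.linalg.norm(resid) /
            (np.linalg.norm(img - img.mean()) + 1e-12)) > max_rel_residual:
        raise MeasurementRejected("relative residual above 0.5")
    fwhm_r = FWHM_FACTOR * abs(sig_r) * pixel_um
    fwhm_c = FWHM_FACTOR * abs(sig_c) * pixel_um
    return float(np.sqrt(fwhm_r * fwhm_c))


# ---------------------------------------------------------------------------
# Doppler flow
# ---------------------------------------------------------------------------

def doppler_flow(vmap: np.ndarray, mask: np.ndarray, pixel_um: float,
                 denoise: bool = True, velocity_floor: float = 0.0,
                 median_size: int = 3) -> float:
    """Area-integral flow through a penetrating vessel, in nL/min.

    flow = Σ_mask v_z(x, y) · ΔA with v_z in µm/s and ΔA = pixel_um².
    Signed: positive = toward the cortex. The area integral is nominally
    independent of vessel inclination (a tilt reduces v_z by cosθ and
    grows the en-face area by 1/cosθ). Noise reduction is a median filter
    followed by zeroing sub-threshold |v_z| pixels.
    """
    v = np.asarray(vmap, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if m.shape != v.shape:
        raise ValueError("mask and velocity map shapes differ")
    border = np.zeros_like(m)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (m & border).any():
        log.warning("mask touches the image border; vessel may be truncated")
    if denoise:
        v = ndimage.median_filter(v, size=median_size)
        if velocity_floor > 0:
            v = np.where(np.abs(v) < velocity_floor, 0.0, v)
    flow_um3_s = float(v[m].sum() * pixel_um ** 2)
    return flow_um3_s * 60.0 / 1e6  # µm³/s -> nL/min


def fractional_change(values, baseline: float) -> np.ndarray:
    """Values relative to a baseline (the model intercept); errors on a
    zero baseline."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return np.asarray(values, dtype=float) / float(baseline)
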