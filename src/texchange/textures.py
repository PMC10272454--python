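"""Self-affine rough-surface synthesis with a prescribed isotropic PSD.

The stimulus surface is a realization of an isotropic Gaussian random field
whose height power spectral density is piecewise in the wavenumber magnitude
q = ||**q**|| (rad/m):

    phi(q) = C                      for q0 <= q <= qr     (plateau)
    phi(q) = C * (q/qr)^(-2(1+H))   for qr <  q <= q1     (self-affine roll-off)
    phi(q) = 0                      otherwise

C sets the roughness amplitude, [q0, q1] bound the retained wavenumbers, qr
is the roll-off wavenumber and H is the Hurst roughness exponent.  With the
convention used throughout this module the height variance is the isotropic
Parseval integral

    sigma^2 = (1/2pi) * Integral phi(q) * q dq .

Fields are synthesized spectrally: complex Gaussian Fourier coefficients are
drawn with Hermitian symmetry (by filtering white noise in the Fourier
domain) and amplitudes shaped by sqrt(phi).  The amplitude constant is then
rescaled so the realized RMS height matches a target (0.15 mm by default),
and the smooth/transition/rough stimulus tile is composed with a linear
cross-fade over the 10 mm central transition band.

Physical units: wavenumbers in rad/m, all lengths and heights in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DegenerateInputError,
    GeometryError,
    ParameterError,
    ResolutionError,
)

__all__ = [
    "SpectralParams",
    "HeightField",
    "TileSpec",
    "psd_value",
    "synthesize_field",
    "calibrate_amplitude",
    "compose_tile",
    "export_heightfield",
    "load_heightfield",
]

#: Default stimulus spectrum (rad/m) and target roughness (mm).
DEFAULT_Q0 = 1200.0
DEFAULT_Q1 = 3600.0
DEFAULT_QR = 2400.0
DEFAULT_H = 0.8
DEFAULT_RMS_MM = 0.15


@dataclass(frozen=True)
class SpectralParams:
    """Parameters of the piecewise isotropic height PSD.

    Attributes
    ----------
    C : float
        Plateau amplitude of the PSD (m^4).
    q0, q1 : float
        Lower / upper wavenumber cutoffs (rad/m); power outside [q0, q1]
        is zero.
    qr : float
        Roll-off wavenumber (rad/m) above which the PSD decays as
        (q/qr)^(-2(1+H)).
    H : float
        Hurst roughness exponent (dimensionless, typically in (0, 1)).
    rms_target : float
        Target RMS surface roughness in mm used for amplitude calibration.
    """

    C: float = 1.0e-16
    q0: float = DEFAULT_Q0
    q1: float = DEFAULT_Q1
    qr: float = DEFAULT_QR
    H: float = DEFAULT_H
    rms_target: float = DEFAULT_RMS_MM

    def __post_init__(self) -> None:
        if not (0.0 < self.q0 <= self.qr <= self.q1):
            raise ParameterError(
                f"require 0 < q0 <= qr <= q1, got q0={self.q0}, "
                f"qr={self.qr}, q1={self.q1}"
            )
        if self.H <= 0.0:
            raise ParameterError(f"Hurst exponent must be positive, got {self.H}")
        if self.C <= 0.0:
            raise ParameterError(f"C must be positive, got {self.C}")
        if self.rms_target <= 0.0:
            raise ParameterError(f"rms_target must be positive, got {self.rms_target}")

    @property
    def wavelength_long_mm(self) -> float:
        """Longest retained wavelength 2*pi/q0, in mm."""
        return 2.0 * np.pi / self.q0 * 1e3

    @property
    def wavelength_rolloff_mm(self) -> float:
        """Roll-off wavelength 2*pi/qr, in mm."""
        return 2.0 * np.pi / self.qr * 1e3

    @property
    def wavelength_short_mm(self) -> float:
        """Shortest retained wavelength 2*pi/q1, in mm."""
        return 2.0 * np.pi / self.q1 * 1e3


@dataclass(frozen=True)
class HeightField:
    """Regular 2D grid of surface heights.

    ``heights`` has shape (ny, nx); axis 1 (columns) runs along the tile's
    long (x) axis.  ``spacing`` is the uniform grid pitch in mm and
    ``origin`` the physical (x, y) coordinate of ``heights[0, 0]`` in mm.
    """

    heights: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2:
            raise ParameterError("heights must be a 2D array")
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")
        object.__setattr__(self, "heights", h)

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(x, y) physical size in mm."""
        ny, nx = self.heights.shape
        return nx * self.spacing, ny * self.spacing

    @property
    def x_mm(self) -> np.ndarray:
        """Physical x coordinate of each column (mm)."""
        return self.origin[0] + self.spacing * np.arange(self.heights.shape[1])

    def rms(self) -> float:
        """RMS height about zero, in mm."""
        return float(np.sqrt(np.mean(self.heights**2)))


@dataclass(frozen=True)
class TileSpec:
    """Partition of the stimulus tile along its long axis (mm).

    The printed tile is 100 mm long but the stated segments (40 smooth +
    10 transition + 40 rough) only cover 90 mm; the remaining length is
    split evenly between the two ends as margins that continue the
    adjacent texture (``margin`` per end).
    """

    length_smooth: float = 40.0
    length_transition: float = 10.0
    length_rough: float = 40.0
    width: float = 50.0
    margin: float = 5.0

    def __post_init__(self) -> None:
        for name in ("length_smooth", "length_transition", "length_rough", "width"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.margin < 0:
            raise ParameterError("margin must be non-negative")

    @property
    def total_length(self) -> float:
        return (
            self.length_smooth
            + self.length_transition
            + self.length_rough
            + 2.0 * self.margin
        )


def psd_value(q, params: SpectralParams):
    """Evaluate the piecewise isotropic PSD phi(q) in m^4.

    Parameters
    ----------
    q : float or array-like
        Wavenumber magnitude(s), rad/m, q >= 0.
    params : SpectralParams

    Returns
    -------
    float or ndarray
        C on the plateau [q0, qr], the self-affine roll-off
        C*(q/qr)^(-2(1+H)) on (qr, q1], and 0 outside [q0, q1].
        Continuous at q = qr.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ParameterError("wavenumber magnitudes must be non-negative")
    out = np.zeros_like(q)
    plateau = (q >= params.q0) & (q <= params.qr)
    rolloff = (q > params.qr) & (q <= params.q1)
    out[plateau] = params.C
    with np.errstate(divide="ignore"):
        out[rolloff] = params.C * (q[rolloff] / params.qr) ** (-2.0 * (1.0 + params.H))
    if out.ndim == 0:
        return float(out)
    return out


def rms_from_psd(params: SpectralParams) -> float:
    """Closed-form RMS height (mm) implied by the PSD.

    Evaluates sqrt((1/2pi) * Integral_q0^q1 phi(q) q dq) analytically for
    the piecewise spectrum.
    """
    C, q0, qr, q1, H = params.C, params.q0, params.qr, params.q1, params.H
    plateau = C * (qr**2 - q0**2) / 2.0
    # Integral of q^(1-2(1+H)) = q^(-1-2H) from qr to q1, times C*qr^(2(1+H)).
    a = -2.0 * H
    if a == 0.0:  # pragma: no cover - H=0 excluded by validation
        tail = C * qr ** (2.0 * (1.0 + H)) * np.log(q1 / qr)
    else:
        tail = C * qr ** (2.0 * (1.0 + H)) * (q1**a - qr**a) / a
    var_m2 = (plateau + tail) / (2.0 * np.pi)
    return float(np.sqrt(var_m2) * 1e3)


def synthesize_field(
    params: SpectralParams,
    extent: tuple[float, float] = (100.0, 50.0),
    spacing: float = 0.1,
    seed: int | None = None,
) -> HeightField:
    """Synthesize a random rough surface with the prescribed PSD.

    White Gaussian noise is filtered in the 2D Fourier domain with transfer
    amplitude sqrt(phi(q) / (dx*dy)), which yields a real, zero-mean field
    whose expected periodogram equals phi.  Reproducible for a fixed seed.

    Parameters
    ----------
    params : SpectralParams
    extent : (float, float)
        Physical (x, y) size in mm.
    spacing : float
        Grid pitch in mm; must give at least 4 samples per shortest
        retained wavelength 2*pi/q1.
    seed : int, optional
        Seed for the random generator.

    Returns
    -------
    HeightField
        Heights in mm, zero mean, origin at (0, 0).
    """
    lam_min_mm = 2.0 * np.pi / params.q1 * 1e3
    if spacing > lam_min_mm / 4.0:
        raise ResolutionError(
            f"spacing {spacing} mm too coarse: need <= {lam_min_mm / 4.0:.4f} mm "
            f"(4 samples per shortest wavelength {lam_min_mm:.4f} mm)"
        )
    lam_max_mm = 2.0 * np.pi / params.q0 * 1e3
    if min(extent) < 2.0 * lam_max_mm:
        raise ResolutionError(
            f"extent {extent} mm too small relative to the longest "
            f"wavelength {lam_max_mm:.2f} mm"
        )
    nx = int(round(extent[0] / spacing))
    ny = int(round(extent[1] / spacing))
    d_m = spacing * 1e-3
    qx = 2.0 * np.pi * np.fft.fftfreq(nx, d=d_m)
    qy = 2.0 * np.pi * np.fft.fftfreq(ny, d=d_m)
    qmag = np.hypot(qy[:, None], qx[None, :])

    rng = np.random.default_rng(seed)
    white = rng.standard_normal((ny, nx))
    amp = np.sqrt(psd_value(qmag.ravel(), params).reshape(qmag.shape) / (d_m * d_m))
    spec = np.fft.fft2(white) * amp
    spec[0, 0] = 0.0  # zero mean
    heights_m = np.fft.ifft2(spec).real
    return HeightField(heights=heights_m * 1e3, spacing=spacing, origin=(0.0, 0.0))


def calibrate_amplitude(field: HeightField, rms_target: float = DEFAULT_RMS_MM) -> HeightField:
    """Rescale a field so its RMS height equals ``rms_target`` mm exactly.

    The output is a scalar multiple of the input; a zero-mean input stays
    zero-mean.  Raises ``DegenerateInputError`` for a flat field.
    """
    if rms_target <= 0:
        raise ParameterError("rms_target must be positive")
    rms = field.rms()
    if rms == 0.0:
        raise DegenerateInputError("cannot calibrate a zero-variance field")
    return replace(field, heights=field.heights * (rms_target / rms))


def transition_weight(x_mm, tile: TileSpec):
    """Linear cross-fade weight of the rough texture at tile coordinate x.

    x is in the tile-centre frame (x = 0 at the middle of the transition
    band, positive toward the rough end).  Returns 0 on the smooth side,
    1 on the rough side and a linear ramp across the transition band.
    """
    half = tile.length_transition / 2.0
    return np.clip((np.asarray(x_mm, dtype=float) + half) / (2.0 * half), 0.0, 1.0)


def compose_tile(rough: HeightField, tile: TileSpec | None = None) -> HeightField:
    """Compose the smooth/transition/rough stimulus tile.

    The rough field must cover the full tile extent.  The returned field is
    expressed in the tile-centre frame: heights are 0 over the smooth half,
    equal to ``rough`` over the rough half, and cross-faded linearly (hence
    continuously, with no step edge) over the central transition band.
    """
    tile = tile or TileSpec()
    ext_x, ext_y = rough.extent_mm
    if ext_x + 1e-9 < tile.total_length or ext_y + 1e-9 < tile.width:
        raise GeometryError(
            f"rough field extent {ext_x:.2f}x{ext_y:.2f} mm does not cover "
            f"tile {tile.total_length:.2f}x{tile.width:.2f} mm"
        )
    nx = int(round(tile.total_length / rough.spacing))
    ny = int(round(tile.width / rough.spacing))
    h = rough.heights[:ny, :nx]
    origin_x = -tile.total_length / 2.0
    x = origin_x + rough.spacing * np.arange(nx)
    w = transition_weight(x, tile)
    return HeightField(
        heights=h * w[None, :],
        spacing=rough.spacing,
        origin=(origin_x, -tile.width / 2.0),
    )


def export_heightfield(field: HeightField, path, format: str = "txt") -> None:
    """Write a height field to disk.

    Formats
    -------
    ``txt``
        Delimited text grid with a comment header carrying spacing and
        origin; lossless round trip via :func:`load_heightfield`.
    ``png``
        16-bit grayscale heightmap plus a JSON sidecar (``<path>.json``)
        with the height range, spacing and origin; quantization error is
        bounded by (zmax - zmin)/65535.
    ``stl``
        Binary STL triangulation of the grid (2*(nx-1)*(ny-1) facets),
        via trimesh.
    """
    path = str(path)
    if format == "txt":
        header = (
            f"spacing_mm={field.spacing!r} "
            f"origin_x_mm={field.origin[0]!r} origin_y_mm={field.origin[1]!r}"
        )
        np.savetxt(path, field.heights, header=header)
    elif format == "png":
        from PIL import Image

        zmin = float(field.heights.min())
        zmax = float(field.heights.max())
        span = zmax - zmin
        if span == 0.0:
            quant = np.zeros_like(field.heights, dtype=np.uint16)
        else:
            quant = np.round((field.heights - zmin) / span * 65535.0).astype(np.uint16)
        Image.fromarray(quant).save(path)
        sidecar = {
            "zmin_mm": zmin,
            "zmax_mm": zmax,
            "spacing_mm": field.spacing,
            "origin_mm": list(field.origin),
        }
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1, sort_keys=True)
    elif format == "stl":
        import trimesh

        ny, nx = field.heights.shape
        xs = field.origin[0] + field.spacing * np.arange(nx)
        ys = field.origin[1] + field.spacing * np.arange(ny)
        xx, yy = np.meshgrid(xs, ys)
        verts = np.column_stack(
            [xx.ravel(), yy.ravel(), field.heights.ravel()]
        )
        idx = np.arange(ny * nx).reshape(ny, nx)
        a = idx[:-1, :-1].ravel()
        b = idx[:-1, 1:].ravel()
        c = idx[1:, :-1].ravel()
        d = idx[1:, 1:].ravel()
        faces = np.concatenate(
            [np.column_stack([a, b, c]), np.column_stack([b, d, c])]
        )
        trimesh.Trimesh(vertices=verts, faces=faces, process=False).export(path)
    else:
        raise ParameterError(f"unknown export format {format!r}")


def load_heightfield(path, format: str = "txt") -> HeightField:
    """Read a height field written by :func:`export_heightfield`."""
    path = str(path)
    if format == "txt":
        spacing, ox, oy = 1.0, 0.0, 0.0
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                key, _, val = tok.partition("=")
                if key == "spacing_mm":
                    spacing = float(val)
                elif key == "origin_x_mm":
                    ox = float(val)
                elif key == "origin_y_mm":
                    oy = float(val)
        heights = np.loadtxt(path)
        return HeightField(heights=np.atleast_2d(heights), spacing=spacing, origin=(ox, oy))
    if format == "png":
        from PIL import Image

        with open(path + ".json") as fh:
            meta = json.load(fh)
        quant = np.asarray(Image.open(path), dtype=float)
        span = meta["zmax_mm"] - meta["zmin_mm"]
        heights = meta["zmin_mm"] + quant / 65535.0 * span
        return HeightField(
            heights=heights,
            spacing=meta["spacing_mm"],
            origin=tuple(meta["origin_mm"]),
        )
    raise ParameterError(f"unknown load format {format!r}")


def radial_psd(field: HeightField, n_bins: int = 60):
    """Radially averaged empirical periodogram of a height field.

    Returns (q_centres, psd) with q in rad/m and psd in m^4, using the
    convention in which the expected periodogram of a synthesized field
    equals phi(q).
    """
    h_m = (field.heights - field.heights.mean()) * 1e-3
    ny, nx = h_m.shape
    d_m = field.spacing * 1e-3
    per = np.abs(np.fft.fft2(h_m)) ** 2 * (d_m * d_m) / (nx * ny)
    qx = 2.0 * np.pi * np.fft.fftfreq(nx, d=d_m)
    qy = 2.0 * np.pi * np.fft.fftfreq(ny, d=d_m)
    qmag = np.hypot(qy[:, None], qx[None, :]).ravel()
    per = per.ravel()
    qmax = min(abs(qx).max(), abs(qy).max())
    edges = np.linspace(0.0, qmax, n_bins + 1)
    which = np.digitize(qmag, edges) - 1
    keep = (which >= 0) & (which < n_bins)
    sums = np.bincount(which[keep], weights=per[keep], minlength=n_bins)
    counts = np.bincount(which[keep], minlength=n_bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        return centres, sums / counts
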