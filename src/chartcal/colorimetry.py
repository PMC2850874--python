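"""Self-contained sRGB / CIE colorimetry.

Conversions among 8-bit sRGB code values, linear-light RGB, CIE XYZ and CIE
L*a*b* (D65, 2 degree observer), plus the Euclidean colour difference
dE_ab (CIE76).  All functions are vectorised over arrays whose last axis has
length 3; scalars-per-channel triples work too.

Conventions
-----------
* 8-bit sRGB code values are integers in [0, 255].
* Linear RGB is unitless linear light, nominally in [0, 1]; out-of-gamut
  values are preserved during computation and clipped only when encoding back
  to 8 bits, so that downstream least-squares fits are not biased.
* XYZ is normalised so the D65 reference white has Y = 1.
* L* is in [0, 100] for in-gamut colours.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "D65_WHITE",
    "decode_srgb",
    "encode_srgb",
    "linear_to_xyz",
    "xyz_to_linear",
    "xyz_to_lab",
    "lab_to_xyz",
    "srgb8_to_lab",
    "lab_to_srgb8",
    "lab_to_linear",
    "delta_e_ab",
]

# CIE D65 white point, 2 degree standard observer, Y normalised to 1.
D65_WHITE = np.array([0.95047, 1.0, 1.08883])

# sRGB primaries (IEC 61966-2-1) as xy chromaticities.
_PRIMARIES_XY = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])


def _rgb_xyz_matrix() -> np.ndarray:
    """Derive the linear-sRGB -> XYZ matrix from the primaries and D65 white."""
    x, y = _PRIMARIES_XY[:, 0], _PRIMARIES_XY[:, 1]
    # XYZ of each primary at unit Y, columns of the unscaled matrix
    m = np.stack([x / y, np.ones(3), (1 - x - y) / y])
    scale = np.linalg.solve(m, D65_WHITE)
    return m * scale


_M_RGB2XYZ = _rgb_xyz_matrix()
_M_XYZ2RGB = np.linalg.inv(_M_RGB2XYZ)


def _as_triples(c, name: str) -> np.ndarray:
    a = np.asarray(c, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"{name}: expected last axis of length 3, got shape {a.shape}")
    return a


def decode_srgb(c) -> np.ndarray:
    """8-bit sRGB code values -> linear RGB via the standard sRGB EOTF.

    Raises ``ValueError`` for channels outside [0, 255].
    """
    a = _as_triples(c, "decode_srgb")
    if not np.all(np.isfinite(a)) or a.min(initial=0) < 0 or a.max(initial=0) > 255:
        raise ValueError("decode_srgb: code values must be finite and in [0, 255]")
    v = a / 255.0
    lin = np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)
    return lin


def encode_srgb(c) -> np.ndarray:
    """Linear RGB -> 8-bit sRGB code values (clip to [0,1], OETF, round).

    Exact inverse of :func:`decode_srgb` on all 256 code values per channel.
    Raises ``ValueError`` on non-finite input.
    """
    a = _as_triples(c, "encode_srgb")
    if not np.all(np.isfinite(a)):
        raise ValueError("encode_srgb: non-finite input")
    v = np.clip(a, 0.0, 1.0)
    enc = np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1 / 2.4) - 0.055)
    return np.rint(enc * 255.0).astype(np.uint8)


def encode_srgb_float(c) -> np.ndarray:
    """Like :func:`encode_srgb` but returns unrounded code values (float)."""
    a = _as_triples(c, "encode_srgb")
    if not np.all(np.isfinite(a)):
        raise ValueError("encode_srgb: non-finite input")
    v = np.clip(a, 0.0, 1.0)
    return 255.0 * np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1 / 2.4) - 0.055)


def linear_to_xyz(c) -> np.ndarray:
    """Linear sRGB -> CIE XYZ (D65)."""
    a = _as_triples(c, "linear_to_xyz")
    if not np.all(np.isfinite(a)):
        raise ValueError("linear_to_xyz: non-finite input")
    return a @ _M_RGB2XYZ.T


def xyz_to_linear(c) -> np.ndarray:
    """CIE XYZ (D65) -> linear sRGB; mutual inverse of :func:`linear_to_xyz`."""
    a = _as_triples(c, "xyz_to_linear")
    if not np.all(np.isfinite(a)):
        raise ValueError("xyz_to_linear: non-finite input")
    return a @ _M_XYZ2RGB.T


_EPS = (6.0 / 29.0) ** 3
_KAPPA_D = 3.0 * (6.0 / 29.0) ** 2


def _f_lab(t: np.ndarray) -> np.ndarray:
    return np.where(t > _EPS, np.cbrt(t), t / _KAPPA_D + 4.0 / 29.0)


def _f_lab_inv(ft: np.ndarray) -> np.ndarray:
    return np.where(ft > 6.0 / 29.0, ft**3, (ft - 4.0 / 29.0) * _KAPPA_D)


def xyz_to_lab(c, white=D65_WHITE) -> np.ndarray:
    """CIE XYZ -> CIE 1976 L*a*b* relative to `white` (default D65)."""
    a = _as_triples(c, "xyz_to_lab")
    if not np.all(np.isfinite(a)):
        raise ValueError("xyz_to_lab: non-finite input")
    f = _f_lab(a / np.asarray(white, dtype=float))
    L = 116.0 * f[..., 1] - 16.0
    aa = 500.0 * (f[..., 0] - f[..., 1])
    bb = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, aa, bb], axis=-1)


def lab_to_xyz(c, white=D65_WHITE) -> np.ndarray:
    """CIE L*a*b* -> XYZ relative to `white` (default D65)."""
    a = _as_triples(c, "lab_to_xyz")
    fy = (a[..., 0] + 16.0) / 116.0
    fx = fy + a[..., 1] / 500.0
    fz = fy - a[..., 2] / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    return _f_lab_inv(f) * np.asarray(white, dtype=float)


def srgb8_to_lab(c) -> np.ndarray:
    """Convenience: 8-bit sRGB codes (ints or real-valued means) -> Lab."""
    return xyz_to_lab(linear_to_xyz(decode_srgb(c)))


def lab_to_srgb8(c) -> np.ndarray:
    """Convenience: Lab -> 8-bit sRGB (with gamut clipping at encoding)."""
    return encode_srgb(xyz_to_linear(lab_to_xyz(c)))


def lab_to_linear(c) -> np.ndarray:
    """Lab -> linear sRGB, unclipped (may leave [0,1] for out-of-gamut colours)."""
    return xyz_to_linear(lab_to_xyz(c))


def delta_e_ab(c1, c2) -> np.ndarray:
    """CIE76 colour difference: Euclidean distance in L*a*b*."""
    a1 = _as_triples(c1, "delta_e_ab")
    a2 = _as_triples(c2, "delta_e_ab")
    return np.sqrt(np.sum((a1 - a2) ** 2, axis=-1))
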