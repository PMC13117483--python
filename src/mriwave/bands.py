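"""Level-1 four-band Daubechies decomposition and the band-weighted WaveletLoss.

Each 2D slice is decomposed into the four level-1 DWT sub-bands

    AA  approximation (lowpass rows, lowpass columns)
    AD  lowpass rows, highpass columns (vertical detail)
    DA  highpass rows, lowpass columns (horizontal detail)
    DD  highpass rows and columns (diagonal detail)

using orthonormal Daubechies filters of order 1..6.  The band channel order
(AA, AD, DA, DD) is fixed everywhere, including the network channel axis.

Boundary handling defaults to periodization so a side of length N yields bands
of exactly N/2 — the dyadic halving the four-level pooling ladder of the U-Net
relies on.  Odd-sized inputs are padded to even (edge replication) before the
transform and cropped after reconstruction; the original shape is recorded in
the BandSet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

#: Band-weighted L1 default weights {w_AA, w_AD, w_DA, w_DD}.  The uneven
#: weighting pushes the correction toward the high-frequency bands where
#: periodic artifacts concentrate; the printed sum (1.1) is deliberately not
#: renormalized.
DEFAULT_BAND_WEIGHTS: dict[str, float] = {"AA": 0.1, "AD": 0.3, "DA": 0.4, "DD": 0.3}

BAND_NAMES = ("AA", "AD", "DA", "DD")

MAX_ORDER = 6


@dataclass(frozen=True)
class FilterBank:
    """Orthonormal Daubechies analysis pair of order ``L`` (2L taps each).

    The highpass is the quadrature mirror of the lowpass,
    ``h[k] = (-1)**k * l[2L-1-k]``.
    """

    order: int
    lowpass: np.ndarray
    highpass: np.ndarray

    @property
    def name(self) -> str:
        return f"db{self.order}"

    def __len__(self) -> int:
        return 2 * self.order


def daubechies_filters(order: int) -> FilterBank:
    """Return the order-``L`` Daubechies analysis filter bank.

    The lowpass coefficients are the standard Daubechies extremal-phase
    scaling coefficients (sum sqrt(2), unit energy, L vanishing moments in
    the mirror); the highpass is derived through the quadrature-mirror
    relation above, so ``sum(h) == 0`` and ``sum(k**m h[k]) == 0`` for
    ``m < L``.
    """
    if not isinstance(order, (int, np.integer)) or isinstance(order, bool):
        raise TypeError(f"order must be an integer, got {order!r}")
    if not 1 <= order <= MAX_ORDER:
        raise ValueError(f"Daubechies order must be in [1, {MAX_ORDER}], got {order}")
    lo = np.asarray(pywt.Wavelet(f"db{order}").dec_lo, dtype=float)
    L = len(lo)
    k = np.arange(L)
    hi = (-1.0) ** k * lo[L - 1 - k]
    return FilterBank(order=int(order), lowpass=lo, highpass=hi)


def _pywt_wavelet(fb: FilterBank) -> pywt.Wavelet:
    # Custom wavelet so the transform uses exactly the FilterBank taps
    # (pywt's stock dec_hi differs from the stated mirror relation by a sign).
    dec_lo, dec_hi = fb.lowpass, fb.highpass
    rec_lo, rec_hi = dec_lo[::-1], dec_hi[::-1]
    return pywt.Wavelet(fb.name, filter_bank=[dec_lo, dec_hi, rec_lo, rec_hi])


def _resolve_family(family) -> FilterBank:
    if isinstance(family, FilterBank):
        return family
    if isinstance(family, (int, np.integer)):
        return daubechies_filters(int(family))
    if isinstance(family, str):
        name = family.lower()
        if not name.startswith("db"):
            raise ValueError(f"only Daubechies families db1..db{MAX_ORDER} are supported, got {family!r}")
        return daubechies_filters(int(name[2:]))
    raise TypeError(f"cannot interpret wavelet family {family!r}")


@dataclass
class BandSet:
    """The four level-1 sub-bands of one slice plus reconstruction metadata."""

    AA: np.ndarray
    AD: np.ndarray
    DA: np.ndarray
    DD: np.ndarray
    family: str = "db2"
    source_shape: tuple = (0, 0)
    boundary_mode: str = "periodization"

    def __post_init__(self):
        shapes = {np.shape(self.AA), np.shape(self.AD), np.shape(self.DA), np.shape(self.DD)}
        if len(shapes) != 1:
            raise ValueError(f"band shapes differ: {shapes}")

    @property
    def bands(self) -> dict[str, np.ndarray]:
        return {"AA": self.AA, "AD": self.AD, "DA": self.DA, "DD": self.DD}

    def stack(self) -> np.ndarray:
        """Bands as a (4, h, w) array in the fixed (AA, AD, DA, DD) order."""
        return np.stack([self.AA, self.AD, self.DA, self.DD])

    @classmethod
    def from_stack(cls, arr: np.ndarray, family: str, source_shape, boundary_mode="periodization") -> "BandSet":
        if arr.ndim != 3 or arr.shape[0] != 4:
            raise ValueError(f"expected a (4, h, w) stack, got shape {arr.shape}")
        return cls(arr[0], arr[1], arr[2], arr[3], family=family,
                   source_shape=tuple(source_shape), boundary_mode=boundary_mode)


def dwt2_bands(slice2d: np.ndarray, family="db2", mode: str = "periodization") -> BandSet:
    """Separable level-1 2D DWT of a slice into (AA, AD, DA, DD).

    pywt's axis convention: cH carries detail along rows (our DA, highpass
    applied to the first axis after transposition bookkeeping) — mapping is
    pinned by the convention that AD is approximation along rows and detail
    along columns.
    """
    fb = _resolve_family(family)
    x = np.asarray(slice2d, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a 2D slice, got ndim={x.ndim}")
    if min(x.shape) < 2 * fb.order:
        raise ValueError(
            f"slice {x.shape} smaller than the {fb.name} filter length {2 * fb.order}"
        )
    source_shape = x.shape
    pad = [(0, s % 2) for s in x.shape]
    if any(p[1] for p in pad):
        x = np.pad(x, pad, mode="edge")
    w = _pywt_wavelet(fb)
    cA, (cH, cV, cD) = pywt.dwt2(x, w, mode=mode)
    # pywt cH = lowpass along axis 1 / highpass along axis 0 (detail across
    # rows); with AD defined as "approximation along rows, detail along
    # columns", AD = cV and DA = cH.
    return BandSet(AA=cA, AD=cV, DA=cH, DD=cD, family=fb.name,
                   source_shape=source_shape, boundary_mode=mode)


def idwt2_bands(b: BandSet) -> np.ndarray:
    """Inverse of :func:`dwt2_bands`; returns an array of ``b.source_shape``."""
    fb = _resolve_family(b.family)
    w = _pywt_wavelet(fb)
    rec = pywt.idwt2((b.AA, (b.DA, b.AD, b.DD)), w, mode=b.boundary_mode)
    sh = b.source_shape
    if sh != (0, 0):
        rec = rec[: sh[0], : sh[1]]
    return rec


def band_energies(b: BandSet) -> tuple[float, float, float, float]:
    """Mean squared coefficient per band, in (AA, AD, DA, DD) order."""
    return tuple(float(np.mean(np.square(b.bands[n]))) for n in BAND_NAMES)


def wavelet_loss(pred, truth, weights: dict[str, float] | None = None) -> float:
    """Band-weighted L1: sum_b w_b * mean(|pred_b - truth_b|).

    ``pred``/``truth`` may be BandSets or (…, 4, h, w) stacks; the mean runs
    over batch and spatial dimensions of each band independently.
    """
    if weights is None:
        weights = DEFAULT_BAND_WEIGHTS
    missing = set(BAND_NAMES) - set(weights)
    if missing:
        raise ValueError(f"missing band weights for {sorted(missing)}")
    wv = [float(weights[n]) for n in BAND_NAMES]
    if any(w < 0 for w in wv):
        raise ValueError("band weights must be non-negative")
    p = pred.stack() if isinstance(pred, BandSet) else np.asarray(pred, dtype=float)
    t = truth.stack() if isinstance(truth, BandSet) else np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"band shapes differ: {p.shape} vs {t.shape}")
    err = np.abs(p - t)
    band_axis = p.ndim - 3  # (..., 4, h, w)
    total = 0.0
    for i, w in enumerate(wv):
        total += w * float(np.mean(np.take(err, i, axis=band_axis)))
    return total
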