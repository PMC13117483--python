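"""k-space and image-domain corruption operators for periodic MRI artifacts.

Three operators with controlled severity:

* **ringing** — two point-symmetric angular sectors of a radial band in
  k-space are attenuated by a factor alpha in [0, 1]; truncation-like loss of
  directional high-frequency content reconstructs as oscillatory bands along
  high-contrast edges.
* **herringbone** — a small ks x ks kernel copied from around the k-space
  center is re-inserted, scaled by beta = S/100, at a location displaced by a
  distance d from the center; the spike reconstructs as coherent oblique
  banding across the field of view.  The conjugate-mirrored kernel is written
  at the point-symmetric location so the corrupted image stays real.
* **zipper** — amplitude-modulated uniform noise: full intensity i inside
  stripe intervals along the propagation axis, half intensity i/2 elsewhere.

All radii and displacement distances are stored as fractions of the Nyquist
radius (the reference ranges are quoted for 256-voxel grids, Nyquist radius
128), so severities transfer across grid sizes.  Parameters are sampled once
per volume so severity is coherent across slices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from mriwave.phantoms import Volume

log = logging.getLogger(__name__)

KINDS = ("ringing", "herringbone", "zipper")

#: Reference grid for the raw parameter tables (Nyquist radius in pixels).
REF_NYQUIST = 128.0

# Raw severity-parameter ranges on the 256 reference grid.
RINGING_RANGES = {
    "theta2": (0, 360),        # end angle, degrees, integer
    "theta1_offset": (10, 100),  # theta1 = theta2 - offset, integer
    "re": (118, 123),          # outer radius, pixels on the 256 grid, integer
    "ri_offset": (10, 20),     # ri = re - offset, integer
}
HERRINGBONE_RANGES = {
    "S": (3, 20),              # smoothing parameter -> beta = S/100
    "selection_point": (0, 3),  # displacement direction index
    "ks": (3, 13),             # kernel size, odd integer
    "d": (-30, 30),            # displacement, pixels on the 256 grid
}
ZIPPER_RANGES = {
    "intensity": (15, 50),     # raw-intensity noise amplitude i
    "n_artifacts": (1, 16),    # number of stripes
    "variability": (20, 40),   # spacing jitter range, pixels on the 256 grid
    "amplitude": (10, 50),     # stripe width scale a, pixels on the 256 grid
}


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact application: kind, propagation axis, parameters, seed."""

    kind: str
    axis: int
    params: dict
    seed: int

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}; expected one of {KINDS}")
        if self.axis not in (0, 1, 2):
            raise ValueError(f"axis must be 0, 1 or 2, got {self.axis}")

    def validate(self) -> None:
        """Range-check parameters against the per-kind severity tables."""
        p = self.params
        if self.kind == "ringing":
            _need(p, ["alpha", "theta1", "theta2", "ri_frac", "re_frac"])
            if not 0.0 <= p["alpha"] <= 1.0:
                raise ValueError(f"alpha must be in [0, 1], got {p['alpha']}")
            # theta1 == theta2 (empty sector) is allowed as a degenerate no-op
            if not p["theta2"] - 100 <= p["theta1"] <= p["theta2"]:
                raise ValueError("theta1 must lie in [theta2-100, theta2]")
            if p["ri_frac"] >= p["re_frac"]:
                raise ValueError("inner radius must be strictly below the outer radius")
            if p["re_frac"] > 1.0:
                raise ValueError("outer radius exceeds the Nyquist radius")
        elif self.kind == "herringbone":
            _need(p, ["S", "selection_point", "ks", "d_frac"])
            lo, hi = HERRINGBONE_RANGES["S"]
            if not lo <= p["S"] <= hi:
                raise ValueError(f"S must be in [{lo}, {hi}]")
            if p["selection_point"] not in (0, 1, 2, 3):
                raise ValueError("selection_point must be one of {0, 1, 2, 3}")
            ks = p["ks"]
            if ks % 2 != 1 or not 3 <= ks <= 13:
                raise ValueError("ks must be odd and in [3, 13]")
        elif self.kind == "zipper":
            _need(p, ["intensity", "n_artifacts", "variability_frac", "amplitude_frac"])
            lo, hi = ZIPPER_RANGES["intensity"]
            if not 0 <= p["intensity"] <= hi:
                raise ValueError(f"intensity must be in [0, {hi}]")
            lo, hi = ZIPPER_RANGES["n_artifacts"]
            if not lo <= p["n_artifacts"] <= hi:
                raise ValueError(f"n_artifacts must be in [{lo}, {hi}]")


def _need(params: dict, names) -> None:
    missing = [n for n in names if n not in params]
    if missing:
        raise ValueError(f"spec params missing {missing}")


@dataclass
class KSpace:
    """Complex 2D spectrum of a slice, DC coefficient at the array center."""

    values: np.ndarray
    dc_at_center: bool = True

    @property
    def shape(self):
        return self.values.shape


def to_kspace(slice2d: np.ndarray) -> KSpace:
    x = np.asarray(slice2d)
    if x.ndim != 2:
        raise ValueError(f"expected a 2D slice, got ndim={x.ndim}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    return KSpace(values=np.fft.fftshift(np.fft.fft2(x)), dc_at_center=True)


def from_kspace(k: KSpace) -> np.ndarray:
    vals = k.values if not k.dc_at_center else np.fft.ifftshift(k.values)
    return np.fft.ifft2(vals).real


def _mirror(a: np.ndarray) -> np.ndarray:
    """Point reflection through the DC coefficient, in centered coordinates."""
    n0, n1 = a.shape
    # centered index i holds frequency i - n//2; reflection maps frequency f
    # to -f, i.e. (in the unshifted frame) index k to (-k) mod n.
    i0 = (-(np.arange(n0) - n0 // 2)) % n0
    i1 = (-(np.arange(n1) - n1 // 2)) % n1
    # back to centered positions
    return a[np.ix_((i0 + n0 // 2) % n0, (i1 + n1 // 2) % n1)]


def _polar_grid(shape):
    n0, n1 = shape
    u = np.arange(n0) - n0 // 2
    v = np.arange(n1) - n1 // 2
    uu, vv = np.meshgrid(u, v, indexing="ij")
    r = np.hypot(uu, vv)
    theta = np.degrees(np.arctan2(vv, uu)) % 360.0
    return r, theta


def _slices_along(vox: np.ndarray, axis: int):
    return np.moveaxis(vox, axis, 0)


def ringing_alpha(ri_frac: float, re_frac: float, u: float) -> float:
    """Attenuation factor alpha = clamp(0.5*sin(pi*(1-ri/re)^0.55 - pi/2) + 0.5*u, 0, 1)."""
    val = 0.5 * np.sin(np.pi * (1.0 - ri_frac / re_frac) ** 0.55 - np.pi / 2.0) + 0.5 * u
    return float(np.clip(val, 0.0, 1.0))


def apply_ringing(v: Volume, spec: ArtifactSpec) -> Volume:
    """Attenuate two point-symmetric k-space sectors of every slice by alpha."""
    if spec.kind != "ringing":
        raise ValueError(f"spec kind {spec.kind!r} is not 'ringing'")
    spec.validate()
    p = spec.params
    alpha = float(p["alpha"])
    out = np.moveaxis(v.voxels.copy(), spec.axis, 0)
    nyq = min(out.shape[1], out.shape[2]) // 2
    ri, re = p["ri_frac"] * nyq, p["re_frac"] * nyq
    r, theta = _polar_grid(out.shape[1:])
    span = (p["theta2"] - p["theta1"]) % 360.0
    ang = (theta - (p["theta1"] % 360.0)) % 360.0
    mask = (ang <= span) & (span > 0) & (r >= ri) & (r <= re)
    mask = mask | _mirror(mask)
    mult = np.where(mask, alpha, 1.0)
    for i in range(out.shape[0]):
        ks = to_kspace(out[i])
        out[i] = from_kspace(KSpace(ks.values * mult))
    out = np.moveaxis(out, 0, spec.axis)
    return v.with_voxels(out, provenance="corrupted", extra_specs=[spec])


_DIRECTIONS = {0: (1, 0), 1: (-1, 0), 2: (0, 1), 3: (0, -1)}  # {+u, -u, +v, -v}


def apply_herringbone(v: Volume, spec: ArtifactSpec) -> Volume:
    """Insert a displaced, beta-scaled copy of the central k-space kernel."""
    if spec.kind != "herringbone":
        raise ValueError(f"spec kind {spec.kind!r} is not 'herringbone'")
    spec.validate()
    p = spec.params
    beta = float(p["S"]) / 100.0
    ks_size = int(p["ks"])
    h = ks_size // 2
    out = np.moveaxis(v.voxels.copy(), spec.axis, 0)
    n0, n1 = out.shape[1:]
    nyq = min(n0, n1) // 2
    d = p["d_frac"] * nyq
    # the spike is an off-center insertion: keep the displaced kernel clear of
    # the DC coefficient (overwriting DC models a brightness change, not a
    # herringbone pattern), so the displacement is at least the kernel radius
    step = int(round(abs(d)))
    step = max(step, h + 1)
    if d < 0:
        step = -step
    du, dv = _DIRECTIONS[int(p["selection_point"])]
    up = n0 // 2 + du * step
    vp = n1 // 2 + dv * step
    if not (h <= up < n0 - h and h <= vp < n1 - h):
        raise ValueError(
            f"displaced kernel at ({up}, {vp}) with size {ks_size} falls outside the "
            f"{n0}x{n1} grid; displacement distances are fractions of the Nyquist "
            "radius — reduce |d| or use a larger grid"
        )
    c0, c1 = n0 // 2, n1 // 2
    for i in range(out.shape[0]):
        ksp = to_kspace(out[i]).values
        kernel = beta * ksp[c0 - h: c0 + h + 1, c1 - h: c1 + h + 1]
        mod = ksp.copy()
        mod[up - h: up + h + 1, vp - h: vp + h + 1] = kernel
        # conjugate mirror at the point-symmetric block keeps the image real
        mu, mv = 2 * c0 - up, 2 * c1 - vp
        mod[mu - h: mu + h + 1, mv - h: mv + h + 1] = np.conj(kernel[::-1, ::-1])
        # exact Hermitian symmetrization: a no-op where the two blocks do not
        # overlap, and the consistent resolution where they do
        mod = 0.5 * (mod + np.conj(_mirror(mod)))
        out[i] = from_kspace(KSpace(mod))
    out = np.moveaxis(out, 0, spec.axis)
    return v.with_voxels(out, provenance="corrupted", extra_specs=[spec])


def zipper_stripes(spec: ArtifactSpec, extent: int) -> list[tuple[int, int]]:
    """Deterministic stripe intervals [start, stop) along the propagation axis."""
    p = spec.params
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x21B]))
    n = int(p["n_artifacts"])
    var_px = p["variability_frac"] * extent
    amp_px = p["amplitude_frac"] * extent
    stripes = []
    for k in range(n):
        base = (k + 0.5) * extent / n
        start = base + rng.uniform(-0.5, 0.5) * var_px
        width = amp_px * rng.uniform()  # a * U, U ~ U(0,1)
        a = int(np.floor(start))
        b = int(np.ceil(start + width))
        if a < 0 or b > extent:
            log.info("zipper stripe [%d, %d) clipped to [0, %d)", a, b, extent)
        a, b = max(a, 0), min(b, extent)
        if b > a:
            stripes.append((a, b))
    return stripes


def apply_zipper(v: Volume, spec: ArtifactSpec) -> Volume:
    """Uniform noise at intensity i inside stripes, i/2 elsewhere."""
    if spec.kind != "zipper":
        raise ValueError(f"spec kind {spec.kind!r} is not 'zipper'")
    spec.validate()
    p = spec.params
    i = float(p["intensity"])
    extent = v.voxels.shape[spec.axis]
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x21A]))
    noise = rng.uniform(-1.0, 1.0, size=v.voxels.shape)
    amp = np.full(extent, i / 2.0)
    for a, b in zipper_stripes(spec, extent):
        amp[a:b] = i
    shape = [1, 1, 1]
    shape[spec.axis] = extent
    out = v.voxels + amp.reshape(shape) * noise
    return v.with_voxels(out, provenance="corrupted", extra_specs=[spec])


_APPLY = {"ringing": apply_ringing, "herringbone": apply_herringbone, "zipper": apply_zipper}


def apply_artifact(v: Volume, spec: ArtifactSpec) -> Volume:
    return _APPLY[spec.kind](v, spec)


def sample_artifact_params(kind: str, rng_seed: int) -> ArtifactSpec:
    """Draw one ArtifactSpec with all parameters inside their table ranges.

    Integer-typed parameters are drawn as integers; radius/distance parameters
    are converted to fractions of the reference Nyquist radius (128) so they
    transfer across grid sizes.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), KINDS.index(kind)]))
    axis = int(rng.integers(0, 3))
    sub_seed = int(rng.integers(0, 2**31 - 1))
    if kind == "ringing":
        theta2 = int(rng.integers(RINGING_RANGES["theta2"][0], RINGING_RANGES["theta2"][1] + 1))
        theta1 = theta2 - int(rng.integers(RINGING_RANGES["theta1_offset"][0],
                                           RINGING_RANGES["theta1_offset"][1] + 1))
        re_px = int(rng.integers(RINGING_RANGES["re"][0], RINGING_RANGES["re"][1] + 1))
        ri_px = re_px - int(rng.integers(RINGING_RANGES["ri_offset"][0],
                                         RINGING_RANGES["ri_offset"][1] + 1))
        re_frac, ri_frac = re_px / REF_NYQUIST, ri_px / REF_NYQUIST
        alpha = ringing_alpha(ri_frac, re_frac, rng.uniform())
        params = {"alpha": alpha, "theta1": theta1, "theta2": theta2,
                  "ri_frac": ri_frac, "re_frac": re_frac}
    elif kind == "herringbone":
        d_px = int(rng.integers(HERRINGBONE_RANGES["d"][0], HERRINGBONE_RANGES["d"][1] + 1))
        params = {
            "S": int(rng.integers(HERRINGBONE_RANGES["S"][0], HERRINGBONE_RANGES["S"][1] + 1)),
            "selection_point": int(rng.integers(0, 4)),
            "ks": int(rng.choice(np.arange(3, 14, 2))),
            "d_frac": d_px / REF_NYQUIST,
        }
    else:
        params = {
            "intensity": int(rng.integers(ZIPPER_RANGES["intensity"][0],
                                          ZIPPER_RANGES["intensity"][1] + 1)),
            "n_artifacts": int(rng.integers(ZIPPER_RANGES["n_artifacts"][0],
                                            ZIPPER_RANGES["n_artifacts"][1] + 1)),
            "variability_frac": int(rng.integers(ZIPPER_RANGES["variability"][0],
                                                 ZIPPER_RANGES["variability"][1] + 1)) / 256.0,
            "amplitude_frac": int(rng.integers(ZIPPER_RANGES["amplitude"][0],
                                               ZIPPER_RANGES["amplitude"][1] + 1)) / 256.0,
        }
    spec = ArtifactSpec(kind=kind, axis=axis, params=params, seed=sub_seed)
    spec.validate()
    return spec


def compose_mixture(v: Volume, specs) -> Volume:
    """Apply corruption operators sequentially, recording application order."""
    specs = list(specs)
    if not specs:
        raise ValueError("compose_mixture needs at least one ArtifactSpec")
    out = v
    for spec in specs:
        out = apply_artifact(out, spec)
    return out


# ---------------------------------------------------------------------------
# severity stratification

#: Per-kind severity parameter used for mild/moderate/severe stratification.
#: ringing uses the attenuation depth 1 - alpha (alpha = 1 is the identity),
#: zipper the raw noise intensity, herringbone the smoothing parameter S.
def severity_parameter(spec: ArtifactSpec) -> float:
    if spec.kind == "ringing":
        return 1.0 - float(spec.params["alpha"])
    if spec.kind == "herringbone":
        return float(spec.params["S"])
    return float(spec.params["intensity"])


@dataclass(frozen=True)
class SeverityThresholds:
    """p25/p75 thresholds of the severity parameter for one artifact kind."""

    kind: str
    p25: float
    p75: float


def compute_severity_thresholds(specs) -> dict:
    """Empirical p25/p75 of the severity parameter per kind over a spec population."""
    by_kind: dict = {}
    for s in specs:
        by_kind.setdefault(s.kind, []).append(severity_parameter(s))
    return {
        kind: SeverityThresholds(kind, *np.percentile(vals, [25, 75]))
        for kind, vals in by_kind.items()
    }


def severity_label(spec: ArtifactSpec, thresholds: SeverityThresholds) -> str:
    """mild if parameter <= p25, severe if >= p75, moderate otherwise."""
    if thresholds.kind != spec.kind:
        raise ValueError(
            f"thresholds for kind {thresholds.kind!r} applied to a {spec.kind!r} spec"
        )
    val = severity_parameter(spec)
    if val <= thresholds.p25:
        return "mild"
    if val >= thresholds.p75:
        return "severe"
    return "moderate"
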