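"""Synthetic spinal-cord DWI phantom.

Generates diffusion-weighted volumes of a cord cross-section with known
ground truth, emulating a cardiac-gated cord DTI protocol: 20 diffusion
directions at b = 700 s/mm^2 plus one b = 0 volume, 1.2 x 1.2 mm in-plane
resolution, 3 mm slices, 28 contiguous slices per region assembled from 7
interleaved 4-slice series.

The cord model is an elliptical white-matter cross-section containing a
grey-matter "butterfly" (two dorsal and two ventral horn lobes joined by a
central bridge), surrounded by a CSF rim.  Partial-volume fractions are
computed by in-plane supersampling, the diffusion signal mixes the
per-tissue tensor signals by volume fraction, and noise is Rician
(magnitude of a complex Gaussian-perturbed signal).

All diffusivities are expressed in 1e-3 mm^2/s so that MD and FA are both
order one, which keeps later feature-space clustering well conditioned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .reference import GM_AREA_PERCENT, REGIONS

# integer label codes shared across the package
BACKGROUND, WM, GM, CSF, EXCLUDED = 0, 1, 2, 3, 4
TISSUE_CODES: dict[str, int] = {"WM": WM, "GM": GM, "CSF": CSF}
CODE_NAMES: dict[int, str] = {
    BACKGROUND: "background",
    WM: "WM",
    GM: "GM",
    CSF: "CSF",
    EXCLUDED: "excluded",
}


# ---------------------------------------------------------------------------
# gradient scheme
# ---------------------------------------------------------------------------

@dataclass
class GradientScheme:
    """Diffusion directions and b-values for one acquisition.

    ``bvalues`` in s/mm^2; ``directions`` are unit vectors for b > 0 entries
    and zero vectors for b = 0 entries.
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        if len(self.bvalues) != len(self.directions):
            raise ValueError("bvalues and directions lengths differ")
        if np.any(self.bvalues < 0):
            raise ValueError("negative b-value")
        norms = np.linalg.norm(self.directions[self.bvalues > 0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("diffusion directions must be unit vectors")

    @property
    def n_volumes(self) -> int:
        return len(self.bvalues)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    def rotated(self, rotation: np.ndarray) -> "GradientScheme":
        """Scheme with every direction rotated by the 3x3 matrix ``rotation``."""
        return GradientScheme(self.bvalues.copy(), self.directions @ np.asarray(rotation).T)


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic, approximately uniform point set on the upper hemisphere."""
    i = np.arange(n)
    z = (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    r = np.sqrt(1.0 - z**2)
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def tensor_design_columns(directions: np.ndarray) -> np.ndarray:
    """Six quadratic direction products g g^T (xx, yy, zz, 2xy, 2xz, 2yz)."""
    g = np.asarray(directions, dtype=float)
    return np.stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )


def make_gradient_scheme(n_directions: int = 20, b: float = 700.0) -> GradientScheme:
    """Build a scheme of ``n_directions`` unit vectors at ``b`` plus one b = 0.

    The direction set is a fixed Fibonacci-lattice hemisphere sampling, which
    is deterministic and close to uniform; at least six non-collinear
    directions are required to determine the six unique tensor elements.
    """
    if n_directions < 6:
        raise ValueError("tensor underdetermined: need at least 6 directions")
    if b <= 0:
        raise ValueError("b must be positive")
    dirs = _fibonacci_hemisphere(n_directions)
    if np.linalg.matrix_rank(tensor_design_columns(dirs)) < 6:
        raise ValueError("tensor underdetermined: direction set rank-deficient")
    bvalues = np.concatenate([[0.0], np.full(n_directions, float(b))])
    directions = np.vstack([np.zeros(3), dirs])
    return GradientScheme(bvalues, directions)


# ---------------------------------------------------------------------------
# interleaved slice plan
# ---------------------------------------------------------------------------

@dataclass
class SliceInterleavePlan:
    """Slice-center positions produced by interleaved multi-series acquisition.

    Positions are on a 1-D axis in mm with 0 at the first slice of series 1.
    """

    series: int
    per_series: int
    thickness: float
    gap: float
    shift: float
    positions: np.ndarray = field(init=False)
    contiguous: bool = field(init=False)

    def __post_init__(self) -> None:
        if min(self.series, self.per_series) < 1 or min(self.thickness, self.gap, self.shift) <= 0:
            raise ValueError("all slice-plan parameters must be positive")
        step = self.thickness + self.gap  # center-to-center within a series
        pos = np.array(
            [s * self.shift + j * step for s in range(self.series) for j in range(self.per_series)]
        )
        self.positions = np.unique(np.round(pos, 9))
        diffs = np.diff(self.positions)
        self.contiguous = bool(diffs.size == 0 or np.allclose(diffs, self.thickness))

    @property
    def n_slices(self) -> int:
        """Number of distinct slice positions."""
        return len(self.positions)

    @property
    def coverage_mm(self) -> float:
        """Total tissue thickness covered by the distinct slices."""
        return self.n_slices * self.thickness


def plan_slices(
    series: int = 7,
    per_series: int = 4,
    thickness: float = 3.0,
    gap: float = 18.0,
    shift: float = 3.0,
) -> SliceInterleavePlan:
    """Plan an interleaved acquisition; defaults give 28 contiguous 3 mm slices."""
    return SliceInterleavePlan(series, per_series, thickness, gap, shift)


# ---------------------------------------------------------------------------
# tissue models
# ---------------------------------------------------------------------------

@dataclass
class TissueModel:
    """Single-tissue diffusion tensor model.

    ``eigenvalues`` are descending, in 1e-3 mm^2/s; ``principal_axis`` is the
    direction of the largest eigenvalue (the cord's long axis for WM/GM).
    """

    name: str
    eigenvalues: tuple[float, float, float]
    principal_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    #: unweighted (b = 0) signal relative to white matter.  The spin-echo EPI
    #: readout has a long echo time, so the b = 0 image is heavily
    #: T2-weighted: CSF (T2 ~ 2 s) is several times brighter than cord
    #: tissue (T2 ~ 70 ms).
    s0_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.s0_weight <= 0:
            raise ValueError("s0_weight must be positive")
        lam = np.asarray(self.eigenvalues, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("tissue eigenvalues must be strictly positive")
        if np.any(np.diff(lam) > 0):
            raise ValueError("eigenvalues must be in descending order")
        axis = np.asarray(self.principal_axis, dtype=float)
        self.principal_axis = tuple(axis / np.linalg.norm(axis))

    @property
    def md(self) -> float:
        return float(np.mean(self.eigenvalues))

    @property
    def fa(self) -> float:
        lam = np.asarray(self.eigenvalues)
        lhat = lam.mean()
        return float(np.sqrt(1.5 * np.sum((lam - lhat) ** 2) / np.sum(lam**2)))

    @property
    def tensor(self) -> np.ndarray:
        """3x3 tensor with the principal eigenvector along ``principal_axis``."""
        e1 = np.asarray(self.principal_axis, dtype=float)
        helper = np.array([1.0, 0.0, 0.0]) if abs(e1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e2 = helper - e1 * (helper @ e1)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        basis = np.stack([e1, e2, e3], axis=1)
        return basis @ np.diag(self.eigenvalues) @ basis.T

    @classmethod
    def from_md_fa(
        cls,
        name: str,
        md: float,
        fa: float,
        principal_axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
        s0_weight: float = 1.0,
    ) -> "TissueModel":
        """Axially symmetric tensor (lambda2 = lambda3) with given MD and FA.

        For lambda1 >= lambda2 = lambda3 and d = lambda1 - lambda2,
        FA = d / sqrt(lambda1^2 + 2 lambda2^2), which inverts to
        d = FA * MD * sqrt(3) / sqrt(1 - 2 FA^2 / 3).
        """
        if not 0 <= fa < math.sqrt(1.5):
            raise ValueError("FA out of range for a positive-definite tensor")
        d = fa * md * math.sqrt(3.0) / math.sqrt(1.0 - 2.0 * fa**2 / 3.0)
        lam1 = md + 2.0 * d / 3.0
        lam23 = md - d / 3.0
        return cls(name, (lam1, lam23, lam23), principal_axis, s0_weight)


def default_tissue_models() -> dict[str, TissueModel]:
    """WM / GM / CSF tensors targeting healthy-cord cluster-centroid values.

    The relative b = 0 signals combine proton density (WM ~ 0.65, GM ~ 0.8,
    CSF ~ 1.0) with the T2 weighting of a long-echo-time spin-echo EPI
    readout (TE on the order of 100 ms; cord tissue T2 ~ 70-75 ms, CSF
    ~ 2 s): grey matter is about 1.35x brighter than white matter and CSF
    about 6x brighter.
    """
    return {
        "WM": TissueModel.from_md_fa("WM", md=0.97, fa=0.70, s0_weight=1.0),
        "GM": TissueModel.from_md_fa("GM", md=1.80, fa=0.44, s0_weight=1.35),
        "CSF": TissueModel.from_md_fa("CSF", md=3.00, fa=0.05, s0_weight=6.0),
    }


# ---------------------------------------------------------------------------
# cord phantom geometry
# ---------------------------------------------------------------------------

#: Cord ellipse semi-axes (transverse, antero-posterior) in mm, per region.
REGION_SEMI_AXES: dict[str, tuple[float, float]] = {
    "cervical": (6.0, 4.2),
    "thoracic": (4.8, 4.0),
    "lumbar": (5.5, 4.5),
}

# Width of the CSF margin around the cord included in the ROI.  A manually
# drawn whole-cord ROI hugs the cord boundary, so only a thin rim of CSF
# (about one voxel) enters the analysis — which is why the CSF cluster is
# the smallest of the three.
CSF_RIM_MM = 1.2

# grey-matter butterfly ("H") in cord-normalized coordinates (unit disk).
# The H's skeleton is fixed — four horn lobes joined by a central
# commissural bridge, tips staying a white-column's width inside the cord
# surface — because in the real cord the grey matter spans most of the
# cross-section at every level; the regional area fraction is realized by
# varying the arm THICKNESS.  The ventral lobes are thicker than the dorsal
# ones (bulky motor-neuron pools versus slender dorsal horns).
_HORN_CENTER = (0.33, 0.32)     # |u|, |v| of each horn-lobe center
_HORN_HEIGHT = 0.30             # lobe semi-axis along v (fixed reach)
_VENTRAL_BULK = 1.7             # ventral / dorsal horn thickness ratio
_BRIDGE_HALFWIDTH = 0.45        # bridge semi-axis along u
_MAX_THICKNESS = 0.25           # upper bound of the dorsal horn semi-width


def _butterfly(u: np.ndarray, v: np.ndarray, thickness: float) -> np.ndarray:
    """Boolean grey-matter mask in cord-normalized coordinates."""
    inside = (u / _BRIDGE_HALFWIDTH) ** 2 + (v / (0.6 * thickness)) ** 2 <= 1.0
    cx, cy = _HORN_CENTER
    for su in (-1.0, 1.0):
        for sv, w in ((1.0, thickness), (-1.0, _VENTRAL_BULK * thickness)):
            inside = inside | (
                ((u - su * cx) / w) ** 2 + ((v - sv * cy) / _HORN_HEIGHT) ** 2 <= 1.0
            )
    return inside


def _gm_fraction_of_thickness(thickness: float, n: int = 401) -> float:
    """Grey-matter area fraction of the unit-disk cord at a horn thickness."""
    u = np.linspace(-1.0, 1.0, n)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    cord = uu**2 + vv**2 <= 1.0
    gm = _butterfly(uu, vv, thickness) & cord
    return gm.sum() / cord.sum()


@lru_cache(maxsize=64)
def _solve_butterfly_thickness(target_fraction: float) -> float:
    """Bisection for the horn thickness realizing a GM area fraction."""
    lo, hi = 1e-3, _MAX_THICKNESS
    if _gm_fraction_of_thickness(hi) < target_fraction:
        raise ValueError(f"GM fraction {target_fraction:.3f} exceeds butterfly capacity")
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _gm_fraction_of_thickness(mid) < target_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class CordPhantom:
    """Ground-truth tissue-fraction field and geometry for one cord region.

    ``fractions`` has shape (nx, ny, nslices, 3) in (WM, GM, CSF) order and
    sums to one inside the spinal canal (cord + CSF rim), zero outside.
    ``labels`` is the argmax tissue code per voxel (0 = background).
    """

    region: str
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    fractions: np.ndarray
    labels: np.ndarray
    canal_mask: np.ndarray
    tissues: dict[str, TissueModel]
    gm_area_fraction_target: float
    gm_area_fraction: float
    seed: int

    @property
    def roi_mask(self) -> np.ndarray:
        """Whole-canal ROI, the simulated analogue of a manually drawn cord ROI."""
        return self.canal_mask

    def pure_voxel_mask(self, tissue: str) -> np.ndarray:
        """Voxels containing only the named tissue (fraction exactly 1)."""
        idx = {"WM": 0, "GM": 1, "CSF": 2}[tissue]
        return self.fractions[..., idx] == 1.0

    def rotated_tissues(self, rotation: np.ndarray) -> "CordPhantom":
        """Copy of the phantom with every tissue tensor rotated."""
        rot = np.asarray(rotation, dtype=float)
        tissues = {
            name: TissueModel(
                name, t.eigenvalues, tuple(rot @ np.asarray(t.principal_axis)), t.s0_weight
            )
            for name, t in self.tissues.items()
        }
        return CordPhantom(
            self.region, self.shape, self.voxel_size, self.fractions, self.labels,
            self.canal_mask, tissues, self.gm_area_fraction_target,
            self.gm_area_fraction, self.seed,
        )


def build_phantom(
    region: str,
    shape: tuple[int, int, int] = (64, 64, 28),
    gm_fraction: float | None = None,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.2, 1.2, 3.0),
    tissues: dict[str, TissueModel] | None = None,
    supersample: int = 4,
    jitter: float = 0.02,
) -> CordPhantom:
    """Build the ground-truth cord phantom for one region.

    Parameters
    ----------
    region:
        "cervical", "thoracic" or "lumbar"; sets cord ellipse size and the
        default grey-matter area fraction (18 / 13.2 / 36.3 percent).
    gm_fraction:
        Target grey-matter fraction of the cord cross-section, in percent.
    seed:
        Seeds a smooth per-slice modulation (+/- ``jitter``) of the cord
        caliber, mimicking anatomical variation along the cord. The
        modulation rescales cord and grey matter together, so the GM area
        fraction is preserved.
    supersample:
        In-plane subsamples per voxel edge used to compute partial-volume
        fractions at tissue boundaries.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    if gm_fraction is None:
        gm_fraction = GM_AREA_PERCENT[region]
    if not 0 < gm_fraction < 100:
        raise ValueError("gm_fraction must be in (0, 100) percent")
    nx, ny, nz = shape
    dx, dy, dz = voxel_size
    a, b = REGION_SEMI_AXES[region]
    if 2 * max(a, b) / max(dx, dy) < 8:
        raise ValueError("cord diameter must span at least 8 voxels")
    margin = 1.0 + jitter
    if (a + CSF_RIM_MM) * margin * 2 > nx * dx or (b + CSF_RIM_MM) * margin * 2 > ny * dy:
        raise ValueError("cord does not fit in grid")

    tissues = dict(tissues) if tissues is not None else default_tissue_models()
    thickness = _solve_butterfly_thickness(gm_fraction / 100.0)

    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(nz)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(np.pad(raw, 2, mode="edge"), kernel, mode="valid")
    sd = smooth.std()
    caliber = 1.0 + jitter * (smooth / sd if sd > 0 else smooth)

    ss = supersample
    # subvoxel sample coordinates (mm), voxel centers at (i - (n-1)/2) * d
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    x = ((np.arange(nx) - (nx - 1) / 2.0)[:, None] + sub[None, :]).ravel() * dx
    y = ((np.arange(ny) - (ny - 1) / 2.0)[:, None] + sub[None, :]).ravel() * dy
    xx = x[:, None]
    yy = y[None, :]

    def voxel_mean(mask: np.ndarray) -> np.ndarray:
        return mask.reshape(nx, ss, ny, ss).mean(axis=(1, 3))

    fractions = np.zeros((nx, ny, nz, 3))
    for k in range(nz):
        c = caliber[k]
        cord = (xx / (a * c)) ** 2 + (yy / (b * c)) ** 2 <= 1.0
        canal = (xx / ((a + CSF_RIM_MM) * c)) ** 2 + (yy / ((b + CSF_RIM_MM) * c)) ** 2 <= 1.0
        gm = _butterfly(xx / (a * c), yy / (b * c), thickness) & cord
        f_gm = voxel_mean(gm)
        f_cord = voxel_mean(cord)
        f_canal = voxel_mean(canal)
        fractions[:, :, k, 0] = f_cord - f_gm
        fractions[:, :, k, 1] = f_gm
        fractions[:, :, k, 2] = f_canal - f_cord

    canal_frac = fractions.sum(axis=-1)
    canal_mask = canal_frac >= 0.5
    # renormalize interior voxels to a partition of unity; zero out the rest
    fractions = np.where(
        canal_mask[..., None], fractions / np.maximum(canal_frac, 1e-12)[..., None], 0.0
    )

    labels = np.zeros(shape, dtype=np.uint8)
    labels[canal_mask] = np.argmax(fractions[canal_mask], axis=-1) + 1  # WM=1, GM=2, CSF=3

    wm_area = fractions[..., 0].sum()
    gm_area = fractions[..., 1].sum()
    realized = 100.0 * gm_area / (gm_area + wm_area)
    if abs(realized - gm_fraction) > 2.0:
        warnings.warn(
            f"realized GM area fraction {realized:.1f}% deviates from "
            f"target {gm_fraction:.1f}% by more than 2 points",
            stacklevel=2,
        )

    return CordPhantom(
        region=region,
        shape=shape,
        voxel_size=voxel_size,
        fractions=fractions,
        labels=labels,
        canal_mask=canal_mask,
        tissues=tissues,
        gm_area_fraction_target=float(gm_fraction),
        gm_area_fraction=float(realized),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------

@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal array with its gradient scheme.

    ``data`` has shape (nx, ny, nslices, n_volumes), arbitrary units.
    """

    data: np.ndarray
    scheme: GradientScheme
    voxel_size: tuple[float, float, float]
    s0: float
    snr: float
    seed: int | None = None
    phantom: CordPhantom | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4-D (x, y, slice, volume)")
        if self.data.shape[3] != self.scheme.n_volumes:
            raise ValueError("number of volumes does not match gradient scheme")
        if np.any(self.data < 0):
            raise ValueError("signals must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def b0(self) -> np.ndarray:
        """Mean unweighted (b = 0) image."""
        return self.data[..., self.scheme.b0_mask].mean(axis=-1)


def tissue_attenuations(tissues: dict[str, TissueModel], scheme: GradientScheme) -> np.ndarray:
    """Per-tissue, per-volume signal attenuation exp(-b g^T D g).

    Rows in (WM, GM, CSF) order; b is converted so that diffusivities in
    1e-3 mm^2/s contract with b in s/mm^2 to a dimensionless exponent.
    Each tissue's row is scaled by its relative b = 0 signal (T2 weighting).
    """
    q = scheme.bvalues * 1e-3
    g = scheme.directions
    att = np.empty((3, scheme.n_volumes))
    for t, name in enumerate(("WM", "GM", "CSF")):
        tissue = tissues[name]
        D = tissue.tensor
        att[t] = tissue.s0_weight * np.exp(-q * np.einsum("ij,jk,ik->i", g, D, g))
    return att


def simulate_dwi(
    phantom: CordPhantom,
    scheme: GradientScheme,
    snr: float = 20.0,
    seed: int = 0,
    s0: float = 1000.0,
) -> DWIVolume:
    """Simulate the DWI series for a phantom.

    The noise-free signal in a voxel mixes each tissue's monoexponential
    tensor signal by its volume fraction:
    S_i = S0 * sum_t f_t * w_t * exp(-b_i g_i^T D_t g_i), where w_t is the
    tissue's relative b = 0 signal (T2 weighting; w_WM = 1).  Noise is
    Rician with channel sigma = S0 / snr (SNR referenced to the b = 0
    white-matter signal, which equals S0); pass ``snr=np.inf`` for
    noise-free data.
    """
    if not snr > 0:
        raise ValueError("snr must be positive (np.inf for noise-free)")
    att = tissue_attenuations(phantom.tissues, scheme)
    signal = s0 * np.einsum("xyzt,tv->xyzv", phantom.fractions, att)
    if np.isfinite(snr):
        sigma = s0 / snr
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((2,) + signal.shape) * sigma
        signal = np.hypot(signal + noise[0], noise[1])
    return DWIVolume(
        data=signal,
        scheme=scheme,
        voxel_size=phantom.voxel_size,
        s0=s0,
        snr=float(snr),
        seed=seed,
        phantom=phantom,
    )
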