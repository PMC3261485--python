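"""Per-voxel diffusion tensor estimation and FA/MD scalar maps.

The tensor is estimated by linear least squares on log-signals: for each
voxel, ln S_i = ln S0 - b_i g_i^T D g_i is linear in the six unique tensor
elements and ln S0, which is estimated jointly as a seventh unknown rather
than fixed to the measured b = 0 signal.  Eigenvalues are obtained from the
symmetric 3x3 tensor, and

    MD = (lambda1 + lambda2 + lambda3) / 3
    FA = sqrt( 3/2 * sum_i (lambda_i - MD)^2 / sum_i lambda_i^2 )

Diffusivities are carried in 1e-3 mm^2/s throughout, so MD and FA are both
order one.  Voxels whose fit is degenerate (nonpositive signals clamped,
nonpositive eigenvalues, non-finite estimates) are flagged and excluded
from the scalar maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DWIVolume, GradientScheme, tensor_design_columns

# tensor element order: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
_TENSOR_IDX = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


@dataclass
class DiffusionTensorField:
    """Fitted symmetric tensors for the voxels of an ROI.

    ``tensors`` holds the six unique elements (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    per voxel in 1e-3 mm^2/s; ``coords`` the integer voxel indices; ``flags``
    marks degenerate fits (clamped signals or nonpositive eigenvalues).
    """

    coords: np.ndarray          # (n, 3) int
    tensors: np.ndarray         # (n, 6)
    s0: np.ndarray              # (n,) estimated S0
    flags: np.ndarray           # (n,) bool
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.tensors)

    def matrices(self) -> np.ndarray:
        """Full (n, 3, 3) symmetric tensor array."""
        out = np.zeros((len(self), 3, 3))
        for col, (i, j) in enumerate(_TENSOR_IDX):
            out[:, i, j] = self.tensors[:, col]
            out[:, j, i] = self.tensors[:, col]
        return out


@dataclass
class EigenSpectrum:
    """Sorted eigenvalues per voxel, descending (lambda1 >= lambda2 >= lambda3)."""

    lambdas: np.ndarray  # (n, 3)

    @property
    def mean(self) -> np.ndarray:
        return self.lambdas.mean(axis=-1)


@dataclass
class ScalarMaps:
    """Per-voxel FA and MD within the cord ROI, with voxel coordinates.

    Only unflagged voxels are included, so FA is in [0, 1] and MD >= 0.
    """

    coords: np.ndarray  # (n, 3) int
    fa: np.ndarray      # (n,)
    md: np.ndarray      # (n,) 1e-3 mm^2/s
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.fa)

    def volume(self, which: str = "fa", fill: float = 0.0) -> np.ndarray:
        """Scatter FA or MD values back onto the image grid."""
        vals = {"fa": self.fa, "md": self.md}[which]
        out = np.full(self.shape, fill)
        out[tuple(self.coords.T)] = vals
        return out


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(n_volumes, 7) matrix mapping (D elements, ln S0) to log-signals."""
    bq = scheme.bvalues[:, None] * 1e-3  # contract with D in 1e-3 mm^2/s
    return np.concatenate(
        [-bq * tensor_design_columns(scheme.directions), np.ones((scheme.n_volumes, 1))],
        axis=1,
    )


def _check_scheme(scheme: GradientScheme) -> None:
    dwi = scheme.bvalues > 0
    if dwi.sum() < 6 or not scheme.b0_mask.any():
        raise ValueError("insufficient directions: need >= 6 weighted volumes and a b = 0")
    if np.linalg.matrix_rank(tensor_design_columns(scheme.directions[dwi])) < 6:
        raise ValueError("insufficient directions: design matrix rank-deficient")


def fit_tensor_field(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    weighted: bool = False,
) -> DiffusionTensorField:
    """Fit a diffusion tensor in every masked voxel.

    ``mask`` defaults to the phantom's cord ROI when the volume carries one.
    With ``weighted=True`` a weighted least-squares fit is used (weights equal
    to the squared observed signals, the usual first-order variance
    approximation for log-transformed magnitude data); the default is
    ordinary least squares.

    Nonpositive signals cannot be log-transformed; they are clamped to half
    the smallest positive masked signal and the voxel is flagged.
    """
    _check_scheme(dwi.scheme)
    if mask is None:
        if dwi.phantom is None:
            raise ValueError("mask required when the volume has no attached phantom")
        mask = dwi.phantom.roi_mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape:
        raise ValueError("mask geometry does not match DWI volume")
    coords = np.argwhere(mask)
    if len(coords) == 0:
        raise ValueError("empty mask")

    signals = dwi.data[mask].astype(float)  # (n, nvol)
    nonpos = signals <= 0
    flags = nonpos.any(axis=1)
    if nonpos.any():
        positive = signals[~nonpos]
        floor = 0.5 * positive.min() if positive.size else 1.0
        signals = np.where(nonpos, floor, signals)

    A = design_matrix(dwi.scheme)
    log_s = np.log(signals)
    if weighted:
        w = signals**2  # (n, nvol)
        ata = np.einsum("nv,vi,vj->nij", w, A, A)
        atb = np.einsum("nv,vi,nv->ni", w, A, log_s)
        coef = np.linalg.solve(ata, atb[..., None])[..., 0]
    else:
        coef = np.linalg.lstsq(A, log_s.T, rcond=None)[0].T  # (n, 7)

    tensors = coef[:, :6]
    s0 = np.exp(coef[:, 6])
    bad = ~np.isfinite(tensors).all(axis=1)
    tensors = np.where(bad[:, None], 0.0, tensors)
    flags = flags | bad
    return DiffusionTensorField(
        coords=coords,
        tensors=tensors,
        s0=s0,
        flags=flags,
        shape=dwi.shape,
        voxel_size=dwi.voxel_size,
    )


def eigendecompose(field: DiffusionTensorField) -> EigenSpectrum:
    """Eigenvalues of each voxel tensor, sorted descending.

    Voxels with any nonpositive eigenvalue are flagged in ``field`` (the
    eigenvalues themselves are kept, so MD remains unbiased if the caller
    wants it); non-finite tensors were zeroed and flagged during fitting.
    """
    lam = np.linalg.eigvalsh(field.matrices())[:, ::-1]
    field.flags |= (lam <= 0).any(axis=1)
    return EigenSpectrum(lambdas=lam)


def compute_md(lambdas: np.ndarray) -> np.ndarray:
    """Mean diffusivity: the eigenvalue mean, per voxel."""
    return np.asarray(lambdas, dtype=float).mean(axis=-1)


def compute_fa(lambdas: np.ndarray, clip_clamped: bool = True) -> np.ndarray:
    """Fractional anisotropy from sorted (or unsorted) eigenvalues.

    FA is computed on the raw eigenvalues; when negative eigenvalues are
    present (noise-clamped fits) the value can exceed 1 and is clipped to
    [0, 1] if ``clip_clamped``.  An all-zero spectrum has undefined FA and
    yields NaN.
    """
    lam = np.asarray(lambdas, dtype=float)
    lhat = lam.mean(axis=-1, keepdims=True)
    num = ((lam - lhat) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * np.where(den > 0, num / den, np.nan))
    if clip_clamped:
        clamped = (lam < 0).any(axis=-1)
        fa = np.where(clamped, np.clip(fa, 0.0, 1.0), fa)
    return fa


def make_scalar_maps(
    field: DiffusionTensorField,
    spectrum: EigenSpectrum | None = None,
) -> ScalarMaps:
    """FA and MD for every unflagged voxel of a fitted field."""
    if spectrum is None:
        spectrum = eigendecompose(field)
    keep = ~field.flags
    if not keep.any():
        raise ValueError("no valid voxels after flagging")
    lam = spectrum.lambdas[keep]
    return ScalarMaps(
        coords=field.coords[keep],
        fa=compute_fa(lam),
        md=compute_md(lam),
        shape=field.shape,
        voxel_size=field.voxel_size,
    )


def fit_scalar_maps(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    weighted: bool = False,
) -> ScalarMaps:
    """Convenience chain: fit tensors, eigendecompose, build scalar maps."""
    field = fit_tensor_field(dwi, mask=mask, weighted=weighted)
    return make_scalar_maps(field)
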