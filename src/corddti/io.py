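"""File I/O: NIfTI volumes, FSL-dialect gradient tables, provenance sidecars.

Conventions: 0-based voxel indices with a voxel-center coordinate
convention; the NIfTI affine is diagonal with the voxel sizes (RAS).
bvecs files hold one row per axis (3 rows x N columns); bvals one row of N
values.  Every written result carries a JSON sidecar with the configuration
hash and seeds, so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DWIVolume, GradientScheme

__version__ = "0.1.0"


def affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_nifti(data: np.ndarray, voxel_size, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine_from_voxel_size(voxel_size))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj, dtype=np.float32), tuple(float(z) for z in zooms)


def write_gradients(scheme: GradientScheme, bvals_path, bvecs_path) -> None:
    """Write FSL-dialect bvals (1 x N) and bvecs (3 x N) text files."""
    np.savetxt(bvals_path, scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(bvecs_path, scheme.directions.T, fmt="%.10f")


def _parse_rows(path, expected_rows: int) -> list[list[float]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            vals = []
            for tok in line.split():
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {tok!r} on line {lineno}"
                    ) from None
            rows.append(vals)
    if len(rows) != expected_rows:
        raise ValueError(f"{path}: expected {expected_rows} row(s), found {len(rows)}")
    return rows


def read_gradients(bvals_path, bvecs_path) -> GradientScheme:
    """Read FSL bvals/bvecs into a validated GradientScheme.

    Near-unit direction vectors are normalized; norms deviating from 1 by
    more than 1e-2 (for b > 0) are rejected, as are zero directions with
    nonzero b.
    """
    bvals = np.array(_parse_rows(bvals_path, 1)[0])
    bvec_rows = _parse_rows(bvecs_path, 3)
    if len({len(r) for r in bvec_rows}) != 1:
        raise ValueError(f"{bvecs_path}: rows have unequal lengths")
    bvecs = np.array(bvec_rows).T  # (N, 3)
    if len(bvals) != len(bvecs):
        raise ValueError(
            f"gradient table length mismatch: {len(bvals)} b-values vs {len(bvecs)} directions"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals > 0
    if np.any(weighted & (norms == 0)):
        raise ValueError("zero direction with nonzero b")
    if np.any(np.abs(norms[weighted] - 1.0) > 1e-2):
        raise ValueError("direction norms deviate from unit by more than 1e-2")
    dirs = bvecs.copy()
    dirs[weighted] /= norms[weighted, None]
    dirs[~weighted] = 0.0
    return GradientScheme(bvals, dirs)


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping or dataclass."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sidecar(path, payload: dict) -> None:
    """JSON sidecar with provenance metadata (stage version included)."""
    payload = dict(payload)
    payload.setdefault("corddti_version", __version__)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_dwi_dataset(dwi: DWIVolume, out_dir, stem: str = "dwi", extra_meta: dict | None = None) -> dict:
    """Write a simulated dataset: 4-D DWI, gradients, ground truth, sidecar.

    Returns the mapping of artifact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwi": out / f"{stem}.nii.gz",
        "bvals": out / f"{stem}.bval",
        "bvecs": out / f"{stem}.bvec",
        "sidecar": out / f"{stem}.json",
    }
    save_nifti(dwi.data, dwi.voxel_size, paths["dwi"])
    write_gradients(dwi.scheme, paths["bvals"], paths["bvecs"])
    meta = {
        "s0": dwi.s0,
        "snr": dwi.snr,
        "seed": dwi.seed,
        "voxel_size_mm": list(dwi.voxel_size),
        "shape": list(dwi.data.shape),
    }
    if dwi.phantom is not None:
        ph = dwi.phantom
        paths["labels"] = out / f"{stem}_truth_labels.nii.gz"
        paths["fractions"] = out / f"{stem}_truth_fractions.nii.gz"
        paths["mask"] = out / f"{stem}_mask.nii.gz"
        save_nifti(ph.labels, ph.voxel_size, paths["labels"])
        save_nifti(ph.fractions, ph.voxel_size, paths["fractions"])
        save_nifti(ph.canal_mask.astype(np.float32), ph.voxel_size, paths["mask"])
        meta.update(
            {
                "region": ph.region,
                "gm_area_fraction_target_pct": ph.gm_area_fraction_target,
                "gm_area_fraction_realized_pct": ph.gm_area_fraction,
                "phantom_seed": ph.seed,
                "tissues": {
                    name: {"eigenvalues": list(t.eigenvalues), "md": t.md, "fa": t.fa}
                    for name, t in ph.tissues.items()
                },
            }
        )
    if extra_meta:
        meta.update(extra_meta)
    meta["config_hash"] = config_hash(meta)
    write_sidecar(paths["sidecar"], meta)
    return {k: str(v) for k, v in paths.items()}
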