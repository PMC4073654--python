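"""Voxelwise execution engine and NIfTI input/output.

The estimator core is voxel-separable: the bread, hat diagonals and the
degrees-of-freedom machinery depend only on the design, so they are computed
once; per-voxel work (residual cross-products, contrast variance, nu, p) runs
over batches of masked voxels to bound memory.  Batching never changes the
result.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from . import sandwich
from .design import LongitudinalDesign, fit_ols, hat_diagonals
from .inference import DofEstimate, SatterthwaiteDof, naive_dof, wald_test

logger = logging.getLogger("longswe")

__all__ = ["VoxelBatch", "read_images", "write_map", "run_voxelwise"]


@dataclass
class VoxelBatch:
    data: np.ndarray           # (n, V_batch)
    indices: np.ndarray        # columns into the full in-mask voxel array
    shape: tuple
    affine: np.ndarray


def read_images(paths, mask_path):
    """Load a 4D NIfTI (or list of 3D) plus a mask into an (n, V) matrix.

    Scan order is the order of ``paths`` (or the 4th axis); callers are
    responsible for matching it to the design-table row order explicitly —
    never rely on filesystem ordering.
    """
    mask_img = nib.load(str(mask_path))
    mask = np.asanyarray(mask_img.dataobj) > 0
    if not mask.any():
        raise ValueError("empty mask")
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        img = nib.load(str(paths))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 4:
            raise ValueError("single image input must be 4D")
        _check_geometry(img, mask_img)
        Y = data[mask].T                     # (n, V)
    else:
        vols = []
        for p in paths:
            img = nib.load(str(p))
            _check_geometry(img, mask_img)
            vols.append(np.asanyarray(img.dataobj)[mask])
        Y = np.stack(vols)
    return np.asarray(Y, dtype=np.float64), mask, mask_img.affine


def _check_geometry(img, mask_img, tol=1e-4):
    if img.shape[:3] != mask_img.shape[:3]:
        raise ValueError(f"image shape {img.shape[:3]} does not match mask "
                         f"{mask_img.shape[:3]}")
    if not np.allclose(img.affine, mask_img.affine, atol=tol):
        raise ValueError("image affine does not match mask affine")


def write_map(values, mask, affine, path, dtype=np.float64):
    """Write an in-mask voxel vector back into a 3D NIfTI volume."""
    vol = np.zeros(mask.shape, dtype=dtype)
    vol[mask] = np.asarray(values, dtype=dtype)
    nib.save(nib.Nifti1Image(vol, affine), str(path))


# ----------------------------------------------------------------------
def run_voxelwise(design: LongitudinalDesign, Y, contrasts: dict,
                  variant: str = "hom", adjustment: str = "S3",
                  dof_method: str = "satterthwaite", batch_size: int = 4096,
                  max_failure_fraction: float = 0.01):
    """Fit the sandwich model at every voxel, batched.

    Parameters
    ----------
    Y : (n, V) response matrix (in-mask voxels).
    contrasts : dict name -> (q, p) array.

    Returns
    -------
    dict name -> dict with keys ``stat`` (F), ``t`` (q=1 only), ``p``, ``nu``
    and ``beta`` ((p, V)); per-voxel failures are NaN.  More than
    ``max_failure_fraction`` failing voxels aborts with diagnostics.
    """
    Y = np.asarray(Y, dtype=np.float64)
    n, V = Y.shape
    if n != design.n:
        raise ValueError(f"{n} scans but design has {design.n} rows")
    h = hat_diagonals(design)
    sdofs = {name: SatterthwaiteDof(design, C)
             for name, C in contrasts.items()} if dof_method == "satterthwaite" else {}
    nu_naive = naive_dof(design)

    beta_all, resid_all = fit_ols(design, Y)
    out = {name: {"stat": np.full(V, np.nan), "t": np.full(V, np.nan),
                  "p": np.full(V, np.nan), "nu": np.full(V, np.nan)}
           for name in contrasts}
    n_failed = 0
    for start in range(0, V, batch_size):
        sl = slice(start, min(start + batch_size, V))
        beta = beta_all[:, sl]
        resid = resid_all[:, sl]
        e_adj = sandwich.adjust_residuals(resid, h, design.n, design.p,
                                          adjustment)
        try:
            if variant == "hom":
                gc = sandwich.estimate_group_covariance(design, e_adj)
                sw = sandwich.swe_homogeneous(design, gc)
            else:
                gc = None
                sw = sandwich.swe_heterogeneous(design, e_adj)
        except Exception as err:   # batch-level failure: mark all voxels
            logger.warning("batch %d failed: %s", start // batch_size, err)
            n_failed += sl.stop - sl.start
            continue
        for name, C in contrasts.items():
            if dof_method == "satterthwaite":
                if variant == "hom":
                    nu = DofEstimate(nu=sdofs[name].nu_hom(gc),
                                     method="satterthwaite")
                else:
                    nu = DofEstimate(nu=sdofs[name].nu_het(resid),
                                     method="satterthwaite")
            else:
                nu = nu_naive
            res = wald_test(beta, sw.S, C, nu)
            o = out[name]
            o["stat"][sl] = np.atleast_1d(res.stat)
            o["p"][sl] = np.atleast_1d(res.p)
            o["nu"][sl] = np.atleast_1d(res.nu)
            if res.t is not None:
                o["t"][sl] = np.atleast_1d(res.t)
    for name in contrasts:
        out[name]["beta"] = beta_all
        bad = int(np.isnan(out[name]["p"]).sum())
        out[name]["n_failed"] = bad
        if bad > max_failure_fraction * V:
            raise RuntimeError(
                f"contrast {name!r}: {bad}/{V} voxels failed "
                f"(> {max_failure_fraction:.0%}); aborting")
    if n_failed:
        logger.warning("%d voxel(s) failed across batches", n_failed)
    return out


def write_manifest(path, **entries):
    """Machine-readable run manifest (inputs, options, seed, counts)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(entries, fh, indent=2, default=str)
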