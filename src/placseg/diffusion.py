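"""Voxel-wise diffusion-tensor fitting and scalar metrics.

Standard log-linear DTI: ``ln S = ln S0 - b g^T D g`` solved by least
squares with a 7-parameter design matrix (6 tensor components + ln S0),
followed by eigen-decomposition.  Derived metrics: AD = lambda1,
RD = (lambda2 + lambda3)/2, ADC = trace/3 and
FA = sqrt(3/2) ||lambda - mean|| / ||lambda||.  Tensors are carried in
1e-3 mm^2/s so physiologic placental diffusivities are order 1-4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import fa_from_eigenvalues


@dataclass(frozen=True)
class DiffusionScheme:
    """b-values (s/mm^2) and unit gradient directions of a DWI acquisition."""

    b_values: np.ndarray
    b_vectors: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b_values, float)
        g = np.asarray(self.b_vectors, float)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "b_vectors", g)
        if b.ndim != 1 or g.shape != (b.size, 3):
            raise ValueError("b_values (m,) and b_vectors (m, 3) required")
        nz = b > 0
        if nz.sum() < 6 or (~nz).sum() < 1:
            raise ValueError("need >= 1 b=0 and >= 6 diffusion directions")
        norms = np.linalg.norm(g[nz], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("gradient directions must be unit vectors")
        # distinct up to sign, and spanning rank 3
        dirs = g[nz]
        dots = np.abs(dirs @ dirs.T)
        np.fill_diagonal(dots, 0.0)
        n_distinct = dirs.shape[0] - np.count_nonzero(
            np.triu(dots, 1) > 1.0 - 1e-9) // 1
        if n_distinct < 6:
            raise ValueError("need >= 6 distinct (non-collinear) directions")
        if np.linalg.matrix_rank(_design(b[nz], dirs)[:, :6]) < 6:
            raise ValueError("diffusion design matrix is rank deficient")


def _design(b, g):
    """Rows of [-b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz, 1]."""
    gx, gy, gz = g.T
    return np.column_stack([
        -b * gx**2, -b * gy**2, -b * gz**2,
        -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
        np.ones_like(b),
    ])


@dataclass
class TensorMaps:
    """Per-voxel tensor (1e-3 mm^2/s), eigenvalues and scalar metrics."""

    tensor: np.ndarray       # (..., 3, 3)
    eigenvalues: np.ndarray  # (..., 3) sorted descending
    adc: np.ndarray
    fa: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    fit_valid: np.ndarray


def fit_tensor(dwi: np.ndarray, scheme: DiffusionScheme,
               mask: np.ndarray | None = None) -> TensorMaps:
    """Fit the diffusion tensor in every masked voxel.

    Voxels with any non-positive measurement are flagged invalid.  Negative
    eigenvalues are clipped to zero (the voxel stays usable but is flagged),
    mirroring common DTI practice so masks remain comparable across features.
    """
    dwi = np.asarray(dwi, float)
    spatial = dwi.shape[:-1]
    m = scheme.b_values.size
    if dwi.shape[-1] != m:
        raise ValueError("DWI volume count does not match scheme")
    if mask is None:
        mask = np.ones(spatial, bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")

    X = _design(scheme.b_values, scheme.b_vectors)  # (m, 7)
    S = dwi[mask]  # (n, m)
    pos = np.all(S > 0, axis=1)

    logS = np.log(np.where(S > 0, S, 1.0))
    beta = np.linalg.lstsq(X, logS.T, rcond=None)[0].T  # (n, 7)
    # design carries the 1e-3 scale: b (s/mm^2) * D (1e-3 mm^2/s) * 1e-3
    d = beta[:, :6] * 1e3

    n = d.shape[0]
    tensor = np.empty((n, 3, 3))
    tensor[:, 0, 0] = d[:, 0]
    tensor[:, 1, 1] = d[:, 1]
    tensor[:, 2, 2] = d[:, 2]
    tensor[:, 0, 1] = tensor[:, 1, 0] = d[:, 3]
    tensor[:, 0, 2] = tensor[:, 2, 0] = d[:, 4]
    tensor[:, 1, 2] = tensor[:, 2, 1] = d[:, 5]

    eigvals = np.linalg.eigvalsh(tensor)[:, ::-1]  # descending
    clipped = eigvals[:, 2] < 0
    eigvals = np.clip(eigvals, 0.0, None)

    valid = pos & ~clipped
    l1, l2, l3 = eigvals.T
    adc = (l1 + l2 + l3) / 3.0
    fa = fa_from_eigenvalues(l1, l2, l3)
    rd = (l2 + l3) / 2.0

    def unmask(vals, fill=np.nan):
        out = np.full(spatial + vals.shape[1:], fill)
        out[mask] = vals
        return out

    out_valid = np.zeros(spatial, bool)
    out_valid[mask] = valid
    return TensorMaps(
        tensor=unmask(tensor), eigenvalues=unmask(eigvals),
        adc=unmask(adc), fa=unmask(fa), ad=unmask(l1), rd=unmask(rd),
        fit_valid=out_valid)
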