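"""Linear degradation model: expected counts ``E[Y] = A X`` with Poisson noise.

The system matrix ``A`` (n x m, entries ``a_ij >= 0``) maps the unknown
activity raster to expected detector counts.  The package realizes ``A`` by
default as a shift-invariant point-spread-function (PSF) blur: row ``i``
holds a truncated, normalized Gaussian kernel centred on pixel ``i``.
Kernel mass falling off the grid is dropped, so rows near the border sum to
slightly less than one — counts lost off-detector.  Arbitrary nonnegative
matrices can be supplied instead (see :mod:`mixmrf.cli_io`).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .phantom import ConfigurationError


def psf_system_matrix(rows: int, cols: int, kernel_sd: float) -> sparse.csc_array:
    """Gaussian-PSF system matrix for a ``rows x cols`` raster.

    Parameters
    ----------
    rows, cols
        Raster dimensions; the matrix is square with ``n = m = rows*cols``
        in row-major pixel order.
    kernel_sd
        Standard deviation of the Gaussian PSF in pixel units.  Values
        below ~1e-3 px return the identity (no blur).

    Returns
    -------
    scipy.sparse.csc_array
        Column-compressed storage so the rows touched by one pixel (one
        column) are cheap to enumerate during MCMC updates.
    """
    if rows < 1 or cols < 1:
        raise ConfigurationError("grid dimensions must be >= 1")
    if kernel_sd <= 0:
        raise ConfigurationError("kernel_sd must be positive")
    m = rows * cols
    if kernel_sd < 1e-3:
        return sparse.identity(m, format="csc", dtype=float)
    radius = max(1, int(np.ceil(3.0 * kernel_sd)))
    ax = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-0.5 * (ax / kernel_sd) ** 2)
    kernel = np.outer(k1, k1)
    kernel /= kernel.sum()

    data, row_idx, col_idx = [], [], []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            w = kernel[dr + radius, dc + radius]
            if w <= 0.0:
                continue
            # pixel (r, c) contributes w to observation (r+dr, c+dc)
            r0, r1 = max(0, -dr), min(rows, rows - dr)
            c0, c1 = max(0, -dc), min(cols, cols - dc)
            if r0 >= r1 or c0 >= c1:
                continue
            rr, cc = np.mgrid[r0:r1, c0:c1]
            src = (rr * cols + cc).ravel()
            dst = ((rr + dr) * cols + (cc + dc)).ravel()
            col_idx.append(src)
            row_idx.append(dst)
            data.append(np.full(src.size, w))
    A = sparse.coo_array(
        (np.concatenate(data), (np.concatenate(row_idx), np.concatenate(col_idx))),
        shape=(m, m),
    )
    return A.tocsc()


def validate_system_matrix(A: sparse.sparray | np.ndarray) -> sparse.csc_array:
    """Check nonnegativity and observability; return CSC storage."""
    A = sparse.csc_array(A)
    if A.data.size and A.data.min() < 0:
        raise ConfigurationError("system matrix entries must be nonnegative")
    colsum = np.asarray(np.abs(A).sum(axis=0)).ravel()
    if np.any(colsum == 0):
        raise ConfigurationError("system matrix has an all-zero column (unobservable pixel)")
    return A


def project(A: sparse.sparray | np.ndarray, x: np.ndarray) -> np.ndarray:
    """Expected counts ``lambda_i = sum_j a_ij x_j`` for activity image x."""
    x = np.asarray(x, dtype=float)
    flat = x.ravel()
    if np.any(flat < 0):
        raise ValueError("activity must be nonnegative")
    if A.shape[1] != flat.size:
        raise ValueError(f"dimension mismatch: A has {A.shape[1]} columns, image has {flat.size} pixels")
    lam = A @ flat
    return np.asarray(lam, dtype=float)


def sample_observation(lam: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Independent Poisson counts with means ``lam`` (reproducible by seed)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("expected counts must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(lam).astype(np.int64)


def degrade(
    truth: np.ndarray,
    A: sparse.sparray | None = None,
    kernel_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, sparse.csc_array]:
    """Blur a truth image through the PSF and add Poisson counting noise.

    Returns the observed count image (same shape as ``truth``) and the
    system matrix used, so downstream fitting sees exactly the same model.
    """
    truth = np.asarray(truth, dtype=float)
    if A is None:
        A = psf_system_matrix(truth.shape[0], truth.shape[1], kernel_sd)
    else:
        A = validate_system_matrix(A)
    lam = project(A, truth)
    y = sample_observation(lam, seed)
    return y.reshape(truth.shape), A
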