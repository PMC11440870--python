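"""Numba-compiled inner loops of the Metropolis-within-Gibbs samplers.

The pixel sweep updates pixels one at a time in raster order with a
Gaussian random-walk proposal truncated at zero.  Each acceptance ratio is
assembled from the local terms only: the likelihood rows whose system-matrix
column touches the pixel (CSC slices, with the expected-count vector
``lam`` maintained incrementally) and the neighbour-pair prior terms.  The
per-pixel potential code (0 = absolute/Laplace, 1 = quadratic/Gaussian) and
scale arrays cover both the homogeneous priors (uniform arrays) and the
mixture prior (driven by the current spatial factor).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _pair_term(code, d, scale):
    # contribution of one directed half-pair, weight 0.5 included
    if code == 0:
        return 0.5 * abs(d) / scale
    return 0.5 * d * d / (2.0 * scale * scale)


@njit(cache=True)
def _sweep_once(x, lam, y, indptr, indices, data, colsum,
                nbr, nnbr, pcode, pscale, prop_sd, z, u):
    m = x.shape[0]
    acc = 0
    for j in range(m):
        xp = x[j] + prop_sd * z[j]
        if xp < 0.0:
            continue  # truncated proposal: rejected outright
        d = xp - x[j]
        dlog = -d * colsum[j]
        ok = True
        for p in range(indptr[j], indptr[j + 1]):
            i = indices[p]
            if y[i] > 0:
                lnew = lam[i] + data[p] * d
                if lnew <= 0.0:
                    ok = False
                    break
                dlog += y[i] * (np.log(lnew) - np.log(lam[i]))
        if not ok:
            continue
        for q in range(nnbr[j]):
            t = nbr[j, q]
            dnew = xp - x[t]
            dold = x[j] - x[t]
            dlog -= _pair_term(pcode[j], dnew, pscale[j]) - _pair_term(pcode[j], dold, pscale[j])
            dlog -= _pair_term(pcode[t], dnew, pscale[t]) - _pair_term(pcode[t], dold, pscale[t])
        if dlog >= 0.0 or np.log(u[j]) <= dlog:
            x[j] = xp
            for p in range(indptr[j], indptr[j + 1]):
                lam[indices[p]] += data[p] * d
            acc += 1
    return acc


@njit(cache=True)
def sweep_block(x, lam, y, indptr, indices, data, colsum,
                nbr, nnbr, pcode, pscale, prop_sd, Z, U, out_x, thin):
    """Run ``Z.shape[0]`` raster sweeps with fixed prior parameters.

    Records the state every ``thin`` sweeps into ``out_x`` when
    ``thin > 0``.  Returns the total number of accepted pixel moves.
    """
    acc = 0
    for k in range(Z.shape[0]):
        acc += _sweep_once(x, lam, y, indptr, indices, data, colsum,
                           nbr, nnbr, pcode, pscale, prop_sd, Z[k], U[k])
        if thin > 0 and (k + 1) % thin == 0:
            out_x[(k + 1) // thin - 1, :] = x
    return acc
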