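"""Numerical inner loops for connection-field projections and recurrent settling.

Two implementations are provided: numba-compiled loops (used when numba is
importable) and vectorized numpy equivalents.  Both operate on the same flat
patch representation: each target unit carries a fixed-size patch of source
indices ``idx`` (int32, flattened source sheet) and weights ``w``; absent
connections (outside the circular field or the sheet) have weight 0 and are
kept at 0 by the mask.

The numba lateral-settling path exploits two structural facts: settled V1
activity is sparse (silent units contribute nothing, so lateral sums scatter
from active units only), and lateral patches on a same-density sheet are
centered exactly on the target unit, so the weight column for a (target,
source) pair follows from their grid offset.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by the import machinery
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


# ---------------------------------------------------------------------------
# numpy reference implementations (and non-numba fallbacks)
# ---------------------------------------------------------------------------


def _project_np(src_flat: np.ndarray, idx: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.einsum("np,np->n", w, src_flat[idx])


def _out_np(x, theta, mode, slope):
    if mode == 0:
        return np.clip(x - theta, 0.0, 1.0)
    return 1.0 / (1.0 + np.exp(-slope * (x - theta - 0.5)))


def _settle_np(aff, wE, idxE, hE, wI, idxI, hI, theta, n_side, gE, gI, n_steps, mode, slope):
    """Recurrent settling, gather-based numpy path: (activity, first_bad_step)."""
    act = _out_np(aff, theta, mode, slope)
    for step in range(n_steps):
        exc = _project_np(act, idxE, wE)
        inh = _project_np(act, idxI, wI)
        act = _out_np(aff + gE * exc - gI * inh, theta, mode, slope)
        if not np.all(np.isfinite(act)):
            return act, step + 1
    return act, -1


def _hebb_np(w, mask, pre, post, alpha):
    """Hebbian step with sum-to-one normalization on pre-gathered activity."""
    active = post != 0.0
    if not np.any(active):
        return 0
    rows = np.where(active)[0]
    updated = (w[rows] + alpha * pre[rows] * post[rows, None]) * mask[rows]
    sums = updated.sum(axis=1)
    degenerate = int(np.sum(sums <= 0.0))
    ok = sums > 0.0
    w[rows[ok]] = updated[ok] / sums[ok, None]
    return degenerate


def _hebb_gather_np(w, mask, idx, srcs, post, alpha):
    pre = np.concatenate([s[idx] for s in srcs], axis=1)
    reps = w.shape[1] // mask.shape[1]
    full_mask = mask if reps == 1 else np.tile(mask, (1, reps))
    return _hebb_np(w, full_mask, pre, post, alpha)


# ---------------------------------------------------------------------------
# numba implementations
# ---------------------------------------------------------------------------

if HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _project_nb(src_flat, idx, w):  # pragma: no cover - compiled
        n, p = idx.shape
        out = np.empty(n)
        for i in range(n):
            acc = 0.0
            for k in range(p):
                acc += w[i, k] * src_flat[idx[i, k]]
            out[i] = acc
        return out

    @numba.njit(cache=True, fastmath=True)
    def _scatter_lateral(act, w, h, n_side, out):  # pragma: no cover - compiled
        """out[i] += sum_j w[i, pos(i,j)] * act[j], scattered from active j."""
        width = 2 * h + 1
        for j in range(act.shape[0]):
            a = act[j]
            if a == 0.0:
                continue
            rj = j // n_side
            cj = j % n_side
            r0 = rj - h if rj - h > 0 else 0
            r1 = rj + h if rj + h < n_side - 1 else n_side - 1
            c0 = cj - h if cj - h > 0 else 0
            c1 = cj + h if cj + h < n_side - 1 else n_side - 1
            for ri in range(r0, r1 + 1):
                drow = (rj - ri + h) * width
                base = ri * n_side
                for ci in range(c0, c1 + 1):
                    out[base + ci] += w[base + ci, drow + (cj - ci + h)] * a

    @numba.njit(cache=True, fastmath=True)
    def _settle_nb(aff, wE, hE, wI, hI, theta, n_side, gE, gI, n_steps, mode, slope):  # pragma: no cover
        n = aff.shape[0]
        act = np.empty(n)
        for i in range(n):
            x = aff[i] - theta[i]
            if mode == 0:
                act[i] = 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)
            else:
                act[i] = 1.0 / (1.0 + np.exp(-slope * (x - 0.5)))
        exc = np.empty(n)
        inh = np.empty(n)
        for step in range(n_steps):
            for i in range(n):
                exc[i] = 0.0
                inh[i] = 0.0
            _scatter_lateral(act, wE, hE, n_side, exc)
            _scatter_lateral(act, wI, hI, n_side, inh)
            bad = False
            for i in range(n):
                x = aff[i] + gE * exc[i] - gI * inh[i] - theta[i]
                if x != x:
                    bad = True
                    act[i] = x
                elif mode == 0:
                    act[i] = 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)
                else:
                    act[i] = 1.0 / (1.0 + np.exp(-slope * (x - 0.5)))
            if bad:
                return act, step + 1
        return act, -1

    @numba.njit(cache=True, fastmath=True)
    def _hebb_gather_nb(w, mask, idx, srcs, post, alpha):  # pragma: no cover - compiled
        """Fused gather + Hebbian update + normalization, skipping silent units.

        ``srcs`` is a (n_channels, n_src) array; ``w`` concatenates one patch
        per channel.  Returns the number of degenerate (zero-sum) rows.
        """
        n, p = idx.shape
        n_ch = srcs.shape[0]
        degenerate = 0
        backup = np.empty(n_ch * p)
        for i in range(n):
            eta = post[i]
            if eta == 0.0:
                continue
            for k in range(n_ch * p):
                backup[k] = w[i, k]
            s = 0.0
            for ch in range(n_ch):
                off = ch * p
                for k in range(p):
                    wv = (w[i, off + k] + alpha * srcs[ch, idx[i, k]] * eta) * mask[i, k]
                    w[i, off + k] = wv
                    s += wv
            if s <= 0.0:
                degenerate += 1
                for k in range(n_ch * p):
                    w[i, k] = backup[k]
                continue
            inv = 1.0 / s
            for k in range(n_ch * p):
                w[i, k] *= inv
        return degenerate

    project = _project_nb
    settle = _settle_nb

    def hebb_gather(w, mask, idx, srcs, post, alpha):
        return _hebb_gather_nb(w, mask, idx, np.stack(srcs), post, alpha)

else:  # pragma: no cover
    project = _project_np
    settle = _settle_np
    hebb_gather = _hebb_gather_np

hebb = _hebb_np
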