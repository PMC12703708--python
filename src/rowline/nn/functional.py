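"""Hand-differentiated array operations for the network.

These are the performance-critical primitives (im2col convolution, pooling,
batch normalization, bilinear gather/scatter) written as single tape nodes so
the graph stays short.  Sampling positions passed to the bilinear operations
are plain ndarrays: gradients flow into feature maps, not into coordinates —
anchor geometry is trained through the regression losses, not through the
pooling grid.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d", "conv1d_seq", "maxpool2x2", "batchnorm", "groupnorm",
    "upsample_nearest", "bilinear_sample", "bilinear_scatter", "softmax",
    "linear",
]


_POOL: dict = {}     # scratch-buffer pool: (nelems, dtype) -> [flat arrays]


def _pool_get(shape, dtype):
    n = int(np.prod(shape))
    key = (n, np.dtype(dtype).str)
    lst = _POOL.get(key)
    flat = lst.pop() if lst else np.empty(n, dtype=dtype)
    return flat, flat[:n].reshape(shape)


def _pool_put(flat):
    key = (flat.size, flat.dtype.str)
    _POOL.setdefault(key, []).append(flat)


def _im2colT(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Transposed im2col: returns (scratch, colsT (C*kh*kw, B*OH*OW), OH, OW).

    Rows of colsT are filled by contiguous strided-slice copies; for
    stride > 1 the polyphase components are extracted once so every copy is
    row-contiguous.  The scratch handle must be returned via _pool_put.
    """
    B, C, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    OH = (H + 2 * pad - kh) // stride + 1
    OW = (W + 2 * pad - kw) // stride + 1
    s = stride
    flat, colsT4 = _pool_get((C * kh * kw, B, OH, OW), x.dtype)
    if s == 1:
        # one bulk windowed copy instead of C*kh*kw sliced copies
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        np.copyto(colsT4.reshape(C, kh, kw, B, OH, OW),
                  win.transpose(1, 4, 5, 0, 2, 3))
    else:
        phases = {}
        for pi in range(min(s, kh)):
            for pj in range(min(s, kw)):
                phases[(pi, pj)] = np.ascontiguousarray(xp[:, :, pi::s, pj::s])
        col = 0
        for c in range(C):
            for i in range(kh):
                for j in range(kw):
                    ph = phases[(i % s, j % s)]
                    colsT4[col] = ph[:, c, i // s:i // s + OH, j // s:j // s + OW]
                    col += 1
    return flat, colsT4.reshape(C * kh * kw, B * OH * OW), OH, OW


def _col2imT(dcolsT: np.ndarray, xshape, kh, kw, stride, pad, OH, OW):
    B, C, H, W = xshape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    dxp = np.zeros((B, C, Hp, Wp), dtype=dcolsT.dtype)
    d4 = dcolsT.reshape(C * kh * kw, B, OH, OW)
    s = stride
    col = 0
    for c in range(C):
        for i in range(kh):
            for j in range(kw):
                dxp[:, c, i:i + s * OH:s, j:j + s * OW:s] += d4[col]
                col += 1
    if pad:
        dxp = dxp[:, :, pad:Hp - pad, pad:Wp - pad]
    return dxp


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1) -> Tensor:
    """Pointwise convolution as a single matmul (no im2col)."""
    B, C, H, W = x.shape
    OC = w.shape[0]
    wmat = w.data.reshape(OC, C)
    if stride > 1:
        xs = np.ascontiguousarray(x.data[:, :, ::stride, ::stride])
    else:
        xs = x.data
    OH, OW = xs.shape[2], xs.shape[3]
    xmat = xs.reshape(B, C, OH * OW)
    out = np.matmul(wmat, xmat)                     # (B, OC, OH*OW)
    if b is not None:
        out += b.data[:, None]
    parents = (x, w) + ((b,) if b is not None else ())
    res = Tensor(out.reshape(B, OC, OH, OW), parents=parents)
    if res.requires_grad:
        def bw(g, x=x, w=w, b=b, wmat=wmat, xmat=xmat, stride=stride,
               B=B, C=C, H=H, W=W, OC=OC, OH=OH, OW=OW):
            gmat = g.reshape(B, OC, OH * OW)
            if w.requires_grad:
                w._accum(np.matmul(gmat, xmat.transpose(0, 2, 1)).sum(axis=0)
                         .reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(gmat.sum(axis=(0, 2)))
            if x.requires_grad:
                dxs = np.matmul(wmat.T, gmat).reshape(B, C, OH, OW)
                if stride > 1:
                    dx = np.zeros((B, C, H, W), dtype=dxs.dtype)
                    dx[:, :, ::stride, ::stride] = dxs
                else:
                    dx = dxs
                x._accum(dx)
        res._backward = bw
    return res


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout."""
    OC, C, kh, kw = w.shape
    if kh == 1 and kw == 1 and pad == 0:
        return _conv1x1(x, w, b, stride=stride)
    B = x.shape[0]
    scratch, colsT, OH, OW = _im2colT(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(OC, -1)
    out = wmat @ colsT                              # (OC, B*OH*OW)
    if b is not None:
        out += b.data[:, None]
    out = np.ascontiguousarray(
        out.reshape(OC, B, OH, OW).transpose(1, 0, 2, 3))
    parents = (x, w) + ((b,) if b is not None else ())
    res = Tensor(out, parents=parents)
    if res.requires_grad:
        def bw(g, x=x, w=w, b=b, scratch=scratch, colsT=colsT, wmat=wmat,
               stride=stride, pad=pad, kh=kh, kw=kw, OH=OH, OW=OW, OC=OC):
            gmat = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(OC, -1)
            if w.requires_grad:
                w._accum((gmat @ colsT.T).reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(gmat.sum(axis=1))
            if x.requires_grad:
                dcolsT = wmat.T @ gmat
                x._accum(_col2imT(dcolsT, x.data.shape, kh, kw, stride, pad, OH, OW))
            _pool_put(scratch)
        res._backward = bw
    else:
        _pool_put(scratch)
    return res


def conv1d_seq(x: Tensor, w: Tensor, b: Tensor | None, pad: int = 1) -> Tensor:
    """1-D convolution along the last axis of a (B, C, N) sequence.

    Fused single-node implementation: the windowed column matrix is built by
    one sliding-window view + reshape rather than per-column copies."""
    B, C, N = x.shape
    OC, _, K = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad))) if pad else x.data
    ON = xp.shape[2] - K + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)   # (B,C,ON,K)
    colsT = np.ascontiguousarray(win.transpose(1, 3, 0, 2)).reshape(C * K, B * ON)
    wmat = w.data.reshape(OC, C * K)
    out = wmat @ colsT
    if b is not None:
        out += b.data[:, None]
    out = np.ascontiguousarray(out.reshape(OC, B, ON).transpose(1, 0, 2))
    parents = (x, w) + ((b,) if b is not None else ())
    res = Tensor(out, parents=parents)
    if res.requires_grad:
        def bw(g, x=x, w=w, b=b, colsT=colsT, wmat=wmat, pad=pad,
               B=B, C=C, N=N, K=K, ON=ON, OC=OC):
            gmat = np.ascontiguousarray(g.transpose(1, 0, 2)).reshape(OC, B * ON)
            if w.requires_grad:
                w._accum((gmat @ colsT.T).reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(gmat.sum(axis=1))
            if x.requires_grad:
                dcols = (wmat.T @ gmat).reshape(C, K, B, ON)
                dxp = np.zeros((B, C, N + 2 * pad), dtype=gmat.dtype)
                for k in range(K):
                    dxp[:, :, k:k + ON] += dcols[:, k].transpose(1, 0, 2)
                x._accum(dxp[:, :, pad:pad + N] if pad else dxp)
        res._backward = bw
    return res


def maxpool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    H2, W2 = H // 2, W // 2
    v = x.data[:, :, :2 * H2, :2 * W2].reshape(B, C, H2, 2, W2, 2)
    flat = v.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, 4)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    res = Tensor(out, parents=(x,))
    if res.requires_grad:
        def bw(g, x=x, arg=arg, B=B, C=C, H=H, W=W, H2=H2, W2=W2):
            dflat = np.zeros((B, C, H2, W2, 4), dtype=g.dtype)
            np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
            dv = dflat.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            dx = np.zeros_like(x.data, dtype=g.dtype)
            dx[:, :, :2 * H2, :2 * W2] = dv.reshape(B, C, 2 * H2, 2 * W2)
            x._accum(dx)
        res._backward = bw
    return res


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
              training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over all axes except channel axis 1."""
    axes = tuple(i for i in range(x.ndim) if i != 1)
    shape = [1] * x.ndim
    shape[1] = x.shape[1]
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.size / x.shape[1]
        # in-place so the running-stat dtype never drifts
        running["mean"] *= 1 - momentum
        running["mean"] += momentum * mu.astype(running["mean"].dtype)
        running["var"] *= 1 - momentum
        running["var"] += (momentum * n / max(n - 1, 1)) * var.astype(running["var"].dtype)
    else:
        mu, var = running["mean"], running["var"]
    std = np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) / std.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    res = Tensor(out, parents=(x, gamma, beta))
    if res.requires_grad:
        def bw(g, x=x, gamma=gamma, beta=beta, xhat=xhat, std=std, axes=axes, shape=shape,
               training=training):
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if x.requires_grad:
                gs = g * gamma.data.reshape(shape)
                if training:
                    m = x.data.size / x.shape[1]
                    dx = (gs - gs.mean(axis=axes, keepdims=True)
                          - xhat * (gs * xhat).sum(axis=axes, keepdims=True) / m) / std.reshape(shape)
                else:
                    dx = gs / std.reshape(shape)
                x._accum(dx)
        res._backward = bw
    return res


def groupnorm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
              eps: float = 1e-5) -> Tensor:
    """Group normalization over (B, C, H, W): batch-size independent, so
    training and inference compute identical statistics."""
    B, C = x.shape[0], x.shape[1]
    G = groups
    m = x.data.size // (B * G)
    xg = x.data.reshape(B, G, m)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (xg - mu) / std
    shape = (1, C) + (1,) * (x.ndim - 2)
    out = gamma.data.reshape(shape) * xhat.reshape(x.shape) + beta.data.reshape(shape)
    res = Tensor(out, parents=(x, gamma, beta))
    if res.requires_grad:
        def bw(g, x=x, gamma=gamma, beta=beta, xhat=xhat, std=std,
               B=B, G=G, m=m, shape=shape):
            axes = (0,) + tuple(range(2, x.ndim))
            xh4 = xhat.reshape(x.shape)
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if gamma.requires_grad:
                gamma._accum((g * xh4).sum(axis=axes))
            if x.requires_grad:
                dxh = (g * gamma.data.reshape(shape)).reshape(B, G, m)
                dx = (dxh - dxh.mean(axis=2, keepdims=True)
                      - xhat * (dxh * xhat).mean(axis=2, keepdims=True)) / std
                x._accum(dx.reshape(x.shape))
        res._backward = bw
    return res


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    f = int(factor)
    out = x.data.repeat(f, axis=2).repeat(f, axis=3)
    res = Tensor(out, parents=(x,))
    if res.requires_grad:
        def bw(g, x=x, f=f):
            B, C, H, W = x.shape
            x._accum(g.reshape(B, C, H, f, W, f).sum(axis=(3, 5)))
        res._backward = bw
    return res


def _scatter_csr(idx, wts, P, HW, dtype):
    """Sparse (HW, P) splat operator for one batch element."""
    from scipy import sparse
    rows = np.concatenate(idx)
    cols = np.tile(np.arange(P), 4)
    data = np.concatenate(wts).astype(dtype)
    return sparse.csr_matrix((data, (rows, cols)), shape=(HW, P))


# several bilinear ops per cascade stage share one positions array; cache
# the derived corner indices and splat operators for the current forward
_GEOM_CACHE: dict = {}


def clear_geometry_cache():
    _GEOM_CACHE.clear()


def _cached_corners(pts: np.ndarray, H: int, W: int):
    key = (pts.ctypes.data, pts.shape[-2] if pts.ndim > 1 else 0, H, W)
    got = _GEOM_CACHE.get(key)
    if got is None:
        got = {"corners": _corner_indices(pts, H, W), "csr": {}}
        _GEOM_CACHE[key] = got
    return got


def _cached_csr(pts: np.ndarray, H: int, W: int, dtype):
    entry = _cached_corners(pts, H, W)
    dkey = np.dtype(dtype).str
    csr = entry["csr"].get(dkey)
    if csr is None:
        idx, wts = entry["corners"]
        P = pts.shape[1]
        csr = [_scatter_csr([ix[b] for ix in idx], [w[b] for w in wts],
                            P, H * W, dtype) for b in range(pts.shape[0])]
        entry["csr"][dkey] = csr
    return csr


def _corner_indices(pts: np.ndarray, H: int, W: int):
    """Bilinear corner indices and weights with border clamping.

    pts: (..., 2) as (x, y) in feature-map pixel coordinates.
    """
    x = np.clip(pts[..., 0], 0.0, W - 1.0)
    y = np.clip(pts[..., 1], 0.0, H - 1.0)
    x0 = np.clip(np.floor(x).astype(np.int64), 0, max(W - 2, 0))
    y0 = np.clip(np.floor(y).astype(np.int64), 0, max(H - 2, 0))
    wx = x - x0
    wy = y - y0
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    idx = [y0 * W + x0, y0 * W + x1, y1 * W + x0, y1 * W + x1]
    wts = [(1 - wy) * (1 - wx), (1 - wy) * wx, wy * (1 - wx), wy * wx]
    return idx, wts


def bilinear_sample(fmap: Tensor, pts: np.ndarray) -> Tensor:
    """Sample a (B, C, H, W) map at (B, P, 2) positions -> (B, P, C)."""
    B, C, H, W = fmap.shape
    P = pts.shape[1]
    entry = _cached_corners(pts, H, W)
    idx, wts = entry["corners"]
    cat = entry.get("cat")
    if cat is None:
        cat = (np.concatenate(idx, axis=1),
               np.stack(wts, axis=1).astype(np.float32))
        entry["cat"] = cat
    idx_cat, wts_cat = cat
    wts_cat = wts_cat.astype(fmap.dtype, copy=False)
    flat = fmap.data.reshape(B, C, H * W)
    out = np.empty((B, C, P), dtype=fmap.dtype)
    for b in range(B):
        g4 = flat[b][:, idx_cat[b]].reshape(C, 4, P)
        np.einsum('ckp,kp->cp', g4, wts_cat[b], out=out[b])
    res = Tensor(out.transpose(0, 2, 1), parents=(fmap,))
    if res.requires_grad:
        def bw(g, fmap=fmap, pts=pts, B=B, C=C, H=H, W=W):
            csr = _cached_csr(pts, H, W, g.dtype)
            dflat = np.empty((B, H * W, C), dtype=g.dtype)
            for b in range(B):
                dflat[b] = csr[b] @ g[b]              # (HW,P) @ (P,C)
            fmap._accum(dflat.transpose(0, 2, 1).reshape(B, C, H, W))
        res._backward = bw
    return res


def bilinear_scatter(feats: Tensor, pts: np.ndarray, H: int, W: int) -> Tensor:
    """Splat (B, P, C) features at (B, P, 2) positions onto a zero (B, C, H, W) map.

    Mass-conserving: the sum over the output map equals the sum over feats.
    """
    B, P, C = feats.shape
    idx, wts = _cached_corners(pts, H, W)["corners"]
    dt = np.result_type(feats.dtype, np.float32)
    csr = _cached_csr(pts, H, W, dt)
    flat = np.empty((B, H * W, C), dtype=dt)
    for b in range(B):
        flat[b] = csr[b] @ feats.data[b]
    res = Tensor(flat.transpose(0, 2, 1).reshape(B, C, H, W).copy(), parents=(feats,))
    if res.requires_grad:
        def bw(g, feats=feats, idx=idx, wts=wts, B=B, C=C, H=H, W=W):
            gflat = g.reshape(B, C, H * W)
            dp = np.zeros((B, C, feats.shape[1]), dtype=g.dtype)
            wtsg = [w.astype(g.dtype, copy=False) for w in wts]
            for b in range(B):
                gb = gflat[b]
                for k in range(4):
                    dp[b] += gb[:, idx[k][b]] * wtsg[k][b]
            feats._accum(dp.transpose(0, 2, 1))
        res._backward = bw
    return res


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = z.exp()
    return e / e.sum(axis=axis, keepdims=True)


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """x @ w.T + b for (..., in) inputs."""
    out = x @ w.T
    if b is not None:
        out = out + b
    return out
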