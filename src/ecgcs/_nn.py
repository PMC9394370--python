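"""Internal NumPy autodiff engine for the compressive autoencoder.

All network stages are implemented as explicit forward passes with cached
intermediates and matching hand-derived backward passes over a flat
``{name: ndarray}`` parameter dict.  The public module surfaces
(:mod:`ecgcs.reconstruction_net`, :mod:`ecgcs.training`) are thin views over
these primitives, so there is exactly one forward implementation.

Parameter-dict layout (C = channel count, H = LSTM hidden size, F = 64
feature channels, kernels (7, 9, 11, 13)):

========================  =============================
key                        shape
========================  =============================
comp.w{0,1,2}              (C, {1,C,C}, 4)
comp.b{0,1,2}              (C,)
init.w / init.b            (64, C) / (64,)
entry.w / entry.b          (16, 1, 11) / (16,)
inc{n}.w1 / inc{n}.b1      (16, 16, k_n) / (16,)
inc{n}.w2 / inc{n}.b2      (16, 16, k_n) / (16,)
lstm.W / lstm.b            (4H, H+F) / (4H,)  gate order f, i, g, o
proj.w / proj.b            (H,) / ()
========================  =============================
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

INCEPTION_KERNELS = (7, 9, 11, 13)
FEATURE_CHANNELS = 64
LINE_CHANNELS = 16
ENTRY_KERNEL = 11


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def leaky_relu_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def conv_stride4(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid stride-4 conv: (B, Cin, L) -> (B, Cout, L//4)."""
    bsz, c_in, length = x.shape
    xr = x.reshape(bsz, c_in, length // 4, 4)
    return np.einsum("bcpk,ock->bop", xr, w, optimize=True) + b[None, :, None]


def conv_stride4_backward(x, w, dout):
    bsz, c_in, length = x.shape
    xr = x.reshape(bsz, c_in, length // 4, 4)
    dw = np.einsum("bcpk,bop->ock", xr, dout, optimize=True)
    db = dout.sum(axis=(0, 2))
    dxr = np.einsum("bop,ock->bcpk", dout, w, optimize=True)
    return dxr.reshape(x.shape), dw, db


def conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Stride-1 'same' conv for odd kernels: (B, Cin, L) -> (B, Cout, L)."""
    k = w.shape[2]
    pad = k // 2
    length = x.shape[2]
    xpad = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    out = np.einsum("oc,bcl->bol", w[:, :, 0], xpad[:, :, 0:length], optimize=True)
    for j in range(1, k):
        out += np.einsum("oc,bcl->bol", w[:, :, j], xpad[:, :, j:j + length], optimize=True)
    return out + b[None, :, None]


def conv_same_backward(x, w, dout):
    k = w.shape[2]
    pad = k // 2
    length = x.shape[2]
    xpad = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    dw = np.empty_like(w)
    dxpad = np.zeros_like(xpad)
    for j in range(k):
        dw[:, :, j] = np.einsum("bol,bcl->oc", dout, xpad[:, :, j:j + length], optimize=True)
        dxpad[:, :, j:j + length] += np.einsum("bol,oc->bcl", dout, w[:, :, j], optimize=True)
    db = dout.sum(axis=(0, 2))
    return dxpad[:, :, pad:pad + length], dw, db


# ---------------------------------------------------------------------------
# full forward / backward
# ---------------------------------------------------------------------------

def forward(params: dict, x: np.ndarray, channel_count: int, slope: float,
            fixed_matrix: np.ndarray | None = None,
            return_cache: bool = True):
    """Run compressor + decoder on a batch ``x`` of shape (B, N).

    When ``fixed_matrix`` is given it replaces the learned convolutional
    compressor (classical y = Phi x); the flat measurement is reshaped
    position-major into (positions, C) either way.

    Returns ``(out, cache)`` where ``out`` is (B, N); ``cache`` is None when
    ``return_cache`` is False.
    """
    bsz, n = x.shape
    c = channel_count
    positions = n // 64
    cache: dict = {"x": x, "slope": slope, "fixed": fixed_matrix is not None}

    # -- compression ------------------------------------------------------
    if fixed_matrix is None:
        h = x[:, None, :]
        comp_inputs = []
        for i in range(3):
            comp_inputs.append(h)
            h = conv_stride4(h, params[f"comp.w{i}"], params[f"comp.b{i}"])
        y3 = h  # (B, C, P)
        cache["comp_inputs"] = comp_inputs
    else:
        meas = x @ fixed_matrix.T                       # (B, M)
        y3 = meas.reshape(bsz, positions, c).transpose(0, 2, 1)
    return decode(params, y3, slope, cache=cache, return_cache=return_cache)


def decode(params: dict, y3: np.ndarray, slope: float,
           cache: dict | None = None, return_cache: bool = True):
    """Decoder only: measurement grid ``y3`` of shape (B, C, P) -> (B, N)."""
    bsz = y3.shape[0]
    n = y3.shape[2] * 64
    if cache is None:
        cache = {"slope": slope, "fixed": True}
    cache["y3"] = y3

    # -- initial reconstruction: 1x1 conv C->64 + LeakyReLU + reshape ------
    z_init = np.einsum("bcp,oc->bop", y3, params["init.w"], optimize=True) \
        + params["init.b"][None, :, None]
    a_init = leaky_relu(z_init, slope)
    initial = a_init.transpose(0, 2, 1).reshape(bsz, n)  # position-major
    cache["z_init"] = z_init

    # -- entry conv 1->16 k=11 + LeakyReLU ---------------------------------
    x1 = initial[:, None, :]
    u_entry = conv_same(x1, params["entry.w"], params["entry.b"])
    e = leaky_relu(u_entry, slope)
    cache["x1"] = x1
    cache["u_entry"] = u_entry

    # -- modified Inception block ------------------------------------------
    line_outs = []
    for ln in range(4):
        u1 = conv_same(e, params[f"inc{ln}.w1"], params[f"inc{ln}.b1"])
        a1 = leaky_relu(u1, slope)
        u2 = conv_same(a1, params[f"inc{ln}.w2"], params[f"inc{ln}.b2"])
        a2 = leaky_relu(u2, slope)
        line_outs.append(a2 + e)
        cache[f"u1_{ln}"] = u1
        cache[f"a1_{ln}"] = a1
        cache[f"u2_{ln}"] = u2
    feat = np.concatenate(line_outs, axis=1)            # (B, 64, N)
    cache["e"] = e

    # -- LSTM over time ----------------------------------------------------
    w_lstm, b_lstm = params["lstm.W"], params["lstm.b"]
    hidden = w_lstm.shape[0] // 4
    fseq = np.ascontiguousarray(feat.transpose(2, 0, 1))  # (T, B, F)
    t_steps = fseq.shape[0]
    zx = np.einsum("tbf,gf->tbg", fseq, w_lstm[:, hidden:], optimize=True) + b_lstm
    w_hh = w_lstm[:, :hidden]

    f_g = np.empty((t_steps, bsz, hidden))
    i_g = np.empty_like(f_g)
    g_g = np.empty_like(f_g)
    o_g = np.empty_like(f_g)
    c_s = np.empty_like(f_g)
    tanh_c = np.empty_like(f_g)
    h_s = np.empty_like(f_g)

    h_prev = np.zeros((bsz, hidden))
    c_prev = np.zeros((bsz, hidden))
    for t in range(t_steps):
        z = zx[t] + h_prev @ w_hh.T
        f_t = expit(z[:, :hidden])
        i_t = expit(z[:, hidden:2 * hidden])
        g_t = np.tanh(z[:, 2 * hidden:3 * hidden])
        o_t = expit(z[:, 3 * hidden:])
        c_t = f_t * c_prev + i_t * g_t
        tc = np.tanh(c_t)
        h_t = o_t * tc
        f_g[t], i_g[t], g_g[t], o_g[t] = f_t, i_t, g_t, o_t
        c_s[t], tanh_c[t], h_s[t] = c_t, tc, h_t
        h_prev, c_prev = h_t, c_t

    cache.update(fseq=fseq, f_g=f_g, i_g=i_g, g_g=g_g, o_g=o_g,
                 c_s=c_s, tanh_c=tanh_c, h_s=h_s, hidden=hidden)

    # -- per-step linear projection H -> 1 ---------------------------------
    out = np.einsum("tbh,h->bt", h_s, params["proj.w"], optimize=True) + params["proj.b"]
    if not return_cache:
        return out, None
    return out, cache


def backward(params: dict, cache: dict, dout: np.ndarray) -> dict:
    """Gradients of a scalar loss w.r.t. every parameter, given d(loss)/d(out)."""
    slope = cache["slope"]
    h_s, fseq = cache["h_s"], cache["fseq"]
    f_g, i_g, g_g, o_g = cache["f_g"], cache["i_g"], cache["g_g"], cache["o_g"]
    c_s, tanh_c = cache["c_s"], cache["tanh_c"]
    hidden = cache["hidden"]
    t_steps, bsz, _ = h_s.shape
    w_lstm = params["lstm.W"]
    w_hh = w_lstm[:, :hidden]
    grads: dict = {}

    # projection
    grads["proj.w"] = np.einsum("tbh,bt->h", h_s, dout, optimize=True)
    grads["proj.b"] = np.array(dout.sum())
    pw = params["proj.w"]

    # LSTM BPTT
    dz_all = np.empty((t_steps, bsz, 4 * hidden))
    dfeat_seq = np.empty_like(fseq)
    dh_next = np.zeros((bsz, hidden))
    dc_next = np.zeros((bsz, hidden))
    for t in range(t_steps - 1, -1, -1):
        dh = dout[:, t][:, None] * pw[None, :] + dh_next
        do = dh * tanh_c[t]
        dc = dc_next + dh * o_g[t] * (1.0 - tanh_c[t] ** 2)
        c_prev = c_s[t - 1] if t > 0 else 0.0
        df = dc * c_prev
        di = dc * g_g[t]
        dg = dc * i_g[t]
        dz = np.empty((bsz, 4 * hidden))
        dz[:, :hidden] = df * f_g[t] * (1.0 - f_g[t])
        dz[:, hidden:2 * hidden] = di * i_g[t] * (1.0 - i_g[t])
        dz[:, 2 * hidden:3 * hidden] = dg * (1.0 - g_g[t] ** 2)
        dz[:, 3 * hidden:] = do * o_g[t] * (1.0 - o_g[t])
        dz_all[t] = dz
        dhx = dz @ w_lstm
        dh_next = dhx[:, :hidden]
        dfeat_seq[t] = dhx[:, hidden:]
        dc_next = dc * f_g[t]

    h_prev_seq = np.concatenate(
        [np.zeros((1, bsz, hidden)), h_s[:-1]], axis=0)
    grads["lstm.W"] = np.concatenate(
        [np.einsum("tbg,tbh->gh", dz_all, h_prev_seq, optimize=True),
         np.einsum("tbg,tbf->gf", dz_all, fseq, optimize=True)], axis=1)
    grads["lstm.b"] = dz_all.sum(axis=(0, 1))

    dfeat = dfeat_seq.transpose(1, 2, 0)  # (B, 64, N)

    # Inception block
    e = cache["e"]
    de = np.zeros_like(e)
    for ln in range(4):
        d_line = dfeat[:, ln * LINE_CHANNELS:(ln + 1) * LINE_CHANNELS, :]
        de += d_line                                   # skip path
        da2 = d_line * leaky_relu_grad(cache[f"u2_{ln}"], slope)
        da1, dw2, db2 = conv_same_backward(cache[f"a1_{ln}"], params[f"inc{ln}.w2"], da2)
        du1 = da1 * leaky_relu_grad(cache[f"u1_{ln}"], slope)
        de_ln, dw1, db1 = conv_same_backward(e, params[f"inc{ln}.w1"], du1)
        de += de_ln
        grads[f"inc{ln}.w1"], grads[f"inc{ln}.b1"] = dw1, db1
        grads[f"inc{ln}.w2"], grads[f"inc{ln}.b2"] = dw2, db2

    # entry conv
    du_entry = de * leaky_relu_grad(cache["u_entry"], slope)
    dx1, dw_e, db_e = conv_same_backward(cache["x1"], params["entry.w"], du_entry)
    grads["entry.w"], grads["entry.b"] = dw_e, db_e

    # initial reconstruction
    bsz, _, n = dx1.shape
    d_initial = dx1[:, 0, :]
    da_init = d_initial.reshape(bsz, n // 64, 64).transpose(0, 2, 1)  # (B, 64, P)
    dz_init = da_init * leaky_relu_grad(cache["z_init"], slope)
    y3 = cache["y3"]
    grads["init.w"] = np.einsum("bop,bcp->oc", dz_init, y3, optimize=True)
    grads["init.b"] = dz_init.sum(axis=(0, 2))

    # compressor (only when learned)
    if not cache["fixed"]:
        dy3 = np.einsum("bop,oc->bcp", dz_init, params["init.w"], optimize=True)
        d_h = dy3
        for i in range(2, -1, -1):
            d_h, dw, db = conv_stride4_backward(
                cache["comp_inputs"][i], params[f"comp.w{i}"], d_h)
            grads[f"comp.w{i}"], grads[f"comp.b{i}"] = dw, db
    return grads


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    """Plain Adam over a flat parameter dict (no weight decay, no clipping)."""

    def __init__(self, params: dict, learning_rate: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            m = self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            v = self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] = params[k] - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def init_params(channel_count: int, hidden: int = 64, seed: int = 0,
                include_compressor: bool = True) -> dict:
    """Glorot-uniform weights, zero biases, for the full parameter dict."""
    rng = np.random.default_rng(seed)
    c = channel_count

    def glorot(shape, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    params: dict = {}
    if include_compressor:
        for i, c_in in enumerate((1, c, c)):
            params[f"comp.w{i}"] = glorot((c, c_in, 4), c_in * 4, c * 4)
            params[f"comp.b{i}"] = np.zeros(c)
    params["init.w"] = glorot((FEATURE_CHANNELS, c), c, FEATURE_CHANNELS)
    params["init.b"] = np.zeros(FEATURE_CHANNELS)
    params["entry.w"] = glorot((LINE_CHANNELS, 1, ENTRY_KERNEL),
                               ENTRY_KERNEL, LINE_CHANNELS * ENTRY_KERNEL)
    params["entry.b"] = np.zeros(LINE_CHANNELS)
    for ln, k in enumerate(INCEPTION_KERNELS):
        fan = LINE_CHANNELS * k
        params[f"inc{ln}.w1"] = glorot((LINE_CHANNELS, LINE_CHANNELS, k), fan, fan)
        params[f"inc{ln}.b1"] = np.zeros(LINE_CHANNELS)
        params[f"inc{ln}.w2"] = glorot((LINE_CHANNELS, LINE_CHANNELS, k), fan, fan)
        params[f"inc{ln}.b2"] = np.zeros(LINE_CHANNELS)
    params["lstm.W"] = glorot((4 * hidden, hidden + FEATURE_CHANNELS),
                              hidden + FEATURE_CHANNELS, hidden)
    params["lstm.b"] = np.zeros(4 * hidden)
    params["proj.w"] = glorot((hidden,), hidden, 1)
    params["proj.b"] = np.array(0.0)
    return params
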