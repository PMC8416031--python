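"""Time-attention encoder: bidirectional GRU -> sigmoid gate -> linear emissions.

For a night of T epochs with F features each, a single-layer bidirectional GRU
with hidden size F/2 per direction produces a (T, F) hidden sequence H (the two
directions concatenated). The attention gate is

    Attention(X, X) = sigmoid(H) * X        (elementwise)

i.e. each feature of each epoch is scaled by a data-dependent weight in (0, 1).
A linear layer maps the gated features to five per-epoch stage scores (the CRF
emissions).

Everything is plain NumPy. Gradients are hand-derived (truncated-nothing BPTT
over the full night) and checked against central finite differences in the test
suite. Parameters live in a flat ``dict[str, ndarray]`` so the optimizer and
gradient checks can treat them uniformly:

    fwd.Wz fwd.Uz fwd.bz fwd.Wr fwd.Ur fwd.br fwd.Wh fwd.Uh fwd.bh
    bwd.*  (same shapes)
    emit.W (5, F)   emit.b (5,)

GRU cell (the common formulation with the reset gate inside the candidate's
recurrent term):

    z_t = sigmoid(Wz x_t + Uz h_{t-1} + bz)
    r_t = sigmoid(Wr x_t + Ur h_{t-1} + br)
    hc_t = tanh(Wh x_t + Uh (r_t * h_{t-1}) + bh)
    h_t = (1 - z_t) * h_{t-1} + z_t * hc_t,     h_0 = 0

An odd feature count is zero-padded by one column so the bidirectional hidden
width 2 * floor(F/2) equals the (padded) feature width.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "init_encoder_params",
    "gru_forward",
    "attention_gate",
    "emissions",
    "encoder_forward",
    "encoder_backward",
    "pad_features",
]

_GATE_KEYS = ("Wz", "Uz", "bz", "Wr", "Ur", "br", "Wh", "Uh", "bh")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def pad_features(X: np.ndarray) -> np.ndarray:
    """Zero-pad one feature column when the feature count is odd."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
    if X.shape[1] % 2:
        X = np.concatenate([X, np.zeros((X.shape[0], 1))], axis=1)
    return X


def init_encoder_params(n_features: int, seed=None) -> dict[str, np.ndarray]:
    """Seeded uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization.

    ``n_features`` is the raw feature width; one zero column is added
    internally when it is odd, so the stored shapes always use the padded
    width F and hidden size H = F/2.
    """
    F = n_features + (n_features % 2)
    H = F // 2
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    bound_rec = 1.0 / np.sqrt(H)
    for direction in ("fwd", "bwd"):
        for gate in ("z", "r", "h"):
            params[f"{direction}.W{gate}"] = rng.uniform(-bound_rec, bound_rec, (H, F))
            params[f"{direction}.U{gate}"] = rng.uniform(-bound_rec, bound_rec, (H, H))
            params[f"{direction}.b{gate}"] = rng.uniform(-bound_rec, bound_rec, H)
    bound_emit = 1.0 / np.sqrt(F)
    params["emit.W"] = rng.uniform(-bound_emit, bound_emit, (5, F))
    params["emit.b"] = rng.uniform(-bound_emit, bound_emit, 5)
    return params


def _direction_params(params: dict, direction: str) -> dict:
    prefix = {"forward": "fwd", "backward": "bwd", "fwd": "fwd", "bwd": "bwd"}.get(
        direction
    )
    if prefix is None:
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    return {k: params[f"{prefix}.{k}"] for k in _GATE_KEYS}


def _gru_run(X: np.ndarray, p: dict):
    """One-directional GRU over X (already in scan order). Returns (H, cache)."""
    T, F = X.shape
    Hn = p["Wz"].shape[0]
    if p["Wz"].shape[1] != F:
        raise ValueError(
            f"GRU input weight expects {p['Wz'].shape[1]} features, got {F}"
        )
    # Input-side projections for the whole sequence in three big matmuls.
    ax_z = X @ p["Wz"].T + p["bz"]
    ax_r = X @ p["Wr"].T + p["br"]
    ax_h = X @ p["Wh"].T + p["bh"]

    z = np.empty((T, Hn))
    r = np.empty((T, Hn))
    hc = np.empty((T, Hn))
    h = np.empty((T, Hn))
    h_prev = np.zeros(Hn)
    Uz, Ur, Uh = p["Uz"], p["Ur"], p["Uh"]
    for t in range(T):
        zt = _sigmoid(ax_z[t] + Uz @ h_prev)
        rt = _sigmoid(ax_r[t] + Ur @ h_prev)
        hct = np.tanh(ax_h[t] + Uh @ (rt * h_prev))
        ht = (1.0 - zt) * h_prev + zt * hct
        z[t], r[t], hc[t], h[t] = zt, rt, hct, ht
        h_prev = ht
    h_prev_all = np.vstack([np.zeros(Hn), h[:-1]])
    cache = {"X": X, "z": z, "r": r, "hc": hc, "h_prev": h_prev_all}
    return h, cache


def _gru_backprop(dH: np.ndarray, cache: dict, p: dict) -> dict:
    """Backprop through one GRU direction. dH in the cell's scan order."""
    X, z, r, hc, h_prev = cache["X"], cache["z"], cache["r"], cache["hc"], cache["h_prev"]
    T, Hn = dH.shape
    Uz, Ur, Uh = p["Uz"], p["Ur"], p["Uh"]

    da_z = np.empty((T, Hn))
    da_r = np.empty((T, Hn))
    da_h = np.empty((T, Hn))
    carry = np.zeros(Hn)
    for t in range(T - 1, -1, -1):
        dh = dH[t] + carry
        dz = dh * (hc[t] - h_prev[t])
        dhc = dh * z[t]
        dprev = dh * (1.0 - z[t])
        dah = dhc * (1.0 - hc[t] ** 2)
        ds = dah @ Uh  # gradient w.r.t. s = r * h_prev
        dr = ds * h_prev[t]
        dprev = dprev + ds * r[t]
        daz = dz * z[t] * (1.0 - z[t])
        dar = dr * r[t] * (1.0 - r[t])
        dprev = dprev + daz @ Uz + dar @ Ur
        da_z[t], da_r[t], da_h[t] = daz, dar, dah
        carry = dprev

    s_prev = r * h_prev
    return {
        "Wz": da_z.T @ X,
        "Uz": da_z.T @ h_prev,
        "bz": da_z.sum(axis=0),
        "Wr": da_r.T @ X,
        "Ur": da_r.T @ h_prev,
        "br": da_r.sum(axis=0),
        "Wh": da_h.T @ X,
        "Uh": da_h.T @ s_prev,
        "bh": da_h.sum(axis=0),
    }


def gru_forward(X, params: dict, direction: str = "forward") -> np.ndarray:
    """Hidden sequence (T, F/2) of one GRU direction, in original time order.

    The backward direction scans reversed time and its output is re-reversed,
    so row t of either direction refers to epoch t.
    """
    X = pad_features(X)
    p = _direction_params(params, direction)
    if direction in ("backward", "bwd"):
        h, _ = _gru_run(X[::-1], p)
        return h[::-1]
    h, _ = _gru_run(X, p)
    return h


def attention_gate(X, params: dict) -> np.ndarray:
    """sigmoid(concat(h_fwd, h_bwd)) * X, elementwise; same shape as (padded) X."""
    X = pad_features(X)
    Hcat = np.concatenate(
        [gru_forward(X, params, "forward"), gru_forward(X, params, "backward")], axis=1
    )
    return _sigmoid(Hcat) * X


def emissions(gated, params: dict) -> np.ndarray:
    """Affine map of gated features to five per-epoch stage scores."""
    gated = np.asarray(gated, dtype=float)
    W, b = params["emit.W"], params["emit.b"]
    if gated.shape[1] != W.shape[1]:
        raise ValueError(
            f"emission layer expects {W.shape[1]} features, got {gated.shape[1]}"
        )
    return gated @ W.T + b


def encoder_forward(X, params: dict):
    """Full encoder pass. Returns (E, cache) with E the (T, 5) emission matrix."""
    X = pad_features(X)
    p_f = _direction_params(params, "forward")
    p_b = _direction_params(params, "backward")
    h_f, cache_f = _gru_run(X, p_f)
    h_b_rev, cache_b = _gru_run(X[::-1], p_b)
    Hcat = np.concatenate([h_f, h_b_rev[::-1]], axis=1)
    s = _sigmoid(Hcat)
    G = s * X
    E = G @ params["emit.W"].T + params["emit.b"]
    cache = {"X": X, "s": s, "G": G, "cache_f": cache_f, "cache_b": cache_b}
    return E, cache


def encoder_backward(dE: np.ndarray, cache: dict, params: dict) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss w.r.t. all encoder parameters given dLoss/dE."""
    X, s, G = cache["X"], cache["s"], cache["G"]
    Hn = s.shape[1] // 2

    grads: dict[str, np.ndarray] = {
        "emit.W": dE.T @ G,
        "emit.b": dE.sum(axis=0),
    }
    dG = dE @ params["emit.W"]
    ds = dG * X
    dHcat = ds * s * (1.0 - s)

    g_f = _gru_backprop(dHcat[:, :Hn], cache["cache_f"], _direction_params(params, "forward"))
    g_b = _gru_backprop(
        dHcat[:, Hn:][::-1], cache["cache_b"], _direction_params(params, "backward")
    )
    for k, v in g_f.items():
        grads[f"fwd.{k}"] = v
    for k, v in g_b.items():
        grads[f"bwd.{k}"] = v
    return grads
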