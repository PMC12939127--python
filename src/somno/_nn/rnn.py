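"""Multi-layer bidirectional LSTM with hand-written BPTT.

Gate parameterization follows the common convention of two bias vectors
(input-hidden and hidden-hidden) per layer and direction, gate order
(input, forget, cell, output). The input-hidden products for all time
steps are evaluated as one GEMM; the recurrence loops only over the
hidden-hidden term and the elementwise gate math.
"""

from __future__ import annotations

import numpy as np

from .layers import F32, Module, _uniform


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class _LSTMCellParams:
    """Parameter name helper for one (layer, direction)."""

    def __init__(self, layer: int, direction: int):
        suffix = f"l{layer}" + ("_reverse" if direction else "")
        self.w_ih = f"weight_ih_{suffix}"
        self.w_hh = f"weight_hh_{suffix}"
        self.b_ih = f"bias_ih_{suffix}"
        self.b_hh = f"bias_hh_{suffix}"


class LSTM(Module):
    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator, bidirectional: bool = True,
                 dropout: float = 0.0):
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.bidirectional = bidirectional
        self.dropout = dropout
        self.n_dir = 2 if bidirectional else 1
        self.rng = np.random.default_rng(0)  # dropout stream, reseeded by owner

        h = hidden_size
        bound = 1.0 / np.sqrt(h)
        for layer in range(num_layers):
            in_f = input_size if layer == 0 else h * self.n_dir
            for d in range(self.n_dir):
                names = _LSTMCellParams(layer, d)
                self.params[names.w_ih] = _uniform(rng, bound, (4 * h, in_f))
                self.params[names.w_hh] = _uniform(rng, bound, (4 * h, h))
                self.params[names.b_ih] = _uniform(rng, bound, (4 * h,))
                self.params[names.b_hh] = _uniform(rng, bound, (4 * h,))
                # forget-gate bias starts at 1: keeps the cell path open at
                # initialization, which markedly speeds up early training
                self.params[names.b_ih][h:2 * h] = 1.0
                self.params[names.b_hh][h:2 * h] = 0.0
        self.zero_grad()
        self._cache = None

    def _run_direction(self, x: np.ndarray, names: _LSTMCellParams, reverse: bool):
        """x: (B, T, in) -> h_seq (B, T, H) plus caches for BPTT."""
        b, t, _ = x.shape
        h = self.hidden_size
        w_ih = self.params[names.w_ih]
        w_hh = self.params[names.w_hh]
        bias = self.params[names.b_ih] + self.params[names.b_hh]
        pre = x @ w_ih.T + bias  # (B, T, 4H), the non-recurrent part
        order = range(t - 1, -1, -1) if reverse else range(t)
        h_t = np.zeros((b, h), dtype=F32)
        c_t = np.zeros((b, h), dtype=F32)
        gates = np.empty((t, b, 4 * h), dtype=F32)  # post-activation i,f,g,o
        cells = np.empty((t, b, h), dtype=F32)
        tanhc = np.empty((t, b, h), dtype=F32)
        hs = np.empty((t, b, h), dtype=F32)
        hprev = np.empty((t, b, h), dtype=F32)
        for step in order:
            a = pre[:, step] + h_t @ w_hh.T
            i = _sigmoid(a[:, :h])
            f = _sigmoid(a[:, h:2 * h])
            g = np.tanh(a[:, 2 * h:3 * h])
            o = _sigmoid(a[:, 3 * h:])
            hprev[step] = h_t
            c_prev = c_t
            c_t = f * c_prev + i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            gates[step, :, :h] = i
            gates[step, :, h:2 * h] = f
            gates[step, :, 2 * h:3 * h] = g
            gates[step, :, 3 * h:] = o
            cells[step] = c_prev
            tanhc[step] = tc
            hs[step] = h_t
        h_seq = hs.transpose(1, 0, 2)
        cache = (x, gates, cells, tanhc, hprev, reverse)
        return h_seq, cache

    def _backward_direction(self, dh_seq: np.ndarray, names: _LSTMCellParams, cache):
        x, gates, cells, tanhc, hprev, reverse = cache
        b, t, _ = x.shape
        h = self.hidden_size
        w_ih = self.params[names.w_ih]
        w_hh = self.params[names.w_hh]
        order = range(t) if reverse else range(t - 1, -1, -1)
        dh_next = np.zeros((b, h), dtype=F32)
        dc_next = np.zeros((b, h), dtype=F32)
        da_all = np.empty((t, b, 4 * h), dtype=F32)
        dw_hh = np.zeros_like(w_hh)
        for step in order:
            i = gates[step, :, :h]
            f = gates[step, :, h:2 * h]
            g = gates[step, :, 2 * h:3 * h]
            o = gates[step, :, 3 * h:]
            tc = tanhc[step]
            dh = dh_seq[:, step] + dh_next
            dc = dc_next + dh * o * (1 - tc * tc)
            da = np.empty((b, 4 * h), dtype=F32)
            da[:, :h] = dc * g * i * (1 - i)
            da[:, h:2 * h] = dc * cells[step] * f * (1 - f)
            da[:, 2 * h:3 * h] = dc * i * (1 - g * g)
            da[:, 3 * h:] = dh * tc * o * (1 - o)
            da_all[step] = da
            dw_hh += da.T @ hprev[step]
            dh_next = da @ w_hh
            dc_next = dc * f
        da_flat = da_all.transpose(1, 0, 2).reshape(b * t, 4 * h)
        x_flat = x.reshape(b * t, -1)
        self.grads[names.w_ih] += da_flat.T @ x_flat
        self.grads[names.w_hh] += dw_hh
        dbias = da_flat.sum(axis=0)
        self.grads[names.b_ih] += dbias
        self.grads[names.b_hh] += dbias
        dx = (da_flat @ w_ih).reshape(b, t, -1)
        return dx

    def forward(self, x: np.ndarray) -> np.ndarray:
        caches = []
        drop_masks = []
        out = x.astype(F32)
        for layer in range(self.num_layers):
            hs = []
            layer_caches = []
            for d in range(self.n_dir):
                names = _LSTMCellParams(layer, d)
                h_seq, cache = self._run_direction(out, names, reverse=bool(d))
                hs.append(h_seq)
                layer_caches.append(cache)
            out = np.concatenate(hs, axis=-1) if self.n_dir == 2 else hs[0]
            caches.append(layer_caches)
            if self.training and self.dropout > 0 and layer < self.num_layers - 1:
                mask = (self.rng.random(out.shape) >= self.dropout).astype(F32)
                mask /= (1 - self.dropout)
                out = out * mask
                drop_masks.append(mask)
            else:
                drop_masks.append(None)
        self._cache = (caches, drop_masks) if self.training else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        caches, drop_masks = self._cache
        h = self.hidden_size
        d = dout
        for layer in range(self.num_layers - 1, -1, -1):
            if drop_masks[layer] is not None:
                d = d * drop_masks[layer]
            dx_total = None
            for di in range(self.n_dir):
                names = _LSTMCellParams(layer, di)
                dh_seq = d[:, :, di * h:(di + 1) * h]
                dx = self._backward_direction(dh_seq, names, caches[layer][di])
                dx_total = dx if dx_total is None else dx_total + dx
            d = dx_total
        self._cache = None
        return d
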