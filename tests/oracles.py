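"""Independent brute-force oracles used across the test suite.

Everything here is written with explicit Python loops and ``math``
functions, deliberately sharing no code path with the package, so that
agreement between the two is meaningful.
"""

import math


def rms_windows_oracle(signal, N, offset):
    """Per-window RMS via a double loop; window h (1-based) covers samples
    (h-1)*N + offset + 1 .. h*N + offset."""
    signal = list(signal)
    n_win = (len(signal) - offset) // N
    out = []
    for h in range(1, n_win + 1):
        acc = 0.0
        for i in range((h - 1) * N + offset + 1, h * N + offset + 1):  # 1-based
            acc += signal[i - 1] ** 2
        out.append(math.sqrt(acc / N))
    return out


def subsample_angle_oracle(angle, lag):
    angle = list(angle)
    n = (len(angle) - lag) // 2
    out = []
    for h in range(1, n + 1):
        i0 = 2 * (h - 1) + lag + 1  # 1-based first sample
        out.append((angle[i0 - 1] + angle[i0]) / 2.0)
    return out


def _sig(z):
    return 1.0 / (1.0 + math.exp(-z))


def lstm_cell_oracle(x, h_prev, c_prev, w):
    """Scalar-by-scalar transcription of the gated cell update.

    ``w`` is a dict of nested lists: U_f/U_i/U_c/U_o [H][D],
    W_f/W_i/W_c/W_o [H][H], b_f/b_i/b_c/b_o [H].
    """
    H = len(w["b_f"])
    D = len(x)

    def gate(name, squash):
        out = []
        for j in range(H):
            z = w[f"b_{name}"][j]
            for jj in range(H):
                z += w[f"W_{name}"][j][jj] * h_prev[jj]
            for d in range(D):
                z += w[f"U_{name}"][j][d] * x[d]
            out.append(squash(z))
        return out

    f = gate("f", _sig)
    i = gate("i", _sig)
    cc = gate("c", math.tanh)
    o = gate("o", _sig)
    c = [f[j] * c_prev[j] + i[j] * cc[j] for j in range(H)]
    h = [o[j] * math.tanh(c[j]) for j in range(H)]
    return {"f": f, "i": i, "c_candidate": cc, "o": o, "c": c, "h": h}


def bpnn_forward_oracle(x, W_in, b_in, W_out, b_out, sigmoid_output=True):
    """Scalar transcription of tansig hidden layer + printed output form."""
    H = len(b_in)
    z = []
    for j in range(H):
        a = b_in[j]
        for d in range(len(x)):
            a += W_in[j][d] * x[d]
        z.append(2.0 / (1.0 + math.exp(-2.0 * a)) - 1.0)
    u = sum(W_out[j] * z[j] for j in range(H))
    if sigmoid_output:
        return 1.0 / (1.0 + math.exp(-u)) + b_out
    return u + b_out


def rmse_oracle(est, act):
    acc = 0.0
    for e, a in zip(est, act):
        acc += (e - a) ** 2
    return math.sqrt(acc / len(est))


def rho_oracle(est, act):
    """Two-pass Pearson correlation."""
    n = len(est)
    me = sum(est) / n
    ma = sum(act) / n
    num = sum((a - ma) * (e - me) for e, a in zip(est, act)) / n
    ve = math.sqrt(sum((e - me) ** 2 for e in est) / n)
    va = math.sqrt(sum((a - ma) ** 2 for a in act) / n)
    return num / (ve * va)


def xcorr_lag_oracle(env, ang, fs, max_lag):
    """Brute-force integer-lag scan maximizing the Pearson correlation of
    env[i] with ang[i - lag]; returns the best lag in seconds."""
    best_lag, best_r = 0, -float("inf")
    n = min(len(env), len(ang))
    env, ang = list(env[:n]), list(ang[:n])
    for lag in range(-max_lag, max_lag + 1):
        if lag < 0:
            e, a = env[:lag], ang[-lag:]
        elif lag > 0:
            e, a = env[lag:], ang[:-lag]
        else:
            e, a = env, ang
        r = rho_oracle(e, a)
        if r > best_r:
            best_r, best_lag = r, lag
    return best_lag / fs
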