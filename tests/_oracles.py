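"""Independent, loop-based reference implementations used as test oracles.

Everything here is written with explicit scalar loops and python's math
module, deliberately sharing no code path with the package, so that
agreement between the two is evidence of correctness rather than of a
shared bug.
"""

import math

import numpy as np


def mscn_oracle(img, radius=3, sigma=7.0 / 6.0):
    """MSCN field by direct windowed sums on a symmetric-padded image."""
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    coords = range(-radius, radius + 1)
    weights = {}
    total = 0.0
    for k in coords:
        for l in coords:
            wt = math.exp(-(k * k + l * l) / (2.0 * sigma * sigma))
            weights[(k, l)] = wt
            total += wt
    for key in weights:
        weights[key] /= total

    padded = np.pad(img, radius, mode="symmetric")
    mu = np.zeros((h, w))
    sd = np.zeros((h, w))
    for m in range(h):
        for n in range(w):
            acc = 0.0
            for (k, l), wt in weights.items():
                acc += wt * padded[m + radius + k, n + radius + l]
            mu[m, n] = acc
            acc2 = 0.0
            for (k, l), wt in weights.items():
                d = padded[m + radius + k, n + radius + l] - acc
                acc2 += wt * d * d
            sd[m, n] = math.sqrt(max(acc2, 0.0))
    return (img - mu) / (sd + 1.0), mu, sd


def products_oracle(mscn):
    """Neighbour-product fields by direct index evaluation."""
    m = np.asarray(mscn, dtype=float)
    rows, cols = m.shape
    H1 = np.array([[m[i, j] * m[i, j + 1] for j in range(cols - 1)] for i in range(rows)])
    V1 = np.array([[m[i, j] * m[i + 1, j] for j in range(cols)] for i in range(rows - 1)])
    D1 = np.array([[m[i, j] * m[i + 1, j + 1] for j in range(cols - 1)] for i in range(rows - 1)])
    D2 = np.array([[m[i, j] * m[i + 1, j - 1] for j in range(1, cols)] for i in range(rows - 1)])
    return {"H1": H1, "V1": V1, "D1": D1, "D2": D2}


def mirror_products_oracle(mscn):
    """The four opposite orientations (left, up, both back-diagonals)."""
    m = np.asarray(mscn, dtype=float)
    rows, cols = m.shape
    H2 = np.array([[m[i, j] * m[i, j - 1] for j in range(1, cols)] for i in range(rows)])
    V2 = np.array([[m[i, j] * m[i - 1, j] for j in range(cols)] for i in range(1, rows)])
    D3 = np.array([[m[i, j] * m[i - 1, j - 1] for j in range(1, cols)] for i in range(1, rows)])
    D4 = np.array([[m[i, j] * m[i - 1, j + 1] for j in range(cols - 1)] for i in range(1, rows)])
    return {"H2": H2, "V2": V2, "D3": D3, "D4": D4}


def _rho(alpha):
    return math.gamma(1.0 / alpha) * math.gamma(3.0 / alpha) / math.gamma(2.0 / alpha) ** 2


def ggd_oracle(samples, lo=0.2, hi=10.0, step=0.001):
    """GGD moment-matching fit with a scalar grid scan."""
    x = [float(v) for v in np.ravel(samples)]
    n = len(x)
    sigma2 = sum(v * v for v in x) / n
    mean_abs = sum(abs(v) for v in x) / n
    target = sigma2 / (mean_abs * mean_abs)
    best_alpha, best_err = None, None
    k = 0
    while True:
        alpha = lo + k * step
        if alpha > hi + step / 2:
            break
        err = (_rho(alpha) - target) ** 2
        if best_err is None or err < best_err:
            best_alpha, best_err = alpha, err
        k += 1
    return best_alpha, sigma2


def aggd_oracle(samples, lo=0.2, hi=10.0, step=0.001):
    """AGGD moment-matching fit with a scalar grid scan."""
    x = [float(v) for v in np.ravel(samples)]
    n = len(x)
    neg = [v for v in x if v < 0]
    pos = [v for v in x if v > 0]
    sigma_l = math.sqrt(sum(v * v for v in neg) / len(neg)) if neg else 0.0
    sigma_r = math.sqrt(sum(v * v for v in pos) / len(pos)) if pos else 0.0
    gamma_hat = sigma_l / sigma_r
    r_hat = (sum(abs(v) for v in x) / n) ** 2 / (sum(v * v for v in x) / n)
    r_norm = (
        r_hat
        * (gamma_hat**3 + 1.0)
        * (gamma_hat + 1.0)
        / (gamma_hat**2 + 1.0) ** 2
    )
    best_nu, best_err = None, None
    k = 0
    while True:
        nu = lo + k * step
        if nu > hi + step / 2:
            break
        err = (1.0 / _rho(nu) - r_norm) ** 2
        if best_err is None or err < best_err:
            best_nu, best_err = nu, err
        k += 1
    conv = math.sqrt(math.gamma(1.0 / best_nu) / math.gamma(3.0 / best_nu))
    eta = (
        (sigma_r * conv - sigma_l * conv)
        * math.gamma(2.0 / best_nu)
        / math.gamma(1.0 / best_nu)
    )
    return best_nu, eta, sigma_l**2, sigma_r**2


def aggd_sample(nu, sigma_l, sigma_r, n, rng):
    """Draw AGGD variates by inverse-CDF-style composition.

    A side is chosen with probability proportional to its scale βl or
    βr; the magnitude on that side is β·G^(1/ν) with G ~ Gamma(1/ν, 1),
    which is exactly the one-sided generalized Gaussian law.
    """
    conv = math.sqrt(math.gamma(1.0 / nu) / math.gamma(3.0 / nu))
    beta_l, beta_r = sigma_l * conv, sigma_r * conv
    left = rng.random(n) < beta_l / (beta_l + beta_r)
    mag = rng.gamma(1.0 / nu, 1.0, size=n) ** (1.0 / nu)
    return np.where(left, -beta_l * mag, beta_r * mag)
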