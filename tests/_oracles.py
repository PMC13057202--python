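"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (dict accumulation, per-row loops)
kept separate from the package code paths they check.
"""

import math

import numpy as np


def glcm_oracle(image, levels, offsets, symmetric=True):
    """Whole-image GLCM metrics by explicit pair enumeration into a dict."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi > lo:
        q = np.clip(np.floor((image - lo) / (hi - lo) * levels), 0, levels - 1)
    else:
        q = np.zeros_like(image)
    q = q.astype(int)
    H, W = q.shape
    counts: dict[tuple[int, int], float] = {}
    for dr, dc in offsets:
        for i in range(H):
            for j in range(W):
                i2, j2 = i + dr, j + dc
                if 0 <= i2 < H and 0 <= j2 < W:
                    pairs = [(q[i, j], q[i2, j2])]
                    if symmetric:
                        pairs.append((q[i2, j2], q[i, j]))
                    for key in pairs:
                        counts[key] = counts.get(key, 0.0) + 1.0
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    con = sum(pv * (a - b) ** 2 for (a, b), pv in p.items())
    dis = sum(pv * abs(a - b) for (a, b), pv in p.items())
    hom = sum(pv / (1 + (a - b) ** 2) for (a, b), pv in p.items())
    asm = sum(pv**2 for pv in p.values())
    ent = -sum(pv * math.log(pv) for pv in p.values() if pv > 0)
    pi: dict[int, float] = {}
    pj: dict[int, float] = {}
    for (a, b), pv in p.items():
        pi[a] = pi.get(a, 0.0) + pv
        pj[b] = pj.get(b, 0.0) + pv
    mui = sum(a * v for a, v in pi.items())
    muj = sum(b * v for b, v in pj.items())
    vari = sum((a - mui) ** 2 * v for a, v in pi.items())
    varj = sum((b - muj) ** 2 * v for b, v in pj.items())
    cov = sum((a - mui) * (b - muj) * pv for (a, b), pv in p.items())
    sig = math.sqrt(vari * varj)
    cor = cov / sig if sig > 0 else 0.0
    return dict(Con=con, Cor=cor, Dis=dis, Ent=ent, Hom=hom, Mean=mui,
                Asm=asm, Var=vari)


def quadratic_discriminant_oracle(X, class_params):
    """Per-row argmax of ln π − ½ln|Σ| − ½(x−μ)ᵀΣ⁻¹(x−μ), coded row by row."""
    X = np.atleast_2d(X)
    labels = []
    for x in X:
        best_label, best_g = None, -np.inf
        for label, mean, cov, prior in class_params:
            mean = np.atleast_1d(mean)
            cov = np.atleast_2d(cov)
            sign, logdet = np.linalg.slogdet(cov)
            diff = x - mean
            g = (
                math.log(prior)
                - 0.5 * logdet
                - 0.5 * float(diff @ np.linalg.solve(cov, diff))
            )
            if g > best_g:  # strict: first max wins ties (lowest class index)
                best_g, best_label = g, label
        labels.append(best_label)
    return np.array(labels)


def ols_normal_equations(X, y):
    """OLS coefficients [intercept, slopes] via explicit normal equations."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = np.column_stack([np.ones(len(X)), X])
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(y, dtype=float))


def idw_predict_oracle(xy, z, query, power, n_points):
    """IDW at one query point by explicit sorting and weighting."""
    d = np.sqrt(((xy - query) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:n_points]
    if d[order[0]] < 1e-9:
        return z[order[0]]
    w = d[order] ** (-power)
    return float((w * z[order]).sum() / w.sum())
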