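"""Independent brute-force evaluators used as test oracles.

These deliberately re-derive the windowed features and the AUC from their
definitions with plain Python loops, staying independent of the library
code paths they are used to check.
"""

import numpy as np


def brute_force_features(bg, t, weight, hr=None):
    """Loop evaluation of the window features, straight from the definitions."""
    bg = [float(x) for x in bg]
    t = [float(x) for x in t]
    dt = t[1] - t[0]
    out = {"w": float(weight), "d": bg[14] - bg[0]}
    for i in range(14):
        out[f"dp{i}"] = bg[i + 1] - bg[i]
    for i in range(3):
        acc = 0.0
        for j in range(4):
            acc += bg[5 * i + j + 1] - bg[5 * i + j]
        out[f"dpp{i}"] = acc
    out["v"] = (bg[14] - bg[0]) / (t[14] - t[0])
    for i in range(14):
        out[f"vp{i}"] = (bg[i + 1] - bg[i]) / (t[i + 1] - t[i])
    for i in range(3):
        out[f"vpp{i}"] = out[f"dpp{i}"] / (t[5 * i + 4] - t[5 * i])
    for i in range(13):
        out[f"ap{i}"] = (bg[i + 2] - bg[i]) / (t[i + 2] - t[i]) ** 2
    if hr is not None:
        hr = [float(x) for x in hr]
        out["hr"] = hr[14]
        out["hrp"] = hr[14] - hr[13]
    return out


def concordance_auc(y_true, scores):
    """AUC as the Mann-Whitney concordance probability over all +/- pairs."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
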