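"""Independent brute-force oracles for the classifier and the spatial
operators. Deliberately naive (explicit Python loops, no scipy.ndimage, no
vectorized shortcuts shared with the implementation)."""

import math

import numpy as np


def mlc_brute_force(unit_pixels, stats, class_ids, eps=1e-6):
    """Per-pixel argmax of the Gaussian log-discriminant, evaluated one
    pixel and one class at a time with plain linear algebra."""
    h, w, _ = unit_pixels.shape
    k = len(class_ids)
    out = np.zeros((h, w), dtype=np.int64)
    prior = 1.0 / k
    prepared = {}
    for cid in class_ids:
        cov = np.array(stats.cov[cid], dtype=float)
        if np.linalg.matrix_rank(cov) < 3:
            ridge = eps * np.trace(cov) / 3.0
            if ridge <= 0:
                ridge = eps
            cov = cov + ridge * np.eye(3)
        prepared[cid] = (np.array(stats.mean[cid], dtype=float),
                         np.linalg.inv(cov),
                         math.log(np.linalg.det(cov)))
    for r in range(h):
        for c in range(w):
            x = unit_pixels[r, c]
            best, best_g = None, -np.inf
            for cid in class_ids:
                mean, inv, logdet = prepared[cid]
                d = x - mean
                g = math.log(prior) - 0.5 * logdet - 0.5 * float(d @ inv @ d)
                if g > best_g:  # strict: ties keep the lowest class id
                    best, best_g = cid, g
            out[r, c] = best
    return out


def majority_vote_brute_force(labels, kernel, center_weight):
    """Exhaustive windowed vote with the centre-keeps-on-tie rule."""
    h, w = labels.shape
    half = kernel // 2
    out = np.empty_like(labels)
    for r in range(h):
        for c in range(w):
            votes = {}
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w:
                        lab = labels[rr, cc]
                        weight = center_weight if (dr, dc) == (0, 0) else 1
                        votes[lab] = votes.get(lab, 0) + weight
            best = max(votes.values())
            center = labels[r, c]
            if votes.get(center, 0) == best:
                out[r, c] = center
            else:
                out[r, c] = min(lab for lab, v in votes.items() if v == best)
    return out


def flood_fill_components(labels, connectivity):
    """Connected components per nonzero class via iterative flood fill.

    Returns a list of (class_label, set of (row, col)) components.
    """
    h, w = labels.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    seen = np.zeros((h, w), dtype=bool)
    components = []
    for r in range(h):
        for c in range(w):
            if seen[r, c] or labels[r, c] == 0:
                continue
            lab = labels[r, c]
            stack, pixels = [(r, c)], set()
            seen[r, c] = True
            while stack:
                pr, pc = stack.pop()
                pixels.add((pr, pc))
                for dr, dc in steps:
                    nr, nc = pr + dr, pc + dc
                    if (0 <= nr < h and 0 <= nc < w and not seen[nr, nc]
                            and labels[nr, nc] == lab):
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            components.append((lab, pixels))
    return components


def sieve_brute_force(labels, connectivity, min_size):
    out = labels.copy()
    for lab, pixels in flood_fill_components(labels, connectivity):
        if len(pixels) < min_size:
            for r, c in pixels:
                out[r, c] = 0
    return out


def _shift_or(mask, size):
    """Dilation by a size x size square via explicit shifts."""
    h, w = mask.shape
    half_lo = (size - 1) // 2
    half_hi = size // 2
    out = np.zeros_like(mask)
    for dr in range(-half_hi, half_lo + 1):
        for dc in range(-half_hi, half_lo + 1):
            src = mask[max(0, -dr):h - max(0, dr),
                       max(0, -dc):w - max(0, dc)]
            out[max(0, dr):h - max(0, -dr),
                max(0, dc):w - max(0, -dc)] |= src
    return out


def closing_brute_force(mask, size):
    """Dilate-then-erode with a square element, background-padded, built
    from shift unions only (erosion as the complement of a dilation)."""
    pad = size
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    dil = _shift_or(padded, size)
    # erosion of X = complement of dilation of complement with the
    # reflected element; the square element is symmetric under reflection
    # only for odd sizes, so reflect explicitly
    comp = ~dil
    h, w = comp.shape
    refl = np.zeros_like(comp)
    half_lo = (size - 1) // 2
    half_hi = size // 2
    for dr in range(-half_lo, half_hi + 1):
        for dc in range(-half_lo, half_hi + 1):
            src = comp[max(0, -dr):h - max(0, dr),
                       max(0, -dc):w - max(0, dc)]
            refl[max(0, dr):h - max(0, -dr),
                 max(0, dc):w - max(0, -dc)] |= src
    ero = ~refl
    return ero[pad:-pad, pad:-pad]


def logistic(z):
    return 1.0 / (1.0 + math.exp(-z))


def nn_forward_by_hand(x, w1, b1, w2, b2):
    """Scalar-arithmetic forward pass through hidden and output layers."""
    hidden = []
    for j in range(w1.shape[1]):
        z = b1[j] + sum(x[i] * w1[i, j] for i in range(len(x)))
        hidden.append(logistic(z))
    outputs = []
    for k in range(w2.shape[1]):
        z = b2[k] + sum(hidden[j] * w2[j, k] for j in range(len(hidden)))
        outputs.append(logistic(z))
    return np.array(outputs)
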