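"""Label algebra for multi-target activity profiles.

An activity profile over ``n`` binary targets is handled in two forms:

* **combination-class (one-hot) mode** — the full profile is one of
  ``2**n`` classes, indexed by reading the binary vector left to right
  with the first target as the most significant bit (so ``[0,1,1,0,1]``
  is class 13 for five targets).  The all-negative profile is class 0.
* **multi-label mode** — each target is an independent binary output
  (the convention used for the 12-pathway toxicity formulation).

A *partial* label stores ``MISSING`` (-1) where no measurement exists.
Completing a partial label against a teacher's predicted class
distribution restricts that distribution to the classes consistent with
the observed entries and renormalises it to sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1

#: combination-class mode refuses more targets than this (2**n blow-up)
MAX_ONEHOT_TARGETS = 16


@dataclass
class MixupConfig:
    """Mixup noise settings: coefficients are drawn from Beta(alpha, alpha)."""

    alpha: float = 0.4
    enabled: bool = True

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError(f"mixup alpha must be > 0, got {self.alpha}")


def _as_label_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.int64).ravel()
    bad = ~np.isin(arr, (0, 1, MISSING))
    if bad.any():
        raise ValueError(f"label entries must be 0, 1 or MISSING; got {arr[bad]}")
    return arr


def n_classes(n_targets: int) -> int:
    if n_targets > MAX_ONEHOT_TARGETS:
        raise ValueError(
            f"one-hot combination mode supports at most {MAX_ONEHOT_TARGETS} "
            f"targets (2**n classes); got {n_targets}"
        )
    return 1 << n_targets


def encode_full_label(binary) -> int:
    """Class index of a fully observed binary profile (first target = MSB)."""
    arr = _as_label_array(binary)
    if (arr == MISSING).any():
        raise ValueError("label has missing entries; use enumerate_candidates")
    n_classes(arr.size)
    idx = 0
    for b in arr:
        idx = (idx << 1) | int(b)
    return idx


def decode_class(class_index: int, n_targets: int) -> np.ndarray:
    """Binary profile for a class index; exact inverse of encode_full_label."""
    total = n_classes(n_targets)
    if not 0 <= class_index < total:
        raise ValueError(f"class index {class_index} out of range [0, {total})")
    return np.array(
        [(class_index >> (n_targets - 1 - i)) & 1 for i in range(n_targets)],
        dtype=np.int64,
    )


def enumerate_candidates(partial) -> np.ndarray:
    """All class indices consistent with the observed entries, ascending.

    With ``m`` missing positions there are exactly ``2**m`` candidates.
    """
    arr = _as_label_array(partial)
    n = arr.size
    n_classes(n)
    missing = np.flatnonzero(arr == MISSING)
    base = arr.copy()
    base[missing] = 0
    base_idx = encode_full_label(base)
    # bit weight of each missing position under MSB-first encoding
    weights = [1 << (n - 1 - int(pos)) for pos in missing]
    cands = []
    for mask in range(1 << len(missing)):
        idx = base_idx
        for j, w in enumerate(weights):
            if (mask >> j) & 1:
                idx += w
        cands.append(idx)
    return np.array(sorted(cands), dtype=np.int64)


def complete_partial_label(partial, teacher_probs) -> np.ndarray:
    """Teacher distribution restricted to the candidate classes, renormalised.

    Entries outside the candidate set are zero.  If the teacher assigns
    zero mass to every candidate the completion falls back to a uniform
    distribution over the candidates (logged).
    """
    arr = _as_label_array(partial)
    total = n_classes(arr.size)
    probs = np.asarray(teacher_probs, dtype=np.float64).ravel()
    if probs.size != total:
        raise ValueError(f"teacher output length {probs.size}, expected {total}")
    if (probs < 0).any():
        raise ValueError("teacher probabilities must be non-negative")
    cands = enumerate_candidates(arr)
    out = np.zeros(total, dtype=np.float64)
    mass = probs[cands].sum()
    if mass > 0:
        out[cands] = probs[cands] / mass
    else:
        logger.warning(
            "teacher assigned zero mass to all %d candidate classes; "
            "falling back to uniform", cands.size,
        )
        out[cands] = 1.0 / cands.size
    return out


def complete_partial_multilabel(partial, per_target_probs) -> np.ndarray:
    """Multi-label completion: each missing target takes the teacher's
    per-target probability; observed targets keep their hard value."""
    arr = _as_label_array(partial)
    probs = np.asarray(per_target_probs, dtype=np.float64).ravel()
    if probs.size != arr.size:
        raise ValueError(f"teacher output length {probs.size}, expected {arr.size}")
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("per-target probabilities must lie in [0, 1]")
    out = arr.astype(np.float64)
    miss = arr == MISSING
    out[miss] = probs[miss]
    return out


def one_hot(class_index: int, n_targets: int) -> np.ndarray:
    """Hard one-hot distribution over the 2**n combination classes."""
    total = n_classes(n_targets)
    if not 0 <= class_index < total:
        raise ValueError(f"class index {class_index} out of range [0, {total})")
    v = np.zeros(total, dtype=np.float64)
    v[class_index] = 1.0
    return v


def mixup_pair(x_i, y_i, x_j, y_j, lam: float):
    """Convex combination x~ = lam*x_i + (1-lam)*x_j and likewise for y."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    y_i = np.asarray(y_i, dtype=np.float64)
    y_j = np.asarray(y_j, dtype=np.float64)
    if x_i.shape != x_j.shape:
        raise ValueError(f"input shape mismatch {x_i.shape} vs {x_j.shape}")
    if y_i.shape != y_j.shape:
        raise ValueError(f"label shape mismatch {y_i.shape} vs {y_j.shape}")
    return lam * x_i + (1.0 - lam) * x_j, lam * y_i + (1.0 - lam) * y_j


def sample_lambda(config: MixupConfig, rng: np.random.Generator) -> float:
    if not config.alpha > 0:
        raise ValueError("mixup alpha must be > 0")
    return float(rng.beta(config.alpha, config.alpha))
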