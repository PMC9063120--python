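"""Partially-LAbeled Noisy Student (PLANS) training.

The loop: a Small MLP teacher is trained on the fully labeled training
split only; the teacher then pseudo-labels the partially labeled pool
(candidate-restricted completion) and the unlabeled pool (its full soft
class distribution); a larger *noisy* student (dropout + optional mixup)
is trained on the union; the student becomes the next teacher.  The
staged tiers are Small -> Medium -> Large; optional extra rounds repeat
the Large tier until the validation metric stops improving.  Noise is
active only while training students — teachers always run inference with
dropout and mixup off.  Class balancing, when enabled, re-adds
pseudo-labeled unlabeled rows per class until each class reaches the
all-negative class count, never adding pseudo all-negative rows, and is
redone from scratch whenever a new teacher is promoted.

Labels use the combination-class (one-hot over 2**n classes) formulation
by default; a per-target sigmoid multi-label mode is available for
datasets framed as independent binary tasks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from . import labels as L
from . import evaluation

logger = logging.getLogger(__name__)

TIERS = ("Small", "Medium", "Large")


# ---------------------------------------------------------------------------
# Architecture specs


@dataclass
class MLPSpec:
    tier: str
    input_len: int
    hidden_widths: list[int]
    dropout_rate: float
    output_dim: int


def _small_widths(L_in: int) -> list[int]:
    return [2 * L_in, 4 * L_in, 4 * L_in, 2 * L_in, L_in, L_in // 2, L_in // 4]


def build_mlp_spec(tier: str, input_len: int, output_dim: int,
                   dropout_rate: float = 0.3) -> MLPSpec:
    """Hidden-width plan of a tier.

    Small: seven hidden layers of 2x, 4x, 4x, 2x, 1x, 0.5x and 0.25x the
    input length.  Medium adds a 3x layer after Small layers 1 and 3.
    Large additionally inserts two 6x layers after Small layer 2.
    """
    if input_len < 4:
        raise ValueError("input_len must be >= 4")
    small = _small_widths(input_len)
    if tier == "Small":
        widths = small
    elif tier == "Medium":
        widths = [small[0], 3 * input_len, small[1], small[2], 3 * input_len] + small[3:]
    elif tier == "Large":
        widths = [small[0], 3 * input_len, small[1],
                  6 * input_len, 6 * input_len,
                  small[2], 3 * input_len] + small[3:]
    else:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    return MLPSpec(tier, input_len, widths, dropout_rate, output_dim)


def parameter_count(spec: MLPSpec) -> int:
    dims = [spec.input_len, *spec.hidden_widths, spec.output_dim]
    return sum((a + 1) * b for a, b in zip(dims[:-1], dims[1:]))


# ---------------------------------------------------------------------------
# Configs and data containers


@dataclass
class TrainingConfig:
    split_ratio: float = 0.7
    mixup: L.MixupConfig = field(default_factory=L.MixupConfig)
    balancing: bool = False
    use_unlabeled: bool = True
    max_plans_rounds: int = 3
    repeats: int = 5
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 5
    validation_fraction: float = 0.1
    dropout_rate: float = 0.3
    label_mode: str = "onehot"   # or "multilabel"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.label_mode not in ("onehot", "multilabel"):
            raise ValueError("label_mode must be 'onehot' or 'multilabel'")


@dataclass
class DatasetBundle:
    """Feature matrices for the three pools.

    ``y_full`` is the complete binary target matrix of the fully labeled
    pool; ``y_partial`` uses MISSING (-1) for unobserved cells.  The test
    split is always drawn from the fully labeled pool — partial and
    unlabeled rows are used for training only.
    """

    X_full: np.ndarray
    y_full: np.ndarray
    X_partial: np.ndarray
    y_partial: np.ndarray
    X_unlabeled: np.ndarray
    feature_kind: str = "ECFP"

    def __post_init__(self):
        self.X_full = np.asarray(self.X_full, dtype=nn.DTYPE)
        self.X_partial = np.asarray(self.X_partial, dtype=nn.DTYPE)
        self.X_unlabeled = np.asarray(self.X_unlabeled, dtype=nn.DTYPE)
        dims = {m.shape[1] for m in (self.X_full, self.X_partial, self.X_unlabeled)
                if m.size}
        if len(dims) > 1:
            raise ValueError(f"feature lengths differ across pools: {dims}")

    @property
    def n_targets(self) -> int:
        return self.y_full.shape[1]

    @property
    def input_len(self) -> int:
        return self.X_full.shape[1]


@dataclass
class TrainedModel:
    spec: MLPSpec
    net: nn.MLPNet
    history: dict
    role: str = "student"
    label_mode: str = "onehot"
    n_targets: int = 5

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Noise-free inference: soft class distribution (one-hot mode) or
        per-target sigmoid probabilities (multi-label mode)."""
        X = np.asarray(X, dtype=nn.DTYPE)
        if X.shape[1] != self.spec.input_len:
            raise ValueError(
                f"feature length {X.shape[1]} != model input {self.spec.input_len}")
        logits = self.net.forward(X, train=False)
        if self.label_mode == "onehot":
            return nn.softmax(logits.astype(np.float64))
        return nn.sigmoid(logits.astype(np.float64))


def predict(model: TrainedModel, X: np.ndarray):
    """Soft predictions plus the decoded per-target binary matrix.

    One-hot mode: hard class = argmax (lowest index wins ties), decoded
    through the combination-class inverse.  Multi-label mode: per-target
    threshold at 0.5.  Returns ``(probs, hard_classes, binary_matrix)``;
    ``hard_classes`` is None in multi-label mode.
    """
    probs = model.predict_proba(X)
    if model.label_mode == "onehot":
        hard = probs.argmax(axis=1)
        binary = np.vstack([L.decode_class(int(c), model.n_targets) for c in hard])
        return probs, hard, binary
    return probs, None, (probs >= 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# Core fitting


def _fit_mlp(spec: MLPSpec, X, Y, config: TrainingConfig, seed: int,
             noisy: bool, X_val=None, Y_val=None) -> TrainedModel:
    rng = np.random.default_rng(seed)
    dims = [spec.input_len, *spec.hidden_widths, spec.output_dim]
    net = nn.MLPNet(dims, rng, dropout_rate=spec.dropout_rate if noisy else 0.0)
    adam = nn.Adam(net.parameters(), lr=config.learning_rate)
    loss_fn = (nn.softmax_cross_entropy if config.label_mode == "onehot"
               else nn.sigmoid_bce)
    X = np.asarray(X, dtype=nn.DTYPE)
    Y = np.asarray(Y, dtype=nn.DTYPE)
    use_mixup = noisy and config.mixup.enabled
    history = {"train_loss": [], "val_loss": []}
    best_loss, best_state, since_best = np.inf, None, 0
    have_val = X_val is not None and len(X_val) > 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(X))
        total, seen = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            xb, yb = X[sel], Y[sel]
            if use_mixup and len(sel) > 1:
                lam = rng.beta(config.mixup.alpha, config.mixup.alpha,
                               size=len(sel)).astype(nn.DTYPE)
                pair = rng.permutation(len(sel))
                xb = lam[:, None] * xb + (1 - lam)[:, None] * xb[pair]
                yb = lam[:, None] * yb + (1 - lam)[:, None] * yb[pair]
            logits = net.forward(xb, train=noisy, rng=rng)
            loss, dlogits = loss_fn(logits, yb)
            net.backward(dlogits)
            adam.step()
            total += loss * len(sel)
            seen += len(sel)
        history["train_loss"].append(total / max(seen, 1))
        if have_val:
            val_logits = net.forward(np.asarray(X_val, dtype=nn.DTYPE), train=False)
            val_loss, _ = loss_fn(val_logits, np.asarray(Y_val, dtype=nn.DTYPE))
        else:
            val_loss = history["train_loss"][-1]
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss, since_best = val_loss, 0
            best_state = nn.snapshot(net.parameters())
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best_state is not None:
        nn.restore(net.parameters(), best_state)
    return TrainedModel(spec, net, history, label_mode=config.label_mode)


def _onehot_targets(y_binary: np.ndarray) -> np.ndarray:
    n_t = y_binary.shape[1]
    C = L.n_classes(n_t)
    out = np.zeros((y_binary.shape[0], C), dtype=nn.DTYPE)
    for i, row in enumerate(y_binary):
        out[i, L.encode_full_label(row)] = 1.0
    return out


def train_teacher(X, y_binary, config: TrainingConfig, seed: int | None = None,
                  tier: str = "Small", X_val=None, Y_val=None) -> TrainedModel:
    """Initial teacher: trained on fully labeled data only, noise off."""
    if len(X) == 0:
        raise ValueError("teacher training set is empty")
    if config.label_mode == "onehot":
        Y = _onehot_targets(np.asarray(y_binary))
        if len(np.unique(Y.argmax(axis=1))) == 1:
            logger.warning("teacher training set is single-class (degenerate)")
        out_dim = Y.shape[1]
    else:
        Y = np.asarray(y_binary, dtype=nn.DTYPE)
        out_dim = Y.shape[1]
    spec = build_mlp_spec(tier, X.shape[1], out_dim, config.dropout_rate)
    model = _fit_mlp(spec, X, Y, config, config.seed if seed is None else seed,
                     noisy=False, X_val=X_val, Y_val=Y_val)
    model.role = "teacher"
    model.n_targets = np.asarray(y_binary).shape[1]
    return model


def pseudo_label(teacher: TrainedModel, bundle: DatasetBundle):
    """Teacher-completed labels for the partial and unlabeled pools.

    Partial rows: the teacher's class distribution restricted to the
    candidate classes of the partial label (hard one-hot if nothing is
    missing).  Unlabeled rows: the teacher's full soft distribution.
    Returns ``(Y_partial_soft, Y_unlabeled_soft)`` (empty arrays when the
    corresponding pool is empty).
    """
    n_t = bundle.n_targets
    if teacher.label_mode == "onehot":
        C = L.n_classes(n_t)
        if len(bundle.X_partial):
            probs = teacher.predict_proba(bundle.X_partial)
            Yp = np.vstack([
                L.complete_partial_label(bundle.y_partial[i], probs[i])
                for i in range(len(bundle.X_partial))
            ])
        else:
            Yp = np.zeros((0, C))
        Yu = (teacher.predict_proba(bundle.X_unlabeled)
              if len(bundle.X_unlabeled) else np.zeros((0, C)))
    else:
        if len(bundle.X_partial):
            probs = teacher.predict_proba(bundle.X_partial)
            Yp = np.vstack([
                L.complete_partial_multilabel(bundle.y_partial[i], probs[i])
                for i in range(len(bundle.X_partial))
            ])
        else:
            Yp = np.zeros((0, n_t))
        Yu = (teacher.predict_proba(bundle.X_unlabeled)
              if len(bundle.X_unlabeled) else np.zeros((0, n_t)))
    return Yp, Yu


def balance_training_set(X_labeled, Y_labeled, X_pool, Y_pool):
    """Cap-balance with pseudo-labeled pool rows (one-hot mode).

    Pool rows whose argmax class is 0 (all-negative) are never added.
    Other classes receive pool rows, in pool order, until their count
    reaches the all-negative class count in the current labeled set.
    The original labeled rows are always kept.
    """
    X_labeled = np.asarray(X_labeled, dtype=nn.DTYPE)
    Y_labeled = np.asarray(Y_labeled)
    if len(X_pool) == 0:
        return X_labeled, Y_labeled
    C = Y_labeled.shape[1]
    counts = np.bincount(Y_labeled.argmax(axis=1), minlength=C)
    cap = counts[0]
    pool_classes = np.asarray(Y_pool).argmax(axis=1)
    keep = []
    for i, c in enumerate(pool_classes):
        if c != 0 and counts[c] < cap:
            keep.append(i)
            counts[c] += 1
    if not keep:
        return X_labeled, Y_labeled
    X_add = np.asarray(X_pool, dtype=nn.DTYPE)[keep]
    Y_add = np.asarray(Y_pool)[keep]
    return np.vstack([X_labeled, X_add]), np.vstack([Y_labeled, Y_add])


# ---------------------------------------------------------------------------
# The PLANS loop


@dataclass
class PlansResult:
    model: TrainedModel
    round_history: list[dict]
    test_report: "evaluation.MetricsReport"
    train_idx: np.ndarray
    test_idx: np.ndarray


def _split(n: int, config: TrainingConfig, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_train = int(round(config.split_ratio * n))
    n_train = min(max(n_train, 1), n - 1) if n > 1 else n
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    n_val = max(1, int(round(config.validation_fraction * len(train_idx))))
    val_idx, fit_idx = train_idx[:n_val], train_idx[n_val:]
    if fit_idx.size == 0:
        fit_idx = val_idx
    return fit_idx, val_idx, test_idx


def _evaluate_model(model: TrainedModel, X, y_binary) -> "evaluation.MetricsReport":
    probs, _, binary = predict(model, X)
    if model.label_mode == "onehot":
        scores = evaluation.per_target_scores(probs, model.n_targets)
    else:
        scores = probs
    return evaluation.score(binary, np.asarray(y_binary), scores=scores)


def run_plans(bundle: DatasetBundle, config: TrainingConfig) -> PlansResult:
    """One full PLANS run: split, staged teachers/students, final test scores.

    The fully labeled pool is split ``split_ratio : 1 - split_ratio`` into
    train and test; a validation slice of the training part drives early
    stopping.  The test split is never seen during training.
    """
    if len(bundle.X_full) == 0:
        raise ValueError("bundle has no fully labeled data")
    rng = np.random.default_rng(config.seed)
    fit_idx, val_idx, test_idx = _split(len(bundle.X_full), config, rng)
    X_fit, y_fit = bundle.X_full[fit_idx], bundle.y_full[fit_idx]
    X_val, y_val = bundle.X_full[val_idx], bundle.y_full[val_idx]
    if config.label_mode == "onehot":
        Y_fit, Y_val = _onehot_targets(y_fit), _onehot_targets(y_val)
    else:
        Y_fit = np.asarray(y_fit, dtype=nn.DTYPE)
        Y_val = np.asarray(y_val, dtype=nn.DTYPE)

    teacher = train_teacher(X_fit, y_fit, config, seed=config.seed,
                            X_val=X_val, Y_val=Y_val)
    teacher.n_targets = bundle.n_targets
    history = [{
        "round": 0, "tier": "Small",
        "val_micro_f1": _evaluate_model(teacher, X_val, y_val).micro_f1,
    }]

    tiers = ["Medium", "Large"]
    extra = max(0, config.max_plans_rounds - 3)
    tiers += ["Large"] * extra
    best_large_val = None
    for rnd, tier in enumerate(tiers, start=1):
        Yp, Yu = pseudo_label(teacher, bundle)
        X_train = [X_fit]
        Y_train = [Y_fit]
        if len(bundle.X_partial):
            X_train.append(bundle.X_partial)
            Y_train.append(Yp.astype(nn.DTYPE))
        X_cat = np.vstack(X_train)
        Y_cat = np.vstack(Y_train)
        if config.use_unlabeled and len(bundle.X_unlabeled):
            if config.balancing and config.label_mode == "onehot":
                # balancing is redone from scratch for every new teacher
                shuffle = rng.permutation(len(bundle.X_unlabeled))
                X_cat, Y_cat = balance_training_set(
                    X_cat, Y_cat, bundle.X_unlabeled[shuffle],
                    Yu.astype(nn.DTYPE)[shuffle])
            else:
                X_cat = np.vstack([X_cat, bundle.X_unlabeled])
                Y_cat = np.vstack([Y_cat, Yu.astype(nn.DTYPE)])
        spec = build_mlp_spec(tier, bundle.input_len, Y_cat.shape[1],
                              config.dropout_rate)
        student = _fit_mlp(spec, X_cat, Y_cat, config, config.seed + 1000 + rnd,
                           noisy=True, X_val=X_val, Y_val=Y_val)
        student.n_targets = bundle.n_targets
        val_f1 = _evaluate_model(student, X_val, y_val).micro_f1
        history.append({"round": rnd, "tier": tier, "val_micro_f1": val_f1,
                        "n_train_rows": int(len(X_cat))})
        student.role = "teacher"
        teacher = student
        if tier == "Large":
            # optional extra Large rounds stop as soon as the validation
            # metric fails to improve (patience 1)
            if best_large_val is not None and val_f1 <= best_large_val:
                break
            best_large_val = val_f1 if best_large_val is None else max(
                best_large_val, val_f1)
    teacher.role = "student"
    test_report = _evaluate_model(teacher, bundle.X_full[test_idx],
                                  bundle.y_full[test_idx])
    return PlansResult(teacher, history, test_report,
                       np.concatenate([fit_idx, val_idx]), test_idx)


def run_supervised_baseline(bundle: DatasetBundle, config: TrainingConfig,
                            tier: str = "Large") -> PlansResult:
    """Same split and seeds as run_plans, but the given tier is trained on
    the fully labeled training data only (no pseudo-labels)."""
    if len(bundle.X_full) == 0:
        raise ValueError("bundle has no fully labeled data")
    rng = np.random.default_rng(config.seed)
    fit_idx, val_idx, test_idx = _split(len(bundle.X_full), config, rng)
    X_fit, y_fit = bundle.X_full[fit_idx], bundle.y_full[fit_idx]
    X_val, y_val = bundle.X_full[val_idx], bundle.y_full[val_idx]
    if config.label_mode == "onehot":
        Y_fit, Y_val = _onehot_targets(y_fit), _onehot_targets(y_val)
    else:
        Y_fit = np.asarray(y_fit, dtype=nn.DTYPE)
        Y_val = np.asarray(y_val, dtype=nn.DTYPE)
    spec = build_mlp_spec(tier, bundle.input_len, Y_fit.shape[1],
                          config.dropout_rate)
    model = _fit_mlp(spec, X_fit, Y_fit, config, config.seed, noisy=True,
                     X_val=X_val, Y_val=Y_val)
    model.n_targets = bundle.n_targets
    test_report = _evaluate_model(model, bundle.X_full[test_idx],
                                  bundle.y_full[test_idx])
    return PlansResult(model, [], test_report,
                       np.concatenate([fit_idx, val_idx]), test_idx)


def repeat_plans(bundle: DatasetBundle, config: TrainingConfig,
                 baseline: bool = False) -> list[PlansResult]:
    """Repeat a run ``config.repeats`` times with fresh random splits."""
    import dataclasses

    results = []
    for r in range(config.repeats):
        cfg = dataclasses.replace(config, seed=config.seed + r)
        runner = run_supervised_baseline if baseline else run_plans
        results.append(runner(bundle, cfg))
    return results


# ---------------------------------------------------------------------------
# Checkpoints


def save_model(path, model: TrainedModel) -> None:
    arrays = {f"param_{i}": p for i, (p, _) in enumerate(model.net.parameters())}
    meta = {"spec": asdict(model.spec), "label_mode": model.label_mode,
            "n_targets": model.n_targets, "role": model.role}
    arrays["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_model(path) -> TrainedModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta_json"]))
    spec = MLPSpec(**meta["spec"])
    net = nn.MLPNet([spec.input_len, *spec.hidden_widths, spec.output_dim],
                    np.random.default_rng(0), dropout_rate=spec.dropout_rate)
    for i, (p, _) in enumerate(net.parameters()):
        p[...] = data[f"param_{i}"]
    return TrainedModel(spec, net, {}, role=meta["role"],
                        label_mode=meta["label_mode"], n_targets=meta["n_targets"])
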