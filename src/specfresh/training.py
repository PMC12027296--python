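"""Training loop, data splitting, classification metrics and the ablation
runner for the dual-branch network."""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grading import GRADE_VOCABULARY, HierarchyMap
from .model.network import DBHSNet, DBHSNetConfig, dynamic_weight
from .spectra_io import SpectrumSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvalCounts",
    "RunConfig",
    "TrainHistory",
    "split",
    "kfold",
    "train",
    "evaluate",
    "evaluate_predictions",
    "run_ablation",
]


@dataclass
class EvalCounts:
    """Per-class confusion counts: EP (tp), UP (fn), FAP (fp), EN (tn)."""

    classes: list
    confusion: np.ndarray  # rows true, cols predicted

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        if self.confusion.shape != (len(self.classes), len(self.classes)):
            raise ValueError("confusion matrix shape must be n_classes x n_classes")

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    @property
    def class_sizes(self) -> np.ndarray:
        return self.confusion.sum(axis=1)

    @property
    def ep(self) -> np.ndarray:
        return np.diag(self.confusion)

    @property
    def up(self) -> np.ndarray:
        return self.class_sizes - self.ep

    @property
    def fap(self) -> np.ndarray:
        return self.confusion.sum(axis=0) - self.ep

    @property
    def en(self) -> np.ndarray:
        return self.n - self.ep - self.up - self.fap

    # -- metrics (fractions in [0,1]) --------------------------------------
    def accuracy(self) -> float:
        return float(self.ep.sum() / self.n)

    def weighted_recall(self) -> float:
        w = self.class_sizes / self.n
        denom = self.ep + self.up
        rec = np.divide(self.ep, denom, out=np.zeros(len(self.classes)), where=denom > 0)
        return float((w * rec).sum())

    def weighted_precision(self) -> float:
        w = self.class_sizes / self.n
        denom = self.ep + self.fap
        zero = denom == 0
        if np.any(zero & (self.class_sizes > 0)):
            warnings.warn(
                "class(es) with no predictions contribute 0 precision: "
                f"{[self.classes[i] for i in np.nonzero(zero)[0]]}"
            )
        prec = np.divide(self.ep, denom, out=np.zeros(len(self.classes)), where=~zero)
        return float((w * prec).sum())

    def weighted_f1(self) -> float:
        p, r = self.weighted_precision(), self.weighted_recall()
        return 0.0 if p + r == 0 else 2 * p * r / (p + r)

    def report(self) -> dict:
        """All four metrics on the percent scale, as reported."""
        return {
            "accuracy": 100 * self.accuracy(),
            "weighted_precision": 100 * self.weighted_precision(),
            "weighted_recall": 100 * self.weighted_recall(),
            "weighted_f1": 100 * self.weighted_f1(),
        }


def evaluate_predictions(y_true, y_pred, classes=None) -> EvalCounts:
    """Confusion counts from label vectors (labels may be str or int)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return EvalCounts(classes=list(classes), confusion=cm)


@dataclass
class RunConfig:
    ratios: tuple[float, float, float] = (4.0, 1.0, 1.0)
    folds: int = 5
    seed: int = 0
    epochs: int = 40
    batch_size: int = 64
    lr: float = 1e-3
    loss_mode: str = "blend"
    patience: int = 10
    stratify: bool = True

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run config from a YAML mapping of field overrides."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "ratios" in data:
            data["ratios"] = tuple(data["ratios"])
        return cls(**data)


@dataclass
class TrainHistory:
    epochs: list[int] = field(default_factory=list)
    l_coarse: list[float] = field(default_factory=list)
    l_fine: list[float] = field(default_factory=list)
    w_dynamic: list[float] = field(default_factory=list)
    l_total: list[float] = field(default_factory=list)
    val_fine_accuracy: list[float] = field(default_factory=list)

    def digest(self) -> str:
        h = hashlib.sha256()
        for name in ("l_coarse", "l_fine", "w_dynamic", "l_total", "val_fine_accuracy"):
            h.update(np.asarray(getattr(self, name), dtype=float).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _proportional_counts(n: int, ratios: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items to len(ratios) parts."""
    ratios = ratios / ratios.sum()
    raw = n * ratios
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def split(sset: SpectrumSet, ratios=(4.0, 1.0, 1.0), seed: int = 0,
          stratify: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified (by fine label) train/val/test index split, deterministic."""
    ratios = np.asarray(ratios, dtype=float)
    n = sset.n_samples
    rng = np.random.default_rng(seed)
    if not stratify or sset.labels is None:
        perm = rng.permutation(n)
        counts = _proportional_counts(n, ratios)
        cuts = np.cumsum(counts)[:-1]
        tr, va, te = np.split(perm, cuts)
        return np.sort(tr), np.sort(va), np.sort(te)
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in sorted(set(sset.labels)):
        idx = np.nonzero(sset.labels == cls)[0]
        if idx.size < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 samples; cannot stratify")
        idx = rng.permutation(idx)
        counts = _proportional_counts(idx.size, ratios)
        cuts = np.cumsum(counts)[:-1]
        for part, chunk in zip(parts, np.split(idx, cuts)):
            part.append(chunk)
    return tuple(np.sort(np.concatenate(p)) for p in parts)


def kfold(sset: SpectrumSet, folds: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (train, test) index pairs; each sample tests once."""
    n = sset.n_samples
    rng = np.random.default_rng(seed)
    assignments = np.empty(n, dtype=int)
    if sset.labels is None:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, folds)):
            assignments[chunk] = f
    else:
        for cls in sorted(set(sset.labels)):
            idx = np.nonzero(sset.labels == cls)[0]
            if idx.size < folds:
                raise ValueError(f"class {cls!r} smaller than fold count")
            idx = rng.permutation(idx)
            for f, chunk in enumerate(np.array_split(idx, folds)):
                assignments[chunk] = f
    out = []
    for f in range(folds):
        test = np.nonzero(assignments == f)[0]
        train_ = np.nonzero(assignments != f)[0]
        out.append((train_, test))
    return out


# ---------------------------------------------------------------------------
# label encoding
# ---------------------------------------------------------------------------

def encode_labels(labels: np.ndarray, hierarchy: HierarchyMap | None = None):
    """Fine and coarse integer label vectors plus their vocabularies."""
    hierarchy = hierarchy or HierarchyMap()
    fine_vocab = list(GRADE_VOCABULARY)
    coarse_vocab = hierarchy.coarse_labels
    fine_ix = {c: i for i, c in enumerate(fine_vocab)}
    coarse_ix = {c: i for i, c in enumerate(coarse_vocab)}
    fine = np.array([fine_ix[l] for l in labels], dtype=int)
    coarse = np.array([coarse_ix[hierarchy.coarse_of[l]] for l in labels], dtype=int)
    return fine, coarse, fine_vocab, coarse_vocab


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(train_set: SpectrumSet, val_set: SpectrumSet, model_config: DBHSNetConfig,
          run_config: RunConfig, hierarchy: HierarchyMap | None = None
          ) -> tuple[DBHSNet, TrainHistory]:
    """Train the network with the dynamically weighted joint loss.

    Records per-epoch loss components, the dynamic weight and validation
    fine accuracy; early-stops on validation fine accuracy with the
    configured patience and restores the best parameters.
    """
    hierarchy = hierarchy or HierarchyMap()
    if train_set.labels is None or val_set.labels is None:
        raise ValueError("training requires labelled SpectrumSets")
    fine_tr, coarse_tr, _, coarse_vocab = encode_labels(train_set.labels, hierarchy)
    fine_va, _, _, _ = encode_labels(val_set.labels, hierarchy)
    if model_config.n_coarse != len(coarse_vocab):
        raise ValueError("model n_coarse does not match the hierarchy map")

    model = DBHSNet(model_config)
    opt = Adam(model.params, lr=run_config.lr)
    rng = np.random.default_rng(run_config.seed)
    x_tr = train_set.values
    n = x_tr.shape[0]
    history = TrainHistory()
    best_acc, best_state, since_best = -1.0, model.state_dict(), 0
    l_coarse_prev, l_fine_prev = 1.0, 1.0  # for the loss-ratio term at epoch 0

    for epoch in range(run_config.epochs):
        w = dynamic_weight(epoch, run_config.epochs, l_coarse_prev, l_fine_prev,
                           mode=run_config.loss_mode)
        order = rng.permutation(n)
        lc_sum = lf_sum = lt_sum = 0.0
        n_batches = 0
        for start in range(0, n, run_config.batch_size):
            rows = order[start:start + run_config.batch_size]
            model.zero_grad()
            use_hcm = model_config.use_hcm
            joint, lc, lf = model.loss(
                x_tr[rows], fine_tr[rows],
                coarse_tr[rows] if use_hcm else None,
                w if use_hcm else 0.0,
            )
            joint.backward()
            if not math.isfinite(float(joint.data)):
                raise FloatingPointError(f"loss diverged (NaN/Inf) at epoch {epoch}")
            opt.step()
            lc_sum += 0.0 if math.isnan(lc) else lc
            lf_sum += lf
            lt_sum += float(joint.data)
            n_batches += 1
        l_coarse_prev = lc_sum / n_batches
        l_fine_prev = lf_sum / n_batches

        fine_pred, _ = model.predict(val_set.values)
        val_acc = float((fine_pred == fine_va).mean())
        history.epochs.append(epoch)
        history.l_coarse.append(l_coarse_prev)
        history.l_fine.append(l_fine_prev)
        history.w_dynamic.append(w)
        history.l_total.append(lt_sum / n_batches)
        history.val_fine_accuracy.append(val_acc)

        if val_acc > best_acc + 1e-12:
            best_acc, best_state, since_best = val_acc, model.state_dict(), 0
        else:
            since_best += 1
            if since_best >= run_config.patience:
                logger.info("early stop at epoch %d (best val acc %.4f)", epoch, best_acc)
                break
    model.load_state_dict(best_state)
    return model, history


def evaluate(model: DBHSNet, test_set: SpectrumSet,
             hierarchy: HierarchyMap | None = None) -> tuple[EvalCounts, dict]:
    """Confusion counts + percent metrics for the fine task on a test set."""
    hierarchy = hierarchy or HierarchyMap()
    if test_set.labels is None:
        raise ValueError("test set has no labels")
    fine_true, _, fine_vocab, _ = encode_labels(test_set.labels, hierarchy)
    fine_pred, _ = model.predict(test_set.values)
    counts = evaluate_predictions(fine_true, fine_pred, classes=list(range(len(fine_vocab))))
    counts.classes = fine_vocab
    return counts, counts.report()


#: Table-style default toggle grid: (pbca, msmha, hcm) rows.
DEFAULT_ABLATION_GRID = (
    (False, False, False),
    (False, False, True),
    (False, True, True),
    (True, False, True),
    (True, True, False),
    (True, True, True),
)


def run_ablation(dataset: SpectrumSet, model_config: DBHSNetConfig,
                 run_config: RunConfig, grid=DEFAULT_ABLATION_GRID,
                 hierarchy: HierarchyMap | None = None) -> pd.DataFrame:
    """Train/evaluate one row per module-toggle combination.

    All rows share the same split and seed (paired comparison).
    """
    from dataclasses import replace

    tr, va, te = split(dataset, run_config.ratios, run_config.seed, run_config.stratify)
    train_set, val_set, test_set = dataset.subset(tr), dataset.subset(va), dataset.subset(te)
    rows = []
    for pbca, msmha, hcm in grid:
        cfg = replace(model_config, use_pbca=pbca, use_msmha=msmha, use_hcm=hcm)
        model, _ = train(train_set, val_set, cfg, run_config, hierarchy)
        _, report = evaluate(model, test_set, hierarchy)
        rows.append({"pbca": pbca, "msmha": msmha, "hcm": hcm, **report})
    return pd.DataFrame(rows)
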