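"""Cross-validation, imbalance handling, and model fitting.

Splits are *subject-exclusive*: all sessions of a subject land in one fold,
so longitudinal repeats can never leak between training and validation.
Stratification works on each subject's session-label profile (majority
label; dual-class subjects travel as whole units) and balances per-class
session counts across folds.

Class imbalance is handled per modality: SMOTE oversampling of minority
connectomes (linear interpolation between k-nearest minority neighbours in
upper-triangle edge space) before graph training, and inverse-frequency
class weights in the binary cross-entropy for volume training.

Each fold trains with early stopping on validation loss and retains the
epoch state with the highest validation AUC; performance is summarized as
the median and IQR of TPR, TNR and accuracy across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from ._nn import bce_with_logits, sigmoid
from .atlas import ConnectivityGraph, VolumeScan
from .synthetic import CohortDataset, Session

__all__ = [
    "FoldSplit", "TrainConfig", "MetricsSummary",
    "stratified_subject_kfold", "smote_oversample", "class_weights",
    "train_model", "final_fit",
]

LABEL_TO_Y = {"HC": 0.0, "AD": 1.0}


@dataclass
class FoldSplit:
    folds: list[list[str]]  # session ids per fold
    session_to_subject: dict[str, str]

    def __post_init__(self) -> None:
        for i, fold in enumerate(self.folds):
            subs = {self.session_to_subject[s] for s in fold}
            for j, other in enumerate(self.folds):
                if j <= i:
                    continue
                overlap = subs & {self.session_to_subject[s] for s in other}
                if overlap:
                    raise ValueError(
                        f"subjects {sorted(overlap)} span folds {i} and {j}"
                    )

    @property
    def k(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    imbalance: str | None = "class_weight"  # "smote" | "class_weight" | None
    patience: int = 10
    max_epochs: int = 200
    lr: float = 1e-3
    min_delta: float = 1e-3  # minimum val-loss improvement that resets patience
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class MetricsSummary:
    per_fold: pd.DataFrame  # fold, tpr, tnr, accuracy
    median: dict = field(default_factory=dict)
    iqr: dict = field(default_factory=dict)
    confusion_median: np.ndarray | None = None  # row-normalized [[TN,FP],[FN,TP]]
    confusion_iqr: np.ndarray | None = None

    @classmethod
    def from_fold_frames(cls, frames: list[pd.DataFrame]) -> "MetricsSummary":
        rows, confusions = [], []
        for i, df in enumerate(frames):
            y = df["y_true"].to_numpy()
            p = df["y_pred"].to_numpy()
            tp = int(((y == 1) & (p == 1)).sum())
            tn = int(((y == 0) & (p == 0)).sum())
            fp = int(((y == 0) & (p == 1)).sum())
            fn = int(((y == 1) & (p == 0)).sum())
            tpr = tp / (tp + fn) if tp + fn else np.nan
            tnr = tn / (tn + fp) if tn + fp else np.nan
            acc = (tp + tn) / len(y)
            rows.append({"fold": i, "tpr": tpr, "tnr": tnr, "accuracy": acc})
            conf = np.array([[tn, fp], [fn, tp]], dtype=float)
            sums = conf.sum(axis=1, keepdims=True)
            confusions.append(np.divide(conf, sums, out=np.full_like(conf, np.nan),
                                        where=sums > 0))
        per_fold = pd.DataFrame(rows)
        med = {m: float(np.nanmedian(per_fold[m])) for m in ("tpr", "tnr", "accuracy")}
        iqr = {
            m: float(np.nanpercentile(per_fold[m], 75) - np.nanpercentile(per_fold[m], 25))
            for m in ("tpr", "tnr", "accuracy")
        }
        stack = np.stack(confusions)
        return cls(
            per_fold=per_fold, median=med, iqr=iqr,
            confusion_median=np.nanmedian(stack, axis=0),
            confusion_iqr=(np.nanpercentile(stack, 75, axis=0)
                           - np.nanpercentile(stack, 25, axis=0)),
        )


# ---------------------------------------------------------------------------
# splitting

def _subject_profiles(dataset: CohortDataset) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for s in dataset.sessions:
        d = out.setdefault(s.subject_id, {"sessions": [], "labels": []})
        d["sessions"].append(s.session_id)
        d["labels"].append(s.label)
    for d in out.values():
        n_ad = d["labels"].count("AD")
        # majority label of the subject's sessions; AD on ties
        d["stratum"] = "AD" if n_ad * 2 >= len(d["labels"]) else "HC"
    return out


def stratified_subject_kfold(dataset: CohortDataset, k: int = 10,
                             seed: int = 0) -> FoldSplit:
    """Subject-exclusive k folds with per-fold class ratios near global."""
    profiles = _subject_profiles(dataset)
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the {len(profiles)} available subjects")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    label_counts = np.zeros((k, 2))  # columns: HC, AD sessions
    col = {"HC": 0, "AD": 1}
    for stratum in ("AD", "HC"):
        subjects = [s for s, d in profiles.items() if d["stratum"] == stratum]
        rng.shuffle(subjects)
        subjects.sort(key=lambda s: -len(profiles[s]["sessions"]))
        c = col[stratum]
        for sub in subjects:
            totals = label_counts.sum(axis=1)
            order = sorted(range(k), key=lambda f: (label_counts[f, c], totals[f], f))
            f = order[0]
            folds[f].extend(profiles[sub]["sessions"])
            for lab in profiles[sub]["labels"]:
                label_counts[f, col[lab]] += 1
    session_to_subject = {
        s.session_id: s.subject_id for s in dataset.sessions
    }
    return FoldSplit(folds=folds, session_to_subject=session_to_subject)


# ---------------------------------------------------------------------------
# SMOTE

def smote_oversample(graphs: list[ConnectivityGraph], k_neighbors: int = 5,
                     seed: int = 0) -> list[ConnectivityGraph]:
    """Balance classes by synthesizing minority connectomes.

    Feature space is the vectorized upper triangle (symmetry is structural,
    not a feature).  Each synthetic sample is x + lambda (x_nn - x) with
    lambda ~ U(0,1) and x_nn one of the k nearest minority neighbours; the
    matrix is rebuilt symmetric with a zero diagonal.
    """
    labels = np.array([g.label for g in graphs])
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or counts.iloc[0] == counts.iloc[-1]:
        return list(graphs)
    minority = counts.index[-1]
    n_needed = int(counts.iloc[0] - counts.iloc[-1])
    minority_graphs = [g for g in graphs if g.label == minority]
    if len(minority_graphs) <= k_neighbors:
        raise ValueError(
            f"minority class has {len(minority_graphs)} samples, need more than "
            f"k_neighbors={k_neighbors}; reduce k"
        )
    n = minority_graphs[0].n_nodes
    iu = np.triu_indices(n, k=1)
    X = np.stack([g.matrix[iu] for g in minority_graphs])
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    rng = np.random.default_rng(seed)
    out = list(graphs)
    node_ids = minority_graphs[0].node_ids
    for j in range(n_needed):
        base = int(rng.integers(len(X)))
        neigh = int(idx[base][1 + rng.integers(k_neighbors)])
        lam = rng.uniform()
        vec = X[base] + lam * (X[neigh] - X[base])
        m = np.zeros((n, n))
        m[iu] = vec
        m = m + m.T
        out.append(ConnectivityGraph(
            matrix=m, node_ids=node_ids,
            subject_id=f"smote-{j:05d}", session_id=f"smote-{j:05d}_ses-00",
            label=minority,
        ))
    return out


def class_weights(labels: np.ndarray | list[str]) -> dict[str, float]:
    """Inverse-frequency weights; both 1 for a balanced set."""
    labels = np.asarray(labels)
    n = len(labels)
    out = {}
    for lab in ("HC", "AD"):
        n_c = int((labels == lab).sum())
        out[lab] = n / (2.0 * n_c) if n_c else 0.0
    return out


# ---------------------------------------------------------------------------
# fitting

def _payload_array(s: Session | ConnectivityGraph | VolumeScan) -> np.ndarray:
    p = s.payload if isinstance(s, Session) else s
    if isinstance(p, ConnectivityGraph):
        return p.matrix
    if isinstance(p, VolumeScan):
        return p.voxels
    return np.asarray(p, dtype=float)


def _design(sessions: list) -> tuple[np.ndarray, np.ndarray]:
    # training and inference run in single precision for speed
    X = np.stack([_payload_array(s) for s in sessions])[:, None]
    labels = [s.label if isinstance(s, Session) else s.label for s in sessions]
    y = np.array([LABEL_TO_Y[l] for l in labels])
    return X.astype(np.float32), y


def _fit(model, X_tr, y_tr, X_val, y_val, cfg: TrainConfig,
         weights: np.ndarray | None = None) -> dict:
    """Early-stopped fit retaining the max-validation-AUC state."""
    rng = np.random.default_rng(cfg.seed + 7919)
    opt = model.make_optimizer(lr=cfg.lr)
    n = len(X_tr)
    best = {"auc": -np.inf, "loss": np.inf, "state": model.get_state(),
            "epoch": -1}
    best_val_loss, since_improve = np.inf, 0
    history = []
    for epoch in range(cfg.max_epochs):
        # cosine learning-rate decay stabilizes the late epochs
        opt.lr = cfg.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.max_epochs))
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start:start + cfg.batch_size]
            model.zero_grad()
            logits = model.forward_logits(X_tr[sel], train=True)
            w = None if weights is None else weights[sel]
            loss, dlogits = bce_with_logits(logits, y_tr[sel], w)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (loss={loss}) at epoch {epoch}")
            model.backward(dlogits)
            opt.step()
        val_logits = _predict_logits(model, X_val, cfg.batch_size)
        val_loss, _ = bce_with_logits(val_logits, y_val)
        if len(np.unique(y_val)) == 2:
            auc = roc_auc_score(y_val, val_logits)
        else:  # degenerate validation set: fall back to loss-based selection
            auc = -val_loss
        history.append({"epoch": epoch, "val_loss": val_loss, "val_auc": auc})
        # ties in AUC resolve to the better-calibrated (lower val loss) epoch
        if auc > best["auc"] or (auc == best["auc"] and val_loss <= best["loss"]):
            best = {"auc": auc, "loss": val_loss, "state": model.get_state(),
                    "epoch": epoch}
        if val_loss < best_val_loss - cfg.min_delta:
            best_val_loss, since_improve = val_loss, 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break
    model.set_state(best["state"])
    return {"history": pd.DataFrame(history), "best_epoch": best["epoch"],
            "best_auc": best["auc"]}


def _predict_logits(model, X: np.ndarray, batch_size: int) -> np.ndarray:
    out = []
    for start in range(0, len(X), batch_size):
        out.append(model.forward_logits(X[start:start + batch_size], train=False))
    return np.concatenate(out) if out else np.empty(0)


def _set_input_stats(model, X: np.ndarray) -> None:
    """Let the model derive its input standardization from the training set."""
    if hasattr(model, "fit_input_stats"):
        model.fit_input_stats(X)


def _prepare_training_set(sessions: list[Session], cfg: TrainConfig,
                          fold_seed: int):
    X, y = _design(sessions)
    weights = None
    if cfg.imbalance == "smote":
        graphs = [s.payload for s in sessions]
        if not all(isinstance(g, ConnectivityGraph) for g in graphs):
            raise ValueError("SMOTE applies to connectome datasets only")
        augmented = smote_oversample(graphs, cfg.k_neighbors, seed=fold_seed)
        X = np.stack([g.matrix for g in augmented])[:, None].astype(np.float32)
        y = np.array([LABEL_TO_Y[g.label] for g in augmented])
    elif cfg.imbalance == "class_weight":
        cw = class_weights([s.label for s in sessions])
        weights = np.array([cw["AD"] if yy == 1 else cw["HC"] for yy in y])
    return X, y, weights


def train_model(build_fn, dataset: CohortDataset, folds: FoldSplit,
                cfg: TrainConfig):
    """Cross-validate: for each fold, train on the rest and test on it.

    ``build_fn(seed)`` must return a freshly initialized model.  Returns
    (models, MetricsSummary, predictions) where predictions holds one row
    per session with its held-out probability.
    """
    by_id = {s.session_id: s for s in dataset.sessions}
    models, frames = [], []
    for f, fold_ids in enumerate(folds.folds):
        fold_seed = (cfg.seed * 131 + f) % (2 ** 31)
        train_sessions = [by_id[sid] for g, fold in enumerate(folds.folds)
                          if g != f for sid in fold]
        val_sessions = [by_id[sid] for sid in fold_ids]
        X_tr, y_tr, w = _prepare_training_set(train_sessions, cfg, fold_seed)
        X_val, y_val = _design(val_sessions)
        model = build_fn(fold_seed)
        model.astype(np.float32)
        _set_input_stats(model, X_tr)
        _fit(model, X_tr, y_tr, X_val, y_val,
             TrainConfig(**{**cfg.__dict__, "seed": fold_seed}), w)
        probs = sigmoid(_predict_logits(model, X_val, cfg.batch_size))
        frames.append(pd.DataFrame({
            "session_id": [s.session_id for s in val_sessions],
            "subject_id": [s.subject_id for s in val_sessions],
            "fold": f,
            "y_true": y_val.astype(int),
            "prob_ad": probs,
            "y_pred": (probs >= 0.5).astype(int),
        }))
        models.append(model)
    summary = MetricsSummary.from_fold_frames(frames)
    predictions = pd.concat(frames, ignore_index=True)
    predictions["true_label"] = predictions["y_true"].map({0: "HC", 1: "AD"})
    predictions["predicted_label"] = predictions["y_pred"].map({0: "HC", 1: "AD"})
    return models, summary, predictions


def final_fit(build_fn, dataset: CohortDataset, cfg: TrainConfig,
              val_fraction: float = 0.1):
    """Fit one final model on a subject-exclusive 90/10 split.

    The 10% validation part only drives early stopping and AUC-based model
    retention.  The returned predictions cover every session of the dataset;
    sessions the model trained on are flagged ``in_sample``.
    """
    k = max(2, int(round(1.0 / val_fraction)))
    folds = stratified_subject_kfold(dataset, k=k, seed=cfg.seed)
    val_ids = set(folds.folds[0])
    by_id = {s.session_id: s for s in dataset.sessions}
    train_sessions = [s for s in dataset.sessions if s.session_id not in val_ids]
    val_sessions = [by_id[sid] for sid in folds.folds[0]]
    X_tr, y_tr, w = _prepare_training_set(train_sessions, cfg, cfg.seed)
    X_val, y_val = _design(val_sessions)
    model = build_fn(cfg.seed)
    model.astype(np.float32)
    _set_input_stats(model, X_tr)
    info = _fit(model, X_tr, y_tr, X_val, y_val, cfg, w)
    X_all, y_all = _design(dataset.sessions)
    probs = sigmoid(_predict_logits(model, X_all, cfg.batch_size))
    predictions = pd.DataFrame({
        "session_id": [s.session_id for s in dataset.sessions],
        "subject_id": [s.subject_id for s in dataset.sessions],
        "y_true": y_all.astype(int),
        "prob_ad": probs,
        "y_pred": (probs >= 0.5).astype(int),
        "in_sample": [s.session_id not in val_ids for s in dataset.sessions],
    })
    predictions["true_label"] = predictions["y_true"].map({0: "HC", 1: "AD"})
    predictions["predicted_label"] = predictions["y_pred"].map({0: "HC", 1: "AD"})
    return model, predictions, info
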