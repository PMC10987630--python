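"""AI classification of nuclear D maps.

Four stages, mirroring the analysis pipeline the package reproduces:

1. **Preprocess** — crop each segmented D map to its mask bounding box,
   zero-fill outside the mask, min-max normalize, resize to the backbone
   input and replicate to 3 channels.
2. **Feature extraction** — a pluggable convolutional backbone maps each
   image to a fixed-length vector (spatial average of its final
   convolutional activations). The default in-repo backbone is a
   fixed-seed random-weight CNN, so the pipeline is deterministic and
   self-contained; a pretrained ResNet50 can be plugged in when torch
   and its weights are available, and an identity-downsample baseline is
   provided for sanity checks. Random-projection features preserve
   geometry (Johnson-Lindenstrauss), which is all the downstream
   classifier needs on synthetic data.
3. **Compression** — a symmetric 5-layer autoencoder trained for 50
   epochs squeezes features to a 40-dimensional latent code.
4. **Classification** — a grid-searched random forest on the latent
   codes, evaluated by repeated stratified fourfold cross-validation
   (5 repeats = 20 folds) with patient-level stratification: all cells
   of a patient stay on one side of every split.

Per-fold metrics are the rank AUC and the sensitivity/specificity at the
cut-point maximizing the number of correct classifications within the
fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from cspws.errors import ValidationError
from cspws.models import CVReport, DMap


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess_dmap(dmap: DMap, out_size: tuple[int, int] = (224, 224)) -> np.ndarray:
    """D map -> backbone-ready ``(H, W, 3)`` image in [0, 1].

    Crops to the mask bounding box, zero-fills outside the mask, min-max
    scales in-mask values, resizes (anisotropically) to ``out_size`` and
    replicates to 3 channels. A constant in-mask map scales to 0.5 by
    convention; otherwise the output's min and max are exactly 0 and 1.
    """
    from skimage.transform import resize

    m = dmap.mask.values
    if not m.any():
        raise ValidationError("mask is empty")
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    if rows.size < 2 or cols.size < 2:
        raise ValidationError("degenerate mask bounding box")
    sub = dmap.values[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].copy()
    subm = m[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    sub[~subm] = 0.0
    vals = sub[subm]
    vmin, vmax = float(np.nanmin(vals)), float(np.nanmax(vals))
    constant = vmax == vmin
    if constant:
        sub[subm] = 0.5
    else:
        sub[subm] = (vals - vmin) / (vmax - vmin)
    sub = np.nan_to_num(sub, nan=0.0)
    img = resize(sub, out_size, order=1, preserve_range=True, anti_aliasing=True)
    img = np.clip(img, 0.0, 1.0)
    if not constant:
        lo, hi = img.min(), img.max()
        if hi > lo:  # restore exact [0, 1] span lost to interpolation
            img = (img - lo) / (hi - lo)
    return np.repeat(img[..., None], 3, axis=-1)


# ---------------------------------------------------------------------------
# Feature-extraction backbones
# ---------------------------------------------------------------------------

class Backbone(Protocol):
    """Feature-extractor contract: deterministic image -> vector map."""

    name: str
    out_dim: int

    def __call__(self, image: np.ndarray) -> np.ndarray: ...


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """Valid-mode strided 2-D convolution, channels-last."""
    kh, kw = w.shape[:2]
    win = sliding_window_view(x, (kh, kw), axis=(0, 1))[::stride, ::stride]
    return np.tensordot(win, w, axes=([3, 4, 2], [0, 1, 2]))


class RandomConvBackbone:
    """Fixed-seed random-weight CNN feature extractor.

    A stack of 3x3 stride-2 convolutions with ReLU, a final 1x1
    projection to ``out_dim`` channels, and global average pooling over
    the final convolutional activation map. Weights are He-initialized
    from the seed at construction and never trained, so the map is fully
    deterministic; it requires no downloads and stands in for a
    pretrained network wherever the tests need a backbone.
    """

    def __init__(
        self,
        out_dim: int = 2048,
        seed: int = 0,
        channels: Sequence[int] = (16, 32, 64, 64),
        in_channels: int = 3,
    ):
        self.name = f"random-cnn-{out_dim}d-seed{seed}"
        self.out_dim = int(out_dim)
        rng = np.random.default_rng(seed)
        self._convs = []
        prev = in_channels
        for c in channels:
            w = rng.standard_normal((3, 3, prev, c)) * math.sqrt(2.0 / (9 * prev))
            self._convs.append(w)
            prev = c
        self._proj = rng.standard_normal((1, 1, prev, self.out_dim)) * math.sqrt(
            2.0 / prev
        )

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=float)
        if x.ndim != 3 or x.shape[2] != self._convs[0].shape[2]:
            raise ValidationError(
                f"expected (H, W, {self._convs[0].shape[2]}) image, got {x.shape}"
            )
        if min(x.shape[:2]) < 3 * 2 ** len(self._convs):
            raise ValidationError("image too small for the conv stack")
        for w in self._convs:
            x = np.maximum(_conv2d(x, w, stride=2), 0.0)
        x = np.maximum(_conv2d(x, self._proj, stride=1), 0.0)
        return x.mean(axis=(0, 1))


class IdentityDownsampleBackbone:
    """Baseline: channel-averaged ``grid x grid`` downsample, flattened."""

    def __init__(self, grid: int = 16):
        self.grid = int(grid)
        self.name = f"identity-downsample-{grid}"
        self.out_dim = self.grid**2

    def __call__(self, image: np.ndarray) -> np.ndarray:
        from skimage.transform import resize

        x = np.asarray(image, dtype=float)
        if x.ndim != 3:
            raise ValidationError("expected (H, W, C) image")
        small = resize(x.mean(axis=-1), (self.grid, self.grid),
                       order=1, preserve_range=True, anti_aliasing=True)
        return small.ravel()


def resnet50_backbone():  # pragma: no cover - optional heavy dependency
    """Pretrained ResNet50 backbone (2048-d global-average features).

    Requires torch/torchvision and a weight download; raises ImportError
    otherwise. Provided for users with real data and network access.
    """
    import torch
    import torchvision

    net = torchvision.models.resnet50(weights="IMAGENET1K_V2")
    net.eval()
    trunk = torch.nn.Sequential(*list(net.children())[:-1])

    class _Wrap:
        name = "resnet50-imagenet"
        out_dim = 2048

        def __call__(self, image):
            with torch.no_grad():
                t = torch.as_tensor(
                    np.moveaxis(image, -1, 0)[None], dtype=torch.float32
                )
                return trunk(t).numpy().ravel()

    return _Wrap()


def extract_features(image: np.ndarray, backbone: Backbone) -> np.ndarray:
    """Apply a backbone to one preprocessed image; validates the output."""
    vec = np.asarray(backbone(image), dtype=float)
    if vec.ndim != 1 or vec.size != backbone.out_dim:
        raise ValidationError(
            f"backbone '{backbone.name}' returned shape {vec.shape}, "
            f"expected ({backbone.out_dim},)"
        )
    if not np.all(np.isfinite(vec)):
        raise ValidationError("backbone produced non-finite features")
    return vec


# ---------------------------------------------------------------------------
# Autoencoder
# ---------------------------------------------------------------------------

class Autoencoder:
    """Symmetric 5-layer MLP autoencoder with a linear latent layer.

    Layer widths taper geometrically from the input dimension to the
    latent dimension over 5 encoder layers; the decoder mirrors them.
    Hidden activations are tanh; the latent and output layers are
    linear. Inputs are standardized per dimension (the scaler is part of
    the model); the training loss is the mean squared reconstruction
    error in standardized space.
    """

    N_LAYERS = 5

    def __init__(self, input_dim: int, latent_dim: int = 40, seed: int = 0):
        if latent_dim >= input_dim:
            raise ValidationError("latent_dim must be smaller than the input dim")
        self.input_dim = input_dim
        self.latent_dim = latent_dim
        dims = np.geomspace(input_dim, latent_dim, self.N_LAYERS + 1)
        self.dims = [int(round(d)) for d in dims]
        self.dims[0], self.dims[-1] = input_dim, latent_dim
        rng = np.random.default_rng(seed)
        full = self.dims + self.dims[-2::-1]  # encoder then decoder widths
        self.weights = []
        self.biases = []
        for a, b in zip(full[:-1], full[1:]):
            lim = math.sqrt(6.0 / (a + b))
            self.weights.append(rng.uniform(-lim, lim, size=(a, b)))
            self.biases.append(np.zeros(b))
        self.mu = np.zeros(input_dim)
        self.scale = np.ones(input_dim)

    # -- forward passes -----------------------------------------------------
    def _forward(self, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [x]
        h = x
        n_enc = self.N_LAYERS
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            # latent (i == n_enc-1) and final output stay linear
            if i != n_enc - 1 and i != len(self.weights) - 1:
                h = np.tanh(h)
            acts.append(h)
        return acts, h

    def encode(self, x: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(x) - self.mu) / self.scale
        for i in range(self.N_LAYERS):
            z = z @ self.weights[i] + self.biases[i]
            if i != self.N_LAYERS - 1:
                z = np.tanh(z)
        return z if np.asarray(x).ndim > 1 else z[0]

    def reconstruction_loss(self, x: np.ndarray) -> float:
        z = (np.atleast_2d(x) - self.mu) / self.scale
        _, out = self._forward(z)
        return float(np.mean((out - z) ** 2))


def train_autoencoder(
    features: np.ndarray,
    latent_dim: int = 40,
    epochs: int = 50,
    seed: int = 0,
    lr: float = 3e-3,
    batch_size: int = 64,
) -> tuple[Autoencoder, list[float]]:
    """Train an :class:`Autoencoder` with Adam; returns (model, loss curve).

    The loss curve has exactly ``epochs`` entries (mean per-batch MSE).
    Training is bit-deterministic for a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValidationError("features must be a 2-D (n, d) array")
    n, d = X.shape
    if n < latent_dim:
        raise ValidationError(f"need >= {latent_dim} training vectors, got {n}")
    model = Autoencoder(d, latent_dim=latent_dim, seed=seed)
    model.mu = X.mean(axis=0)
    model.scale = np.maximum(X.std(axis=0), 1e-8)
    Z = (X - model.mu) / model.scale

    rng = np.random.default_rng(seed + 1)
    params = model.weights + model.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n_enc = model.N_LAYERS
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = Z[idx]
            acts, out = model._forward(xb)
            diff = out - xb
            batch_losses.append(float(np.mean(diff**2)))
            grad = 2.0 * diff / diff.size
            grads_w = [None] * len(model.weights)
            grads_b = [None] * len(model.biases)
            for i in range(len(model.weights) - 1, -1, -1):
                pre_act = acts[i]
                post = acts[i + 1]
                if i != n_enc - 1 and i != len(model.weights) - 1:
                    grad = grad * (1.0 - post**2)  # tanh'
                grads_w[i] = pre_act.T @ grad
                grads_b[i] = grad.sum(axis=0)
                grad = grad @ model.weights[i].T
            step += 1
            all_grads = grads_w + grads_b
            for j, (p, g) in enumerate(zip(params, all_grads)):
                m[j] = beta1 * m[j] + (1 - beta1) * g
                v[j] = beta2 * v[j] + (1 - beta2) * g**2
                mh = m[j] / (1 - beta1**step)
                vh = v[j] / (1 - beta2**step)
                p -= lr * mh / (np.sqrt(vh) + eps)
        losses.append(float(np.mean(batch_losses)))
    return model, losses


def encode(features: np.ndarray, encoder: Autoencoder) -> np.ndarray:
    """Map features to the latent space (single vector or batch)."""
    X = np.asarray(features, dtype=float)
    if X.shape[-1] != encoder.input_dim:
        raise ValidationError(
            f"feature length {X.shape[-1]} != encoder input {encoder.input_dim}"
        )
    return encoder.encode(X)


# ---------------------------------------------------------------------------
# Classification and metrics
# ---------------------------------------------------------------------------

DEFAULT_RF_GRID: dict = {
    "n_estimators": [100],
    "max_depth": [None, 6],
    "max_features": ["sqrt"],
}


def train_classifier(
    latents: np.ndarray,
    labels: np.ndarray,
    grid: dict | None = None,
    inner_seed: int = 0,
    inner_splits: int = 3,
):
    """Grid-searched random-forest probability classifier.

    The grid search scores configurations by inner stratified CV on the
    training data only; returns ``(fitted classifier, chosen config)``.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import GridSearchCV, StratifiedKFold

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("training labels contain a single class")
    grid = grid or DEFAULT_RF_GRID
    inner = StratifiedKFold(n_splits=inner_splits, shuffle=True,
                            random_state=inner_seed)
    search = GridSearchCV(
        RandomForestClassifier(random_state=inner_seed),
        param_grid=grid,
        cv=inner,
        scoring="roc_auc",
        n_jobs=1,
    )
    search.fit(np.asarray(latents), labels)
    return search.best_estimator_, dict(search.best_params_)


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute one half."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def optimal_cutpoint(scores, labels) -> tuple[float, float, float]:
    """Threshold maximizing the number of correct classifications.

    Candidates are the midpoints of sorted unique scores plus one
    sentinel beyond each extreme (call-everything / call-nothing), so
    the achieved accuracy always equals the brute-force maximum over all
    thresholds (a score is called positive when >= threshold). Ties in
    correct-count are broken toward higher sensitivity, then toward the
    lower threshold. Returns ``(threshold, sensitivity, specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size > 1:
        mid = (uniq[:-1] + uniq[1:]) / 2.0
        lo = uniq[0] - (uniq[1] - uniq[0]) / 2.0
        hi = uniq[-1] + (uniq[-1] - uniq[-2]) / 2.0
        cands = np.concatenate([[lo], mid, [hi]])
    else:
        cands = np.array([uniq[0], uniq[0] + 1.0])
    best = None
    for t in cands:
        pred = scores >= t
        tp = int((pred & pos).sum())
        tn = int((~pred & ~pos).sum())
        se, sp = tp / n1, tn / n0
        key = (tp + tn, se, -t)
        if best is None or key > best[0]:
            best = (key, float(t), se, sp)
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# Repeated stratified cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ClassificationDataset:
    """Per-cell feature matrix with patient structure.

    ``features`` is ``(n_cells, d)``; ``patient_ids`` assigns each cell
    to a patient; ``labels`` maps patient id -> binary class.
    """

    features: np.ndarray
    patient_ids: np.ndarray
    labels: dict[str, int]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.patient_ids = np.asarray(self.patient_ids)
        if self.features.ndim != 2:
            raise ValidationError("features must be (n_cells, d)")
        if self.patient_ids.shape[0] != self.features.shape[0]:
            raise ValidationError("one patient id per cell required")
        missing = set(np.unique(self.patient_ids)) - set(self.labels)
        if missing:
            raise ValidationError(f"patients without labels: {sorted(missing)}")

    @classmethod
    def from_dmaps(
        cls,
        dmaps: Sequence[DMap],
        patient_ids: Sequence[str],
        labels: dict[str, int],
        backbone: Backbone,
        out_size: tuple[int, int] = (224, 224),
    ) -> "ClassificationDataset":
        feats = np.stack(
            [extract_features(preprocess_dmap(d, out_size), backbone) for d in dmaps]
        )
        return cls(features=feats, patient_ids=np.asarray(patient_ids),
                   labels=dict(labels))

    @property
    def cell_labels(self) -> np.ndarray:
        return np.array([self.labels[p] for p in self.patient_ids], dtype=int)


@dataclass
class ClassifierConfig:
    """Tunables of the autoencoder + random-forest pipeline."""

    latent_dim: int = 40
    epochs: int = 50
    ae_lr: float = 3e-3
    rf_grid: dict = field(default_factory=lambda: dict(DEFAULT_RF_GRID))
    aggregate: str = "patient"  # or "cell"

    def to_dict(self) -> dict:
        return {
            "latent_dim": self.latent_dim,
            "epochs": self.epochs,
            "ae_lr": self.ae_lr,
            "rf_grid": {k: list(v) for k, v in self.rf_grid.items()},
            "aggregate": self.aggregate,
        }


def _stratified_patient_folds(
    patients_by_class: dict[int, list[str]], k: int, rng: np.random.Generator
) -> list[list[str]]:
    """Round-robin assignment of shuffled patients to k folds per class."""
    folds: list[list[str]] = [[] for _ in range(k)]
    for label in sorted(patients_by_class):
        ids = list(patients_by_class[label])
        order = rng.permutation(len(ids))
        for j, idx in enumerate(order):
            folds[j % k].append(ids[idx])
    return folds


def repeated_stratified_cv(
    dataset: ClassificationDataset,
    k: int = 4,
    repeats: int = 5,
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold CV of the full pipeline.

    Folds are stratified by class at the patient level, so every cell of
    a patient lies on one side of each split. Within each of the
    ``k * repeats`` folds the autoencoder and the grid-searched random
    forest are fit on the training side only; scores on the held-out side
    are aggregated to patient level (mean of cell scores) unless
    ``config.aggregate == "cell"``, and the fold reports the rank AUC
    plus sensitivity/specificity at the fold's optimal cut-point. Each
    fold entry also records the train/test patient ids and cell indices
    for leakage auditing.
    """
    config = config or ClassifierConfig()
    by_class: dict[int, list[str]] = {}
    for pid in dict.fromkeys(dataset.patient_ids.tolist()):  # stable order
        by_class.setdefault(dataset.labels[pid], []).append(pid)
    if len(by_class) != 2:
        raise ValidationError("need exactly two classes")
    for label, ids in by_class.items():
        if len(ids) < k:
            raise ValidationError(
                f"class {label} has {len(ids)} patients; need >= {k}"
            )

    rng = np.random.default_rng(seed)
    cell_labels = dataset.cell_labels
    folds_out: list[dict] = []
    for rep in range(repeats):
        fold_patients = _stratified_patient_folds(by_class, k, rng)
        for fold_idx in range(k):
            test_patients = set(fold_patients[fold_idx])
            train_patients = {
                p for j, fp in enumerate(fold_patients) if j != fold_idx for p in fp
            }
            if train_patients & test_patients:
                raise RuntimeError("leakage guard: patient on both sides")
            test_mask = np.isin(dataset.patient_ids, sorted(test_patients))
            train_idx = np.flatnonzero(~test_mask)
            test_idx = np.flatnonzero(test_mask)

            fold_seed = int(
                np.random.SeedSequence([seed, rep, fold_idx]).generate_state(1)[0]
                % (2**31)
            )
            ae, _curve = train_autoencoder(
                dataset.features[train_idx],
                latent_dim=config.latent_dim,
                epochs=config.epochs,
                seed=fold_seed,
                lr=config.ae_lr,
            )
            z_train = ae.encode(dataset.features[train_idx])
            z_test = ae.encode(dataset.features[test_idx])
            clf, chosen = train_classifier(
                z_train, cell_labels[train_idx],
                grid=config.rf_grid, inner_seed=fold_seed,
            )
            cell_scores = clf.predict_proba(z_test)[:, 1]

            if config.aggregate == "patient":
                pids = dataset.patient_ids[test_idx]
                uniq = sorted(set(pids.tolist()))
                scores = np.array(
                    [cell_scores[pids == p].mean() for p in uniq]
                )
                labels = np.array([dataset.labels[p] for p in uniq], dtype=int)
            else:
                scores = cell_scores
                labels = cell_labels[test_idx]

            auc = roc_auc(scores, labels)
            thr, se, sp = optimal_cutpoint(scores, labels)
            folds_out.append(
                {
                    "repeat": rep,
                    "fold": fold_idx,
                    "auc": auc,
                    "sensitivity": se,
                    "specificity": sp,
                    "threshold": thr,
                    "rf_config": chosen,
                    "train_patients": sorted(train_patients),
                    "test_patients": sorted(test_patients),
                    "train_cell_indices": train_idx.tolist(),
                    "test_cell_indices": test_idx.tolist(),
                }
            )
    return CVReport(
        folds=folds_out, k=k, repeats=repeats, seed=seed,
        config=config.to_dict(),
    )
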