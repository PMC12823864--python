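"""Two-backbone neural classifier for connectome + Betti-curve features.

One backbone embeds the vectorized off-diagonal connectome, the other
the 18 concatenated subnetwork Betti curves; the embeddings are
concatenated and mapped by a fully connected head (with dropout) to
two-class softmax probabilities.  The network, its gradients and the
decoupled-weight-decay Adam optimizer are implemented directly in
NumPy, which keeps the whole model differentiable by hand — in
particular the gradient of the output with respect to the Betti inputs
that drives the subnetwork importance analysis.

Betti-curve inputs are standardized per dimension with training-fold
statistics before entering their backbone (integer Betti counts and
correlations otherwise live on incompatible scales); the connectome
branch is left on its natural [-1, 1] scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .curves import SUBNETWORKS
from .exceptions import ConfigurationError, SingleClassError, UndefinedMetricError


@dataclass
class NetConfig:
    """Hyperparameters of the two-backbone network and its training."""

    backbone_hidden: int = 128
    head_layers: int = 1
    dropout_head: float = 0.5
    learning_rate: float = 1e-5
    weight_decay: float = 1e-5
    epochs: int = 50
    batch_size: int = 8
    seed: int = 0
    standardize_betti: bool = True

    def __post_init__(self) -> None:
        if self.backbone_hidden < 1 or self.head_layers < 1 or self.epochs < 1:
            raise ConfigurationError("sizes and epochs must be positive")
        if not (0 <= self.dropout_head < 1):
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ConfigurationError("learning_rate must be positive")


def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class BMHNet:
    """The two-backbone classifier.

    Parameters are created lazily from the input dimensions; all
    randomness (initialization, batching, dropout) flows from
    ``config.seed``.
    """

    def __init__(self, n_connectome: int, n_betti: int, config: NetConfig):
        self.config = config
        self.n_connectome = n_connectome
        self.n_betti = n_betti
        self._rng = np.random.default_rng(config.seed)
        h = config.backbone_hidden
        self.params: dict[str, np.ndarray] = {}
        self._add_linear("emb_c", n_connectome, h)
        self._add_linear("emb_b", n_betti, h)
        head_in = 2 * h
        for i in range(config.head_layers - 1):
            self._add_linear(f"head{i}", head_in, h)
            head_in = h
        self._add_linear("out", head_in, 2)
        self.betti_mean = np.zeros(n_betti)
        self.betti_std = np.ones(n_betti)
        self.loss_history: list[float] = []

    def _add_linear(self, name: str, fan_in: int, fan_out: int) -> None:
        scale = np.sqrt(2.0 / fan_in)
        self.params[f"{name}_W"] = self._rng.normal(0, scale, size=(fan_in, fan_out))
        self.params[f"{name}_b"] = np.zeros(fan_out)

    # -- forward / backward -------------------------------------------------

    def _scale_betti(self, xb: np.ndarray) -> np.ndarray:
        if not self.config.standardize_betti:
            return xb
        return (xb - self.betti_mean) / self.betti_std

    def _forward(self, xc: np.ndarray, xb_scaled: np.ndarray,
                 train: bool = False,
                 rng: np.random.Generator | None = None) -> dict:
        p = self.params
        cache: dict = {"xc": xc, "xb": xb_scaled}
        zc = xc @ p["emb_c_W"] + p["emb_c_b"]
        zb = xb_scaled @ p["emb_b_W"] + p["emb_b_b"]
        hc, hb = _relu(zc), _relu(zb)
        cache.update(zc=zc, zb=zb)
        h = np.concatenate([hc, hb], axis=1)
        if train and self.config.dropout_head > 0:
            keep = 1.0 - self.config.dropout_head
            mask = (rng.random(h.shape) < keep) / keep
            h = h * mask
            cache["drop_mask"] = mask
        cache["h0"] = h
        for i in range(self.config.head_layers - 1):
            z = h @ p[f"head{i}_W"] + p[f"head{i}_b"]
            cache[f"hz{i}"] = z
            h = _relu(z)
            cache[f"h{i + 1}"] = h
        logits = h @ p["out_W"] + p["out_b"]
        cache["logits"] = logits
        cache["probs"] = _softmax(logits)
        return cache

    def _backward(self, cache: dict, dlogits: np.ndarray) -> tuple[dict, np.ndarray]:
        """Gradients of the loss wrt parameters and the scaled Betti input."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        n_head = self.config.head_layers - 1
        h = cache[f"h{n_head}"]
        grads["out_W"] = h.T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        dh = dlogits @ p["out_W"].T
        for i in range(n_head - 1, -1, -1):
            dz = dh * (cache[f"hz{i}"] > 0)
            grads[f"head{i}_W"] = cache[f"h{i}"].T @ dz
            grads[f"head{i}_b"] = dz.sum(axis=0)
            dh = dz @ p[f"head{i}_W"].T
        if "drop_mask" in cache:
            dh = dh * cache["drop_mask"]
        hdim = self.config.backbone_hidden
        dhc, dhb = dh[:, :hdim], dh[:, hdim:]
        dzc = dhc * (cache["zc"] > 0)
        dzb = dhb * (cache["zb"] > 0)
        grads["emb_c_W"] = cache["xc"].T @ dzc
        grads["emb_c_b"] = dzc.sum(axis=0)
        grads["emb_b_W"] = cache["xb"].T @ dzb
        grads["emb_b_b"] = dzb.sum(axis=0)
        dxb = dzb @ p["emb_b_W"].T
        return grads, dxb

    # -- public API ---------------------------------------------------------

    def predict_proba(self, Xc: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        """Positive-class probability per subject (inference mode)."""
        Xc, Xb = self._check_shapes(Xc, Xb)
        cache = self._forward(Xc, self._scale_betti(Xb), train=False)
        return cache["probs"][:, 1]

    def _check_shapes(self, Xc, Xb) -> tuple[np.ndarray, np.ndarray]:
        Xc = np.atleast_2d(np.asarray(Xc, dtype=float))
        Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
        if Xc.shape[1] != self.n_connectome:
            raise ValueError(
                f"x_connectome has {Xc.shape[1]} features, expected {self.n_connectome}"
            )
        if Xb.shape[1] != self.n_betti:
            raise ValueError(
                f"x_betti has {Xb.shape[1]} features, expected {self.n_betti}"
            )
        return Xc, Xb

    def fit(self, Xc: np.ndarray, Xb: np.ndarray, y: np.ndarray) -> "BMHNet":
        """Train with softmax cross-entropy and decoupled weight decay."""
        Xc, Xb = self._check_shapes(Xc, Xb)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise SingleClassError("training data contains a single class")
        cfg = self.config
        if cfg.standardize_betti:
            self.betti_mean = Xb.mean(axis=0)
            sd = Xb.std(axis=0)
            self.betti_std = np.where(sd > 0, sd, 1.0)
        Xb_s = self._scale_betti(Xb)
        rng = np.random.default_rng(cfg.seed + 1)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(w) for k, w in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(y)
        onehot = np.eye(2)[y]
        self.loss_history = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                cache = self._forward(Xc[idx], Xb_s[idx], train=True, rng=rng)
                probs = cache["probs"]
                batch = len(idx)
                loss = -np.mean(
                    np.log(np.clip(probs[np.arange(batch), y[idx]], 1e-12, None))
                )
                epoch_loss += loss * batch
                dlogits = (probs - onehot[idx]) / batch
                grads, _ = self._backward(cache, dlogits)
                step += 1
                for k, w in self.params.items():
                    g = grads[k]
                    m[k] = beta1 * m[k] + (1 - beta1) * g
                    v[k] = beta2 * v[k] + (1 - beta2) * g * g
                    mh = m[k] / (1 - beta1**step)
                    vh = v[k] / (1 - beta2**step)
                    w -= cfg.learning_rate * (
                        mh / (np.sqrt(vh) + eps) + cfg.weight_decay * w
                    )
            self.loss_history.append(epoch_loss / n)
        return self

    def input_gradients(self, Xc: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        """d(positive-class probability)/d(Betti input) per subject.

        Gradients are taken at the standardized Betti inputs the
        backbone actually consumes, in inference mode.
        """
        Xc, Xb = self._check_shapes(Xc, Xb)
        cache = self._forward(Xc, self._scale_betti(Xb), train=False)
        probs = cache["probs"]
        # d p1 / d logits = p1 * (e1 - p)
        dlogits = probs[:, 1:2] * (np.array([0.0, 1.0]) - probs)
        _, dxb = self._backward(cache, dlogits)
        return dxb

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path,
            betti_mean=self.betti_mean,
            betti_std=self.betti_std,
            **self.params,
        )
        meta = dict(
            config=asdict(self.config),
            n_connectome=self.n_connectome,
            n_betti=self.n_betti,
        )
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "BMHNet":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        model = cls(meta["n_connectome"], meta["n_betti"],
                    NetConfig(**meta["config"]))
        data = np.load(path if path.suffix == ".npz" else f"{path}.npz")
        for k in model.params:
            model.params[k] = data[k]
        model.betti_mean = data["betti_mean"]
        model.betti_std = data["betti_std"]
        return model


def train(dataset: tuple[np.ndarray, np.ndarray, np.ndarray],
          config: NetConfig) -> BMHNet:
    """Train a fresh network on a (Xc, Xb, y) dataset."""
    Xc, Xb, y = dataset
    model = BMHNet(Xc.shape[1], Xb.shape[1], config)
    return model.fit(Xc, Xb, y)


# ---------------------------------------------------------------------------
# Evaluation: argmax-F binarization threshold
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    f_score: float
    accuracy: float
    precision: float
    sensitivity: float
    binarization_threshold: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _confusion_metrics(preds: np.ndarray, labels: np.ndarray) -> tuple[float, ...]:
    tp = int(np.sum((preds == 1) & (labels == 1)))
    fp = int(np.sum((preds == 1) & (labels == 0)))
    fn = int(np.sum((preds == 0) & (labels == 1)))
    tn = int(np.sum((preds == 0) & (labels == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    f = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    accuracy = (tp + tn) / len(labels)
    return f, accuracy, precision, sensitivity


def evaluate(scores: np.ndarray, labels: np.ndarray) -> EvalReport:
    """Binarize at the argmax-F threshold and report all four metrics.

    Candidate thresholds are the midpoints of consecutive sorted unique
    scores plus 0 and 1; prediction is positive when score >= threshold
    and ties in F are broken toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    warnings: list[str] = []
    if not np.any(labels == 1):
        raise UndefinedMetricError("no positive labels: sensitivity undefined")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([])
    candidates = np.unique(np.concatenate([[0.0, 1.0], mids]))
    best = None
    for thr in candidates:  # ascending; strict improvement keeps lower ties
        metrics = _confusion_metrics((scores >= thr).astype(int), labels)
        if best is None or metrics[0] > best[0][0]:
            best = (metrics, float(thr))
    (f, acc, prec, sens), thr = best
    if not np.any(scores >= thr):
        warnings.append("no predicted positives at chosen threshold")
    return EvalReport(
        f_score=f, accuracy=acc, precision=prec, sensitivity=sens,
        binarization_threshold=thr, warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

def cross_validate(Xc: np.ndarray, Xb: np.ndarray, y: np.ndarray,
                   config: NetConfig, n_splits: int = 5,
                   seeds: tuple[int, ...] = (0, 1, 2, 3, 4)) -> dict:
    """Stratified k-fold x seeds protocol.

    For every (seed, fold): train on the training folds, choose the
    binarization threshold and report metrics on the validation fold,
    and record the gradient-based subnetwork importances of the
    validation subjects.
    """
    y = np.asarray(y, dtype=int)
    reports: list[EvalReport] = []
    importances: list[dict[str, float]] = []
    for seed in seeds:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        for tr, va in skf.split(Xc, y):
            cfg = NetConfig(**{**asdict(config), "seed": seed})
            model = train((Xc[tr], Xb[tr], y[tr]), cfg)
            rep = evaluate(model.predict_proba(Xc[va], Xb[va]), y[va])
            reports.append(rep)
            importances.append(subnetwork_importance(model, Xc[va], Xb[va]))
    agg = {
        metric: (
            float(np.mean([getattr(r, metric) for r in reports])),
            float(np.std([getattr(r, metric) for r in reports])),
        )
        for metric in ("f_score", "accuracy", "precision", "sensitivity")
    }
    return {
        "reports": reports,
        "importances": importances,
        "aggregate": agg,
        "importance_aggregate": aggregate_importance(importances),
    }


# ---------------------------------------------------------------------------
# Gradient-based subnetwork importance
# ---------------------------------------------------------------------------

def subnetwork_importance(model: BMHNet, Xc_val: np.ndarray,
                          Xb_val: np.ndarray) -> dict[str, float]:
    """Importance of each subnetwork's Betti curves for one validation set.

    Per-input importance is the mean absolute gradient of the model
    output over validation subjects; a subnetwork's importance is the
    sum over its 2T inputs (its beta0 block and its beta1 block).
    """
    grads = model.input_gradients(Xc_val, Xb_val)
    per_input = np.mean(np.abs(grads), axis=0)
    n_betti = per_input.shape[0]
    if n_betti % (2 * len(SUBNETWORKS)):
        raise ConfigurationError("Betti feature length is not 18*T")
    T = n_betti // (2 * len(SUBNETWORKS))
    half = n_betti // 2
    out: dict[str, float] = {}
    for j, sub in enumerate(SUBNETWORKS):
        block0 = per_input[j * T:(j + 1) * T]
        block1 = per_input[half + j * T: half + (j + 1) * T]
        out[sub] = float(block0.sum() + block1.sum())
    return out


def aggregate_importance(
    per_split: list[dict[str, float]]
) -> dict[str, tuple[float, float]]:
    """Mean +- sd of importances over (seed, split) pairs."""
    return {
        sub: (
            float(np.mean([d[sub] for d in per_split])),
            float(np.std([d[sub] for d in per_split])),
        )
        for sub in SUBNETWORKS
    }


# ---------------------------------------------------------------------------
# Group-level Betti-curve comparison
# ---------------------------------------------------------------------------

def group_curve_test(betti_group0: np.ndarray, betti_group1: np.ndarray,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Independent-samples t-tests per grid point of the 18 curves.

    Inputs are (subjects, 18*T) stacks of ``x_betti`` vectors, one per
    group.  Returns a frame with raw and Holm-adjusted p-values and a
    significance flag; grid points where both groups have zero variance
    are flagged undefined and excluded from the correction.
    """
    g0 = np.atleast_2d(np.asarray(betti_group0, dtype=float))
    g1 = np.atleast_2d(np.asarray(betti_group1, dtype=float))
    if g0.shape[0] < 2 or g1.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if g0.shape[1] != g1.shape[1]:
        raise ValueError("groups have different feature lengths")
    D = g0.shape[1]
    if D % (2 * len(SUBNETWORKS)):
        raise ConfigurationError("Betti feature length is not 18*T")
    T = D // (2 * len(SUBNETWORKS))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, praw = stats.ttest_ind(g0, g1, axis=0)
    undefined = ~np.isfinite(praw)
    p_holm = np.full(D, np.nan)
    if np.any(~undefined):
        _, adj, _, _ = multipletests(praw[~undefined], method="holm")
        p_holm[~undefined] = adj
    half = D // 2
    n_index = np.where(np.arange(D) < half, 0, 1)
    sub_index = ((np.arange(D) % half) // T)
    return pd.DataFrame(
        {
            "subnetwork": [SUBNETWORKS[j] for j in sub_index],
            "n": n_index,
            "grid_index": np.arange(D) % T,
            "t": tstat,
            "p_raw": praw,
            "p_holm": p_holm,
            "significant": np.where(undefined, False, p_holm <= alpha),
            "undefined": undefined,
        }
    )
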