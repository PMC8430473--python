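"""MLP spectral classifier and Kohonen self-organizing map.

The classifier is a 196-18-6 multilayer perceptron: logistic hidden
layer, softmax output, categorical cross-entropy E = -sum_i d_i ln y_i
summed over training pairs, trained with BFGS (an optional gradient-
descent-with-momentum trainer is provided).  Classification uses
acceptance/rejection thresholds: a case is assigned to class c only if
y_c >= 0.95 and every other output <= 0.05, otherwise it is undecided;
the recognition rate counts thresholded hits and treats undecided as
incorrect.

The SOM is a 5 x 5 Kohonen map trained by the winner-takes-most rule
w(t+1) = w(t) + alpha(t) h_ci(t) [x - w(t)] with a Gaussian neighborhood
on the 2-D grid, linearly decaying learning rate (0.9 -> 0.01) and
radius (5 -> 0); its error metric is the quantization error, the mean
distance of each input to its best-matching unit.

Data are split into training / test / validation sets in proportions
5:1:1; sensitivity analysis scores each wavenumber by the loss ratio
after replacing its column with the training mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


UNDECIDED = -1


# --------------------------------------------------------------------------
# train / test / validation split


@dataclass
class SplitConfig:
    ratios: tuple[float, float, float] = (75.0, 15.0, 15.0)
    seed: int = 0
    stratified: bool = True

    def fractions(self) -> np.ndarray:
        r = np.asarray(self.ratios, dtype=float)
        if np.any(r < 0) or r.sum() <= 0:
            raise ValueError("split ratios must be non-negative with a positive sum")
        return r / r.sum()


def _partition_sizes(d: int, fractions: np.ndarray) -> list[int]:
    """Floor all but the last partition; the residual goes to the last."""
    sizes = [int(np.floor(d * f + 1e-9)) for f in fractions[:-1]]
    sizes.append(d - sum(sizes))
    return sizes


def _stratified_counts(class_counts: list[int], targets: list[int]) -> np.ndarray:
    """Per-class x per-partition counts matching row and column totals.

    Capped largest-remainder rounding of the ideal allocation
    n_c * T_p / d, preferring (on remainder ties) the class with the
    largest remaining deficit; keeps every class within one case of its
    proportional share.
    """
    d = sum(class_counts)
    n_cls, n_part = len(class_counts), len(targets)
    ideal = np.array([[c * t / d for t in targets] for c in class_counts])
    alloc = np.floor(ideal + 1e-9).astype(int)
    row_def = np.array(class_counts) - alloc.sum(axis=1)
    col_def = np.array(targets) - alloc.sum(axis=0)
    while row_def.sum() > 0:
        best, best_key = None, None
        for c in range(n_cls):
            if row_def[c] <= 0:
                continue
            for p in range(n_part):
                if col_def[p] <= 0:
                    continue
                key = (ideal[c, p] - alloc[c, p], row_def[c], -c, -p)
                if best_key is None or key > best_key:
                    best, best_key = (c, p), key
        if best is None:  # pragma: no cover - infeasible only if totals disagree
            raise RuntimeError("stratified allocation failed")
        c, p = best
        alloc[c, p] += 1
        row_def[c] -= 1
        col_def[p] -= 1
    return alloc


@dataclass
class Split:
    train: np.ndarray
    test: np.ndarray
    validation: np.ndarray

    def __iter__(self):
        return iter((self.train, self.test, self.validation))


def split_data(labels, cfg: SplitConfig | None = None) -> Split:
    """Disjoint, exhaustive, seeded (optionally stratified) index partition.

    ``labels`` is a per-row class label array (used when stratifying) or
    any sequence whose length is the number of rows.
    """
    cfg = cfg or SplitConfig()
    labels = np.asarray(labels)
    d = labels.shape[0]
    fractions = cfg.fractions()
    targets = _partition_sizes(d, fractions)
    rng = np.random.default_rng(cfg.seed)

    if not cfg.stratified:
        perm = rng.permutation(d)
        cuts = np.cumsum(targets)[:-1]
        parts = np.split(perm, cuts)
        return Split(*[np.sort(p) for p in parts])

    classes, class_idx = np.unique(labels, return_inverse=True)
    counts = [int(np.sum(class_idx == c)) for c in range(classes.size)]
    n_parts = len(targets)
    if any(c < n_parts for c in counts):
        raise ValueError("every class needs at least as many rows as partitions")
    alloc = _stratified_counts(counts, targets)
    parts: list[list[int]] = [[] for _ in targets]
    for c in range(classes.size):
        rows = np.flatnonzero(class_idx == c)
        rows = rng.permutation(rows)
        start = 0
        for p in range(n_parts):
            take = alloc[c, p]
            parts[p].extend(rows[start : start + take].tolist())
            start += take
    return Split(*[np.sort(np.array(p, dtype=int)) for p in parts])


# --------------------------------------------------------------------------
# multilayer perceptron


@dataclass
class MLPConfig:
    n_inputs: int = 196
    n_hidden: int = 18
    n_outputs: int = 6
    optimizer: str = "bfgs"  # or "momentum"
    epochs: int = 100
    learning_rate: float = 0.01  # used by the momentum trainer
    momentum: float = 0.80
    accept_threshold: float = 0.95
    reject_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.reject_threshold < self.accept_threshold < 1.0):
            raise ValueError("thresholds must satisfy 0 < reject < accept < 1")


@dataclass
class TrainReport:
    loss_history: list[float]
    recognition: dict[str, float]
    confusion: pd.DataFrame
    n_train: int


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


class MLP:
    """Feed-forward classifier with one logistic hidden layer and softmax output."""

    def __init__(self, config: MLPConfig | None = None):
        self.config = config or MLPConfig()
        self._params: np.ndarray | None = None

    # ----- parameter plumbing

    def _shapes(self):
        c = self.config
        return [(c.n_inputs, c.n_hidden), (c.n_hidden,), (c.n_hidden, c.n_outputs), (c.n_outputs,)]

    def _unpack(self, theta: np.ndarray):
        chunks, start = [], 0
        for shape in self._shapes():
            size = int(np.prod(shape))
            chunks.append(theta[start : start + size].reshape(shape))
            start += size
        return chunks

    def _init_params(self) -> np.ndarray:
        c = self.config
        rng = np.random.default_rng(c.seed)
        w1 = rng.normal(0.0, 1.0 / np.sqrt(c.n_inputs), size=(c.n_inputs, c.n_hidden))
        w2 = rng.normal(0.0, 1.0 / np.sqrt(c.n_hidden), size=(c.n_hidden, c.n_outputs))
        return np.concatenate([w1.ravel(), np.zeros(c.n_hidden), w2.ravel(), np.zeros(c.n_outputs)])

    # ----- forward / loss / gradient

    def _forward(self, X: np.ndarray, theta: np.ndarray):
        w1, b1, w2, b2 = self._unpack(theta)
        h = _logistic(X @ w1 + b1)
        y = _softmax(h @ w2 + b2)
        return h, y

    def loss_and_grad(self, theta: np.ndarray, X: np.ndarray, D: np.ndarray):
        """Summed cross-entropy -sum d ln y and its analytic gradient."""
        w1, b1, w2, b2 = self._unpack(theta)
        h, y = self._forward(X, theta)
        loss = -float(np.sum(D * np.log(np.clip(y, 1e-300, None))))
        delta_out = y - D  # (n, K)
        g_w2 = h.T @ delta_out
        g_b2 = delta_out.sum(axis=0)
        delta_h = (delta_out @ w2.T) * h * (1.0 - h)
        g_w1 = X.T @ delta_h
        g_b1 = delta_h.sum(axis=0)
        grad = np.concatenate([g_w1.ravel(), g_b1, g_w2.ravel(), g_b2])
        return loss, grad

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        D = one_hot(np.asarray(y), self.config.n_outputs)
        return self.loss_and_grad(self._params, X, D)[0]

    # ----- training

    def fit(self, X: np.ndarray, y: np.ndarray) -> list[float]:
        """Train on integer class labels; returns the per-epoch loss history."""
        c = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size < c.n_outputs:
            raise ValueError("every class must be present in the training set")
        D = one_hot(y, c.n_outputs)
        theta = self._init_params()
        history = [self.loss_and_grad(theta, X, D)[0]]

        if c.optimizer == "bfgs":
            theta = self._bfgs(theta, X, D, c.epochs, history)
        elif c.optimizer == "momentum":
            velocity = np.zeros_like(theta)
            for _ in range(c.epochs):
                loss, grad = self.loss_and_grad(theta, X, D)
                velocity = c.momentum * velocity - c.learning_rate * grad
                theta = theta + velocity
                history.append(self.loss_and_grad(theta, X, D)[0])
        else:
            raise ValueError(f"unknown optimizer {c.optimizer!r}")

        if not np.all(np.isfinite(theta)):
            raise FloatingPointError("training diverged to non-finite parameters")
        self._params = theta
        self.loss_history_ = history
        return history

    def _bfgs(
        self,
        theta: np.ndarray,
        X: np.ndarray,
        D: np.ndarray,
        maxiter: int,
        history: list[float],
        gtol: float = 1e-10,
    ) -> np.ndarray:
        """BFGS with an Armijo backtracking line search.

        The inverse-Hessian approximation is kept dense but refreshed with
        the rank-2 update written as outer products (O(n^2) per epoch), so
        the several-thousand-parameter spectral network trains in seconds.
        """
        n = theta.size
        H = np.eye(n)
        f, g = self.loss_and_grad(theta, X, D)
        for _ in range(maxiter):
            if np.linalg.norm(g, ord=np.inf) < gtol:
                break
            p = -H @ g
            gTp = float(g @ p)
            if gTp >= 0:  # lost positive-definiteness; restart from steepest descent
                H = np.eye(n)
                p = -g
                gTp = -float(g @ g)
            # Armijo backtracking
            alpha, ok = 1.0, False
            for _ls in range(40):
                f_new, g_new = self.loss_and_grad(theta + alpha * p, X, D)
                if np.isfinite(f_new) and f_new <= f + 1e-4 * alpha * gTp:
                    ok = True
                    break
                alpha *= 0.5
            if not ok:
                history.append(f)
                break
            s = alpha * p
            yk = g_new - g
            theta = theta + s
            f, g = f_new, g_new
            history.append(f)
            sy = float(s @ yk)
            if sy > 1e-12 * float(np.linalg.norm(s) * np.linalg.norm(yk) + 1e-300):
                rho = 1.0 / sy
                Hy = H @ yk
                yHy = float(yk @ Hy)
                H -= rho * (np.outer(s, Hy) + np.outer(Hy, s))
                H += (rho * rho * yHy + rho) * np.outer(s, s)
        return theta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise ValueError("model is not trained")
        return self._forward(np.asarray(X, dtype=float), self._params)[1]


def classify(proba: np.ndarray, accept: float = 0.95, reject: float = 0.05) -> np.ndarray:
    """Thresholded class decision per row; UNDECIDED (-1) when ambiguous."""
    proba = np.atleast_2d(proba)
    top = proba.argmax(axis=1)
    decided = proba[np.arange(len(proba)), top] >= accept
    others_ok = np.array(
        [np.all(np.delete(row, t) <= reject) for row, t in zip(proba, top)]
    )
    out = np.where(decided & others_ok, top, UNDECIDED)
    return out


def recognition_rate(proba: np.ndarray, y_true: np.ndarray, accept: float = 0.95, reject: float = 0.05) -> float:
    """Fraction of cases whose thresholded decision equals the true class."""
    decided = classify(proba, accept, reject)
    return float(np.mean(decided == np.asarray(y_true)))


def confusion_table(proba: np.ndarray, y_true: np.ndarray, class_names, accept=0.95, reject=0.05) -> pd.DataFrame:
    """Rows = true classes, columns = decided classes plus an 'undecided' column."""
    decided = classify(proba, accept, reject)
    names = list(class_names)
    table = pd.DataFrame(
        0, index=names, columns=names + ["undecided"], dtype=int
    )
    for t, d in zip(np.asarray(y_true), decided):
        col = "undecided" if d == UNDECIDED else names[d]
        table.loc[names[t], col] += 1
    return table


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    split: Split,
    class_names,
    config: MLPConfig | None = None,
) -> tuple[MLP, TrainReport]:
    """Train on the split's training rows; report all three recognition rates."""
    config = config or MLPConfig()
    model = MLP(config)
    history = model.fit(X[split.train], y[split.train])
    recog = {}
    for name, idx in (("train", split.train), ("test", split.test), ("validation", split.validation)):
        if idx.size == 0:
            recog[name] = np.nan
            continue
        proba = model.predict_proba(X[idx])
        recog[name] = recognition_rate(proba, y[idx], config.accept_threshold, config.reject_threshold)
    confusion = confusion_table(
        model.predict_proba(X), y, class_names, config.accept_threshold, config.reject_threshold
    )
    report = TrainReport(
        loss_history=history, recognition=recog, confusion=confusion, n_train=int(split.train.size)
    )
    return model, report


def gain_curve(proba: np.ndarray, y_true: np.ndarray, target_class: int) -> pd.DataFrame:
    """Cumulative-gain curve for one class.

    Cases are ranked by descending predicted probability of the target
    class; the curve gives the fraction of that class captured within the
    top x fraction of cases, alongside the random-baseline diagonal.
    """
    proba = np.atleast_2d(proba)
    y_true = np.asarray(y_true)
    is_target = y_true == target_class
    n_target = int(is_target.sum())
    if n_target == 0:
        raise ValueError(f"class {target_class} absent from the data")
    order = np.argsort(-proba[:, target_class], kind="stable")
    captured = np.cumsum(is_target[order]) / n_target
    frac_cases = np.arange(1, len(y_true) + 1) / len(y_true)
    return pd.DataFrame(
        {"fraction_cases": frac_cases, "fraction_captured": captured, "baseline": frac_cases}
    )


# --------------------------------------------------------------------------
# Kohonen self-organizing map


@dataclass
class SOMConfig:
    grid_shape: tuple[int, int] = (5, 5)
    epochs: int = 1000
    alpha_start: float = 0.9
    alpha_end: float = 0.01
    radius_start: float = 5.0
    radius_end: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_start < 1.0 and 0.0 <= self.alpha_end < 1.0):
            raise ValueError("learning rates must lie in (0, 1)")
        if self.radius_start < 0 or self.radius_end < 0:
            raise ValueError("neighborhood radii must be non-negative")


class SOM:
    """5 x 5 Kohonen map trained by the winner-takes-most update rule."""

    def __init__(self, config: SOMConfig | None = None):
        self.config = config or SOMConfig()
        gy, gx = self.config.grid_shape
        yy, xx = np.meshgrid(np.arange(gy), np.arange(gx), indexing="ij")
        self.grid_coords = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
        self.n_neurons = gy * gx
        self.weights: np.ndarray | None = None
        # pairwise squared grid distances between neurons
        diff = self.grid_coords[:, None, :] - self.grid_coords[None, :, :]
        self._grid_d2 = np.sum(diff**2, axis=-1)

    def _schedule(self, epoch: int) -> tuple[float, float]:
        c = self.config
        frac = epoch / max(c.epochs - 1, 1)
        alpha = c.alpha_start + (c.alpha_end - c.alpha_start) * frac
        radius = c.radius_start + (c.radius_end - c.radius_start) * frac
        return alpha, max(radius, 1e-3)

    def fit(self, X: np.ndarray) -> "SOM":
        c = self.config
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(c.seed)
        lo, hi = X.min(axis=0), X.max(axis=0)
        W = rng.uniform(lo, hi, size=(self.n_neurons, X.shape[1]))
        last_max_update = np.inf
        for epoch in range(c.epochs):
            alpha, radius = self._schedule(epoch)
            h_cache = np.exp(-self._grid_d2 / (2.0 * radius**2))
            if radius <= 1e-3:  # winner-takes-all limit
                h_cache = np.eye(self.n_neurons)
            order = rng.permutation(X.shape[0])
            max_update = 0.0
            for i in order:
                x = X[i]
                bmu = int(np.argmin(np.einsum("nj,nj->n", W - x, W - x)))
                step = alpha * h_cache[bmu][:, None] * (x - W)
                W += step
                if epoch == c.epochs - 1:
                    max_update = max(max_update, float(np.abs(step).max()))
            last_max_update = max_update
        self.weights = W
        self.final_max_update_ = last_max_update
        return self

    def bmu(self, X: np.ndarray) -> np.ndarray:
        if self.weights is None:
            raise ValueError("SOM is not trained")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=-1)
        return d2.argmin(axis=1)


def quantization_error(som: SOM, X: np.ndarray) -> float:
    """Mean Euclidean distance of each input to its best-matching unit."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty data set")
    winners = som.bmu(X)
    return float(np.linalg.norm(X - som.weights[winners], axis=1).mean())


@dataclass
class ClusterMap:
    neuron_class: np.ndarray  # majority class per neuron, -1 when empty
    hit_counts: np.ndarray  # inputs mapped to each neuron
    clusters: dict  # class label -> sorted neuron indices
    n_clusters: int


def map_clusters(som: SOM, X: np.ndarray, labels) -> ClusterMap:
    """Label each neuron by the majority class of the inputs it wins."""
    labels = np.asarray(labels)
    winners = som.bmu(X)
    classes = np.unique(labels)
    neuron_class = np.full(som.n_neurons, -1, dtype=object)
    hits = np.zeros(som.n_neurons, dtype=int)
    for n in range(som.n_neurons):
        mine = labels[winners == n]
        hits[n] = mine.size
        if mine.size:
            vals, counts = np.unique(mine, return_counts=True)
            neuron_class[n] = vals[np.argmax(counts)]
    clusters = {
        c: sorted(np.flatnonzero(neuron_class == c).tolist())
        for c in classes
        if np.any(neuron_class == c)
    }
    return ClusterMap(
        neuron_class=neuron_class, hit_counts=hits, clusters=clusters, n_clusters=len(clusters)
    )


# --------------------------------------------------------------------------
# sensitivity analysis


@dataclass
class SensitivityResult:
    ratios: np.ndarray  # E(perturbed) / E(full) per variable
    important: np.ndarray  # ratio >= 1
    count_important: int
    ranges: list[tuple[float, float]]  # contiguous important wavenumber ranges


def sensitivity(
    model: MLP,
    X: np.ndarray,
    y: np.ndarray,
    wavenumbers: np.ndarray | None = None,
    mode: str = "mean",
    seed: int = 0,
) -> SensitivityResult:
    """Per-variable loss ratio after knocking the variable out.

    A variable is removed by replacing its column with the data mean
    (``mode='mean'``) or a seeded within-column permutation
    (``mode='permute'``); variables whose ratio is >= 1 are 'important'.
    """
    if model._params is None:
        raise ValueError("model is not trained")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    e_full = model.loss(X, y)
    if e_full <= 0:
        e_full = 1e-12
    rng = np.random.default_rng(seed)
    ratios = np.empty(X.shape[1])
    col_backup = None
    Xp = X.copy()
    for j in range(X.shape[1]):
        col_backup = Xp[:, j].copy()
        if mode == "mean":
            Xp[:, j] = X[:, j].mean()
        elif mode == "permute":
            Xp[:, j] = X[rng.permutation(X.shape[0]), j]
        else:
            raise ValueError(f"unknown sensitivity mode {mode!r}")
        ratios[j] = model.loss(Xp, y) / e_full
        Xp[:, j] = col_backup
    important = ratios >= 1.0

    ranges: list[tuple[float, float]] = []
    if wavenumbers is not None:
        w = np.asarray(wavenumbers, dtype=float)
        start = None
        for j in range(len(w) + 1):
            flag = important[j] if j < len(w) else False
            if flag and start is None:
                start = j
            elif not flag and start is not None:
                seg = w[start:j]
                ranges.append((float(seg.max()), float(seg.min())))
                start = None
    return SensitivityResult(
        ratios=ratios, important=important, count_important=int(important.sum()), ranges=ranges
    )
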