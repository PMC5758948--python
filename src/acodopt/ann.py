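"""Feed-forward neural predictor of biogas yield and methane content.

A single-hidden-layer perceptron maps nine digestion-kinetics variables
(TAN, FAN, TVFA, the four individual VFAs, temperature, pH) to two outputs
(cumulative biogas yield in mL/gVS and biomethane content in %).  The
hidden layer is tanh, the output layer linear, and training is full-batch
Levenberg–Marquardt on the sum of squared residuals:

    delta_w = (J'J + mu*I)^-1 J' e

with the damping factor mu decreased tenfold after every accepted step and
increased tenfold after every rejected one — a damped Gauss–Newton scheme
that interpolates between Newton steps (mu -> 0) and short gradient-descent
steps (mu large).  Inputs and targets are affinely normalized to [-1, 1]
per variable on the training split; data are partitioned 70/15/15 into
training, validation and test sets, and training stops early once the
validation error has risen for ``patience`` consecutive epochs (the weights
from the best validation epoch are returned).

The hidden-layer width is chosen by :func:`architecture_search`: candidates
are trained, tabulated by split MSE and correlation, candidates whose
validation or test MSE exceeds ``kappa`` times their training MSE are
flagged as overfit, and the best remaining overall correlation wins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANN_INPUT_COLUMNS",
    "ANN_TARGET_COLUMNS",
    "Dataset",
    "TrainHyperparams",
    "TrainedMLP",
    "FitMetrics",
    "LMConvergenceError",
    "split_labels",
    "mse",
    "r2",
    "corrcoef",
    "init_network",
    "train_lm",
    "evaluate",
    "architecture_search",
    "select_architecture",
]

#: Fixed input-column order of the kinetics feature vector.
ANN_INPUT_COLUMNS = (
    "tan_mg_l",
    "fan_mg_l",
    "tvfa_mg_l",
    "acetic_mg_l",
    "propionic_mg_l",
    "butyric_mg_l",
    "valeric_mg_l",
    "temp_c",
    "ph",
)
ANN_TARGET_COLUMNS = ("bgp_ml_per_gvs", "bmp_content_pct")

SPLITS = ("train", "val", "test")


class LMConvergenceError(RuntimeError):
    """Levenberg–Marquardt could not accept a single damped step."""


def mse(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Mean squared error ``(1/n) * sum (pred - obs)^2``."""
    p = np.asarray(pred, dtype=float).ravel()
    o = np.asarray(obs, dtype=float).ravel()
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("mse requires at least one sample")
    return float(np.mean((p - o) ** 2))


def r2(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Coefficient of determination ``1 - SSres/SStot``."""
    p = np.asarray(pred, dtype=float).ravel()
    o = np.asarray(obs, dtype=float).ravel()
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size < 2:
        raise ValueError("r2 requires at least two samples")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r2 undefined: observations have zero variance")
    return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot


def corrcoef(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Pearson correlation between predictions and observations."""
    p = np.asarray(pred, dtype=float).ravel()
    o = np.asarray(obs, dtype=float).ravel()
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size < 2:
        raise ValueError("corrcoef requires at least two samples")
    return float(np.corrcoef(p, o)[0, 1])


def split_labels(
    n: int,
    seed: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> np.ndarray:
    """Random 70/15/15 train/val/test assignment, deterministic under seed.

    Counts are floors of ``n * fraction``; leftover rows go to train, then
    validation, then test (so 20 rows split 14/3/3).
    """
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    counts = [int(np.floor(n * f)) for f in fractions]
    i = 0
    while sum(counts) < n:
        counts[i % 3] += 1
        i += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    start = 0
    for name, c in zip(SPLITS, counts):
        labels[perm[start:start + c]] = name
        start += c
    return labels.astype(str)


@dataclass
class Dataset:
    """Feature matrix (n x 9), target matrix (n x 2) and split assignment."""

    X: np.ndarray
    Y: np.ndarray
    split: np.ndarray | None = None
    feature_names: tuple[str, ...] = ANN_INPUT_COLUMNS
    target_names: tuple[str, ...] = ANN_TARGET_COLUMNS

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        missing = [c for c in (*ANN_INPUT_COLUMNS, *ANN_TARGET_COLUMNS)
                   if c not in df.columns]
        if missing:
            raise ValueError(f"ANN dataset missing columns: {missing}")
        return cls(
            X=df.loc[:, list(ANN_INPUT_COLUMNS)].to_numpy(float),
            Y=df.loc[:, list(ANN_TARGET_COLUMNS)].to_numpy(float),
        )

    def with_split(self, seed: int) -> "Dataset":
        return Dataset(self.X, self.Y, split_labels(len(self.X), seed),
                       self.feature_names, self.target_names)

    def rows(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        if self.split is None:
            raise ValueError("dataset has no split assignment")
        m = self.split == which
        return self.X[m], self.Y[m]


@dataclass(frozen=True)
class TrainHyperparams:
    """LM training knobs (defaults follow common toolbox practice)."""

    max_epochs: int = 1000
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    patience: int = 6          # consecutive validation-MSE rises tolerated
    min_grad: float = 1e-10    # stop when max |gradient| falls below this
    goal: float = 0.0          # stop when training SSE reaches this


@dataclass
class _AffineNorm:
    """Per-column affine map to [-1, 1] (constant columns map to 0)."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_AffineNorm":
        return cls(lo=X.min(axis=0), hi=X.max(axis=0))

    def forward(self, X: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        safe = np.where(span == 0, 1.0, span)
        out = 2.0 * (X - self.lo) / safe - 1.0
        return np.where(span == 0, 0.0, out)

    def inverse(self, Xn: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        return (Xn + 1.0) / 2.0 * span + self.lo


@dataclass
class TrainedMLP:
    """A trained (or freshly initialized) 9-h-2 perceptron."""

    W1: np.ndarray            # (h, 9)
    b1: np.ndarray            # (h,)
    W2: np.ndarray            # (2, h)
    b2: np.ndarray            # (2,)
    x_norm: _AffineNorm
    y_norm: _AffineNorm
    seed: int
    trace_train: list[float] = field(default_factory=list)
    trace_val: list[float] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = "init"

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.W1.shape[1], self.W1.shape[0], self.W2.shape[0])

    @property
    def n_params(self) -> int:
        n_in, h, n_out = self.layer_sizes
        return n_in * h + h + n_out * h + n_out

    def forward_normalized(self, Xn: np.ndarray) -> np.ndarray:
        A = np.tanh(Xn @ self.W1.T + self.b1)
        return A @ self.W2.T + self.b2

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predictions in original target units."""
        Xn = self.x_norm.forward(np.asarray(X, dtype=float))
        return self.y_norm.inverse(self.forward_normalized(Xn))

    # --- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "layer_sizes": list(self.layer_sizes),
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "x_lo": self.x_norm.lo.tolist(), "x_hi": self.x_norm.hi.tolist(),
            "y_lo": self.y_norm.lo.tolist(), "y_hi": self.y_norm.hi.tolist(),
            "seed": self.seed,
            "trace_train": self.trace_train, "trace_val": self.trace_val,
            "stop_epoch": self.stop_epoch, "stop_reason": self.stop_reason,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedMLP":
        d = json.loads(Path(path).read_text())
        return cls(
            W1=np.array(d["W1"]), b1=np.array(d["b1"]),
            W2=np.array(d["W2"]), b2=np.array(d["b2"]),
            x_norm=_AffineNorm(np.array(d["x_lo"]), np.array(d["x_hi"])),
            y_norm=_AffineNorm(np.array(d["y_lo"]), np.array(d["y_hi"])),
            seed=int(d["seed"]),
            trace_train=list(d["trace_train"]),
            trace_val=list(d["trace_val"]),
            stop_epoch=int(d["stop_epoch"]),
            stop_reason=str(d["stop_reason"]),
        )


def init_network(h: int, seed: int, n_in: int = 9, n_out: int = 2,
                 x_norm: _AffineNorm | None = None,
                 y_norm: _AffineNorm | None = None) -> TrainedMLP:
    """Seeded uniform [-0.5, 0.5] weight initialization."""
    if h < 1:
        raise ValueError(f"hidden width must be >= 1, got {h}")
    rng = np.random.default_rng(seed)
    return TrainedMLP(
        W1=rng.uniform(-0.5, 0.5, (h, n_in)),
        b1=rng.uniform(-0.5, 0.5, h),
        W2=rng.uniform(-0.5, 0.5, (n_out, h)),
        b2=rng.uniform(-0.5, 0.5, n_out),
        x_norm=x_norm or _AffineNorm(np.zeros(n_in) - 1, np.zeros(n_in) + 1),
        y_norm=y_norm or _AffineNorm(np.zeros(n_out) - 1, np.zeros(n_out) + 1),
        seed=seed,
    )


def _pack(net: TrainedMLP) -> np.ndarray:
    return np.concatenate([net.W1.ravel(), net.b1,
                           net.W2.ravel(), net.b2])


def _unpack(w: np.ndarray, n_in: int, h: int, n_out: int):
    i = 0
    W1 = w[i:i + h * n_in].reshape(h, n_in); i += h * n_in
    b1 = w[i:i + h]; i += h
    W2 = w[i:i + n_out * h].reshape(n_out, h); i += n_out * h
    b2 = w[i:i + n_out]
    return W1, b1, W2, b2


def _residuals(w, Xn, Tn, n_in, h, n_out):
    W1, b1, W2, b2 = _unpack(w, n_in, h, n_out)
    A = np.tanh(Xn @ W1.T + b1)
    R = A @ W2.T + b2 - Tn          # (n, n_out)
    return R, A


def _jacobian(w, Xn, A, n_in, h, n_out):
    """Jacobian of the stacked residual vector wrt the packed parameters.

    Row block k (k = 0..n_out-1) holds the n residuals of output k; the
    column order matches :func:`_pack`.
    """
    W1, b1, W2, b2 = _unpack(w, n_in, h, n_out)
    n = Xn.shape[0]
    G = 1.0 - A ** 2                 # tanh'(z), (n, h)
    p = h * n_in + h + n_out * h + n_out
    J = np.zeros((n_out * n, p))
    for k in range(n_out):
        rows = slice(k * n, (k + 1) * n)
        GW = G * W2[k]                                # (n, h)
        J[rows, : h * n_in] = np.einsum("nh,ni->nhi", GW, Xn).reshape(n, -1)
        J[rows, h * n_in: h * n_in + h] = GW
        J[rows, h * n_in + h + k * h: h * n_in + h + (k + 1) * h] = A
        J[rows, -n_out + k] = 1.0
    return J


def train_lm(
    data: Dataset,
    h: int,
    hyper: TrainHyperparams | None = None,
    seed: int = 0,
) -> TrainedMLP:
    """Train a 9-h-2 network by Levenberg–Marquardt with early stopping.

    One epoch is one accepted damped Gauss–Newton step.  The returned
    network carries the weights from the best validation epoch (or the last
    epoch when the dataset has no validation rows), the per-epoch training
    and validation MSE trace on the normalized scale, and the stop reason.
    ``max_epochs = 0`` returns the seeded initial network unchanged.
    """
    hp = hyper or TrainHyperparams()
    if data.split is None:
        raise ValueError("train_lm requires a dataset with a split assignment")
    Xtr, Ytr = data.rows("train")
    Xva, Yva = data.rows("val")
    if len(Xtr) == 0:
        raise ValueError("empty training split")

    x_norm = _AffineNorm.fit(Xtr)
    y_norm = _AffineNorm.fit(Ytr)
    net = init_network(h, seed, data.X.shape[1], data.Y.shape[1],
                       x_norm, y_norm)
    n_in, _, n_out = net.layer_sizes

    Xn, Tn = x_norm.forward(Xtr), y_norm.forward(Ytr)
    has_val = len(Xva) > 0
    Xvn = x_norm.forward(Xva) if has_val else None
    Tvn = y_norm.forward(Yva) if has_val else None

    w = _pack(net)
    R, A = _residuals(w, Xn, Tn, n_in, h, n_out)
    sse = float(np.sum(R ** 2))

    def val_mse(wv):
        Rv, _ = _residuals(wv, Xvn, Tvn, n_in, h, n_out)
        return float(np.mean(Rv ** 2))

    net.trace_train.append(sse / R.size)
    best_val = val_mse(w) if has_val else np.inf
    if has_val:
        net.trace_val.append(best_val)
    best_w = w.copy()
    best_epoch = 0
    fails = 0
    mu = hp.mu0
    accepted_any = False
    stop_reason = "max_epochs"

    epoch = 0
    while epoch < hp.max_epochs:
        J = _jacobian(w, Xn, A, n_in, h, n_out)
        e = R.T.ravel()              # output-major stacking, matches J
        g = J.T @ e
        if np.max(np.abs(g)) < hp.min_grad:
            stop_reason = "min_grad"
            break
        H = J.T @ J
        accepted = False
        while mu <= hp.mu_max:
            try:
                delta = np.linalg.solve(H + mu * np.eye(len(w)), -g)
            except np.linalg.LinAlgError:
                mu *= hp.mu_inc
                continue
            w_try = w + delta
            R_try, A_try = _residuals(w_try, Xn, Tn, n_in, h, n_out)
            sse_try = float(np.sum(R_try ** 2))
            if np.isfinite(sse_try) and sse_try < sse:
                w, R, A, sse = w_try, R_try, A_try, sse_try
                mu = max(mu * hp.mu_dec, 1e-20)
                accepted = True
                accepted_any = True
                break
            mu *= hp.mu_inc
        if not accepted:
            if not accepted_any:
                raise LMConvergenceError(
                    "no damped step decreased the error before mu was "
                    f"exhausted (mu > {hp.mu_max:g})"
                )
            stop_reason = "mu_max"
            break

        epoch += 1
        net.trace_train.append(sse / R.size)
        if has_val:
            v = val_mse(w)
            net.trace_val.append(v)
            if v < best_val:
                best_val, best_w, best_epoch = v, w.copy(), epoch
                fails = 0
            else:
                fails += 1
                if fails >= hp.patience:
                    stop_reason = "early_stop"
                    break
        else:
            best_w, best_epoch = w.copy(), epoch
        if sse <= hp.goal:
            stop_reason = "goal"
            break

    if not has_val:
        best_w, best_epoch = w.copy(), epoch
    net.W1, net.b1, net.W2, net.b2 = _unpack(best_w, n_in, h, n_out)
    net.stop_epoch = best_epoch
    net.stop_reason = stop_reason
    return net


@dataclass(frozen=True)
class FitMetrics:
    """Split-wise fit quality in original target units."""

    mse: Mapping[str, float]          # per split, averaged over both outputs
    r: Mapping[str, float]            # Pearson R per split and "all"
    r2_per_output: Mapping[str, float]        # over all rows
    r2_test_per_output: Mapping[str, float]   # over the test split


def evaluate(model: TrainedMLP, data: Dataset) -> FitMetrics:
    """MSE per split, correlation per split and overall, R² per output."""
    if data.split is None:
        raise ValueError("evaluate requires a dataset with a split assignment")
    mses, rs = {}, {}
    for which in SPLITS:
        X, Y = data.rows(which)
        if len(X) == 0:
            continue
        P = model.predict(X)
        mses[which] = mse(P, Y)
        rs[which] = corrcoef(P, Y)
    P_all = model.predict(data.X)
    rs["all"] = corrcoef(P_all, data.Y)
    r2_all = {name: r2(P_all[:, j], data.Y[:, j])
              for j, name in enumerate(data.target_names)}
    Xte, Yte = data.rows("test")
    Pte = model.predict(Xte)
    r2_test = {name: r2(Pte[:, j], Yte[:, j])
               for j, name in enumerate(data.target_names)}
    return FitMetrics(mse=mses, r=rs, r2_per_output=r2_all,
                      r2_test_per_output=r2_test)


#: Hidden-layer candidates: coarse sweep then refinement around the knee.
DEFAULT_CANDIDATES = (5, 10, 15, 20, 25, 30, 50, 16, 17, 18, 19)


def select_architecture(
    table: pd.DataFrame, kappa: float = 10.0
) -> tuple[int, list[int]]:
    """Pick the hidden width from a candidate metrics table.

    Flags a candidate as overfit when its validation or test MSE exceeds
    ``kappa`` times its training MSE; among the rest, returns the candidate
    with the highest overall correlation.  Expects columns
    ``hidden_neurons, mse_train, mse_val, mse_test, r_all``.
    """
    required = {"hidden_neurons", "mse_train", "mse_val", "mse_test", "r_all"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metrics table missing columns {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("empty candidate table")
    t = table.dropna(subset=["mse_train", "mse_val", "mse_test", "r_all"])
    overfit = t[
        (t["mse_val"] > kappa * t["mse_train"])
        | (t["mse_test"] > kappa * t["mse_train"])
    ]["hidden_neurons"].astype(int).tolist()
    ok = t[~t["hidden_neurons"].isin(overfit)]
    if len(ok) == 0:
        warnings.warn("every candidate flagged overfit; selecting among all")
        ok = t
    h_star = int(ok.loc[ok["r_all"].idxmax(), "hidden_neurons"])
    return h_star, overfit


def architecture_search(
    data: Dataset,
    candidates: Sequence[int] = DEFAULT_CANDIDATES,
    seed: int = 0,
    hyper: TrainHyperparams | None = None,
    kappa: float = 10.0,
) -> tuple[int, pd.DataFrame]:
    """Train each candidate width and select the best by overall R.

    Training failures are recorded as NaN rows and skipped by the selection
    rule.  Each candidate trains from its own seed derived from ``seed`` so
    the comparison is reproducible.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list must be nonempty")
    rows = []
    for h in candidates:
        child_seed = int(
            np.random.SeedSequence(seed, spawn_key=(h,)).generate_state(1)[0]
            % (2**31)
        )
        rec: dict[str, float] = {"hidden_neurons": h}
        try:
            net = train_lm(data, h, hyper, seed=child_seed)
            m = evaluate(net, data)
            rec.update(
                mse_train=m.mse["train"], mse_val=m.mse.get("val", np.nan),
                mse_test=m.mse.get("test", np.nan),
                r_train=m.r["train"], r_val=m.r.get("val", np.nan),
                r_test=m.r.get("test", np.nan), r_all=m.r["all"],
            )
        except LMConvergenceError:
            rec.update(mse_train=np.nan, mse_val=np.nan, mse_test=np.nan,
                       r_train=np.nan, r_val=np.nan, r_test=np.nan,
                       r_all=np.nan)
        rows.append(rec)
    table = pd.DataFrame(rows)
    h_star, _ = select_architecture(table, kappa=kappa)
    return h_star, table
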