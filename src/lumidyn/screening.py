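"""Plate-reader screening statistics and PLS structure-activity modelling.

Plate processing follows a six-step normalization of injection-based
luminescence readings: (1) average the negative-control wells per time point,
(2) blank every other well against that average, (3) split each well's series
into pre-injection and post-injection segments (the post segment starts once
the signal is stable, a settle delay after injection) and Tukey-filter each
segment, (4) raw intensity = mean(post) - mean(pre), (5) plate reference =
mean raw intensity of the positive controls, (6) relative intensity =
raw / reference.

PLS regression (autoscaled, centred X and Y) relates structural descriptors
to activities; importance is assessed with VIP scores (sum of squared VIPs
equals the number of X variables), predictivity with leave-1/7-out
cross-validated Q2, and significance with a 999-fold Y-permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "Well",
    "PlateReading",
    "WellIntensity",
    "PLSDataset",
    "PLSModel",
    "PLSValidation",
    "tukey_filter",
    "process_plate",
    "activity_summary",
    "pls_fit",
    "pls_validate",
]


# ---------------------------------------------------------------------------
# plate statistics
# ---------------------------------------------------------------------------

@dataclass
class Well:
    well_id: str
    role: str                  # "negative" | "positive" | "variant"
    signal: np.ndarray

    def __post_init__(self) -> None:
        if self.role not in ("negative", "positive", "variant"):
            raise ValueError(f"unknown well role {self.role!r}")
        self.signal = np.asarray(self.signal, dtype=float)


@dataclass
class PlateReading:
    time: np.ndarray               # s, shared by all wells
    wells: list[Well]
    injection_time: float = 10.0   # s
    settle_delay: float = 0.2      # s after injection before the signal is stable

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        roles = {w.role for w in self.wells}
        if "negative" not in roles or "positive" not in roles:
            raise ValueError("plate needs at least one negative and one positive control")
        for w in self.wells:
            if len(w.signal) != len(self.time):
                raise ValueError(f"well {w.well_id}: signal length differs from time grid")
        if not (self.time[0] <= self.injection_time <= self.time[-1]):
            raise ValueError("injection time lies outside the time grid")


@dataclass(frozen=True)
class WellIntensity:
    well_id: str
    role: str
    raw: float
    relative: float


def tukey_filter(series: np.ndarray) -> np.ndarray:
    """Drop points outside the Tukey fences [Q1 - 1.5*IQR, Q3 + 1.5*IQR].

    Quartiles use linear interpolation of order statistics.  With fewer than
    4 points the fences are undefined and the series is returned unfiltered
    with a warning.  Applied once, not iterated.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 4:
        warnings.warn("Tukey filter undefined for fewer than 4 points; series unchanged")
        return x
    q1, q3 = np.quantile(x, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return x[(x >= lo) & (x <= hi)]


def process_plate(plate: PlateReading) -> list[WellIntensity]:
    """Run the six-step plate normalization; returns one record per
    non-negative-control well."""
    t = plate.time
    negatives = [w for w in plate.wells if w.role == "negative"]
    blank = np.mean([w.signal for w in negatives], axis=0)        # step 1

    pre_mask = t < plate.injection_time                           # step 3 split
    post_mask = t >= plate.injection_time + plate.settle_delay
    if not pre_mask.any() or not post_mask.any():
        raise ValueError("injection split leaves an empty pre- or post-segment")

    raws: dict[str, tuple[str, float]] = {}
    for w in plate.wells:
        if w.role == "negative":
            continue
        blanked = w.signal - blank                                # step 2
        pre = tukey_filter(blanked[pre_mask])                     # step 3b
        post = tukey_filter(blanked[post_mask])
        raws[w.well_id] = (w.role, float(np.mean(post) - np.mean(pre)))  # step 4

    pos_raws = [r for role, r in raws.values() if role == "positive"]
    reference = float(np.mean(pos_raws))                          # step 5
    if reference <= 0:
        raise ValueError(
            f"plate reference intensity is non-positive ({reference}); "
            "relative intensities are undefined"
        )
    return [
        WellIntensity(well_id=wid, role=role, raw=raw, relative=raw / reference)
        for wid, (role, raw) in raws.items()                      # step 6
    ]


def activity_summary(
    relative: np.ndarray,
    template_value: float,
    factor: float = 2.0,
    bins: int | np.ndarray = 10,
) -> dict:
    """Histogram of activities relative to the template and the proportion of
    variants reaching at least `factor` times the template activity."""
    rel = np.asarray(relative, dtype=float)
    if rel.size == 0:
        raise ValueError("no activities supplied")
    if template_value <= 0:
        raise ValueError("template activity must be > 0")
    ratio = rel / template_value
    counts, edges = np.histogram(ratio, bins=bins)
    return {
        "n": int(rel.size),
        "ratio": ratio,
        "hist_counts": counts,
        "hist_edges": edges,
        "proportion_ge_factor": float(np.mean(ratio >= factor)),
        "factor": factor,
    }


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

@dataclass
class PLSDataset:
    X: np.ndarray                      # (n, p)
    Y: np.ndarray                      # (n, q)
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Y.shape[0] == 1 and self.X.shape[0] != 1:
            self.Y = self.Y.T
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        if np.any(np.std(self.X, axis=0) == 0):
            bad = [i for i in range(self.X.shape[1]) if np.std(self.X[:, i]) == 0]
            raise ValueError(f"constant X columns cannot be autoscaled: {bad}")
        if not self.x_names:
            self.x_names = [f"x{i + 1}" for i in range(self.X.shape[1])]
        if not self.y_names:
            self.y_names = [f"y{i + 1}" for i in range(self.Y.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _autoscale(A: np.ndarray, mean=None, std=None):
    mean = A.mean(axis=0) if mean is None else mean
    std = A.std(axis=0, ddof=1) if std is None else std
    std = np.where(std == 0, 1.0, std)
    return (A - mean) / std, mean, std


@dataclass
class PLSModel:
    n_components: int
    coefficients: np.ndarray       # (p, q), on autoscaled variables
    r2: np.ndarray                 # per response
    vip: np.ndarray                # (p,)
    x_scores: np.ndarray
    x_weights: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    x_names: list[str]
    y_names: list[str]

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        return (Xs @ self.coefficients) * self.y_std + self.y_mean


def _vip_scores(pls: PLSRegression, Ys: np.ndarray) -> np.ndarray:
    """Standard VIP: weighted by the Y-variance explained per component."""
    T = pls.x_scores_
    W = pls.x_weights_
    Q = pls.y_loadings_
    p, a = W.shape
    # SS of Y explained by each component
    ssy = np.array([
        np.sum(T[:, k] ** 2) * np.sum(Q[:, k] ** 2) for k in range(a)
    ])
    wnorm2 = np.sum(W**2, axis=0)
    vip = np.sqrt(p * (W**2 / wnorm2) @ ssy / np.sum(ssy))
    return vip


def pls_fit(data: PLSDataset, n_components: int | str = "auto") -> PLSModel:
    """PLS regression on autoscaled, centred X and Y.

    ``n_components="auto"`` picks the count (up to min(10, rank)) maximizing
    7-fold cross-validated Q2 with a fixed fold seed.
    """
    max_comp = min(10, data.n - 1, data.p)
    if n_components == "auto":
        best, best_q2 = 1, -np.inf
        for a in range(1, max_comp + 1):
            q2 = pls_validate(data, n_components=a, n_perm=0, seed=0).q2
            if q2 > best_q2 + 1e-12:
                best, best_q2 = a, q2
        n_components = best
    n_components = int(n_components)
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds usable rank {max_comp}")

    Xs, xm, xs = _autoscale(data.X)
    Ys, ym, ys = _autoscale(data.Y)
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xs, Ys)
    Yhat = pls.predict(Xs)
    ss_res = np.sum((Ys - Yhat) ** 2, axis=0)
    ss_tot = np.sum(Ys**2, axis=0)  # Ys is centred
    r2 = 1.0 - ss_res / ss_tot
    return PLSModel(
        n_components=n_components,
        coefficients=pls.coef_.T if pls.coef_.shape[0] == data.Y.shape[1] else pls.coef_,
        r2=r2, vip=_vip_scores(pls, Ys),
        x_scores=pls.x_scores_, x_weights=pls.x_weights_,
        x_mean=xm, x_std=xs, y_mean=ym, y_std=ys,
        x_names=data.x_names, y_names=data.y_names,
    )


@dataclass
class PLSValidation:
    q2: float
    press: float
    tss: float
    n_components: int
    perm_q2: np.ndarray
    perm_r2: np.ndarray
    p_value: float | None

    def null_central_interval(self, level: float = 0.95):
        lo = np.quantile(self.perm_q2, (1 - level) / 2)
        hi = np.quantile(self.perm_q2, 1 - (1 - level) / 2)
        return float(lo), float(hi)


def _cv_q2(X: np.ndarray, Y: np.ndarray, n_components: int, n_folds: int,
           rng: np.random.Generator) -> tuple[float, float, float]:
    n = X.shape[0]
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    press = 0.0
    _, ym_all, ys_all = _autoscale(Y)
    Ys_all = (Y - ym_all) / ys_all
    for hold in folds:
        train = np.setdiff1d(order, hold)
        Xs_tr, xm, xs = _autoscale(X[train])
        Ys_tr, ym, ys = _autoscale(Y[train])
        a = min(n_components, len(train) - 1, X.shape[1])
        pls = PLSRegression(n_components=a, scale=False)
        pls.fit(Xs_tr, Ys_tr)
        pred = pls.predict((X[hold] - xm) / xs) * ys + ym
        press += float(np.sum(((Y[hold] - pred) / ys_all) ** 2))
    tss = float(np.sum(Ys_all**2))
    return 1.0 - press / tss, press, tss


def pls_validate(
    data: PLSDataset,
    model: PLSModel | None = None,
    n_components: int | None = None,
    n_folds: int = 7,
    n_perm: int = 999,
    seed: int = 0,
) -> PLSValidation:
    """Cross-validated Q2 and its permutation null.

    Q2 = 1 - PRESS/TSS from `n_folds`-fold CV (seeded shuffle, contiguous
    blocks); the null recomputes Q2 (and R2) `n_perm` times with the rows of
    Y randomly re-ordered.  The empirical p-value is the fraction of permuted
    Q2 values at or above the observed one.
    """
    if n_components is None:
        if model is None:
            raise ValueError("give either a fitted model or n_components")
        n_components = model.n_components
    if data.n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} samples, have {data.n}")
    rng = np.random.default_rng(seed)
    q2, press, tss = _cv_q2(data.X, data.Y, n_components, n_folds, rng)

    perm_q2 = np.empty(n_perm)
    perm_r2 = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(data.n)
        Yp = data.Y[perm]
        perm_q2[b], _, _ = _cv_q2(data.X, Yp, n_components, n_folds, rng)
        pm = pls_fit(PLSDataset(data.X, Yp), n_components=n_components)
        perm_r2[b] = float(np.mean(pm.r2))
    p_value = None
    if n_perm:
        p_value = float((1 + np.sum(perm_q2 >= q2)) / (1 + n_perm))
    return PLSValidation(
        q2=float(q2), press=press, tss=tss, n_components=n_components,
        perm_q2=perm_q2, perm_r2=perm_r2, p_value=p_value,
    )
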