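"""KDE class-conditional densities and likelihood-ratio score fusion.

The decoder estimates, for every (class, feature) pair, a one-dimensional
Gaussian-kernel density from the training trials' cumulant features.  A test
vector Y = [y_1 .. y_K] is scored per class by the product of its per-feature
marginal densities (independence fusion), computed in the log domain:

    score_c(Y) = sum_k log p_c(y_k).

Binary decisions follow the likelihood-ratio test LR = p(Y|H0)/p(Y|H1) against
a threshold theta: the H0-side class is returned iff log LR >= log(theta);
theta defaults to 1 (maximum-likelihood decision, boundary to H0).  Multiclass
decoding takes the argmax of the per-class scores, ties going to the lowest
class label.

Bandwidths follow Silverman's rule h = 0.9 * min(sd, IQR/1.34) * n^(-1/5);
densities are floored at 1e-300 so log ratios stay finite far from the
training support.  Features are z-scored with training-set statistics that are
stored in the model and applied to every test vector.  A joint multivariate
KDE (one density per class over all K features, via scipy) is available as an
alternative to independence fusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cumulants import CumulantFeatureTable

__all__ = [
    "KdeDensity",
    "LrbsfModel",
    "DecodeResult",
    "fit_kde",
    "likelihood_ratio",
    "decide_binary",
    "fit_decoder",
    "predict_multiclass",
    "predict_table",
    "DENSITY_FLOOR",
]

DENSITY_FLOOR = 1e-300
_LOG_FLOOR = np.log(DENSITY_FLOOR)
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class KdeDensity:
    """Univariate Gaussian-kernel density over one class's feature samples."""

    samples: np.ndarray
    bandwidth: float
    floor: float = DENSITY_FLOOR

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")

    def logpdf(self, y) -> np.ndarray:
        """Floored log density at scalar or vector y."""
        y = np.atleast_1d(np.asarray(y, dtype=float))
        z = (y[:, None] - self.samples[None, :]) / self.bandwidth
        # log mean of kernel pdfs, stabilized
        log_k = -0.5 * z**2 - _LOG_SQRT_2PI - np.log(self.bandwidth)
        m = log_k.max(axis=1)
        lp = m + np.log(np.mean(np.exp(log_k - m[:, None]), axis=1))
        lp = np.where(np.isfinite(lp), lp, _LOG_FLOOR)
        return np.maximum(lp, np.log(self.floor))

    def pdf(self, y) -> np.ndarray:
        return np.exp(self.logpdf(y))


def silverman_bandwidth(samples: np.ndarray) -> float:
    """h = 0.9 * min(sd, IQR/1.34) * n^(-1/5), with a degenerate fallback.

    If both spread measures are zero (all samples identical) the bandwidth
    falls back to 1e-3 * (|value| + 1).  If only one is zero, the positive one
    is used.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    n = samples.size
    sd = samples.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(samples, [75, 25])
    iqr_scale = (q75 - q25) / 1.34
    candidates = [s for s in (sd, iqr_scale) if s > 0]
    if not candidates:
        return 1e-3 * (abs(float(samples[0])) + 1.0)
    return 0.9 * min(candidates) * n ** (-1.0 / 5.0)


def fit_kde(samples: np.ndarray) -> KdeDensity:
    """Fit one univariate density; >= 2 samples expected (degenerate spread ok)."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("cannot fit a density to zero samples")
    return KdeDensity(samples=samples, bandwidth=silverman_bandwidth(samples))


@dataclass
class LrbsfModel:
    """Trained decoder: per-(class, feature) densities + decision threshold.

    ``densities[c]`` is the list of K univariate densities for class c, in
    ``feature_names`` order.  ``mu``/``sigma`` are the training-set feature
    standardization applied to every input.  When ``joint`` is set the model
    instead holds one multivariate KDE per class in ``joint_densities``.
    """

    classes: list[int]
    densities: dict[int, list[KdeDensity]]
    theta: float
    feature_names: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray
    joint: bool = False
    joint_densities: dict[int, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if not self.joint:
            k = len(self.feature_names)
            for c in self.classes:
                if c not in self.densities or len(self.densities[c]) != k:
                    raise ValueError(f"class {c} lacks a density per feature")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _standardize(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mu) / self.sigma

    def class_log_likelihood(self, y: np.ndarray, cls: int) -> float:
        """Fused log score sum_k log p_cls(y_k) for one standardized-input vector."""
        if cls not in self.densities and cls not in self.joint_densities:
            raise KeyError(f"unknown class label {cls!r}")
        y = np.asarray(y, dtype=float).ravel()
        if y.size != self.n_features:
            raise ValueError(
                f"feature vector has length {y.size}, model expects {self.n_features}"
            )
        z = self._standardize(y)
        if self.joint:
            kde = self.joint_densities[cls]
            lp = float(kde.logpdf(z[:, None])[0])
            return max(lp, _LOG_FLOOR)
        return float(
            sum(d.logpdf(z[k])[0] for k, d in enumerate(self.densities[cls]))
        )

    def to_json(self) -> str:
        if self.joint:
            raise NotImplementedError("joint-KDE models are not serializable")
        obj = {
            "classes": [int(c) for c in self.classes],
            "theta": self.theta,
            "feature_names": list(self.feature_names),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "densities": {
                str(c): [
                    {"samples": d.samples.tolist(), "bandwidth": d.bandwidth}
                    for d in ds
                ]
                for c, ds in self.densities.items()
            },
        }
        return json.dumps(obj, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LrbsfModel":
        obj = json.loads(text)
        densities = {
            int(c): [
                KdeDensity(np.asarray(d["samples"]), d["bandwidth"]) for d in ds
            ]
            for c, ds in obj["densities"].items()
        }
        return cls(
            classes=[int(c) for c in obj["classes"]],
            densities=densities,
            theta=obj["theta"],
            feature_names=tuple(obj["feature_names"]),
            mu=np.asarray(obj["mu"], dtype=float),
            sigma=np.asarray(obj["sigma"], dtype=float),
        )


@dataclass
class DecodeResult:
    """Predictions (and accuracy when the truth is supplied)."""

    predicted: np.ndarray
    log_likelihoods: np.ndarray  # trials x classes
    classes: list[int]
    truth: np.ndarray | None = None

    @property
    def accuracy(self) -> float | None:
        """Percent correct, or None without ground truth."""
        if self.truth is None:
            return None
        return 100.0 * float(np.mean(self.predicted == self.truth))


def fit_decoder(
    train: CumulantFeatureTable, theta: float = 1.0, joint: bool = False
) -> LrbsfModel:
    """Train the decoder: z-score features, then one KDE per (class, feature).

    Requires >= 2 classes with >= 2 training trials each.  Training is
    deterministic: refitting on the same table gives an identical model.
    """
    labels = np.asarray(train.labels)
    classes = sorted(int(c) for c in np.unique(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes to train a decoder")
    mu = train.values.mean(axis=0)
    sigma = train.values.std(axis=0, ddof=0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    z = (train.values - mu) / sigma
    densities: dict[int, list[KdeDensity]] = {}
    joint_densities: dict[int, object] = {}
    for c in classes:
        rows = z[labels == c]
        if rows.shape[0] < 2:
            raise ValueError(f"class {c} has fewer than 2 training trials")
        if joint:
            from scipy.stats import gaussian_kde

            joint_densities[c] = gaussian_kde(rows.T)
            densities[c] = []
        else:
            densities[c] = [fit_kde(rows[:, k]) for k in range(rows.shape[1])]
    return LrbsfModel(
        classes=classes,
        densities=densities,
        theta=theta,
        feature_names=train.feature_names,
        mu=mu,
        sigma=sigma,
        joint=joint,
        joint_densities=joint_densities,
    )


def likelihood_ratio(
    model: LrbsfModel, y: np.ndarray, class_a: int, class_b: int
) -> float:
    """log LR = log p(Y|a) - log p(Y|b) under independence fusion."""
    return model.class_log_likelihood(y, class_a) - model.class_log_likelihood(
        y, class_b
    )


def decide_binary(
    log_lr: float, theta: float, class_a: int, class_b: int
) -> int:
    """H0-side class_a iff log LR >= log(theta); boundary goes to class_a."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    return class_a if log_lr >= np.log(theta) else class_b


def predict_multiclass(model: LrbsfModel, y: np.ndarray) -> int:
    """argmax over classes of the fused log likelihood; ties to lowest label."""
    if len(model.classes) < 2:
        raise ValueError("model must have at least two classes")
    scores = [model.class_log_likelihood(y, c) for c in model.classes]
    return model.classes[int(np.argmax(scores))]


def predict_table(
    model: LrbsfModel, table: CumulantFeatureTable, binary_theta: bool = True
) -> DecodeResult:
    """Decode every trial of a feature table.

    For two-class models with ``binary_theta`` the thresholded LR rule is used
    (identical to the argmax when theta = 1); otherwise the multiclass argmax.
    """
    if tuple(table.feature_names) != tuple(model.feature_names):
        raise ValueError(
            f"feature mismatch: table has {table.feature_names}, "
            f"model expects {model.feature_names}"
        )
    n = table.n_trials
    ll = np.empty((n, len(model.classes)))
    for i in range(n):
        for j, c in enumerate(model.classes):
            ll[i, j] = model.class_log_likelihood(table.values[i], c)
    if len(model.classes) == 2 and binary_theta:
        a, b = model.classes
        log_lr = ll[:, 0] - ll[:, 1]
        predicted = np.where(log_lr >= np.log(model.theta), a, b)
    else:
        predicted = np.asarray([model.classes[j] for j in np.argmax(ll, axis=1)])
    return DecodeResult(
        predicted=predicted,
        log_likelihoods=ll,
        classes=model.classes,
        truth=np.asarray(table.labels),
    )
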