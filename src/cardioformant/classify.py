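"""One-dimensional linear discriminant classification with leave-one-out
cross-validation and sensitivity/specificity reporting.

On a single scalar feature the equal-variance Gaussian discriminant reduces
to a threshold: the midpoint of the class means, shifted by
``pooled_variance * log(prior ratio) / (mean difference)`` for unequal
priors.  PAH is the positive class throughout; ties at the threshold resolve
to normal (conservative screening default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

POSITIVE = "PAH"
NEGATIVE = "normal"


@dataclass
class DiscriminantModel:
    mean_pah: float
    mean_normal: float
    pooled_variance: float
    prior_pah: float
    prior_normal: float

    @property
    def threshold(self) -> float:
        """Decision boundary in feature units (inf when the means coincide)."""
        diff = self.mean_pah - self.mean_normal
        if diff == 0.0:
            return np.inf if self.prior_pah >= self.prior_normal else -np.inf
        mid = 0.5 * (self.mean_pah + self.mean_normal)
        return mid + self.pooled_variance * np.log(self.prior_normal / self.prior_pah) / diff

    @property
    def pah_side(self) -> str:
        """Which side of the threshold maps to PAH ('low' or 'high')."""
        return "low" if self.mean_pah < self.mean_normal else "high"

    def log_posteriors(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unnormalized class log-posteriors (PAH, normal) at each value."""
        values = np.asarray(values, dtype=np.float64)
        v2 = 2.0 * self.pooled_variance
        lp_pah = np.log(self.prior_pah) - (values - self.mean_pah) ** 2 / v2
        lp_norm = np.log(self.prior_normal) - (values - self.mean_normal) ** 2 / v2
        return lp_pah, lp_norm

    def predict(self, values) -> np.ndarray:
        """Class labels by posterior comparison; exact ties go to normal."""
        lp_pah, lp_norm = self.log_posteriors(values)
        return np.where(lp_pah > lp_norm, POSITIVE, NEGATIVE)


@dataclass
class ClassificationResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float  # percent
    specificity: float  # percent
    predictions: list = field(default_factory=list)  # (subject index, true, predicted)

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return 100.0 * (self.tp + self.tn) / total


def _coerce(values, labels) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    if values.ndim != 1 or values.shape != labels.shape:
        raise ParameterError("values and labels must be matching 1-D sequences")
    bad = set(labels) - {POSITIVE, NEGATIVE}
    if bad:
        raise ParameterError(f"labels must be {POSITIVE!r}/{NEGATIVE!r}, got extras {bad}")
    return values, labels


def fit_lda(values, labels, priors: str | tuple[float, float] = "empirical") -> DiscriminantModel:
    """Fit the equal-variance Gaussian discriminant on one scalar feature.

    ``priors`` is ``"empirical"`` (class frequencies), ``"equal"``, or an
    explicit ``(prior_pah, prior_normal)`` pair.
    """
    values, labels = _coerce(values, labels)
    pah = values[labels == POSITIVE]
    normal = values[labels == NEGATIVE]
    if pah.size == 0 or normal.size == 0:
        raise ParameterError(
            f"both classes must be present; got {pah.size} PAH / {normal.size} normal"
        )
    if pah.size + normal.size < 3:
        raise ParameterError("need >= 3 values to estimate a pooled variance")
    # single-member classes contribute zero degrees of freedom, not NaN
    ss = sum((g.size - 1) * np.var(g, ddof=1) for g in (pah, normal) if g.size > 1)
    pooled = ss / (pah.size + normal.size - 2)
    if pooled <= 0.0:
        raise ParameterError("pooled variance is zero; discriminant is undefined")
    if priors == "empirical":
        p_pah = pah.size / values.size
    elif priors == "equal":
        p_pah = 0.5
    else:
        p_pah, p_norm = priors
        if not np.isclose(p_pah + p_norm, 1.0) or p_pah <= 0 or p_norm <= 0:
            raise ParameterError("explicit priors must be positive and sum to 1")
    return DiscriminantModel(
        mean_pah=float(pah.mean()),
        mean_normal=float(normal.mean()),
        pooled_variance=float(pooled),
        prior_pah=float(p_pah),
        prior_normal=float(1.0 - p_pah),
    )


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    """Sensitivity 100*TP/(TP+FN) and specificity 100*TN/(TN+FP), percent."""
    for name, v in (("TP", tp), ("FN", fn), ("TN", tn), ("FP", fp)):
        if v < 0 or int(v) != v:
            raise ParameterError(f"{name} must be a non-negative integer, got {v}")
    if tp + fn == 0:
        raise ParameterError("no positive cases: sensitivity is undefined")
    if tn + fp == 0:
        raise ParameterError("no negative cases: specificity is undefined")
    return 100.0 * tp / (tp + fn), 100.0 * tn / (tn + fp)


def loo_evaluate(
    values, labels, priors: str | tuple[float, float] = "empirical"
) -> ClassificationResult:
    """Leave-one-out cross-validation of the 1-D discriminant.

    Each subject is held out once; the model refit on the remaining n-1
    subjects predicts it.  Confusion counts aggregate held-out predictions
    only.
    """
    values, labels = _coerce(values, labels)
    n = values.size
    if n < 3:
        raise ParameterError(f"LOO needs >= 3 subjects, got {n}")
    n_pah = int(np.sum(labels == POSITIVE))
    if n_pah < 2 or n - n_pah < 2:
        raise ParameterError("each class needs >= 2 members for LOO splits")
    tp = fp = tn = fn = 0
    predictions = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_lda(values[mask], labels[mask], priors=priors)
        pred = str(model.predict(values[i : i + 1])[0])
        truth = str(labels[i])
        if truth == POSITIVE:
            tp += pred == POSITIVE
            fn += pred == NEGATIVE
        else:
            tn += pred == NEGATIVE
            fp += pred == POSITIVE
        predictions.append((i, truth, pred))
    sens, spec = confusion_metrics(tp, fn, tn, fp)
    return ClassificationResult(
        tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec, predictions=predictions
    )
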