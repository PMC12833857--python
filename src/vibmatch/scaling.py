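"""Frequency scaling factors: derivation, error statistics, resampling.

Harmonic normal-mode frequencies systematically overestimate observed
fundamentals because the quadratic-potential model neglects
anharmonicity.  A multiplicative scaling factor lambda corrects this:

    lambda = argmin_l sum_i (l * omega_i - nu_i)^2 = sum nu_i omega_i / sum omega_i^2

the standard least-squares estimator of the scaling-factor literature.
Three schemes are supported: one *global* factor, *range-dependent*
factors (high >2000 cm-1, mid 1000-2000 cm-1, low <1000 cm-1) and
*mode-dependent* factors that split the high range into O-H, N-H,
aromatic C-H and aliphatic (ethyl) C-H stretches.

The uncertainty Delta-lambda is, by default, the sample standard
deviation of the per-pair ratios nu_i/omega_i; an RMS-residual-based
alternative sqrt(sum (nu - lambda*omega)^2 / sum omega^2) is available
for sensitivity checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    ClassificationError,
    InsufficientDataError,
    ValidationError,
    VibmatchError,
)
from .records import (
    MODE_SCHEME_CLASSES,
    RANGE_SCHEME_CLASSES,
    STRETCH_CLASSES,
    FrequencyPair,
    ModeClass,
    Peak,
    Scheme,
    SpectrumRecord,
    TheoryLevel,
    ensure_pairs,
)

__all__ = [
    "ScalingFactorSet",
    "ErrorStats",
    "SplitStats",
    "StabilityEntry",
    "classify_mode",
    "classify_frequency",
    "fit_scaling_factor",
    "fit_scaling_set",
    "apply_scaling",
    "error_stats",
    "resample_splits",
    "top_fraction_stability",
    "pearson_check",
    "scheme_classes",
]

logger = logging.getLogger(__name__)

#: Wavenumber cutoffs separating low/mid/high ranges, cm-1.  The
#: boundaries themselves belong to mid (the quoted windows "<1000" and
#: ">2000" are strict).
LOW_MID_CUTOFF = 1000.0
MID_HIGH_CUTOFF = 2000.0


def scheme_classes(scheme: Scheme) -> tuple[ModeClass, ...]:
    """The mode classes a scheme partitions the database into."""
    scheme = Scheme(scheme)
    if scheme is Scheme.GLOBAL:
        return (ModeClass.GLOBAL,)
    if scheme is Scheme.RANGE_DEPENDENT:
        return RANGE_SCHEME_CLASSES
    return MODE_SCHEME_CLASSES


def classify_frequency(
    nu: float, scheme: Scheme, stretch_label: Optional[ModeClass] = None
) -> ModeClass:
    """Classify a frequency under a scheme, given an optional stretch label."""
    scheme = Scheme(scheme)
    if scheme is Scheme.GLOBAL:
        return ModeClass.GLOBAL
    if nu < LOW_MID_CUTOFF:
        return ModeClass.LOW
    if nu <= MID_HIGH_CUTOFF:
        return ModeClass.MID
    if scheme is Scheme.RANGE_DEPENDENT:
        return ModeClass.HIGH
    if stretch_label in STRETCH_CLASSES:
        return stretch_label
    raise ClassificationError(
        f"feature at {nu:.1f} cm-1 needs a stretch label "
        "(OH/NH/CH_ring/CH_ethyl) under the mode-dependent scheme"
    )


def classify_mode(pair: FrequencyPair, scheme: Scheme) -> ModeClass:
    """Assign a frequency pair to its scaling class under ``scheme``.

    The experimental fundamental decides the range; database stretch
    labels are honored (and required above 2000 cm-1) by the
    mode-dependent scheme.
    """
    label = pair.mode_class if pair.mode_class in STRETCH_CLASSES else None
    try:
        return classify_frequency(pair.nu_exp, scheme, stretch_label=label)
    except ClassificationError as exc:
        raise ClassificationError(
            f"pair (nu={pair.nu_exp}, omega={pair.omega_calc}): {exc}"
        ) from exc


def fit_scaling_factor(
    pairs: Sequence[FrequencyPair], uncertainty: str = "ratio_std"
) -> tuple[float, float]:
    """Least-squares scaling factor and its uncertainty for one class.

    Returns ``(lambda, delta_lambda)`` with
    ``lambda = sum(nu*omega) / sum(omega^2)``.  ``uncertainty`` selects
    the Delta-lambda estimator: ``"ratio_std"`` (sample std of
    nu_i/omega_i, the default) or ``"rms"``
    (``sqrt(sum (nu-lambda*omega)^2 / sum omega^2)``).
    """
    ensure_pairs(pairs, 2)
    nu = np.array([p.nu_exp for p in pairs])
    omega = np.array([p.omega_calc for p in pairs])
    if np.any(omega == 0):
        raise ValidationError("harmonic frequency omega = 0 in scaling fit")
    lam = float(np.dot(nu, omega) / np.dot(omega, omega))
    if uncertainty == "ratio_std":
        dlam = float(np.std(nu / omega, ddof=1))
    elif uncertainty == "rms":
        resid = nu - lam * omega
        dlam = float(math.sqrt(np.dot(resid, resid) / np.dot(omega, omega)))
    else:
        raise ValueError(f"unknown uncertainty estimator {uncertainty!r}")
    return lam, dlam


@dataclass(frozen=True)
class ScalingFactorSet:
    """Fitted scaling factors for one scheme at one theory level.

    ``factors`` maps each populated :class:`ModeClass` to
    ``(lambda, delta_lambda, n_pairs)``.
    """

    scheme: Scheme
    theory: Optional[TheoryLevel]
    factors: Mapping[ModeClass, tuple[float, float, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        allowed = set(scheme_classes(self.scheme))
        extra = set(self.factors) - allowed
        if extra:
            raise ValidationError(
                f"classes {sorted(c.value for c in extra)} not valid for "
                f"{self.scheme.value} scheme"
            )
        object.__setattr__(self, "factors", dict(self.factors))

    def lambda_for(self, mode_class: ModeClass) -> float:
        try:
            return self.factors[mode_class][0]
        except KeyError:
            raise ClassificationError(
                f"no scaling factor fitted for class {mode_class.value!r}"
            ) from None

    def items(self):
        return self.factors.items()


def fit_scaling_set(
    pairs: Sequence[FrequencyPair],
    scheme: Scheme,
    theory: Optional[TheoryLevel] = None,
    uncertainty: str = "ratio_std",
) -> ScalingFactorSet:
    """Fit one scaling factor per class of ``scheme`` on its pair subset.

    Classes with fewer than two pairs are reported absent (with a
    warning) rather than raising.
    """
    scheme = Scheme(scheme)
    by_class: dict[ModeClass, list[FrequencyPair]] = {}
    for pair in pairs:
        by_class.setdefault(classify_mode(pair, scheme), []).append(pair)
    factors = {}
    for cls in scheme_classes(scheme):
        subset = by_class.get(cls, [])
        if len(subset) < 2:
            logger.warning(
                "class %s has %d pairs (<2) under %s scheme; entry absent",
                cls.value,
                len(subset),
                scheme.value,
            )
            continue
        lam, dlam = fit_scaling_factor(subset, uncertainty=uncertainty)
        factors[cls] = (lam, dlam, len(subset))
    return ScalingFactorSet(scheme=scheme, theory=theory, factors=factors)


def apply_scaling(
    record: SpectrumRecord, factor_set: ScalingFactorSet
) -> SpectrumRecord:
    """Scale every harmonic frequency of a computed record.

    Each peak's frequency omega becomes lambda_class * omega.  The class
    is decided from the harmonic position and, for the mode-dependent
    scheme, from an optional ``record.metadata["mode_classes"]``
    sequence of stretch labels aligned with the sorted peaks.
    Intensities are untouched; sorted order is re-established.
    """
    if record.source != "computed":
        raise ValidationError("apply_scaling expects a computed record")
    labels = record.metadata.get("mode_classes")
    scaled = []
    for i, peak in enumerate(record.peaks):
        label = None
        if labels is not None:
            label = labels[i]
            if label is not None and not isinstance(label, ModeClass):
                label = ModeClass(label)
            if label not in STRETCH_CLASSES:
                label = None
        try:
            cls = classify_frequency(
                peak.frequency, factor_set.scheme, stretch_label=label
            )
        except ClassificationError as exc:
            raise ClassificationError(
                f"peak at {peak.frequency:.1f} cm-1: {exc}"
            ) from exc
        lam = factor_set.lambda_for(cls)
        scaled.append(
            Peak(
                frequency=lam * peak.frequency,
                intensity=peak.intensity,
                fwhm=peak.fwhm,
                snr=peak.snr,
                channel=peak.channel,
            )
        )
    return record.with_peaks(scaled)


@dataclass(frozen=True)
class ErrorStats:
    """Statistics of the scaled-minus-observed frequency errors.

    Signed errors are ``e_i = lambda_class * omega_i - nu_i`` in cm-1.
    ``rms``/``mad``/``sigma`` summarize spread, ``mape`` is the mean
    absolute percentage error (percent of nu), and ``q1``/``q2``/``q3``
    are quartiles of the |e| distribution (linear interpolation).
    """

    rms: float
    mad: float
    sigma: float
    mape: float
    q1: float
    q2: float
    q3: float
    err_min: float
    err_max: float
    n: int

    FIELDS = ("rms", "mad", "sigma", "mape", "q1", "q2", "q3", "err_min", "err_max")

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in self.FIELDS} | {"n": self.n}


def error_stats(
    pairs: Sequence[FrequencyPair], factor_set: ScalingFactorSet
) -> ErrorStats:
    """Full error battery for ``pairs`` under a fitted factor set."""
    ensure_pairs(pairs, 1)
    errors = np.empty(len(pairs))
    nu = np.empty(len(pairs))
    for i, pair in enumerate(pairs):
        lam = factor_set.lambda_for(classify_mode(pair, factor_set.scheme))
        errors[i] = lam * pair.omega_calc - pair.nu_exp
        nu[i] = pair.nu_exp
    abs_err = np.abs(errors)
    q1, q2, q3 = np.percentile(abs_err, [25, 50, 75])
    sigma = float(np.std(errors, ddof=1)) if len(pairs) > 1 else 0.0
    return ErrorStats(
        rms=float(np.sqrt(np.mean(errors**2))),
        mad=float(np.mean(abs_err)),
        sigma=sigma,
        mape=float(100.0 * np.mean(abs_err / nu)),
        q1=float(q1),
        q2=float(q2),
        q3=float(q3),
        err_min=float(errors.min()),
        err_max=float(errors.max()),
        n=len(pairs),
    )


@dataclass(frozen=True)
class SplitStats:
    """Averages over repeated random training/test partitions.

    ``per_class`` maps each mode class to (mean lambda, std lambda)
    over iterations; ``test_stats`` maps each :class:`ErrorStats` field
    to (mean, std) over the held-out test sets.
    """

    n_iter: int
    train_frac: float
    seed: int
    per_class: Mapping[ModeClass, tuple[float, float]]
    test_stats: Mapping[str, tuple[float, float]]
    n_redraws: int = 0


def _stratified_split(
    by_class: Mapping[ModeClass, list[FrequencyPair]],
    train_frac: float,
    rng: np.random.Generator,
) -> tuple[list[FrequencyPair], list[FrequencyPair]]:
    train: list[FrequencyPair] = []
    test: list[FrequencyPair] = []
    for subset in by_class.values():
        idx = rng.permutation(len(subset))
        n_train = int(round(train_frac * len(subset)))
        n_train = min(max(n_train, 0), len(subset))
        train.extend(subset[i] for i in idx[:n_train])
        test.extend(subset[i] for i in idx[n_train:])
    return train, test


def resample_splits(
    pairs: Sequence[FrequencyPair],
    scheme: Scheme,
    n_iter: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    theory: Optional[TheoryLevel] = None,
    uncertainty: str = "ratio_std",
) -> SplitStats:
    """Randomized train/test protocol for scaling-factor stability.

    Each iteration draws a stratified-by-class ``train_frac`` split,
    fits a :class:`ScalingFactorSet` on the training pairs and computes
    :func:`error_stats` on the held-out test pairs; means and standard
    deviations over iterations are returned.  Iterations whose training
    side leaves some class unfittable, or whose test side is empty, are
    redrawn (up to 1000 attempts) and counted.
    """
    scheme = Scheme(scheme)
    ensure_pairs(pairs, 4)
    by_class: dict[ModeClass, list[FrequencyPair]] = {}
    for pair in pairs:
        by_class.setdefault(classify_mode(pair, scheme), []).append(pair)
    classes = [c for c in scheme_classes(scheme) if c in by_class]

    rng = np.random.default_rng(seed)
    lam_draws: dict[ModeClass, list[float]] = {c: [] for c in classes}
    stat_draws: dict[str, list[float]] = {f: [] for f in ErrorStats.FIELDS}
    n_redraws = 0
    for _ in range(n_iter):
        for _attempt in range(1000):
            train, test = _stratified_split(by_class, train_frac, rng)
            fitted = fit_scaling_set(
                train, scheme, theory=theory, uncertainty=uncertainty
            )
            if set(fitted.factors) == set(classes) and test:
                break
            n_redraws += 1
        else:
            raise InsufficientDataError(
                "could not draw a stratified split with >=2 training pairs "
                "per class after 1000 attempts"
            )
        for cls in classes:
            lam_draws[cls].append(fitted.factors[cls][0])
        stats = error_stats(test, fitted)
        for f in ErrorStats.FIELDS:
            stat_draws[f].append(getattr(stats, f))

    per_class = {
        c: (float(np.mean(v)), float(np.std(v, ddof=1)))
        for c, v in lam_draws.items()
    }
    test_stats = {
        f: (float(np.mean(v)), float(np.std(v, ddof=1)))
        for f, v in stat_draws.items()
    }
    return SplitStats(
        n_iter=n_iter,
        train_frac=train_frac,
        seed=seed,
        per_class=per_class,
        test_stats=test_stats,
        n_redraws=n_redraws,
    )


@dataclass(frozen=True)
class StabilityEntry:
    """Per-class comparison of a subset refit against the full fit."""

    lambda_full: float
    delta_full: float
    lambda_sub: Optional[float]
    n_sub: int
    assessable: bool

    @property
    def shift(self) -> Optional[float]:
        if self.lambda_sub is None:
            return None
        return abs(self.lambda_sub - self.lambda_full)

    @property
    def within_uncertainty(self) -> Optional[bool]:
        if self.shift is None:
            return None
        return self.shift <= self.delta_full


def top_fraction_stability(
    pairs: Sequence[FrequencyPair],
    scheme: Scheme,
    frac: float = 0.2,
    theory: Optional[TheoryLevel] = None,
) -> dict[ModeClass, StabilityEntry]:
    """Refit on the most intense features and compare with the full fit.

    Keeps the top ``frac`` of pairs by experimental intensity (globally,
    across classes), refits each class, and reports |lambda_sub -
    lambda_full| against the full-fit Delta-lambda.  Classes with fewer
    than two surviving pairs are marked not assessable.
    """
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    ensure_pairs(pairs, 2)
    full = fit_scaling_set(pairs, scheme, theory=theory)
    order = sorted(pairs, key=lambda p: p.intensity_exp, reverse=True)
    n_keep = max(1, int(round(frac * len(order))))
    subset = order[:n_keep]
    sub_by_class: dict[ModeClass, list[FrequencyPair]] = {}
    for pair in subset:
        sub_by_class.setdefault(classify_mode(pair, scheme), []).append(pair)

    report: dict[ModeClass, StabilityEntry] = {}
    for cls, (lam_full, dlam_full, _n) in full.items():
        sub = sub_by_class.get(cls, [])
        if len(sub) < 2:
            report[cls] = StabilityEntry(lam_full, dlam_full, None, len(sub), False)
            continue
        lam_sub, _ = fit_scaling_factor(sub)
        report[cls] = StabilityEntry(lam_full, dlam_full, lam_sub, len(sub), True)
    return report


def pearson_check(
    pairs: Sequence[FrequencyPair], factor_set: ScalingFactorSet
) -> float:
    """Pearson r between scaled harmonic and experimental frequencies."""
    ensure_pairs(pairs, 3)
    scaled = np.array(
        [
            factor_set.lambda_for(classify_mode(p, factor_set.scheme)) * p.omega_calc
            for p in pairs
        ]
    )
    nu = np.array([p.nu_exp for p in pairs])
    if np.std(scaled) == 0 or np.std(nu) == 0:
        raise VibmatchError("Pearson correlation undefined for zero-variance data")
    r, _ = sps.pearsonr(scaled, nu)
    return float(r)
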