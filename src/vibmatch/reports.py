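"""Tabular summaries of fitted scaling factors and their statistics."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .records import FrequencyPair, ModeClass, Scheme, TheoryLevel
from .scaling import (
    ScalingFactorSet,
    error_stats,
    fit_scaling_set,
    resample_splits,
    scheme_classes,
)

__all__ = ["factor_table", "split_table", "factor_set_to_dict", "factor_set_from_dict"]

_ALL_CLASSES = (
    ModeClass.GLOBAL,
    ModeClass.OH,
    ModeClass.NH,
    ModeClass.CH_RING,
    ModeClass.CH_ETHYL,
    ModeClass.MID,
    ModeClass.LOW,
    ModeClass.HIGH,
)


def factor_table(
    pairs_by_level: Mapping[TheoryLevel, Sequence[FrequencyPair]],
    uncertainty: str = "ratio_std",
) -> pd.DataFrame:
    """Deterministic full-data scaling factors, one row per theory level.

    Columns ``lambda_<class>`` / ``dlambda_<class>`` cover the global
    factor, the four stretch classes, mid, low and high, pooling the
    three schemes into one benchmark-style table.
    """
    rows = []
    for level, pairs in pairs_by_level.items():
        row: dict = {"theory": str(level)}
        for scheme in Scheme:
            fitted = fit_scaling_set(pairs, scheme, theory=level, uncertainty=uncertainty)
            for cls, (lam, dlam, n) in fitted.items():
                row[f"lambda_{cls.value}"] = lam
                row[f"dlambda_{cls.value}"] = dlam
                row[f"n_{cls.value}"] = n
        rows.append(row)
    columns = ["theory"]
    for cls in _ALL_CLASSES:
        columns += [f"lambda_{cls.value}", f"dlambda_{cls.value}", f"n_{cls.value}"]
    return pd.DataFrame(rows, columns=[c for c in columns if any(c in r for r in rows)])


def split_table(
    pairs_by_level: Mapping[TheoryLevel, Sequence[FrequencyPair]],
    n_iter: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Resampled factors and test-set error statistics per scheme and level.

    One row per (theory level, scheme); columns hold the mean and std
    over the random train/test iterations of each class factor and of
    MAPE and the absolute-error quartiles.
    """
    rows = []
    for level, pairs in pairs_by_level.items():
        for scheme in Scheme:
            stats = resample_splits(
                pairs, scheme, n_iter=n_iter, train_frac=train_frac,
                seed=seed, theory=level,
            )
            row: dict = {"theory": str(level), "scheme": scheme.value}
            for cls, (mean, std) in stats.per_class.items():
                row[f"lambda_{cls.value}_mean"] = mean
                row[f"lambda_{cls.value}_std"] = std
            for stat in ("mape", "q1", "q2", "q3"):
                mean, std = stats.test_stats[stat]
                row[f"{stat}_mean"] = mean
                row[f"{stat}_std"] = std
            rows.append(row)
    return pd.DataFrame(rows)


def factor_set_to_dict(factor_set: ScalingFactorSet) -> dict:
    """JSON-ready representation of a fitted factor set."""
    doc: dict = {"scheme": factor_set.scheme.value}
    if factor_set.theory is not None:
        doc["functional"] = factor_set.theory.functional
        doc["basis"] = factor_set.theory.basis
    doc["factors"] = {
        cls.value: {"lambda": lam, "delta_lambda": dlam, "n": n}
        for cls, (lam, dlam, n) in factor_set.items()
    }
    return doc


def factor_set_from_dict(doc: Mapping) -> ScalingFactorSet:
    """Inverse of :func:`factor_set_to_dict`."""
    theory: Optional[TheoryLevel] = None
    if doc.get("functional") and doc.get("basis"):
        theory = TheoryLevel(doc["functional"], doc["basis"])
    factors = {
        ModeClass(cls): (entry["lambda"], entry["delta_lambda"], int(entry["n"]))
        for cls, entry in doc["factors"].items()
    }
    return ScalingFactorSet(scheme=Scheme(doc["scheme"]), theory=theory, factors=factors)
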