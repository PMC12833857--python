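"""Spectral similarity metrics and candidate-conformer ranking.

Four complementary ways of scoring a measured fundamental-band spectrum
against scaled calculated spectra of candidate structures:

1. *Cross-correlation* of whole convolved spectra, maximized over a
   bounded displacement window; tolerant of small systematic shifts.
2. *Euclidean distance* between discrete features, either on frequency
   alone (1-D) or jointly on frequency and weighted intensity (2-D),
   assembled into a cost matrix.
3. *Manhattan distance* on the same (frequency, weighted intensity)
   coordinates.
4. *Optimal transport* (Wasserstein-1): the minimal work needed to move
   normalized intensity mass between the two peak sets along the
   frequency axis.

For (2) and (3) the Kuhn-Munkres (Hungarian) algorithm assigns each
measured feature to a distinct calculated feature at minimal total
cost, producing a *spectral barcode*; the average per-pair cost ranks
candidates.  Intensity enters the cost via a weight ``w`` (cm-1 per
unit normalized intensity), so a full-scale intensity mismatch costs
the same as a ``w`` cm-1 frequency shift.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import wasserstein_distance

from .errors import ValidationError, VibmatchError
from .preprocess import (
    ContinuousSpectrum,
    DEFAULT_GRID,
    lorentzian_convolve,
    normalize_intensities,
)
from .records import SpectrumRecord
from .scaling import ScalingFactorSet, apply_scaling

__all__ = [
    "Metric",
    "MatchConfig",
    "CostMatrix",
    "Barcode",
    "XCorrScore",
    "CandidateScore",
    "SimilarityResult",
    "cross_correlate",
    "cost_matrix",
    "kuhn_munkres",
    "average_distance",
    "ot_distance",
    "rank_candidates",
    "distance_uncertainty",
]

logger = logging.getLogger(__name__)

METRICS = ("euclid_1d", "euclid_2d", "manhattan_2d")
Metric = str  # one of METRICS


@dataclass(frozen=True)
class MatchConfig:
    """Knobs of the matching pipeline.

    ``weight`` is the intensity weight w in cm-1 per unit normalized
    intensity (default 10, placing typical intensity errors on the same
    cost scale as median frequency errors); ``max_lag`` bounds the
    cross-correlation displacement window.
    """

    weight: float = 10.0
    fwhm: float = 4.0
    grid_start: float = DEFAULT_GRID[0]
    grid_end: float = DEFAULT_GRID[1]
    grid_step: float = DEFAULT_GRID[2]
    max_lag: float = 20.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValidationError(f"weight must be >= 0, got {self.weight}")
        if self.max_lag < 0:
            raise ValidationError(f"max_lag must be >= 0, got {self.max_lag}")


class XCorrScore(NamedTuple):
    """Best normalized cross-correlation and the displacement achieving it."""

    score: float
    lag: float


def cross_correlate(
    measured: ContinuousSpectrum,
    calc: ContinuousSpectrum,
    max_lag: float = 20.0,
) -> XCorrScore:
    """Maximum normalized cross-correlation over a bounded lag window.

    Both spectra are zero-meaned and scaled to unit Euclidean norm, then
    the calculated spectrum is displaced by every integer multiple of
    the grid step within ``[-max_lag, +max_lag]``; positive lag means
    the calculated spectrum moves to *higher* wavenumber.  The returned
    score lies in [-1, 1]; 1 means a perfect match at some lag.
    """
    if not math.isclose(measured.grid_step, calc.grid_step):
        raise ValidationError(
            f"grid steps differ: {measured.grid_step} vs {calc.grid_step}"
        )
    step = measured.grid_step
    # embed both onto a common grid covering their union
    start = min(measured.grid_start, calc.grid_start)
    end = max(measured.grid_end, calc.grid_end)
    n = int(round((end - start) / step)) + 1
    m = np.zeros(n)
    c = np.zeros(n)
    im = int(round((measured.grid_start - start) / step))
    ic = int(round((calc.grid_start - start) / step))
    m[im : im + len(measured)] = measured.values
    c[ic : ic + len(calc)] = calc.values

    m = m - m.mean()
    c = c - c.mean()
    nm, nc = np.linalg.norm(m), np.linalg.norm(c)
    if nm == 0 or nc == 0:
        raise VibmatchError("cross-correlation undefined for a flat spectrum")
    m /= nm
    c /= nc

    max_shift = int(round(max_lag / step))
    pad = np.zeros(max_shift)
    c_padded = np.concatenate([pad, c, pad])
    best_score, best_lag = -np.inf, 0.0
    for shift in range(-max_shift, max_shift + 1):
        # c displaced by +shift samples: c_shifted[i] = c[i - shift]
        c_shifted = c_padded[max_shift - shift : max_shift - shift + n]
        score = float(np.dot(m, c_shifted))
        if score > best_score:
            best_score, best_lag = score, shift * step
    return XCorrScore(score=min(best_score, 1.0), lag=best_lag)


def _check_normalized(record: SpectrumRecord, label: str) -> None:
    if not record.peaks:
        raise ValidationError(f"{label} record has no peaks")
    peak_max = max(p.intensity for p in record.peaks)
    if not math.isclose(peak_max, 1.0, rel_tol=1e-9):
        raise ValidationError(
            f"{label} record is not normalized (max intensity {peak_max:g}); "
            "call normalize_intensities first"
        )


@dataclass(frozen=True)
class CostMatrix:
    """Pairwise feature-distance matrix between two peak lists.

    Rows index measured peaks, columns calculated peaks.  ``dnu`` and
    ``dintensity`` keep the signed coordinate differences so that
    assignment uncertainties can be propagated later.
    """

    entries: np.ndarray
    metric: Metric
    weight: float
    dnu: np.ndarray
    dintensity: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


def cost_matrix(
    measured: SpectrumRecord,
    calc: SpectrumRecord,
    metric: Metric = "euclid_2d",
    weight: float = 10.0,
) -> CostMatrix:
    """Build the cost matrix between measured and calculated features.

    Metrics (nu in cm-1, I normalized to max 1):

    - ``euclid_1d``:    ``|nu_i - nu_j|``
    - ``euclid_2d``:    ``sqrt((nu_i - nu_j)^2 + w^2 (I_i - I_j)^2)``
    - ``manhattan_2d``: ``|nu_i - nu_j| + w |I_i - I_j|``

    Both records must be intensity-normalized (and the calculated one
    already scaled).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    _check_normalized(measured, "measured")
    _check_normalized(calc, "calculated")
    nu_m = np.asarray(measured.frequencies)[:, None]
    nu_c = np.asarray(calc.frequencies)[None, :]
    i_m = np.asarray(measured.intensities)[:, None]
    i_c = np.asarray(calc.intensities)[None, :]
    dnu = nu_m - nu_c
    di = i_m - i_c
    if metric == "euclid_1d":
        entries = np.abs(dnu)
    elif metric == "euclid_2d":
        entries = np.sqrt(dnu**2 + weight**2 * di**2)
    else:
        entries = np.abs(dnu) + weight * np.abs(di)
    return CostMatrix(
        entries=entries, metric=metric, weight=weight, dnu=dnu, dintensity=di
    )


@dataclass(frozen=True)
class Barcode:
    """A minimal-cost assignment of measured to calculated features.

    ``pairs`` lists ``(measured index, calculated index, cost)``;
    calculated peaks in excess of the measured count remain unassigned
    at zero penalty.  ``transposed`` flags the unusual case of more
    measured than calculated features (assignment ran on the transpose).
    """

    pairs: tuple[tuple[int, int, float], ...]
    total_cost: float
    unmatched_calc: tuple[int, ...]
    metric: Metric
    weight: float
    pair_dnu: tuple[float, ...] = ()
    pair_dintensity: tuple[float, ...] = ()
    transposed: bool = False

    def __len__(self) -> int:
        return len(self.pairs)


def kuhn_munkres(costs: CostMatrix) -> Barcode:
    """Minimal-total-cost bipartite assignment (Hungarian method).

    Every measured feature is matched to a distinct calculated feature;
    with more calculated than measured features the surplus stays
    unmatched.  When measured features outnumber calculated ones the
    matrix is transposed internally and the result flagged.
    """
    entries = costs.entries
    if entries.size == 0:
        raise ValidationError("cannot assign on an empty cost matrix")
    m, c = entries.shape
    transposed = m > c
    work = entries.T if transposed else entries
    row_ind, col_ind = linear_sum_assignment(work)
    if transposed:
        pairs = [(int(j), int(i), float(entries[j, i])) for i, j in zip(row_ind, col_ind)]
    else:
        pairs = [(int(i), int(j), float(entries[i, j])) for i, j in zip(row_ind, col_ind)]
    pairs.sort(key=lambda t: t[0])
    matched_calc = {j for _, j, _ in pairs}
    unmatched = tuple(j for j in range(c) if j not in matched_calc)
    return Barcode(
        pairs=tuple(pairs),
        total_cost=float(sum(cost for _, _, cost in pairs)),
        unmatched_calc=unmatched,
        metric=costs.metric,
        weight=costs.weight,
        pair_dnu=tuple(float(costs.dnu[i, j]) for i, j, _ in pairs),
        pair_dintensity=tuple(float(costs.dintensity[i, j]) for i, j, _ in pairs),
        transposed=transposed,
    )


def average_distance(barcode: Barcode) -> float:
    """Total assignment cost divided by the number of matched pairs."""
    if not barcode.pairs:
        raise ValidationError("barcode has no assigned pairs")
    return barcode.total_cost / len(barcode.pairs)


def ot_distance(measured: SpectrumRecord, calc: SpectrumRecord) -> float:
    """Wasserstein-1 distance between normalized intensity distributions.

    Each peak list is treated as a discrete probability distribution on
    the frequency axis (intensities normalized to unit total mass); the
    returned value is the minimal transport work with ``|delta nu|``
    ground cost, in cm-1.
    """
    for label, rec in (("measured", measured), ("calculated", calc)):
        if not rec.peaks or sum(p.intensity for p in rec.peaks) <= 0:
            raise ValidationError(f"{label} record has zero total intensity")
    return float(
        wasserstein_distance(
            measured.frequencies,
            calc.frequencies,
            u_weights=measured.intensities,
            v_weights=calc.intensities,
        )
    )


@dataclass(frozen=True)
class CandidateScore:
    """All four similarity scores (and ranks) for one candidate."""

    label: str
    xcorr: Optional[float] = None
    xcorr_lag: Optional[float] = None
    avg_euclid: Optional[float] = None
    avg_manhattan: Optional[float] = None
    ot_dist: Optional[float] = None
    ranks: dict = field(default_factory=dict)
    failed: bool = False
    error: str = ""


@dataclass(frozen=True)
class SimilarityResult:
    """Scores and per-method ranks for a candidate set.

    Rank 1 is the best match per method (highest cross-correlation,
    lowest distance).  ``best(method)`` returns the winning candidate
    label.
    """

    measured_label: str
    candidates: tuple[CandidateScore, ...]
    config: MatchConfig

    METHODS = ("xcorr", "avg_euclid", "avg_manhattan", "ot_dist")

    def best(self, method: str) -> str:
        for cand in self.candidates:
            if cand.ranks.get(method) == 1:
                return cand.label
        raise VibmatchError(f"no candidate ranked 1 by {method}")

    def to_rows(self) -> list[dict]:
        rows = []
        for cand in self.candidates:
            row = {"candidate": cand.label, "failed": cand.failed}
            for method in self.METHODS:
                row[method] = getattr(cand, method)
                row[f"rank_{method}"] = cand.ranks.get(method)
            rows.append(row)
        return rows


def _assign_ranks(values: list, reverse: bool) -> list:
    """Ranks 1..k over non-None values; ties broken by input order."""
    order = [i for i, v in enumerate(values) if v is not None]
    order.sort(key=lambda i: (-values[i] if reverse else values[i]))
    ranks = [None] * len(values)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    for a, b in zip(order, order[1:]):
        if values[a] == values[b]:
            logger.info("tie between candidates %d and %d broken by input order", a, b)
    return ranks


def rank_candidates(
    measured: SpectrumRecord,
    candidates: Sequence[SpectrumRecord],
    factor_set: ScalingFactorSet,
    config: MatchConfig = MatchConfig(),
) -> SimilarityResult:
    """Score and rank candidate conformers against a measured spectrum.

    Pipeline per candidate: scale harmonic frequencies with
    ``factor_set``, normalize intensities, then compute (a) whole-
    spectrum cross-correlation after Lorentzian convolution, (b) average
    Euclidean and (c) Manhattan barcode distances via Kuhn-Munkres
    assignment on (frequency, weighted intensity) costs, and (d) the
    optimal-transport distance on the stick spectra.  The measured
    record is expected to be pre-filtered; it is normalized here.

    Candidates that cannot be scaled are marked failed and excluded
    from the rankings; the rest are ranked 1..k per method.
    """
    if not candidates:
        raise ValidationError("need at least one candidate")
    measured = normalize_intensities(measured)
    measured_cont = lorentzian_convolve(
        measured,
        fwhm=config.fwhm,
        grid_start=config.grid_start,
        grid_end=config.grid_end,
        grid_step=config.grid_step,
    )

    scores: list[CandidateScore] = []
    for cand in candidates:
        label = cand.conformer or cand.species
        try:
            scaled = normalize_intensities(apply_scaling(cand, factor_set))
            cont = lorentzian_convolve(
                scaled,
                fwhm=config.fwhm,
                grid_start=config.grid_start,
                grid_end=config.grid_end,
                grid_step=config.grid_step,
            )
            xc = cross_correlate(measured_cont, cont, max_lag=config.max_lag)
            eu = average_distance(
                kuhn_munkres(cost_matrix(measured, scaled, "euclid_2d", config.weight))
            )
            ma = average_distance(
                kuhn_munkres(cost_matrix(measured, scaled, "manhattan_2d", config.weight))
            )
            ot = ot_distance(measured, scaled)
        except VibmatchError as exc:
            logger.warning("candidate %s failed: %s", label, exc)
            scores.append(CandidateScore(label=label, failed=True, error=str(exc)))
            continue
        scores.append(
            CandidateScore(
                label=label,
                xcorr=xc.score,
                xcorr_lag=xc.lag,
                avg_euclid=eu,
                avg_manhattan=ma,
                ot_dist=ot,
            )
        )

    ranked: list[CandidateScore] = []
    rank_table = {
        "xcorr": _assign_ranks([s.xcorr for s in scores], reverse=True),
        "avg_euclid": _assign_ranks([s.avg_euclid for s in scores], reverse=False),
        "avg_manhattan": _assign_ranks([s.avg_manhattan for s in scores], reverse=False),
        "ot_dist": _assign_ranks([s.ot_dist for s in scores], reverse=False),
    }
    for i, s in enumerate(scores):
        ranks = {
            method: rank_table[method][i]
            for method in rank_table
            if rank_table[method][i] is not None
        }
        ranked.append(
            CandidateScore(
                label=s.label,
                xcorr=s.xcorr,
                xcorr_lag=s.xcorr_lag,
                avg_euclid=s.avg_euclid,
                avg_manhattan=s.avg_manhattan,
                ot_dist=s.ot_dist,
                ranks=ranks,
                failed=s.failed,
                error=s.error,
            )
        )
    return SimilarityResult(
        measured_label=measured.conformer or measured.species,
        candidates=tuple(ranked),
        config=config,
    )


def distance_uncertainty(
    barcode: Barcode, freq_sigma: float, intensity_sigma: float = 0.0
) -> float:
    """First-order uncertainty of the average barcode distance.

    Assumes independent Gaussian uncertainties ``freq_sigma`` (cm-1) on
    every peak position and ``intensity_sigma`` on every normalized
    intensity, on both the measured and the calculated side, and
    propagates them through each assigned pair's cost to the average.
    For a coincident pair (zero cost) the gradient of the Euclidean
    metric is undefined; the Manhattan-style bound is used there.
    """
    if freq_sigma < 0 or intensity_sigma < 0:
        raise ValidationError("sigmas must be >= 0")
    if not barcode.pairs:
        raise ValidationError("barcode has no assigned pairs")
    w = barcode.weight
    var_total = 0.0
    for (_, _, cost), dnu, di in zip(
        barcode.pairs, barcode.pair_dnu, barcode.pair_dintensity
    ):
        if barcode.metric == "euclid_1d":
            var = 2.0 * freq_sigma**2
        elif barcode.metric == "manhattan_2d":
            var = 2.0 * freq_sigma**2 + 2.0 * (w * intensity_sigma) ** 2
        else:  # euclid_2d
            if cost <= 0:
                var = 2.0 * freq_sigma**2 + 2.0 * (w * intensity_sigma) ** 2
            else:
                var = (
                    2.0 * (dnu / cost) ** 2 * freq_sigma**2
                    + 2.0 * (w**2 * di / cost) ** 2 * intensity_sigma**2
                )
        var_total += var
    return math.sqrt(var_total) / len(barcode.pairs)
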