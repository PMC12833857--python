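"""Synthetic conformer libraries, pseudo-measured spectra and databases.

The generator emulates the statistical structure of a jet-cooled
stimulated-Raman fundamentals database for neurotransmitter-like
molecules (aromatic ring + ethyl alcohol/amine side chain, plus
hydrates):

* mode-class composition dominated by mid- and low-frequency collective
  modes, with O-H, N-H, aromatic C-H and ethyl C-H stretches above
  2000 cm-1;
* per-class true scaling factors lambda* relating harmonic to
  fundamental frequencies, defaulting to benchmark mode-dependent
  values at each supported theory level;
* Gaussian frequency jitter, log-normal intensity noise, random peak
  dropout (population and line-overlap losses), and interloper peaks
  from the gain channel of co-present conformers, some of which fail
  the SNR/fwhm inclusion filter.

Everything is driven by one integer seed, so whole scenarios are
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .errors import ValidationError
from .io import write_peak_table
from .records import (
    Channel,
    FrequencyPair,
    ModeClass,
    Peak,
    SpectrumRecord,
    TheoryLevel,
)

__all__ = [
    "SynthConfig",
    "Scenario",
    "REFERENCE_MODE_LAMBDA",
    "DATABASE_CLASS_COUNTS",
    "HARMONIC_WINDOWS",
    "make_conformer_library",
    "make_measured_from",
    "make_scenario",
    "make_pair_database",
    "write_scenario",
]

logger = logging.getLogger(__name__)

#: Benchmark mode-dependent scaling factors lambda* per theory level,
#: used as the generator's ground truth.
REFERENCE_MODE_LAMBDA: dict[TheoryLevel, dict[ModeClass, float]] = {
    TheoryLevel("M06-2X", "6-311++G(d,p)"): {
        ModeClass.OH: 0.9402, ModeClass.NH: 0.9454, ModeClass.CH_RING: 0.9533,
        ModeClass.CH_ETHYL: 0.9493, ModeClass.MID: 0.9735, ModeClass.LOW: 0.9727,
    },
    TheoryLevel("M06-2X-D3", "6-311++G(d,p)"): {
        ModeClass.OH: 0.9402, ModeClass.NH: 0.9454, ModeClass.CH_RING: 0.9533,
        ModeClass.CH_ETHYL: 0.9493, ModeClass.MID: 0.9735, ModeClass.LOW: 0.9728,
    },
    TheoryLevel("M06-2X-D3", "cc-pVTZ"): {
        ModeClass.OH: 0.9454, ModeClass.NH: 0.9485, ModeClass.CH_RING: 0.9535,
        ModeClass.CH_ETHYL: 0.9499, ModeClass.MID: 0.9723, ModeClass.LOW: 0.9672,
    },
    TheoryLevel("B3LYP", "6-311++G(d,p)"): {
        ModeClass.OH: 0.9583, ModeClass.NH: 0.9564, ModeClass.CH_RING: 0.9640,
        ModeClass.CH_ETHYL: 0.9631, ModeClass.MID: 0.9833, ModeClass.LOW: 0.9837,
    },
    TheoryLevel("B3LYP-D3", "6-311++G(d,p)"): {
        ModeClass.OH: 0.9599, ModeClass.NH: 0.9566, ModeClass.CH_RING: 0.9642,
        ModeClass.CH_ETHYL: 0.9634, ModeClass.MID: 0.9818, ModeClass.LOW: 0.9790,
    },
    TheoryLevel("B3LYP-D3", "cc-pVTZ"): {
        ModeClass.OH: 0.9641, ModeClass.NH: 0.9590, ModeClass.CH_RING: 0.9637,
        ModeClass.CH_ETHYL: 0.9640, ModeClass.MID: 0.9790, ModeClass.LOW: 0.9731,
    },
    TheoryLevel("wB97X-D", "6-311++G(d,p)"): {
        ModeClass.OH: 0.9399, ModeClass.NH: 0.9435, ModeClass.CH_RING: 0.9566,
        ModeClass.CH_ETHYL: 0.9543, ModeClass.MID: 0.9712, ModeClass.LOW: 0.9699,
    },
    TheoryLevel("wB97X-D", "cc-pVTZ"): {
        ModeClass.OH: 0.9435, ModeClass.NH: 0.9453, ModeClass.CH_RING: 0.9556,
        ModeClass.CH_ETHYL: 0.9537, ModeClass.MID: 0.9688, ModeClass.LOW: 0.9655,
    },
}

_DEFAULT_THEORY = TheoryLevel("M06-2X-D3", "6-311++G(d,p)")

#: Mode-class composition of the full-database stand-in (824 rows,
#: proportions of a typical jet-cooled fundamentals benchmark).
DATABASE_CLASS_COUNTS: dict[ModeClass, int] = {
    ModeClass.OH: 35,
    ModeClass.NH: 56,
    ModeClass.CH_RING: 118,
    ModeClass.CH_ETHYL: 112,
    ModeClass.MID: 321,
    ModeClass.LOW: 182,
}

#: Harmonic-frequency draw windows (cm-1, pre-scaling) per class.
#: Chosen from standard vibrational ranges and kept clear of the
#: 1000/2000 cm-1 range cutoffs after multiplying by lambda* and adding
#: jitter and conformer offsets, so generated features stay in class.
HARMONIC_WINDOWS: dict[ModeClass, tuple[float, float]] = {
    ModeClass.OH: (3650.0, 3900.0),
    ModeClass.NH: (3450.0, 3600.0),
    ModeClass.CH_RING: (3150.0, 3250.0),
    ModeClass.CH_ETHYL: (3050.0, 3150.0),
    ModeClass.MID: (1080.0, 1970.0),
    ModeClass.LOW: (420.0, 980.0),
}

#: Per-conformer mode counts (~50 modes, same class proportions as the
#: database stand-in, at the scale of one mid-sized aromatic molecule).
DEFAULT_MODES_PER_CLASS: dict[ModeClass, int] = {
    ModeClass.OH: 2,
    ModeClass.NH: 3,
    ModeClass.CH_RING: 7,
    ModeClass.CH_ETHYL: 7,
    ModeClass.MID: 20,
    ModeClass.LOW: 11,
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    Defaults: 8 candidate conformers of ~50 modes each, 5 cm-1 frequency
    jitter between scaled-harmonic and fundamental positions, 20%
    intensity noise (coefficient of variation of the log-normal factor),
    30% peak dropout, and 0.5 interloper gain lines per 1000 cm-1.
    ``conformer_shift`` bounds the correlated per-class frequency
    offsets (cm-1) that distinguish conformers from one another.
    """

    n_conformers: int = 8
    modes_per_class: Mapping[ModeClass, int] = field(
        default_factory=lambda: dict(DEFAULT_MODES_PER_CLASS)
    )
    true_lambda: Mapping[ModeClass, float] = field(
        default_factory=lambda: dict(REFERENCE_MODE_LAMBDA[_DEFAULT_THEORY])
    )
    theory: TheoryLevel = _DEFAULT_THEORY
    freq_jitter_sigma: float = 5.0
    intensity_noise_cv: float = 0.2
    dropout_p: float = 0.3
    interloper_rate: float = 0.5  # per 1000 cm-1
    conformer_shift: tuple[float, float] = (2.0, 15.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValidationError("n_conformers must be >= 1")
        counts = {ModeClass(k): int(v) for k, v in self.modes_per_class.items()}
        if not counts or all(v == 0 for v in counts.values()):
            raise ValidationError("modes_per_class requests zero modes")
        if any(v < 0 for v in counts.values()):
            raise ValidationError("mode counts must be >= 0")
        object.__setattr__(self, "modes_per_class", counts)
        lam = {ModeClass(k): float(v) for k, v in self.true_lambda.items()}
        for cls, value in lam.items():
            if not 0.9 < value < 1.0:
                raise ValidationError(
                    f"true lambda for {cls.value} must lie in (0.9, 1.0), got {value}"
                )
        object.__setattr__(self, "true_lambda", lam)
        if not 0 <= self.dropout_p <= 1:
            raise ValidationError("dropout_p must be a probability")
        if self.freq_jitter_sigma < 0 or self.intensity_noise_cv < 0:
            raise ValidationError("noise parameters must be >= 0")
        if self.interloper_rate < 0:
            raise ValidationError("interloper_rate must be >= 0")


def _draw_base_modes(
    config: SynthConfig, rng: np.random.Generator
) -> list[tuple[float, float, ModeClass]]:
    """Base (omega, intensity, class) triples shared by all conformers."""
    modes = []
    for cls, count in config.modes_per_class.items():
        lo, hi = HARMONIC_WINDOWS[cls]
        freqs = rng.uniform(lo, hi, size=count)
        intens = rng.lognormal(mean=0.0, sigma=0.8, size=count)
        modes.extend(zip(freqs, intens, [cls] * count))
    return modes


def _sorted_record(
    species: str,
    conformer: str,
    triples: Sequence[tuple[float, float, ModeClass]],
    theory: TheoryLevel,
) -> SpectrumRecord:
    triples = sorted(triples, key=lambda t: t[0])
    peaks = tuple(
        Peak(freq, inten, channel=Channel.COMPUTED) for freq, inten, _ in triples
    )
    labels = tuple(cls.value for _, _, cls in triples)
    return SpectrumRecord(
        species=species,
        conformer=conformer,
        source="computed",
        theory=theory,
        peaks=peaks,
        metadata={"mode_classes": labels},
    )


def make_conformer_library(
    config: SynthConfig, species: str = "synth"
) -> list[SpectrumRecord]:
    """Generate a library of similar candidate conformers.

    All conformers share a base normal-mode set; each one perturbs it
    by a correlated per-class frequency offset (uniform magnitude within
    ``config.conformer_shift``, random sign, plus 2 cm-1 per-mode
    scatter) and a log-normal intensity redistribution — mimicking the
    subtle spectral differences between real conformers.  Mode-class
    labels ride along in ``metadata["mode_classes"]`` so the
    mode-dependent scaling scheme can classify the stretches.
    """
    rng = np.random.default_rng(config.seed)
    base = _draw_base_modes(config, rng)
    lo, hi = config.conformer_shift
    library = []
    for k in range(config.n_conformers):
        class_shift = {
            cls: rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi)
            for cls in config.modes_per_class
        }
        triples = []
        for freq, inten, cls in base:
            shifted = freq + class_shift[cls] + rng.normal(0.0, 2.0)
            redistributed = inten * rng.lognormal(0.0, 0.3)
            triples.append((shifted, redistributed, cls))
        library.append(
            _sorted_record(species, f"conf{k}", triples, config.theory)
        )
    return library


def make_measured_from(
    truth: SpectrumRecord,
    config: SynthConfig,
    seed: Optional[int] = None,
) -> tuple[SpectrumRecord, dict[int, int]]:
    """Degrade a computed record into a pseudo-measured spectrum.

    Each harmonic peak omega becomes a fundamental
    ``nu = lambda*_class * omega + N(0, freq_jitter_sigma)`` with
    multiplicative log-normal intensity noise, survives with
    probability ``1 - dropout_p``, and receives plausible SNR/fwhm
    metadata.  Interloper peaks (gain-channel lines of co-present
    species) are inserted at ``interloper_rate`` per 1000 cm-1; their
    SNR/fwhm straddle the inclusion thresholds so some are removed by
    the fundamentals filter and some survive as contamination.

    Returns the experimental record and a pairing key mapping measured
    peak index -> truth peak index (interlopers absent from the map).
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    labels = truth.metadata.get("mode_classes")
    if labels is None:
        raise ValidationError("truth record lacks mode_classes metadata")
    sigma_ln = (
        float(np.sqrt(np.log(1.0 + config.intensity_noise_cv**2)))
        if config.intensity_noise_cv > 0
        else 0.0
    )
    entries: list[tuple[float, float, Optional[float], Optional[float], Channel, int]] = []
    for idx, (peak, label) in enumerate(zip(truth.peaks, labels)):
        if rng.uniform() < config.dropout_p:
            continue
        lam = config.true_lambda[ModeClass(label)]
        nu = lam * peak.frequency + rng.normal(0.0, config.freq_jitter_sigma)
        inten = peak.intensity * (
            rng.lognormal(0.0, sigma_ln) if sigma_ln else 1.0
        )
        snr = rng.uniform(3.0, 30.0)
        fwhm = rng.uniform(4.5, 12.0)
        entries.append((nu, inten, fwhm, snr, Channel.LOSS, idx))

    span = (400.0, 3755.0)
    n_interlopers = rng.poisson(config.interloper_rate * (span[1] - span[0]) / 1000.0)
    ref_intensity = max((p.intensity for p in truth.peaks), default=1.0)
    for _ in range(n_interlopers):
        nu = rng.uniform(*span)
        inten = rng.uniform(0.05, 0.6) * ref_intensity
        snr = rng.uniform(1.0, 8.0)
        fwhm = rng.uniform(2.0, 9.0)
        entries.append((nu, inten, fwhm, snr, Channel.GAIN, -1))

    entries.sort(key=lambda e: e[0])
    peaks = []
    pairing: dict[int, int] = {}
    for measured_idx, (nu, inten, fwhm, snr, channel, truth_idx) in enumerate(entries):
        peaks.append(Peak(nu, inten, fwhm=fwhm, snr=snr, channel=channel))
        if truth_idx >= 0:
            pairing[measured_idx] = truth_idx
    record = SpectrumRecord(
        species=truth.species,
        conformer=truth.conformer,
        source="experimental",
        peaks=tuple(peaks),
    )
    return record, pairing


@dataclass(frozen=True)
class Scenario:
    """A complete simulated identification problem."""

    library: tuple[SpectrumRecord, ...]
    measured: SpectrumRecord
    pairing: Mapping[int, int]
    generating_index: int
    config: SynthConfig

    @property
    def generating_conformer(self) -> SpectrumRecord:
        return self.library[self.generating_index]


def make_scenario(config: SynthConfig, species: str = "synth") -> Scenario:
    """Library + pseudo-measured spectrum of one randomly chosen member."""
    library = make_conformer_library(config, species=species)
    rng = np.random.default_rng(config.seed + 7)
    generating = int(rng.integers(config.n_conformers))
    measured, pairing = make_measured_from(
        library[generating], config, seed=config.seed + 11
    )
    return Scenario(
        library=tuple(library),
        measured=measured,
        pairing=pairing,
        generating_index=generating,
        config=config,
    )


def pairs_from_scenario(scenario: Scenario) -> list[FrequencyPair]:
    """Frequency pairs for the surviving true correspondences."""
    truth = scenario.generating_conformer
    labels = truth.metadata["mode_classes"]
    pairs = []
    for m_idx, t_idx in scenario.pairing.items():
        m_peak = scenario.measured.peaks[m_idx]
        t_peak = truth.peaks[t_idx]
        pairs.append(
            FrequencyPair(
                nu_exp=m_peak.frequency,
                omega_calc=t_peak.frequency,
                intensity_exp=m_peak.intensity,
                mode_class=ModeClass(labels[t_idx]),
                record_key=(truth.species, truth.conformer, scenario.config.theory),
            )
        )
    return pairs


def make_pair_database(
    class_counts: Optional[Mapping[ModeClass, int]] = None,
    levels: Optional[Sequence[TheoryLevel]] = None,
    freq_jitter_sigma: float = 5.0,
    seed: int = 0,
) -> list[FrequencyPair]:
    """Synthetic stand-in for a full fundamentals/harmonics database.

    One experimental fundamental per row (824 by default, with the
    class composition of :data:`DATABASE_CLASS_COUNTS`), paired with a
    harmonic frequency at every requested theory level via that level's
    benchmark lambda* plus Gaussian jitter:

        omega_L = (nu - N(0, sigma)) / lambda*_{class, L}

    so the per-class least-squares fit recovers lambda*_{class, L} up
    to sampling noise.
    """
    class_counts = dict(DATABASE_CLASS_COUNTS if class_counts is None else class_counts)
    levels = list(REFERENCE_MODE_LAMBDA if levels is None else levels)
    rng = np.random.default_rng(seed)
    ref_level = levels[0]
    pairs: list[FrequencyPair] = []
    row = 0
    for cls, count in class_counts.items():
        lo, hi = HARMONIC_WINDOWS[cls]
        lam_ref = REFERENCE_MODE_LAMBDA[ref_level][cls]
        for _ in range(count):
            nu = lam_ref * rng.uniform(lo, hi)
            intensity = float(rng.lognormal(0.0, 0.8))
            for level in levels:
                lam = REFERENCE_MODE_LAMBDA[level][cls]
                omega = (nu - rng.normal(0.0, freq_jitter_sigma)) / lam
                pairs.append(
                    FrequencyPair(
                        nu_exp=nu,
                        omega_calc=omega,
                        intensity_exp=intensity,
                        mode_class=cls,
                        record_key=("synthdb", f"row{row}", level),
                    )
                )
            row += 1
    return pairs


PathLike = Union[str, Path]


def write_scenario(scenario: Scenario, directory: PathLike) -> None:
    """Write a scenario as peak-table CSVs plus a ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for record in scenario.library:
        write_peak_table(record, directory / f"candidate_{record.conformer}.csv")
    write_peak_table(scenario.measured, directory / "measured.csv")
    truth = {
        "generating_conformer": scenario.generating_conformer.conformer,
        "generating_index": scenario.generating_index,
        "true_lambda": {
            cls.value: lam for cls, lam in scenario.config.true_lambda.items()
        },
        "pairing": {str(k): v for k, v in scenario.pairing.items()},
        "seed": scenario.config.seed,
    }
    (directory / "truth.json").write_text(
        json.dumps(truth, indent=1) + "\n", encoding="utf-8"
    )
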