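"""Core domain types for discrete vibrational spectra.

A spectrum here is a *peak list*: band maxima (Q-branch positions) with
intensities, not a continuous trace.  Measured features come from
ionization-detected stimulated Raman spectra and carry loss/gain channel
tags plus quality metadata (signal-to-noise ratio, full width at half
maximum); calculated features are harmonic normal-mode frequencies with
Raman activities at one of eight density-functional theory levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError

__all__ = [
    "Channel",
    "ModeClass",
    "Scheme",
    "TheoryLevel",
    "THEORY_LEVELS",
    "Peak",
    "SpectrumRecord",
    "FrequencyPair",
    "STRETCH_CLASSES",
    "MODE_SCHEME_CLASSES",
    "RANGE_SCHEME_CLASSES",
]


class Channel(str, Enum):
    """Origin of a spectral feature."""

    LOSS = "loss"
    GAIN = "gain"
    COMPUTED = "computed"


class ModeClass(str, Enum):
    """Vibrational mode classes used by the scaling schemes.

    ``OH``/``NH``/``CH_RING``/``CH_ETHYL`` are well-isolated stretching
    modes above 2000 cm-1; ``MID`` (1000-2000 cm-1) and ``LOW``
    (<1000 cm-1) are collective-motion windows.  ``HIGH`` (>2000 cm-1)
    is used only by the range-dependent scheme, which pools all
    stretches; ``GLOBAL`` is the single catch-all class of the global
    scheme.
    """

    OH = "OH"
    NH = "NH"
    CH_RING = "CH_ring"
    CH_ETHYL = "CH_ethyl"
    MID = "mid"
    LOW = "low"
    HIGH = "high"
    GLOBAL = "global"


class Scheme(str, Enum):
    """Scaling-factor scheme: one factor, per-range, or per-mode."""

    GLOBAL = "global"
    RANGE_DEPENDENT = "range_dependent"
    MODE_DEPENDENT = "mode_dependent"


#: Stretch-mode labels that must be supplied by the database for
#: high-frequency (>2000 cm-1) features under the mode-dependent scheme.
STRETCH_CLASSES = frozenset(
    {ModeClass.OH, ModeClass.NH, ModeClass.CH_RING, ModeClass.CH_ETHYL}
)

MODE_SCHEME_CLASSES = (
    ModeClass.OH,
    ModeClass.NH,
    ModeClass.CH_RING,
    ModeClass.CH_ETHYL,
    ModeClass.MID,
    ModeClass.LOW,
)

RANGE_SCHEME_CLASSES = (ModeClass.HIGH, ModeClass.MID, ModeClass.LOW)


_FUNCTIONAL_ALIASES = {
    "M06-2X": "M06-2X",
    "M06-2X-D3": "M06-2X-D3",
    "B3LYP": "B3LYP",
    "B3LYP-D3": "B3LYP-D3",
    "wB97X-D": "wB97X-D",
    "ωB97X-D": "wB97X-D",  # accept the Greek-omega spelling
}

_VALID_COMBOS = frozenset(
    {
        ("M06-2X", "6-311++G(d,p)"),
        ("M06-2X-D3", "6-311++G(d,p)"),
        ("M06-2X-D3", "cc-pVTZ"),
        ("B3LYP", "6-311++G(d,p)"),
        ("B3LYP-D3", "6-311++G(d,p)"),
        ("B3LYP-D3", "cc-pVTZ"),
        ("wB97X-D", "6-311++G(d,p)"),
        ("wB97X-D", "cc-pVTZ"),
    }
)


@dataclass(frozen=True, order=True)
class TheoryLevel:
    """A functional/basis-set combination used for harmonic frequencies.

    Only the eight combinations benchmarked by the database are valid:
    M06-2X(-D3), B3LYP(-D3) and wB97X-D paired with 6-311++G(d,p)
    and/or cc-pVTZ.
    """

    functional: str
    basis: str

    def __post_init__(self) -> None:
        func = _FUNCTIONAL_ALIASES.get(self.functional)
        if func is None:
            raise ValidationError(
                f"unknown functional {self.functional!r}; expected one of "
                f"{sorted(set(_FUNCTIONAL_ALIASES.values()))}"
            )
        object.__setattr__(self, "functional", func)
        if (func, self.basis) not in _VALID_COMBOS:
            raise ValidationError(
                f"unsupported theory level {func}/{self.basis}"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.functional}/{self.basis}"

    @property
    def column(self) -> str:
        """Column name used in the pair-database CSV dialect.

        Commas in the basis name are replaced by ``.`` so the header
        stays unambiguous without CSV quoting.
        """
        return f"omega__{self.functional}__{self.basis.replace(',', '.')}"

    @classmethod
    def from_column(cls, column: str) -> "TheoryLevel":
        """Inverse of :attr:`column`."""
        prefix = "omega__"
        if not column.startswith(prefix):
            raise ValidationError(f"not an omega column: {column!r}")
        functional, _, basis_token = column[len(prefix):].partition("__")
        for _func, basis in _VALID_COMBOS:
            if basis.replace(",", ".") == basis_token:
                return cls(functional, basis)
        raise ValidationError(f"unknown basis in column {column!r}")


#: The eight benchmarked theory levels, in database column order.
THEORY_LEVELS: tuple[TheoryLevel, ...] = tuple(
    TheoryLevel(f, b) for f, b in sorted(_VALID_COMBOS)
)


@dataclass(frozen=True)
class Peak:
    """One spectral feature: a band maximum with an intensity.

    Parameters
    ----------
    frequency:
        Band position in cm-1; must be positive.
    intensity:
        Non-negative intensity in arbitrary units (normalized downstream).
    fwhm:
        Full width at half maximum in cm-1, if measured.
    snr:
        Signal-to-noise ratio, if measured.
    channel:
        ``loss``/``gain`` for measured features, ``computed`` otherwise.
    """

    frequency: float
    intensity: float
    fwhm: Optional[float] = None
    snr: Optional[float] = None
    channel: Channel = Channel.LOSS

    def __post_init__(self) -> None:
        if not math.isfinite(self.frequency) or self.frequency <= 0:
            raise ValidationError(
                f"peak frequency must be finite and > 0, got {self.frequency!r}"
            )
        if not math.isfinite(self.intensity) or self.intensity < 0:
            raise ValidationError(
                f"peak intensity must be finite and >= 0, got {self.intensity!r}"
            )
        if self.fwhm is not None and not self.fwhm > 0:
            raise ValidationError(f"fwhm must be > 0 when present, got {self.fwhm!r}")
        if self.snr is not None and not math.isfinite(self.snr):
            raise ValidationError(f"snr must be finite, got {self.snr!r}")
        if not isinstance(self.channel, Channel):
            object.__setattr__(self, "channel", Channel(self.channel))


@dataclass(frozen=True)
class SpectrumRecord:
    """A labeled peak list for one species/conformer.

    Peaks are kept sorted by ascending frequency and duplicate
    frequencies within a record are rejected; ``source`` distinguishes
    measured (``experimental``) from calculated (``computed``) spectra,
    and computed records carry their :class:`TheoryLevel`.
    """

    species: str
    conformer: str = ""
    source: str = "experimental"
    theory: Optional[TheoryLevel] = None
    peaks: tuple[Peak, ...] = ()
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source not in ("experimental", "computed"):
            raise ValidationError(
                f"source must be 'experimental' or 'computed', got {self.source!r}"
            )
        if self.source == "experimental" and self.theory is not None:
            raise ValidationError("experimental records carry no theory level")
        peaks = tuple(sorted(self.peaks, key=lambda p: p.frequency))
        freqs = [p.frequency for p in peaks]
        for a, b in zip(freqs, freqs[1:]):
            if a == b:
                raise ValidationError(
                    f"duplicate peak frequency {a} cm-1 in record "
                    f"{self.species}/{self.conformer}"
                )
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(self, "metadata", dict(self.metadata))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(p.frequency for p in self.peaks)

    @property
    def intensities(self) -> tuple[float, ...]:
        return tuple(p.intensity for p in self.peaks)

    def with_peaks(self, peaks: Iterable[Peak]) -> "SpectrumRecord":
        """Return a copy of this record with a different peak list."""
        return replace(self, peaks=tuple(peaks))


#: Sanity window on nu/omega: harmonic frequencies overestimate
#: fundamentals, so the ratio should sit modestly below one.
RATIO_WINDOW = (0.8, 1.1)


@dataclass(frozen=True)
class FrequencyPair:
    """One database row at one theory level.

    Pairs an experimental fundamental ``nu_exp`` with the corresponding
    calculated harmonic frequency ``omega_calc``; carries the measured
    intensity and the mode class used by the scaling schemes.
    """

    nu_exp: float
    omega_calc: float
    intensity_exp: float = 1.0
    mode_class: Optional[ModeClass] = None
    record_key: tuple = ()

    def __post_init__(self) -> None:
        if not self.nu_exp > 0:
            raise ValidationError(f"nu_exp must be > 0, got {self.nu_exp!r}")
        if not self.omega_calc > 0:
            raise ValidationError(
                f"omega_calc must be > 0, got {self.omega_calc!r}"
            )

    @property
    def ratio(self) -> float:
        """nu/omega — the per-pair empirical scaling factor."""
        return self.nu_exp / self.omega_calc

    def ratio_in_window(self) -> bool:
        lo, hi = RATIO_WINDOW
        return lo < self.ratio < hi


def ensure_pairs(pairs: Sequence[FrequencyPair], minimum: int = 1) -> None:
    """Raise :class:`InsufficientDataError` when fewer than ``minimum`` pairs."""
    from .errors import InsufficientDataError

    if len(pairs) < minimum:
        raise InsufficientDataError(
            f"need at least {minimum} frequency pairs, got {len(pairs)}"
        )
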