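"""Three-state myoglobin spectral model.

Reference molar-absorptivity curves (relative units) for the deoxy, oxy and
met states are modeled as sums of Gaussian bands.  Oxy band centers are
418 nm (Soret) and 545/580 nm (Q bands); deoxy and met centers are
configurable defaults from standard myoglobin spectroscopy.  The module
provides Beer-Lambert composition of state mixtures and non-negative
least-squares decomposition of observed spectra into state fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

STATES = ("deoxy", "oxy", "met")

#: (center_nm, fwhm-ish width_nm, relative amplitude) per state.
DEFAULT_BANDS: dict[str, list[tuple[float, float, float]]] = {
    "oxy": [(418.0, 11.0, 1.00), (545.0, 10.0, 0.13), (580.0, 10.0, 0.12)],
    "deoxy": [(434.0, 13.0, 1.15), (556.0, 12.0, 0.12)],
    "met": [(409.0, 11.5, 1.05), (505.0, 11.0, 0.09), (635.0, 13.0, 0.04)],
}

_COVERAGE = (350.0, 700.0)


def default_wavelengths(step: float = 1.0) -> np.ndarray:
    """Default 350-700 nm wavelength grid."""
    return np.arange(_COVERAGE[0], _COVERAGE[1] + 0.5 * step, step)


@dataclass(frozen=True)
class StateSpectrum:
    """Molar absorptivity curve for one oxidation/ligation state."""

    state: str
    wavelengths: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing 1-D array")
        if eps.shape != wl.shape:
            raise ValueError("epsilon and wavelengths shape mismatch")
        if np.any(eps < 0):
            raise ValueError("epsilon must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "epsilon", eps)


def basis_spectrum(
    state: str,
    wavelengths: np.ndarray | None = None,
    bands: list[tuple[float, float, float]] | None = None,
) -> StateSpectrum:
    """Sum-of-Gaussians reference spectrum for one state.

    Parameters
    ----------
    state : {"deoxy", "oxy", "met"}
    wavelengths : array, optional
        Must cover 350-700 nm.  Defaults to a 1 nm grid.
    bands : list of (center, width, amplitude), optional
        Overrides the per-state default band table.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    if wl[0] > _COVERAGE[0] or wl[-1] < _COVERAGE[1]:
        raise ValueError("wavelength grid must cover 350-700 nm")
    table = DEFAULT_BANDS[state] if bands is None else bands
    eps = np.zeros_like(wl)
    for center, width, amp in table:
        eps += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return StateSpectrum(state=state, wavelengths=wl, epsilon=eps)


@dataclass(frozen=True)
class BasisSet:
    """Basis matrix of state spectra sharing one wavelength axis."""

    wavelengths: np.ndarray
    states: tuple[str, ...]
    matrix: np.ndarray  # (n_wavelengths, n_states)

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate states make the basis singular")
        if self.matrix.shape != (self.wavelengths.size, len(self.states)):
            raise ValueError("basis matrix shape mismatch")

    @classmethod
    def default(cls, wavelengths: np.ndarray | None = None) -> "BasisSet":
        wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
        cols = [basis_spectrum(s, wl).epsilon for s in STATES]
        return cls(wavelengths=wl, states=STATES, matrix=np.column_stack(cols))

    def column(self, state: str) -> np.ndarray:
        if state not in self.states:
            raise ValueError(f"basis has no state {state!r}")
        return self.matrix[:, self.states.index(state)]


@dataclass(frozen=True)
class StateFractions:
    """Fractions of the deoxy/oxy/met states; sum to 1 after normalization."""

    f_deoxy: float
    f_oxy: float
    f_met: float

    def __post_init__(self) -> None:
        for f in (self.f_deoxy, self.f_oxy, self.f_met):
            if not (-1e-9 <= f <= 1 + 1e-9):
                raise ValueError("fractions must lie in [0, 1]")
        if abs(self.f_deoxy + self.f_oxy + self.f_met - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 (use .normalized())")

    @classmethod
    def normalized(cls, f_deoxy: float, f_oxy: float, f_met: float) -> "StateFractions":
        v = np.clip([f_deoxy, f_oxy, f_met], 0.0, None)
        total = v.sum()
        if total <= 0:
            raise ValueError("all fractions are zero")
        v = v / total
        return cls(*v)

    def as_array(self, states: tuple[str, ...] = STATES) -> np.ndarray:
        lookup = {"deoxy": self.f_deoxy, "oxy": self.f_oxy, "met": self.f_met}
        return np.array([lookup[s] for s in states])


def compose(
    fractions: StateFractions,
    basis: BasisSet,
    concentration: float = 1.0,
    path: float = 1.0,
) -> np.ndarray:
    """Beer-Lambert absorbance of a state mixture.

    Linear in both ``concentration`` and ``path``.
    """
    return concentration * path * (basis.matrix @ fractions.as_array(basis.states))


@dataclass(frozen=True)
class Decomposition:
    fractions: StateFractions
    residual_norm: float
    raw_coefficients: np.ndarray = field(repr=False, default=None)


def decompose(spectrum: np.ndarray, basis: BasisSet) -> Decomposition:
    """Non-negative least-squares state fractions of an observed spectrum.

    Coefficients are clipped at zero by construction (NNLS) and renormalized
    to sum to one, which makes the result invariant to the overall
    concentration * pathlength scale.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.shape != (basis.wavelengths.size,):
        raise ValueError("spectrum does not match basis wavelength grid")
    if y.size < 3:
        raise ValueError("need at least 3 wavelengths to decompose 3 states")
    coef, rnorm = nnls(basis.matrix, y)
    by_state = dict(zip(basis.states, coef))
    fractions = StateFractions.normalized(
        by_state.get("deoxy", 0.0), by_state.get("oxy", 0.0), by_state.get("met", 0.0)
    )
    return Decomposition(fractions=fractions, residual_norm=float(rnorm), raw_coefficients=coef)


def basis_to_csv(basis: BasisSet) -> str:
    """Serialize a basis as CSV: wavelength_nm plus one column per state."""
    header = "wavelength_nm," + ",".join(basis.states)
    rows = [
        f"{wl:.6g}," + ",".join(f"{v:.8g}" for v in row)
        for wl, row in zip(basis.wavelengths, basis.matrix)
    ]
    return "\n".join([header, *rows]) + "\n"


def basis_from_csv(text: str) -> BasisSet:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    states = tuple(lines[0].split(",")[1:])
    data = np.array([[float(x) for x in ln.split(",")] for ln in lines[1:]])
    return BasisSet(wavelengths=data[:, 0], states=states, matrix=data[:, 1:])
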