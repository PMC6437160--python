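"""Reduction-potential determination.

Two routes: (i) spectroelectrochemical titrations analyzed with a
two-wavelength Nernst progress plot, and (ii) square-wave voltammetry
net-current peak extraction.  Both report E deg' versus SHE via additive
reference-electrode conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import R, physical_constants

F = physical_constants["Faraday constant"][0]

#: Reference electrode potentials vs SHE at 25 degC (standard-table values).
REFERENCE_POTENTIALS: dict[str, float] = {
    "SHE": 0.0,
    "SCE": 0.2412,
    "Ag/AgCl/3M KCl": 0.210,
}


def nernst_slope(temperature_C: float = 25.0) -> float:
    """RT ln(10) / F in volts per decade (0.05916 V at 25 degC)."""
    return R * (273.15 + temperature_C) * np.log(10.0) / F


def convert_reference(E: float, from_ref: str, to_ref: str) -> float:
    """Additive shift between named reference electrodes.

    Results are quantized to 0.1 uV so that A -> B -> A round trips are
    bit-exact for physically meaningful potentials (raw float addition is
    not associative at the last ulp).
    """
    for ref in (from_ref, to_ref):
        if ref not in REFERENCE_POTENTIALS:
            raise ValueError(
                f"unknown reference {ref!r}; known: {sorted(REFERENCE_POTENTIALS)}"
            )
    if from_ref == to_ref:
        return E
    shifted = E + REFERENCE_POTENTIALS[from_ref] - REFERENCE_POTENTIALS[to_ref]
    return round(shifted * 1e7) / 1e7


@dataclass(frozen=True)
class RedoxTitration:
    """Spectra recorded at a series of applied potentials.

    ``spectra`` is (n_wavelengths, n_potentials).  At least five potentials
    are required.
    """

    potentials: np.ndarray
    reference: str
    wavelengths: np.ndarray
    spectra: np.ndarray
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        E = np.asarray(self.potentials, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        A = np.asarray(self.spectra, dtype=float)
        if E.size < 5:
            raise ValueError("titration needs at least five potentials")
        if self.reference not in REFERENCE_POTENTIALS:
            raise ValueError(f"unknown reference {self.reference!r}")
        if A.shape != (wl.size, E.size):
            raise ValueError("spectra must be (n_wavelengths, n_potentials)")
        if not np.all(np.isfinite(A)):
            raise ValueError("spectra must be finite")
        object.__setattr__(self, "potentials", E)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "spectra", A)


@dataclass(frozen=True)
class NernstPoints:
    """Usable Nernst-plot points from a titration."""

    E: np.ndarray            # potentials (titration reference)
    log_ratio: np.ndarray    # log10(oxidized progress / reduced progress)
    x_red: np.ndarray        # normalized reduced-species progress, all points
    x_ox: np.ndarray         # normalized oxidized-species progress, all points


def nernst_variable(
    titration: RedoxTitration,
    lambda_red: float,
    lambda_ox: float,
    floor: float = 0.02,
) -> NernstPoints:
    """Two-wavelength redox progress signals and their log10 ratio.

    The reduced-species progress at each potential is the absorbance rise at
    ``lambda_red`` above its titration minimum; the oxidized-species progress
    is the rise at ``lambda_ox`` above its minimum.  Each signal is
    normalized to its own maximum across the titration so that, for a
    titration driven to near-complete conversion at both ends, the ratio
    equals [Ox]/[Red] independently of the two bands' absorptivities.
    Points where either normalized signal falls below ``floor`` are dropped
    from the log-ratio (noise-dominated ends of the titration).
    """
    wl = titration.wavelengths

    def _row(lam: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(wl - lam)))
        if abs(wl[idx] - lam) > 0.25 * (wl[1] - wl[0]) + 1e-9:
            raise ValueError(f"wavelength {lam} nm not on the spectral grid")
        return titration.spectra[idx, :]

    a_red = _row(lambda_red)
    a_ox = _row(lambda_ox)
    x_red = a_red - a_red.min()
    x_ox = a_ox - a_ox.min()
    if x_red.max() <= 0 or x_ox.max() <= 0:
        raise ValueError("no redox progress at the chosen wavelengths")
    x_red = x_red / x_red.max()
    x_ox = x_ox / x_ox.max()
    usable = (x_red > floor) & (x_ox > floor)
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable Nernst points after flooring")
    log_ratio = np.log10(x_ox[usable] / x_red[usable])
    return NernstPoints(
        E=titration.potentials[usable], log_ratio=log_ratio, x_red=x_red, x_ox=x_ox
    )


@dataclass(frozen=True)
class NernstFit:
    E0: float                 # V vs SHE
    slope: float              # V per decade
    n_electrons: int
    r_squared: float
    points_used: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")


def fit_nernst(
    E: np.ndarray,
    log_ratio: np.ndarray,
    reference: str = "SHE",
    temperature_C: float = 25.0,
) -> NernstFit:
    """Ordinary least squares of E on log10([Ox]/[Red]).

    E0 is the potential at zero log ratio, converted to SHE; the electron
    count is round(slope_1e / |slope|) with slope_1e = RT ln10 / F.  A
    negative slope (inconsistent with the reduction convention used here)
    is flagged, not auto-corrected.
    """
    E = np.asarray(E, dtype=float)
    lr = np.asarray(log_ratio, dtype=float)
    if E.size != lr.size or E.size < 2:
        raise ValueError("need matching E / log-ratio arrays with >= 2 points")
    flags: list[str] = []
    if E.size < 5:
        flags.append("fewer than 5 points")
    slope, intercept = np.polyfit(lr, E, 1)
    fitted = intercept + slope * lr
    ss_res = float(np.sum((E - fitted) ** 2))
    ss_tot = float(np.sum((E - E.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope < 0:
        flags.append("slope sign inconsistent with reduction convention")
    s1 = nernst_slope(temperature_C)
    n = max(1, round(s1 / abs(slope))) if slope != 0 else 1
    E0_she = convert_reference(float(intercept), reference, "SHE")
    return NernstFit(
        E0=E0_she, slope=float(slope), n_electrons=int(n),
        r_squared=float(np.clip(r2, 0.0, 1.0)), points_used=int(E.size),
        flags=tuple(flags),
    )


def fit_titration(
    titration: RedoxTitration,
    lambda_red: float = 434.0,
    lambda_ox: float = 409.0,
    floor: float = 0.02,
) -> NernstFit:
    """Convenience wrapper: progress signals then Nernst fit, vs SHE."""
    pts = nernst_variable(titration, lambda_red, lambda_ox, floor=floor)
    return fit_nernst(
        pts.E, pts.log_ratio,
        reference=titration.reference, temperature_C=titration.temperature_C,
    )


@dataclass(frozen=True)
class Voltammogram:
    """Square-wave net current versus applied potential."""

    potential: np.ndarray
    net_current: np.ndarray
    reference: str = "SCE"

    def __post_init__(self) -> None:
        E = np.asarray(self.potential, dtype=float)
        i = np.asarray(self.net_current, dtype=float)
        d = np.diff(E)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("potential axis must be strictly monotone")
        if i.shape != E.shape:
            raise ValueError("current/potential shape mismatch")
        if self.reference not in REFERENCE_POTENTIALS:
            raise ValueError(f"unknown reference {self.reference!r}")
        object.__setattr__(self, "potential", E)
        object.__setattr__(self, "net_current", i)


@dataclass(frozen=True)
class SwvPeak:
    E_peak: float            # V, in the voltammogram's reference
    E_peak_she: float        # V vs SHE
    reference: str
    flags: tuple[str, ...] = ()


def swv_peak(vgram: Voltammogram, baseline_window: float = 0.05) -> SwvPeak:
    """Peak potential of a square-wave voltammogram.

    A straight baseline is fitted to the flanking ``baseline_window`` volts
    at each end of the scan and subtracted; the maximum of the corrected
    current is refined with a parabola through the five surrounding points.
    Plateau ties break toward the lowest potential; a maximum at the scan
    edge is flagged as a truncated peak.
    """
    E = vgram.potential
    i = vgram.net_current
    lo, hi = E.min(), E.max()
    edge = (E <= lo + baseline_window) | (E >= hi - baseline_window)
    if edge.sum() >= 2:
        coeff = np.polyfit(E[edge], i[edge], 1)
        corrected = i - np.polyval(coeff, E)
    else:
        corrected = i - i.min()
    peak_val = corrected.max()
    # lowest potential wins plateau ties
    candidates = np.where(np.isclose(corrected, peak_val, rtol=0, atol=0))[0]
    idx = int(candidates[np.argmin(E[candidates])])
    flags: list[str] = []
    if idx <= 1 or idx >= E.size - 2:
        flags.append("truncated peak")
        e_pk = float(E[idx])
    else:
        sl = slice(max(idx - 2, 0), min(idx + 3, E.size))
        a, b, _c = np.polyfit(E[sl], corrected[sl], 2)
        e_pk = float(-b / (2 * a)) if a < 0 else float(E[idx])
    return SwvPeak(
        E_peak=e_pk,
        E_peak_she=convert_reference(e_pk, vgram.reference, "SHE"),
        reference=vgram.reference,
        flags=tuple(flags),
    )


def titration_to_csv(titration: RedoxTitration) -> str:
    """Wavelength rows x potential columns; header names potentials + reference."""
    header = "wavelength_nm," + ",".join(
        f"E={e:.6g}V vs {titration.reference}" for e in titration.potentials
    )
    rows = [
        f"{wl:.6g}," + ",".join(f"{v:.8g}" for v in row)
        for wl, row in zip(titration.wavelengths, titration.spectra)
    ]
    return "\n".join([header, *rows]) + "\n"


def titration_from_csv(text: str, temperature_C: float = 25.0) -> RedoxTitration:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    cols = lines[0].split(",")[1:]
    potentials = np.array([float(c.split("=")[1].split("V")[0]) for c in cols])
    reference = cols[0].split(" vs ", 1)[1].strip()
    data = np.array([[float(x) for x in ln.split(",")] for ln in lines[1:]])
    return RedoxTitration(
        potentials=potentials, reference=reference,
        wavelengths=data[:, 0], spectra=data[:, 1:], temperature_C=temperature_C,
    )


def voltammogram_to_csv(vgram: Voltammogram) -> str:
    rows = [f"{e:.9g},{c:.9g}" for e, c in zip(vgram.potential, vgram.net_current)]
    return "\n".join([f"# reference: {vgram.reference}", "potential_V,net_current", *rows]) + "\n"


def voltammogram_from_csv(text: str) -> Voltammogram:
    reference = "SCE"
    data = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            if "reference:" in ln:
                reference = ln.split("reference:", 1)[1].strip()
            continue
        if ln.startswith("potential"):
            continue
        e, c = ln.split(",")[:2]
        data.append((float(e), float(c)))
    arr = np.array(data)
    return Voltammogram(potential=arr[:, 0], net_current=arr[:, 1], reference=reference)
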