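"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and seed: identical
arguments give bit-identical output, and at sigma = 0 the data equal their
closed forms to machine precision.  Noise is iid Gaussian on the
absorbance / current / log-expression scale (sigma defaults to 0.002 AU,
typical stopped-flow noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .electrochem import RedoxTitration, Voltammogram, nernst_slope
from .kinetics import KineticTrace
from .spectra import BasisSet
from .genetics.pedigree import AFFECTED, UNAFFECTED, Individual, Pedigree
from .genetics.linkage import DiseaseModel

#: Stopped-flow dead time (s): earliest observable point after mixing.
DEAD_TIME_S = 0.68e-3

#: Default O2 concentration panel (M).
DEFAULT_O2_PANEL = (2.5e-6, 5e-6, 10e-6, 20e-6, 30e-6, 40e-6)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian measurement noise: sigma in AU plus the generator seed."""

    sigma_abs: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_abs < 0:
            raise ValueError("sigma_abs must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NOISELESS = NoiseSpec(sigma_abs=0.0, seed=0)


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth parameter set for one protein variant.

    Rates use the units of the matching estimators: k_on M^-1 s^-1,
    k_off s^-1, k_minus_H h^-1, k_ox min^-1, E0 V vs SHE.
    """

    k_on: float
    k_off: float
    k_minus_H: float
    k_ox: float
    E0: float
    n_electrons: int = 1
    enriched_gene_ids: frozenset = frozenset()
    theta_true: float = 0.0
    k_minus_H_ph5: float | None = None
    E0_swv: float | None = None

    def __post_init__(self) -> None:
        for r in (self.k_on, self.k_off, self.k_minus_H, self.k_ox):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if not (0.0 <= self.theta_true <= 0.5):
            raise ValueError("theta_true must lie in [0, 0.5]")
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")

    @property
    def K_D(self) -> float:
        return self.k_off / self.k_on if self.k_on > 0 else np.inf


# Two-variant truth sets.  k_off is K_D * k_on (the equilibrium constant and
# slope are the directly reported quantities; the intercept follows).
WT_TRUTH = GroundTruth(
    k_on=1.16e7, k_off=1.2e-6 * 1.16e7, k_minus_H=0.22, k_ox=1.96,
    E0=0.040, k_minus_H_ph5=1.44, E0_swv=-0.056,
)
H98Y_TRUTH = GroundTruth(
    k_on=5.6e6, k_off=8.4e-6 * 5.6e6, k_minus_H=1.19, k_ox=1.97,
    E0=0.021, k_minus_H_ph5=1.86, E0_swv=-0.105,
)


def default_binding_grid(k_obs: float, n: int = 300) -> np.ndarray:
    """Time grid from the dead time through ~8 observed half-lives."""
    span = max(8.0 * np.log(2.0) / max(k_obs, 1e-9), 10.0 * DEAD_TIME_S)
    return np.linspace(DEAD_TIME_S, DEAD_TIME_S + span, n)


def gen_binding_traces(
    k_on: float,
    k_off: float,
    o2_concs=DEFAULT_O2_PANEL,
    t_grid: np.ndarray | None = None,
    noise: NoiseSpec = NOISELESS,
    a_start: float = 0.05,
    a_end: float = 0.15,
) -> list[KineticTrace]:
    """Pseudo-first-order O2-binding traces at 418 nm.

    Each trace follows A(t) = A_inf - (A_inf - A_0) exp(-k_obs t) with
    k_obs = k_on [O2] + k_off; A_0/A_inf are the signal values extrapolated
    to t = 0, so the dead-time gap is honored by the grid, not the model.
    One independent noise stream per concentration (single parent seed).
    """
    concs = np.asarray(list(o2_concs), dtype=float)
    if concs.size == 0 or np.any(concs <= 0):
        raise ValueError("O2 concentrations must be positive and non-empty")
    if t_grid is not None:
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid.size == 0:
            raise ValueError("empty time grid")
        if np.any(np.diff(t_grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
    rng = noise.rng()
    traces = []
    for conc in concs:
        k_obs = k_on * conc + k_off
        t = default_binding_grid(k_obs) if t_grid is None else t_grid
        signal = a_end - (a_end - a_start) * np.exp(-k_obs * t)
        signal = signal + rng.normal(0.0, noise.sigma_abs, size=t.size)
        traces.append(KineticTrace(
            time=t, signal=signal, time_unit="s", wavelength_nm=418.0,
            temperature_C=25.0, ligand_conc_M=float(conc),
        ))
    return traces


def gen_hemin_loss_trace(
    k_minus_H: float,
    t_grid_min: np.ndarray | None = None,
    amplitude: float = 0.6,
    offset: float = 0.25,
    noise: NoiseSpec = NOISELESS,
) -> KineticTrace:
    """410 nm hemin-transfer decay over a 0-350 min grid, time in hours.

    A(t) = offset + amplitude * exp(-k t) with k in h^-1.
    """
    if k_minus_H < 0:
        raise ValueError("k_minus_H must be >= 0")
    if amplitude < 0:
        raise ValueError("a positive decay requires non-negative amplitude")
    if t_grid_min is None:
        t_grid_min = np.arange(0.0, 350.0 + 1e-9, 2.0)
    t_h = np.asarray(t_grid_min, dtype=float) / 60.0
    signal = offset + amplitude * np.exp(-k_minus_H * t_h)
    signal = signal + noise.rng().normal(0.0, noise.sigma_abs, size=t_h.size)
    return KineticTrace(
        time=t_h, signal=signal, time_unit="h", wavelength_nm=410.0,
        temperature_C=37.0,
    )


@dataclass(frozen=True)
class SpectrumSeries:
    """Spectra recorded at successive times, (n_wavelengths, n_times)."""

    wavelengths: np.ndarray
    times: np.ndarray
    spectra: np.ndarray
    time_unit: str = "min"


def gen_autoxidation_series(
    k_ox: float,
    t_grid_min: np.ndarray,
    basis: BasisSet,
    noise: NoiseSpec = NOISELESS,
    concentration: float = 1.0,
) -> SpectrumSeries:
    """First-order oxy -> met conversion rendered through the basis.

    spectrum(t) = c * [f_met(t) * eps_met + (1 - f_met(t)) * eps_oxy] with
    f_met(t) = 1 - exp(-k_ox t).
    """
    for state in ("oxy", "met"):
        if state not in basis.states:
            raise ValueError(f"basis is missing the {state!r} state")
    t = np.asarray(t_grid_min, dtype=float)
    f_met = 1.0 - np.exp(-k_ox * t)
    oxy = basis.column("oxy")
    met = basis.column("met")
    clean = concentration * (np.outer(oxy, 1.0 - f_met) + np.outer(met, f_met))
    spectra = clean + noise.rng().normal(0.0, noise.sigma_abs, size=clean.shape)
    return SpectrumSeries(
        wavelengths=basis.wavelengths, times=t, spectra=spectra, time_unit="min"
    )


def default_titration_potentials(
    E0: float, span: float = 0.12, n: int = 9, plateau: float = 0.35
) -> np.ndarray:
    """n potentials across E0 +/- span plus two plateau potentials.

    The extreme potentials drive the sample to full reduction/oxidation so
    that the titration minima/maxima used by the two-wavelength progress
    analysis are true conversion limits (the analog of recording fully
    reduced and fully oxidized reference spectra).
    """
    return np.concatenate((
        [E0 - plateau], np.linspace(E0 - span, E0 + span, n), [E0 + plateau]
    ))


def fraction_reduced(E: np.ndarray, E0: float, n_electrons: int = 1,
                     temperature_C: float = 25.0) -> np.ndarray:
    """Nernstian fraction reduced: 1 / (1 + 10^((E - E0) n / s))."""
    s = nernst_slope(temperature_C)
    return 1.0 / (1.0 + 10.0 ** ((np.asarray(E, float) - E0) * n_electrons / s))


def gen_redox_titration(
    E0: float,
    n_electrons: int,
    potentials,
    basis: BasisSet,
    noise: NoiseSpec = NOISELESS,
    reference: str = "SHE",
    temperature_C: float = 25.0,
    concentration: float = 1.0,
) -> RedoxTitration:
    """Spectroelectrochemical titration through the 3-state spectral model.

    ``E0`` and ``potentials`` are in the named reference.  Spectra are
    f-weighted mixes of the reduced (deoxy) and oxidized (met) basis with
    the one-(or n-)electron Nernstian fraction reduced.
    """
    E = np.asarray(list(potentials), dtype=float)
    if E.size < 2:
        raise ValueError("need at least 2 potentials")
    f = fraction_reduced(E, E0, n_electrons, temperature_C)
    red = basis.column("deoxy")
    ox = basis.column("met")
    clean = concentration * (np.outer(red, f) + np.outer(ox, 1.0 - f))
    spectra = clean + noise.rng().normal(0.0, noise.sigma_abs, size=clean.shape)
    return RedoxTitration(
        potentials=E, reference=reference, wavelengths=basis.wavelengths,
        spectra=spectra, temperature_C=temperature_C,
    )


def gen_swv(
    E_peak: float,
    width: float = 0.04,
    baseline_slope: float = 0.0,
    baseline_offset: float = 0.0,
    potentials: np.ndarray | None = None,
    amplitude: float = 1.0,
    noise: NoiseSpec = NOISELESS,
    reference: str = "SCE",
) -> Voltammogram:
    """Gaussian net-current peak on a linear baseline."""
    if width <= 0:
        raise ValueError("peak width must be positive")
    if potentials is None:
        # 2 mV steps, a typical square-wave step potential
        potentials = np.linspace(E_peak - 0.25, E_peak + 0.25, 251)
    E = np.asarray(potentials, dtype=float)
    current = (
        amplitude * np.exp(-0.5 * ((E - E_peak) / width) ** 2)
        + baseline_offset + baseline_slope * E
    )
    current = current + noise.rng().normal(0.0, noise.sigma_abs, size=E.size)
    return Voltammogram(potential=E, net_current=current, reference=reference)


# ---------------------------------------------------------------------------
# FTIR maps

#: Band name -> (center cm^-1, gaussian width cm^-1).
FTIR_BAND_TABLE: dict[str, tuple[float, float]] = {
    "ch2": (2925.0, 18.0),
    "ch3": (2958.0, 14.0),
    "carbonyl": (1739.0, 12.0),
    "amide_i": (1654.0, 14.0),
    "amide_ii": (1545.0, 16.0),
    "beta_sheet": (1627.0, 9.0),
}

#: Region -> band -> weight; inclusions carry more carbonyl (lipid
#: oxidation) and a beta-sheet component.
DEFAULT_COMPOSITION: dict[str, dict[str, float]] = {
    "inclusion": {"ch2": 0.50, "carbonyl": 0.30, "amide_i": 0.60,
                  "amide_ii": 0.30, "beta_sheet": 0.25},
    "surround": {"ch2": 0.60, "carbonyl": 0.06, "amide_i": 1.00,
                 "amide_ii": 0.50},
    "background": {},
}


def gen_ftir_map(
    shape: tuple[int, int] = (8, 8),
    region_labels: np.ndarray | None = None,
    composition: dict[str, dict[str, float]] | None = None,
    band_table: dict[str, tuple[float, float]] | None = None,
    noise: NoiseSpec = NOISELESS,
    pixel_um: float = 10.0,
    wavenumbers: np.ndarray | None = None,
):
    """Grid of sum-of-Gaussian-band spectra with per-region composition.

    With no explicit labels, the central square quarter of the grid is the
    inclusion and the rest surround.  Unknown band names are rejected.
    """
    from .ftir import FtirMap, default_wavenumbers

    nx, ny = shape
    wn = default_wavenumbers() if wavenumbers is None else np.asarray(wavenumbers, float)
    table = FTIR_BAND_TABLE if band_table is None else band_table
    comp = DEFAULT_COMPOSITION if composition is None else composition
    for region, weights in comp.items():
        for band in weights:
            if band not in table:
                raise ValueError(f"unknown band name {band!r} in region {region!r}")
    if region_labels is None:
        region_labels = np.full((nx, ny), "surround", dtype=object)
        cx0, cx1 = nx // 4, max(nx // 4 + nx // 2, nx // 4 + 1)
        cy0, cy1 = ny // 4, max(ny // 4 + ny // 2, ny // 4 + 1)
        region_labels[cx0:cx1, cy0:cy1] = "inclusion"
    labels = np.asarray(region_labels, dtype=object).reshape(nx, ny)

    profiles = {}
    for region, weights in comp.items():
        spec = np.zeros_like(wn)
        for band, weight in weights.items():
            center, width = table[band]
            spec += weight * np.exp(-0.5 * ((wn - center) / width) ** 2)
        profiles[region] = spec

    rng = noise.rng()
    coords, regions, spectra = [], [], []
    for ix in range(nx):
        for iy in range(ny):
            region = labels[ix, iy]
            if region not in profiles:
                raise ValueError(f"region {region!r} has no composition")
            spec = profiles[region] + rng.normal(0.0, noise.sigma_abs, size=wn.size)
            coords.append((ix * pixel_um, iy * pixel_um))
            regions.append(region)
            spectra.append(spec)
    return FtirMap(
        wavenumber=wn, coords=np.array(coords, dtype=float),
        regions=np.array(regions, dtype=object), absorbance=np.array(spectra),
    )


# ---------------------------------------------------------------------------
# Expression matrices

def gen_expression_matrix(
    n_promoters: int,
    n_samples: int,
    group_labels,
    enriched_ids,
    fold: float,
    seed: int = 0,
    target_group: str = "skeletal_muscle",
    log_mean: float = 0.5,
    log_sigma: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal expression with a planted enriched gene set.

    ``enriched_ids`` promoters are multiplied by ``fold`` in samples whose
    group is ``target_group`` only.  Returns (matrix, groups).
    """
    labels = list(group_labels)
    if len(labels) != n_samples:
        raise ValueError("group_labels must have one entry per sample")
    promoters = [f"g{i:05d}" for i in range(n_promoters)]
    enriched = set(enriched_ids)
    if not enriched.issubset(promoters):
        raise ValueError("enriched_ids must be a subset of the promoter ids")
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=log_mean, sigma=log_sigma,
                           size=(n_promoters, n_samples))
    samples = [f"s{j:03d}" for j in range(n_samples)]
    matrix = pd.DataFrame(values, index=promoters, columns=samples)
    groups = pd.Series(labels, index=samples)
    target_cols = [s for s, g in zip(samples, labels) if g == target_group]
    for pid in sorted(enriched):
        matrix.loc[pid, target_cols] *= fold
    return matrix, groups


# ---------------------------------------------------------------------------
# Pedigree genotypes

def gen_pedigree_genotypes(
    pedigree: Pedigree,
    marker_freqs,
    theta_true: float,
    model: DiseaseModel,
    seed: int = 0,
    carrier_founders: tuple[str, ...] | None = None,
) -> Pedigree:
    """Simulate marker genotypes and affection through the pedigree.

    Founder haplotypes are drawn at Hardy-Weinberg / linkage equilibrium,
    except for ``carrier_founders`` (default: the first founder) who are
    forced heterozygous for the disease allele so the simulated family
    segregates disease.  Transmissions recombine at ``theta_true``;
    affection status is drawn from the penetrance vector.
    """
    freqs = np.asarray(marker_freqs, dtype=float)
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError("marker allele frequencies must sum to 1")
    if not (0.0 <= theta_true <= 0.5):
        raise ValueError("theta_true must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    if carrier_founders is None:
        carrier_founders = (pedigree.founders[0].id,)

    k = freqs.size
    q = model.disease_allele_freq
    haplos: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}

    def draw_founder(iid: str):
        m1, m2 = rng.choice(k, size=2, p=freqs)
        if iid in carrier_founders:
            d1, d2 = 1, 0
        else:
            d1 = int(rng.random() < q)
            d2 = int(rng.random() < q)
        return ((d1, int(m1)), (d2, int(m2)))

    def gamete(parent_haplos):
        (d1, m1), (d2, m2) = parent_haplos
        first = rng.random() < 0.5
        recomb = rng.random() < theta_true
        if first:
            return (d1, m2) if recomb else (d1, m1)
        return (d2, m1) if recomb else (d2, m2)

    genotypes: dict[str, tuple[int, int]] = {}
    affection: dict[str, int] = {}
    for m in pedigree.members:
        if m.is_founder:
            haplos[m.id] = draw_founder(m.id)
        else:
            haplos[m.id] = (gamete(haplos[m.father]), gamete(haplos[m.mother]))
        (d1, m1), (d2, m2) = haplos[m.id]
        genotypes[m.id] = (m1 + 1, m2 + 1)
        dosage = d1 + d2
        affection[m.id] = AFFECTED if rng.random() < model.penetrances[dosage] else UNAFFECTED
    return pedigree.with_genotypes(genotypes).with_affection(affection)


def spawn_noise(base: NoiseSpec, *key: int) -> NoiseSpec:
    """Derive an independent child noise spec deterministically from a key."""
    child_seed = int(np.random.SeedSequence(base.seed, spawn_key=key).generate_state(1)[0])
    return replace(base, seed=child_seed)
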