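"""End-to-end characterization runs.

``run`` executes the requested stages for each configured variant on
synthetic data generated at that variant's ground-truth parameters and
assembles a two-variant comparison table (K_D, hemin-loss rates at two pH
values, E deg' by both routes, autoxidation rate, heme SASA), each cell with
its uncertainty and provenance.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .electrochem import fit_titration, swv_peak
from .kinetics import fit_autoxidation, fit_binding_panel, fit_hemin_loss
from .spectra import BasisSet
from .structure import heme_sasa, parse_structure
from .synthetic_data import (
    NoiseSpec,
    default_titration_potentials,
    gen_autoxidation_series,
    gen_binding_traces,
    gen_hemin_loss_trace,
    gen_redox_titration,
    gen_swv,
    spawn_noise,
)

STAGES = ("binding", "heminloss", "heminloss_ph5", "autox", "ottle", "swv", "sasa")

_COLUMNS = [
    ("K_D_uM", "K_D (uM)"),
    ("k_minus_H_ph7", "k-H pH7 (1/h)"),
    ("k_minus_H_ph5", "k-H pH5 (1/h)"),
    ("E0_spectro_V", "E0' spectro (V vs SHE)"),
    ("E0_swv_V", "E0' SWV (V vs SHE)"),
    ("k_ox", "k_ox (1/min)"),
    ("heme_sasa_nm2", "Heme SASA (nm2)"),
]


@dataclass
class VariantRow:
    name: str
    values: dict[str, float] = field(default_factory=dict)
    errors: dict[str, float] = field(default_factory=dict)


@dataclass
class CharacterizationReport:
    rows: list[VariantRow]
    seed: int
    stages: tuple[str, ...]
    version: str = __version__

    def to_csv(self) -> str:
        header = "variant," + ",".join(label for _, label in _COLUMNS)
        lines = [header]
        for row in self.rows:
            cells = [row.name]
            for key, _ in _COLUMNS:
                v = row.values.get(key)
                cells.append("" if v is None else f"{v:.6g}")
            lines.append(",".join(cells))
        return "\n".join(lines) + "\n"

    def to_markdown(self) -> str:
        lines = [
            f"# Characterization report (seed={self.seed}, "
            f"stages={'+'.join(self.stages)}, v{self.version})",
            "",
            "| variant | " + " | ".join(label for _, label in _COLUMNS) + " |",
            "|" + "---|" * (len(_COLUMNS) + 1),
        ]
        for row in self.rows:
            cells = [row.name]
            for key, _ in _COLUMNS:
                v = row.values.get(key)
                if v is None:
                    cells.append("")
                else:
                    se = row.errors.get(key)
                    cells.append(f"{v:.4g}" + (f" +/- {se:.2g}" if se is not None else ""))
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"


class StageError(RuntimeError):
    pass


def _require(params: dict, keys: list[str], stage: str, variant: str) -> None:
    missing = [k for k in keys if k not in params]
    if missing:
        raise StageError(
            f"stage {stage!r} for variant {variant!r} is missing inputs: {missing}"
        )


def run(config: dict) -> CharacterizationReport:
    """Run the configured stages; see STAGES for valid names.

    Config schema::

        seed: int
        noise_sigma: float          # default 0.002
        stages: [binding, ...]
        variants:
          WT:
            k_on: 1.16e7            # binding
            K_D_uM: 1.2             #   (or k_off directly)
            k_minus_H: 0.22         # heminloss
            k_minus_H_ph5: 1.44     # heminloss_ph5
            k_ox: 1.96              # autox
            E0_spectro: 0.040       # ottle (V vs SHE)
            E0_swv: -0.056          # swv   (V vs SHE)
            pdb: path/to/file.pdb   # sasa
    """
    stages = tuple(config.get("stages", ()))
    if not stages:
        raise StageError("config requests no stages")
    for s in stages:
        if s not in STAGES:
            raise StageError(f"unknown stage {s!r}; valid: {STAGES}")
    variants = config.get("variants") or {}
    if not variants:
        raise StageError("config defines no variants")
    seed = int(config.get("seed", 0))
    sigma = float(config.get("noise_sigma", 0.002))
    basis = BasisSet.default()

    rows = []
    for vi, (name, params) in enumerate(variants.items()):
        row = VariantRow(name=name)
        for si, stage in enumerate(stages):
            noise = spawn_noise(NoiseSpec(sigma_abs=sigma, seed=seed), vi, si)
            if stage == "binding":
                _require(params, ["k_on"], stage, name)
                k_on = float(params["k_on"])
                if "k_off" in params:
                    k_off = float(params["k_off"])
                else:
                    _require(params, ["K_D_uM"], stage, name)
                    k_off = float(params["K_D_uM"]) * 1e-6 * k_on
                traces = gen_binding_traces(k_on, k_off, noise=noise)
                fit = fit_binding_panel(traces)
                row.values["K_D_uM"] = fit.K_D * 1e6
                row.errors["K_D_uM"] = fit.K_D_se * 1e6
            elif stage in ("heminloss", "heminloss_ph5"):
                key = "k_minus_H" if stage == "heminloss" else "k_minus_H_ph5"
                _require(params, [key], stage, name)
                trace = gen_hemin_loss_trace(float(params[key]), noise=noise)
                fit = fit_hemin_loss(trace)
                col = "k_minus_H_ph7" if stage == "heminloss" else "k_minus_H_ph5"
                row.values[col] = fit.rate
                row.errors[col] = fit.rate_se
            elif stage == "autox":
                _require(params, ["k_ox"], stage, name)
                k_ox = float(params["k_ox"])
                t = np.linspace(0.0, 3.0 * np.log(2.0) / k_ox, 12)
                series = gen_autoxidation_series(k_ox, t, basis, noise=noise)
                fit = fit_autoxidation(series, basis)
                row.values["k_ox"] = fit.rate
                row.errors["k_ox"] = fit.rate_se
            elif stage == "ottle":
                _require(params, ["E0_spectro"], stage, name)
                e0 = float(params["E0_spectro"])
                potentials = default_titration_potentials(e0)
                titr = gen_redox_titration(e0, 1, potentials, basis, noise=noise)
                fit = fit_titration(titr)
                row.values["E0_spectro_V"] = fit.E0
            elif stage == "swv":
                _require(params, ["E0_swv"], stage, name)
                e0_she = float(params["E0_swv"])
                from .electrochem import convert_reference

                e_sce = convert_reference(e0_she, "SHE", "SCE")
                vgram = gen_swv(e_sce, baseline_slope=0.3, baseline_offset=0.2,
                                noise=noise, reference="SCE")
                peak = swv_peak(vgram)
                row.values["E0_swv_V"] = peak.E_peak_she
            elif stage == "sasa":
                _require(params, ["pdb"], stage, name)
                with open(params["pdb"]) as fh:
                    struct = parse_structure(fh.read())
                row.values["heme_sasa_nm2"] = heme_sasa(struct)
        rows.append(row)
    return CharacterizationReport(rows=rows, seed=seed, stages=stages)
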