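"""Schedule-faithful synthetic datasets for the exosome loop-exchange study.

The presets reproduce the published acquisition grids (67 CEST offsets from
-2450 to +2450 Hz referenced at +/-10000 Hz, t_CEST = 0.4 s, B1 of 10-25 Hz;
constant-time CPMG with T_CPMG of 2-20 ms and nu_CPMG up to 5000 Hz; the 12
EXSY mixing delays from 1 to 600 ms; the printed inversion-recovery delay
lists) and carry the published dynamics values as generating truths:
p_E = 5% / k_ex = 5800 s^-1 for the nine-subunit core (Exo9, fast exchange),
p_E = 26% / k_ex = 35 s^-1 with the catalytic subunit bound (Exo10, slow
exchange), 100% open with RNA bound, order parameters ~0.1 (open) / ~0.7
(closed), tau_R = 100 ns (Exo9) / 140 ns (Exo10), tau_s = 100 ns.

Values the study does not print — the ground/excited 19F shift separation,
intrinsic R1/R2, spectrum scales and signal-to-noise ratios — are package
placeholders; each preset marks them as such in ``provenance`` so no
synthetic number masquerades as a published one.  The placeholder shift
separation is 2 ppm at 471 MHz (940 Hz).

Noise is homoscedastic per experiment, Gaussian with sigma =
signal_scale / SNR.  CPMG noise is injected on the decayed intensities
I/I0 = exp(-R2eff * T_CPMG) and propagated back to R2,eff, which makes the
R2,eff uncertainties heteroscedastic in the physically correct way.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .datasets import Dataset, DatasetCollection
from .exchange import (CESTSchedule, CPMGSchedule, EXSYSchedule, IRSchedule,
                       SpectrumGrid)
from .fitting import Parameter, ParameterGraph, _predict, _resolve
from .pre import PREPhysicsParams, gamma1_sb, gamma2_sb

__all__ = ["StudyPreset", "generate_dataset", "preset_exo9_apo",
           "preset_exo10_apo", "preset_plus_rna", "replica_study",
           "merge_presets",
           "cest_schedule", "cpmg_schedule", "exsy_schedule", "ir_schedule"]

#: placeholder ground/excited shift positions, Hz at 471 MHz (2 ppm apart)
OMEGA_G_HZ = 0.0
OMEGA_E_HZ = 940.0

#: printed EXSY mixing delays, s
EXSY_DELAYS = np.array([1, 2, 5, 10, 25, 50, 75, 100, 150, 200, 400, 600]) / 1e3

#: printed inversion-recovery delay list (apo samples), s
IR_DELAYS_APO = np.array([0.001, 0.05, 0.05, 0.1, 0.25, 0.5, 0.8, 1.5, 3, 5, 5, 8])
#: printed inversion-recovery delay list (RNA-bound samples), s
IR_DELAYS_RNA = np.array([0.001, 0.05, 0.1, 0.25, 0.5, 0.8, 1.5, 3, 5])

DEFAULT_SNR = {"CEST": 200.0, "CPMG": 200.0, "EXSY": 50.0, "IR": 100.0,
               "SPECTRUM": 50.0}


def cest_schedule(B1: float, t_CEST: float = 0.4, n_offsets: int = 67,
                  span: float = 2450.0) -> CESTSchedule:
    return CESTSchedule(B1=B1, t_CEST=t_CEST,
                        offsets=np.linspace(-span, span, n_offsets),
                        reference_offsets=np.array([-10000.0, 10000.0]))


def cpmg_schedule(T_CPMG: float = 0.01, nu_max: float = 5000.0,
                  n_freq: int = 20, spectrometer_freq: float = 471.0) -> CPMGSchedule:
    """nu grid of multiples of 1/T_CPMG up to nu_max (integer cycle counts)."""
    base = 1.0 / T_CPMG
    n_max = int(nu_max / base)
    cycles = np.unique(np.round(np.linspace(1, n_max, n_freq)).astype(int))
    return CPMGSchedule(T_CPMG=T_CPMG, nu_CPMG=cycles * base,
                        spectrometer_freq=spectrometer_freq)


def exsy_schedule(scale: float = 1.0) -> EXSYSchedule:
    return EXSYSchedule(mixing_times=EXSY_DELAYS, scale=scale)


def ir_schedule(rna: bool = False, I_inf: float = 1.0) -> IRSchedule:
    delays = IR_DELAYS_RNA if rna else np.unique(IR_DELAYS_APO)
    return IRSchedule(delays=delays, I_inf=I_inf)


def spectrum_grid(n: int = 301, span: float = 2450.0) -> SpectrumGrid:
    return SpectrumGrid(offsets=np.linspace(-span, span, n))


@dataclass
class StudyPreset:
    """One synthetic study: generating truths, parameter graph, experiments.

    ``experiments`` is a list of (name, kind, schedule, tags, param_map)
    tuples; ``truth`` maps every graph parameter to its generating value;
    ``provenance`` marks each truth as 'published' or 'placeholder';
    ``snr`` gives the per-experiment-kind signal-to-noise ratio;
    ``tolerance`` is the preset's documented recovery envelope, used by the
    round-trip checks.
    """

    name: str
    truth: dict
    parameters: list
    experiments: list
    provenance: dict = dc_field(default_factory=dict)
    snr: dict = dc_field(default_factory=lambda: dict(DEFAULT_SNR))
    seed: int = 0
    tolerance: dict = dc_field(default_factory=dict)

    def graph(self) -> ParameterGraph:
        """Fresh parameter graph initialized at the generating truths."""
        return ParameterGraph([Parameter(**{**p.__dict__}) for p in self.parameters])

    def validate(self) -> None:
        for pname in (p.name for p in self.parameters):
            if pname not in self.truth:
                raise ValueError(f"preset {self.name}: no truth for {pname}")


def _param(name, value, transform="linear", vary=True, lo=0.0, hi=1.0):
    return Parameter(name=name, value=value, vary=vary, transform=transform,
                     lo=lo, hi=hi)


def preset_exo9_apo(seed: int = 0) -> StudyPreset:
    """Fast-exchange study: CEST at two B1 fields + dispersion at two fields.

    Exchange is fast on the shift timescale in the sense that the exchange
    lifetime 1/k_ex (~0.17 ms) is far below a millisecond and k_ex (s^-1)
    far exceeds the shift separation expressed in Hz; validated at
    construction.
    """
    truth = {
        "pE_exo9": 0.05, "kex_exo9": 5800.0,
        "omega_G": OMEGA_G_HZ, "omega_E": OMEGA_E_HZ,
        "R1_exo9": 1.0, "R2_exo9": 120.0,
        "R2inf_471": 105.0, "R2inf_565": 110.0,
    }
    if not (1.0 / truth["kex_exo9"] < 1e-3 and truth["kex_exo9"]
            > abs(truth["omega_E"] - truth["omega_G"])):
        raise ValueError("Exo9 preset must be in the fast-exchange regime")
    parameters = [
        _param("pE_exo9", truth["pE_exo9"], "logit"),
        _param("kex_exo9", truth["kex_exo9"], "log"),
        _param("omega_G", truth["omega_G"]),
        _param("omega_E", truth["omega_E"]),
        _param("R1_exo9", truth["R1_exo9"], "log"),
        _param("R2_exo9", truth["R2_exo9"], "log"),
        _param("R2inf_471", truth["R2inf_471"], "log"),
        _param("R2inf_565", truth["R2inf_565"], "log"),
    ]
    cest_map = {"p_E": "pE_exo9", "k_ex": "kex_exo9", "omega_G": "omega_G",
                "omega_E": "omega_E", "R1_G": "R1_exo9", "R1_E": "R1_exo9",
                "R2_G": "R2_exo9", "R2_E": "R2_exo9"}
    rd_map = {"p_E": "pE_exo9", "k_ex": "kex_exo9", "omega_G": "omega_G",
              "omega_E": "omega_E"}
    tags = {"complex": "Exo9", "rna": "apo"}
    experiments = [
        ("cest_exo9_b10", "CEST", cest_schedule(10.0), {**tags, "B1": 10.0},
         cest_map),
        ("cest_exo9_b25", "CEST", cest_schedule(25.0), {**tags, "B1": 25.0},
         cest_map),
        ("cpmg_exo9_471", "CPMG", cpmg_schedule(spectrometer_freq=471.0),
         {**tags, "field": 471.0}, {**rd_map, "R2_inf": "R2inf_471"}),
        ("cpmg_exo9_565", "CPMG", cpmg_schedule(spectrometer_freq=565.0),
         {**tags, "field": 565.0}, {**rd_map, "R2_inf": "R2inf_565"}),
    ]
    provenance = {"pE_exo9": "published", "kex_exo9": "published",
                  **{k: "placeholder" for k in
                     ("omega_G", "omega_E", "R1_exo9", "R2_exo9", "R2inf_471",
                      "R2inf_565")}}
    return StudyPreset(name="exo9_apo", truth=truth, parameters=parameters,
                       experiments=experiments, provenance=provenance,
                       seed=seed,
                       tolerance={"pE_exo9": 0.01, "kex_exo9_rel": 0.25})


def preset_exo10_apo(seed: int = 0) -> StudyPreset:
    """Slow-exchange study: CEST (two B1), EXSY, inversion recovery, 1D
    spectrum.  Two resolved resonances, cross-peak build-up on the tens of
    milliseconds scale."""
    truth = {
        "pE_exo10": 0.26, "kex_exo10": 35.0,
        "omega_G": OMEGA_G_HZ, "omega_E": OMEGA_E_HZ,
        "R1_exo10": 0.8, "R2_exo10": 120.0, "S_exsy": 1.0, "S_ir": 1.0, "S_spec": 1.0,
    }
    parameters = [
        _param("pE_exo10", truth["pE_exo10"], "logit"),
        _param("kex_exo10", truth["kex_exo10"], "log"),
        _param("omega_G", truth["omega_G"]),
        _param("omega_E", truth["omega_E"]),
        _param("R1_exo10", truth["R1_exo10"], "log"),
        _param("R2_exo10", truth["R2_exo10"], "log"),
        _param("S_exsy", truth["S_exsy"], "log"),
        _param("S_ir", truth["S_ir"], "log"),
        _param("S_spec", truth["S_spec"], "log"),
    ]
    cest_map = {"p_E": "pE_exo10", "k_ex": "kex_exo10", "omega_G": "omega_G",
                "omega_E": "omega_E", "R1_G": "R1_exo10", "R1_E": "R1_exo10",
                "R2_G": "R2_exo10", "R2_E": "R2_exo10"}
    tags = {"complex": "Exo10", "rna": "apo"}
    experiments = [
        ("cest_exo10_b10", "CEST", cest_schedule(10.0), {**tags, "B1": 10.0},
         cest_map),
        ("cest_exo10_b25", "CEST", cest_schedule(25.0), {**tags, "B1": 25.0},
         cest_map),
        ("exsy_exo10", "EXSY", exsy_schedule(), tags,
         {"p_E": "pE_exo10", "k_ex": "kex_exo10", "R1_G": "R1_exo10",
          "R1_E": "R1_exo10", "scale": "S_exsy"}),
        ("ir_exo10", "IR", ir_schedule(), tags,
         {"p_E": "pE_exo10", "k_ex": "kex_exo10", "R1_G": "R1_exo10",
          "R1_E": "R1_exo10", "scale": "S_ir"}),
        ("spectrum_exo10", "SPECTRUM", spectrum_grid(), tags,
         {"p_E": "pE_exo10", "k_ex": "kex_exo10", "omega_G": "omega_G",
          "omega_E": "omega_E", "R2_G": "R2_exo10", "R2_E": "R2_exo10",
          "scale": "S_spec"}),
    ]
    provenance = {"pE_exo10": "published", "kex_exo10": "published",
                  **{k: "placeholder" for k in
                     ("omega_G", "omega_E", "R1_exo10", "R2_exo10", "S_exsy",
                      "S_ir", "S_spec")}}
    return StudyPreset(name="exo10_apo", truth=truth, parameters=parameters,
                       experiments=experiments, provenance=provenance,
                       seed=seed,
                       tolerance={"pE_exo10": 0.02, "kex_exo10_factor": 2.0})


# published motional truths for the loop probe geometry
S2_OPEN, S2_CLOSED = 0.1, 0.7
TAU_R = {"Exo9": 100e-9, "Exo10": 140e-9}
TAU_S = 100e-9
TAU_I_PLACEHOLDER = 2e-9
#: placeholder spin-label--nucleus distances, Angstrom (closed state on the
#: published 6.8 A scale; open state remote)
R_CLOSED, R_OPEN = 6.8, 12.0


def pre_params(state: str, complex_: str = "Exo10") -> PREPhysicsParams:
    """Published-scale motional parameters for the open/closed loop states."""
    if state == "open":
        return PREPhysicsParams(r=R_OPEN, S2=S2_OPEN, tau_i=TAU_I_PLACEHOLDER,
                                tau_R=TAU_R[complex_], tau_s=TAU_S)
    return PREPhysicsParams(r=R_CLOSED, S2=S2_CLOSED, tau_i=TAU_I_PLACEHOLDER,
                            tau_R=TAU_R[complex_], tau_s=TAU_S)


def preset_plus_rna(complex_: str = "Exo10", seed: int = 0) -> StudyPreset:
    """RNA-bound study: the loop is 100% open; paramagnetic/diamagnetic
    inversion-recovery and 1D spectrum pairs carry the open-state PREs."""
    open_p = pre_params("open", complex_)
    truth = {
        "pE_rna": 0.0, "kex_rna": 0.0,
        "omega_G": OMEGA_G_HZ, "omega_E": OMEGA_E_HZ,
        "R1_rna": 0.8, "R2_rna": 120.0, "S_ir_rna": 1.0, "S_spec_rna": 1.0,
        "Gamma1_open": gamma1_sb(open_p), "Gamma2_open": gamma2_sb(open_p),
    }
    parameters = [
        _param("pE_rna", 0.0, vary=False),
        _param("kex_rna", 0.0, vary=False),
        _param("omega_G", truth["omega_G"]),
        _param("omega_E", truth["omega_E"], vary=False),
        _param("R1_rna", truth["R1_rna"], "log"),
        _param("R2_rna", truth["R2_rna"], "log"),
        _param("S_ir_rna", truth["S_ir_rna"], "log"),
        _param("S_spec_rna", truth["S_spec_rna"], "log"),
        _param("Gamma1_open", truth["Gamma1_open"], "log"),
        _param("Gamma2_open", truth["Gamma2_open"], "log"),
    ]
    tags = {"complex": complex_, "rna": "plusRNA"}
    ir_map = {"p_E": "pE_rna", "k_ex": "kex_rna", "R1_G": "R1_rna",
              "R1_E": "R1_rna", "scale": "S_ir_rna"}
    spec_map = {"p_E": "pE_rna", "k_ex": "kex_rna", "omega_G": "omega_G",
                "omega_E": "omega_E", "R2_G": "R2_rna", "R2_E": "R2_rna",
                "scale": "S_spec_rna"}
    experiments = [
        ("ir_rna_dia", "IR", ir_schedule(rna=True),
         {**tags, "pre_state": "dia"}, ir_map),
        ("ir_rna_para", "IR", ir_schedule(rna=True),
         {**tags, "pre_state": "para"},
         {**ir_map, "Gamma1_G": "Gamma1_open", "Gamma1_E": "Gamma1_open"}),
        ("spectrum_rna_dia", "SPECTRUM", spectrum_grid(),
         {**tags, "pre_state": "dia"}, spec_map),
        ("spectrum_rna_para", "SPECTRUM", spectrum_grid(),
         {**tags, "pre_state": "para"},
         {**spec_map, "Gamma2_G": "Gamma2_open", "Gamma2_E": "Gamma2_open"}),
    ]
    provenance = {"pE_rna": "published",
                  **{k: "placeholder" for k in truth if k != "pE_rna"}}
    return StudyPreset(name=f"plus_rna_{complex_.lower()}", truth=truth,
                       parameters=parameters, experiments=experiments,
                       provenance=provenance, seed=seed,
                       tolerance={"Gamma1_open_rel": 0.15,
                                  "Gamma2_open_rel": 0.15})


def replica_study() -> list[StudyPreset]:
    """The three sample conditions of the full study.

    Shared-parameter rules across the presets (probe shifts shared across
    complexes and RNA states; per-complex populations and rates; RNA-bound
    forced 100% open) are encoded in each preset's param_map names.
    """
    return [preset_exo9_apo(), preset_exo10_apo(), preset_plus_rna()]


def merge_presets(presets: list[StudyPreset], seed: int = 0):
    """Combine presets into one global study.

    Returns (DatasetCollection, ParameterGraph, truth).  Parameters that
    appear in several presets under the same name (the shared probe shifts)
    are merged after checking that their definitions agree; everything else
    stays per-condition, reproducing the study's sharing assumptions.
    """
    graph = ParameterGraph()
    truth: dict = {}
    data = DatasetCollection()
    for k, preset in enumerate(presets):
        for p in preset.parameters:
            if p.name in graph:
                if (graph[p.name].value != p.value
                        or graph[p.name].transform != p.transform):
                    raise ValueError(f"conflicting definitions for shared "
                                     f"parameter {p.name!r}")
                continue
            graph.add(Parameter(**{**p.__dict__}))
        for name, val in preset.truth.items():
            if name in truth and truth[name] != val:
                raise ValueError(f"conflicting truths for {name!r}")
            truth[name] = val
        for ds in generate_dataset(preset, seed=seed + k):
            data.add(ds)
    data.truth = truth
    return data, graph, truth


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_dataset(preset: StudyPreset, seed: int | None = None,
                     noiseless: bool = False) -> DatasetCollection:
    """Generate one noisy realization of a preset's experiments.

    Calls the forward models at the preset's truth values and adds Gaussian
    noise with sigma = signal_scale / SNR (none if ``noiseless``).
    Deterministic per seed; the truth values are recorded on the returned
    collection.
    """
    preset.validate()
    rng = np.random.default_rng(preset.seed if seed is None else seed)
    out = DatasetCollection(truth=dict(preset.truth))
    for name, kind, schedule, tags, param_map in preset.experiments:
        ds = Dataset(name=name, kind=kind, schedule=schedule, tags=tags,
                     param_map=param_map,
                     y=np.zeros(_n_points(kind, schedule)),
                     sigma=np.ones(_n_points(kind, schedule)))
        clean = _predict(ds, _resolve(ds, preset.truth))
        snr = preset.snr[kind]
        if kind == "CPMG":
            # noise lives on intensities I/I0 = exp(-R2eff * T)
            T = schedule.T_CPMG
            I = np.exp(-clean * T)
            sigma_I = 1.0 / snr
            if noiseless:
                y = clean
            else:
                I_noisy = np.clip(I + rng.normal(0.0, sigma_I, I.size),
                                  1e-8, None)
                y = -np.log(I_noisy) / T
            sigma = sigma_I / (I * T)
        else:
            scale = float(np.max(np.abs(clean)))
            sigma = np.full(clean.size, scale / snr)
            y = clean if noiseless else clean + rng.normal(0.0, sigma)
        ds.y = np.asarray(y, dtype=float)
        ds.sigma = np.asarray(sigma, dtype=float)
        out.add(ds)
    return out


def _n_points(kind: str, schedule) -> int:
    if kind == "CEST":
        return schedule.offsets.size
    if kind == "CPMG":
        return schedule.nu_CPMG.size
    if kind == "EXSY":
        return 4 * schedule.mixing_times.size
    if kind == "IR":
        return schedule.delays.size
    return schedule.offsets.size
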