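"""Seeded generators for synthetic DSC experiments.

Provides the parameter sets of the six case-study proteins (chicken egg
lysozyme, the SpA double mutant, and the haloalkane dehalogenases DbjA,
LinB, DhaA and the stabilized mutant DhaA115) as ready-made models, the
simulated alternative-refolding scenario (a one-step irreversible
unfolding whose reheat follows the same kinetics but with a reduced
enthalpy, mimicking refolding into a non-native conformation), and
generic first+reheat experiment generators.  Every generator is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .io import Experiment, ExperimentSet, Thermogram
from .models import (
    Baseline,
    UnfoldingModel,
    equilibrium_step,
    heat_cool_reheat,
    irreversible_step,
    make_model,
    simulate_thermogram,
    single_scan,
    two_rate_step,
)

__all__ = [
    "PROTEIN_PRESETS",
    "protein_preset",
    "make_refolding_case",
    "add_noise",
    "make_reheat_experiments",
    "REFOLDING_DEFAULTS",
]

C_TO_K = 273.15

# Case-study parameter sets from global fits of the six proteins (SI units;
# enthalpies referenced at each step's own Tm/Tf; a combined dCp is carried
# on the first step of two-step chains).
_PRESET_SPECS: dict[str, dict] = {
    "lysozyme": dict(
        scheme="C",
        steps=lambda: (
            equilibrium_step(Tm=345.03, dH=516e3, dCp=7.5e3),
            irreversible_step(E=18e3, Tf=3200.0, dH=-37e3),
        ),
    ),
    "SpA": dict(
        scheme="A",
        steps=lambda: (
            equilibrium_step(Tm=328.44, dH=102.4e3, dCp=1.38e3, dH_vh=169e3),
        ),
    ),
    "DbjA": dict(
        scheme="B",
        steps=lambda: (
            irreversible_step(E=418e3, Tf=337.6, dH=337e3, dCp=5.4e3),
        ),
    ),
    "LinB": dict(
        scheme="B",
        steps=lambda: (
            irreversible_step(E=294e3, Tf=338.6, dH=397e3, dCp=8.0e3),
        ),
    ),
    "DhaA": dict(
        scheme="C",
        steps=lambda: (
            equilibrium_step(Tm=323.8, dH=338e3, dCp=10.2e3),
            irreversible_step(E=75e3, Tf=436.0, dH=1126e3),
        ),
    ),
    "DhaA115": dict(
        scheme="D",
        steps=lambda: (
            two_rate_step(E_fwd=436.5e3, Tf_fwd=358.0, E_rev=46.7e3,
                          Tf_rev=689.4, dH=596e3, dCp=6.1e3),
            irreversible_step(E=109.1e3, Tf=431.6, dH=-566e3),
        ),
    ),
}

PROTEIN_PRESETS = tuple(_PRESET_SPECS)


def protein_preset(protein: str, baseline: Baseline | None = None) -> UnfoldingModel:
    """Model with the fitted parameter set of a case-study protein.

    ``protein`` is one of ``lysozyme, SpA, DbjA, LinB, DhaA, DhaA115``.
    Enthalpies are the values at each step's reference temperature
    (Tm or Tf); SpA carries an independent van't Hoff enthalpy.
    """
    try:
        spec = _PRESET_SPECS[protein]
    except KeyError:
        raise ValueError(
            f"unknown protein {protein!r}; valid names: {', '.join(PROTEIN_PRESETS)}"
        ) from None
    return make_model(spec["steps"](), baseline=baseline)


def preset_scheme(protein: str) -> str:
    """Basic scheme letter (A-D) of a case-study protein's model."""
    return _PRESET_SPECS[protein]["scheme"]


def add_noise(tg: Thermogram, sd: float, seed=None) -> Thermogram:
    """Add independent zero-mean Gaussian noise (J mol^-1 K^-1) per point."""
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return tg
    rng = np.random.default_rng(seed)
    from dataclasses import replace

    return replace(tg, Cp=tg.Cp + rng.normal(0.0, sd, size=tg.Cp.size))


# defaults of the simulated alternative-refolding scenario: one-step
# irreversible unfolding, E = 300 kJ/mol, Tf = 360 K, dH = 800 kJ/mol,
# scanned 20-100 degC at 1 K/min with noise SD 2.1 kJ/mol/K.
REFOLDING_DEFAULTS = dict(
    E=300e3, Tf=360.0, dH=800e3,
    T0=20.0 + C_TO_K, T_end=100.0 + C_TO_K,
    rate=1.0 / 60.0, noise_sd=2.1e3, grid_step=0.1,
)


def make_refolding_case(
    f: float,
    noise_sd: float | None = None,
    seed=0,
    grid_step: float | None = None,
) -> ExperimentSet:
    """Simulated first+reheat pair probing alternative refolding.

    The first scan follows the one-step irreversible model with the
    defaults above.  The reheat is *not* the model's propagated reheat
    (which would be flat after a complete transition): it restarts from a
    fully "native" alternative state and follows the same kinetics with
    the enthalpy scaled by ``f``, so its peak area is a fraction ``f`` of
    the first run's.  Both scans carry independent Gaussian noise.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("reheat area fraction f must lie in [0, 1]")
    d = REFOLDING_DEFAULTS
    noise_sd = d["noise_sd"] if noise_sd is None else noise_sd
    grid_step = d["grid_step"] if grid_step is None else grid_step
    ss = np.random.SeedSequence(seed)
    s_first, s_reheat = ss.spawn(2)

    model_first = make_model([irreversible_step(d["E"], d["Tf"], d["dH"])])
    model_reheat = make_model([irreversible_step(d["E"], d["Tf"], d["dH"] * f)])

    (first,) = simulate_thermogram(
        model_first, single_scan(d["T0"], d["T_end"], d["rate"]),
        grid_step=grid_step, noise_sd=noise_sd, seed=s_first,
        meta=dict(experiment_id="refold", protein="simulated"),
    )
    (reheat,) = simulate_thermogram(
        model_reheat, single_scan(d["T0"], d["T_end"], d["rate"], role="reheat"),
        grid_step=grid_step, noise_sd=noise_sd, seed=s_reheat,
        meta=dict(experiment_id="refold", protein="simulated"),
    )
    reheat.T_prime = d["T_end"]
    return ExperimentSet([Experiment("refold", first, [reheat])])


def make_reheat_experiments(
    model: UnfoldingModel,
    T0: float,
    T_max: float,
    rate: float,
    T_primes: tuple[float, ...] = (),
    noise_sd: float = 0.0,
    seed=0,
    grid_step: float = 0.1,
    protein: str = "",
    include_full_first: bool = True,
    reheat_to_T_max: bool = True,
) -> ExperimentSet:
    """Generate a set of first+reheat experiments from one model.

    One optional full-range first run (no reheat) plus, per terminal
    temperature in ``T_primes``, an experiment heated to T', cooled at the
    same rate, and reheated (to ``T_max`` by default, else back to T').
    Noise is Gaussian with per-scan independent draws; the whole set is
    reproducible from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    experiments: list[Experiment] = []
    idx = 0
    if include_full_first:
        (first,) = simulate_thermogram(
            model, single_scan(T0, T_max, rate), grid_step=grid_step,
            noise_sd=noise_sd, seed=ss.spawn(1)[0],
            meta=dict(experiment_id=f"exp{idx}", protein=protein),
        )
        experiments.append(Experiment(f"exp{idx}", first))
        idx += 1
    for tp in T_primes:
        program = heat_cool_reheat(
            T0, tp, rate, T_reheat_end=(T_max if reheat_to_T_max else tp)
        )
        scans = simulate_thermogram(
            model, program, grid_step=grid_step,
            noise_sd=noise_sd, seed=ss.spawn(1)[0],
            meta=dict(experiment_id=f"exp{idx}", protein=protein),
        )
        first = next(s for s in scans if s.role == "first")
        reheats = [s for s in scans if s.role == "reheat"]
        experiments.append(Experiment(f"exp{idx}", first, reheats))
        idx += 1
    return ExperimentSet(experiments)
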