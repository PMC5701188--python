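"""Structured-text (YAML) configuration for models and temperature programs.

The on-disk schema uses bench units — kJ mol^-1, degC, degC min^-1 — and
round-trips losslessly to the internal SI representation:

.. code-block:: yaml

    model:
      baseline: {B0_kJ: 0.0, B1_kJ: 0.0}
      steps:
        - {kind: equilibrium, Tm_K: 345.03, dH_kJ: 516.0, dCp_kJ: 7.5}
        - {kind: irreversible, E_kJ: 18.0, Tf_K: 3200.0, dH_kJ: -37.0}
    program:
      - {start_C: 20.0, end_C: 80.0, rate_C_per_min: 1.0, role: first}
      - {start_C: 80.0, end_C: 20.0, rate_C_per_min: -1.0, role: cool}
      - {start_C: 20.0, end_C: 80.0, rate_C_per_min: 1.0, role: reheat}
"""

from __future__ import annotations

import yaml

from .models import (
    ScanSegment,
    TemperatureProgram,
    TransitionStep,
    UnfoldingModel,
    equilibrium_step,
    irreversible_step,
    make_model,
    two_rate_step,
)

__all__ = [
    "model_to_dict",
    "model_from_dict",
    "program_to_dict",
    "program_from_dict",
    "load_model",
    "load_program",
    "dump_config",
    "load_config",
]

C_TO_K = 273.15
KJ = 1e3


def _step_to_dict(step: TransitionStep) -> dict:
    p = step.params
    if step.kind == "equilibrium":
        d = dict(kind="equilibrium", Tm_K=p.Tm, dH_kJ=p.dH_ref / KJ,
                 dCp_kJ=p.dCp / KJ)
        if p.dH_vh is not None:
            d["dHvh_kJ"] = p.dH_vh / KJ
        return d
    if step.kind == "irreversible":
        return dict(kind="irreversible", E_kJ=p.E / KJ, Tf_K=p.Tf,
                    dH_kJ=p.dH_ref / KJ, dCp_kJ=p.dCp / KJ)
    return dict(kind="two_rate", E1_kJ=p.forward.E / KJ, Tf1_K=p.forward.Tf,
                Erev_kJ=p.reverse.E / KJ, Tfrev_K=p.reverse.Tf,
                dH_kJ=p.dH_ref / KJ, dCp_kJ=p.dCp / KJ)


def _step_from_dict(d: dict) -> TransitionStep:
    kind = d["kind"]
    if kind == "equilibrium":
        vh = d.get("dHvh_kJ")
        return equilibrium_step(d["Tm_K"], d["dH_kJ"] * KJ,
                                d.get("dCp_kJ", 0.0) * KJ,
                                None if vh is None else vh * KJ)
    if kind == "irreversible":
        return irreversible_step(d["E_kJ"] * KJ, d["Tf_K"],
                                 d.get("dH_kJ", 0.0) * KJ,
                                 d.get("dCp_kJ", 0.0) * KJ)
    if kind == "two_rate":
        return two_rate_step(d["E1_kJ"] * KJ, d["Tf1_K"],
                             d["Erev_kJ"] * KJ, d["Tfrev_K"],
                             d.get("dH_kJ", 0.0) * KJ,
                             d.get("dCp_kJ", 0.0) * KJ)
    raise ValueError(f"unknown step kind {kind!r}")


def model_to_dict(model: UnfoldingModel) -> dict:
    return dict(
        baseline=dict(B0_kJ=model.baseline.B0 / KJ, B1_kJ=model.baseline.B1 / KJ),
        steps=[_step_to_dict(s) for s in model.steps],
    )


def model_from_dict(d: dict) -> UnfoldingModel:
    if "preset" in d:
        model = make_model(d["preset"])
    else:
        model = make_model([_step_from_dict(s) for s in d["steps"]])
    b = d.get("baseline")
    if b:
        model = model.with_baseline(b.get("B0_kJ", 0.0) * KJ,
                                    b.get("B1_kJ", 0.0) * KJ)
    return model


def program_to_dict(program: TemperatureProgram) -> list[dict]:
    return [
        dict(start_C=s.T_start - C_TO_K, end_C=s.T_end - C_TO_K,
             rate_C_per_min=s.rate * 60.0, role=s.role)
        for s in program.segments
    ]


def program_from_dict(segments: list[dict]) -> TemperatureProgram:
    return TemperatureProgram(tuple(
        ScanSegment(s["start_C"] + C_TO_K, s["end_C"] + C_TO_K,
                    s["rate_C_per_min"] / 60.0, s.get("role", "first"))
        for s in segments
    ))


def dump_config(path, model: UnfoldingModel | None = None,
                program: TemperatureProgram | None = None,
                extra: dict | None = None) -> None:
    doc: dict = dict(extra or {})
    if model is not None:
        doc["model"] = model_to_dict(model)
    if program is not None:
        doc["program"] = program_to_dict(program)
    with open(path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path, "rt", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def load_model(path) -> UnfoldingModel:
    return model_from_dict(load_config(path)["model"])


def load_program(path) -> TemperatureProgram:
    return program_from_dict(load_config(path)["program"])
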