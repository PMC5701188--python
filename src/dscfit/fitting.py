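"""Global nonlinear least-squares fitting of unfolding models to DSC scan sets.

One model (shared thermodynamic/kinetic parameters) is fitted
simultaneously to every scan of an :class:`~dscfit.io.ExperimentSet` —
first runs and reheats, possibly at several scan rates.  Reheat curves are
always generated through the full heat/cool/reheat propagation of the
model, never fitted independently: this is what makes reheats informative
about irreversibility.  Baseline coefficients B0/B1 are shared within a
scan-rate group (a first run and its reheats at the same rate).

The optimizer is bounded trust-region least squares (via lmfit), with a
seeded multistart over log-spaced perturbations of the activation-energy
and enthalpy parameters to mitigate the multimodality typical of
Lumry-Eyring objectives.  Confidence intervals are linearized: half-width
= t(0.975, dof) x standard error from the Jacobian at the optimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
from scipy.stats import t as student_t

from .io import ExperimentSet
from .models import (
    Baseline,
    ScanSegment,
    SimulationError,
    TemperatureProgram,
    TransitionStep,
    UnfoldingModel,
    equilibrium_step,
    irreversible_step,
    simulate_fractions,
    two_rate_step,
)
from .thermo import R

__all__ = [
    "FitOptions",
    "FitProblem",
    "ScanFit",
    "FitResult",
    "build_problem",
    "initial_model_from_data",
    "global_fit",
    "confidence_intervals",
    "compare_models",
]

_log = logging.getLogger(__name__)

_BOUNDS = {
    "Tm": (260.0, 420.0),
    "Tf": (260.0, 6000.0),
    "E": (1e3, 5e6),
    "dH": (-5e6, 5e6),
    "dHvh": (1e3, 5e6),
    "dCp": (-1e5, 1e5),
}


# ---------------------------------------------------------------------------
# parameter encoding


def _step_param_names(step: TransitionStep, i: int) -> dict[str, float]:
    p = step.params
    if step.kind == "equilibrium":
        out = {f"s{i}_Tm": p.Tm, f"s{i}_dH": p.dH_ref, f"s{i}_dCp": p.dCp}
        if p.dH_vh is not None:
            out[f"s{i}_dHvh"] = p.dH_vh
        return out
    if step.kind == "irreversible":
        return {f"s{i}_E": p.E, f"s{i}_Tf": p.Tf, f"s{i}_dH": p.dH_ref,
                f"s{i}_dCp": p.dCp}
    return {f"s{i}_E1": p.forward.E, f"s{i}_Tf1": p.forward.Tf,
            f"s{i}_Erev": p.reverse.E, f"s{i}_Tfrev": p.reverse.Tf,
            f"s{i}_dH": p.dH_ref, f"s{i}_dCp": p.dCp}


def _default_bounds(name: str) -> tuple[float, float]:
    tail = name.split("_", 1)[1]
    if tail in ("Tf1", "Tfrev"):
        tail = "Tf"
    if tail in ("E1", "Erev"):
        tail = "E"
    return _BOUNDS.get(tail, (-np.inf, np.inf))


def _steps_from_params(template: UnfoldingModel, p: lmfit.Parameters) -> tuple[TransitionStep, ...]:
    steps = []
    for i, step in enumerate(template.steps, start=1):
        if step.kind == "equilibrium":
            vh = p[f"s{i}_dHvh"].value if f"s{i}_dHvh" in p else None
            steps.append(equilibrium_step(
                p[f"s{i}_Tm"].value, p[f"s{i}_dH"].value, p[f"s{i}_dCp"].value, vh))
        elif step.kind == "irreversible":
            steps.append(irreversible_step(
                p[f"s{i}_E"].value, p[f"s{i}_Tf"].value,
                p[f"s{i}_dH"].value, p[f"s{i}_dCp"].value))
        else:
            steps.append(two_rate_step(
                p[f"s{i}_E1"].value, p[f"s{i}_Tf1"].value,
                p[f"s{i}_Erev"].value, p[f"s{i}_Tfrev"].value,
                p[f"s{i}_dH"].value, p[f"s{i}_dCp"].value))
    return tuple(steps)


# ---------------------------------------------------------------------------
# problem definition


@dataclass
class FitOptions:
    """Numerical settings of a global fit."""

    grid_step: float = 0.2        # K, simulation grid during fitting
    rtol: float = 1e-7
    atol: float = 1e-10
    n_starts: int = 5             # multistart count
    seed: int = 0
    stall_starts: int = 2         # stop after this many non-improving starts
    improve_tol: float = 0.02     # relative SSR improvement that counts
    max_nfev: int | None = None
    ftol: float = 1e-8            # trust-region stopping tolerances
    xtol: float = 1e-8


@dataclass
class FitProblem:
    """Data + model template + parameter roles for one global fit."""

    data: ExperimentSet
    template: UnfoldingModel
    params: lmfit.Parameters
    rate_groups: list[float]      # distinct scan rates, one baseline pair each

    @property
    def n_free(self) -> int:
        return sum(1 for q in self.params.values() if q.vary)


def _rate_group(rate: float, groups: list[float]) -> int:
    for g, r in enumerate(groups):
        if abs(rate - r) < 1e-12:
            return g
    raise ValueError(f"scan rate {rate} not in any group")


def build_problem(
    data: ExperimentSet,
    model: UnfoldingModel,
    vary: dict[str, bool] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> FitProblem:
    """Assemble a :class:`FitProblem` from data and an initialized model.

    All step parameters and per-rate-group baselines are free by default;
    ``vary={'s1_dCp': False, ...}`` fixes individual parameters and
    ``bounds`` overrides the defaults.
    """
    params = lmfit.Parameters()
    for i, step in enumerate(model.steps, start=1):
        for name, value in _step_param_names(step, i).items():
            lo, hi = (bounds or {}).get(name, _default_bounds(name))
            params.add(name, value=float(np.clip(value, lo, hi)), min=lo, max=hi,
                       vary=(vary or {}).get(name, True))
    groups: list[float] = []
    for e in data.experiments:
        if not any(abs(e.first.rate - r) < 1e-12 for r in groups):
            groups.append(e.first.rate)
    for g in range(len(groups)):
        params.add(f"B0_g{g}", value=model.baseline.B0,
                   vary=(vary or {}).get(f"B0_g{g}", True))
        params.add(f"B1_g{g}", value=model.baseline.B1,
                   vary=(vary or {}).get(f"B1_g{g}", True))
    if not any(q.vary for q in params.values()):
        raise ValueError("at least one parameter must be free")
    return FitProblem(data=data, template=model, params=params, rate_groups=groups)


# ---------------------------------------------------------------------------
# prediction


def _experiment_program(e) -> TemperatureProgram:
    segs = [ScanSegment(float(e.first.T.min()), float(e.first.T.max()),
                        e.first.rate, "first")]
    t_hi = float(e.first.T.max())
    for r in e.reheats:
        lo = float(r.T.min())
        segs.append(ScanSegment(t_hi, lo, -r.rate, "cool"))
        segs.append(ScanSegment(lo, float(r.T.max()), r.rate, "reheat"))
        t_hi = float(r.T.max())
    return TemperatureProgram(tuple(segs))


def predict_scans(
    problem: FitProblem,
    params: lmfit.Parameters,
    grid_step: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> list[np.ndarray]:
    """Model curves on every scan's own temperature grid, in data order."""
    steps = _steps_from_params(problem.template, params)
    out = []
    for e in problem.data.experiments:
        g = _rate_group(e.first.rate, problem.rate_groups)
        model = UnfoldingModel(steps, Baseline(params[f"B0_g{g}"].value,
                                               params[f"B1_g{g}"].value))
        traj = simulate_fractions(model, _experiment_program(e), grid_step,
                                  rtol=rtol, atol=atol)
        heat_segments = [s for s in traj.segments if s.role != "cool"]
        H_Csum = model.cumulative_dCp()
        for scan, seg in zip(e.scans, heat_segments):
            H = model.cumulative_dH(seg.T)
            Cp = model.baseline(seg.T) + np.sum(H * seg.dxdT, axis=1) + seg.x @ H_Csum
            out.append(np.interp(scan.T, seg.T, Cp))
    return out


# ---------------------------------------------------------------------------
# results


@dataclass
class ScanFit:
    experiment_id: str
    role: str
    T: np.ndarray
    Cp_obs: np.ndarray
    Cp_pred: np.ndarray

    @property
    def residual(self) -> np.ndarray:
        return self.Cp_obs - self.Cp_pred


@dataclass
class FitResult:
    problem: FitProblem
    params: lmfit.Parameters
    scans: list[ScanFit]
    ssr: float
    success: bool
    message: str
    nfev: int
    covar: np.ndarray | None
    var_names: list[str]
    n_starts_run: int = 1
    options: FitOptions = field(default_factory=FitOptions)

    @property
    def ndata(self) -> int:
        return sum(s.T.size for s in self.scans)

    @property
    def n_free(self) -> int:
        return sum(1 for q in self.params.values() if q.vary)

    @property
    def dof(self) -> int:
        return max(1, self.ndata - self.n_free)

    @property
    def redchi(self) -> float:
        return self.ssr / self.dof

    @property
    def aic(self) -> float:
        n = self.ndata
        return n * math.log(self.ssr / n) + 2 * self.n_free

    def value(self, name: str) -> float:
        return self.params[name].value

    def stderr(self, name: str) -> float | None:
        q = self.params[name]
        return None if q.stderr is None else float(q.stderr)

    def predict(self, grid_step: float | None = None) -> list[np.ndarray]:
        """Regenerate model curves from the stored estimates."""
        o = self.options
        return predict_scans(self.problem, self.params,
                             grid_step or o.grid_step, o.rtol, o.atol)

    def parameter_table(self) -> list[dict]:
        ci = confidence_intervals(self)
        rows = []
        for name, q in self.params.items():
            rows.append(dict(name=name, value=q.value, vary=q.vary,
                             stderr=q.stderr, ci95_half=ci.get(name)))
        return rows


def _residual_factory(problem: FitProblem, options: FitOptions):
    obs = np.concatenate([s.Cp for s in problem.data.scans])
    scale = max(np.std(obs), 1.0)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        try:
            preds = predict_scans(problem, params, options.grid_step,
                                  options.rtol, options.atol)
        except (SimulationError, OverflowError, ValueError):
            return np.full(obs.size, 10.0 * scale)
        return obs - np.concatenate(preds)

    return residual, obs


_PERTURB_TAILS = ("E", "E1", "Erev", "dH", "dHvh")


def _perturbed_starts(params: lmfit.Parameters, n_starts: int, seed: int):
    """Start 0: the given inits; later starts scale E/dH-like params log-spaced."""
    yield params.copy()
    rng = np.random.default_rng(seed)
    factors = np.exp(np.linspace(-0.5, 0.5, max(n_starts - 1, 1)))
    rng.shuffle(factors)
    for k in range(n_starts - 1):
        p = params.copy()
        for name, q in p.items():
            if not q.vary:
                continue
            tail = name.split("_", 1)[1] if "_" in name else name
            if tail in _PERTURB_TAILS:
                jitter = factors[k] * math.exp(rng.normal(0.0, 0.15))
                q.set(value=float(np.clip(q.value * jitter, q.min, q.max)))
        yield p


def global_fit(problem: FitProblem, options: FitOptions | None = None) -> FitResult:
    """Minimize the summed squared residual over all scans.

    Deterministic for fixed data, initial values and options.  On
    non-convergence the best parameters found are returned with
    ``success=False``; a singular Jacobian leaves the affected standard
    errors as ``None`` (confidence intervals flagged unavailable).
    """
    options = options or FitOptions()
    residual, obs = _residual_factory(problem, options)
    best = None
    best_ssr = np.inf
    stall = 0
    n_run = 0
    for start in _perturbed_starts(problem.params, options.n_starts, options.seed):
        n_run += 1
        mini = lmfit.Minimizer(residual, start)
        try:
            res = mini.minimize(method="least_squares",
                                max_nfev=options.max_nfev,
                                ftol=options.ftol, xtol=options.xtol)
        except Exception as exc:  # keep best-so-far on optimizer failure
            _log.warning("fit start %d failed: %s", n_run, exc)
            continue
        ssr = float(np.sum(np.asarray(res.residual) ** 2))
        if ssr < best_ssr * (1.0 - options.improve_tol):
            best, best_ssr, stall = res, ssr, 0
        else:
            if best is None or ssr < best_ssr:
                best, best_ssr = res, ssr
            stall += 1
            if stall >= options.stall_starts:
                break
    if best is None:
        raise RuntimeError("all fit starts failed")
    preds = predict_scans(problem, best.params, options.grid_step,
                          options.rtol, options.atol)
    scan_fits = []
    i = 0
    for e in problem.data.experiments:
        for s in e.scans:
            scan_fits.append(ScanFit(e.experiment_id, s.role, s.T, s.Cp, preds[i]))
            i += 1
    return FitResult(
        problem=problem,
        params=best.params,
        scans=scan_fits,
        ssr=best_ssr,
        success=bool(best.success),
        message=str(getattr(best, "message", "")),
        nfev=int(best.nfev),
        covar=getattr(best, "covar", None),
        var_names=list(getattr(best, "var_names", [])),
        n_starts_run=n_run,
        options=options,
    )


def confidence_intervals(result: FitResult) -> dict[str, float | None]:
    """Linearized 95% CI half-widths per free parameter.

    half-width = t(0.975, n - p) x stderr; ``None`` where the Jacobian was
    rank-deficient for that parameter.
    """
    tq = student_t.ppf(0.975, result.dof)
    out: dict[str, float | None] = {}
    for name, q in result.params.items():
        if not q.vary:
            continue
        out[name] = None if q.stderr is None else float(tq * q.stderr)
    return out


# ---------------------------------------------------------------------------
# initialization heuristics


def _first_run_features(data: ExperimentSet):
    first = max((e.first for e in data.experiments), key=lambda s: s.T.max())
    n = first.n
    npre = max(5, n // 8)
    coef = np.polyfit(first.T[:npre], first.Cp[:npre], 1)
    base = np.polyval(coef, first.T)
    excess = first.Cp - base
    ip = int(np.argmax(excess))
    Tp = float(first.T[ip])
    height = float(excess[ip])
    area = float(np.trapezoid(np.clip(excess, 0.0, None), first.T))
    npost = max(5, n // 20)
    dcp = float(np.mean(excess[-npost:]) - np.mean(excess[:npost]))
    return dict(Tp=Tp, height=height, area=area, dCp=max(dcp, 0.0),
                B1=float(coef[0]), B0=float(coef[1]), rate=first.rate)


def _tf_from_point(E: float, T: float, k_at_T: float) -> float:
    # 1/Tf = 1/T + R ln k(T) / E
    return 1.0 / (1.0 / T + R * math.log(k_at_T) / E)


def initial_model_from_data(data: ExperimentSet, preset: str) -> UnfoldingModel:
    """Data-driven initial model for one of the basic schemes A-D.

    Tm/Tf start at the apparent peak temperature, dH at the peak area,
    activation energies at the irreversible-peak width relation
    E ~ e R Tp^2 Cp_max / area, and the baseline at a linear fit of the
    pre-transition region.  The scheme's extra rate parameters start at
    magnitudes that make both refolding and the drain noticeable on the
    scan's own time scale.
    """
    f = _first_run_features(data)
    Tp, h, A, v = f["Tp"], f["height"], max(f["area"], 1e3), f["rate"]
    width = max(A / max(h, 1e-9), 1.0)
    E_irr = math.e * R * Tp**2 * h / A
    baseline = Baseline(f["B0"], f["B1"])
    preset = preset.upper()
    if preset == "A":
        dHvh = 4.0 * R * Tp**2 * h / A
        steps = (equilibrium_step(Tp, A, f["dCp"], dH_vh=dHvh),)
    elif preset == "B":
        k_at_Tp = v * E_irr / (R * Tp**2)
        steps = (irreversible_step(E_irr, _tf_from_point(E_irr, Tp, k_at_Tp),
                                   A, f["dCp"]),)
    elif preset == "C":
        E2 = 150e3
        k2_at_Tp = v / width  # drain noticeable across the peak width
        steps = (equilibrium_step(Tp, A, f["dCp"]),
                 irreversible_step(E2, _tf_from_point(E2, Tp, k2_at_Tp), 0.05 * A))
    elif preset == "D":
        E1 = max(E_irr, 50e3)
        k1_at_Tp = v * E1 / (R * Tp**2)
        Erev = 60e3
        krev_at_Tp = 0.5 * k1_at_Tp
        E2 = 120e3
        k2_at_Tp = 2.0 * v / width
        steps = (
            two_rate_step(E1, _tf_from_point(E1, Tp, k1_at_Tp),
                          Erev, _tf_from_point(Erev, Tp, krev_at_Tp),
                          A, f["dCp"]),
            irreversible_step(E2, _tf_from_point(E2, Tp, k2_at_Tp), 0.05 * A),
        )
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return UnfoldingModel(steps, baseline)


def _embed_b_in_d(b: UnfoldingModel) -> UnfoldingModel:
    """Two-rate start from a fitted irreversible two-state model.

    The forward rate copies the fitted k; the reverse rate starts slow
    (k_rev ~ 0.1 at the fitted Tf) and the drain fast, i.e. near the
    k2 >> k1, k-1 limit in which the general scheme reduces to the
    irreversible two-state one.
    """
    p = b.steps[0].params
    Erev = 60e3
    E2 = max(p.E / 2.0, 20e3)
    return UnfoldingModel(
        (
            two_rate_step(p.E, p.Tf, Erev, _tf_from_point(Erev, p.Tf, 0.1),
                          p.dH_ref * 0.9, p.dCp),
            irreversible_step(E2, _tf_from_point(E2, p.Tf, 20.0), p.dH_ref * 0.1),
        ),
        b.baseline,
    )


def _embed_c_in_d(c: UnfoldingModel) -> UnfoldingModel:
    """Two-rate start from a fitted fast-equilibrium three-state model.

    Forward/reverse rates are chosen fast compared to the fitted drain,
    with k1/k-1 matching the fitted K(T): the k1 + k-1 >> k2 limit in
    which the general scheme reduces to the equilibrium one.
    """
    eq = c.steps[0].params
    dr = c.steps[1].params
    k2_at_Tm = math.exp(min(-(dr.E / R) * (1.0 / eq.Tm - 1.0 / dr.Tf), 50.0))
    c_rate = max(100.0 * k2_at_Tm, 1e-2)
    Erev = 80e3
    E1 = abs(eq.dH_K) + Erev
    return UnfoldingModel(
        (
            two_rate_step(E1, _tf_from_point(E1, eq.Tm, c_rate),
                          Erev, _tf_from_point(Erev, eq.Tm, c_rate),
                          eq.dH_ref, eq.dCp),
            irreversible_step(dr.E, dr.Tf, dr.dH_ref, dr.dCp),
        ),
        c.baseline,
    )


def _d_structured_starts(data: ExperimentSet) -> list[UnfoldingModel]:
    """Coarse grid of two-rate starting models from first-run peak features.

    The physically undetermined quantities — how fast the first step
    reverses and whether the drain is endo- or exothermic — are scanned
    over a small factorial grid; the forward rate starts from the
    irreversible-peak width relation as for the two-state scheme.
    """
    f = _first_run_features(data)
    Tp, h, A, v = f["Tp"], f["height"], max(f["area"], 1e3), f["rate"]
    width = max(A / max(h, 1e-9), 1.0)
    E1 = max(math.e * R * Tp**2 * h / A, 50e3)
    k1_at_Tp = v * E1 / (R * Tp**2)
    Erev, E2 = 60e3, 120e3
    k2_at_Tp = 3.0 * v / width
    baseline = Baseline(f["B0"], f["B1"])
    out = []
    for r_rev in (1e-3, 0.3):
        for dH2 in (0.5 * A, -0.5 * A):
            out.append(UnfoldingModel(
                (
                    two_rate_step(E1, _tf_from_point(E1, Tp, k1_at_Tp),
                                  Erev, _tf_from_point(Erev, Tp, r_rev * k1_at_Tp),
                                  A - dH2, f["dCp"]),
                    irreversible_step(E2, _tf_from_point(E2, Tp, k2_at_Tp), dH2),
                ),
                baseline,
            ))
    return out


def _model_from_result(result: FitResult) -> UnfoldingModel:
    g0 = 0
    return UnfoldingModel(
        _steps_from_params(result.problem.template, result.params),
        Baseline(result.params[f"B0_g{g0}"].value, result.params[f"B1_g{g0}"].value),
    )


# ---------------------------------------------------------------------------
# model comparison


def compare_models(
    data: ExperimentSet,
    candidates: tuple[str, ...] = ("A", "B", "C", "D"),
    options: FitOptions | None = None,
    sd_ratio_threshold: float = 2.0,
    bias_threshold: float = 0.05,
    ssr_rel_tol: float = 0.10,
    initial_models: dict[str, UnfoldingModel] | None = None,
) -> dict:
    """Fit each candidate scheme and rank them by reheat-consistent quality.

    A candidate is rejected when its reheat residuals are inconsistent with
    its first-run residuals (SD ratio >= ``sd_ratio_threshold`` or mean
    reheat bias above ``bias_threshold`` of the first-run peak amplitude) —
    the reheat misfit diagnostic.  Among the surviving candidates the one
    with the fewest free parameters whose SSR is within ``ssr_rel_tol`` of
    the best survivor is selected (a parsimony rule); AIC is reported
    informationally.
    """
    from .diagnostics import refold_statistics

    options = options or FitOptions()
    entries = []
    fitted: dict[str, FitResult] = {}
    # A-C first: their optima seed the general scheme through its limiting cases
    order = sorted(candidates, key=lambda c: (c == "D",))
    for cand in order:
        inits = [(initial_models or {}).get(cand) or initial_model_from_data(data, cand)]
        screen_opts = options
        if cand == "D":
            if "B" in fitted:
                inits.append(_embed_b_in_d(_model_from_result(fitted["B"])))
            if "C" in fitted:
                inits.append(_embed_c_in_d(_model_from_result(fitted["C"])))
            inits.extend(_d_structured_starts(data))
            screen_opts = replace(options, n_starts=1, max_nfev=200,
                                  ftol=1e-6, xtol=1e-6)
        result = None
        err = None
        for init in inits:
            problem = build_problem(data, init)
            try:
                r = global_fit(problem, screen_opts)
            except RuntimeError as exc:
                err = exc
                continue
            if result is None or r.ssr < result.ssr:
                result = r
        if result is None:
            entries.append(dict(candidate=cand, error=str(err), rejected=True,
                                reason="fit failed", ssr=np.inf, n_free=np.nan,
                                aic=np.nan, result=None))
            continue
        if cand == "D" and screen_opts is not options:
            # polish the best screened start without the evaluation cap
            problem = build_problem(data, _model_from_result(result))
            try:
                r = global_fit(problem, replace(options, n_starts=1))
                if r.ssr < result.ssr:
                    result = r
            except RuntimeError:
                pass
        fitted[cand] = result
        rep = refold_statistics(result)
        rejected = False
        reason = ""
        if rep.sd_ratio >= sd_ratio_threshold:
            rejected, reason = True, (
                f"reheat/first residual SD ratio {rep.sd_ratio:.2f} >= "
                f"{sd_ratio_threshold:g}")
        elif abs(rep.mean_reheat) > bias_threshold * rep.first_peak_amplitude:
            rejected, reason = True, (
                f"mean reheat residual {rep.mean_reheat:.3g} exceeds "
                f"{bias_threshold:.0%} of the first-run peak amplitude")
        entries.append(dict(candidate=cand, ssr=result.ssr, n_free=result.n_free,
                            aic=result.aic, sd_first=rep.sd_first,
                            sd_reheat=rep.sd_reheat, sd_ratio=rep.sd_ratio,
                            rejected=rejected, reason=reason, result=result))
    survivors = [e for e in entries if not e["rejected"]]
    pool = survivors if survivors else [e for e in entries if e.get("result")]
    best_ssr = min(e["ssr"] for e in pool)
    eligible = [e for e in pool if e["ssr"] <= (1.0 + ssr_rel_tol) * best_ssr]
    selected = min(eligible, key=lambda e: (e["n_free"], e["ssr"]))
    ranked = sorted(entries, key=lambda e: (e["rejected"],
                                            e is not selected, e["ssr"]))
    for e in entries:
        e["selected"] = e is selected
    return dict(selected=selected["candidate"], entries=ranked,
                all_rejected=not survivors)
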