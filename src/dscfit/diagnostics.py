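"""Residual diagnostics, reversibility classification and reheat planning.

After a global fit, residuals are split into first-run and reheat groups;
if the reheat group's mean or spread is much larger than the first run's,
the model explains reheating poorly — the signature of refolding into an
alternative (non-native) conformation upon cooling.  The working
thresholds are a mean reheat residual above 5% of the first-run peak
amplitude (the practical precision of concentration measurements) or a
reheat/first residual-SD ratio of 2.

Reversibility is classified by reheating from the foot of a peak: the
surviving native fraction is estimated from baseline-corrected peak
heights, with >=99% calling the fully reversible scheme, 20-99% the
fast-equilibrium partially reversible scheme, and <20% the fully
irreversible one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Thermogram

__all__ = [
    "RefoldReport",
    "RefoldFlag",
    "refold_statistics",
    "flag_alternative_refolding",
    "classify_reversibility",
    "suggest_reheat_temperatures",
]

_log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RefoldReport:
    """Residual statistics split by scan role (J mol^-1 K^-1)."""

    mean_first: float
    mean_reheat: float
    mean_abs_first: float
    mean_abs_reheat: float
    sd_first: float
    sd_reheat: float
    first_peak_amplitude: float
    n_first: int
    n_reheat: int

    @property
    def sd_ratio(self) -> float:
        return self.sd_reheat / self.sd_first if self.sd_first > 0 else np.inf


@dataclass(frozen=True)
class RefoldFlag:
    flag: bool
    rationale: str
    signal_threshold: float
    sd_ratio_threshold: float


def _scan_baseline(result, scan) -> np.ndarray:
    """Fitted linear baseline under one scan, if the fit carries one."""
    g = None
    try:
        g = result.problem.rate_groups.index(
            next(e.first.rate for e in result.problem.data.experiments
                 if e.experiment_id == scan.experiment_id))
    except (AttributeError, StopIteration):
        pass
    if g is not None and f"B0_g{g}" in result.params:
        return result.params[f"B0_g{g}"].value + result.params[f"B1_g{g}"].value * scan.T
    npre = max(5, scan.T.size // 8)
    coef = np.polyfit(scan.T[:npre], scan.Cp_obs[:npre], 1)
    return np.polyval(coef, scan.T)


def refold_statistics(result) -> RefoldReport:
    """Group the fit residuals by scan role and summarize each group.

    Means are signed (bias detection); SDs are about each group's own mean
    over the scans' full recorded temperature ranges.  Requires at least
    one reheat scan in the fit.
    """
    first_res, reheat_res, amps = [], [], []
    for scan in result.scans:
        r = scan.residual
        if scan.role == "reheat":
            reheat_res.append(r)
        else:
            first_res.append(r)
            amps.append(float(np.max(scan.Cp_obs - _scan_baseline(result, scan))))
    if not reheat_res:
        raise ValueError("refold statistics require at least one reheat scan")
    fr = np.concatenate(first_res)
    rr = np.concatenate(reheat_res)
    return RefoldReport(
        mean_first=float(fr.mean()),
        mean_reheat=float(rr.mean()),
        mean_abs_first=float(np.abs(fr).mean()),
        mean_abs_reheat=float(np.abs(rr).mean()),
        sd_first=float(fr.std(ddof=1)),
        sd_reheat=float(rr.std(ddof=1)),
        first_peak_amplitude=float(max(amps)),
        n_first=fr.size,
        n_reheat=rr.size,
    )


def flag_alternative_refolding(
    report: RefoldReport,
    signal_threshold: float = 0.05,
    sd_ratio_threshold: float = 2.0,
) -> RefoldFlag:
    """Raise the alternative-refolding flag from a :class:`RefoldReport`.

    Triggers when the reheat group's |mean residual| exceeds
    ``signal_threshold`` of the first-run peak amplitude, or when the
    reheat/first SD ratio reaches ``sd_ratio_threshold``.
    """
    reasons = []
    if abs(report.mean_reheat) > signal_threshold * report.first_peak_amplitude:
        reasons.append(
            f"|mean reheat residual| = {abs(report.mean_reheat):.3g} exceeds "
            f"{signal_threshold:.0%} of the first-run peak amplitude "
            f"({report.first_peak_amplitude:.3g})")
    if report.sd_ratio >= sd_ratio_threshold:
        reasons.append(
            f"reheat/first residual SD ratio = {report.sd_ratio:.2f} >= "
            f"{sd_ratio_threshold:g}")
    if reasons:
        return RefoldFlag(True, "; ".join(reasons), signal_threshold,
                          sd_ratio_threshold)
    return RefoldFlag(False,
                      "reheat residuals consistent with first-run residuals",
                      signal_threshold, sd_ratio_threshold)


# ---------------------------------------------------------------------------
# peak geometry helpers


def _baseline_corrected(tg: Thermogram, pre_window=None):
    if pre_window is not None:
        mask = (tg.T >= pre_window[0]) & (tg.T <= pre_window[1])
        if mask.sum() < 2:
            raise ValueError("pre-transition window contains fewer than 2 points")
    else:
        mask = np.zeros(tg.n, dtype=bool)
        mask[: max(5, tg.n // 8)] = True
    coef = np.polyfit(tg.T[mask], tg.Cp[mask], 1)
    excess = tg.Cp - np.polyval(coef, tg.T)
    noise = float(np.std(excess[mask], ddof=1)) if mask.sum() > 2 else 0.0
    return excess, noise


def _peak(tg: Thermogram, pre_window=None):
    excess, noise = _baseline_corrected(tg, pre_window)
    ip = int(np.argmax(excess))
    height = float(excess[ip])
    if height <= max(5.0 * noise, 1e-12):
        raise ValueError("no detectable peak above the baseline noise")
    return ip, height, excess


def classify_reversibility(
    first: Thermogram,
    reheat_from_foot: Thermogram,
    pre_window=None,
    reversible_bound: float = 0.99,
    partial_bound: float = 0.20,
) -> tuple[str, float]:
    """Classify a transition from a reheat recorded after a foot-terminated run.

    Returns ``(scheme, native_fraction)`` with scheme ``"A"`` (fully
    reversible), ``"C"`` (partially reversible, equilibrium first step
    applicable) or ``"B"`` (essentially irreversible).  The surviving
    native fraction is the ratio of the baseline-corrected reheat peak
    height to the first-run peak height; the comparison requires identical
    scan rates.
    """
    if abs(first.rate - reheat_from_foot.rate) > 1e-9 * first.rate:
        raise ValueError("reversibility test requires identical scan rates")
    _, h_first, _ = _peak(first, pre_window)
    try:
        _, h_reheat, _ = _peak(reheat_from_foot, pre_window)
    except ValueError:
        h_reheat = 0.0
    fraction = min(max(h_reheat / h_first, 0.0), 1.0 + 1e-9)
    if fraction >= reversible_bound:
        return "A", fraction
    if fraction >= partial_bound:
        return "C", fraction
    return "B", fraction


def suggest_reheat_temperatures(
    first: Thermogram,
    pre_window=None,
    foot_fraction: float = 0.02,
) -> tuple[float, float, float]:
    """Three terminal temperatures for reheat experiments (K).

    Point III is the apparent peak temperature; point V the post-transition
    foot (first temperature past the peak where the baseline-corrected
    excess falls below ``foot_fraction`` of the peak height); point IV the
    midpoint — the most sensitive region for discriminating the kinetic
    schemes lies between the summit and the foot.
    """
    ip, height, excess = _peak(first, pre_window)
    T3 = float(first.T[ip])
    after = excess[ip:]
    # measure the decline against the post-transition level so that a
    # positive dCp step does not mask the foot
    ntail = max(3, after.size // 20)
    post = float(np.median(after[-ntail:]))
    post = min(post, 0.98 * height)
    below = np.nonzero(after - post < foot_fraction * (height - post))[0]
    if below.size:
        T5 = float(first.T[ip + below[0]])
    else:
        T5 = float(first.T[-1])
        _log.warning(
            "signal never falls below %.0f%% of the peak height; using the "
            "scan end %.2f K as the post-transition foot", 100 * foot_fraction, T5)
    return T3, 0.5 * (T3 + T5), T5
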