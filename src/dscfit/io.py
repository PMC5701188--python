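"""Reading, writing, normalizing and superimposing DSC scan data.

Scan files are two-column delimited text (tab or comma, autodetected) with
``#`` comment lines; metadata travels in ``# key: value`` header lines.
Instrument exports are in degC and kJ mol^-1 K^-1 by default; everything is
kelvin and J mol^-1 K^-1 internally.
"""

from __future__ import annotations

import io as _stdio
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Thermogram",
    "Experiment",
    "ExperimentSet",
    "ThermogramParseError",
    "read_thermogram",
    "write_thermogram",
    "normalize_concentration",
    "subtract_baseline_series",
    "superimpose",
]

_log = logging.getLogger(__name__)

C_TO_K = 273.15


class ThermogramParseError(ValueError):
    pass


@dataclass
class Thermogram:
    """One scan: temperature (K) vs apparent molar heat capacity (J mol^-1 K^-1).

    ``role`` is ``"first"`` or ``"reheat"``; for reheats ``T_prime`` records
    the terminal temperature of the preceding first run, which determines
    how much protein was lost before cooling.
    """

    T: np.ndarray
    Cp: np.ndarray
    rate: float = float("nan")  # K s^-1, positive for recorded (heating) scans
    role: str = "first"
    T_prime: float | None = None
    experiment_id: str = ""
    protein: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.Cp = np.asarray(self.Cp, dtype=float)
        if self.T.shape != self.Cp.shape or self.T.ndim != 1:
            raise ValueError("T and Cp must be 1-D arrays of equal length")
        if self.T.size < 2:
            raise ValueError("a thermogram needs at least two points")
        if not (np.all(np.isfinite(self.T)) and np.all(np.isfinite(self.Cp))):
            raise ValueError("non-finite values in thermogram")
        if self.role not in {"first", "reheat"}:
            raise ValueError(f"unknown scan role {self.role!r}")

    @property
    def n(self) -> int:
        return self.T.size

    def shifted(self, offset: float) -> "Thermogram":
        return replace(self, Cp=self.Cp + offset,
                       meta={**self.meta, "offset": self.meta.get("offset", 0.0) + offset})


@dataclass
class Experiment:
    """One loaded sample: a first run plus the reheats recorded after it."""

    experiment_id: str
    first: Thermogram
    reheats: list[Thermogram] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.first.role != "first":
            raise ValueError("Experiment.first must have role 'first'")
        for r in self.reheats:
            if r.role != "reheat":
                raise ValueError("Experiment.reheats must have role 'reheat'")
            if r.T_prime is None:
                r.T_prime = float(self.first.T.max())
            elif abs(r.T_prime - self.first.T.max()) > 0.5:
                _log.warning(
                    "experiment %s: reheat T'=%.2f K differs from the first run's "
                    "maximum %.2f K; accepted (the model has no such limitation)",
                    self.experiment_id, r.T_prime, self.first.T.max(),
                )

    @property
    def scans(self) -> list[Thermogram]:
        return [self.first, *self.reheats]


@dataclass
class ExperimentSet:
    experiments: list[Experiment]

    def __post_init__(self) -> None:
        for e in self.experiments:
            for s in e.scans:
                if not (s.rate > 0) or math.isnan(s.rate):
                    raise ValueError(
                        f"experiment {e.experiment_id}: scan rate must be positive"
                    )

    @property
    def scans(self) -> list[Thermogram]:
        return [s for e in self.experiments for s in e.scans]

    def __len__(self) -> int:
        return len(self.experiments)


# ---------------------------------------------------------------------------
# file I/O


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_thermogram(path, temperature_unit: str = "celsius",
                    energy_unit: str = "kJ") -> Thermogram:
    """Read one scan from delimited text.

    Column 1 is temperature (degC by default; pass ``temperature_unit='kelvin'``
    explicitly for kelvin files), column 2 apparent molar heat capacity
    (kJ mol^-1 K^-1 by default).  ``# key: value`` header lines populate the
    scan metadata (rate_C_per_min, role, T_prime_C, experiment, protein).
    Rows are sorted by temperature and duplicate temperatures collapsed by
    their mean.
    """
    if temperature_unit not in {"celsius", "kelvin"}:
        raise ValueError("temperature_unit must be 'celsius' or 'kelvin'")
    if energy_unit not in {"kJ", "J"}:
        raise ValueError("energy_unit must be 'kJ' or 'J'")
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split(_detect_delimiter(line))
            if len(parts) < 2:
                raise ThermogramParseError(f"{path}:{lineno}: expected two columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                # allow a single header row of column names
                if lineno <= len(meta) + 1 and not rows:
                    continue
                raise ThermogramParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
    if len(rows) < 10:
        raise ThermogramParseError(f"{path}: fewer than 10 data points")
    arr = np.asarray(rows, dtype=float)
    if not np.all(np.diff(arr[:, 0]) > 0):
        _log.warning("%s: rows not sorted by temperature; sorting", path)
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
    # collapse duplicate temperatures by mean
    T, inverse = np.unique(arr[:, 0], return_inverse=True)
    if T.size != arr.shape[0]:
        Cp = np.bincount(inverse, weights=arr[:, 1]) / np.bincount(inverse)
    else:
        Cp = arr[:, 1]
    if temperature_unit == "celsius":
        T = T + C_TO_K
    if energy_unit == "kJ":
        Cp = Cp * 1e3
    if "rate_C_per_min" not in meta and "rate_K_per_s" not in meta:
        raise ThermogramParseError(f"{path}: missing scan-rate metadata")
    rate = (float(meta["rate_K_per_s"]) if "rate_K_per_s" in meta
            else float(meta["rate_C_per_min"]) / 60.0)
    t_prime = None
    if "T_prime_C" in meta:
        t_prime = float(meta["T_prime_C"]) + C_TO_K
    elif "T_prime_K" in meta:
        t_prime = float(meta["T_prime_K"])
    return Thermogram(
        T=T, Cp=Cp, rate=rate,
        role=meta.get("role", "first"),
        T_prime=t_prime,
        experiment_id=meta.get("experiment", ""),
        protein=meta.get("protein", ""),
        meta={k: v for k, v in meta.items()
              if k not in {"rate_C_per_min", "rate_K_per_s", "role",
                           "T_prime_C", "T_prime_K", "experiment", "protein"}},
    )


def write_thermogram(tg: Thermogram, path, temperature_unit: str = "celsius",
                     energy_unit: str = "kJ", delimiter: str = ",") -> None:
    """Write a scan in the same delimited-text format ``read_thermogram`` reads."""
    buf = _stdio.StringIO()
    buf.write("# dscfit thermogram\n")
    if tg.protein:
        buf.write(f"# protein: {tg.protein}\n")
    if tg.experiment_id:
        buf.write(f"# experiment: {tg.experiment_id}\n")
    buf.write(f"# role: {tg.role}\n")
    buf.write(f"# rate_C_per_min: {tg.rate * 60.0:.10g}\n")
    if tg.T_prime is not None:
        buf.write(f"# T_prime_C: {tg.T_prime - C_TO_K:.10g}\n")
    for k, v in tg.meta.items():
        buf.write(f"# {k}: {v}\n")
    T = tg.T - C_TO_K if temperature_unit == "celsius" else tg.T
    Cp = tg.Cp / 1e3 if energy_unit == "kJ" else tg.Cp
    for t, c in zip(T, Cp):
        buf.write(f"{t:.10g}{delimiter}{c:.10g}\n")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# normalization and superimposition


def normalize_concentration(raw: Thermogram, concentration: float,
                            cell_volume: float) -> Thermogram:
    """Convert a per-cell heat signal (J K^-1) to molar heat capacity.

    Divides by the moles of protein in the cell,
    n = concentration (mol L^-1) x cell_volume (L).
    """
    if concentration <= 0 or cell_volume <= 0:
        raise ValueError("concentration and cell_volume must be positive")
    moles = concentration * cell_volume
    out = replace(raw, Cp=raw.Cp / moles)
    out.meta = {**raw.meta, "normalization_moles": moles}
    return out


def subtract_baseline_series(sample: Thermogram, buffer: Thermogram) -> Thermogram:
    """Optional buffer-buffer baseline subtraction (interpolated onto sample T)."""
    base = np.interp(sample.T, buffer.T, buffer.Cp)
    return replace(sample, Cp=sample.Cp - base)


def superimpose(experiments: ExperimentSet,
                reference_window: tuple[float, float]) -> ExperimentSet:
    """Vertically align experiments on their first runs over a window.

    One additive offset per experiment is chosen by least squares so that
    all first runs agree with the first experiment's first run over
    ``reference_window`` (a pre-transition temperature range, K).  Each
    experiment's reheats receive the same offset as their first run, so the
    dCp-carrying first/reheat shift within an experiment is preserved.
    """
    lo, hi = reference_window
    if not hi > lo:
        raise ValueError("reference_window must be (low, high) with high > low")
    ref = experiments.experiments[0].first
    ref_mask = (ref.T >= lo) & (ref.T <= hi)
    if not ref_mask.any():
        raise ValueError("reference window does not overlap the reference scan")
    out = []
    for e in experiments.experiments:
        mask = (e.first.T >= lo) & (e.first.T <= hi)
        if not mask.any():
            raise ValueError(
                f"reference window does not overlap experiment {e.experiment_id}"
            )
        Tw = e.first.T[mask]
        # least-squares additive offset: mean difference on the window
        offset = float(np.mean(np.interp(Tw, ref.T, ref.Cp) - e.first.Cp[mask]))
        if e is experiments.experiments[0]:
            offset = 0.0
        out.append(
            Experiment(
                e.experiment_id,
                e.first.shifted(offset),
                [r.shifted(offset) for r in e.reheats],
            )
        )
    return ExperimentSet(out)
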