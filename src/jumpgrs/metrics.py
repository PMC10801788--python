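"""Pruning-method comparison metrics and summary tables.

For a dataset ``d``, let ``Acc_X(d)``, ``FLOPs_X(d)``, ``Params_X(d)`` and
``Runtime_X(d)`` be the accuracy, cost counts and pruning runtime of method
``X`` (O = original unpruned model, G = GRS, J = JGRS, plus the NWM and RRS
baselines).  The signed, original-normalized comparison metrics are

* ``AL_difference  = (Acc_G - Acc_J) / Acc_O``    (positive: JGRS worse)
* ``FCI_difference = (FLOPs_G - FLOPs_J) / FLOPs_O`` (positive: JGRS better)
* ``PCI_difference = (Params_G - Params_J) / Params_O``
* ``Time_ratio     = Runtime_G / Runtime_J``       (>1: JGRS faster)

and summaries report their min/max/avg over the dataset collection.  The
signed convention keeps negative minima visible rather than folding them
into magnitudes.  Runtime is hardware-dependent; retrain-call counters are
the portable speed proxy and are carried alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethodRunRecord",
    "ComparisonSummary",
    "al_difference",
    "fci_difference",
    "pci_difference",
    "time_ratio",
    "percent_of_initial",
    "relative_lost_percent",
    "summarize",
]


@dataclass(frozen=True)
class MethodRunRecord:
    """One (method, dataset) measurement."""

    method: str          # "O" | "G" | "J" | "NWM" | "RRS"
    dataset: str
    accuracy: float
    flops: int
    params: int
    runtime: float = 0.0
    fine_tune_calls: int = 0

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if self.flops <= 0 or self.params <= 0:
            raise ValueError("cost counts must be positive")
        if self.runtime < 0:
            raise ValueError("runtime must be non-negative")


@dataclass
class MetricSummary:
    min: float
    max: float
    avg: float


@dataclass
class ComparisonSummary:
    al_difference: MetricSummary
    fci_difference: MetricSummary
    pci_difference: MetricSummary
    time_ratio: MetricSummary
    n_datasets: int = 0
    per_dataset: pd.DataFrame = field(default_factory=pd.DataFrame)


def al_difference(acc_g: float, acc_j: float, acc_o: float) -> float:
    """Signed accuracy-loss difference ``(Acc_G - Acc_J) / Acc_O``; positive
    means JGRS kept less accuracy than GRS."""
    if acc_o == 0:
        raise ZeroDivisionError("original accuracy is zero")
    return (acc_g - acc_j) / acc_o


def fci_difference(flops_g: float, flops_j: float, flops_o: float) -> float:
    """Signed FLOP-count improvement ``(FLOPs_G - FLOPs_J) / FLOPs_O``;
    positive means JGRS produced the smaller model."""
    if flops_o == 0:
        raise ZeroDivisionError("original FLOP count is zero")
    return (flops_g - flops_j) / flops_o


def pci_difference(params_g: float, params_j: float, params_o: float) -> float:
    """Signed parameter-count improvement; same convention as FCI."""
    if params_o == 0:
        raise ZeroDivisionError("original parameter count is zero")
    return (params_g - params_j) / params_o


def time_ratio(runtime_g: float, runtime_j: float) -> float:
    """``Runtime_G / Runtime_J``: above 1 means JGRS was faster."""
    if runtime_j == 0:
        raise ZeroDivisionError("JGRS runtime is zero")
    return runtime_g / runtime_j


def percent_of_initial(final: float, initial: float) -> float:
    """Pruned cost as a percentage of the unpruned cost (e.g. 27.80)."""
    if initial == 0:
        raise ZeroDivisionError("initial count is zero")
    return 100.0 * final / initial


def relative_lost_percent(original: float, pruned: float) -> float:
    """Relative accuracy lost to pruning, ``100*(orig - pruned)/orig``."""
    if original == 0:
        raise ZeroDivisionError("original accuracy is zero")
    return 100.0 * (original - pruned) / original


def _stat(values) -> MetricSummary:
    v = np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    # the mean lies in [min, max] mathematically; clamp away summation rounding
    return MetricSummary(min=lo, max=hi, avg=float(np.clip(v.mean(), lo, hi)))


def summarize(records: list[MethodRunRecord]) -> ComparisonSummary:
    """Min/max/avg of the four comparison metrics over every dataset that
    carries all of the O, G and J methods.  Datasets missing a method are
    excluded with a warning."""
    by_dataset: dict[str, dict[str, MethodRunRecord]] = {}
    for r in records:
        by_dataset.setdefault(r.dataset, {})[r.method] = r
    rows = []
    for d, methods in by_dataset.items():
        if not {"O", "G", "J"} <= set(methods):
            warnings.warn(f"dataset {d!r} missing a method; excluded from summary")
            continue
        o, g, j = methods["O"], methods["G"], methods["J"]
        rows.append({
            "dataset": d,
            "al_difference": al_difference(g.accuracy, j.accuracy, o.accuracy),
            "fci_difference": fci_difference(g.flops, j.flops, o.flops),
            "pci_difference": pci_difference(g.params, j.params, o.params),
            "time_ratio": time_ratio(g.runtime, j.runtime) if j.runtime else np.nan,
            "fine_tune_calls_g": g.fine_tune_calls,
            "fine_tune_calls_j": j.fine_tune_calls,
            "flops_pct_of_initial_j": percent_of_initial(j.flops, o.flops),
            "params_pct_of_initial_j": percent_of_initial(j.params, o.params),
            "flops_pct_of_initial_g": percent_of_initial(g.flops, o.flops),
            "params_pct_of_initial_g": percent_of_initial(g.params, o.params),
        })
    if not rows:
        raise ValueError("no dataset carries all of the O, G and J methods")
    df = pd.DataFrame(rows)
    tr = df["time_ratio"].dropna()
    return ComparisonSummary(
        al_difference=_stat(df["al_difference"]),
        fci_difference=_stat(df["fci_difference"]),
        pci_difference=_stat(df["pci_difference"]),
        time_ratio=_stat(tr) if len(tr) else MetricSummary(np.nan, np.nan, np.nan),
        n_datasets=len(df),
        per_dataset=df,
    )


def summary_to_dict(s: ComparisonSummary) -> dict:
    return {
        name: {"min": m.min, "max": m.max, "avg": m.avg}
        for name, m in (("AL_difference", s.al_difference),
                        ("FCI_difference", s.fci_difference),
                        ("PCI_difference", s.pci_difference),
                        ("Time_ratio", s.time_ratio))
    } | {"n_datasets": s.n_datasets}
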