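"""Mitochondrial respiration parameters from oxygen-consumption-rate traces.

An extracellular-flux assay measures the oxygen consumption rate (OCR) of a
well over time while inhibitors are injected sequentially: oligomycin (ATP
synthase inhibitor), FCCP (uncoupler, elicits maximal respiration), then
rotenone plus antimycin A (Complex I/III inhibitors, leaving only
non-mitochondrial oxygen consumption). Four parameters are derived:

* non-mitochondrial respiration — mean OCR after rotenone/antimycin A;
* basal respiration — the 3rd baseline measurement minus non-mitochondrial;
* maximal respiration — mean OCR after FCCP minus non-mitochondrial;
* spare capacity rate (SCR) — maximal minus basal, exactly.

Oligomycin-phase values are parsed and stored (for trace plots) but enter no
parameter formula. Rates are normalized to protein content before analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PHASES = ("baseline", "oligomycin", "fccp", "rot_anti")
PARAM_NAMES = ("non_mito", "basal", "maximal", "scr")


@dataclass
class OCRTrace:
    """Phase-labeled OCR time course for one well."""

    well: str
    group: str
    times: np.ndarray          # minutes
    ocr: np.ndarray            # pmol O2/min (per µg protein once normalized)
    phases: list[str]
    protein: float | None = None   # µg
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        if not (len(self.times) == len(self.ocr) == len(self.phases)):
            raise ValueError("times, ocr and phases must have equal length")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase label(s): {sorted(unknown)}")
        order = [PHASES.index(p) for p in self.phases]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError(
                "phases must appear in baseline -> oligomycin -> fccp -> "
                "rot_anti order"
            )

    def phase_values(self, phase: str) -> np.ndarray:
        return self.ocr[[p == phase for p in self.phases]]


@dataclass
class RespirationParams:
    """The four derived respiration parameters (scr = maximal − basal)."""

    non_mito: float
    basal: float
    maximal: float
    scr: float

    def __post_init__(self) -> None:
        # exact identity, not a tolerance check
        if self.scr != self.maximal - self.basal:
            raise ValueError("scr must equal maximal - basal exactly")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PARAM_NAMES}


def read_ocr_table(path, sep: str | None = None) -> list[OCRTrace]:
    """Read OCR traces from a CSV/TSV with columns
    well, group, time, phase, ocr[, protein]."""
    df = pd.read_csv(path, sep=sep, engine="python")
    required = {"well", "group", "time", "phase", "ocr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    traces = []
    for well, sub in df.groupby("well", sort=False):
        sub = sub.sort_values("time")
        protein = None
        if "protein" in sub.columns and sub["protein"].notna().any():
            protein = float(sub["protein"].dropna().iloc[0])
        traces.append(OCRTrace(
            well=str(well),
            group=str(sub["group"].iloc[0]),
            times=sub["time"].to_numpy(),
            ocr=sub["ocr"].to_numpy(),
            phases=[str(p) for p in sub["phase"]],
            protein=protein,
        ))
    return traces


def normalize_trace(trace: OCRTrace) -> OCRTrace:
    """Divide every OCR value by the well's protein content (µg).

    A second normalization is an error (the trace carries a flag); a trace
    without a protein value is returned unchanged with a warning.
    """
    if trace.normalized:
        raise ValueError(f"trace {trace.well} is already protein-normalized")
    if trace.protein is None or not trace.protein > 0:
        warnings.warn(
            f"trace {trace.well}: no positive protein value; not normalized"
        )
        return trace
    return replace(trace, ocr=trace.ocr / trace.protein, normalized=True)


def derive_params(trace: OCRTrace) -> RespirationParams:
    """Derive the four respiration parameters from a phase-labeled trace.

    Requires ≥3 baseline points (the 3rd is the basal reference — the last
    and most stabilized pre-injection measurement) and non-empty FCCP and
    rotenone/antimycin phases.
    """
    baseline = trace.phase_values("baseline")
    fccp = trace.phase_values("fccp")
    rot_anti = trace.phase_values("rot_anti")
    if len(baseline) < 3:
        raise ValueError(f"trace {trace.well}: need >=3 baseline points, "
                         f"got {len(baseline)}")
    if len(fccp) == 0 or len(rot_anti) == 0:
        raise ValueError(f"trace {trace.well}: empty fccp or rot_anti phase")
    non_mito = float(np.mean(rot_anti))
    basal = float(baseline[2] - non_mito)
    maximal = float(np.mean(fccp) - non_mito)
    return RespirationParams(non_mito=non_mito, basal=basal, maximal=maximal,
                             scr=maximal - basal)


def params_table(traces: Iterable[OCRTrace]) -> pd.DataFrame:
    """Per-well parameter table (well, group, the four parameters)."""
    rows = []
    for t in traces:
        p = derive_params(t)
        rows.append({"well": t.well, "group": t.group, **p.as_dict()})
    return pd.DataFrame(rows)


def compare_groups(
    params: pd.DataFrame,
    welch: bool = False,
) -> pd.DataFrame:
    """Group means ± SD and two-sided unpaired t-tests per parameter.

    Pooled-variance (Student's) t-test by default; set ``welch=True`` for
    unequal variances. All group pairs are compared. A pair involving a
    single-well group gets descriptive output only (no test).
    """
    groups = list(dict.fromkeys(params["group"]))
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        for name in PARAM_NAMES:
            a = params.loc[params["group"] == g1, name].to_numpy(dtype=float)
            b = params.loc[params["group"] == g2, name].to_numpy(dtype=float)
            row = {
                "parameter": name, "group_1": g1, "group_2": g2,
                "mean_1": a.mean(), "sd_1": a.std(ddof=1) if len(a) > 1 else np.nan,
                "mean_2": b.mean(), "sd_2": b.std(ddof=1) if len(b) > 1 else np.nan,
                "n_1": len(a), "n_2": len(b),
            }
            if len(a) >= 2 and len(b) >= 2:
                if np.ptp(np.concatenate([a, b])) == 0:
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_ind(a, b, equal_var=not welch)
                row["t"] = float(t)
                row["p_value"] = float(p)
            else:
                row["t"] = np.nan
                row["p_value"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
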