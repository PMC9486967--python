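"""Phenotypic benchmarking readout analysis.

The screen measures growth of sRNA-expression strains in a plate
reader under an antibiotic challenge, with and without the inducer
(l-arabinose).  Because β-lactam-induced filamentation makes growth
curves too irregular for parametric fits, growth is summarized by the
empirical area under the OD600 curve (trapezoid rule) and the effect
statistic is the log2 fold-change of induced vs. uninduced AUC.
MIC calling follows broth microdilution (2.5-fold series); reporter
fluorescence is background-corrected and OD-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssayError


@dataclass
class GrowthCurve:
    """An OD600 time series with assay metadata."""

    times: np.ndarray  # hours, strictly ascending
    od: np.ndarray     # background-corrected OD600, >= 0
    strain: str = ""
    oxacillin: float = 0.0  # µg/mL
    induced: bool = False   # +l-arabinose

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size < 2 or self.times.size != self.od.size:
            raise AssayError("growth curve needs >= 2 matched (time, OD) points")
        if np.any(np.diff(self.times) <= 0):
            raise AssayError("time points must be strictly ascending")
        if np.any(self.od < 0):
            raise AssayError("negative OD after background correction")


def auc(curve: GrowthCurve) -> float:
    """Empirical trapezoidal area under the OD600 curve (OD·h)."""
    return float(np.trapezoid(curve.od, curve.times))


def log2fc(auc_plus: float, auc_minus: float) -> float:
    """log2(AUC+ara / AUC-ara); antisymmetric under swapping the arms."""
    if auc_plus <= 0 or auc_minus <= 0:
        raise AssayError("AUC values must be positive for a log fold-change")
    return float(np.log2(auc_plus / auc_minus))


@dataclass
class ScreenResult:
    strain: str
    oxacillin: float
    auc_plus: float
    auc_minus: float
    log2fc: float
    n_replicates: int


@dataclass
class MICResult:
    """MIC (µg/mL) or a ">max" sentinel when nothing inhibits growth."""

    mic: float | str
    series: list[tuple[float, float, bool]]  # (conc, endpoint OD, growth?)
    flags: list[str] = field(default_factory=list)


def mic_call(
    series: list[tuple[float, float]],
    control_od: float,
    threshold_frac: float = 0.1,
) -> MICResult:
    """MIC from a broth dilution series of (concentration, endpoint OD).

    Growth at a concentration means endpoint OD >= threshold_frac x
    the no-drug control endpoint.  The MIC is the lowest concentration
    with no growth such that all higher concentrations also show no
    growth; an inverted well below a no-growth run is flagged and the
    topmost contiguous no-growth run decides.
    """
    if control_od is None:
        raise AssayError("no-drug growth control is required")
    if not series:
        raise AssayError("empty dilution series")
    if control_od <= 0:
        raise AssayError("invalid assay: the no-drug growth control shows no growth")
    cutoff = threshold_frac * control_od
    ordered = sorted(series, key=lambda t: -t[0])
    annotated = [(c, od, od >= cutoff) for c, od in ordered]
    flags: list[str] = []

    growth_flags = [g for _, _, g in annotated]
    if growth_flags[0]:
        mic: float | str = f">{ordered[0][0]:g}"
    else:
        run_end = 0
        while run_end < len(annotated) and not growth_flags[run_end]:
            run_end += 1
        mic = annotated[run_end - 1][0]
        if any(not g for g in growth_flags[run_end:]):
            flags.append(
                "non-monotone series: no-growth wells below a growth well; "
                "MIC taken from the topmost no-growth run"
            )
    return MICResult(mic=mic, series=annotated, flags=flags)


def normalize_fluorescence(f: float, od: float, f_blank: float, od_blank: float) -> float:
    """Background-corrected fluorescence per unit OD600."""
    if od <= od_blank:
        raise AssayError("culture OD must exceed the blank OD")
    return (f - f_blank) / (od - od_blank)


def correlate_energy_phenotype(energies, log2fcs) -> float:
    """Pearson r between predicted binding energies and screen log2FCs."""
    x = np.asarray(energies, dtype=float)
    y = np.asarray(log2fcs, dtype=float)
    if x.size != y.size or x.size < 3:
        raise AssayError("need equal-length vectors of >= 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AssayError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class GroupComparison:
    method: str
    statistic: float
    pvalue: float
    posthoc: pd.DataFrame | None = None


def compare_groups(*groups) -> GroupComparison:
    """Two groups → Student's t-test; more → one-way ANOVA + Tukey HSD."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise AssayError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise AssayError("each group needs >= 2 observations")
    if len(arrays) == 2:
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        return GroupComparison("t-test", float(res.statistic), float(res.pvalue))
    f = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group_a": i,
                    "group_b": j,
                    "statistic": float(tk.statistic[i][j]),
                    "pvalue": float(tk.pvalue[i][j]),
                }
            )
    return GroupComparison(
        "anova+tukey", float(f.statistic), float(f.pvalue), posthoc=pd.DataFrame(rows)
    )


# ---------------------------------------------------------------------------
# plate-reader I/O
# ---------------------------------------------------------------------------

def load_plate(growth_csv, map_csv) -> list[GrowthCurve]:
    """Long-format plate data + well map → per-well growth curves.

    ``growth_csv`` columns: time_h, well, od600 [, fluor];
    ``map_csv`` columns: well, strain, oxacillin_ug_ml, arabinose.
    """
    data = pd.read_csv(growth_csv)
    wells = pd.read_csv(map_csv)
    required = {"time_h", "well", "od600"}
    if not required <= set(data.columns):
        raise AssayError(f"growth table must have columns {sorted(required)}")
    meta = wells.set_index("well")
    curves = []
    for well, grp in data.groupby("well"):
        if well not in meta.index:
            raise AssayError(f"well {well} missing from the well map")
        grp = grp.sort_values("time_h")
        row = meta.loc[well]
        curves.append(
            GrowthCurve(
                times=grp["time_h"].to_numpy(),
                od=grp["od600"].to_numpy().clip(min=0.0),
                strain=str(row["strain"]),
                oxacillin=float(row["oxacillin_ug_ml"]),
                induced=bool(row["arabinose"]),
            )
        )
    return curves


def screen_table(curves: list[GrowthCurve]) -> pd.DataFrame:
    """Per (strain, oxacillin) screen summary: mean AUCs and log2FC."""
    rows = []
    groups: dict[tuple[str, float], dict[bool, list[float]]] = {}
    for c in curves:
        groups.setdefault((c.strain, c.oxacillin), {True: [], False: []})[c.induced].append(auc(c))
    for (strain, oxa), arms in sorted(groups.items()):
        if not arms[True] or not arms[False]:
            continue
        ap = float(np.mean(arms[True]))
        am = float(np.mean(arms[False]))
        rows.append(
            {
                "strain": strain,
                "oxacillin_ug_ml": oxa,
                "auc_plus": ap,
                "auc_minus": am,
                "log2fc": log2fc(ap, am),
                "n_replicates": min(len(arms[True]), len(arms[False])),
            }
        )
    return pd.DataFrame(rows)
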