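"""Anaerobic/aerobic cycle accounting for GAO enrichment reactors.

The phenotype of a glycogen-accumulating metabolism (GAM) is read off a
single anaerobic–aerobic cycle: acetate (the VFA) is taken up
anaerobically while intracellular glycogen is consumed and PHB/PHV are
formed, with essentially no phosphate release; aerobically the PHAs are
respired and glycogen is replenished.  The classical dimensionless
yields are expressed per C-mol of VFA taken up (mol-P for phosphorus):

    P/VFA, Gly/VFA, PHB/VFA, PHV/VFA, PHAs/VFA, PHV/PHB

Carbon-mol is the basis used by the GAO/PAO models this module compares
against; it is the only basis under which mass deltas in g/gSS reduce
to the dimensionless ratios of those models.  Monomer constants:
acetate C2H4O2 (60.05 g/mol), glucosyl unit of glycogen C6H10O5
(162.14), PHB monomer C4H6O2 (86.09), PHV monomer C5H8O2 (100.12);
phosphorus is tracked as mol P (31.0 g/mol).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Analyte:
    name: str
    monomer_formula_mass: float  # g/mol of the monomer unit
    carbons_per_monomer: int  # mol C (or mol P for phosphate) per monomer


ANALYTES: dict[str, Analyte] = {
    "acetate": Analyte("acetate", 60.05, 2),
    "glycogen": Analyte("glycogen", 162.14, 6),
    "PHB": Analyte("PHB", 86.09, 4),
    "PHV": Analyte("PHV", 100.12, 5),
    "phosphate_P": Analyte("phosphate_P", 31.0, 1),  # mol P, not C
}

# CSV column carrying each analyte's concentration
ANALYTE_COLUMNS = {
    "acetate": "acetate_mg_L",
    "glycogen": "glycogen_g_gSS",
    "PHB": "phb_g_gSS",
    "PHV": "phv_g_gSS",
    "phosphate_P": "phosphate_mgP_L",
}

PHASES = ("anaerobic", "settle", "decant", "aerobic", "idle")

CYCLE_COLUMNS = ["time_min", "phase"] + list(ANALYTE_COLUMNS.values())


@dataclass(frozen=True)
class RatioSet:
    """The six dimensionless cycle ratios (C-mol basis, mol-P for P)."""

    p_per_vfa: float
    gly_per_vfa: float
    phb_per_vfa: float
    phv_per_vfa: float
    phas_per_vfa: float
    phv_per_phb: float

    def as_dict(self) -> dict[str, float]:
        return {
            "P/VFA": self.p_per_vfa,
            "Gly/VFA": self.gly_per_vfa,
            "PHB/VFA": self.phb_per_vfa,
            "PHV/VFA": self.phv_per_vfa,
            "PHAs/VFA": self.phas_per_vfa,
            "PHV/PHB": self.phv_per_phb,
        }

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        # + 0.0 normalises -0.0 so reports never print "-0.00"
        return {k: round(v, ndigits) + 0.0 for k, v in self.as_dict().items()}


def read_cycle(source: str | Path) -> pd.DataFrame:
    """Read a cycle CSV and validate ordering and non-negativity."""
    df = pd.read_csv(source, comment="#")
    missing = set(CYCLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cycle file missing columns: {sorted(missing)}")
    t = df["time_min"].to_numpy()
    if len(t) > 1 and not (t[1:] > t[:-1]).all():
        raise ValueError("cycle times must be strictly increasing")
    bad = set(df["phase"]) - set(PHASES)
    if bad:
        raise ValueError(f"unknown phase labels: {sorted(bad)}")
    if (df[list(ANALYTE_COLUMNS.values())] < 0).any().any():
        raise ValueError("concentrations must be non-negative")
    return df


def phase_delta(series: pd.DataFrame, analyte: str, phase: str) -> float:
    """Last-minus-first concentration of ``analyte`` over ``phase``.

    The value is signed and in the analyte's native units (g/gSS for
    intracellular polymers, mg/L for dissolved species).
    """
    col = ANALYTE_COLUMNS.get(analyte)
    if col is None:
        raise KeyError(f"unknown analyte {analyte!r}")
    rows = series[series["phase"] == phase]
    if len(rows) < 2:
        raise KeyError(f"phase {phase!r} needs >=2 rows, found {len(rows)}")
    return float(rows[col].iloc[-1] - rows[col].iloc[0])


def to_cmol(mass_delta: float, analyte: str) -> float:
    """Convert a signed mass delta (g per gSS) to C-mol (mol-P) per gSS."""
    try:
        a = ANALYTES[analyte]
    except KeyError:
        raise KeyError(f"unknown analyte {analyte!r}") from None
    return mass_delta / a.monomer_formula_mass * a.carbons_per_monomer


def gam_ratios(deltas: Mapping[str, float], vfa_uptake: float) -> RatioSet:
    """Cycle ratios from anaerobic mass deltas and the VFA uptake.

    ``deltas`` carries the signed anaerobic change of each analyte in
    g per gSS (glycogen negative when consumed, PHB/PHV positive when
    formed, phosphate_P positive when released); ``vfa_uptake`` is the
    acetate taken up, in C-mol per gSS, and must be positive.
    Consumption and release magnitudes enter the ratios as positive
    numbers.  A zero-PHB cycle with nonzero PHV leaves PHV/PHB as NaN
    with a warning.
    """
    if vfa_uptake <= 0:
        raise ValueError("vfa_uptake must be positive")
    gly = to_cmol(-deltas.get("glycogen", 0.0), "glycogen")  # consumption > 0
    phb = to_cmol(deltas.get("PHB", 0.0), "PHB")
    phv = to_cmol(deltas.get("PHV", 0.0), "PHV")
    p_rel = to_cmol(deltas.get("phosphate_P", 0.0), "phosphate_P")
    if phb == 0 and phv != 0:
        logger.warning("zero PHB formation with nonzero PHV: PHV/PHB undefined")
        phv_per_phb = math.nan
    elif phb == 0:
        phv_per_phb = math.nan
    else:
        phv_per_phb = phv / phb
    return RatioSet(
        p_per_vfa=p_rel / vfa_uptake,
        gly_per_vfa=gly / vfa_uptake,
        phb_per_vfa=phb / vfa_uptake,
        phv_per_vfa=phv / vfa_uptake,
        phas_per_vfa=(phb + phv) / vfa_uptake,
        phv_per_phb=phv_per_phb,
    )


def ratios_from_cycle(
    series: pd.DataFrame, mlss_g_per_L: float, window: str = "full"
) -> RatioSet:
    """Ratios straight from a measured cycle time series.

    ``mlss_g_per_L`` converts dissolved acetate and phosphate (mg/L) to
    a per-gSS basis.  ``window`` is ``full`` (whole anaerobic phase) or
    ``to-depletion`` (from anaerobic start until the first time acetate
    reaches zero, where the stoichiometric conversion is complete).
    """
    if mlss_g_per_L <= 0:
        raise ValueError("MLSS must be positive")
    ana = series[series["phase"] == "anaerobic"]
    if len(ana) < 2:
        raise KeyError("anaerobic phase needs >=2 rows")
    if window == "to-depletion":
        depleted = ana[ana["acetate_mg_L"] <= 0]
        if len(depleted):
            ana = ana.loc[: depleted.index[0]]
    elif window != "full":
        raise ValueError(f"unknown window {window!r}")

    def delta(col: str) -> float:
        return float(ana[col].iloc[-1] - ana[col].iloc[0])

    # dissolved species: mg/L -> g/L -> g per gSS
    acetate_g_gSS = -delta("acetate_mg_L") / 1000.0 / mlss_g_per_L
    vfa_cmol = to_cmol(acetate_g_gSS, "acetate")
    deltas = {
        "glycogen": delta("glycogen_g_gSS"),
        "PHB": delta("phb_g_gSS"),
        "PHV": delta("phv_g_gSS"),
        "phosphate_P": delta("phosphate_mgP_L") / 1000.0 / mlss_g_per_L,
    }
    return gam_ratios(deltas, vfa_cmol)


def classify_metabolism(ratios: RatioSet) -> str:
    """GAM / PAM / mixed phenotype from the P and glycogen yields.

    Thresholds reflect the spread of published enrichments: GAM-type
    cultures release essentially no phosphate (P/VFA <= 0.10) while
    consuming at least as much glycogen carbon as VFA carbon
    (Gly/VFA >= 1.0); PAM cultures release P/VFA >= 0.30.
    """
    p = ratios.p_per_vfa
    if p >= 0.30:
        return "PAM"
    if p <= 0.10 and ratios.gly_per_vfa >= 1.0:
        return "GAM"
    return "mixed"


def carbon_balance(
    pha_formed_cmol: float, vfa_consumed_cmol: float, glycogen_consumed_cmol: float
) -> float:
    """Anaerobic carbon recovery: PHA carbon over consumed carbon.

    Values below 1 are expected (CO2 loss through decarboxylation);
    above 1 indicates measurement inconsistency and is warned about.
    """
    denom = vfa_consumed_cmol + glycogen_consumed_cmol
    if denom <= 0:
        raise ValueError("no carbon consumed: balance undefined")
    frac = pha_formed_cmol / denom
    if frac > 1:
        logger.warning("carbon recovery %.3f > 1: check measurements", frac)
    return frac


# Published anaerobic cycle ratios of GAO/PAO enrichment studies, used
# as the comparison panel for a newly measured cycle.  P/VFA of the
# first row was not reported.
LITERATURE_RATIOS = pd.DataFrame(
    [
        ("Zeng 2003", "GAO", math.nan, 1.20, 1.39, 0.52, 1.91, 0.38),
        ("Lopez-Vazquez 2007", "GAO", 0.01, 1.20, 1.28, 0.69, 1.97, 0.54),
        ("Lu 2006", "PAO", 0.62, 0.46, 1.18, 0.07, 1.25, 0.06),
        ("Acevedo 2012", "PAO", 0.73, 0.35, 1.30, 0.06, 1.36, 0.05),
        ("Welles 2015", "PAOII-GAO-GAM", 0.03, 1.28, 1.45, 0.50, 1.95, 0.34),
        ("Acevedo 2012", "PAO-GAM", 0.08, 1.08, 1.74, 0.28, 2.02, 0.16),
        ("Acevedo 2017", "PAO-GAM", 0.05, 1.19, 1.31, 0.63, 1.94, 0.48),
    ],
    columns=["reference", "model", "P/VFA", "Gly/VFA", "PHB/VFA", "PHV/VFA",
             "PHAs/VFA", "PHV/PHB"],
)

_RATIO_COLS = ["P/VFA", "Gly/VFA", "PHB/VFA", "PHV/VFA", "PHAs/VFA", "PHV/PHB"]


def compare_to_literature(ratios: RatioSet) -> pd.DataFrame:
    """Append the measured row to the literature panel and flag the nearest.

    Distance is Euclidean over the six ratios, restricted to the
    dimensions a literature row reports (NaN entries are skipped).
    """
    table = LITERATURE_RATIOS.copy()
    mine = ratios.as_dict()
    dists = []
    for _, row in table.iterrows():
        sq = 0.0
        for col in _RATIO_COLS:
            ref_v, my_v = row[col], mine[col]
            if math.isnan(ref_v) or math.isnan(my_v):
                continue
            sq += (ref_v - my_v) ** 2
        dists.append(math.sqrt(sq))
    table["distance"] = dists
    table["nearest"] = table["distance"] == min(dists)
    this = {"reference": "this run", "model": classify_metabolism(ratios),
            "distance": 0.0, "nearest": False, **mine}
    return pd.concat([pd.DataFrame([this]), table], ignore_index=True)
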