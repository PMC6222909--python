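"""Thermodynamic-cycle assembly and agreement metrics.

A hydration free energy is obtained by alchemical annihilation in both
phases: dG_hyd = dG_annih(gas) - dG_annih(aq).  A low-level (MM) cycle is
promoted to a high-level target Hamiltonian by "bookend" corrections at
the two fully interacting end points:

    dG_hyd(TARGET) = dG_hyd(MM) + dG_corr(aq) - dG_corr(gas),

where each correction is a MM -> TARGET free energy computed by one of
three theoretically equivalent routes: (a) direct one-sided reweighting
(Zwanzig), (b) via a tailored MM' force field (BAR for MM -> MM', Zwanzig
for MM' -> TARGET), or (c) Non-Boltzmann Bennett combining both data sets.

Agreement with reference values is summarized by RMSD (root mean squared
deviation), MSD (mean signed deviation) and R^2, where R^2 is the square
of the Pearson correlation coefficient between predicted and reference
values (not the regression coefficient of determination).  Metrics are
reported both for all rows and for a starred subset that excludes
designated poorly converged entries.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import EstimatorError, FreeEnergyResult
from .sampling import LegResult
from .systems import ValidationError

__all__ = [
    "HydrationCycleResult",
    "CorrectedHydrationResult",
    "MetricsTable",
    "STARRED_EXCLUSIONS",
    "BOOKEND_ROUTES",
    "hydration_cycle",
    "bookend_correct",
    "metrics",
    "scale_fit",
    "load_table",
    "list_packaged_tables",
]

#: Solutes excluded from starred metrics because of high repeat SDs.
STARRED_EXCLUSIONS = ("ethanol", "acetamide")

#: The three bookend routes: direct Zwanzig, via the tailored MM' force
#: field, and Non-Boltzmann Bennett.
BOOKEND_ROUTES = ("direct", "via_mm_prime", "nbb")


def _stage_totals(leg) -> dict[str, tuple[float, float]]:
    """(delta_g, std_dev) per stage from a LegResult or FreeEnergyResult."""
    if isinstance(leg, LegResult):
        return {s: (r.delta_g, r.std_dev) for s, r in leg.stage_totals.items()}
    if isinstance(leg, FreeEnergyResult):
        stages: dict[str, float] = {}
        for w in leg.per_window:
            stage = w.window.split(":")[0] if ":" in w.window else "total"
            stages[stage] = stages.get(stage, 0.0) + w.delta_g
        return {s: (g, float("nan")) for s, g in stages.items()}
    raise ValidationError(f"unsupported leg type {type(leg).__name__}")


def _leg_total(leg) -> tuple[float, float, int]:
    if isinstance(leg, LegResult):
        return leg.delta_g, leg.std_dev, leg.result.n_repeats
    return leg.delta_g, leg.std_dev, leg.n_repeats


@dataclass
class HydrationCycleResult:
    """Two-phase annihilation combined into a hydration free energy.

    ``dg_hyd = dg_annih_gas - dg_annih_aq``; SDs combine in quadrature.
    """

    dg_annih_gas: float
    dg_annih_aq: float
    dg_hyd: float
    stages: dict = field(default_factory=dict)  # stage -> {"gas": dg, "aq": dg}
    repeats: int = 1
    sd_gas: float = 0.0
    sd_aq: float = 0.0

    @property
    def sd_hyd(self) -> float:
        return math.hypot(self.sd_gas, self.sd_aq)

    def __post_init__(self) -> None:
        if abs(self.dg_hyd - (self.dg_annih_gas - self.dg_annih_aq)) > 1e-9:
            raise ValidationError("dg_hyd must equal dg_annih_gas - dg_annih_aq")


def hydration_cycle(gas_leg, aq_leg) -> HydrationCycleResult:
    """Combine gas- and aqueous-phase annihilation legs.

    Both legs must cover the same stages (charge + vdW in the full
    protocol).  Accepts :class:`~bookend.sampling.LegResult` or plain
    :class:`~bookend.estimators.FreeEnergyResult` objects.
    """
    st_gas = _stage_totals(gas_leg)
    st_aq = _stage_totals(aq_leg)
    if set(st_gas) != set(st_aq):
        raise ValidationError(
            f"stage mismatch between legs: gas {sorted(st_gas)} vs aqueous {sorted(st_aq)}"
        )
    g_gas, sd_gas, rep_gas = _leg_total(gas_leg)
    g_aq, sd_aq, rep_aq = _leg_total(aq_leg)
    return HydrationCycleResult(
        dg_annih_gas=g_gas,
        dg_annih_aq=g_aq,
        dg_hyd=g_gas - g_aq,
        stages={s: {"gas": st_gas[s][0], "aq": st_aq[s][0]} for s in st_gas},
        repeats=min(rep_gas, rep_aq),
        sd_gas=sd_gas,
        sd_aq=sd_aq,
    )


@dataclass
class CorrectedHydrationResult:
    """An MM hydration free energy promoted to the target level."""

    dg_hyd_mm: float
    dg_corr_gas: float
    dg_corr_aq: float
    dg_hyd_target: float
    route: str
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.route not in BOOKEND_ROUTES:
            raise ValidationError(f"route must be one of {BOOKEND_ROUTES}")
        expected = self.dg_hyd_mm + self.dg_corr_aq - self.dg_corr_gas
        if abs(self.dg_hyd_target - expected) > 1e-9:
            raise ValidationError("corrected cycle does not close")


def bookend_correct(
    mm_cycle: HydrationCycleResult,
    gas_corr: FreeEnergyResult,
    aq_corr: FreeEnergyResult,
    route: str = "direct",
) -> CorrectedHydrationResult:
    """Promote an MM hydration cycle using end-point corrections.

    ``gas_corr`` and ``aq_corr`` are MM -> TARGET free energies computed on
    fully interacting end-point ensembles of each phase; the route tag
    records which of the three equivalent estimation routes produced them.
    """
    if gas_corr is None or aq_corr is None:
        raise ValidationError("both gas and aqueous corrections are required")
    dg = mm_cycle.dg_hyd + aq_corr.delta_g - gas_corr.delta_g
    sd = math.sqrt(mm_cycle.sd_hyd ** 2 + gas_corr.std_dev ** 2 + aq_corr.std_dev ** 2)
    return CorrectedHydrationResult(
        dg_hyd_mm=mm_cycle.dg_hyd,
        dg_corr_gas=gas_corr.delta_g,
        dg_corr_aq=aq_corr.delta_g,
        dg_hyd_target=dg,
        route=route,
        sd=sd,
    )


# ---------------------------------------------------------------------------
# Agreement metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsTable:
    """Predicted-vs-reference summary.

    ``rows`` are (label, reference, predicted, sd) tuples; summary metrics
    are computed on all rows and, when exclusions apply, on the starred
    subset as well.
    """

    rows: list[tuple[str, float, float, float]]
    rmsd: float
    msd: float
    r2: float
    starred_exclusions: list[str] = field(default_factory=list)
    rmsd_starred: float | None = None
    msd_starred: float | None = None
    r2_starred: float | None = None

    def __post_init__(self) -> None:
        if self.rmsd < abs(self.msd) - 1e-12:
            raise ValidationError("rmsd must be >= |msd|")
        if not -1e-12 <= self.r2 <= 1.0 + 1e-12:
            raise ValidationError("r2 must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "rmsd": self.rmsd,
            "msd": self.msd,
            "r2": self.r2,
            "rmsd_starred": self.rmsd_starred,
            "msd_starred": self.msd_starred,
            "r2_starred": self.r2_starred,
            "starred_exclusions": list(self.starred_exclusions),
            "n_rows": len(self.rows),
        }


def _summary(ref: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    d = pred - ref
    rmsd = float(np.sqrt(np.mean(d ** 2)))
    msd = float(np.mean(d))
    r2 = float(np.corrcoef(pred, ref)[0, 1] ** 2)
    return rmsd, msd, r2


def metrics(
    table_rows: Sequence[tuple],
    exclusions: Sequence[str] = (),
) -> MetricsTable:
    """RMSD / MSD / R^2 of predictions against references.

    ``table_rows`` holds (label, reference, predicted[, sd]) tuples; at
    least two rows must survive the exclusion filter (the correlation is
    undefined otherwise).
    """
    rows = []
    for row in table_rows:
        label, ref, pred = row[0], float(row[1]), float(row[2])
        sd = float(row[3]) if len(row) > 3 else 0.0
        rows.append((label, ref, pred, sd))
    kept = [r for r in rows if r[0] not in exclusions]
    if len(kept) < 2:
        raise ValidationError("need at least 2 rows after exclusions (correlation undefined)")
    ref_all = np.array([r[1] for r in rows])
    pred_all = np.array([r[2] for r in rows])
    rmsd, msd, r2 = _summary(ref_all, pred_all)
    out = MetricsTable(rows, rmsd, msd, r2, starred_exclusions=list(exclusions))
    if exclusions:
        ref_s = np.array([r[1] for r in kept])
        pred_s = np.array([r[2] for r in kept])
        out.rmsd_starred, out.msd_starred, out.r2_starred = _summary(ref_s, pred_s)
    return out


def scale_fit(table_rows: Sequence[tuple]) -> tuple[float, MetricsTable]:
    """Least-squares multiplicative correction of systematic over/under-
    binding: s = sum(ref * pred) / sum(pred^2), applied to the predictions.
    This is the simplest one-parameter empirical rescaling; the returned
    table carries the post-fit metrics."""
    rows = [(r[0], float(r[1]), float(r[2])) for r in table_rows]
    if len(rows) < 2:
        raise ValidationError("need at least 2 rows")
    pred = np.array([r[2] for r in rows])
    ref = np.array([r[1] for r in rows])
    denom = float(np.sum(pred ** 2))
    if denom == 0.0:
        raise EstimatorError("all predictions are zero; the scale factor is undefined")
    s = float(np.sum(ref * pred) / denom)
    rescaled = [(label, r, s * p) for (label, r, p) in rows]
    return s, metrics(rescaled)


# ---------------------------------------------------------------------------
# Packaged table fixtures
# ---------------------------------------------------------------------------

_PM = re.compile(r"\s*±\s*")


def _parse_cell(cell: str) -> tuple[float, float]:
    """'−6.91 ± 0.04' -> (-6.91, 0.04); plain numbers get sd 0."""
    text = str(cell).replace("−", "-").strip()
    parts = _PM.split(text)
    value = float(parts[0])
    sd = float(parts[1]) if len(parts) > 1 else 0.0
    return value, sd


def list_packaged_tables() -> list[str]:
    root = importlib.resources.files("bookend") / "data"
    return sorted(p.name.removesuffix(".tsv") for p in root.iterdir() if p.name.endswith(".tsv"))


def load_table(name_or_path) -> pd.DataFrame:
    """Load a printed-table fixture.

    ``name_or_path`` is either a packaged fixture name (``table1`` ...
    ``table5``) or a path to a TSV/CSV with the same layout: a ``molecule``
    column, a reference column, and value columns whose cells may carry
    ``value ± sd``.  Returns a DataFrame with numeric ``<col>`` and
    ``<col>_sd`` columns; the unicode minus is normalized on read.
    """
    path = Path(str(name_or_path))
    if not path.exists():
        resource = importlib.resources.files("bookend") / "data" / f"{name_or_path}.tsv"
        if not resource.is_file():
            raise FileNotFoundError(
                f"no such fixture {name_or_path!r}; packaged: {list_packaged_tables()}"
            )
        raw = pd.read_csv(resource.open("r"), sep="\t", dtype=str)
    else:
        raw = pd.read_csv(path, sep="\t" if path.suffix == ".tsv" else ",", dtype=str)
    out = pd.DataFrame({"molecule": raw.iloc[:, 0].str.strip()})
    for col in raw.columns[1:]:
        parsed = raw[col].map(_parse_cell)
        out[col] = [v for v, _ in parsed]
        sds = np.array([s for _, s in parsed])
        if np.any(sds != 0.0):
            out[f"{col}_sd"] = sds
    return out
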