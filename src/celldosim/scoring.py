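"""Tally aggregation: per-region energy deposits, batch statistics, dose
conversion, relative enhancement and linearity fits.

Reporting conventions follow the usual microdosimetry tabulation for this
kind of experiment: the "cell" row is the sum over membrane, cytosol,
nucleus, mitochondria and nanoparticles; the "cytosol" row excludes the
nanoparticle deposit, while "cytosol_with_np" includes it (both are
reported because published tables use the inclusive convention and figures
the exclusive one); mitochondria and nanoparticle energies are sums over
all objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .geometry import (ROLE_CYTOSOL, ROLE_MEMBRANE, ROLE_MITOCHONDRION,
                       ROLE_NANOPARTICLE, ROLE_NUCLEUS, CellGeometry)

MEMBER_ROLES = (ROLE_MEMBRANE, ROLE_CYTOSOL, ROLE_NUCLEUS,
                ROLE_MITOCHONDRION, ROLE_NANOPARTICLE)
REPORT_REGIONS = ("cell", "cytosol_with_np") + MEMBER_ROLES


@dataclass
class EnergyTally:
    """Energy deposits (eV) of one simulation batch, by region role, plus
    per-object breakdowns for mitochondria and nanoparticles."""

    n_decays: int
    energy: dict = field(default_factory=lambda: {r: 0.0 for r in MEMBER_ROLES})
    mito_energy: np.ndarray | None = None
    np_energy: np.ndarray | None = None
    escaped: float = 0.0

    @property
    def cell(self) -> float:
        """Total deposit in the cell: sum of all member regions (the
        nanoparticle deposit is part of the cell and of the inclusive
        cytosol, matching the tabulation convention)."""
        return sum(self.energy[r] for r in MEMBER_ROLES)

    def value(self, region: str) -> float:
        if region == "cell":
            return self.cell
        if region == "cytosol_with_np":
            return self.energy[ROLE_CYTOSOL] + self.energy[ROLE_NANOPARTICLE]
        return self.energy[region]

    def per_decay(self, region: str) -> float:
        return self.value(region) / self.n_decays


@dataclass
class RunSummary:
    """Mean and sample standard deviation (eV/decay) over batches."""

    mean: dict  # region -> eV/decay
    sd: dict | None  # region -> eV/decay, None for a single batch
    n_batches: int
    n_decays: int  # per batch


@dataclass
class EnhancementResult:
    x_values: np.ndarray  # targeted fractions
    energy: dict  # region -> array of eV/decay, one per x
    energy_sd: dict  # region -> array of eV/decay (batch SD)
    e_rel: dict  # region -> array of percent, 100 * E(x)/E(0)
    fits: dict  # region -> (slope eV/decay per unit x, intercept, r2)


def summarize(batches: list[EnergyTally]) -> RunSummary:
    """Mean and sample SD (n-1 denominator) of per-decay deposits across
    batches.  All batches must share the same number of decays."""
    if not batches:
        raise ValueError("need at least one batch")
    n_set = {b.n_decays for b in batches}
    if len(n_set) > 1:
        raise ValueError(f"batches have unequal n_decays: {sorted(n_set)}")
    values = {r: np.array([b.per_decay(r) for b in batches])
              for r in REPORT_REGIONS}
    mean = {r: float(v.mean()) for r, v in values.items()}
    sd = None
    if len(batches) >= 2:
        sd = {r: float(v.std(ddof=1)) for r, v in values.items()}
    return RunSummary(mean, sd, len(batches), batches[0].n_decays)


def dose_gy(total_energy_ev: float, region_mass_kg: float) -> float:
    """Absorbed dose in gray from a total deposit in eV and a mass in kg."""
    if region_mass_kg <= 0:
        raise ValueError("region mass must be positive")
    return total_energy_ev * C.EV_TO_JOULE / region_mass_kg


def cell_dose_gy(ev_per_decay: float, n_decays: float,
                 geom: CellGeometry) -> float:
    """Whole-cell dose after ``n_decays`` decays at the given mean deposit."""
    return dose_gy(ev_per_decay * n_decays, geom.cell_mass_kg())


def relative_enhancement(summary_x: RunSummary, summary_0: RunSummary,
                         regions=REPORT_REGIONS) -> dict:
    """Relative energy deposit 100 * E(x) / E(0) per region, in percent.
    E(0) is the all-nanoparticles-random baseline."""
    out = {}
    for region in regions:
        baseline = summary_0.mean[region]
        if baseline <= 0:
            raise ValueError(f"zero baseline deposit in region {region!r}")
        out[region] = 100.0 * summary_x.mean[region] / baseline
    return out


def linearity_fit(x_values, y_values) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R^2).

    R^2 = 1 - SS_res/SS_tot; for degenerate exactly-constant y (SS_tot = 0)
    the fit is perfect by convention and R^2 = 1.  Constant x is an error.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("x values are constant; no line can be fitted")
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def enhancement_from_sweep(x_values, summaries: list[RunSummary]) -> EnhancementResult:
    """Assemble E(x), E_rel(x) and per-region linear fits from the summaries
    of a targeting sweep (x = fraction of nanoparticles at the target)."""
    x = np.asarray(x_values, dtype=float)
    if len(x) != len(summaries):
        raise ValueError("one summary per x value required")
    order = np.argsort(x)
    x = x[order]
    summaries = [summaries[i] for i in order]
    if x[0] != 0.0:
        raise ValueError("sweep must include the x = 0 baseline")
    energy, energy_sd, e_rel, fits = {}, {}, {}, {}
    for region in REPORT_REGIONS:
        e = np.array([s.mean[region] for s in summaries])
        energy[region] = e
        energy_sd[region] = np.array(
            [math.nan if s.sd is None else s.sd[region] for s in summaries])
        e_rel[region] = 100.0 * e / e[0]
        fits[region] = linearity_fit(x, e)
    return EnhancementResult(x, energy, energy_sd, e_rel, fits)


def summary_frame(summaries: dict[str, RunSummary]):
    """Long-format DataFrame of run summaries: one row per condition and
    region with columns (condition, region, mean_eV_per_decay, sd,
    n_batches, n_decays)."""
    import pandas as pd

    rows = []
    for condition, s in summaries.items():
        for region in REPORT_REGIONS:
            rows.append({
                "condition": condition,
                "region": region,
                "mean_eV_per_decay": s.mean[region],
                "sd": math.nan if s.sd is None else s.sd[region],
                "n_batches": s.n_batches,
                "n_decays": s.n_decays,
            })
    return pd.DataFrame(rows)


def enhancement_frame(result: EnhancementResult):
    """Long-format DataFrame of a targeting sweep keyed by x."""
    import pandas as pd

    rows = []
    for region in REPORT_REGIONS:
        for i, x in enumerate(result.x_values):
            rows.append({
                "x": x,
                "region": region,
                "E_eV_per_decay": result.energy[region][i],
                "sd": result.energy_sd[region][i],
                "E_rel_percent": result.e_rel[region][i],
                "fit_slope": result.fits[region][0],
                "fit_intercept": result.fits[region][1],
                "fit_r2": result.fits[region][2],
            })
    return pd.DataFrame(rows)
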