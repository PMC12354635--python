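"""Probit analysis of dose-response mortality and LC50 estimation.

The classical Bliss probit method: observed mortality fractions are mapped
through the inverse standard-normal quantile with a +5 offset (so probit 5
corresponds to 50% mortality), concentrations are log10-transformed, and an
ordinary least-squares line ``probit = slope * log10(c) + intercept`` is
fitted.  The LC50 is the concentration where the line crosses probit 5:

    LC50 = 10 ** ((5 - intercept) / slope)

Doses with 0% or 100% observed mortality carry no probit information on
this scale (the transform diverges); they are excluded from the fit and
reported, not continuity-corrected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import stats

from .synthetic import DoseResponseTable

PROBIT_OFFSET = 5.0


class FitError(ValueError):
    """Raised when the probit line cannot be fitted."""


def probit_transform(p: float | np.ndarray) -> float | np.ndarray:
    """Probit of a mortality fraction: ``Phi^-1(p) + 5``.

    Defined only for 0 < p < 1; exact 0/1 fractions are an excluded-row
    signal handled by :func:`fit_probit_line`, so they raise here too.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("mortality fraction must lie in [0, 1]")
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("probit is undefined at 0% or 100% mortality (row excluded from fits)")
    out = stats.norm.ppf(arr) + PROBIT_OFFSET
    return float(out) if np.isscalar(p) else out


@dataclasses.dataclass(frozen=True)
class ProbitFit:
    """Fitted log10-dose/probit line."""

    slope: float
    intercept: float
    r_squared: float
    included_rows: tuple[int, ...]
    excluded_rows: tuple[int, ...]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self) | {"lc50": lc50_from_fit(self)}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def fit_probit_line(table: DoseResponseTable) -> ProbitFit:
    """OLS of probit(mortality fraction) on log10(concentration).

    Rows with 0% or 100% mortality are excluded (and reported on the fit);
    at least two usable rows are required.
    """
    frac = table.mortality_fraction
    usable = (frac > 0) & (frac < 1)
    included = np.flatnonzero(usable)
    excluded = np.flatnonzero(~usable)
    if len(included) < 2:
        raise FitError(
            f"need at least 2 doses with partial mortality, found {len(included)}"
        )
    x = np.log10(table.concentration[included])
    y = probit_transform(frac[included])
    if np.allclose(x, x[0]):
        raise FitError("all usable doses have the same concentration")
    res = stats.linregress(x, y)
    return ProbitFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        included_rows=tuple(int(i) for i in included),
        excluded_rows=tuple(int(i) for i in excluded),
    )


def lc50_from_fit(fit: ProbitFit) -> float:
    """Concentration at probit 5: ``10 ** ((5 - intercept) / slope)``."""
    if fit.slope == 0:
        raise FitError("zero slope: LC50 is undefined")
    return float(10.0 ** ((PROBIT_OFFSET - fit.intercept) / fit.slope))


def estimate_lc50(table: DoseResponseTable) -> tuple[float, ProbitFit]:
    """Convenience wrapper: fit the line and read off the LC50."""
    fit = fit_probit_line(table)
    return lc50_from_fit(fit), fit


def plot_fit(table: DoseResponseTable, fit: ProbitFit, path: str | Path) -> None:
    """Observed mortality fraction (Fa) vs dose with the fitted probit curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(table.concentration, table.mortality_fraction, "o", label="observed Fa")
    grid = np.logspace(
        np.log10(table.concentration.min()), np.log10(table.concentration.max()), 200
    )
    curve = stats.norm.cdf(fit.slope * np.log10(grid) + fit.intercept - PROBIT_OFFSET)
    ax.plot(grid, curve, "-", label="probit fit")
    lc50 = lc50_from_fit(fit)
    ax.axvline(lc50, color="grey", ls="--", lw=1, label=f"LC50 = {lc50:.3g} mg/mL")
    ax.axhline(0.5, color="grey", ls=":", lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("concentration [mg/mL]")
    ax.set_ylabel("mortality fraction (Fa)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
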