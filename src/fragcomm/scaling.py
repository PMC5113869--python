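"""Species-area / species-abundance scaling and fragment-level correlations.

The species-area relationship (SAR) is fitted in the common power-function
form S = S0 * A**z by ordinary least squares on the log-log scale (natural
logarithms).  Under a pure power-law SAR the species density
S_A = S / A**z is constant across fragments, so deviations of S_A flag
fragments that are richer or poorer than their area predicts.  Specialist
richness is related to log area / log abundance by a logarithmic
regression S = a*ln(x) + b, and simple Pearson tests relate richness to
the fragment metadata (perimeter, isolation, forest cover).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import FragmentTable, ValidationError

__all__ = [
    "PowerFit",
    "LogFit",
    "power_fit",
    "log_fit",
    "species_density",
    "density_table",
    "pearson_test",
    "DEFAULT_SAR_EXPONENT",
]

#: SAR exponent used for area-corrected species densities, from the
#: empirical all-species fit S = 12.4 * A**0.21.
DEFAULT_SAR_EXPONENT = 0.21


@dataclass
class PowerFit:
    """S = S0 * x**z fitted by OLS of ln S on ln x."""

    s0: float
    z: float
    r_squared: float
    p_slope: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.s0 * np.asarray(x, dtype=float) ** self.z


@dataclass
class LogFit:
    """S = a * ln(x) + b fitted by OLS."""

    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.log(np.asarray(x, dtype=float)) + self.intercept


def _check_positive(x: np.ndarray, name: str) -> None:
    if (x <= 0).any():
        i = int(np.argmax(x <= 0))
        raise ValidationError(f"nonpositive {name} at record {i}")


def power_fit(x: np.ndarray, s: np.ndarray) -> PowerFit:
    """Log-log OLS power-law fit; slope p from the t distribution, df n-2."""
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(x) < 3 or len(x) != len(s):
        raise ValidationError("need >= 3 paired positive observations")
    _check_positive(x, "x")
    _check_positive(s, "richness")
    r = stats.linregress(np.log(x), np.log(s))
    return PowerFit(
        s0=float(np.exp(r.intercept)),
        z=float(r.slope),
        r_squared=float(r.rvalue**2),
        p_slope=float(r.pvalue),
        n=len(x),
    )


def log_fit(x: np.ndarray, s: np.ndarray) -> LogFit:
    """OLS of S on ln(x)."""
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if len(x) < 3 or len(x) != len(s):
        raise ValidationError("need >= 3 paired observations")
    _check_positive(x, "x")
    r = stats.linregress(np.log(x), s)
    return LogFit(
        slope=float(r.slope),
        intercept=float(r.intercept),
        r_squared=float(r.rvalue**2),
        p_slope=float(r.pvalue),
        n=len(x),
    )


def species_density(s: float | np.ndarray, a: float | np.ndarray, z: float = DEFAULT_SAR_EXPONENT) -> float | np.ndarray:
    """Area-corrected richness S_A = S / A**z."""
    a = np.asarray(a, dtype=float)
    if (a <= 0).any():
        raise ValidationError("area must be positive")
    out = np.asarray(s, dtype=float) / a**z
    return float(out) if out.ndim == 0 else out


def density_table(fragments: FragmentTable, z: float = DEFAULT_SAR_EXPONENT) -> pd.DataFrame:
    """Species density per fragment from the metadata table's richness."""
    t = fragments.table
    return pd.DataFrame(
        {
            "fragment_id": t["fragment_id"],
            "S": t["richness"],
            "A": t["area"],
            "z": z,
            "S_A": species_density(t["richness"].to_numpy(), t["area"].to_numpy(), z),
        }
    )


def pearson_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, df n-2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValidationError("need >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in a correlated variable")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
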