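"""Sloan neutral community model fit to occurrence-frequency data.

The model predicts, for a taxon with metacommunity relative abundance p, the
fraction of local communities in which it is detected:

    f_hat(p) = 1 - I_d(Nm * p, Nm * (1 - p))

where I is the regularised incomplete beta function, d the detection limit
(default one read at the rarefied depth, 1/N) and Nm the product of local
community size and immigration rate.  Nm is estimated by nonlinear least
squares of f_hat against observed detection frequencies; goodness of fit is
R^2 about the mean, and uncertainty comes from a taxon bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .io import FeatureTable

__all__ = [
    "occurrence_frequency",
    "predicted_frequency",
    "fit_ncm",
    "ncm_confidence",
    "NCMFit",
]

_LOG_NM_BOUNDS = (0.0, np.log(1e7))


def _occurrence_curve(p: np.ndarray, nm: float, N: int, d: float, detection: str):
    """Model occurrence frequency under either detection model.

    ``"sampling"`` is the exact probability of seeing >= 1 read among N
    drawn from a Beta(Nm*p, Nm*(1-p)) composition, 1 - B(a, b+N)/B(a, b);
    ``"threshold"`` is the classic tail approximation P(x > d).
    """
    if detection == "threshold":
        return predicted_frequency(p, nm, d)
    if detection == "sampling":
        a, b = nm * p, nm * (1.0 - p)
        return 1.0 - np.exp(special.betaln(a, b + N) - special.betaln(a, b))
    raise ValueError(f"unknown detection model {detection!r}")


def occurrence_frequency(table: FeatureTable) -> pd.DataFrame:
    """Mean relative abundance p and detection frequency f per taxon.

    Requires a table rarefied to a common depth (unequal totals rejected);
    taxa absent from every sample are excluded.
    """
    totals = table.sample_totals.to_numpy()
    if len(np.unique(totals)) != 1:
        raise ValueError(
            "sample totals are unequal; rarefy the table to a common depth first"
        )
    counts = table.counts.to_numpy(dtype=float)
    p = (counts / totals[:, None]).mean(axis=0)
    f = (counts > 0).mean(axis=0)
    out = pd.DataFrame({"p": p, "f": f}, index=table.taxon_ids).rename_axis("taxon_id")
    return out[out["f"] > 0]


def predicted_frequency(p, Nm: float, d: float):
    """Expected detection frequency under the neutral model.

    The stationary local relative abundance of a taxon with source abundance
    p is Beta(Nm*p, Nm*(1-p)); the predicted occurrence frequency is the
    probability mass of that beta above the detection limit d.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1)")
    if not (0 < d < 1):
        raise ValueError("detection limit d must lie in (0, 1)")
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    return 1.0 - special.betainc(Nm * p, Nm * (1.0 - p), d)


@dataclass
class NCMFit:
    Nm: float
    m: float
    N: int
    d: float
    r2: float
    n_taxa: int
    detection: str = "sampling"
    reliable: bool = True
    occurrence: pd.DataFrame | None = field(default=None, repr=False)


def _fit_nm(p: np.ndarray, f: np.ndarray, N: int, d: float, detection: str) -> float:
    """Least-squares estimate of Nm on (p, f) pairs via bounded 1-D search."""

    def sse(log_nm: float) -> float:
        resid = f - _occurrence_curve(p, np.exp(log_nm), N, d, detection)
        return float(resid @ resid)

    res = optimize.minimize_scalar(
        sse, bounds=_LOG_NM_BOUNDS, method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:
        raise RuntimeError(f"Nm optimisation failed: {res.message}; last x={res.x}")
    return float(np.exp(res.x))


def fit_ncm(
    table: FeatureTable,
    d: float | None = None,
    min_taxa: int = 20,
    detection: str = "sampling",
) -> NCMFit:
    """Fit Nm to the occurrence-frequency cloud of a rarefied table.

    ``detection`` picks the model for how a taxon's latent relative
    abundance turns into presence in a sample of N reads: ``"sampling"``
    (default) is the exact probability of drawing at least one read,
    1 - B(Nm*p, Nm*(1-p)+N) / B(Nm*p, Nm*(1-p)), which is unbiased for
    count data rarefied to depth N; ``"threshold"`` is the classic tail
    approximation P(x > d) with d defaulting to one read at depth (1/N).
    A flat cloud in which every taxon is detected everywhere carries no
    information about Nm; such fits are flagged unreliable.
    """
    occ = occurrence_frequency(table)
    if len(occ) < min_taxa:
        raise ValueError(
            f"only {len(occ)} taxa with occurrences; need >= {min_taxa} for a fit"
        )
    N = int(table.sample_totals.iloc[0])
    if d is None:
        d = 1.0 / N
    p = occ["p"].to_numpy()
    f = occ["f"].to_numpy()
    nm = _fit_nm(p, f, N, d, detection)
    resid = f - _occurrence_curve(p, nm, N, d, detection)
    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else np.nan
    reliable = True
    if sst == 0 or np.all(f == 1.0):
        warnings.warn("degenerate flat occurrence cloud; Nm fit unreliable")
        reliable = False
    return NCMFit(
        Nm=nm,
        m=nm / N,
        N=N,
        d=d,
        r2=float(r2) if np.isfinite(r2) else np.nan,
        n_taxa=len(occ),
        detection=detection,
        reliable=reliable,
        occurrence=occ,
    )


def ncm_confidence(
    table: FeatureTable,
    fit: NCMFit,
    n_boot: int = 999,
    level: float = 0.95,
    seed: int = 0,
    n_grid: int = 200,
) -> pd.DataFrame:
    """Bootstrap confidence band for the fitted occurrence curve.

    Taxa are resampled with replacement ``n_boot`` times and Nm refit each
    time; the band is the pointwise (1-level)/2 and 1-(1-level)/2 percentile
    envelope of the refit curves over a log-spaced p grid, closed over the
    point-estimate curve so it always contains it.
    """
    occ = fit.occurrence if fit.occurrence is not None else occurrence_frequency(table)
    p = occ["p"].to_numpy()
    f = occ["f"].to_numpy()
    rng = np.random.default_rng(seed)
    grid = np.exp(np.linspace(np.log(p.min()), np.log(p.max()), n_grid))
    curves = np.empty((n_boot, n_grid))
    failures = 0
    for b in range(n_boot):
        idx = rng.integers(0, len(p), size=len(p))
        try:
            nm_b = _fit_nm(p[idx], f[idx], fit.N, fit.d, fit.detection)
            curves[b] = _occurrence_curve(grid, nm_b, fit.N, fit.d, fit.detection)
        except (RuntimeError, ValueError):
            failures += 1
            curves[b] = np.nan
    if failures > 0.2 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    alpha = (1.0 - level) / 2.0
    lo = np.nanpercentile(curves, 100 * alpha, axis=0)
    hi = np.nanpercentile(curves, 100 * (1 - alpha), axis=0)
    point = _occurrence_curve(grid, fit.Nm, fit.N, fit.d, fit.detection)
    return pd.DataFrame(
        {
            "p": grid,
            "predicted": point,
            "ci_lower": np.minimum(lo, point),
            "ci_upper": np.maximum(hi, point),
        }
    )
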