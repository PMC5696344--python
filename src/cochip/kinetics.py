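"""Michaelis-Menten fitting for histone methyltransferase (HMT) assays.

Scintillation-counter rates (d.p.m.) are measured at a ladder of substrate
(nucleosome) concentrations, two replicate series per enzyme.  Each
replicate series is fit to v = Vmax * S / (Km + S) by unweighted nonlinear
least squares; the enzyme's point estimates are the replicate means and the
reported uncertainty is the s.e.m. across replicates (n = 2 in the original
design).  Enzyme variants (e.g. with and without a stimulatory subunit) are
compared per parameter with a pooled two-sample Student's t-test on the
replicate-level estimates.

Positivity of (Vmax, Km) is enforced by optimizing in log space — purely a
numerical choice; reported values are on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "KineticsDataset",
    "KineticsFit",
    "michaelis_menten",
    "fit_mm_single",
    "fit_mm",
    "compare_fits",
    "read_kinetics_csv",
]

MAX_ITER = 500
REL_TOL = 1e-8


def michaelis_menten(S, vmax: float, km: float):
    S = np.asarray(S, dtype=float)
    return vmax * S / (km + S)


@dataclass
class KineticsDataset:
    """Substrate titration with replicate rate measurements.

    ``substrate_conc``: strictly positive, distinct, >= 4 concentrations (µM).
    ``rates``: (n_conc, n_replicates) matrix, n_replicates >= 2.
    """

    substrate_conc: np.ndarray
    rates: np.ndarray
    cofactor_conc_uM: float | None = None  # e.g. 0.23 µM labeled methyl donor
    label: str = ""

    def __post_init__(self):
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if self.rates.shape[0] != len(self.substrate_conc):
            raise ValueError("rates must have one row per substrate concentration")
        if len(self.substrate_conc) < 4:
            raise ValueError("need >= 4 substrate concentrations")
        if (self.substrate_conc <= 0).any():
            raise ValueError("substrate concentrations must be > 0")
        if len(np.unique(self.substrate_conc)) != len(self.substrate_conc):
            raise ValueError("substrate concentrations must be distinct")
        if self.rates.shape[1] < 2:
            raise ValueError("need >= 2 replicate series")

    @property
    def n_replicates(self) -> int:
        return self.rates.shape[1]


@dataclass
class KineticsFit:
    """Aggregated Michaelis-Menten fit for one enzyme."""

    vmax: float
    km: float
    vmax_sem: float
    km_sem: float
    rss: float
    converged: bool
    replicate_vmax: np.ndarray = field(default_factory=lambda: np.array([]))
    replicate_km: np.ndarray = field(default_factory=lambda: np.array([]))
    label: str = ""
    poorly_determined: bool = False


def _init_params(S, v):
    vmax0 = 1.2 * float(np.max(v))
    half = 0.5 * np.max(v)
    order = np.argsort(S)
    km0 = float(np.interp(half, v[order], S[order]))
    if not np.isfinite(km0) or km0 <= 0:
        km0 = float(np.median(S))
    return vmax0, km0


def fit_mm_single(S, v) -> tuple[float, float, float, bool]:
    """Least-squares MM fit of one replicate series.

    Returns (vmax, km, rss, converged).  Initialization: Vmax0 = 1.2 x max
    rate, Km0 = substrate concentration at half-max (interpolated).
    Parameters are optimized as logs so negative excursions cannot occur;
    convergence is declared at relative parameter change < 1e-8.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.ptp(v) == 0 and v[0] == 0:
        return 0.0, 0.0, 0.0, False
    vmax0, km0 = _init_params(S, v)

    def residuals(theta):
        vmax, km = np.exp(theta)
        return michaelis_menten(S, vmax, km) - v

    sol = least_squares(residuals, x0=np.log([max(vmax0, 1e-12), max(km0, 1e-12)]),
                        xtol=REL_TOL, ftol=REL_TOL, gtol=REL_TOL,
                        max_nfev=MAX_ITER)
    vmax, km = np.exp(sol.x)
    rss = float(np.sum(sol.fun ** 2))
    return float(vmax), float(km), rss, bool(sol.status > 0)


def fit_mm(dataset: KineticsDataset, pooled: bool = False) -> KineticsFit:
    """Fit an enzyme's titration: per-replicate fits, then aggregate.

    Point estimates are replicate means; s.e.m. = sd / sqrt(n) with ddof=1
    (the n = 2 design of the assay).  ``pooled=True`` instead fits all
    replicate points jointly (no replicate-level s.e.m.).
    """
    S = dataset.substrate_conc
    if pooled:
        S_all = np.repeat(S, dataset.n_replicates)
        v_all = dataset.rates.ravel()
        vmax, km, rss, ok = fit_mm_single(S_all, v_all)
        return KineticsFit(vmax, km, np.nan, np.nan, rss, ok,
                           np.array([vmax]), np.array([km]), dataset.label,
                           poorly_determined=_degenerate(dataset))
    vmaxs, kms, rsss, oks = [], [], [], []
    for j in range(dataset.n_replicates):
        vmax, km, rss, ok = fit_mm_single(S, dataset.rates[:, j])
        vmaxs.append(vmax)
        kms.append(km)
        rsss.append(rss)
        oks.append(ok)
    vmaxs, kms = np.array(vmaxs), np.array(kms)
    n = len(vmaxs)
    return KineticsFit(
        vmax=float(vmaxs.mean()),
        km=float(kms.mean()),
        vmax_sem=float(vmaxs.std(ddof=1) / np.sqrt(n)),
        km_sem=float(kms.std(ddof=1) / np.sqrt(n)),
        rss=float(np.sum(rsss)),
        converged=all(oks),
        replicate_vmax=vmaxs,
        replicate_km=kms,
        label=dataset.label,
        poorly_determined=_degenerate(dataset) or float(kms.mean()) < 1e-6,
    )


def _degenerate(dataset: KineticsDataset) -> bool:
    """Rate flat over all substrate levels -> Km is at the 0 boundary."""
    means = dataset.rates.mean(axis=1)
    spread = np.ptp(means)
    return bool(spread <= 1e-9 * max(abs(means).max(), 1e-300))


def compare_fits(fit_a: KineticsFit, fit_b: KineticsFit, alpha: float = 0.05) -> dict:
    """Two-sided pooled-variance Student's t-test per parameter.

    Uses the replicate-level estimates of each fit (df = n1 + n2 - 2).
    Zero pooled variance is an error, not a p-value of 0.
    """
    out = {}
    for param in ("vmax", "km"):
        a = getattr(fit_a, f"replicate_{param}")
        b = getattr(fit_b, f"replicate_{param}")
        if len(a) < 2 or len(b) < 2:
            raise ValueError("replicate-level estimates required on both sides")
        n1, n2 = len(a), len(b)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
        if a.mean() == b.mean() and sp2 == 0:
            t, p = 0.0, 1.0
        elif sp2 == 0:
            raise ValueError(f"zero pooled variance for {param}: t undefined")
        else:
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            p = 2 * stats.t.sf(abs(t), df)
        out[param] = {"t": float(t), "p": float(p), "df": df,
                      "significant_at_0.05": bool(p < alpha)}
    return out


def read_kinetics_csv(path, label: str = "") -> KineticsDataset:
    """Read an assay table: column S_uM plus rate_rep1, rate_rep2, ..."""
    df = pd.read_csv(path)
    if "S_uM" not in df.columns:
        raise ValueError("kinetics CSV needs an S_uM column")
    rep_cols = [c for c in df.columns if c.startswith("rate_rep")]
    if len(rep_cols) < 2:
        raise ValueError("kinetics CSV needs >= 2 rate_rep* columns")
    return KineticsDataset(df["S_uM"].to_numpy(), df[rep_cols].to_numpy(),
                           label=label or str(path))
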