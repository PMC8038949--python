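"""Weighted chemical-shift perturbations and the n-equivalent-sites binding isotherm.

Under fast exchange the observed amide peak position is the population-weighted
average of the free and bound states, so the combined CSP of a residue is
proportional to the bound fraction of protein.  The isotherm implemented here
describes a ligand (a DNA duplex) carrying ``n`` equivalent and independent
protein-binding sites, titrated into a protein solution whose concentration is
progressively diluted by the added ligand stock:

    CSP(r) = (CSP_max / 2) * [ (1 + n r + n K_D D)
                               - n * sqrt((1/n + r + K_D D)^2 - 4 r / n) ]

with ``r`` the ligand:protein molar ratio, ``D = 1/C_pro + r/C_lig`` the
dilution factor, ``C_pro`` the initial protein concentration and ``C_lig`` the
ligand stock concentration.  Algebraically this is the standard
ligand-depletion quadratic for total sites ``S_t = n r P_t`` and macroscopic
dissociation constant ``K = n K_D``, where ``P_t = 1/D`` is the diluted total
protein concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .peaks import TitrationSeries

__all__ = [
    "BindingParams",
    "CSPProfile",
    "BindingFitResult",
    "compute_csp",
    "csp_profile",
    "predict_csp",
    "total_protein_conc",
    "fit_kd",
]

#: Weight applied to the 15N shift difference in the combined CSP.
N15_WEIGHT = 1.0 / 5.0

KD_BOUNDS_UM = (1e-4, 1e6)


@dataclass
class BindingParams:
    """Parameters of the n-equivalent-sites isotherm.

    kd : equilibrium dissociation constant per site (uM)
    n_sites : number of equivalent, independent protein-binding sites on the
        ligand; conventionally fixed during fitting
    cspmax : CSP at theoretical saturation (ppm); scalar, or one per residue
    c_pro : initial protein concentration (uM)
    c_lig : ligand stock concentration (uM)
    """

    kd: float
    n_sites: float
    cspmax: float
    c_pro: float
    c_lig: float

    def __post_init__(self) -> None:
        if self.kd < 0:
            raise ValueError("kd must be >= 0")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be > 0")
        if np.any(np.asarray(self.cspmax) < 0):
            raise ValueError("cspmax must be >= 0")
        if self.c_pro <= 0 or self.c_lig <= 0:
            raise ValueError("concentrations must be > 0")


@dataclass
class CSPProfile:
    """Per-residue CSP trajectories referenced to the apo point.

    ``csp[i, j]`` is the combined CSP of residue ``residues[i]`` at molar
    ratio ``ratios[j]``; ``valid`` masks points where the residue was flagged
    (proline / unassigned / overlapped) or missing.
    """

    residues: np.ndarray
    ratios: np.ndarray
    csp: np.ndarray
    valid: np.ndarray
    c_pro: float
    c_lig: float

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.csp = np.asarray(self.csp, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.csp.shape != (self.residues.size, self.ratios.size):
            raise ValueError("csp must have shape (n_residues, n_ratios)")
        if self.valid.shape != self.csp.shape:
            raise ValueError("valid mask must match csp shape")

    def at_ratio(self, r: float) -> tuple[np.ndarray, np.ndarray]:
        """CSP values and validity mask at titration point ``r``."""
        j = int(np.argmin(np.abs(self.ratios - r)))
        if not math.isclose(self.ratios[j], r, rel_tol=0, abs_tol=1e-9):
            raise KeyError(f"ratio {r} not present in profile")
        return self.csp[:, j], self.valid[:, j]


@dataclass
class BindingFitResult:
    """Outcome of a K_D fit.

    ``cspmax`` maps residue number -> fitted saturation CSP (ppm).
    ``kd_ci`` is a residual-resampling bootstrap confidence interval (uM)
    when bootstrapping was requested.
    """

    kd: float
    n_sites: float
    cspmax: dict[int, float]
    c_pro: float
    c_lig: float
    residues_used: list[int]
    residuals: np.ndarray
    rss: float
    converged: bool
    n_was_fixed: bool
    message: str = ""
    kd_ci: tuple[float, float] | None = None

    @property
    def params(self) -> BindingParams:
        cspmax = float(np.mean(list(self.cspmax.values()))) if self.cspmax else 0.0
        return BindingParams(self.kd, self.n_sites, cspmax, self.c_pro, self.c_lig)


def compute_csp(delta_h: float, delta_n: float) -> float:
    """Combined 1H/15N chemical shift perturbation (ppm).

    ``sqrt(delta_h**2 + (delta_n / 5)**2)`` — the standard weighted CSP with
    the 15N difference scaled by 1/5 to account for its larger shift range.
    Accepts scalars or arrays (element-wise).
    """
    dh = np.asarray(delta_h, dtype=float)
    dn = np.asarray(delta_n, dtype=float)
    if not (np.all(np.isfinite(dh)) and np.all(np.isfinite(dn))):
        raise ValueError("shift differences must be finite")
    out = np.sqrt(dh**2 + (dn * N15_WEIGHT) ** 2)
    return float(out) if out.ndim == 0 else out


def total_protein_conc(r: float, c_pro: float, c_lig: float) -> float:
    """Total protein concentration (uM) after dilution by ligand addition.

    Adding ligand from a stock of concentration ``c_lig`` to reach molar
    ratio ``r`` dilutes the protein to ``1 / (1/c_pro + r/c_lig)``.
    """
    if c_pro <= 0 or c_lig <= 0:
        raise ValueError("concentrations must be > 0")
    r = np.asarray(r, dtype=float)
    out = 1.0 / (1.0 / c_pro + r / c_lig)
    return float(out) if out.ndim == 0 else out


def bound_fraction(r, kd: float, n_sites: float, c_pro: float, c_lig: float):
    """Bound fraction of protein at molar ratio ``r`` (0..1).

    Closed form of the mass-action quadratic for ``n`` equivalent independent
    sites per ligand with dilution of the protein by the ligand stock.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("molar ratio must be >= 0")
    n = n_sites
    d = 1.0 / c_pro + r / c_lig
    term = 1.0 / n + r + kd * d
    disc = term**2 - 4.0 * r / n
    bad = disc < -1e-12 * np.maximum(term**2, 1.0)
    if np.any(bad):
        raise ValueError("negative discriminant: invalid isotherm parameters")
    disc = np.clip(disc, 0.0, None)
    f = 0.5 * ((1.0 + n * r + n * kd * d) - n * np.sqrt(disc))
    # guard tiny negative round-off at r = 0
    f = np.clip(f, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


def predict_csp(r, params: BindingParams):
    """Predicted combined CSP (ppm) at molar ratio ``r`` under the isotherm.

    Monotone nondecreasing in ``r``, zero at ``r = 0`` and bounded by
    ``cspmax``.  In the tight-binding limit (kd -> 0) it reduces to the
    stoichiometric ramp ``cspmax * min(1, n * r)``.
    """
    f = bound_fraction(r, params.kd, params.n_sites, params.c_pro, params.c_lig)
    return np.asarray(params.cspmax) * f if np.ndim(params.cspmax) else params.cspmax * f


def csp_profile(series: TitrationSeries) -> CSPProfile:
    """Per-residue CSP trajectory of a titration series, referenced to apo.

    Residues flagged at a point (or missing a record there) are masked at
    that point only; residues flagged at the apo point are masked throughout.
    """
    ratios = np.array(series.ratios, dtype=float)
    apo = series.points[0][1]
    residues = np.array(sorted(apo), dtype=int)
    n_res, n_pts = residues.size, ratios.size
    csp = np.full((n_res, n_pts), np.nan)
    valid = np.zeros((n_res, n_pts), dtype=bool)
    for i, res in enumerate(residues):
        rec0 = apo[res]
        if rec0.flags:
            continue
        for j, (_, table) in enumerate(series.points):
            rec = table.get(res)
            if rec is None or rec.flags:
                continue
            csp[i, j] = compute_csp(rec.shift_h - rec0.shift_h, rec.shift_n - rec0.shift_n)
            valid[i, j] = True
    return CSPProfile(residues, ratios, csp, valid, series.c_pro, series.c_lig)


def _select_residues(profile: CSPProfile) -> list[int]:
    # default global-fit selection: residues whose final-point CSP is >= the
    # mean final-point CSP over valid residues
    last, ok = profile.csp[:, -1], profile.valid[:, -1]
    if not ok.any():
        return []
    thresh = float(np.mean(last[ok]))
    return [int(r) for r, c, v in zip(profile.residues, last, ok) if v and c >= thresh]


def _fit_once(ratios, csp_rows, valid_rows, n_sites, c_pro, c_lig, kd_start,
              cspmax_hi, fix_n, n_start):
    n_res = csp_rows.shape[0]
    f0 = bound_fraction(ratios[-1], kd_start, n_start, c_pro, c_lig)
    f0 = max(f0, 1e-3)
    cm0 = np.clip(np.nanmax(np.where(valid_rows, csp_rows, 0.0), axis=1) / f0,
                  1e-6, cspmax_hi)
    x0 = [math.log10(kd_start)] + list(cm0)
    lo = [math.log10(KD_BOUNDS_UM[0])] + [0.0] * n_res
    hi = [math.log10(KD_BOUNDS_UM[1])] + list(cspmax_hi)
    if not fix_n:
        x0.append(n_start)
        lo.append(0.1)
        hi.append(20.0)

    def resid(x):
        kd = 10.0 ** x[0]
        n = x[n_res + 1] if not fix_n else n_sites
        f = bound_fraction(ratios, kd, n, c_pro, c_lig)
        pred = np.outer(x[1:n_res + 1], f)
        return (pred - csp_rows)[valid_rows]

    try:
        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
    except Exception:  # numerical failure on one start is not fatal
        return None
    return sol


def fit_kd(
    profile: CSPProfile,
    n_sites: float,
    mode: str = "global",
    residues=None,
    fix_n: bool = True,
    n_starts: int = 7,
    n_boot: int = 0,
    seed: int | None = None,
) -> BindingFitResult | dict[int, BindingFitResult]:
    """Fit K_D (and per-residue CSP_max) to a CSP profile.

    Parameters
    ----------
    profile : CSPProfile
        CSP trajectories with titration metadata.
    n_sites : float
        Number of equivalent independent sites per ligand; held fixed unless
        ``fix_n=False``.
    mode : {'global', 'per_residue'}
        ``global`` shares one K_D across the selected residues with a free
        CSP_max per residue (default selection: residues whose final-point
        CSP is at least the mean); ``per_residue`` fits each residue
        independently and returns a dict keyed by residue number.
    n_starts : int
        Number of log-spaced K_D starting values; the best-RSS solution wins.
    n_boot : int
        If > 0, residual-resampling bootstrap draws for a 95% K_D CI.
    """
    if mode not in ("global", "per_residue"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "per_residue":
        sel = residues if residues is not None else [int(r) for r in profile.residues]
        out: dict[int, BindingFitResult] = {}
        for res in sel:
            out[res] = fit_kd(profile, n_sites, mode="global", residues=[res],
                              fix_n=fix_n, n_starts=n_starts, n_boot=n_boot, seed=seed)
        return out

    sel = residues if residues is not None else _select_residues(profile)
    sel = [int(r) for r in sel]
    idx = {int(r): i for i, r in enumerate(profile.residues)}
    missing = [r for r in sel if r not in idx]
    if missing:
        raise KeyError(f"residues not in profile: {missing}")
    rows = np.array([idx[r] for r in sel], dtype=int)
    if rows.size == 0:
        return BindingFitResult(math.nan, n_sites, {}, profile.c_pro, profile.c_lig,
                                [], np.array([]), math.nan, False, fix_n,
                                "no residues selected for fitting")
    csp_rows = profile.csp[rows]
    valid_rows = profile.valid[rows]
    n_points_each = valid_rows.sum(axis=1)
    if np.any(n_points_each < 3):
        bad = [sel[i] for i in np.where(n_points_each < 3)[0]]
        raise ValueError(f"fewer than 3 valid points for residues {bad}")

    max_obs = np.nanmax(np.where(valid_rows, csp_rows, 0.0), axis=1)
    if float(np.max(max_obs)) <= 0.0:
        return BindingFitResult(math.nan, n_sites, {}, profile.c_pro, profile.c_lig,
                                sel, np.array([]), math.nan, False, fix_n,
                                "no binding signal: all CSPs are zero")
    cspmax_hi = np.maximum(10.0 * max_obs, 1e-6)

    kd_starts = np.logspace(-2, 4, n_starts)
    best = None
    for kd0 in kd_starts:
        sol = _fit_once(profile.ratios, csp_rows, valid_rows, n_sites,
                        profile.c_pro, profile.c_lig, kd0, cspmax_hi, fix_n, n_sites)
        if sol is None:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[1]:
            best = (sol, rss)
    if best is None:
        return BindingFitResult(math.nan, n_sites, {}, profile.c_pro, profile.c_lig,
                                sel, np.array([]), math.nan, False, fix_n,
                                "optimizer failed on all starts")
    sol, rss = best
    kd_hat = 10.0 ** sol.x[0]
    n_hat = n_sites if fix_n else float(sol.x[len(sel) + 1])
    cspmax_hat = {r: float(c) for r, c in zip(sel, sol.x[1:len(sel) + 1])}

    ci = None
    if n_boot > 0:
        ci = _bootstrap_kd_ci(profile, sol, sel, rows, csp_rows, valid_rows,
                              n_hat, cspmax_hi, fix_n, n_boot, seed)

    return BindingFitResult(float(kd_hat), n_hat, cspmax_hat, profile.c_pro,
                            profile.c_lig, sel, sol.fun.copy(), rss,
                            bool(sol.success), fix_n, "converged" if sol.success
                            else "optimizer did not report convergence", ci)


def _bootstrap_kd_ci(profile, sol, sel, rows, csp_rows, valid_rows, n_hat,
                     cspmax_hi, fix_n, n_boot, seed):
    """Residual-resampling bootstrap percentile CI (95%) for K_D."""
    rng = np.random.default_rng(seed)
    kd_hat = 10.0 ** sol.x[0]
    f = bound_fraction(profile.ratios, kd_hat, n_hat, profile.c_pro, profile.c_lig)
    pred = np.outer(sol.x[1:len(sel) + 1], f)
    resid = (csp_rows - pred)[valid_rows]
    kds = []
    for _ in range(n_boot):
        draw = rng.choice(resid, size=resid.size, replace=True)
        boot = pred.copy()
        boot[valid_rows] += draw
        bsol = _fit_once(profile.ratios, boot, valid_rows, n_hat, profile.c_pro,
                         profile.c_lig, kd_hat, cspmax_hi, fix_n, n_hat)
        if bsol is not None:
            kds.append(10.0 ** bsol.x[0])
    if len(kds) < max(10, n_boot // 2):
        warnings.warn("bootstrap refits mostly failed; CI not reported")
        return None
    lo, hi = np.percentile(kds, [2.5, 97.5])
    # the interval always brackets the point estimate
    return (float(min(lo, kd_hat)), float(max(hi, kd_hat)))
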