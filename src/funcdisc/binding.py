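"""Hill-equation analysis of fluorescence-anisotropy titrations.

Binding of a transcriptional regulator to its fluorescein-labeled DNA
operator is followed by the change in fluorescence anisotropy ΔA as protein
is titrated in.  The saturation curve is modeled with the Hill form

    ΔA(E) = ΔA_T · E^H / (K_d^H + E^H)

where ΔA_T is the total anisotropy change at saturation, E the total protein
concentration at each titration point, K_d the dissociation constant, and H
the Hill coefficient.  Apparent K_d values measured in the presence of an
effector metabolite use the same functional form with the effector
concentration on the E axis.

Concentration units (nM for protein/operator affinities, mM for effectors)
are carried as tags and never converted automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: total ligand concentration and observed ΔA."""

    E: float
    delta_A: float
    unit: str = "nM"

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class HillFit:
    """Result of a least-squares Hill fit."""

    k_d: float
    h: float
    delta_a_t: float
    unit: str
    residual_norm: float
    stderr_k_d: float
    stderr_h: float
    stderr_delta_a_t: float
    converged: bool
    n_points: int

    def predict(self, E) -> np.ndarray:
        return hill_model(E, self.k_d, self.h, self.delta_a_t)


def hill_model(E, k_d: float, h: float, delta_a_t: float):
    """ΔA at concentration(s) E; vectorized over E.

    ΔA(0) = 0, ΔA(K_d) = ΔA_T / 2 for any Hill coefficient, and ΔA
    approaches ΔA_T from below as E grows.
    """
    if k_d <= 0 or h <= 0 or delta_a_t <= 0:
        raise ValueError("K_d, H and delta_A_T must all be positive")
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = np.where(E > 0, (k_d / np.where(E > 0, E, 1.0)) ** h, np.inf)
    out = delta_a_t / (1.0 + ratio)
    return out if out.ndim else float(out)


def _default_init(E: np.ndarray, dA: np.ndarray) -> tuple[float, float, float]:
    """K_d ≈ concentration at half-max ΔA; H = 1; ΔA_T = max ΔA."""
    da_t0 = float(np.max(dA))
    half = da_t0 / 2.0
    idx = int(np.argmin(np.abs(dA - half)))
    kd0 = float(E[idx]) if E[idx] > 0 else float(np.median(E[E > 0]))
    return max(kd0, 1e-12), 1.0, max(da_t0, 1e-12)


def fit_hill(points, init: tuple[float, float, float] | None = None) -> HillFit:
    """Unweighted nonlinear least-squares fit of the Hill model.

    ``points`` is a list of :class:`TitrationPoint` (or (E, ΔA) pairs).
    Requires at least 5 points; the fit is ill-conditioned unless they span
    both sides of half-saturation, which triggers a warning but not an
    error.  Non-convergence is flagged on the returned :class:`HillFit`
    rather than raised.
    """
    pts = [p if isinstance(p, TitrationPoint) else TitrationPoint(*p)
           for p in points]
    if len(pts) < 5:
        raise ValueError("need at least 5 titration points")
    unit = pts[0].unit
    if any(p.unit != unit for p in pts):
        raise ValueError("mixed concentration units in one titration")
    E = np.array([p.E for p in pts], dtype=float)
    dA = np.array([p.delta_A for p in pts], dtype=float)
    if init is None:
        init = _default_init(E, dA)
    kd0, h0, dat0 = init
    half = np.max(dA) / 2.0
    if not (np.any(dA < half) and np.any(dA > half)):
        logger.warning("titration does not span half-saturation; "
                       "the fit may be poorly constrained")

    def resid(p):
        kd, h, dat = p
        return hill_model(E, kd, h, dat) - dA

    sol = least_squares(resid, x0=[kd0, h0, dat0],
                        bounds=([1e-12, 1e-12, 1e-12], [np.inf] * 3),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    kd, h, dat = (float(v) for v in sol.x)
    residual_norm = float(np.linalg.norm(sol.fun))
    dof = max(len(pts) - 3, 1)
    s2 = residual_norm ** 2 / dof
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return HillFit(k_d=kd, h=h, delta_a_t=dat, unit=unit,
                   residual_norm=residual_norm,
                   stderr_k_d=float(se[0]), stderr_h=float(se[1]),
                   stderr_delta_a_t=float(se[2]),
                   converged=bool(sol.success), n_points=len(pts))


def simulate_titration(k_d: float, h: float, delta_a_t: float,
                       concentrations, noise_sd: float = 0.0,
                       rng: np.random.Generator | None = None,
                       unit: str = "nM") -> list[TitrationPoint]:
    """Synthetic titration from the Hill model with additive Gaussian noise."""
    E = np.asarray(concentrations, dtype=float)
    dA = hill_model(E, k_d, h, delta_a_t)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        dA = dA + rng.normal(0.0, noise_sd, size=E.shape)
    return [TitrationPoint(float(e), float(a), unit) for e, a in zip(E, dA)]


def load_titration(path: str | Path) -> list[TitrationPoint]:
    """Read a titration CSV with columns ``E, delta_A`` and an optional
    ``# unit: <unit>`` comment line."""
    unit = "nM"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "unit" in line:
                unit = line.split(":", 1)[1].strip()
                break
    df = pd.read_csv(path, comment="#")
    if not {"E", "delta_A"} <= set(df.columns):
        raise ValueError("titration CSV needs columns E and delta_A")
    return [TitrationPoint(float(r.E), float(r.delta_A), unit)
            for r in df.itertuples()]


def write_titration(points: list[TitrationPoint], path: str | Path) -> None:
    unit = points[0].unit if points else "nM"
    with open(path, "w") as fh:
        fh.write(f"# unit: {unit}\nE,delta_A\n")
        for p in points:
            fh.write(f"{p.E:.10g},{p.delta_A:.10g}\n")
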