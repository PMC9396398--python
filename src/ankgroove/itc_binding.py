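"""One-site ITC isotherm: forward model, simulation, and nonlinear fitting.

The forward model follows the standard single-site treatment for a
perfusion-type cell: after each injection the cell contents are diluted by
the displaced volume, totals are updated, the 1:1 mass-action equilibrium
is solved in closed form (physically meaningful quadratic root), and the
per-injection heat is the increment in bound-complex heat content.

Conventions: concentrations in molar, volumes in litres, molar enthalpy in
cal/mol, per-injection heats in microcalories.  ``Kd = 1/Ka``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

CAL_TO_UCAL = 1e6

# protocol defaults matching the study's setup: VP-ITC cell, 20 uM binder
# in the cell, 200 uM titrant in the syringe, 27 x 10 ul injections, 25 C
DEFAULT_CELL_VOLUME = 1.43e-3
DEFAULT_CELL_CONC = 20e-6
DEFAULT_SYRINGE_CONC = 200e-6
DEFAULT_N_INJECTIONS = 27
DEFAULT_INJECTION_VOLUME = 10e-6
DEFAULT_INTERVAL_S = 180.0
DEFAULT_TEMPERATURE = 298.15


@dataclass
class TitrationExperiment:
    """Injection schedule and observed (or simulated) heats."""

    cell_conc: float = DEFAULT_CELL_CONC
    syringe_conc: float = DEFAULT_SYRINGE_CONC
    cell_volume: float = DEFAULT_CELL_VOLUME
    injection_volumes: Sequence[float] = field(
        default_factory=lambda: [DEFAULT_INJECTION_VOLUME] * DEFAULT_N_INJECTIONS
    )
    heats: Sequence[float] | None = None  # ucal per injection
    interval_s: float = DEFAULT_INTERVAL_S
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if min(self.cell_conc, self.syringe_conc, self.cell_volume) <= 0:
            raise ValueError("concentrations and cell volume must be > 0")
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if np.any(self.injection_volumes <= 0):
            raise ValueError("injection volumes must be > 0")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if len(self.heats) != len(self.injection_volumes):
                raise ValueError("heats and injection_volumes must have equal length")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def molar_ratios(self) -> np.ndarray:
        """Cumulative titrant:binder molar ratio after each injection."""
        m, x, _ = _titration_totals(self)
        return x / m


@dataclass
class OneSiteParams:
    n: float = 1.0          # stoichiometry
    Ka: float = 1e6         # 1/M
    dH: float = -8000.0     # cal/mol
    baseline: float = 0.0   # ucal per injection

    def __post_init__(self) -> None:
        if self.Ka <= 0 or self.n <= 0:
            raise ValueError("Ka and n must be > 0")

    @property
    def Kd(self) -> float:
        return 1.0 / self.Ka


@dataclass
class OneSiteFit:
    params: OneSiteParams
    param_errors: dict[str, float]
    residual_rms: float
    c_value: float

    @property
    def Kd(self) -> float:
        return self.params.Kd

    @property
    def Kd_error(self) -> float:
        """Kd standard error propagated from the Ka fitting error."""
        return self.param_errors.get("Ka", 0.0) / self.params.Ka**2

    @property
    def low_confidence(self) -> bool:
        return not (1.0 <= self.c_value <= 1000.0)

    def to_dict(self) -> dict:
        return {
            "n": self.params.n,
            "Ka": self.params.Ka,
            "Kd": self.Kd,
            "dH": self.params.dH,
            "baseline": self.params.baseline,
            "param_errors": self.param_errors,
            "Kd_error": self.Kd_error,
            "residual_rms": self.residual_rms,
            "c_value": self.c_value,
            "low_confidence": self.low_confidence,
        }


class FitError(RuntimeError):
    """Non-convergent fit; carries the best iterate."""

    def __init__(self, message: str, best: OneSiteParams | None = None, residual: float = np.nan):
        super().__init__(message)
        self.best = best
        self.residual = residual


# ---------------------------------------------------------------------------
# forward model

def _titration_totals(exp: TitrationExperiment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total binder/titrant cell concentrations after each injection.

    Sequential perfusion model: each injection of volume v displaces v of
    the instantaneously mixed cell contents, so every total is scaled by
    (1 - v/V0) before the fresh titrant is added.
    """
    v0 = exp.cell_volume
    m = np.empty(exp.n_injections)
    x = np.empty(exp.n_injections)
    dilution = np.empty(exp.n_injections)
    m_cur, x_cur = exp.cell_conc, 0.0
    for i, v in enumerate(exp.injection_volumes):
        f = 1.0 - v / v0
        m_cur *= f
        x_cur = x_cur * f + exp.syringe_conc * (v / v0)
        m[i], x[i], dilution[i] = m_cur, x_cur, f
    return m, x, dilution


def _bound_complex(site_total: np.ndarray, x_total: np.ndarray, Ka: float) -> np.ndarray:
    """Closed-form 1:1 equilibrium complex concentration.

    Root of ``C^2 - C (S + X + 1/Ka) + S X = 0`` lying in [0, min(S, X)];
    written in the numerically stable ``2 S X / (b + sqrt(b^2 - 4 S X))``
    form to avoid cancellation at large Ka.
    """
    b = site_total + x_total + 1.0 / Ka
    disc = b * b - 4.0 * site_total * x_total
    if np.any(disc < -1e-12 * np.max(b) ** 2):
        raise ArithmeticError("negative discriminant in mass-action quadratic")
    root = np.sqrt(np.clip(disc, 0.0, None))
    c = 2.0 * site_total * x_total / (b + root)
    upper = np.minimum(site_total, x_total)
    if np.any(c < -1e-9) or np.any(c > upper * (1 + 1e-9) + 1e-15):
        raise ArithmeticError("non-physical root of the binding quadratic")
    return np.clip(c, 0.0, upper)


def wiseman_heats(params: OneSiteParams, exp: TitrationExperiment) -> np.ndarray:
    """Predicted per-injection heats (ucal), baseline included.

    Heat of injection i is ``dH * V0 * (C_i - C_{i-1} * (1 - v_i/V0))``:
    the enthalpy of complex newly formed after the displaced fraction of
    the previous equilibrium mixture has left the cell.
    """
    m, x, dilution = _titration_totals(exp)
    c = _bound_complex(params.n * m, x, params.Ka)
    c_prev = np.concatenate(([0.0], c[:-1])) * dilution
    heats_cal = params.dH * exp.cell_volume * (c - c_prev)
    return heats_cal * CAL_TO_UCAL + params.baseline


def simulate_titration(
    params: OneSiteParams,
    protocol: TitrationExperiment | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> TitrationExperiment:
    """Noisy realization of the one-site isotherm under a protocol.

    ``protocol.heats`` is ignored; the returned experiment carries
    ``wiseman_heats + N(0, noise_sd)`` with an RNG seeded by ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    protocol = protocol if protocol is not None else TitrationExperiment()
    heats = wiseman_heats(params, protocol)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return replace(protocol, heats=heats)


# ---------------------------------------------------------------------------
# fitting

def _initial_guess(exp: TitrationExperiment) -> OneSiteParams:
    heats = np.asarray(exp.heats, dtype=float)
    v = np.asarray(exp.injection_volumes)
    # dH from the first injection heat over moles of titrant injected
    moles_first = exp.syringe_conc * v[0]
    dH0 = (heats[0] - heats[-1]) / moles_first / CAL_TO_UCAL
    if abs(dH0) < 100.0:
        dH0 = -8000.0 if heats.sum() < 0 else 8000.0
    # Kd heuristic: steepest descent of the isotherm sits near molar ratio n;
    # start from c ~ 50
    Ka0 = 50.0 / exp.cell_conc
    return OneSiteParams(n=1.0, Ka=Ka0, dH=dH0, baseline=heats[-1])


def fit_one_site(
    exp: TitrationExperiment,
    init: OneSiteParams | None = None,
) -> OneSiteFit:
    """Nonlinear least-squares fit of (n, log Ka, dH, baseline).

    Standard errors come from the local curvature (JtJ inverse scaled by
    residual variance).  A Wiseman c-value outside [1, 1000] flags the fit
    as low-confidence.
    """
    if exp.heats is None:
        raise ValueError("experiment carries no heats to fit")
    heats = np.asarray(exp.heats, dtype=float)
    if len(heats) < 6:
        raise ValueError("need at least 6 injections to fit")

    p0 = init if init is not None else _initial_guess(exp)
    x0 = np.array([p0.n, np.log(p0.Ka), p0.dH, p0.baseline])

    def unpack(x: np.ndarray) -> OneSiteParams:
        return OneSiteParams(n=x[0], Ka=float(np.exp(x[1])), dH=x[2], baseline=x[3])

    def residuals(x: np.ndarray) -> np.ndarray:
        return wiseman_heats(unpack(x), exp) - heats

    result = least_squares(
        residuals, x0,
        bounds=([1e-3, np.log(1.0), -np.inf, -np.inf], [100.0, np.log(1e15), np.inf, np.inf]),
        method="trf", x_scale=[1.0, 1.0, abs(x0[2]) or 1.0, 1.0],
    )
    best = unpack(result.x)
    dof = max(len(heats) - 4, 1)
    rms = float(np.sqrt(np.mean(result.fun**2)))
    if not result.success:
        raise FitError(f"one-site fit did not converge: {result.message}", best=best, residual=rms)

    # covariance from J^T J (in the internal parameterization), then transform
    # the log-Ka variance to Ka scale
    jac = result.jac
    s_sq = float(np.sum(result.fun**2)) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s_sq
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    param_errors = {
        "n": float(se[0]),
        "Ka": float(se[1] * best.Ka),  # d(Ka) = Ka * d(logKa)
        "dH": float(se[2]),
        "baseline": float(se[3]),
    }
    c_value = best.n * best.Ka * exp.cell_conc
    return OneSiteFit(params=best, param_errors=param_errors, residual_rms=rms, c_value=c_value)


def fold_change(kd_variant: float, kd_reference: float) -> float:
    """Kd ratio variant/reference; > 1 means weakened binding."""
    if kd_variant <= 0 or kd_reference <= 0:
        raise ValueError("dissociation constants must be > 0")
    return kd_variant / kd_reference


# ---------------------------------------------------------------------------
# IO

def read_titration_csv(
    path: str | Path,
    cell_conc: float = DEFAULT_CELL_CONC,
    syringe_conc: float = DEFAULT_SYRINGE_CONC,
    cell_volume: float = DEFAULT_CELL_VOLUME,
) -> TitrationExperiment:
    """Columns: injection_index, volume_ul, heat_ucal."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"injection_index", "volume_ul", "heat_ucal"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    df = df.sort_values("injection_index")
    return TitrationExperiment(
        cell_conc=cell_conc, syringe_conc=syringe_conc, cell_volume=cell_volume,
        injection_volumes=(df["volume_ul"].to_numpy() * 1e-6),
        heats=df["heat_ucal"].to_numpy(),
    )


def write_titration_csv(exp: TitrationExperiment, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "injection_index": np.arange(1, exp.n_injections + 1),
            "volume_ul": np.asarray(exp.injection_volumes) * 1e6,
            "heat_ucal": np.asarray(exp.heats),
        }
    ).to_csv(path, index=False)


def write_fit_json(fit: OneSiteFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")
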