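"""Global Gaussian fits of the circuit model to measurement tables.

Measured odour-evoked spike-rate changes are modelled as independent
normal variables centred on the recursive model's predictions, so the
negative log-likelihood is the familiar half-sum of squared standardized
residuals (plus constants).  Fitting uses bounded multi-start nonlinear
least squares; time constants are fitted on a log scale.  Confidence
intervals (16-84%) come from parametric-bootstrap refits that honour the
stated normal noise model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .circuit import CircuitError, ModelParams
from .synthetic import GroundTruth, MeasurementSchema, default_schema, \
    gen_measurement_table, model_predictions

__all__ = [
    "FREE_PARAMS", "FitResult", "schema_from_table", "gaussian_negloglik",
    "predict_table", "fit_global", "compare_variants", "recovery_study",
]

LOG2PI = math.log(2 * math.pi)


# name -> (getter, setter, (lo, hi), log_scale)
def _get(attr, key=None):
    if key is None:
        return lambda p: getattr(p, attr)
    return lambda p: getattr(p, attr)[key]


def _set(attr, key=None):
    if key is None:
        def s(p, v):
            setattr(p, attr, v)
    else:
        def s(p, v):
            getattr(p, attr)[key] = v
    return s


FREE_PARAMS: dict[str, tuple] = {
    "tau_fast": (_get("tau_fast"), _set("tau_fast"), (300.0, 2.0e4), True),
    "tau_slow": (_get("tau_slow"), _set("tau_slow"), (600.0, 6.0e4), True),
    "eta_g1": (_get("eta", "g1"), _set("eta", "g1"), (1e-4, 0.2), True),
    "eta_a2": (_get("eta", "a2"), _set("eta", "a2"), (1e-4, 0.2), True),
    "eta_a3": (_get("eta", "a3"), _set("eta", "a3"), (1e-4, 0.2), True),
    "w_sn_Dg1": (_get("w_sn", "Dg1"), _set("w_sn", "Dg1"), (0.0, 1.0), False),
    "w_sn_Da3": (_get("w_sn", "Da3"), _set("w_sn", "Da3"), (0.0, 1.0), False),
    "w_Mg1_Da2": (_get("w_fb", ("Mg1", "Da2")), _set("w_fb", ("Mg1", "Da2")),
                  (-1.5, 0.0), False),
    "w_Mg1_Da3": (_get("w_fb", ("Mg1", "Da3")), _set("w_fb", ("Mg1", "Da3")),
                  (-1.5, 0.0), False),
    "w_Ma2_Da3": (_get("w_fb", ("Ma2", "Da3")), _set("w_fb", ("Ma2", "Da3")),
                  (0.0, 0.5), False),
    "w_Ma3_Da3": (_get("w_fb", ("Ma3", "Da3")), _set("w_fb", ("Ma3", "Da3")),
                  (0.0, 0.5), False),
}

DEFAULT_FREE = ("tau_fast", "tau_slow", "eta_g1", "eta_a2", "eta_a3",
                "w_sn_Dg1", "w_sn_Da3", "w_Mg1_Da2", "w_Mg1_Da3",
                "w_Ma2_Da3", "w_Ma3_Da3")


def _free_names(variant: str, free) -> tuple[str, ...]:
    if free is not None:
        return tuple(free)
    if variant == "two_module":
        return tuple(n for n in DEFAULT_FREE
                     if n not in ("eta_a2", "w_Mg1_Da2", "w_Ma2_Da3"))
    return DEFAULT_FREE


def _copy_params(params: ModelParams) -> ModelParams:
    return replace(params,
                   b_dan=dict(params.b_dan), b_mbon=dict(params.b_mbon),
                   w_sn=dict(params.w_sn), w_fb=dict(params.w_fb),
                   valence_gain=dict(params.valence_gain),
                   w0=dict(params.w0), w_max=dict(params.w_max),
                   eta=dict(params.eta))


def _to_vector(params: ModelParams, names) -> np.ndarray:
    out = []
    for n in names:
        get, _, _, logs = FREE_PARAMS[n]
        v = get(params)
        out.append(math.log(v) if logs else v)
    return np.array(out)


def _from_vector(base: ModelParams, names, x) -> ModelParams:
    p = _copy_params(base)
    for n, v in zip(names, x):
        _, setter, _, logs = FREE_PARAMS[n]
        setter(p, math.exp(v) if logs else float(v))
    return p


def _bounds(names):
    lo, hi = [], []
    for n in names:
        _, _, (a, b), logs = FREE_PARAMS[n]
        lo.append(math.log(a) if logs else a)
        hi.append(math.log(b) if logs else b)
    return np.array(lo), np.array(hi)


def schema_from_table(table: pd.DataFrame) -> MeasurementSchema:
    entries = tuple(table[["neuron", "valence_pair", "session", "stimulus"]]
                    .itertuples(index=False, name=None))
    return MeasurementSchema(entries=entries)


def predict_table(params: ModelParams, table: pd.DataFrame) -> np.ndarray:
    """Model prediction for every row of a measurement table."""
    return model_predictions(params, schema_from_table(table))


def gaussian_negloglik(params: ModelParams, table: pd.DataFrame,
                       include_constant: bool = True) -> float:
    """Independent-normal negative log-likelihood of a measurement table.

    ``sum_rows (model - observed)^2 / (2 sd^2) + sum_rows log(sd sqrt(2 pi))``.
    Returns +inf (with the offending error attached) if the forward model
    fails for the supplied parameters.
    """
    sd = table["sd_hz"].to_numpy(dtype=float)
    if np.any(sd <= 0):
        raise CircuitError("all measurement uncertainties must be > 0")
    try:
        model = predict_table(params, table)
    except Exception:
        return float("inf")
    resid = (model - table["delta_rate_hz"].to_numpy(dtype=float)) / sd
    nll = 0.5 * float(np.sum(resid ** 2))
    if include_constant:
        nll += float(np.sum(np.log(sd))) + 0.5 * sd.size * LOG2PI
    return nll


@dataclass
class FitResult:
    """Point estimates with 16-84% bootstrap confidence intervals."""

    params: ModelParams
    estimates: dict            # free-parameter name -> point value
    ci_lo: dict
    ci_hi: dict
    loss: float                # negative log-likelihood at the optimum
    n_restarts: int
    seed: int
    free_names: tuple
    restart_losses: tuple = ()
    underdetermined: bool = False

    def summary(self) -> pd.DataFrame:
        rows = [(n, self.estimates[n], self.ci_lo.get(n, math.nan),
                 self.ci_hi.get(n, math.nan)) for n in self.free_names]
        return pd.DataFrame(rows, columns=["param", "estimate",
                                           "ci16", "ci84"])


def _fit_once(table, base, names, x0, lo, hi):
    obs = table["delta_rate_hz"].to_numpy(dtype=float)
    sd = table["sd_hz"].to_numpy(dtype=float)
    schema = schema_from_table(table)

    def resid(x):
        try:
            model = model_predictions(_from_vector(base, names, x), schema)
        except Exception:
            return np.full(obs.size, 1e6)
        r = (model - obs) / sd
        return np.where(np.isfinite(r), r, 1e6)

    fit = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-10, ftol=1e-10, x_scale="jac")
    nll = 0.5 * float(np.sum(fit.fun ** 2)) \
        + float(np.sum(np.log(sd))) + 0.5 * sd.size * LOG2PI
    return fit.x, nll


def fit_global(table: pd.DataFrame, variant: str = "three_module",
               n_restarts: int = 32, free=None,
               base_params: ModelParams | None = None,
               seed: int = 0, n_bootstrap: int = 40,
               ci_method: str = "bootstrap") -> FitResult:
    """Multi-start bounded fit of the model to a measurement table.

    Starts are drawn uniformly inside the (log-scaled) bounds, always
    including the baseline parameter point; the best restart wins.  CIs
    span the 16th-84th percentiles of parametric-bootstrap refits
    (``ci_method='bootstrap'``) or of the Gaussian curvature approximation
    (``'curvature'``); a table with fewer rows than free parameters is
    flagged under-determined and gets no CIs.
    """
    rng = np.random.default_rng(seed)
    base = _copy_params(base_params or ModelParams(variant=variant))
    base.variant = variant
    names = _free_names(variant, free)
    lo, hi = _bounds(names)
    starts = [_to_vector(base, names)]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(lo + (hi - lo) * rng.uniform(size=lo.size))
    best_x, best_nll, losses = None, float("inf"), []
    for x0 in starts:
        try:
            x, nll = _fit_once(table, base, names, np.clip(x0, lo, hi), lo, hi)
        except Exception:
            losses.append(float("inf"))
            continue
        losses.append(nll)
        if nll < best_nll:
            best_x, best_nll = x, nll
    if best_x is None:
        raise RuntimeError(f"no restart converged; losses: {losses}")
    best_params = _from_vector(base, names, best_x)
    est = {n: FREE_PARAMS[n][0](best_params) for n in names}
    under = len(table) < len(names)

    ci_lo: dict = {}
    ci_hi: dict = {}
    if not under and n_bootstrap > 1:
        model_at_fit = predict_table(best_params, table)
        sd = table["sd_hz"].to_numpy(dtype=float)
        draws = {n: [] for n in names}
        for _ in range(n_bootstrap):
            boot = table.copy()
            boot["delta_rate_hz"] = model_at_fit + rng.normal(0, sd)
            try:  # warm-started single fit per bootstrap replicate
                xb, _ = _fit_once(boot, base, names, best_x, lo, hi)
            except Exception:
                continue
            pb = _from_vector(base, names, xb)
            for n in names:
                draws[n].append(FREE_PARAMS[n][0](pb))
        for n in names:
            if len(draws[n]) >= 8:
                ci_lo[n] = float(np.percentile(draws[n], 16))
                ci_hi[n] = float(np.percentile(draws[n], 84))
    return FitResult(params=best_params, estimates=est,
                     ci_lo=ci_lo, ci_hi=ci_hi, loss=best_nll,
                     n_restarts=n_restarts, seed=seed, free_names=names,
                     restart_losses=tuple(losses), underdetermined=under)


def compare_variants(table: pd.DataFrame, seed: int = 0,
                     n_restarts: int = 16, n_bootstrap: int = 24) -> dict:
    """Fit the three- and two-module variants and compare shared parameters.

    The two-module fit uses only the rows whose neurons exist in that
    variant.  Reports per-shared-parameter estimates and whether the two
    fits' 16-84% intervals overlap.
    """
    from .circuit import TWO_MODULE_NEURONS
    fits = {}
    fits["three_module"] = fit_global(table, "three_module", n_restarts,
                                      seed=seed, n_bootstrap=n_bootstrap)
    sub = table[table["neuron"].isin(TWO_MODULE_NEURONS)].reset_index(drop=True)
    fits["two_module"] = fit_global(sub, "two_module", n_restarts,
                                    seed=seed + 1, n_bootstrap=n_bootstrap)
    shared = [n for n in fits["two_module"].free_names
              if n in fits["three_module"].free_names]
    rows = []
    for n in shared:
        f3, f2 = fits["three_module"], fits["two_module"]
        lo3, hi3 = f3.ci_lo.get(n, -math.inf), f3.ci_hi.get(n, math.inf)
        lo2, hi2 = f2.ci_lo.get(n, -math.inf), f2.ci_hi.get(n, math.inf)
        overlap = max(lo3, lo2) <= min(hi3, hi2)
        rows.append((n, f3.estimates[n], f2.estimates[n], overlap))
    report = pd.DataFrame(rows, columns=["param", "three_module",
                                         "two_module", "ci_overlap"])
    return {"fits": fits, "shared": report,
            "underdetermined": any(f.underdetermined for f in fits.values())}


def recovery_study(truth: GroundTruth, n_replicates: int = 8, seed: int = 0,
                   free=("tau_fast", "tau_slow"), n_restarts: int = 4,
                   n_bootstrap: int = 16) -> pd.DataFrame:
    """Parameter recovery: generate -> fit -> bias / RMSE / CI coverage.

    Each replicate gets an independent seed; results do not depend on the
    replicate ordering.  Returns one row per free parameter.
    """
    if n_replicates < 2:
        raise CircuitError("n_replicates must be >= 2")
    schema = default_schema()
    names = tuple(free)
    truth_vals = {n: FREE_PARAMS[n][0](truth.params) for n in names}
    est = {n: [] for n in names}
    cover = {n: [] for n in names}
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                 ss.spawn(n_replicates)]
    for rs in rep_seeds:
        t = GroundTruth(params=truth.params, noise_sd=truth.noise_sd, seed=rs)
        table = gen_measurement_table(t, schema)
        fit = fit_global(table, truth.params.variant, n_restarts, free=names,
                         base_params=truth.params, seed=rs,
                         n_bootstrap=n_bootstrap)
        for n in names:
            est[n].append(fit.estimates[n])
            if n in fit.ci_lo:
                cover[n].append(fit.ci_lo[n] <= truth_vals[n] <= fit.ci_hi[n])
    rows = []
    for n in names:
        e = np.array(est[n])
        rows.append((n, truth_vals[n], float(e.mean() - truth_vals[n]),
                     float(np.sqrt(np.mean((e - truth_vals[n]) ** 2))),
                     float(np.mean(cover[n])) if cover[n] else math.nan,
                     len(e)))
    return pd.DataFrame(rows, columns=["param", "truth", "bias", "rmse",
                                       "ci_coverage", "n"])
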