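"""Mixed-effects maximum-likelihood estimation of the withdrawal model.

Each patient carries one random effect, a lognormal deviation ``eta`` of the
baseline severity with SD ``omega``.  The marginal likelihood integrates the
conditional score likelihood over ``eta``; the integral is approximated by a
Laplace expansion around the per-patient mode (found by a safeguarded
Newton search with analytic first and second derivatives) or, as an oracle,
by adaptive Gauss-Hermite quadrature centered at the same mode.

Parameters are estimated on an unconstrained scale: logs for strictly
positive parameters (baseline, omega, k_dep, slopes), a logistic transform
for the dispersion ``delta``, and a nested logistic transform for the
Markov inflation probabilities that keeps the total applicable inflation
mass below one for every possible previous score.  The objective function
value (OFV) is -2 log-likelihood, as used for nested model comparison;
AIC = OFV + 2 x (number of free parameters).

Standard errors come from a central-difference numerical Hessian of the
negative marginal log-likelihood on the transformed scale, with
delta-method back-transformation for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit, logsumexp
from scipy.stats import chi2

from .cohort import CohortDataset, Patient
from .dependence import dependence_on_segments
from .params import DrugEffectParams, IWSParams
from .pk import PKParameters, evaluate_segments, modal_plasma
from .scores import N_SCORES, SCORES

__all__ = [
    "CohortEvaluator",
    "FitResult",
    "ModelComparison",
    "individual_loglik",
    "marginal_loglik",
    "fit",
    "compare_models",
    "posthoc_eta",
    "standard_errors",
    "diagnostics",
    "shared_param_names",
    "param_names",
]

_LOG_FACT = gammaln(SCORES + 1.0)
_LOG_2PI = math.log(2.0 * math.pi)

SHARED_PARAMS = ("baseline", "omega", "delta", "pi00", "pi0x", "pipm")


def shared_param_names() -> tuple[str, ...]:
    return SHARED_PARAMS


def param_names(drug_ids) -> list[str]:
    """Canonical parameter-name ordering for a model with the given drugs."""
    names = list(SHARED_PARAMS)
    for d in drug_ids:
        names += [f"kdep_{d}", f"slope_{d}"]
    return names


# ---------------------------------------------------------------- transforms

def _natural_vector(params: IWSParams, names) -> dict[str, float]:
    out = {}
    for n in names:
        if n == "baseline":
            out[n] = params.typical_baseline
        elif n == "omega":
            out[n] = params.omega_baseline
        elif n == "delta":
            out[n] = params.delta
        elif n == "pi00":
            out[n] = params.pi_same_prev0
        elif n == "pi0x":
            out[n] = params.pi_same_prevx
        elif n == "pipm":
            out[n] = params.pi_pm
        elif n.startswith("kdep_"):
            out[n] = params.drug_effects[n[5:]].k_dep
        elif n.startswith("slope_"):
            out[n] = params.drug_effects[n[6:]].slope
        else:
            raise KeyError(f"unknown parameter {n!r}")
    return out


def _to_unconstrained(natural: dict[str, float]) -> dict[str, float]:
    """Map natural values to the unconstrained estimation scale.

    The three inflation probabilities use a nested logistic transform:
    ``pipm`` is bounded by 1/4 (so four +/- targets can never exhaust the
    mass) and the two same-score inflations are scaled by the mass the
    +/- targets leave available for their worst-case previous score.
    """
    x = {}
    pipm = natural.get("pipm")
    for n, v in natural.items():
        if n == "delta":
            x[n] = float(logit(np.clip(v, 1e-12, 1 - 1e-12)))
        elif n == "pipm":
            x[n] = float(logit(np.clip(4.0 * v, 1e-12, 1 - 1e-12)))
        elif n == "pi00":
            x[n] = float(logit(np.clip(v / (1.0 - 2.0 * pipm), 1e-12, 1 - 1e-12)))
        elif n == "pi0x":
            x[n] = float(logit(np.clip(v / (1.0 - 4.0 * pipm), 1e-12, 1 - 1e-12)))
        else:  # strictly positive: log scale
            x[n] = float(np.log(max(v, 1e-300)))
    return x


def _from_unconstrained(x: dict[str, float]) -> dict[str, float]:
    nat = {}
    pipm = float(expit(x["pipm"])) / 4.0 if "pipm" in x else None
    for n, v in x.items():
        if n == "delta":
            nat[n] = float(expit(v))
        elif n == "pipm":
            nat[n] = pipm
        elif n == "pi00":
            nat[n] = float(expit(v)) * (1.0 - 2.0 * pipm)
        elif n == "pi0x":
            nat[n] = float(expit(v)) * (1.0 - 4.0 * pipm)
        else:
            nat[n] = float(np.exp(v))
    return nat


def _apply_natural(base: IWSParams, natural: dict[str, float]) -> IWSParams:
    """Overwrite ``base`` with the natural values in ``natural``."""
    effects = dict(base.drug_effects)
    for n, v in natural.items():
        if n.startswith("kdep_"):
            d = n[5:]
            effects[d] = replace(effects[d], k_dep=v)
        elif n.startswith("slope_"):
            d = n[6:]
            effects[d] = replace(effects[d], slope=v)
    kw = {}
    if "baseline" in natural:
        kw["typical_baseline"] = natural["baseline"]
    if "omega" in natural:
        kw["omega_baseline"] = natural["omega"]
    if "delta" in natural:
        kw["delta"] = natural["delta"]
    if "pi00" in natural:
        kw["pi_same_prev0"] = natural["pi00"]
    if "pi0x" in natural:
        kw["pi_same_prevx"] = natural["pi0x"]
    if "pipm" in natural:
        kw["pi_pm"] = natural["pipm"]
    return replace(base, drug_effects=effects, **kw)


# ---------------------------------------------------------------- evaluator

class CohortEvaluator:
    """Precomputed cohort structures for fast repeated likelihood evaluation.

    Plasma kinetics do not depend on any estimated parameter, so modal
    plasma representations and plasma concentrations at observation times
    are computed once per patient and drug.  Dependence/shortage profiles
    depend only on the drug's ``k_dep`` and are cached per value, which
    makes finite-difference gradients over the non-PK parameters cheap.
    """

    def __init__(self, dataset: CohortDataset, pk_params: dict[str, PKParameters],
                 drug_ids=None):
        self.dataset = dataset
        self.drug_ids = list(drug_ids) if drug_ids is not None else sorted(
            d for d in dataset.drug_ids if d in pk_params
        )
        self.n_pat = dataset.n_patients

        pat_idx, scores, prev, order = [], [], [], []
        self._slices = []
        pos = 0
        for i, p in enumerate(dataset.patients):
            m = p.obs_times.size
            pat_idx.append(np.full(m, i))
            scores.append(p.scores)
            pr = np.concatenate([[-1], p.scores[:-1]]) if m else np.array([], dtype=int)
            prev.append(pr)
            self._slices.append(slice(pos, pos + m))
            pos += m
        self.N = pos
        self.pat_idx = np.concatenate(pat_idx) if pat_idx else np.array([], dtype=int)
        self.y = np.concatenate(scores).astype(int) if scores else np.array([], dtype=int)
        self.prev = np.concatenate(prev).astype(int) if prev else np.array([], dtype=int)
        self.is_first = self.prev < 0
        dy = np.abs(self.y - self.prev)
        self.same = (~self.is_first) & (dy == 0)
        self.near = (~self.is_first) & ((dy == 1) | (dy == 2))
        self.prev0 = (~self.is_first) & (self.prev == 0)
        # number of +/-1, +/-2 targets of the previous score inside 0..10
        pm = np.zeros(self.N)
        pv = np.clip(self.prev, 0, 10)
        pm[~self.is_first] = (
            (np.minimum(pv + 2, 10) - np.maximum(pv - 2, 0))[~self.is_first]
        )
        self.n_pm = pm  # 4 interior, fewer at the boundary

        # theta-independent plasma structures
        self._segments: list[dict] = []
        self._cplasma: list[dict] = []
        for p in dataset.patients:
            segs, cps = {}, {}
            if p.obs_times.size:
                t_end = float(p.obs_times[-1])
                for d in self.drug_ids:
                    ev = p.events_for(d)
                    if not ev:
                        continue
                    if d not in pk_params:
                        raise KeyError(f"no PK parameters for drug {d!r}")
                    segs[d] = modal_plasma(ev, pk_params[d], p.weight, t_end)
                    cps[d] = evaluate_segments(segs[d], p.obs_times)
            self._segments.append(segs)
            self._cplasma.append(cps)
        self._shortage_cache: dict[tuple[str, float], np.ndarray] = {}
        self.eta_warm = np.zeros(self.n_pat)

    # ------------------------------------------------------------- effects
    def shortage(self, drug: str, k_dep: float) -> np.ndarray:
        key = (drug, float(k_dep))
        hit = self._shortage_cache.get(key)
        if hit is not None:
            return hit
        out = np.zeros(self.N)
        for i, p in enumerate(self.dataset.patients):
            segs = self._segments[i].get(drug)
            if segs is None:
                continue
            cd = dependence_on_segments(segs, k_dep, p.obs_times)
            out[self._slices[i]] = np.maximum(cd - self._cplasma[i][drug], 0.0)
        if len(self._shortage_cache) > 64:
            self._shortage_cache.clear()
        self._shortage_cache[key] = out
        return out

    def effects_total(self, params: IWSParams) -> np.ndarray:
        total = np.zeros(self.N)
        for d in self.drug_ids:
            eff = params.drug_effects.get(d)
            if eff is None or eff.slope == 0:
                continue
            total += eff.slope * self.shortage(d, eff.k_dep)
        return total

    # ----------------------------------------------------------- obs logp
    def _inflation_terms(self, params: IWSParams):
        """Per-observation retained inflation mass Pi and added point mass."""
        Pi = np.where(
            self.is_first, 0.0,
            np.where(self.prev0, params.pi_same_prev0, params.pi_same_prevx)
            + params.pi_pm * self.n_pm,
        )
        add = np.zeros(self.N)
        add[self.same] = np.where(
            self.prev0[self.same], params.pi_same_prev0, params.pi_same_prevx
        )
        add[self.near] = params.pi_pm
        return Pi, add

    def obs_logp(self, lam: np.ndarray, params: IWSParams, Pi, add, derivs=False):
        """Log-probability of each observed score given severity ``lam``.

        With ``derivs=True`` also returns d/dlam and d2/dlam2 of the
        log-probability (analytic, used by the inner Newton search).
        """
        lam = np.maximum(lam, 1e-12)
        lamc = lam[:, None]
        shifted = lamc + params.delta * SCORES
        logu = (
            np.log(lamc)
            + (SCORES - 1) * np.log(shifted)
            - lamc
            - params.delta * SCORES
            - _LOG_FACT
        )
        logu -= logsumexp(logu, axis=1, keepdims=True)
        p_base = np.exp(logu)
        rows = np.arange(self.N)
        p_y = p_base[rows, self.y]
        p_obs = np.maximum((1.0 - Pi) * p_y + add, 1e-300)
        logp = np.log(p_obs)
        if not derivs:
            return logp
        s = 1.0 / lamc + (SCORES - 1) / shifted - 1.0
        sp = -1.0 / lamc**2 - (SCORES - 1) / shifted**2
        sbar = np.einsum("ij,ij->i", p_base, s)
        spbar = np.einsum("ij,ij->i", p_base, sp)
        s2bar = np.einsum("ij,ij->i", p_base, s * s)
        var = s2bar - sbar**2
        s_y = s[rows, self.y]
        sp_y = sp[rows, self.y]
        dp_y = p_y * (s_y - sbar)
        d2p_y = p_y * ((s_y - sbar) ** 2 + sp_y - spbar - var)
        d1 = (1.0 - Pi) * dp_y / p_obs
        d2 = (1.0 - Pi) * d2p_y / p_obs - d1**2
        return logp, d1, d2

    # ---------------------------------------------------------- likelihood
    def patient_loglik(self, params: IWSParams, eta: np.ndarray) -> np.ndarray:
        """Conditional log-likelihood per patient at the given eta vector."""
        E = self.effects_total(params)
        Pi, add = self._inflation_terms(params)
        lam = params.typical_baseline * np.exp(eta)[self.pat_idx] + E
        logp = self.obs_logp(lam, params, Pi, add)
        return np.bincount(self.pat_idx, weights=logp, minlength=self.n_pat)

    def _inner_newton(self, params: IWSParams, E, Pi, add, eta0):
        """Per-patient mode of the eta-conditional log-posterior.

        Vectorized safeguarded Newton with analytic derivatives; patients
        that fail to converge fall back to a bracketed grid search.
        Returns (eta_hat, g(eta_hat) per patient, curvature g'' < 0).
        """
        B = params.typical_baseline
        omega = params.omega_baseline
        w2 = omega**2

        def g_and_derivs(eta, want_derivs=True):
            u = B * np.exp(eta)
            lam = u[self.pat_idx] + E
            if want_derivs:
                logp, d1, d2 = self.obs_logp(lam, params, Pi, add, derivs=True)
            else:
                logp = self.obs_logp(lam, params, Pi, add)
            gv = np.bincount(self.pat_idx, weights=logp, minlength=self.n_pat)
            gv = gv - eta**2 / (2 * w2) - 0.5 * np.log(2 * np.pi * w2)
            if not want_derivs:
                return gv
            up = u[self.pat_idx]
            g1 = np.bincount(self.pat_idx, weights=d1 * up, minlength=self.n_pat)
            g1 -= eta / w2
            g2 = np.bincount(
                self.pat_idx, weights=d2 * up**2 + d1 * up, minlength=self.n_pat
            )
            g2 -= 1.0 / w2
            return gv, g1, g2

        eta = eta0.copy()
        gv, g1, g2 = g_and_derivs(eta)
        converged = np.zeros(self.n_pat, dtype=bool)
        for _ in range(50):
            curv = np.minimum(g2, -1e-8)
            step = np.where(converged, 0.0, -g1 / curv)
            step = np.clip(step, -2.0, 2.0)
            if np.max(np.abs(step)) < 1e-8:
                converged[:] = True
                break
            # step halving on patients whose objective decreases
            scale = np.ones(self.n_pat)
            for _ in range(12):
                trial = eta + scale * step
                gt, g1t, g2t = g_and_derivs(trial)
                worse = (gt < gv - 1e-12) & ~converged
                if not worse.any():
                    break
                scale[worse] *= 0.5
            improved = ~converged
            eta = np.where(improved, trial, eta)
            gv = np.where(improved, gt, gv)
            g1 = np.where(improved, g1t, g1)
            g2 = np.where(improved, g2t, g2)
            converged |= np.abs(scale * step) < 1e-8
            if converged.all():
                break
        if not converged.all():
            # grid fallback for the stragglers
            grid = np.linspace(-6 * max(params.omega_baseline, 0.5),
                               6 * max(params.omega_baseline, 0.5), 121)
            for i in np.where(~converged)[0]:
                best, best_g = eta[i], gv[i]
                for e in grid:
                    trial = eta.copy()
                    trial[i] = e
                    gt = g_and_derivs(trial, want_derivs=False)
                    if gt[i] > best_g:
                        best, best_g = e, gt[i]
                eta[i] = best
            gv, g1, g2 = g_and_derivs(eta)
        return eta, gv, np.minimum(g2, -1e-8)

    def laplace(self, params: IWSParams, update_warm: bool = True):
        """Laplace-approximate marginal log-likelihood (total, per patient, eta)."""
        E = self.effects_total(params)
        Pi, add = self._inflation_terms(params)
        if params.omega_baseline < 1e-8:
            eta = np.zeros(self.n_pat)
            lam = params.typical_baseline + E
            logp = self.obs_logp(lam, params, Pi, add)
            per = np.bincount(self.pat_idx, weights=logp, minlength=self.n_pat)
            return float(per.sum()), per, eta
        eta0 = np.clip(self.eta_warm, -5 * params.omega_baseline, 5 * params.omega_baseline)
        eta, gv, g2 = self._inner_newton(params, E, Pi, add, eta0)
        per = gv + 0.5 * _LOG_2PI - 0.5 * np.log(-g2)
        if update_warm:
            self.eta_warm = eta
        return float(per.sum()), per, eta

    def adaptive_quadrature(self, params: IWSParams, n_nodes: int = 15):
        """Adaptive Gauss-Hermite marginal log-likelihood (oracle method)."""
        E = self.effects_total(params)
        Pi, add = self._inflation_terms(params)
        if params.omega_baseline < 1e-8:
            total, per, eta = self.laplace(params, update_warm=False)
            return total, per, eta
        eta0 = np.clip(self.eta_warm, -5 * params.omega_baseline, 5 * params.omega_baseline)
        eta, gv, g2 = self._inner_newton(params, E, Pi, add, eta0)
        sigma = 1.0 / np.sqrt(-g2)
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        B = params.typical_baseline
        w2 = params.omega_baseline**2
        logterms = np.empty((n_nodes, self.n_pat))
        for k, (xk, wk) in enumerate(zip(nodes, weights)):
            ek = eta + math.sqrt(2.0) * sigma * xk
            lam = B * np.exp(ek)[self.pat_idx] + E
            logp = self.obs_logp(lam, params, Pi, add)
            gk = np.bincount(self.pat_idx, weights=logp, minlength=self.n_pat)
            gk = gk - ek**2 / (2 * w2) - 0.5 * np.log(2 * np.pi * w2)
            logterms[k] = math.log(wk) + xk**2 + gk
        per = np.log(math.sqrt(2.0) * sigma) + logsumexp(logterms, axis=0)
        return float(per.sum()), per, eta


# ----------------------------------------------------------------- results

@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    params: IWSParams
    ofv: float
    n_free: int
    free_names: list[str]
    estimates: dict[str, float]
    eta: np.ndarray
    converged: bool
    n_starts: int
    seed: int | None
    trace: list[dict] = field(default_factory=list)
    se: dict[str, float] | None = None
    ci: dict[str, tuple[float, float]] | None = None
    cov_ok: bool | None = None
    method: str = "laplace"

    @property
    def aic(self) -> float:
        return self.ofv + 2.0 * self.n_free

    @property
    def loglik(self) -> float:
        return -0.5 * self.ofv

    def to_dict(self) -> dict:
        return {
            "ofv": self.ofv,
            "aic": self.aic,
            "n_free": self.n_free,
            "free_names": self.free_names,
            "estimates": self.estimates,
            "se": self.se,
            "ci": {k: list(v) for k, v in self.ci.items()} if self.ci else None,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "method": self.method,
            "posthoc_eta": self.eta.tolist(),
            "params": self.params.to_dict(),
            "trace": self.trace,
        }


@dataclass(frozen=True)
class ModelComparison:
    """Likelihood-ratio test and AIC difference between two fits."""

    delta_ofv: float
    df: int
    p_value: float | None
    delta_aic: float
    nested: bool


# ----------------------------------------------------------- public surface

def individual_loglik(
    patient: Patient,
    params: IWSParams,
    pk_params: dict[str, PKParameters],
    eta: float = 0.0,
) -> float:
    """Conditional log-likelihood of one patient's scores at a given eta.

    The first observation uses the uninflated score distribution; later
    ones condition on the previously *observed* score.  Returns ``-inf``
    if any observation has zero probability.
    """
    ev = CohortEvaluator(CohortDataset([patient]), pk_params,
                         drug_ids=list(params.drug_effects))
    val = float(ev.patient_loglik(params, np.array([float(eta)]))[0])
    return val


def marginal_loglik(
    params: IWSParams,
    dataset: CohortDataset,
    pk_params: dict[str, PKParameters],
    method: str = "laplace",
    n_nodes: int = 15,
    evaluator: CohortEvaluator | None = None,
) -> float:
    """Marginal log-likelihood over the baseline random effect.

    ``method`` is ``"laplace"`` or ``"adaptive-quadrature"`` (the slower
    Gauss-Hermite oracle, >= 15 nodes recommended).
    """
    ev = evaluator or CohortEvaluator(dataset, pk_params,
                                      drug_ids=list(params.drug_effects))
    if method == "laplace":
        total, _, _ = ev.laplace(params, update_warm=False)
    elif method in ("adaptive-quadrature", "agq"):
        total, _, _ = ev.adaptive_quadrature(params, n_nodes=n_nodes)
    else:
        raise ValueError(f"unknown method {method!r}")
    return total


def fit(
    dataset: CohortDataset,
    pk_params: dict[str, PKParameters],
    initial: IWSParams,
    free: list[str] | None = None,
    n_starts: int = 3,
    seed: int | None = 0,
    method: str = "laplace",
    maxfun: int = 1000,
    start_maxfun: int | None = 200,
    perturb_sd: float = 0.35,
    compute_se: bool = False,
) -> FitResult:
    """Maximize the marginal likelihood over the chosen free parameters.

    ``free`` lists parameter names (``baseline``, ``omega``, ``delta``,
    ``pi00``, ``pi0x``, ``pipm``, ``kdep_<drug>``, ``slope_<drug>``);
    by default every shared parameter plus the per-drug parameters of the
    drugs present in ``initial.drug_effects`` are free.  Multi-start:
    start 0 begins at ``initial``; further starts perturb the transformed
    vector by N(0, ``perturb_sd``^2) and get a reduced function budget
    (``start_maxfun``); the best start is then polished with the full
    budget.  Ties break by lowest OFV, then lowest parameter norm.
    """
    drug_ids = list(initial.drug_effects)
    all_names = param_names(drug_ids)
    free = list(free) if free is not None else all_names
    unknown = [n for n in free if n not in all_names]
    if unknown:
        raise KeyError(f"unknown free parameters {unknown}")
    evaluator = CohortEvaluator(dataset, pk_params, drug_ids=drug_ids)

    if not free:
        total, _, eta = evaluator.laplace(initial)
        return FitResult(
            params=initial, ofv=-2.0 * total, n_free=0, free_names=[],
            estimates={}, eta=eta, converged=True, n_starts=0, seed=seed,
            method=method,
        )

    x0_dict = _to_unconstrained(_natural_vector(initial, free))
    x0 = np.array([x0_dict[n] for n in free])

    def build(x: np.ndarray) -> IWSParams:
        nat = _from_unconstrained(dict(zip(free, x)))
        return _apply_natural(initial, nat)

    def objective(x: np.ndarray) -> float:
        p = build(x)
        if method == "laplace":
            total, _, _ = evaluator.laplace(p)
        else:
            total, _, _ = evaluator.adaptive_quadrature(p)
        if not np.isfinite(total):
            return 1e12
        return -total

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(x0 + rng.normal(0.0, perturb_sd, size=x0.size))

    opts = {"maxfun": maxfun, "ftol": 1e-10, "gtol": 1e-6, "eps": 1e-5}
    trace, results = [], []
    for si, xs in enumerate(starts):
        o = dict(opts)
        if si > 0 and start_maxfun is not None:
            o["maxfun"] = start_maxfun
        res = minimize(objective, xs, method="L-BFGS-B", options=o)
        trace.append({"start": si, "ofv": 2.0 * float(res.fun),
                      "success": bool(res.success), "nfev": int(res.nfev)})
        results.append(res)
    best = min(results, key=lambda r: (r.fun, np.linalg.norm(r.x)))
    if len(starts) > 1 and start_maxfun is not None:
        polish = minimize(objective, best.x, method="L-BFGS-B", options=opts)
        if polish.fun <= best.fun:
            best = polish
        trace.append({"start": "polish", "ofv": 2.0 * float(best.fun),
                      "success": bool(best.success), "nfev": int(best.nfev)})

    final = build(best.x)
    total, _, eta = evaluator.laplace(final)
    result = FitResult(
        params=final,
        ofv=-2.0 * total,
        n_free=len(free),
        free_names=free,
        estimates=_natural_vector(final, free),
        eta=eta,
        converged=bool(best.success),
        n_starts=len(starts),
        seed=seed,
        trace=trace,
        method=method,
    )
    if compute_se:
        result = standard_errors(result, dataset, pk_params, evaluator=evaluator)
    return result


def compare_models(fit_null: FitResult, fit_alt: FitResult) -> ModelComparison:
    """Likelihood-ratio test (nested fits) and AIC difference.

    The null model must be nested in the alternative (its free parameters a
    subset of the alternative's); otherwise only the AIC difference is
    meaningful and ``p_value`` is ``None``.
    """
    nested = set(fit_null.free_names) <= set(fit_alt.free_names)
    delta_ofv = fit_null.ofv - fit_alt.ofv
    df = fit_alt.n_free - fit_null.n_free
    p = None
    if nested:
        if df == 0:
            p = 1.0
        elif df > 0:
            p = float(chi2.sf(max(delta_ofv, 0.0), df))
    return ModelComparison(
        delta_ofv=float(delta_ofv), df=df, p_value=p,
        delta_aic=fit_alt.aic - fit_null.aic, nested=nested,
    )


def posthoc_eta(
    params: IWSParams,
    dataset: CohortDataset | Patient,
    pk_params: dict[str, PKParameters],
) -> np.ndarray:
    """Empirical-Bayes mode of each patient's baseline deviation eta."""
    if isinstance(dataset, Patient):
        dataset = CohortDataset([dataset])
    ev = CohortEvaluator(dataset, pk_params, drug_ids=list(params.drug_effects))
    _, _, eta = ev.laplace(params, update_warm=False)
    return eta


def _central_hessian(f, x0: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = x0.size
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x0.copy(), x0.copy()
                xp[i] += step
                xm[i] -= step
                H[i, i] = (f(xp) - 2.0 * f(x0) + f(xm)) / step**2
            else:
                xpp, xpm, xmp, xmm = (x0.copy() for _ in range(4))
                xpp[[i, j]] += step
                xmm[[i, j]] -= step
                xpm[i] += step
                xpm[j] -= step
                xmp[i] -= step
                xmp[j] += step
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * step**2)
    return H


def standard_errors(
    fit_result: FitResult,
    dataset: CohortDataset,
    pk_params: dict[str, PKParameters],
    step: float = 1e-4,
    evaluator: CohortEvaluator | None = None,
) -> FitResult:
    """Asymptotic standard errors and 95% CIs at the fitted optimum.

    Numerical (central-difference) Hessian of the negative marginal
    log-likelihood on the transformed scale; its inverse is the covariance.
    CIs are estimate +/- 1.96 SE on the transformed scale, back-transformed;
    natural-scale SEs use the delta method.  A non-positive-definite Hessian
    flags the fit (``cov_ok=False``) and no CIs are reported.
    """
    free = fit_result.free_names
    if not free:
        return replace(fit_result, cov_ok=None)
    ev = evaluator or CohortEvaluator(
        dataset, pk_params, drug_ids=list(fit_result.params.drug_effects)
    )
    base = fit_result.params
    xhat_d = _to_unconstrained(_natural_vector(base, free))
    xhat = np.array([xhat_d[n] for n in free])

    def negll(x):
        p = _apply_natural(base, _from_unconstrained(dict(zip(free, x))))
        total, _, _ = ev.laplace(p, update_warm=False)
        return -total

    H = _central_hessian(negll, xhat, step=step)
    eigvals = np.linalg.eigvalsh(H)
    if eigvals.min() <= 0:
        return replace(fit_result, se=None, ci=None, cov_ok=False)
    cov = np.linalg.inv(H)
    se_x = np.sqrt(np.diag(cov))

    def natural_of(x):
        nat = _from_unconstrained(dict(zip(free, x)))
        return np.array([nat[n] for n in free])

    # delta method: numerical Jacobian of natural parameters wrt x
    J = np.zeros((len(free), len(free)))
    h = 1e-6
    for j in range(len(free)):
        xp, xm = xhat.copy(), xhat.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (natural_of(xp) - natural_of(xm)) / (2 * h)
    cov_nat = J @ cov @ J.T
    se_nat = np.sqrt(np.maximum(np.diag(cov_nat), 0.0))

    ci = {}
    for i, n in enumerate(free):
        lo = xhat.copy()
        hi = xhat.copy()
        lo[i] -= 1.96 * se_x[i]
        hi[i] += 1.96 * se_x[i]
        ci[n] = (float(natural_of(lo)[i]), float(natural_of(hi)[i]))
    se = {n: float(se_nat[i]) for i, n in enumerate(free)}
    return replace(fit_result, se=se, ci=ci, cov_ok=True)


def diagnostics(
    fit_result: FitResult,
    dataset: CohortDataset,
    pk_params: dict[str, PKParameters],
) -> dict[str, pd.DataFrame]:
    """Residual table and mirror-plot frequencies at the post hoc etas.

    Per observation: the expected score (probability-weighted mean of the
    individual post hoc score distribution, conditioned on the observed
    previous score) and the residual observed - expected.  Cohort level:
    observed vs mean-predicted frequencies of each score 0..10 and of each
    transition (current - previous score).
    """
    params = fit_result.params
    ev = CohortEvaluator(dataset, pk_params, drug_ids=list(params.drug_effects))
    eta = fit_result.eta
    if eta is None or len(eta) != ev.n_pat:
        _, _, eta = ev.laplace(params, update_warm=False)

    E = ev.effects_total(params)
    Pi, add = ev._inflation_terms(params)
    lam = np.maximum(params.typical_baseline * np.exp(eta)[ev.pat_idx] + E, 1e-12)
    lamc = lam[:, None]
    shifted = lamc + params.delta * SCORES
    logu = (np.log(lamc) + (SCORES - 1) * np.log(shifted)
            - lamc - params.delta * SCORES - _LOG_FACT)
    logu -= logsumexp(logu, axis=1, keepdims=True)
    p_base = np.exp(logu)
    # full conditional pmf per observation
    pmf = (1.0 - Pi)[:, None] * p_base
    same_val = np.where(ev.prev0, params.pi_same_prev0, params.pi_same_prevx)
    rows = np.arange(ev.N)
    obs_rows = ~ev.is_first
    pv = np.clip(ev.prev, 0, 10)
    pmf[rows[obs_rows], pv[obs_rows]] += same_val[obs_rows]
    for off in (1, 2):
        for sgn in (-1, 1):
            tgt = pv + sgn * off
            ok = obs_rows & (tgt >= 0) & (tgt <= 10)
            pmf[rows[ok], tgt[ok]] += params.pi_pm

    expected = pmf @ SCORES
    ids = np.concatenate([
        np.full(p.obs_times.size, p.patient_id, dtype=object)
        for p in dataset.patients
    ]) if ev.N else np.array([], dtype=object)
    times = np.concatenate([p.obs_times for p in dataset.patients]) if ev.N else np.array([])
    residual_table = pd.DataFrame(
        {
            "patient_id": ids,
            "time_h": times,
            "observed": ev.y,
            "expected": expected,
            "residual": ev.y - expected,
        }
    )
    score_freq = pd.DataFrame(
        {
            "score": SCORES,
            "observed": np.bincount(ev.y, minlength=N_SCORES).astype(float),
            "predicted": pmf.sum(axis=0),
        }
    )
    # transitions: current minus previous, -10..10
    offsets = np.arange(-10, 11)
    obs_tr = np.zeros(offsets.size)
    pred_tr = np.zeros(offsets.size)
    d_obs = (ev.y - ev.prev)[obs_rows]
    for k, off in enumerate(offsets):
        obs_tr[k] = np.sum(d_obs == off)
    for j in range(N_SCORES):
        tr = j - ev.prev[obs_rows] + 10
        np.add.at(pred_tr, np.clip(tr, 0, 20), pmf[obs_rows, j])
    transition_freq = pd.DataFrame(
        {"transition": offsets, "observed": obs_tr, "predicted": pred_tr}
    )
    return {
        "residuals": residual_table,
        "score_frequencies": score_freq,
        "transition_frequencies": transition_freq,
    }
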