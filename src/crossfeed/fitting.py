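"""Inference of effective leakage rates from observed community summaries.

The analytic community model predicts strain frequency and relative growth
from kinetic parameters; most of those are measurable, but effective leakage
rates (which also absorb losses into the agar) are not.  This module fits
them:

* :class:`LeakageFitModel` — fits the two amino acids' effective leakage
  rates simultaneously to the control community's observed composition and
  relative growth rate, minimizing the normalized squared distance
  ``((f_pred - f_data)/f_data)^2 + ((r_pred - r_data)/r_data)^2`` where the
  frequency term is computed on the partner (tryptophan-auxotroph) strain.
* :func:`fit_overproducer_leakage` — given a baseline fit, infers the fold
  increase in one amino acid's leakage in an overproducer strain from that
  community's composition alone.
* :func:`uptake_sweep` — predictions across an assumed fold increase in one
  consumer's uptake rate (the importer-overexpression strain), used to check
  robustness when the fold itself cannot be measured.

Optimization is bounded, multi-start and performed in log10-leakage space;
model-domain failures at a trial point are mapped to a large finite penalty
so the optimizer can continue.  Leakage bounds default to
``[u * 1e-6, u * 1e-3]``, reflecting the prior that leakage is at least a
thousandfold slower than uptake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .model import (
    CommunityPrediction,
    EnvironmentParams,
    ExchangePairParams,
    ModelDomainError,
    StrainRates,
    predict_community,
)

__all__ = [
    "CommunitySpec",
    "ObservedSummary",
    "LeakageFitModel",
    "LeakageFitResults",
    "OverproducerFitResults",
    "default_community",
    "apply_uptake_fold",
    "baseline_objective",
    "fit_baseline_leakage",
    "fit_overproducer_leakage",
    "uptake_sweep",
    "PENALTY",
]

#: Finite penalty returned when the model is undefined at a trial point.
PENALTY = 1e6


@dataclass(frozen=True)
class CommunitySpec:
    """Fixed (non-fitted) parameters of a two-auxotroph community.

    The focal strain ``dP`` is the proline auxotroph; ``dT`` the tryptophan
    auxotroph.  Uptake rates are per amino acid *and* per strain so that
    importer overexpression in one strain can be represented.

    Fields (rates 1/h, concentrations in Monod units):

    - ``mu_dP``, ``mu_dT`` — maximal growth rates; a burden from a transporter
      plasmid is expressed by lowering the carrier strain's ``mu``.
    - ``u_pro_dP`` — proline uptake by the proline auxotroph (consumer side),
      ``u_pro_dT`` — proline uptake by the partner (producer side); likewise
      ``u_trp_dT`` / ``u_trp_dP`` for tryptophan.
    - ``I_C`` — producer internal concentration.  When leakage is far below
      uptake the model depends only on the product ``l * I_C``, so fitted
      leakages absorb any change in ``I_C``.
    """

    env: EnvironmentParams
    mu_dP: float
    mu_dT: float
    I_C: float
    u_pro_dP: float
    u_pro_dT: float
    u_trp_dT: float
    u_trp_dP: float

    @classmethod
    def symmetric_uptake(cls, env: EnvironmentParams, mu_dP: float, mu_dT: float,
                         I_C: float, u_pro: float, u_trp: float) -> "CommunitySpec":
        """All strains take up a given amino acid at the same rate."""
        return cls(env=env, mu_dP=mu_dP, mu_dT=mu_dT, I_C=I_C,
                   u_pro_dP=u_pro, u_pro_dT=u_pro,
                   u_trp_dT=u_trp, u_trp_dP=u_trp)

    def pairs(self, l_pro: float, l_trp: float,
              l_pro_consumer: float | None = None,
              l_trp_consumer: float | None = None,
              ) -> tuple[ExchangePairParams, ExchangePairParams]:
        """Build the two exchange directions for trial leakage rates.

        ``l_pro``/``l_trp`` are the producer-side leakage rates (the fitted
        quantities).  By default every cell leaks a given amino acid at the
        same rate; for overproducer strains only the producer-side rate is
        raised while the consumer keeps the baseline value.
        """
        lpc = l_pro if l_pro_consumer is None else l_pro_consumer
        ltc = l_trp if l_trp_consumer is None else l_trp_consumer
        pair_dP = ExchangePairParams(
            consumer=StrainRates(self.u_pro_dP, lpc, self.mu_dP, self.I_C),
            producer=StrainRates(self.u_pro_dT, l_pro, self.mu_dT, self.I_C),
        )
        pair_dT = ExchangePairParams(
            consumer=StrainRates(self.u_trp_dT, ltc, self.mu_dT, self.I_C),
            producer=StrainRates(self.u_trp_dP, l_trp, self.mu_dP, self.I_C),
        )
        return pair_dP, pair_dT

    def predict(self, l_pro: float, l_trp: float, **kw) -> CommunityPrediction:
        pair_dP, pair_dT = self.pairs(l_pro, l_trp, **kw)
        return predict_community(pair_dP, pair_dT, self.env)


def default_community() -> CommunitySpec:
    """Representative parameters for an *E. coli* auxotroph pair.

    Density 0.65, free diffusion 2e5 um^2/h, cells 3 x 1 um, uptake 1e3 1/h
    for both amino acids, mu_n 0.5 1/h, I_C 10 Monod units.
    """
    env = EnvironmentParams(cell_density=0.65, diffusion_D=2e5,
                            cell_length=3.0, cell_width=1.0)
    return CommunitySpec.symmetric_uptake(env, mu_dP=0.5, mu_dT=0.5, I_C=10.0,
                                          u_pro=1e3, u_trp=1e3)


@dataclass(frozen=True)
class ObservedSummary:
    """Observed summary statistics for one community.

    ``f_dP_obs`` — observed frequency of the focal (proline-auxotroph)
    strain; ``r_rel_obs`` — observed growth relative to amino-acid-
    supplemented conditions (ratio of final colony diameters), optional.
    """

    community_label: str
    f_dP_obs: float
    r_rel_obs: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.f_dP_obs < 1.0:
            raise ValueError("f_dP_obs must lie strictly inside (0, 1)")
        if self.r_rel_obs is not None and not 0.0 < self.r_rel_obs <= 1.0:
            raise ValueError("r_rel_obs must lie in (0, 1]")


def _default_bounds(spec: CommunitySpec) -> dict[str, tuple[float, float]]:
    u_pro = min(spec.u_pro_dP, spec.u_pro_dT)
    u_trp = min(spec.u_trp_dT, spec.u_trp_dP)
    return {"proline": (u_pro * 1e-6, u_pro * 1e-3),
            "tryptophan": (u_trp * 1e-6, u_trp * 1e-3)}


def baseline_objective(l_pro: float, l_trp: float, spec: CommunitySpec,
                       observed: ObservedSummary) -> float:
    """Two-term normalized squared distance at a trial leakage pair.

    ``((f_pred - f_data)/f_data)^2 + ((r_pred - r_data)/r_data)^2`` where the
    frequency term is evaluated on the tryptophan auxotroph (the strain whose
    frequency is furthest from one in the control community, so the relative
    normalization is informative).  Model-domain failures return the finite
    :data:`PENALTY`.
    """
    if observed.r_rel_obs is None:
        raise ValueError("baseline objective needs an observed r_rel")
    try:
        pred = spec.predict(l_pro, l_trp)
    except (ModelDomainError, ValueError):
        return PENALTY
    f_pred_dT = 1.0 - pred.f_dP
    f_data_dT = 1.0 - observed.f_dP_obs
    term_f = ((f_pred_dT - f_data_dT) / f_data_dT) ** 2
    term_r = ((pred.r_rel - observed.r_rel_obs) / observed.r_rel_obs) ** 2
    return term_f + term_r


@dataclass
class LeakageFitResults:
    """Results of a leakage fit: estimates, diagnostics and predictions."""

    params: dict[str, float]
    objective_value: float
    bounds_used: dict[str, tuple[float, float]]
    converged: bool
    n_restarts: int
    at_bounds: dict[str, bool]
    prediction: CommunityPrediction | None
    model: "LeakageFitModel | None" = None
    restart_objectives: tuple[float, ...] = field(default_factory=tuple)

    @property
    def warnings(self) -> list[str]:
        out = [f"{k} pinned at bound" for k, v in self.at_bounds.items() if v]
        if self.prediction is not None:
            out.extend(self.prediction.validity_flags)
        return out

    def summary(self) -> str:
        lines = ["Leakage fit results", "=" * 48]
        for name, val in self.params.items():
            lo, hi = self.bounds_used[name]
            tag = "  [at bound]" if self.at_bounds.get(name) else ""
            lines.append(f"  {name:<12s} l = {val:.6g} 1/h  "
                         f"(bounds {lo:.3g} .. {hi:.3g}){tag}")
        lines.append(f"  objective     {self.objective_value:.6g}")
        lines.append(f"  converged     {self.converged}  "
                     f"(restarts: {self.n_restarts})")
        if self.prediction is not None:
            lines.append(f"  f_dP_pred     {self.prediction.f_dP:.4f}")
            lines.append(f"  r_rel_pred    {self.prediction.r_rel:.4f}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "objective_value": self.objective_value,
            "bounds_used": {k: list(v) for k, v in self.bounds_used.items()},
            "converged": self.converged,
            "n_restarts": self.n_restarts,
            "at_bounds": dict(self.at_bounds),
            "warnings": self.warnings,
        }


class LeakageFitModel:
    """Fit both effective leakage rates to one control-community summary.

    Parameters
    ----------
    observed : ObservedSummary
        Control-community composition and relative growth.
    spec : CommunitySpec
        All fixed kinetic and environmental parameters.
    bounds : dict, optional
        ``{"proline": (lo, hi), "tryptophan": (lo, hi)}`` in 1/h; defaults to
        ``[u*1e-6, u*1e-3]`` per amino acid.
    """

    def __init__(self, observed: ObservedSummary, spec: CommunitySpec,
                 bounds: dict[str, tuple[float, float]] | None = None):
        if observed.r_rel_obs is None:
            raise ValueError("LeakageFitModel requires r_rel_obs")
        self.observed = observed
        self.spec = spec
        self.bounds = bounds if bounds is not None else _default_bounds(spec)
        for name, (lo, hi) in self.bounds.items():
            if not 0 < lo < hi:
                raise ValueError(f"invalid bounds for {name}")

    def objective(self, l_pro: float, l_trp: float) -> float:
        return baseline_objective(l_pro, l_trp, self.spec, self.observed)

    def _objective_log(self, x: np.ndarray) -> float:
        return self.objective(10.0 ** x[0], 10.0 ** x[1])

    def fit(self, n_restarts: int = 16, seed: int = 0) -> LeakageFitResults:
        """Multi-start bounded Nelder-Mead in log10-leakage space.

        Start points are a Latin-hypercube over the log-bounds (seeded, so the
        fit is deterministic for a given seed).  The best restart's optimum is
        returned; an estimate within 0.1% of a bound is flagged as pinned.
        """
        lb = np.log10([self.bounds["proline"][0], self.bounds["tryptophan"][0]])
        ub = np.log10([self.bounds["proline"][1], self.bounds["tryptophan"][1]])
        sampler = qmc.LatinHypercube(d=2, seed=seed)
        starts = lb + sampler.random(n_restarts) * (ub - lb)
        best = None
        restart_objs = []
        for x0 in starts:
            res = optimize.minimize(
                self._objective_log, x0, method="Nelder-Mead",
                bounds=list(zip(lb, ub)),
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
            )
            restart_objs.append(float(res.fun))
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None
        l_pro, l_trp = 10.0 ** best.x
        params = {"proline": float(l_pro), "tryptophan": float(l_trp)}
        at_bounds = {
            name: bool(min(abs(math.log10(params[name]) - math.log10(b))
                           for b in self.bounds[name]) < 1e-3)
            for name in params
        }
        try:
            prediction = self.spec.predict(l_pro, l_trp)
        except ModelDomainError:
            prediction = None
        converged = bool(best.success) and bool(best.fun < PENALTY)
        return LeakageFitResults(
            params=params, objective_value=float(best.fun),
            bounds_used=dict(self.bounds), converged=converged,
            n_restarts=n_restarts, at_bounds=at_bounds,
            prediction=prediction, model=self,
            restart_objectives=tuple(restart_objs),
        )


def fit_baseline_leakage(spec: CommunitySpec, observed: ObservedSummary,
                         bounds: dict[str, tuple[float, float]] | None = None,
                         n_restarts: int = 16, seed: int = 0) -> LeakageFitResults:
    """Convenience wrapper: build a :class:`LeakageFitModel` and fit it."""
    return LeakageFitModel(observed, spec, bounds=bounds).fit(
        n_restarts=n_restarts, seed=seed)


@dataclass
class OverproducerFitResults:
    """One-dimensional leakage fit for an overproducer strain."""

    amino_acid: str
    fitted_leakage: float
    baseline_leakage: float
    fold_change: float
    objective_value: float
    bounds_used: tuple[float, float]
    converged: bool
    at_bound: bool
    prediction: CommunityPrediction | None

    @property
    def warnings(self) -> list[str]:
        out = ["leakage pinned at bound"] if self.at_bound else []
        if self.prediction is not None:
            out.extend(self.prediction.validity_flags)
        return out

    def summary(self) -> str:
        lines = [
            f"Overproducer leakage fit ({self.amino_acid})", "=" * 48,
            f"  fitted leakage  {self.fitted_leakage:.6g} 1/h",
            f"  baseline        {self.baseline_leakage:.6g} 1/h",
            f"  fold change     {self.fold_change:.4g}",
            f"  objective       {self.objective_value:.6g}",
            f"  converged       {self.converged}",
        ]
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "amino_acid": self.amino_acid,
            "fitted_leakage": self.fitted_leakage,
            "baseline_leakage": self.baseline_leakage,
            "fold_change": self.fold_change,
            "objective_value": self.objective_value,
            "bounds_used": list(self.bounds_used),
            "converged": self.converged,
            "warnings": self.warnings,
        }


def _overproducer_objective(l_trial: float, which: str, baseline_params: dict,
                            spec: CommunitySpec, observed: ObservedSummary) -> float:
    l_pro_b = baseline_params["proline"]
    l_trp_b = baseline_params["tryptophan"]
    try:
        if which == "proline":
            pred = spec.predict(l_trial, l_trp_b, l_pro_consumer=l_pro_b)
        else:
            pred = spec.predict(l_pro_b, l_trial, l_trp_consumer=l_trp_b)
    except (ModelDomainError, ValueError):
        return PENALTY
    return (pred.f_dP - observed.f_dP_obs) ** 2


def fit_overproducer_leakage(baseline: LeakageFitResults,
                             observed_overproducer: ObservedSummary,
                             which_amino_acid: str,
                             spec: CommunitySpec | None = None,
                             bounds: tuple[float, float] | None = None,
                             seed: int = 0) -> OverproducerFitResults:
    """Fit one amino acid's overproducer leakage to a community composition.

    The partner amino acid's leakage, and the consumer-side leakage of the
    overproduced amino acid, are held at the baseline fit; only the
    producer-side leakage is free.  The objective is the squared distance
    between predicted and observed focal-strain frequency.  Default bounds
    span baseline/100 to 1000x baseline (capped below the uptake rate).
    """
    if which_amino_acid not in ("proline", "tryptophan"):
        raise ValueError("which_amino_acid must be 'proline' or 'tryptophan'")
    if spec is None:
        if baseline.model is None:
            raise ValueError("pass spec explicitly when baseline has no model")
        spec = baseline.model.spec
    l_base = baseline.params[which_amino_acid]
    if bounds is None:
        u = (min(spec.u_pro_dP, spec.u_pro_dT) if which_amino_acid == "proline"
             else min(spec.u_trp_dT, spec.u_trp_dP))
        bounds = (l_base * 1e-2, min(l_base * 1e3, 0.5 * u))
    lo, hi = math.log10(bounds[0]), math.log10(bounds[1])
    res = optimize.minimize_scalar(
        lambda x: _overproducer_objective(10.0 ** x, which_amino_acid,
                                          baseline.params, spec,
                                          observed_overproducer),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    l_fit = float(10.0 ** res.x)
    at_bound = bool(min(abs(res.x - lo), abs(res.x - hi)) < 1e-3)
    try:
        if which_amino_acid == "proline":
            prediction = spec.predict(l_fit, baseline.params["tryptophan"],
                                      l_pro_consumer=baseline.params["proline"])
        else:
            prediction = spec.predict(baseline.params["proline"], l_fit,
                                      l_trp_consumer=baseline.params["tryptophan"])
    except ModelDomainError:
        prediction = None
    return OverproducerFitResults(
        amino_acid=which_amino_acid, fitted_leakage=l_fit,
        baseline_leakage=l_base, fold_change=l_fit / l_base,
        objective_value=float(res.fun), bounds_used=bounds,
        converged=bool(res.success) and bool(res.fun < PENALTY),
        at_bound=at_bound, prediction=prediction,
    )


def apply_uptake_fold(spec: CommunitySpec, fold: float,
                      amino_acid: str = "proline",
                      uptake_scope: str = "community") -> CommunitySpec:
    """Scale one amino acid's uptake rate by ``fold``.

    ``uptake_scope="community"`` scales every cell's uptake of the amino acid
    (the model treats uptake as a per-molecule property of the community, so
    this is the canonical sweep); ``"consumer"`` scales only the auxotroph
    that depends on it (importer overexpression in one strain).
    """
    if amino_acid == "proline":
        fields = {"u_pro_dP": spec.u_pro_dP * fold}
        if uptake_scope == "community":
            fields["u_pro_dT"] = spec.u_pro_dT * fold
    elif amino_acid == "tryptophan":
        fields = {"u_trp_dT": spec.u_trp_dT * fold}
        if uptake_scope == "community":
            fields["u_trp_dP"] = spec.u_trp_dP * fold
    else:
        raise ValueError("amino_acid must be 'proline' or 'tryptophan'")
    if uptake_scope not in ("community", "consumer"):
        raise ValueError("uptake_scope must be 'community' or 'consumer'")
    return replace(spec, **fields)


def uptake_sweep(spec: CommunitySpec, l_pro: float, l_trp: float,
                 fold_range: tuple[float, float] = (10.0, 100.0),
                 n_points: int = 10, amino_acid: str = "proline",
                 uptake_scope: str = "community",
                 **pair_kw) -> pd.DataFrame:
    """Predictions across an assumed fold increase in one uptake rate.

    Folds are log-spaced over ``fold_range``; an unmodified ``fold=1``
    baseline row is always included first.  By default the fold applies to
    the whole community's uptake of the amino acid (see
    :func:`apply_uptake_fold`), under which the interaction range shrinks as
    ``1/sqrt(u)`` while composition barely moves — the model's core
    uptake/leakage asymmetry.
    """
    if fold_range[0] <= 0 or fold_range[1] < fold_range[0]:
        raise ValueError("fold_range must be positive and ordered")
    folds = np.concatenate([[1.0], np.geomspace(*fold_range, n_points)])
    rows = []
    for fold in folds:
        s = apply_uptake_fold(spec, fold, amino_acid, uptake_scope)
        pred = s.predict(l_pro, l_trp, **pair_kw)
        rows.append({
            "fold": fold,
            "R_int_pro": pred.range_dP.R_int,
            "R_int_trp": pred.range_dT.R_int,
            "N_dP": pred.N_dP, "N_dT": pred.N_dT,
            "f_dP": pred.f_dP, "r_rel": pred.r_rel,
            "flags": ";".join(pred.validity_flags),
        })
    return pd.DataFrame(rows)
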