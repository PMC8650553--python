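"""Synthetic questionnaire cohorts with the study's statistical structure.

Each simulated worker carries a latent dichotomous job-stress state
(P(high) = 0.50) and a latent safety-climate state whose conditional
distribution given job stress (0.37 high | high stress, 0.69 high | low
stress) reproduces the published safety-climate marginal of 0.53.  The
accident outcome is drawn from the published accident CPT
(P(yes | SC, JS) = 0.91 / 0.93 / 0.32 / 0.95), implying an accident
marginal of 0.7202 analytically.  Observable questionnaire scores — 16
job-stress scale mean-scores on the GJSQ 1–5 Likert range and 7
safety-climate dimension mean-scores on the NOSACQ-50 1–4 range — are
truncated normals whose means shift with the corresponding latent state.

The generator is the ground-truth oracle for every recovery test:
cohorts are bit-reproducible given (params, seed), and the latent states
are returned alongside the records.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import study
from .preprocessing import add_composites, discretize, em_impute, fit_rules

__all__ = [
    "CohortParams",
    "GeneratedCohort",
    "generate_cohort",
    "inject_missingness",
    "analytic_accident_marginal",
    "end_to_end_recovery",
]


@dataclass(frozen=True)
class CohortParams:
    """Generating conditions of the synthetic cohort.

    Defaults reproduce the study conditions: n = 1530 male workers,
    P(JS=high) = 0.50, P(SC=high | JS) = (0.37 | high, 0.69 | low) so the
    safety-climate marginal is 0.53, and the published accident CPT.
    ``scale_effect`` is the latent-state mean shift in units of
    ``noise_sd``; 1.0 separates the score distributions by one standard
    deviation.
    """

    n: int = 1530
    seed: int = 0
    p_js_high: float = 0.50
    p_sc_high_given_js_high: float = 0.37
    p_sc_high_given_js_low: float = field(
        default_factory=lambda: round(study.solve_sc_high_given_js_low(), 12)
    )
    accident_cpt: dict = field(
        default_factory=lambda: dict(study.ACCIDENT_CPT_YES)
    )  # (SC state, JS state) -> P(accident = yes)
    scale_count: int = 16
    dim_count: int = 7
    scale_effect: float = 1.0
    noise_sd: float = 0.6
    missing_rate: float = 0.0
    stress_range: tuple[float, float] = (1.0, 5.0)  # GJSQ Likert
    climate_range: tuple[float, float] = (1.0, 4.0)  # NOSACQ-50 Likert
    # group means sit symmetrically about the scale midpoint so truncation
    # compresses both latent groups equally and the designed effect size
    # survives; the uniform-width boundary then falls near the optimum.
    stress_center: float = 3.0
    climate_center: float = 2.5

    def __post_init__(self) -> None:
        probs = [
            self.p_js_high,
            self.p_sc_high_given_js_high,
            self.p_sc_high_given_js_low,
            *self.accident_cpt.values(),
            self.missing_rate,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n < 0:
            raise ValueError("n must be nonnegative")


@dataclass
class GeneratedCohort:
    records: pd.DataFrame  # scores + accident column
    latent: pd.DataFrame  # true job-stress / safety-climate states
    params: CohortParams

    def write(self, records_path, sidecar_path=None) -> None:
        """Write the cohort file plus a ground-truth sidecar (JSON)."""
        from .preprocessing import write_cohort

        write_cohort(self.records, records_path)
        if sidecar_path is not None:
            payload = {
                "params": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(self.params).items()
                    if k != "accident_cpt"
                },
                "accident_cpt": {
                    f"{sc},{js}": p for (sc, js), p in self.params.accident_cpt.items()
                },
                "latent": self.latent.to_dict(orient="list"),
            }
            with open(sidecar_path, "w") as fh:
                json.dump(payload, fh, indent=1)


def _truncated_scores(
    rng: np.random.Generator,
    high_mask: np.ndarray,
    center: float,
    shift: float,
    sd: float,
    bounds: tuple[float, float],
) -> np.ndarray:
    means = np.where(high_mask, center + shift / 2.0, center - shift / 2.0)
    lo, hi = bounds
    a = (lo - means) / sd
    b = (hi - means) / sd
    return truncnorm.rvs(a, b, loc=means, scale=sd, random_state=rng)


def generate_cohort(params: CohortParams | None = None) -> GeneratedCohort:
    """Draw a cohort; deterministic given ``params`` (including its seed)."""
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    n = params.n
    js_high = rng.random(n) < params.p_js_high
    p_sc = np.where(
        js_high, params.p_sc_high_given_js_high, params.p_sc_high_given_js_low
    )
    sc_high = rng.random(n) < p_sc
    sc_state = np.where(sc_high, "high", "low")
    js_state = np.where(js_high, "high", "low")
    p_yes = np.array(
        [params.accident_cpt[(sc, js)] for sc, js in zip(sc_state, js_state)]
    )
    accident = np.where(rng.random(n) < p_yes, "yes", "no")

    shift = params.scale_effect * params.noise_sd
    data: dict[str, np.ndarray] = {}
    for name in study.STRESS_SCALES[: params.scale_count]:
        data[name] = _truncated_scores(
            rng, js_high, params.stress_center, shift, params.noise_sd,
            params.stress_range,
        )
    for name in study.CLIMATE_DIMENSIONS[: params.dim_count]:
        data[name] = _truncated_scores(
            rng, sc_high, params.climate_center, shift, params.noise_sd,
            params.climate_range,
        )
    data["accident"] = accident
    records = pd.DataFrame(data)
    latent = pd.DataFrame({"job_stress": js_state, "safety_climate": sc_state})
    cohort = GeneratedCohort(records, latent, params)
    if params.missing_rate > 0:
        cohort = inject_missingness(cohort, params.missing_rate, seed=params.seed + 1)
    return cohort


def inject_missingness(
    cohort: GeneratedCohort,
    rate: float,
    mechanism: str = "mcar",
    seed: int = 0,
    mar_shift: float = 0.05,
) -> GeneratedCohort:
    """Delete score cells at random; the accident outcome is never deleted.

    MCAR deletes each cell independently with probability ``rate``; MAR
    makes the deletion probability depend on the (observed) accident
    state: ``rate + mar_shift`` for accident = yes, ``rate - mar_shift``
    otherwise.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    records = cohort.records.copy()
    score_cols = [c for c in records.columns if c != "accident"]
    if mechanism == "mcar":
        cell_rate = np.full(len(records), rate)
    elif mechanism == "mar":
        yes = records["accident"].to_numpy(dtype=object) == "yes"
        cell_rate = np.where(yes, rate + mar_shift, rate - mar_shift)
        if np.any(cell_rate < 0) or np.any(cell_rate >= 1):
            raise ValueError("MAR rates leave [0, 1)")
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    for c in score_cols:
        drop = rng.random(len(records)) < cell_rate
        col = records[c].to_numpy(dtype=float)
        col[drop] = np.nan
        records[c] = col
    return GeneratedCohort(records, cohort.latent, replace(cohort.params, missing_rate=rate))


def analytic_accident_marginal(params: CohortParams | None = None) -> float:
    """Closed-form accident marginal implied by the generating parameters."""
    params = params or CohortParams()
    total = 0.0
    for js, p_js in (("high", params.p_js_high), ("low", 1 - params.p_js_high)):
        p_sc_high = (
            params.p_sc_high_given_js_high if js == "high" else params.p_sc_high_given_js_low
        )
        for sc, p_sc in (("high", p_sc_high), ("low", 1 - p_sc_high)):
            total += p_js * p_sc * params.accident_cpt[(sc, js)]
    return total


def end_to_end_recovery(
    params: CohortParams | None = None,
    learning_config=None,
    k: int = 10,
    do_cv: bool = True,
    do_sensitivity: bool = True,
    impute: bool | None = None,
) -> dict:
    """Run the whole pipeline on a generated cohort and score recovery.

    Stages: generate → (EM-impute if missing) → composites → uniform-width
    discretization → EM parameter learning on the full structure →
    posterior queries → delta-p ranking → cross-validation.  The report
    carries two accident-CPT errors: ``accident_cpt_error_latent``
    (empirical frequencies conditioned on the ground-truth latent states;
    converges to zero with n) and ``accident_cpt_error_learned`` (the
    pipeline estimate, which retains the attenuation caused by using
    discretized composite scores as proxies for the latent states).
    """
    from .learning import LearningConfig, em_learn
    from .network import posterior
    from .sensitivity import rank_factors
    from .validation import cross_validate, validation_report

    params = params or CohortParams()
    learning_config = learning_config or LearningConfig(seed=params.seed)
    cohort = generate_cohort(params)
    records = cohort.records
    score_cols = [c for c in records.columns if c != "accident"]
    if impute is None:
        impute = records[score_cols].isna().any().any()
    if impute:
        records, _ = em_impute(records, columns=score_cols)
    scales = list(study.STRESS_SCALES[: params.scale_count])
    dims = list(study.CLIMATE_DIMENSIONS[: params.dim_count])
    records = add_composites(records, scales, dims)
    rules = fit_rules(records, columns=scales + dims + ["job_stress", "safety_climate"])
    ddf = discretize(records, rules)

    structure = study.full_structure(params.scale_count, params.dim_count)
    model = em_learn(structure, ddf, learning_config)
    net = model.network

    queries = {
        "marginal_acc_yes": posterior(net, "accident")["yes"],
        "acc_yes_given_js_high": posterior(net, "accident", {"job_stress": "high"})["yes"],
        "acc_yes_given_sc_low": posterior(net, "accident", {"safety_climate": "low"})["yes"],
        "acc_yes_given_js_high_sc_low": posterior(
            net, "accident", {"job_stress": "high", "safety_climate": "low"}
        )["yes"],
        "js_high_given_acc_yes": posterior(net, "job_stress", {"accident": "yes"})["high"],
        "sc_high_given_acc_yes": posterior(net, "safety_climate", {"accident": "yes"})["high"],
    }

    # accident CPT errors against the generating values
    gen = cohort.params.accident_cpt
    learned_cpt = net.cpts["accident"]
    order = [("low", "low"), ("low", "high"), ("high", "low"), ("high", "high")]
    err_learned = max(
        abs(learned_cpt.table[i, 0] - gen[key]) for i, key in enumerate(order)
    )
    lat = cohort.latent
    acc_yes = cohort.records["accident"].to_numpy(dtype=object) == "yes"
    err_latent = 0.0
    for sc, js in order:
        mask = (lat["safety_climate"] == sc) & (lat["job_stress"] == js)
        if mask.sum() > 0:
            err_latent = max(err_latent, abs(acc_yes[mask].mean() - gen[(sc, js)]))

    report: dict = {
        "queries": queries,
        "accident_cpt_error_learned": float(err_learned),
        "accident_cpt_error_latent": float(err_latent),
        "model": model,
    }
    if do_sensitivity:
        factors = ["job_stress", "safety_climate"] + dims + scales
        ranking = rank_factors(net, "accident", "no", factors)
        report["ranking"] = ranking
        report["top_factors"] = list(ranking["factor"].head(2))
    if do_cv:
        scores, labels, folds = cross_validate(
            structure, ddf, learning_config, k=k, seed=params.seed
        )
        report["validation"] = validation_report(scores, labels, fold_assignment=folds)
    return report
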