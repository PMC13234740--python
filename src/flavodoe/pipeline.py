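"""End-to-end optimization workflow.

Stages mirror the study design for maximizing flavonoid yield:

1. Plackett-Burman screening of five process factors; factors significant
   at p < 0.05 (top three by standardized effect) advance.
2. Box-Behnken design over the three survivors; second-order fit, full
   ANOVA, and exact box-constrained optimum of the fitted surface.
3. Latin-hypercube sample of the same box; 3-4-1 neural-network surrogate
   trained on it; genetic-algorithm maximization of the surrogate.
4. Verification: replicate responses are drawn at both optima and compared
   to the predictions through the relative-error validation table.

Responses come from the synthetic ground truth unless measured data are
supplied. All stage seeds derive from one pipeline seed and are recorded
in the report for exact reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as fio
from .ann import TrainConfig, evaluate, train
from .assays import build_comparison
from .design_space import DesignSpace, default_bbd_space, default_pbd_space
from .designs import box_behnken, latin_hypercube, plackett_burman
from .fitting import anova, fit_model, pareto_effects
from .ga import GAConfig, GAResult, run_ga
from .rsm import optimize_in_box
from .simulate import GroundTruth, simulate_pbd_responses, simulate_responses

__all__ = ["PipelineConfig", "AnnGaOutcome", "ann_ga_pipeline", "run_full_pipeline"]

log = logging.getLogger(__name__)

_CANONICAL_TRIO = ("ratio", "temperature", "ethanol")


@dataclass
class PipelineConfig:
    seed: int = 0
    noise_sd: float | None = None  # None -> ground-truth default
    n_lhs: int = 51
    hidden_size: int = 4
    n_center: int = 5
    significance_alpha: float = 0.05
    n_verification_replicates: int = 3
    train: TrainConfig = field(default_factory=TrainConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    output_dir: str | None = None

    def truth(self) -> GroundTruth:
        gt = GroundTruth()
        if self.noise_sd is not None:
            gt = GroundTruth(sigma=float(self.noise_sd))
        return gt


@dataclass
class AnnGaOutcome:
    """Optimum located by the LHS -> ANN -> GA surrogate chain."""

    ga: GAResult
    coded: np.ndarray
    actual: np.ndarray
    predicted: float
    test_metrics: dict
    seeds: dict


def ann_ga_pipeline(
    space: DesignSpace,
    truth: GroundTruth | None = None,
    responses=None,
    design=None,
    n_lhs: int = 51,
    hidden: int = 4,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    ga_config: GAConfig | None = None,
) -> AnnGaOutcome:
    """Latin-hypercube sample -> surrogate training -> GA maximization.

    Either ``truth`` (responses are simulated at the sample) or an explicit
    (``design``, ``responses``) pair must be given.
    """
    seeds = {"lhs": [int(seed), 101], "noise": [int(seed), 102], "train": int(seed) % (2**31), "ga": int(seed) % (2**31)}
    if design is None:
        design = latin_hypercube(n_lhs, space.k, seed=seeds["lhs"], factor_names=space.names)
    if responses is None:
        if truth is None:
            raise ValueError("need either a ground truth or explicit responses")
        responses = simulate_responses(design, truth, seed=seeds["noise"])
    responses = np.asarray(responses, dtype=float)

    tconf = train_config or TrainConfig()
    tconf = TrainConfig(**{**asdict(tconf), "seed": seeds["train"]})
    model, history = train(design.levels, responses, hidden=hidden, config=tconf)
    from .ann import split_data  # local import to reuse the exact split

    idx_tr, idx_val, idx_te = split_data(design.n_runs, tconf.fractions, tconf.seed)
    metrics = evaluate(model, design.levels[idx_te], responses[idx_te])

    gconf = ga_config or GAConfig()
    gconf = GAConfig(**{**asdict(gconf), "n_genes": space.k, "seed": seeds["ga"]})
    result = run_ga(lambda x: model.predict(x), gconf).decode(space)

    return AnnGaOutcome(
        ga=result,
        coded=result.best_coded,
        actual=result.best_actual,
        predicted=result.best_value,
        test_metrics={
            "mse": metrics.mse,
            "mae": metrics.mae,
            "rmse": metrics.rmse,
            "r_squared": metrics.r_squared,
            "pearson_r": metrics.pearson_r,
            "stop_reason": history.stop_reason,
            "best_epoch": history.best_epoch,
        },
        seeds=seeds,
    )


def _verification_sample(truth: GroundTruth, coded_point: np.ndarray, n: int, seed) -> tuple[float, float]:
    """Replicate 'measurements' at one optimum: truth value + replicate noise."""
    mu = truth.quadratic.predict(np.asarray(coded_point, dtype=float))
    rng = np.random.default_rng(seed)
    reps = mu + rng.normal(0.0, truth.sigma, size=n)
    return float(reps.mean()), float(reps.std(ddof=1))


def run_full_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run screening -> response surface -> surrogate optimization -> validation.

    Returns a report dict with every stage's key numbers and all seeds;
    writes CSV/JSON artifacts when ``config.output_dir`` is set.
    """
    config = config or PipelineConfig()
    seed = int(config.seed)
    truth = config.truth()
    report: dict = {"seed": seed, "noise_sd": truth.sigma}
    chash = fio.config_hash(
        {
            "seed": seed,
            "noise_sd": truth.sigma,
            "n_lhs": config.n_lhs,
            "hidden": config.hidden_size,
            "n_center": config.n_center,
            "alpha": config.significance_alpha,
        }
    )
    meta = {"config_hash": chash, "seed": seed}

    # --- stage 1: Plackett-Burman screening -------------------------------
    pbd_space = default_pbd_space()
    pbd = plackett_burman(pbd_space.k, factor_names=pbd_space.names)
    y_pbd = simulate_pbd_responses(pbd, truth, seed=[seed, 11])
    m1 = fit_model(pbd, y_pbd, order=1)
    a1 = anova(m1, pbd, y_pbd)
    p1 = pareto_effects(m1, a1, alpha=config.significance_alpha)
    pvals = {
        r.Source: r.p for _, r in a1.table.iterrows() if r.Source in pbd_space.names
    }
    significant = [f for f in pbd_space.names if pvals[f] < config.significance_alpha]
    ranked = list(p1.effects.term)  # descending |t|, the tie-break order
    selected = sorted(
        sorted(significant, key=ranked.index)[:3], key=pbd_space.names.index
    )
    report["screening"] = {
        "coefficients": m1.coef,
        "p_values": {k: float(v) for k, v in pvals.items()},
        "significant": significant,
        "selected": selected,
        "t_limit": p1.t_limit,
        "bonferroni_limit": p1.bonferroni_limit,
        "stats": a1.stats,
    }
    if tuple(selected) != _CANONICAL_TRIO:
        log.warning(
            "screening selected %s; response-surface stage proceeds over %s "
            "(the factors the quadratic ground truth spans)",
            selected,
            _CANONICAL_TRIO,
        )

    # --- stage 2: Box-Behnken + RSM optimum -------------------------------
    bbd_space = default_bbd_space()
    bbd = box_behnken(3, config.n_center, factor_names=bbd_space.names)
    y_bbd = simulate_responses(bbd, truth, seed=[seed, 21])
    m2 = fit_model(bbd, y_bbd, order=2)
    a2 = anova(m2, bbd, y_bbd)
    rsm_opt = optimize_in_box(m2, space=bbd_space)
    report["response_surface"] = {
        "coefficients": m2.coef,
        "stats": a2.stats,
        "optimum_coded": rsm_opt.coded.tolist(),
        "optimum_actual": rsm_opt.actual.tolist(),
        "predicted": rsm_opt.predicted,
        "nature": rsm_opt.nature,
    }

    # --- stage 3: LHS -> ANN -> GA ---------------------------------------
    surrogate = ann_ga_pipeline(
        bbd_space,
        truth=truth,
        n_lhs=config.n_lhs,
        hidden=config.hidden_size,
        seed=seed,
        train_config=config.train,
        ga_config=config.ga,
    )
    report["ann_ga"] = {
        "optimum_coded": surrogate.coded.tolist(),
        "optimum_actual": surrogate.actual.tolist(),
        "predicted": surrogate.predicted,
        "test_metrics": surrogate.test_metrics,
        "seeds": surrogate.seeds,
    }

    # --- stage 4: verification against replicate draws --------------------
    nrep = config.n_verification_replicates
    rsm_mean, rsm_sd = _verification_sample(truth, rsm_opt.coded, nrep, [seed, 41])
    ga_mean, ga_sd = _verification_sample(truth, surrogate.coded, nrep, [seed, 42])
    comparison = build_comparison(
        [
            {
                "method": "RSM",
                "conditions": rsm_opt.actual,
                "predicted": rsm_opt.predicted,
                "actual_mean": rsm_mean,
                "actual_sd": rsm_sd,
            },
            {
                "method": "ANN-GA",
                "conditions": surrogate.actual,
                "predicted": surrogate.predicted,
                "actual_mean": ga_mean,
                "actual_sd": ga_sd,
            },
        ],
        bbd_space.names,
    )
    report["comparison"] = comparison.to_dict(orient="records")
    report["config_hash"] = chash

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        fio.write_design_csv(pbd, out / "pbd_design.csv", meta)
        fio.write_response_csv(y_pbd, out / "pbd_response.csv", meta)
        fio.write_anova_csv(a1, out / "pbd_anova.csv", meta)
        fio.write_design_csv(bbd, out / "bbd_design.csv", meta)
        fio.write_response_csv(y_bbd, out / "bbd_response.csv", meta)
        fio.write_anova_csv(a2, out / "bbd_anova.csv", meta)
        fio.write_model_json(m2, out / "bbd_model.json", meta)
        comparison.to_csv(out / "comparison.csv", index=False)
        import json

        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
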