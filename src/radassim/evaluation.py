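"""Prediction-quality metrics and model selection.

Agreement between a predicted and a measured confluence time course is scored
with Lin's concordance correlation coefficient (CCC), which penalises both
imprecision and systematic bias — unlike Pearson's r, and unlike MSE it is
comparable across cell lines with different carrying capacities.  Five model
variants (global prediction, plus assimilation with {plain, time-weighted}
cost x {linear, quadratic} weights) are compared by mean per-sample CCC with a
one-way ANOVA across variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .core import GlobalParams, GrowthParams, TimeCourse, ValidationError
from .assimilation import AssimilationConfig, assimilate, predict_global
from .dynamics import DEFAULT_DSB, DSBRepairSpec

__all__ = [
    "ccc",
    "pcc",
    "one_way_anova",
    "ModelComparison",
    "MODEL_SPECS",
    "compare_models",
    "pairwise_anova",
]

#: model id -> (cost flavor, weight schedule); model 1 is the global prediction
MODEL_SPECS: Dict[str, Tuple[Optional[str], str]] = {
    "model1": (None, "global"),
    "model2": ("basic", "linear"),
    "model3": ("revised", "linear"),
    "model4": ("basic", "quadratic"),
    "model5": ("revised", "quadratic"),
}


def _check_pair(x, y) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValidationError("at least two points are required")
    return x, y


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population 1/n moments).

    ccc = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2); equals 1 only
    for exact agreement, and degrades with either decorrelation or bias.
    """
    x, y = _check_pair(x, y)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()           # population (1/n) variances
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return 1.0  # both series constant and equal
    return float(2.0 * cov / denom)


def pcc(x, y) -> float:
    """Pearson correlation; a constant input yields 0 with a warning."""
    x, y = _check_pair(x, y)
    vx, vy = x.var(), y.var()
    if vx == 0.0 or vy == 0.0:
        warnings.warn("constant series: Pearson correlation undefined, returning 0",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def one_way_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Classical one-way ANOVA (F statistic, p-value) across value groups."""
    if len(groups) < 2:
        raise ValidationError("ANOVA requires at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValidationError("every ANOVA group needs at least two values")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df_b = len(arrays) - 1
    df_w = all_vals.size - len(arrays)
    if ssb == 0.0:
        return 0.0, 1.0
    if ssw == 0.0:
        return float("inf"), 0.0
    f_stat = (ssb / df_b) / (ssw / df_w)
    return float(f_stat), float(f_dist.sf(f_stat, df_b, df_w))


@dataclass
class ModelComparison:
    """Per-sample CCCs and summary statistics for each compared model."""

    per_sample_ccc: Dict[str, List[float]]
    mean: Dict[str, float]
    std: Dict[str, float]
    best_model: str
    anova_f: Optional[float]
    anova_p: Optional[float]

    def table(self) -> pd.DataFrame:
        """Summary table mirroring the model-selection layout."""
        rows = []
        for mid in self.per_sample_ccc:
            cost, weight = MODEL_SPECS[mid]
            rows.append(
                {
                    "model": mid,
                    "cost_function": "none" if cost is None else cost,
                    "weight_schedule": weight,
                    "mean_ccc": self.mean[mid],
                    "std_ccc": self.std[mid],
                }
            )
        return pd.DataFrame(rows)


def _model_cfg(cfg_base: AssimilationConfig, model_id: str, seed: int) -> AssimilationConfig:
    cost, weight = MODEL_SPECS[model_id]
    if cost is None:
        return replace(cfg_base, force_global=True, rng_seed=seed)
    return replace(cfg_base, cost_flavor=cost, weight_schedule=weight,
                   force_global=False, rng_seed=seed)


def _sample_seed(base: int, model_idx: int, sample_idx: int) -> int:
    ss = np.random.SeedSequence([int(base), int(model_idx), int(sample_idx)])
    return int(ss.generate_state(1)[0] % (2**31))


def compare_models(
    test_set: Sequence[TimeCourse],
    pop: GlobalParams,
    g: GrowthParams,
    cfg_base: AssimilationConfig,
    spec: DSBRepairSpec = DEFAULT_DSB,
    models: Optional[Sequence[str]] = None,
) -> ModelComparison:
    """Run every model variant on every test sample and rank them by mean CCC.

    Model 1 is the deterministic global prediction; models 2–5 run the full
    assimilation loop with their cost/weight combination.  The CCC between
    prediction and measurement is computed over the sample's whole course.
    Per-(model, sample) seeds are derived from ``cfg_base.rng_seed``.
    """
    if len(test_set) == 0:
        raise ValidationError("compare_models requires a non-empty test set")
    models = list(MODEL_SPECS) if models is None else list(models)
    per_sample: Dict[str, List[float]] = {m: [] for m in models}
    for mi, mid in enumerate(models):
        for si, tc in enumerate(test_set):
            seed = _sample_seed(cfg_base.rng_seed, mi, si)
            cfg = _model_cfg(cfg_base, mid, seed)
            if MODEL_SPECS[mid][0] is None:
                pred = predict_global(
                    sample_init=tc.confluence[0], schedule=tc.schedule, pop=pop,
                    g=g, cfg=cfg, spec=spec, n0=tc.n0, output_times=tc.times,
                )
                predicted = pred.confluence
            else:
                pred = assimilate(tc, pop, g, cfg, spec)
                if pred.times.size != tc.times.size:
                    raise ValidationError("assimilated prediction does not cover the sample grid")
                predicted = pred.median
            per_sample[mid].append(ccc(tc.confluence, predicted))
    mean = {m: float(np.mean(v)) for m, v in per_sample.items()}
    std = {m: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for m, v in per_sample.items()}
    best = max(mean, key=mean.get)
    if len(models) >= 2 and all(len(v) >= 2 for v in per_sample.values()):
        f_stat, p = one_way_anova([per_sample[m] for m in models])
    else:
        f_stat, p = None, None
    return ModelComparison(
        per_sample_ccc=per_sample, mean=mean, std=std,
        best_model=best, anova_f=f_stat, anova_p=p,
    )


def pairwise_anova(comparison: ModelComparison, model_a: str, model_b: str) -> Tuple[float, float]:
    """Two-group ANOVA between two models' per-sample CCCs."""
    return one_way_anova(
        [comparison.per_sample_ccc[model_a], comparison.per_sample_ccc[model_b]]
    )
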