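"""Factorial evaluation of scanning factors: 2x2x2x2 grid, ANOVA and OLS.

The experiment crosses four binary factors - image Region (full / cropped),
probe Angle (horizontal / vertical), Augmentation group (morphological /
comprehensive) and Model capacity (medium / small) - and treats every
configuration-run metric as one observation.  A general linear model

    y = mu + R + A + B + M + eps                 (main effects)
    y = mu + R + A + B + M + all pairwise terms  (two-way interactions)

is fit by ordinary least squares under treatment coding with the first
level of each factor (full, horizontal, morphological, medium) as the
reference, so coefficient signs read as the effect of switching a factor
to its level-1 setting.  F-tests use marginal (Type II) sums of squares,
which coincide with the sequential decomposition on the balanced grid.
First-order residual autocorrelation (Durbin-Watson) and the design
condition number are reported as diagnostics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from . import evaluation
from .synthetic import Dataset

#: factor names in model order, with (level 0, level 1) per factor
FACTOR_LEVELS: dict[str, tuple[str, str]] = {
    "region": ("full", "cropped"),
    "angle": ("horizontal", "vertical"),
    "augmentation": ("morphological", "comprehensive"),
    "model": ("medium", "small"),
}
FACTORS = tuple(FACTOR_LEVELS)
METRICS = ("precision", "recall", "f1")


class EstimabilityError(ValueError):
    """Raised when the factorial design is rank deficient."""


@dataclass(frozen=True)
class ScanConfig:
    """One cell of the 2x2x2x2 factor grid."""

    region: str = "full"
    angle: str = "horizontal"
    augmentation: str = "morphological"
    model: str = "medium"

    def __post_init__(self):
        for name, (lv0, lv1) in FACTOR_LEVELS.items():
            if getattr(self, name) not in (lv0, lv1):
                raise ValueError(f"{name} must be {lv0!r} or {lv1!r}")

    def codes(self) -> tuple[int, int, int, int]:
        """0/1 level codes in factor order (level 0 is the reference)."""
        return tuple(FACTOR_LEVELS[f].index(getattr(self, f)) for f in FACTORS)


def all_configs() -> list[ScanConfig]:
    """The 16 distinct configurations, in lexicographic level order."""
    return [ScanConfig(*levels) for levels in
            itertools.product(*FACTOR_LEVELS.values())]


@dataclass
class LinearModelReport:
    """ANOVA table, OLS coefficient table and regression diagnostics."""

    metric: str
    anova: pd.DataFrame        # factor, sum_sq, df, F, p
    coefficients: pd.DataFrame  # term, estimate, t, p, ci_low, ci_high
    intercept: float
    residual_ss: float
    residual_df: float
    durbin_watson: float
    condition_number: float       # unit-column-scaled singular-value ratio
    fit_condition_number: float   # statsmodels' reported condition number
    n_observations: int


# ---------------------------------------------------------------------------
# grid execution
# ---------------------------------------------------------------------------

def run_grid(dataset: Dataset, n_runs: int, base_seed: int = 0, *,
             configs: Sequence[ScanConfig] | None = None,
             existing: pd.DataFrame | None = None,
             pooling: str = "pooled") -> pd.DataFrame:
    """Evaluate every configuration ``n_runs`` times.

    Each (config, run) cell gets an independently derived seed, so splits,
    augmentation draws and training are re-randomized per run while the
    whole table is deterministic given ``base_seed``.  Rows already present
    in ``existing`` (same config levels and run index) are carried over
    rather than recomputed, which makes interrupted grids resumable.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    configs = list(configs) if configs is not None else all_configs()
    done = set()
    rows = []
    if existing is not None and len(existing):
        for r in existing.itertuples(index=False):
            done.add((r.region, r.angle, r.augmentation, r.model, r.run))
            rows.append(r._asdict())
    cache: dict = {}
    for run in range(n_runs):
        for cfg in configs:
            key = (cfg.region, cfg.angle, cfg.augmentation, cfg.model, run)
            if key in done:
                continue
            # the seed is keyed by the run and the data-affecting factors,
            # so the two capacity tiers of a cell pair share splits and
            # augmented data (see evaluate_config)
            data_codes = cfg.codes()[:3]
            seed = int(np.random.SeedSequence(
                [int(base_seed) & 0x7FFFFFFF, run, *data_codes])
                .generate_state(1)[0] & 0x7FFFFFFF)
            res = evaluation.evaluate_config(dataset, cfg, seed, run=run,
                                             pooling=pooling, cache=cache)
            rows.append(res.__dict__)
    frame = pd.DataFrame(rows)
    return frame.sort_values(["run", "region", "angle", "augmentation", "model"],
                             ignore_index=True)


# ---------------------------------------------------------------------------
# synthetic factor responses (oracle inputs for the model-fitting machinery)
# ---------------------------------------------------------------------------

def simulate_factor_responses(
    effects: Mapping[str, float], n_runs: int, *, base: float = 0.8,
    noise_sd: float = 0.02, interactions: Mapping[tuple[str, str], float] | None = None,
    metric: str = "recall", seed: int = 0) -> pd.DataFrame:
    """Generate a synthetic result table with known planted effects.

    ``effects[factor]`` is the additive change when the factor sits at its
    level-1 setting; ``interactions[(f, g)]`` adds when both f and g are at
    level 1.  Responses are clipped to [0, 1].  Used to validate the model
    fits against a known truth.
    """
    rng = np.random.default_rng(seed)
    interactions = dict(interactions or {})
    rows = []
    for run in range(n_runs):
        for cfg in all_configs():
            codes = dict(zip(FACTORS, cfg.codes()))
            y = base + sum(effects.get(f, 0.0) * codes[f] for f in FACTORS)
            for (f, g), e in interactions.items():
                y += e * codes[f] * codes[g]
            y += rng.normal(0.0, noise_sd)
            row = {f: getattr(cfg, f) for f in FACTORS}
            row.update(run=run, seed=seed, precision=np.nan, recall=np.nan,
                       f1=np.nan)
            row[metric] = float(np.clip(y, 0.0, 1.0))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _design_frame(results: pd.DataFrame, metric: str) -> pd.DataFrame:
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    missing = [c for c in FACTORS + (metric,) if c not in results.columns]
    if missing:
        raise ValueError(f"results table is missing columns: {missing}")
    frame = pd.DataFrame({"y": results[metric].astype(float).to_numpy()})
    for f in FACTORS:
        lv0, lv1 = FACTOR_LEVELS[f]
        values = results[f].astype(str)
        bad = set(values) - {lv0, lv1}
        if bad:
            raise ValueError(f"unknown {f} levels {sorted(bad)}")
        frame[f] = (values == lv1).astype(float).to_numpy()
    return frame.dropna(subset=["y"]).reset_index(drop=True)


def _missing_cells(frame: pd.DataFrame) -> list[tuple[str, ...]]:
    present = set(map(tuple, frame[list(FACTORS)].astype(int).to_numpy()))
    out = []
    for codes in itertools.product((0, 1), repeat=len(FACTORS)):
        if codes not in present:
            out.append(tuple(FACTOR_LEVELS[f][c] for f, c in zip(FACTORS, codes)))
    return out


_PRETTY = {"region": "Region (Cropped)", "angle": "Angle (Vertical)",
           "augmentation": "Augmentation (Comprehensive)",
           "model": "Model (Small)"}


def _fit(results: pd.DataFrame, metric: str, terms: list[str]) -> LinearModelReport:
    frame = _design_frame(results, metric)
    formula = "y ~ " + " + ".join(terms)
    model = smf.ols(formula, data=frame)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise EstimabilityError(
            "factorial design is rank deficient; missing cells: "
            f"{_missing_cells(frame)}")
    res = model.fit()
    if res.df_resid <= 0:
        raise EstimabilityError("no residual degrees of freedom; "
                                "need at least 2 observations per cell")

    degenerate = bool(np.allclose(frame["y"], frame["y"].iloc[0]))
    table = anova_lm(res, typ=2)
    rows = []
    for term in terms:
        name = ":".join(_PRETTY.get(t, t) for t in term.split(":"))
        ss = float(table.loc[term, "sum_sq"])
        fstat = float(table.loc[term, "F"])
        pval = float(table.loc[term, "PR(>F)"])
        if degenerate or (not np.isfinite(fstat) and ss <= 1e-12):
            fstat, pval = 0.0, 1.0  # all-equal responses: nothing to explain
        rows.append((name, ss, float(table.loc[term, "df"]), fstat, pval))
    anova = pd.DataFrame(rows, columns=["factor", "sum_sq", "df", "F", "p"])

    ci = res.conf_int(alpha=0.05)
    crows = []
    for term in terms:
        name = ":".join(_PRETTY.get(t, t) for t in term.split(":"))
        est = float(res.params[term])
        tval = float(res.tvalues[term])
        pval = float(res.pvalues[term])
        if degenerate:
            est, tval, pval = 0.0, 0.0, 1.0
        crows.append((name, est, tval, pval,
                      float(ci.loc[term, 0]), float(ci.loc[term, 1])))
    coefficients = pd.DataFrame(
        crows, columns=["term", "estimate", "t", "p", "ci_low", "ci_high"])

    resid = np.asarray(res.resid)
    dw = float("nan") if np.allclose(resid, 0.0) else durbin_watson(resid)
    return LinearModelReport(
        metric=metric, anova=anova, coefficients=coefficients,
        intercept=float(res.params["Intercept"]),
        residual_ss=float(res.ssr), residual_df=float(res.df_resid),
        durbin_watson=dw,
        condition_number=condition_number(model.exog),
        fit_condition_number=float(res.condition_number),
        n_observations=int(res.nobs))


def fit_main_effects(results: pd.DataFrame, metric: str) -> LinearModelReport:
    """Fit the main-effects model and its per-factor F-tests."""
    return _fit(results, metric, list(FACTORS))


def fit_two_way(results: pd.DataFrame, metric: str) -> LinearModelReport:
    """Fit the model with all six first-order interaction terms."""
    terms = list(FACTORS) + [f"{a}:{b}" for a, b in
                             itertools.combinations(FACTORS, 2)]
    return _fit(results, metric, terms)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def durbin_watson(residuals: Sequence[float]) -> float:
    """First-order autocorrelation statistic, in [0, 4].

    Sum of squared successive residual differences over the residual sum
    of squares; independent residuals give values near 2.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 2:
        raise ValueError("Durbin-Watson requires at least two residuals")
    ssr = float(np.sum(r * r))
    if ssr == 0.0:
        raise ValueError("Durbin-Watson is undefined for all-zero residuals")
    return float(np.sum(np.diff(r) ** 2) / ssr)


def condition_number(design: np.ndarray, scale: bool = True) -> float:
    """Ratio of the largest to smallest singular value of the design.

    With ``scale=True`` columns are first normalized to unit Euclidean
    length, so orthogonal balanced contrasts (e.g. an intercept plus
    +-1-coded factors of a balanced grid) give exactly 1.0.
    """
    x = np.asarray(design, dtype=float)
    if x.ndim != 2 or x.shape[0] < x.shape[1]:
        raise ValueError("design must be a tall 2-D matrix")
    if scale:
        norms = np.linalg.norm(x, axis=0)
        if np.any(norms == 0):
            raise ValueError("design contains an all-zero column")
        x = x / norms
    s = np.linalg.svd(x, compute_uv=False)
    if s[-1] <= s[0] * 1e-12:
        raise ValueError("design matrix is rank deficient")
    return float(s[0] / s[-1])
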