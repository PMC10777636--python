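"""Averaged ecosystem-multifunctionality (EMF) index.

Each soil function variable is screened for normality (Shapiro-Wilk),
transformed (log, then square root) when needed, min-max standardized to
[0, 1], and the EMF of a sample is the mean of its standardized function
values. Constant functions cannot be min-max scaled and are excluded with
a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rank_tests import GroupComparison, compare_groups
from .tables import FunctionTable, SampleMetadata

logger = logging.getLogger(__name__)


class DegenerateFunctionError(ValueError):
    pass


@dataclass
class TransformChoice:
    transform: str          # "none" | "log" | "sqrt"
    shapiro_p_raw: float
    shapiro_p_final: float
    note: str = ""


@dataclass
class EmfResult:
    sample_ids: list[str]
    emf: np.ndarray                       # per-sample index in [0, 1]
    standardized: pd.DataFrame            # samples x retained functions
    transform_log: dict[str, TransformChoice]
    excluded_functions: list[str]

    def to_frame(self) -> pd.DataFrame:
        out = self.standardized.copy()
        out["EMF"] = self.emf
        return out


def minmax_standardize(v) -> np.ndarray:
    """Scale a vector to [0, 1] by (v - min) / (max - min)."""
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateFunctionError("constant vector cannot be min-max scaled")
    return (v - lo) / (hi - lo)


def _shapiro_p(v: np.ndarray) -> float:
    if np.unique(v).size < 3:
        return 0.0
    return float(stats.shapiro(v).pvalue)


def transform_for_normality(fx: FunctionTable, alpha: float = 0.05
                            ) -> tuple[FunctionTable, dict[str, TransformChoice]]:
    """Per function: keep raw if Shapiro-Wilk p >= alpha, else try log then
    sqrt, keeping the first transform that restores normality; if none does,
    keep the admissible transform with the largest p."""
    out = fx.values.copy()
    log: dict[str, TransformChoice] = {}
    for j, name in enumerate(fx.function_names):
        v = fx.values[:, j]
        if np.unique(v).size < 2:
            log[name] = TransformChoice("none", float("nan"), float("nan"),
                                        "degenerate (constant)")
            continue
        p_raw = _shapiro_p(v)
        candidates: list[tuple[str, np.ndarray, float]] = [("none", v, p_raw)]
        if p_raw >= alpha:
            chosen = candidates[0]
        else:
            if np.all(v > 0):
                lv = np.log(v)
                candidates.append(("log", lv, _shapiro_p(lv)))
            if np.all(v >= 0):
                sv = np.sqrt(v)
                candidates.append(("sqrt", sv, _shapiro_p(sv)))
            chosen = None
            for cand in candidates[1:]:
                if cand[2] >= alpha:
                    chosen = cand
                    break
            if chosen is None:
                chosen = max(candidates, key=lambda c: c[2])
                if len(candidates) == 1:
                    logger.warning(
                        "function %r: non-positive values admit no transform; "
                        "keeping raw (Shapiro p=%.3g)", name, p_raw)
        out[:, j] = chosen[1]
        log[name] = TransformChoice(chosen[0], p_raw, chosen[2])
    return FunctionTable(list(fx.sample_ids), list(fx.function_names), out), log


def emf_index(fx: FunctionTable, alpha: float = 0.05,
              transform: bool = True) -> EmfResult:
    """Compute the per-sample averaged multifunctionality index.

    ``transform=False`` skips the normality screening and standardizes the
    raw variables directly (useful when invariance to affine rescaling of
    the raw data is required).
    """
    if fx.n_samples < 2:
        raise ValueError("need at least two samples")
    if transform:
        fx_t, tlog = transform_for_normality(fx, alpha=alpha)
    else:
        fx_t = fx
        tlog = {name: TransformChoice("none", float("nan"), float("nan"),
                                      "transform disabled")
                for name in fx.function_names}

    cols = {}
    excluded = []
    for j, name in enumerate(fx_t.function_names):
        v = fx_t.values[:, j]
        if np.unique(v).size < 2:
            excluded.append(name)
            logger.warning("function %r is constant; excluded from EMF", name)
            continue
        cols[name] = minmax_standardize(v)
    if not cols:
        raise DegenerateFunctionError("all functions are degenerate")
    std = pd.DataFrame(cols, index=fx_t.sample_ids)
    emf = std.to_numpy().mean(axis=1)
    return EmfResult(list(fx_t.sample_ids), emf, std, tlog, excluded)


def compare_emf_groups(result: EmfResult, meta: SampleMetadata) -> GroupComparison:
    """Kruskal-Wallis across zones plus pairwise exact Wilcoxon tests on EMF."""
    emf_by_sample = dict(zip(result.sample_ids, result.emf))
    groups = meta.groups(result.sample_ids)
    values = {z: np.array([emf_by_sample[s] for s in ss])
              for z, ss in groups.items()}
    return compare_groups(values)
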