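"""Reduced model variants of macrophage activation and AIC ranking.

Variants are named by their active mechanisms — D (DAMP release), A
(antigen binding), C (CD40 contact): the full DAC model and the reduced DC,
AC, DA, D and A models, obtained by structurally fixing the corresponding
activation coefficients to zero and removing them from the free-parameter
list.  Variant C alone is invalid: CD40 engagement requires previously
activated macrophages, so with beta_K = beta_B = 0 and M_a(0) = 0 no
activation ever occurs.  Variants are ranked per patient by

    AIC = 2k + n_d * (1 + LR - ln n_d + ln 2*pi),

with k in {6, 7, 8} free parameters and n_d IL-6 data points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_cli import PatientTimecourse
from .parameter_estimation import (
    LAYER2_FREE,
    FitConfig,
    FitResult,
    fit_cytokine_layer,
)

__all__ = ["ModelVariant", "build_variant", "aic", "rank_variants",
           "STANDARD_VARIANTS", "InvalidVariantError"]

_MECH_BETA = {"D": "beta_K", "A": "beta_B", "C": "beta_C"}


class InvalidVariantError(ValueError):
    """The mechanism subset cannot produce macrophage activation."""


@dataclass(frozen=True)
class ModelVariant:
    """A subset of activation mechanisms with its free-parameter count."""

    mechanisms: frozenset
    label: str
    k: int
    free_names: tuple

    def __str__(self) -> str:
        return self.label


def build_variant(mechanisms) -> ModelVariant:
    """Construct a variant from a mechanism subset (iterable of 'D','A','C').

    The excluded activation coefficients are structurally zero and excluded
    from the free parameters, so k = 8 - (number removed).
    """
    mechs = frozenset(str(m).upper() for m in mechanisms)
    if not mechs or not mechs <= {"D", "A", "C"}:
        raise InvalidVariantError(f"mechanisms must be a non-empty subset of D/A/C, got {set(mechanisms)}")
    if mechs == {"C"}:
        raise InvalidVariantError(
            "variant C alone produces no macrophage activation: CD40 contact "
            "requires previously activated macrophages")
    removed = {_MECH_BETA[m] for m in {"D", "A", "C"} - mechs}
    free = tuple(n for n in LAYER2_FREE if n not in removed)
    label = "".join(m for m in "DAC" if m in mechs)
    return ModelVariant(mechanisms=mechs, label=label, k=len(free), free_names=free)


STANDARD_VARIANTS = ("DAC", "DC", "AC", "DA", "D", "A")


def aic(LR: float, k: int, n_d: int) -> float:
    """Akaike information criterion from the log weighted residual sum LR."""
    if n_d < 1:
        raise ValueError("n_d must be >= 1")
    return 2.0 * k + n_d * (1.0 + LR - np.log(n_d) + np.log(2.0 * np.pi))


def rank_variants(tc: PatientTimecourse, layer1: FitResult,
                  variants=STANDARD_VARIANTS,
                  cfg: FitConfig | None = None):
    """Fit every variant with the same protocol and rank by AIC.

    Each variant receives the same Monte-Carlo + refinement budget and the
    same seed stream so LR values are comparable.  Ranking is ascending in
    AIC, ties broken by fewer free parameters; variants that fail to fit are
    ranked last and flagged.  Returns (table, fits-by-label).
    """
    cfg = cfg or FitConfig()
    vars_ = [build_variant(v) if not isinstance(v, ModelVariant) else v
             for v in variants]
    # fit in ascending complexity and warm-start every variant with the
    # optima of its strict sub-variants: a nested variant's optimum embeds
    # (with the removed coefficients at zero) into the larger model, which
    # guarantees LR(larger) <= LR(nested) even at finite search budgets
    fits = {}
    for var in sorted(vars_, key=lambda v: v.k):
        warm = [fits[w.label].params for w in vars_
                if w.label in fits and fits[w.label] is not None
                and w.mechanisms < var.mechanisms]
        try:
            fits[var.label] = fit_cytokine_layer(
                tc, layer1, cfg, free_names=var.free_names, extra_starts=warm)
        except Exception:              # a variant failing to fit ranks last
            fits[var.label] = None

    # downward polish: every reduced variant also refines from its
    # super-variants' optima projected onto its own parameter space, so a
    # difference in LR reflects model capacity rather than search luck
    polish_cfg = replace(cfg, n_mc=1, n_refine=1)

    def polish(var, related):
        warm = [fits[w.label].params for w in related
                if fits.get(w.label) is not None]
        warm.append(fits[var.label].params)
        try:
            polished = fit_cytokine_layer(
                tc, layer1, polish_cfg, free_names=var.free_names,
                extra_starts=warm)
            if polished.objective < fits[var.label].objective:
                fits[var.label] = polished
        except Exception:
            pass

    for var in sorted(vars_, key=lambda v: v.k, reverse=True):
        if fits.get(var.label) is not None:
            polish(var, [w for w in vars_ if var.mechanisms < w.mechanisms])
    # final ascending pass restores the nesting guarantee after the polish
    for var in sorted(vars_, key=lambda v: v.k):
        if fits.get(var.label) is not None:
            polish(var, [w for w in vars_ if w.mechanisms < var.mechanisms])

    rows = []
    for var in vars_:
        fit = fits.get(var.label)
        if fit is None:
            rows.append({"variant": var.label, "k": var.k,
                         "LR": np.inf, "AIC": np.inf, "failed": True})
        else:
            rows.append({"variant": var.label, "k": var.k,
                         "LR": fit.objective, "AIC": fit.aic,
                         "failed": False})
    table = pd.DataFrame(rows)
    table = table.sort_values(["failed", "AIC", "k"], kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True), fits


def cohort_variant_summary(tables: dict) -> pd.DataFrame:
    """Cohort sums of LR and AIC per variant over per-patient ranking tables."""
    parts = []
    for pid, tab in tables.items():
        t = tab.copy()
        t["patient"] = pid
        parts.append(t)
    allt = pd.concat(parts, ignore_index=True)
    summary = allt.groupby("variant").agg(
        LR_sum=("LR", "sum"), AIC_sum=("AIC", "sum"),
        best_count=("rank", lambda r: int((r == 1).sum())))
    return summary.sort_values("AIC_sum")
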